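"""Sequence and enzyme-table I/O plus IUPAC-aware base operations.

Every other module builds on the primitives here: validated DNA records,
reverse complementation over the full IUPAC alphabet, degenerate pattern
matching, and restriction-enzyme definitions (recognition site + top-strand
cut offset).

Coordinates are 0-based, half-open everywhere inside the library; user-facing
reports (CLI output) convert to 1-based, closed intervals and say so in their
headers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "IUPAC_SETS",
    "IUPAC_COMPLEMENT",
    "SOURCES",
    "SequenceRecord",
    "RestrictionEnzyme",
    "validate_dna",
    "reverse_complement",
    "iupac_match",
    "read_fasta",
    "write_fasta",
    "read_genbank",
    "read_enzyme_table",
    "load_default_enzymes",
]

#: Base sets denoted by each IUPAC nucleotide code (DNA; no U).
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

#: Allowed provenance labels for a SequenceRecord.
SOURCES = ("reference_mitogenome", "amplicon", "honey_isolate", "synthetic")

_SPECIES_RE = re.compile(r"\[species=([^\]]+)\]")


def validate_dna(seq: str, label: str = "sequence") -> str:
    """Uppercase ``seq`` and verify it uses only IUPAC DNA codes.

    RNA (U) is rejected explicitly; this library is DNA-only. Returns the
    uppercased sequence; raises ``ValueError`` naming the first offending
    character and the record it came from.
    """
    if not seq:
        raise ValueError(f"{label}: empty sequence")
    up = seq.upper()
    for ch in up:
        if ch not in IUPAC_SETS:
            if ch == "U":
                raise ValueError(
                    f"{label}: found 'U' — RNA is not supported, DNA only"
                )
            raise ValueError(
                f"{label}: invalid nucleotide character {ch!r}"
            )
    return up


@dataclass
class SequenceRecord:
    """An identified nucleotide sequence with species/source metadata."""

    id: str
    seq: str
    species: str = ""
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be nonempty")
        if self.source not in SOURCES:
            raise ValueError(
                f"unknown source {self.source!r}; expected one of {SOURCES}"
            )
        self.seq = validate_dna(self.seq, label=f"record {self.id!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A named recognition pattern with its top-strand cut offset.

    ``site`` is the recognition sequence written 5'->3' on the top strand
    (IUPAC codes allowed); ``cut_offset`` is where the top strand is cleaved,
    counted from the 5' end of the matched site.  AseI recognizes AT^TAAT,
    i.e. site ``ATTAAT`` with ``cut_offset=2``.
    """

    name: str
    site: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("enzyme name must be nonempty")
        object.__setattr__(
            self, "site", validate_dna(self.site, label=f"enzyme {self.name}")
        )
        if len(self.site) < 4:
            raise ValueError(
                f"enzyme {self.name}: recognition site shorter than 4 bp"
            )
        if not 0 <= self.cut_offset <= len(self.site):
            raise ValueError(
                f"enzyme {self.name}: cut_offset {self.cut_offset} outside "
                f"[0, {len(self.site)}]"
            )

    @property
    def is_palindromic(self) -> bool:
        """True when the site equals its own reverse complement."""
        return self.site == reverse_complement(self.site)


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement. Involution: rc(rc(s)) == s."""
    up = seq.upper()
    try:
        return "".join(IUPAC_COMPLEMENT[ch] for ch in reversed(up))
    except KeyError as exc:
        raise ValueError(f"invalid nucleotide character {exc.args[0]!r}") from None


def iupac_match(pattern: str, window: str) -> tuple[bool, int]:
    """Compare equal-length IUPAC strings position-wise.

    Position i matches iff the base sets denoted by ``pattern[i]`` and
    ``window[i]`` intersect (so N matches everything). Returns
    ``(full_match, mismatch_count)``.
    """
    if len(pattern) != len(window):
        raise ValueError(
            f"length mismatch: pattern {len(pattern)} vs window {len(window)}"
        )
    mismatches = 0
    for p, w in zip(pattern.upper(), window.upper()):
        try:
            if not (IUPAC_SETS[p] & IUPAC_SETS[w]):
                mismatches += 1
        except KeyError as exc:
            raise ValueError(
                f"invalid nucleotide character {exc.args[0]!r}"
            ) from None
    return mismatches == 0, mismatches


def _species_from_description(description: str) -> str:
    m = _SPECIES_RE.search(description)
    return m.group(1).strip() if m else ""


def read_fasta(path: str | Path, source: str = "synthetic") -> list[SequenceRecord]:
    """Read a multi-record FASTA file into SequenceRecords.

    The header is parsed as ``id [species=...]`` when the bracketed key is
    present. Sequences are uppercased and validated; an empty file or a
    non-IUPAC character is an error naming the offending record.
    """
    path = Path(path)
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(
                id=rec.id,
                seq=str(rec.seq),
                species=_species_from_description(rec.description),
                source=source,
            )
        )
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA, encoding species as ``[species=...]``."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = rec.id
            if rec.species:
                header += f" [species={rec.species}]"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), 70):
                fh.write(rec.seq[i : i + 70] + "\n")


def read_genbank(path: str | Path, source: str = "reference_mitogenome") -> list[SequenceRecord]:
    """Read GenBank flat files, keeping only the origin sequence.

    Features are ignored; the organism annotation, when present, becomes the
    species label. Read-only: there is no GenBank writer.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "genbank"):
        records.append(
            SequenceRecord(
                id=rec.id,
                seq=str(rec.seq),
                species=rec.annotations.get("organism", ""),
                source=source,
            )
        )
    if not records:
        raise ValueError(f"{path}: no GenBank records found")
    return records


def read_enzyme_table(path: str | Path) -> list[RestrictionEnzyme]:
    """Read a TSV enzyme table (columns: name, site, cut_offset).

    Lines starting with ``#`` are comments. Duplicate names and cut offsets
    outside [0, site length] are errors.
    """
    path = Path(path)
    enzymes: list[RestrictionEnzyme] = []
    names: set[str] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}"
                )
            name, site, offset_text = (p.strip() for p in parts)
            try:
                cut_offset = int(offset_text)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: cut_offset {offset_text!r} is not an integer"
                ) from None
            if name in names:
                raise ValueError(f"{path}:{lineno}: duplicate enzyme name {name!r}")
            names.add(name)
            enzymes.append(RestrictionEnzyme(name=name, site=site, cut_offset=cut_offset))
    if not enzymes:
        raise ValueError(f"{path}: no enzymes found")
    return enzymes


def load_default_enzymes() -> list[RestrictionEnzyme]:
    """Load the bundled table of common commercial enzymes (includes AseI)."""
    from importlib.resources import files

    return read_enzyme_table(str(files("rflpkit.data") / "enzymes.tsv"))


def get_enzyme(name: str, enzymes: Sequence[RestrictionEnzyme] | None = None) -> RestrictionEnzyme:
    """Look up an enzyme by name in ``enzymes`` (default: bundled table)."""
    pool = list(enzymes) if enzymes is not None else load_default_enzymes()
    for enz in pool:
        if enz.name == name:
            return enz
    raise KeyError(f"unknown enzyme {name!r}")
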