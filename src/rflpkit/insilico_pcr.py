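"""In-silico PCR: primer-site search and amplicon prediction.

A primer anneals wherever its sequence matches a template window within the
configured mismatch budget, with the 3' clamp (the last ``clamp_len`` primer
bases, where the polymerase extends) required to match exactly. Products are
enumerated from every convergent site pair of the two primers, in either
orientation, and normalized to the template + strand.

Templates are treated as linear; an opt-in ``circular`` flag appends a
``max_len``-sized prefix so origin-spanning products of circular molecules
(e.g. mitogenomes) are found, with coordinates reported modulo the template
length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .sequence_io import SequenceRecord, iupac_match, reverse_complement, validate_dna

__all__ = [
    "Primer",
    "PrimerSite",
    "PcrConstraints",
    "Amplicon",
    "find_primer_sites",
    "simulate_pcr",
    "check_universality",
    "UniversalityReport",
]


@dataclass(frozen=True)
class Primer:
    """A non-degenerate oligo, written 5'->3'."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        up = validate_dna(self.seq, label=f"primer {self.name}")
        if not set(up) <= set("ACGT"):
            raise ValueError(f"primer {self.name}: degenerate bases not supported")
        if not 15 <= len(up) <= 40:
            raise ValueError(
                f"primer {self.name}: length {len(up)} outside 15..40"
            )
        object.__setattr__(self, "seq", up)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PcrConstraints:
    """Binding and product-size constraints for the in-silico reaction.

    ``clamp_len`` bases at the primer 3' end must match exactly, modeling the
    polymerase's intolerance of terminal mismatches.
    """

    max_mismatches: int = 0
    clamp_len: int = 3
    min_len: int = 50
    max_len: int = 2000

    def __post_init__(self) -> None:
        if min(self.max_mismatches, self.clamp_len, self.min_len, self.max_len) < 0:
            raise ValueError("constraints must be non-negative")
        if self.min_len >= self.max_len:
            raise ValueError("min_len must be < max_len")


@dataclass(frozen=True)
class PrimerSite:
    """An annealed primer footprint on the template + strand.

    ``start``/``end`` are 0-based half-open template coordinates; ``strand``
    is '+' when the primer sequence reads along the + strand and '-' when it
    anneals to the + strand (its reverse complement appears there).
    """

    template_id: str
    primer: str
    strand: str
    start: int
    end: int
    mismatches: int


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product, normalized to the template + strand.

    Spans from the 5' end of the left footprint to the rightmost base of the
    right footprint (half-open ``end``); ``seq`` is the verbatim template
    substring, primer footprints included.
    """

    template_id: str
    fwd_site: PrimerSite
    rev_site: PrimerSite
    start: int
    end: int
    seq: str

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def id(self) -> str:
        # 1-based closed interval, the convention of all user-facing output
        return f"{self.template_id}:{self.start + 1}-{self.end}"


def _scan(template: str, pattern: str, clamp_at_end: bool, constraints: PcrConstraints):
    """Yield (start, mismatches) of every admissible window for ``pattern``.

    ``clamp_at_end`` selects which end of the window the mismatch-free clamp
    lives on: the 3' end of a + strand primer is the window's right end; for
    a - strand primer (pattern = its reverse complement) it is the left end.
    """
    k = len(pattern)
    clamp = min(constraints.clamp_len, k)
    for i in range(len(template) - k + 1):
        window = template[i : i + k]
        _, mm = iupac_match(pattern, window)
        if mm > constraints.max_mismatches:
            continue
        clamp_region = (pattern[k - clamp :], window[k - clamp :]) if clamp_at_end else (
            pattern[:clamp],
            window[:clamp],
        )
        if clamp and not iupac_match(*clamp_region)[0]:
            continue
        yield i, mm


def find_primer_sites(
    template: SequenceRecord,
    primer: Primer,
    constraints: PcrConstraints = PcrConstraints(),
) -> list[PrimerSite]:
    """All footprints of ``primer`` on both strands of a linear template."""
    sites: list[PrimerSite] = []
    if len(primer) > len(template.seq):
        return sites
    for start, mm in _scan(template.seq, primer.seq, True, constraints):
        sites.append(
            PrimerSite(template.id, primer.name, "+", start, start + len(primer), mm)
        )
    rc = reverse_complement(primer.seq)
    for start, mm in _scan(template.seq, rc, False, constraints):
        sites.append(
            PrimerSite(template.id, primer.name, "-", start, start + len(primer), mm)
        )
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def simulate_pcr(
    template: SequenceRecord,
    fwd: Primer,
    rev: Primer,
    constraints: PcrConstraints = PcrConstraints(),
    circular: bool = False,
) -> list[Amplicon]:
    """Predict every product of the primer pair on one template.

    A product forms between a + strand site of one primer and a downstream
    - strand site of the other (both orientations of the pair are products
    of the same reaction tube). Self-priming (fwd/fwd, rev/rev) is out of
    scope. Products are sorted by length, then start.
    """
    work = template
    n = len(template.seq)
    if circular:
        ext = template.seq + template.seq[: min(constraints.max_len, n)]
        work = SequenceRecord(template.id, ext, template.species, template.source)

    fwd_sites = find_primer_sites(work, fwd, constraints)
    rev_sites = find_primer_sites(work, rev, constraints)

    products: dict[tuple[int, int], Amplicon] = {}
    for left_pool, right_pool in ((fwd_sites, rev_sites), (rev_sites, fwd_sites)):
        for a in left_pool:
            if a.strand != "+":
                continue
            for b in right_pool:
                if b.strand != "-" or b.start <= a.start:
                    continue
                length = b.end - a.start
                if not constraints.min_len <= length <= constraints.max_len:
                    continue
                start, end = a.start, b.end
                if circular:
                    if start >= n:  # duplicate of a wholly-in-first-copy product
                        continue
                    key = (start % n, length)
                else:
                    key = (start, length)
                if key in products:
                    continue
                fwd_site = a if a.primer == fwd.name else b
                rev_site = b if fwd_site is a else a
                products[key] = Amplicon(
                    template_id=template.id,
                    fwd_site=fwd_site,
                    rev_site=rev_site,
                    start=start,
                    end=end,
                    seq=work.seq[start:end],
                )
    return sorted(products.values(), key=lambda amp: (amp.length, amp.start))


@dataclass
class TemplateResult:
    template_id: str
    n_products: int
    length: int | None
    fwd_mismatches: int | None
    rev_mismatches: int | None

    @property
    def amplifies(self) -> bool:
        return self.n_products == 1


@dataclass
class UniversalityReport:
    """Per-template amplification outcome for a candidate universal pair."""

    rows: list[TemplateResult]

    @property
    def universal(self) -> bool:
        return all(r.amplifies for r in self.rows)

    @property
    def failing_templates(self) -> list[str]:
        return [r.template_id for r in self.rows if not r.amplifies]


def check_universality(
    panel: Sequence[SequenceRecord],
    fwd: Primer,
    rev: Primer,
    constraints: PcrConstraints = PcrConstraints(),
) -> UniversalityReport:
    """Test whether the primer pair yields exactly one product per template.

    Multi-product templates are flagged (reported, never suppressed); the
    overall verdict is "universal" only when every panel member amplifies
    uniquely.
    """
    if not panel:
        raise ValueError("panel must be nonempty")
    rows = []
    for template in panel:
        amps = simulate_pcr(template, fwd, rev, constraints)
        if len(amps) == 1:
            amp = amps[0]
            rows.append(
                TemplateResult(
                    template.id, 1, amp.length,
                    amp.fwd_site.mismatches, amp.rev_site.mismatches,
                )
            )
        else:
            rows.append(TemplateResult(template.id, len(amps), None, None, None))
    return UniversalityReport(rows=rows)
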