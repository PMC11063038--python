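"""Restriction-site search and digestion of linear amplicons.

Fragment lengths follow the top-strand cut coordinates; sticky-end overhangs
are ignored because gel migration reflects duplex length. Overlapping
recognition sites each produce a cut. PCR products are linear, so digestion
is always linear (fragment count = cut count + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Protocol, Sequence

from .sequence_io import (
    IUPAC_SETS,
    RestrictionEnzyme,
    iupac_match,
    reverse_complement,
)

__all__ = ["DigestResult", "find_cut_positions", "digest", "digest_panel"]


class _HasIdSeq(Protocol):
    id: str
    seq: str


@dataclass(frozen=True)
class DigestResult:
    """Cut coordinates and the fragment multiset of one (molecule, enzyme) pair."""

    amplicon_id: str
    enzyme: str
    cut_positions: tuple[int, ...]  # sorted, 0-based top-strand coordinates
    fragments: tuple[int, ...]      # descending lengths, sum = molecule length

    @property
    def n_cuts(self) -> int:
        return len(self.cut_positions)


def _site_matches(seq: str, pattern: str, strict: bool) -> Iterable[int]:
    """Start positions where ``pattern`` matches ``seq``.

    strict=True (default): template bases must be unambiguous A/C/G/T and lie
    inside the pattern's base sets — N-runs can never produce phantom cuts.
    strict=False: plain IUPAC set-intersection matching.
    """
    k = len(pattern)
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if strict:
            if all(
                w in "ACGT" and w in IUPAC_SETS[p] for p, w in zip(pattern, window)
            ):
                yield i
        elif iupac_match(pattern, window)[0]:
            yield i


def find_cut_positions(
    seq: str, enzyme: RestrictionEnzyme, strict: bool = True
) -> list[int]:
    """All top-strand cut coordinates of ``enzyme`` on a linear sequence.

    + strand matches cut at ``match_start + cut_offset``. Non-palindromic
    sites are also searched on the - strand (via the site's reverse
    complement on the + strand) and their cuts mapped back as
    ``match_end - cut_offset``. Palindromic sites need one scan only.
    Positions are deduplicated and sorted; overlapping matches all count.
    """
    seq = seq.upper()
    cuts: set[int] = set()
    for i in _site_matches(seq, enzyme.site, strict):
        cuts.add(i + enzyme.cut_offset)
    if not enzyme.is_palindromic:
        rc_site = reverse_complement(enzyme.site)
        for i in _site_matches(seq, rc_site, strict):
            cuts.add(i + len(enzyme.site) - enzyme.cut_offset)
    return sorted(cuts)


def digest(
    molecule: _HasIdSeq, enzyme: RestrictionEnzyme, strict: bool = True
) -> DigestResult:
    """Digest a linear molecule; fragments are successive cut-to-cut spans.

    Accepts anything with ``id`` and ``seq`` attributes (Amplicon,
    SequenceRecord). Cuts at coordinate 0 or at the molecule's end would
    yield zero-length fragments and are dropped.
    """
    length = len(molecule.seq)
    cuts = tuple(c for c in find_cut_positions(molecule.seq, enzyme, strict) if 0 < c < length)
    bounds = (0,) + cuts + (length,)
    fragments = tuple(
        sorted((b - a for a, b in zip(bounds, bounds[1:])), reverse=True)
    )
    return DigestResult(
        amplicon_id=molecule.id,
        enzyme=enzyme.name,
        cut_positions=cuts,
        fragments=fragments,
    )


def digest_panel(
    molecules: Sequence[_HasIdSeq],
    enzymes: Sequence[RestrictionEnzyme],
    strict: bool = True,
) -> list[DigestResult]:
    """One DigestResult per (molecule, enzyme) pair, molecule-major order."""
    if not molecules or not enzymes:
        raise ValueError("molecules and enzymes must both be nonempty")
    return [digest(mol, enz, strict) for mol in molecules for enz in enzymes]
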