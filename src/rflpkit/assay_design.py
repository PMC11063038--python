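"""Discriminating-enzyme screening for a species panel.

Given one amplicon per species, every enzyme in a library is evaluated on
whether the band patterns it produces let a gel tell all species pairs
apart — the computational core of designing a single-enzyme PCR-RFLP assay.
Panels are tiny (a handful of species), so the pair search is exhaustive.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Protocol, Sequence

from .gel_profiles import BandPattern, GelParams, patterns_distinguishable, resolvable_pattern
from .restriction_digest import digest
from .sequence_io import RestrictionEnzyme

__all__ = ["EnzymeScreenResult", "screen_enzymes", "minimal_enzyme_sets"]


class _SpeciesMolecule(Protocol):
    id: str
    seq: str
    species: str


@dataclass
class EnzymeScreenResult:
    """How well one enzyme separates the panel."""

    enzyme: str
    discriminates_all: bool
    n_distinguishable_pairs: int
    failing_pairs: list[tuple[str, str]]
    patterns: dict[str, BandPattern]

    @property
    def total_bands(self) -> int:
        return sum(p.n_bands for p in self.patterns.values())


def _distinguishable_pairs(
    patterns: dict[str, BandPattern],
) -> tuple[set[tuple[str, str]], list[tuple[str, str]]]:
    ok: set[tuple[str, str]] = set()
    failing: list[tuple[str, str]] = []
    species = list(patterns)
    for s1, s2 in combinations(species, 2):
        if patterns_distinguishable(patterns[s1], patterns[s2])[0]:
            ok.add((s1, s2))
        else:
            failing.append((s1, s2))
    return ok, failing


def screen_enzymes(
    panel: Sequence[_SpeciesMolecule],
    library: Sequence[RestrictionEnzyme],
    gel: GelParams = GelParams(),
    strict: bool = True,
) -> list[EnzymeScreenResult]:
    """Rank a library by how completely each enzyme separates the panel.

    Each panel entry needs ``id``, ``seq`` and a nonempty ``species`` label
    (duplicates are an error). For every enzyme, every amplicon is digested,
    turned into a gel pattern, and all species pairs compared. Results are
    ranked by: discriminates_all, then number of distinguishable pairs, then
    fewer total bands (simpler gels read more easily), then name — a total
    order, so repeated runs are identical.

    An uncut amplicon is a legal single-band pattern; two species then
    differ only if their amplicon lengths resolve on the gel, which for
    near-equal-length amplicons they will not. Discrimination must come
    from cut-site variation.
    """
    if len(panel) < 2:
        raise ValueError("panel must contain at least 2 species")
    if not library:
        raise ValueError("enzyme library must be nonempty")
    seen: set[str] = set()
    for mol in panel:
        if not getattr(mol, "species", ""):
            raise ValueError(f"panel member {mol.id!r} lacks a species label")
        if mol.species in seen:
            raise ValueError(f"duplicate species label {mol.species!r}")
        seen.add(mol.species)

    results = []
    for enz in library:
        patterns = {
            mol.species: resolvable_pattern(digest(mol, enz, strict).fragments, gel)
            for mol in panel
        }
        ok, failing = _distinguishable_pairs(patterns)
        results.append(
            EnzymeScreenResult(
                enzyme=enz.name,
                discriminates_all=not failing,
                n_distinguishable_pairs=len(ok),
                failing_pairs=failing,
                patterns=patterns,
            )
        )
    results.sort(
        key=lambda r: (
            not r.discriminates_all,
            -r.n_distinguishable_pairs,
            r.total_bands,
            r.enzyme,
        )
    )
    return results


def minimal_enzyme_sets(
    panel: Sequence[_SpeciesMolecule],
    library: Sequence[RestrictionEnzyme],
    gel: GelParams = GelParams(),
    max_set_size: int = 2,
    strict: bool = True,
) -> list[tuple[str, ...]]:
    """Smallest enzyme combinations that jointly separate every pair.

    A pair is covered if at least one enzyme in the set distinguishes it.
    Exhaustive search over subsets up to ``max_set_size``; only sets of the
    smallest sufficient size are returned, in deterministic name order.
    Empty result means no combination within the size limit works.
    """
    if not library:
        return []
    screened = screen_enzymes(panel, library, gel, strict)
    all_pairs = {
        pair
        for r in screened
        for pair in (set(r.failing_pairs) | _distinguishable_pairs(r.patterns)[0])
    }
    coverage = {
        r.enzyme: _distinguishable_pairs(r.patterns)[0] for r in screened
    }
    names = sorted(coverage)
    for size in range(1, max_set_size + 1):
        hits = [
            combo
            for combo in combinations(names, size)
            if set().union(*(coverage[e] for e in combo)) >= all_pairs
        ]
        if hits:
            return hits
    return []
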