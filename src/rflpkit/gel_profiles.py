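"""Virtual agarose gel: band resolvability, reference profiles, classification.

A digest's fragment multiset is not what a gel shows. Fragments below the
detection floor (smallest reliably sized band, set by the ladder — default
50 bp) disappear into an unsized "<floor" smear, and fragments closer than
the gel's resolving power co-migrate into one band. The resolving power at
length L is ``max(abs_resolution, rel_resolution * L)``: an absolute floor
of a few bp plus a relative term, the usual behavior of high-percentage
agarose.

Band patterns are compared with tolerance-aware one-to-one matching, which
drives both assay design (are two species' patterns distinguishable?) and
classification (which reference profile does an observed lane match?).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .restriction_digest import DigestResult

__all__ = [
    "GelParams",
    "BandPattern",
    "ReferenceProfileSet",
    "SpeciesCall",
    "resolvable_pattern",
    "match_bands",
    "patterns_distinguishable",
    "build_reference_profiles",
    "classify_pattern",
    "save_profiles",
    "load_profiles",
]


@dataclass(frozen=True)
class GelParams:
    """Detection floor and resolving power of the virtual gel.

    Defaults model the 4% agarose / 50 bp ladder setup typical for sub-500 bp
    RFLP work: fragments under 50 bp are visible but unsized; two fragments
    co-migrate when they differ by less than 7% of their mean (and always
    when within 5 bp).
    """

    detection_floor: int = 50
    rel_resolution: float = 0.07
    abs_resolution: int = 5

    def __post_init__(self) -> None:
        if self.detection_floor < 0:
            raise ValueError("detection_floor must be >= 0")
        if not 0 < self.rel_resolution < 1:
            raise ValueError("rel_resolution must be in (0, 1)")
        if self.abs_resolution < 1:
            raise ValueError("abs_resolution must be >= 1")

    def resolution(self, a: float, b: float) -> float:
        """Minimum separation (bp) at which bands of sizes a and b resolve."""
        return max(self.abs_resolution, self.rel_resolution * (a + b) / 2.0)


@dataclass(frozen=True)
class BandPattern:
    """What one lane shows: sized bands plus a sub-floor presence flag."""

    bands: tuple[int, ...]  # descending
    subfloor_present: bool
    gel: GelParams

    @property
    def n_bands(self) -> int:
        return len(self.bands)


def resolvable_pattern(
    fragments: Iterable[int],
    gel: GelParams = GelParams(),
    representative: str = "mean",
) -> BandPattern:
    """Collapse a fragment multiset into the bands a gel can resolve.

    Fragments below the detection floor are dropped and flagged as
    ``subfloor_present``. The rest are single-linkage clustered: adjacent
    sizes merge whenever they differ by no more than the gel's resolution at
    their mean, repeated until stable. Each cluster becomes one band at the
    length-weighted mean (fragment mass on a gel is proportional to length),
    rounded to an integer; ``representative="min"`` reports the smallest
    member instead, matching conventions that print the lower co-migrating
    size.
    """
    frags = sorted(int(f) for f in fragments)
    if not frags:
        raise ValueError("fragment list must be nonempty")
    if frags[0] < 1:
        raise ValueError("fragments must all be >= 1 bp")
    subfloor = any(f < gel.detection_floor for f in frags)
    visible = [f for f in frags if f >= gel.detection_floor]

    # clusters as (weighted_sum, weight, min_member); weight = total bp mass
    clusters = [(float(f * f), float(f), f) for f in visible]
    changed = True
    while changed and len(clusters) > 1:
        changed = False
        merged: list[tuple[float, float, int]] = [clusters[0]]
        for s, w, mn in clusters[1:]:
            ps, pw, pmn = merged[-1]
            rep_prev, rep_cur = ps / pw, s / w
            if abs(rep_cur - rep_prev) <= gel.resolution(rep_prev, rep_cur):
                merged[-1] = (ps + s, pw + w, min(pmn, mn))
                changed = True
            else:
                merged.append((s, w, mn))
        clusters = merged

    if representative == "mean":
        bands = tuple(sorted((round(s / w) for s, w, _ in clusters), reverse=True))
    elif representative == "min":
        bands = tuple(sorted((mn for _, _, mn in clusters), reverse=True))
    else:
        raise ValueError("representative must be 'mean' or 'min'")
    return BandPattern(bands=bands, subfloor_present=subfloor, gel=gel)


def match_bands(
    x: Sequence[int], y: Sequence[int], gel: GelParams
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Greedy closest-first one-to-one pairing of two band lists.

    A pair is admissible when the two sizes differ by at most the gel's
    resolution at their mean. Pairs are taken in order of increasing size
    difference, ties broken toward the larger bands; each band is used at
    most once. Returns (pairs, unmatched_x, unmatched_y). Deterministic.
    """
    candidates = []
    for i, xb in enumerate(x):
        for j, yb in enumerate(y):
            if abs(xb - yb) <= gel.resolution(xb, yb):
                candidates.append((abs(xb - yb), -max(xb, yb), -xb, i, j))
    candidates.sort()
    used_x: set[int] = set()
    used_y: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, _, _, i, j in candidates:
        if i in used_x or j in used_y:
            continue
        used_x.add(i)
        used_y.add(j)
        pairs.append((x[i], y[j]))
    unmatched_x = [xb for i, xb in enumerate(x) if i not in used_x]
    unmatched_y = [yb for j, yb in enumerate(y) if j not in used_y]
    return pairs, unmatched_x, unmatched_y


def patterns_distinguishable(
    a: BandPattern, b: BandPattern
) -> tuple[bool, list[int]]:
    """Can a gel tell two band patterns apart?

    True iff at least one band of either pattern has no counterpart in the
    other within the gel's resolution; the witness list holds the unmatched
    band sizes from both sides. Symmetric. Sub-floor flags are ignored:
    an unsized smear is not a reliable discriminator.
    """
    if a.gel != b.gel:
        raise ValueError("patterns were built under different gel parameters")
    _, ua, ub = match_bands(a.bands, b.bands, a.gel)
    witnesses = sorted(ua + ub, reverse=True)
    return bool(witnesses), witnesses


@dataclass
class ReferenceProfileSet:
    """Species -> band pattern map for one enzyme: the classifier's database."""

    enzyme: str
    gel: GelParams
    profiles: dict[str, BandPattern]
    provenance: dict[str, str] = field(default_factory=dict)  # species -> amplicon id
    warnings: list[str] = field(default_factory=list)

    @property
    def species(self) -> list[str]:
        return list(self.profiles)


def build_reference_profiles(
    labeled_digests: Iterable[tuple[str, DigestResult]],
    gel: GelParams = GelParams(),
    representative: str = "mean",
) -> ReferenceProfileSet:
    """Turn one digest per species into a reference profile set.

    All digests must come from the same enzyme; duplicate species are an
    error. Species pairs whose patterns are not distinguishable under the
    gel parameters produce a warning (not a failure): the set is still
    usable, the classifier will simply return "ambiguous" between them.
    """
    profiles: dict[str, BandPattern] = {}
    provenance: dict[str, str] = {}
    enzyme: str | None = None
    for species, dr in labeled_digests:
        if species in profiles:
            raise ValueError(f"duplicate species label {species!r}")
        if enzyme is None:
            enzyme = dr.enzyme
        elif dr.enzyme != enzyme:
            raise ValueError(
                f"mixed enzymes in profile set: {enzyme!r} vs {dr.enzyme!r}"
            )
        profiles[species] = resolvable_pattern(dr.fragments, gel, representative)
        provenance[species] = dr.amplicon_id
    if enzyme is None:
        raise ValueError("no digests supplied")
    warnings = []
    names = list(profiles)
    for i, s1 in enumerate(names):
        for s2 in names[i + 1 :]:
            ok, _ = patterns_distinguishable(profiles[s1], profiles[s2])
            if not ok:
                warnings.append(
                    f"{s1} and {s2} are not distinguishable under these gel parameters"
                )
    return ReferenceProfileSet(
        enzyme=enzyme, gel=gel, profiles=profiles,
        provenance=provenance, warnings=warnings,
    )


@dataclass
class SpeciesCall:
    """Outcome of classifying an observed lane against reference profiles."""

    best_species: str  # species name, or "ambiguous" / "no_match"
    scores: dict[str, float]
    matched: dict[str, list[tuple[int, int]]]
    unmatched_observed: dict[str, list[int]]
    unmatched_profile: dict[str, list[int]]


def classify_pattern(
    observed: Iterable[int],
    profiles: ReferenceProfileSet,
    call_threshold: float = 0.8,
) -> SpeciesCall:
    """Assign an observed fragment-size list to a species.

    The observed sizes are first passed through the same gel model as the
    references. Against each profile, bands are paired greedily
    closest-first within tolerance and scored with the Dice coefficient
    ``2 * matched_pairs / (n_observed + n_profile)`` — 1.0 means every band
    on both sides found a partner. Sub-floor fragments never enter the score
    (an unsized smear carries no size information). A call is made only for
    a strictly best score at or above the threshold; a tie at the top is
    "ambiguous", and a best score below threshold is "no_match".
    """
    obs_pattern = resolvable_pattern(observed, profiles.gel)
    scores: dict[str, float] = {}
    matched: dict[str, list[tuple[int, int]]] = {}
    un_obs: dict[str, list[int]] = {}
    un_prof: dict[str, list[int]] = {}
    for species, prof in profiles.profiles.items():
        pairs, uo, up = match_bands(obs_pattern.bands, prof.bands, profiles.gel)
        denom = obs_pattern.n_bands + prof.n_bands
        scores[species] = (2.0 * len(pairs) / denom) if denom else 0.0
        matched[species] = pairs
        un_obs[species] = uo
        un_prof[species] = up
    best_score = max(scores.values())
    leaders = [s for s, v in scores.items() if v == best_score]
    if best_score < call_threshold:
        best = "no_match"
    elif len(leaders) > 1:
        best = "ambiguous"
    else:
        best = leaders[0]
    return SpeciesCall(
        best_species=best, scores=scores, matched=matched,
        unmatched_observed=un_obs, unmatched_profile=un_prof,
    )


def save_profiles(profiles: ReferenceProfileSet, path: str | Path) -> None:
    """Serialize a profile set as JSON."""
    doc = {
        "enzyme": profiles.enzyme,
        "gel": {
            "detection_floor": profiles.gel.detection_floor,
            "rel_resolution": profiles.gel.rel_resolution,
            "abs_resolution": profiles.gel.abs_resolution,
        },
        "profiles": {
            sp: {"bands": list(bp.bands), "subfloor_present": bp.subfloor_present}
            for sp, bp in profiles.profiles.items()
        },
        "provenance": profiles.provenance,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def load_profiles(path: str | Path) -> ReferenceProfileSet:
    """Read a profile set written by :func:`save_profiles`."""
    doc = json.loads(Path(path).read_text())
    gel = GelParams(**doc["gel"])
    profiles = {
        sp: BandPattern(tuple(entry["bands"]), entry["subfloor_present"], gel)
        for sp, entry in doc["profiles"].items()
    }
    return ReferenceProfileSet(
        enzyme=doc["enzyme"], gel=gel, profiles=profiles,
        provenance=doc.get("provenance", {}),
    )
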