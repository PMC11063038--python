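"""Synthetic panels with planted primer and restriction sites.

Two generators live here:

* :func:`generate_panel` builds arbitrary species panels from a
  :class:`FixtureConfig` — a shared ancestral background, per-species
  substitutions, planted primer footprints and per-species planted cut
  sites — together with a ground-truth manifest, so the whole
  PCR -> digest -> gel -> classify pipeline can be exercised end to end
  with known answers and no external data.

* :func:`apis_panel` is the bundled six-species honey bee fixture. It is
  synthetic by construction: AseI sites are planted into random backgrounds
  at the cumulative fragment sums that reproduce the published expected
  digestion patterns of the six Apis 16S rRNA amplicons (474/475/470/473/
  474/479 bp), with the real universal primer pair at the amplicon ends and
  every other hexamer guaranteed not to be an AseI site. It mimics the
  fragment structure of the real amplicons, not their actual 16S sequence —
  inter-species sequence distances in this fixture are arbitrary.

Every generator takes a seed and is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .insilico_pcr import Amplicon, PcrConstraints, Primer, find_primer_sites, simulate_pcr
from .restriction_digest import digest, find_cut_positions
from .sequence_io import RestrictionEnzyme, SequenceRecord, reverse_complement

__all__ = [
    "FWD_PRIMER",
    "REV_PRIMER",
    "ASEI",
    "APIS_SPECIES",
    "APIS_TABLE",
    "FixtureConfig",
    "generate_panel",
    "apis_panel",
    "apis_templates",
]

#: The universal 16S rRNA primer pair used for honey bee amplification.
FWD_PRIMER = Primer("16S_rRNA-F", "TGACTTACGTCGATTTGAAC")
REV_PRIMER = Primer("16S_rRNA-R", "GACTGTACAAAGGTAGCATAAT")

#: AseI recognizes AT^TAAT (palindromic, top-strand cut after position 2).
ASEI = RestrictionEnzyme("AseI", "ATTAAT", 2)

APIS_SPECIES = (
    "A. mellifera",
    "A. cerana",
    "A. laboriosa",
    "A. dorsata",
    "A. florea",
    "A. andreniformis",
)

#: species -> (amplicon length bp, expected AseI fragments, largest first).
APIS_TABLE: dict[str, tuple[int, tuple[int, ...]]] = {
    "A. mellifera": (474, (414, 60)),
    "A. cerana": (475, (219, 202, 54)),
    "A. laboriosa": (470, (217, 125, 60, 38, 30)),
    "A. dorsata": (473, (175, 128, 64, 60, 46)),
    "A. florea": (474, (249, 165, 60)),
    "A. andreniformis": (479, (250, 229)),
}

_BASES = np.array(list("ACGT"))
DEFAULT_PANEL_SEED = 101
_MAX_ATTEMPTS = 200


def _random_bases(rng: np.random.Generator, n: int) -> list[str]:
    return list(rng.choice(_BASES, size=n))


def _primer_sites_ok(seq: str, fwd: Primer, rev: Primer) -> bool:
    """Exactly one convergent footprint per primer: fwd at the very start
    (+ strand), rev at the very end (- strand), nothing else anywhere."""
    rec = SequenceRecord("check", seq)
    constraints = PcrConstraints()
    f_sites = find_primer_sites(rec, fwd, constraints)
    r_sites = find_primer_sites(rec, rev, constraints)
    return (
        len(f_sites) == 1
        and f_sites[0].strand == "+"
        and f_sites[0].start == 0
        and len(r_sites) == 1
        and r_sites[0].strand == "-"
        and r_sites[0].end == len(seq)
    )


def _plant_amplicon(
    length: int,
    cuts: Sequence[int],
    enzyme: RestrictionEnzyme,
    fwd: Primer,
    rev: Primer,
    rng: np.random.Generator,
) -> str:
    """One amplicon: primers at the ends, ``enzyme`` cuts exactly at ``cuts``.

    Site blocks are written at ``cut - cut_offset`` over a random background,
    then the result is verified by a full rescan (cut positions and primer
    footprints both exact); accidental extra sites trigger a resample.
    """
    site_len = len(enzyme.site)
    lo = len(fwd)
    hi = length - len(rev)
    blocks = sorted((c - enzyme.cut_offset, c - enzyme.cut_offset + site_len) for c in cuts)
    prev_end = lo
    for s, e in blocks:
        if s < prev_end or e > hi:
            raise ValueError(
                f"planted site [{s},{e}) overlaps a primer footprint or another site"
            )
        prev_end = e
    for _ in range(_MAX_ATTEMPTS):
        bases = _random_bases(rng, length)
        bases[0:lo] = list(fwd.seq)
        bases[length - len(rev):] = list(reverse_complement(rev.seq))
        for s, _e in blocks:
            bases[s : s + site_len] = list(enzyme.site)
        seq = "".join(bases)
        if find_cut_positions(seq, enzyme) == sorted(cuts) and _primer_sites_ok(
            seq, fwd, rev
        ):
            return seq
    raise RuntimeError("could not place sites without accidental matches")


def _embed(
    amplicon_seq: str, flank: int, rng: np.random.Generator,
    fwd: Primer, rev: Primer,
) -> str:
    """Surround an amplicon with random flanks, keeping priming unique."""
    for _ in range(_MAX_ATTEMPTS):
        seq = (
            "".join(_random_bases(rng, flank))
            + amplicon_seq
            + "".join(_random_bases(rng, flank))
        )
        rec = SequenceRecord("check", seq)
        constraints = PcrConstraints()
        if (
            len(find_primer_sites(rec, fwd, constraints)) == 1
            and len(find_primer_sites(rec, rev, constraints)) == 1
        ):
            return seq
    raise RuntimeError("could not embed amplicon without spurious primer sites")


def apis_panel(seed: int = DEFAULT_PANEL_SEED) -> list[SequenceRecord]:
    """The bundled six-species synthetic Apis amplicon panel.

    Returns one amplicon-sized record per species whose AseI digest equals
    the published expected fragment multiset (cut positions are the
    cumulative fragment sums, largest fragment 5'-most).
    """
    rng = np.random.default_rng(seed)
    records = []
    for idx, species in enumerate(APIS_SPECIES):
        length, fragments = APIS_TABLE[species]
        cuts = list(np.cumsum(fragments[:-1]))
        seq = _plant_amplicon(length, cuts, ASEI, FWD_PRIMER, REV_PRIMER, rng)
        records.append(
            SequenceRecord(
                id=f"apis{idx + 1}_{species.replace('. ', '').replace(' ', '_')}",
                seq=seq,
                species=species,
                source="synthetic",
            )
        )
    return records


def apis_templates(seed: int = DEFAULT_PANEL_SEED, flank: int = 80) -> list[SequenceRecord]:
    """The Apis panel embedded in random flanks, for in-silico PCR runs."""
    rng = np.random.default_rng(seed)
    templates = []
    for rec in apis_panel(seed):
        seq = _embed(rec.seq, flank, rng, FWD_PRIMER, REV_PRIMER)
        templates.append(
            SequenceRecord(
                id=f"{rec.id}_template", seq=seq,
                species=rec.species, source="synthetic",
            )
        )
    return templates


@dataclass(frozen=True)
class FixtureConfig:
    """Recipe for a synthetic species panel with known ground truth.

    ``sites`` gives, per species, the planted cut positions in amplicon
    coordinates for ``enzyme``; when omitted, species i receives one cut at
    ``60 + 30*i``. Keeping default cuts in the lower half of the amplicon
    with 30 bp spacing ensures every pair of default fragment patterns is
    resolvable on the default gel (cuts at c and at L-c would collide,
    since both yield the fragment pair {c, L-c}). ``mutation_rate`` is the per-base
    substitution probability applied to each species' copy of the shared
    ancestral background, outside planted features.
    """

    n_species: int
    seed: int
    template_len: int = 650
    amplicon_start: int = 60
    amplicon_len: int = 475
    fwd: Primer = FWD_PRIMER
    rev: Primer = REV_PRIMER
    enzyme: RestrictionEnzyme = ASEI
    sites: tuple[tuple[int, ...], ...] | None = None
    mutation_rate: float = 0.02
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if not 0 <= self.mutation_rate < 1:
            raise ValueError("mutation_rate must be in [0, 1)")
        if self.amplicon_start + self.amplicon_len > self.template_len:
            raise ValueError("amplicon does not fit in the template")
        if self.sites is not None and len(self.sites) != self.n_species:
            raise ValueError("sites must list one entry per species")
        if self.labels is not None and len(self.labels) != self.n_species:
            raise ValueError("labels must list one entry per species")

    def species_sites(self) -> tuple[tuple[int, ...], ...]:
        if self.sites is not None:
            return self.sites
        return tuple((60 + 30 * i,) for i in range(self.n_species))

    def species_labels(self) -> tuple[str, ...]:
        if self.labels is not None:
            return self.labels
        return tuple(f"species_{i + 1:02d}" for i in range(self.n_species))


def _expected_fragments(cuts: Sequence[int], length: int) -> tuple[int, ...]:
    bounds = [0, *sorted(cuts), length]
    return tuple(sorted((b - a for a, b in zip(bounds, bounds[1:])), reverse=True))


def generate_panel(
    config: FixtureConfig,
) -> tuple[list[SequenceRecord], dict]:
    """Build a species panel of templates plus a ground-truth manifest.

    Each species' template is the ancestral background with substitutions at
    ``mutation_rate``, the primer pair planted at the amplicon boundaries,
    and its cut sites planted inside the amplicon. Every template is
    verified end to end before being returned: in-silico PCR must yield
    exactly one product at the planted coordinates and its digest must equal
    the manifest's expected fragments. Same seed, same panel, byte for byte.
    """
    rng = np.random.default_rng(config.seed)
    site_lists = config.species_sites()
    labels = config.species_labels()
    a0, alen = config.amplicon_start, config.amplicon_len
    site_len = len(config.enzyme.site)

    # ancestral background, screened so the bare amplicon region carries no
    # accidental recognition site and no spurious priming
    for _ in range(_MAX_ATTEMPTS):
        ancestor = _random_bases(rng, config.template_len)
        probe = list(ancestor)
        probe[a0 : a0 + len(config.fwd)] = list(config.fwd.seq)
        probe[a0 + alen - len(config.rev) : a0 + alen] = list(
            reverse_complement(config.rev.seq)
        )
        segment = "".join(probe[a0 : a0 + alen])
        if not find_cut_positions(segment, config.enzyme) and _primer_sites_ok(
            segment, config.fwd, config.rev
        ):
            ancestor = probe
            break
    else:
        raise RuntimeError("could not synthesize a clean ancestral background")

    records: list[SequenceRecord] = []
    manifest: dict = {
        "seed": config.seed,
        "enzyme": config.enzyme.name,
        "amplicon_start": a0,
        "amplicon_len": alen,
        "species": [],
    }
    # feature windows (template coords) that substitutions must not touch
    protected = np.zeros(config.template_len, dtype=bool)
    protected[a0 : a0 + len(config.fwd)] = True
    protected[a0 + alen - len(config.rev) : a0 + alen] = True

    for i in range(config.n_species):
        cuts = sorted(site_lists[i])
        expected = _expected_fragments(cuts, alen)
        prev_end = len(config.fwd)
        for c in cuts:
            s = c - config.enzyme.cut_offset
            if s < prev_end or s + site_len > alen - len(config.rev):
                raise ValueError(
                    f"{labels[i]}: planted site at cut {c} overlaps another feature"
                )
            prev_end = s + site_len
        for _ in range(_MAX_ATTEMPTS):
            bases = list(ancestor)
            mutate = (rng.random(config.template_len) < config.mutation_rate) & ~protected
            for pos in np.nonzero(mutate)[0]:
                choices = [b for b in "ACGT" if b != bases[pos]]
                bases[pos] = choices[rng.integers(0, 3)]
            for c in cuts:
                s = a0 + c - config.enzyme.cut_offset
                bases[s : s + site_len] = list(config.enzyme.site)
            seq = "".join(bases)
            rec = SequenceRecord(
                id=f"{labels[i]}_template", seq=seq,
                species=labels[i], source="synthetic",
            )
            products = simulate_pcr(rec, config.fwd, config.rev)
            if len(products) != 1:
                continue
            product = products[0]
            if (product.start, product.end) != (a0, a0 + alen):
                continue
            if digest(product, config.enzyme).fragments != expected:
                continue
            records.append(rec)
            manifest["species"].append(
                {
                    "label": labels[i],
                    "template_id": rec.id,
                    "cuts_amplicon": cuts,
                    "expected_fragments": list(expected),
                }
            )
            break
        else:
            raise RuntimeError(f"could not synthesize a valid template for {labels[i]}")
    return records, manifest
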