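# Methods

## Scope and model

`rflpkit` models a PCR-RFLP species-authentication assay as a chain of
deterministic sequence operations: primer annealing, amplification,
restriction digestion, gel resolution, and pattern comparison, with a
distance-based phylogenetic confirmation step. All internal coordinates are
0-based half-open; user-facing reports are 1-based closed and say so in
their headers.

## In-silico PCR

A primer of length k anneals at any template window where the number of
IUPAC-incompatible positions is at most `max_mismatches` (default 0) and
the 3′-terminal `clamp_len` bases (default 3) match exactly. The clamp
models the polymerase's requirement for a paired 3′ end; without it,
mismatch-tolerant scans report sites that could never extend. Products are
enumerated from every convergent pair of footprints of the two primers, in
both orientations of the pair, then normalized to the template + strand —
reporting multiple products rather than suppressing them, because a
multi-product primer pair is an assay-design failure one needs to see.
Product lengths are bounded by `min_len`/`max_len` (defaults 50/2000 bp).

The default `max_mismatches = 0` reflects the intended use: checking that a
candidate universal pair amplifies every member of a reference panel
exactly. Templates are treated as linear; an opt-in `circular` flag appends
a `max_len`-long prefix copy so origin-spanning products of circular
mitogenomes are found without silently changing results for linear input.

## Restriction digestion

Recognition sites are IUPAC patterns with a top-strand cut offset
(AseI = ATTAAT, offset 2). The + strand is scanned window-by-window; for
non-palindromic sites the reverse-complement pattern is also scanned and
its cuts mapped back as `match_end − offset`. Overlapping matches each cut.
Fragment lengths are successive differences of the sorted cut coordinates
over a linear molecule, so fragment count always equals cut count + 1 and
fragments sum to the molecule length — both enforced as invariants.
Sticky-end overhangs are ignored: gel migration reflects duplex length.

Ambiguity handling defaults to **strict**: a window matches only if every
template base is an unambiguous A/C/G/T inside the pattern's base set.
N-runs in a template can therefore never produce phantom cuts; a
set-intersection mode is available for deliberately degenerate analyses.

## Virtual gel

Two effects separate a digest's fragment multiset from what a gel shows:

* **Detection floor** (`detection_floor`, default 50 bp): fragments below
  the smallest ladder rung are visible at best as an unsized smear. They
  are removed from the band list and recorded as a `subfloor_present`
  flag — never sized, never scored.
* **Co-migration** (`rel_resolution` 0.07, `abs_resolution` 5 bp):
  fragments whose sizes differ by no more than
  `max(abs_resolution, rel_resolution × mean)` run as one band. Visible
  fragments are single-linkage clustered under this tolerance, iterated to
  a fixed point, and each cluster is reported at its length-weighted mean
  (band mass is proportional to fragment length), rounded to an integer.
  A `representative="min"` option reports the smallest cluster member
  instead, the convention of tables that print the lower co-migrating size.

The defaults are calibrated to high-percentage agarose with a 50 bp
ladder: 64 vs 60 bp (6.5% apart) co-migrate while 219 vs 202 bp (8.1%)
resolve, and 46/38/30 bp fragments vanish below the floor while 54 bp
stays visible. Comparisons in tests use the gel tolerance rather than
exact equality wherever the mean-vs-min representative choice could
matter.

Pattern comparison is greedy closest-first one-to-one matching within the
same tolerance, ties broken toward larger bands — deterministic and
auditable. Two patterns are *distinguishable* iff at least one band on
either side has no counterpart. Classification scores a lane against each
reference profile with the Dice coefficient
`2·matched / (n_observed + n_profile)` and calls the strictly best species
at or above a threshold (default 0.8); a tied best is "ambiguous", a weak
best is "no_match". Superimposed patterns from mixed-species samples
therefore resolve to "ambiguous"/"no_match" rather than a wrong species.

## Enzyme screening

For each library enzyme, every panel amplicon is digested and gel-modeled,
and all species pairs compared. Ranking is by complete discrimination,
then distinguishable-pair count, then fewer total bands (simpler gels read
more reliably), then name — a total order, so repeated screens are
byte-identical. Because near-equal amplicon lengths (e.g. 470 vs 479 bp,
1.9% apart) cannot be resolved at 7% tolerance, discrimination must come
from cut-site variation, which is exactly the property the screen
measures. `minimal_enzyme_sets` searches subsets exhaustively (default up
to size 2); panels are small enough that nothing cleverer is warranted.

## Distances and trees

Pairwise divergence is counted over shared unambiguous A/C/G/T columns
(pairwise deletion, the common default for pairwise distance tables;
complete deletion is available for matrix builds). Unaligned input is
globally aligned first (match +1, mismatch −1, gap −2, free end gaps) —
adequate for near-equal-length amplicons of the same locus; multiple
alignment is out of scope. The K2P distance is
`−½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)`; a non-positive log argument
(saturation) yields `inf` rather than an exception or a silent drop, and
matrix consumers refuse saturated entries explicitly.

Neighbor joining follows Saitou–Nei with the Q criterion; ties are broken
by lowest index pair, making topologies reproducible. Negative branch
estimates are clamped to zero and counted on the tree object. On additive
matrices the leaf-to-leaf path lengths reproduce the input exactly (tested
at 1e-9 on 4–8 taxon cases, and cross-checked topologically against an
independent NJ implementation).

Bootstrap support resamples alignment columns with replacement
(`numpy.random.default_rng(seed)`; the seed is a required argument — no
hidden default), rebuilds matrix and tree per replicate, and reports the
percentage of replicates containing each internal bipartition of the
full-data tree. Saturated replicates are skipped with a warning and the
denominator adjusted. Newick output prints branch lengths (`%.6g`) and
integer support labels and round-trips byte-stably through the reader.

## Synthetic data

The fixture generator plants known structure into random uniform-A/C/G/T
backgrounds: the primer pair at chosen amplicon boundaries and per-species
restriction sites at chosen cut positions. Backgrounds are
rejection-sampled so the only recognition sites of the configured enzyme,
and the only primer footprints, are the planted ones; every generated
template is verified end to end (one PCR product at the planted
coordinates, digest equal to the manifest) before being returned. Species
are derived from a shared ancestral background by substitutions at
`mutation_rate` (default 0.02, a plausible intra-genus mitochondrial
divergence scale) outside planted features. Default per-species cut
positions are `60 + 30·i`: cuts kept in the lower half of the amplicon
with 30 bp spacing, because cuts at c and L−c yield the same fragment pair
and would collide.

The bundled `apis_panel()` plants AseI sites at the cumulative fragment
sums that reproduce the published expected digestion multisets of the six
Apis 16S amplicons, with the real primer sequences at the ends. It mimics
fragment structure, not the real 16S sequence: inter-species distances in
this fixture are those of random backgrounds, so phylogenetic results on
it are structural demonstrations only. Passing tests on these fixtures
show the engine's arithmetic and decision logic are correct under planted
ground truth; they cannot show anything about wet-lab effects
(degradation, partial digestion, gel artifacts) or about sequences the
panel does not contain. Checks against the real deposited amplicon and
mitogenome accessions require network access to GenBank and are therefore
not part of the test suite; the synthetic panel carries their structural
content offline.

## Problem sizes and numerical choices

The test suite and the acceptance script run at the assay's natural scale:
six-species panels of ~475 bp amplicons, fixture panels of up to 8
species, 1,000-sequence property sweeps for digest conservation, 200–400
bootstrap replicates (binomial sampling error at B = 400 is under 2.5
percentage points, ample for comparing against an analytic oracle). The
whole suite completes in a few seconds on one CPU. Band sizes are
integers; distances are doubles; the only tolerance-sensitive comparison
is the NJ additivity check at 1e-9, safely above double rounding for
matrices of magnitude ~10².

## Known limitations

- No thermodynamic primer model (Tm, hairpins, dimers): binding is
  mismatch-count plus clamp.
- No methylation sensitivity, star activity, partial digestion, or double
  digests.
- No physical migration model (Rf curves) or band-intensity modeling; the
  gel model is a resolution threshold, not a simulation.
- Multiple sequence alignment is out of scope; phylogenetics expects
  pre-aligned input or aligns pairwise only.
- Mixed-species samples are detected as non-calls, not decomposed.
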