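"""Kimura two-parameter distances and neighbor-joining trees with bootstrap.

The K2P model corrects observed divergence for multiple hits while keeping
transitions (A<->G, C<->T) and transversions as separate change classes:

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

with P and Q the transition and transversion proportions over compared
sites. Sites with a gap or an ambiguity code in either sequence are excluded
pairwise (each pair keeps its own comparable sites); complete deletion —
dropping a column from every comparison if any sequence is gapped or
ambiguous there — is available for matrix construction.

Trees come from the Saitou–Nei neighbor-joining algorithm with deterministic
tie-breaking, and bootstrap support is the percentage of column-resampled
replicates whose NJ tree contains each internal bipartition of the
full-data tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np

from .sequence_io import SequenceRecord

__all__ = [
    "PairwiseDiff",
    "DistanceMatrix",
    "TreeNode",
    "PhyloTree",
    "pairwise_diff",
    "k2p_distance",
    "k2p_matrix",
    "nj_tree",
    "bootstrap_support",
    "write_newick",
    "read_newick",
]

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_UNAMBIG = set("ACGT")


@dataclass(frozen=True)
class PairwiseDiff:
    """Transition/transversion counts over the comparable sites of one pair."""

    sites_compared: int
    transitions: int
    transversions: int

    @property
    def P(self) -> float:
        return self.transitions / self.sites_compared

    @property
    def Q(self) -> float:
        return self.transversions / self.sites_compared

    @property
    def p_distance(self) -> float:
        return (self.transitions + self.transversions) / self.sites_compared


def _align_pair(a: str, b: str) -> tuple[str, str]:
    """Global pairwise alignment with free end gaps (match +1, mismatch -1, gap -2)."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    try:
        aligner.end_insertion_score = 0
        aligner.end_deletion_score = 0
    except AttributeError:  # Biopython < 1.88 naming
        aligner.target_end_gap_score = 0
        aligner.query_end_gap_score = 0
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def pairwise_diff(a: SequenceRecord, b: SequenceRecord, aligned: bool = True) -> PairwiseDiff:
    """Count transitions and transversions between two sequences.

    With ``aligned=True`` the sequences must already be column-aligned (equal
    lengths, gaps as ``-``); otherwise a pairwise global alignment is
    computed first. Columns with a gap or ambiguity in either sequence are
    excluded (pairwise deletion).
    """
    sa, sb = a.seq, b.seq
    if aligned:
        if len(sa) != len(sb):
            raise ValueError(
                f"aligned sequences differ in length: {a.id} {len(sa)} vs {b.id} {len(sb)}"
            )
    else:
        sa, sb = _align_pair(sa, sb)
    n = ts = tv = 0
    for x, y in zip(sa, sb):
        if x not in _UNAMBIG or y not in _UNAMBIG:
            continue
        n += 1
        if x != y:
            if (x, y) in _TRANSITIONS:
                ts += 1
            else:
                tv += 1
    if n == 0:
        raise ValueError(f"no comparable sites between {a.id} and {b.id}")
    return PairwiseDiff(sites_compared=n, transitions=ts, transversions=tv)


def k2p_distance(diff: PairwiseDiff) -> float:
    """K2P distance in substitutions/site; ``inf`` when saturated.

    Saturation (a non-positive log argument) is reported as ``math.inf``
    rather than raised, so matrix builders can flag it without dying.
    """
    P, Q = diff.P, diff.Q
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.inf
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with an ordered label list."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("diagonal must be zero")
        finite = np.isfinite(self.d)
        if not np.allclose(
            np.where(finite, self.d, 0.0), np.where(finite, self.d, 0.0).T
        ):
            raise ValueError("matrix must be symmetric")

    @property
    def saturated(self) -> bool:
        return not np.all(np.isfinite(self.d))

    def offdiagonal(self) -> np.ndarray:
        n = len(self.labels)
        iu = np.triu_indices(n, k=1)
        return self.d[iu]


def k2p_matrix(
    records: Sequence[SequenceRecord],
    aligned: bool = True,
    gap_policy: str = "pairwise",
) -> DistanceMatrix:
    """All-pairs K2P distances.

    ``gap_policy="pairwise"`` (default) excludes gapped/ambiguous sites per
    pair; ``"complete"`` first removes every column that is gapped or
    ambiguous in any sequence, then compares on the common clean columns
    (requires aligned input).
    """
    recs = list(records)
    if gap_policy == "complete":
        if not aligned:
            raise ValueError("complete deletion requires aligned input")
        length = len(recs[0].seq)
        if any(len(r.seq) != length for r in recs):
            raise ValueError("aligned sequences must share one length")
        keep = [
            i for i in range(length)
            if all(r.seq[i] in _UNAMBIG for r in recs)
        ]
        recs = [
            SequenceRecord(r.id, "".join(r.seq[i] for i in keep), r.species, r.source)
            for r in recs
        ]
    elif gap_policy != "pairwise":
        raise ValueError("gap_policy must be 'pairwise' or 'complete'")
    n = len(recs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = k2p_distance(
                pairwise_diff(recs[i], recs[j], aligned=aligned)
            )
    return DistanceMatrix(labels=[r.id for r in recs], d=d)


@dataclass
class TreeNode:
    """One node of an (un)rooted tree; leaves carry labels, edges lengths."""

    label: str | None = None
    length: float | None = None  # length of the edge to the parent
    support: int | None = None   # bootstrap %, internal nodes only
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label] if self.label else []
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class PhyloTree:
    """Unrooted tree stored with a trifurcating root (NJ convention)."""

    root: TreeNode
    labels: list[str]
    negative_branches_clamped: int = 0

    def bipartitions(self) -> set[frozenset[str]]:
        """Leaf sets of all internal edges, canonicalized away from labels[0]."""
        full = set(self.labels)
        ref = self.labels[0]
        out: set[frozenset[str]] = set()
        for node in self.root.walk():
            if node is self.root or node.is_leaf:
                continue
            side = set(node.leaves())
            if len(side) < 2 or len(full) - len(side) < 2:
                continue
            out.add(frozenset(side if ref not in side else full - side))
        return out


def nj_tree(m: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    The pair minimizing the Q criterion is chosen by scan order (lowest
    index pair wins ties), so repeated runs are identical. Negative branch
    estimates — a known NJ artifact on noisy matrices — are clamped to zero
    and counted. On an additive matrix, leaf-to-leaf path lengths reproduce
    the input distances exactly.
    """
    n = len(m.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if m.saturated:
        raise ValueError("distance matrix contains saturated (infinite) entries")
    d = m.d.astype(float).copy()
    nodes = [TreeNode(label=lab) for lab in m.labels]
    active = list(range(n))

    while len(active) > 3:
        k = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        best_q = math.inf
        for ai in range(k):
            for aj in range(ai + 1, k):
                i, j = active[ai], active[aj]
                q = (k - 2) * d[i, j] - r[i] - r[j]
                if q < best_q:
                    best_q = q
                    best = (i, j)
        i, j = best  # type: ignore[misc]
        vi = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (k - 2))
        vj = d[i, j] - vi
        nodes[i].length = vi
        nodes[j].length = vj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        # grow the matrix by one row/col for the new node
        new = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for x in active:
            if x in (i, j):
                continue
            d[new, x] = d[x, new] = 0.5 * (d[i, x] + d[j, x] - d[i, j])
        nodes.append(parent)
        active = [x for x in active if x not in (i, j)] + [new]

    i, j, l = active
    nodes[i].length = 0.5 * (d[i, j] + d[i, l] - d[j, l])
    nodes[j].length = 0.5 * (d[i, j] + d[j, l] - d[i, l])
    nodes[l].length = 0.5 * (d[i, l] + d[j, l] - d[i, j])
    root = TreeNode(children=[nodes[i], nodes[j], nodes[l]])

    clamped = 0
    for node in root.walk():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    return PhyloTree(root=root, labels=list(m.labels), negative_branches_clamped=clamped)


def leaf_path_lengths(tree: PhyloTree) -> DistanceMatrix:
    """Patristic (path-length) distances between all leaf pairs."""
    # pair distances accumulate at each pair's lowest common ancestor
    def collect(node: TreeNode) -> dict[str, float]:
        if node.is_leaf:
            return {node.label: 0.0}  # type: ignore[dict-item]
        below: dict[str, float] = {}
        child_maps = []
        for c in node.children:
            cm = {
                leaf: dist + (c.length or 0.0) for leaf, dist in collect(c).items()
            }
            child_maps.append(cm)
            below.update(cm)
        for a_idx in range(len(child_maps)):
            for b_idx in range(a_idx + 1, len(child_maps)):
                for la, da in child_maps[a_idx].items():
                    for lb, db in child_maps[b_idx].items():
                        out[la][lb] = out[lb][la] = da + db
        return below

    labels = tree.labels
    out: dict[str, dict[str, float]] = {la: {lb: 0.0 for lb in labels} for la in labels}
    collect(tree.root)
    d = np.array([[out[a][b] for b in labels] for a in labels])
    return DistanceMatrix(labels=list(labels), d=d)


@dataclass
class BootstrapResult:
    """NJ tree with supports, plus replicate bookkeeping."""

    tree: PhyloTree
    replicates_requested: int
    replicates_used: int
    warnings: list[str] = field(default_factory=list)


def bootstrap_support(
    records: Sequence[SequenceRecord],
    replicates: int,
    seed: int,
    gap_policy: str = "pairwise",
) -> BootstrapResult:
    """Column-resampling bootstrap of the NJ tree.

    Each replicate resamples alignment columns with replacement, rebuilds the
    K2P matrix and NJ tree, and the support of each internal bipartition of
    the full-data tree is the percentage of replicate trees containing it.
    A replicate whose matrix saturates is skipped with a warning and the
    denominator adjusted. Same seed, same result.
    """
    recs = list(records)
    if replicates < 1:
        raise ValueError("need at least 1 bootstrap replicate")
    length = len(recs[0].seq)
    if any(len(r.seq) != length for r in recs):
        raise ValueError("bootstrap requires column-aligned sequences")
    base = k2p_matrix(recs, aligned=True, gap_policy=gap_policy)
    tree = nj_tree(base)
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}

    rng = np.random.default_rng(seed)
    cols = np.array([list(r.seq) for r in recs])
    used = 0
    warnings: list[str] = []
    for b in range(replicates):
        idx = rng.integers(0, length, size=length)
        sampled = cols[:, idx]
        rep_records = [
            SequenceRecord(r.id, "".join(row), r.species, r.source)
            for r, row in zip(recs, sampled)
        ]
        try:
            rep_matrix = k2p_matrix(rep_records, aligned=True, gap_policy=gap_policy)
            rep_tree = nj_tree(rep_matrix)
        except ValueError:
            warnings.append(f"replicate {b}: saturated distances, skipped")
            continue
        used += 1
        rep_bips = rep_tree.bipartitions()
        for bp in target:
            if bp in rep_bips:
                counts[bp] += 1

    full = set(tree.labels)
    ref = tree.labels[0]
    for node in tree.root.walk():
        if node is tree.root or node.is_leaf:
            continue
        side = set(node.leaves())
        if len(side) < 2 or len(full) - len(side) < 2:
            continue
        key = frozenset(side if ref not in side else full - side)
        if used:
            node.support = round(100.0 * counts[key] / used)
    return BootstrapResult(
        tree=tree, replicates_requested=replicates,
        replicates_used=used, warnings=warnings,
    )


def _fmt_len(x: float | None) -> str:
    return "" if x is None else f":{x:.6g}"


def _newick_node(node: TreeNode) -> str:
    if node.is_leaf:
        return f"{node.label}{_fmt_len(node.length)}"
    inner = ",".join(_newick_node(c) for c in node.children)
    label = "" if node.support is None else str(node.support)
    return f"({inner}){label}{_fmt_len(node.length)}"


def write_newick(tree: PhyloTree) -> str:
    """Newick text with branch lengths and integer support labels."""
    return _newick_node(tree.root) + ";\n"


def read_newick(text: str) -> PhyloTree:
    """Parse newick (via dendropy) back into a PhyloTree."""
    dtree = dendropy.Tree.get(
        data=text, schema="newick", preserve_underscores=True
    )

    def convert(dnode) -> TreeNode:
        if dnode.is_leaf():
            return TreeNode(
                label=dnode.taxon.label if dnode.taxon else dnode.label,
                length=dnode.edge.length,
            )
        support = None
        if dnode.label and dnode.label.isdigit():
            support = int(dnode.label)
        return TreeNode(
            label=None,
            length=dnode.edge.length,
            support=support,
            children=[convert(c) for c in dnode.child_nodes()],
        )

    root = convert(dtree.seed_node)
    root.length = None
    return PhyloTree(root=root, labels=root.leaves())
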