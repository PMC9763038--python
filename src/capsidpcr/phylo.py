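"""p-distances, neighbor joining, bootstrap supports and UA/CY host-range
typing of HcRNAV-derived ASVs.

The distance is the uncorrected amino-acid p-distance (short, closely
related amplicons; a Poisson correction is available via a flag). Neighbor
joining follows the classic Saitou–Nei agglomeration with a deterministic
lexicographic tie-break so trees are reproducible; negative branch-length
estimates are clamped to zero with the deficit logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .classify import ReferencePanel, percent_identity
from .seqcore import SequenceError, SequenceRecord

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Distance matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray  # symmetric, zero diagonal, >= 0

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise SequenceError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise SequenceError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise SequenceError("distance matrix diagonal not zero")
        if np.any(self.d < 0):
            raise SequenceError("negative distances")


def _codes(aln: Sequence[SequenceRecord]) -> np.ndarray:
    """Residues as a (n, L) uint8 matrix for vectorised column work."""
    return np.array(
        [np.frombuffer(r.residues.encode(), dtype=np.uint8) for r in aln]
    )


_GAP = ord("-")


def _p_dist(mat: np.ndarray, labels: Sequence[str], poisson: bool) -> np.ndarray:
    n = mat.shape[0]
    gap = mat == _GAP
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comp = ~(gap[i] | gap[j])
            n_comp = int(comp.sum())
            if n_comp == 0:
                raise SequenceError(
                    f"{labels[i]}/{labels[j]}: no comparable columns"
                )
            p = int((mat[i, comp] != mat[j, comp]).sum()) / n_comp
            if poisson:
                if p >= 1.0:
                    raise SequenceError("p-distance 1.0 not Poisson-correctable")
                p = -math.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return d


def p_distance_matrix(
    aln: Sequence[SequenceRecord], poisson_correct: bool = False
) -> DistanceMatrix:
    """Pairwise proportion of differing residues, skipping columns where
    either row has a gap. With ``poisson_correct``, d = -ln(1 - p)."""
    if len(aln) < 3:
        raise SequenceError("need >= 3 sequences for a distance matrix")
    L = len(aln[0])
    if any(len(r) != L for r in aln):
        raise SequenceError("sequences have unequal lengths")
    labels = tuple(r.id for r in aln)
    return DistanceMatrix(labels, _p_dist(_codes(aln), labels, poisson_correct))


# ---------------------------------------------------------------------------
# Tree structure
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    label: str | None = None  # leaf label (None for internal)
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None  # bootstrap %, internal edges only

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> frozenset[str]:
        if self.is_leaf():
            return frozenset([self.label])
        out: set[str] = set()
        for c, _ in self.children:
            out |= c.leaves()
        return frozenset(out)

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if self.is_leaf():
            return self.label
        inner = ",".join(f"{c._nwk()}:{ln:.6g}" for c, ln in self.children)
        sup = "" if self.support is None else f"{self.support:g}"
        return f"({inner}){sup}"


@dataclass(frozen=True)
class Tree:
    """Unrooted tree held as a root with >= 3 children (the final NJ join)."""

    root: TreeNode

    @property
    def leaf_set(self) -> frozenset[str]:
        return self.root.leaves()

    def total_length(self) -> float:
        total = 0.0
        stack = [self.root]
        while stack:
            node = stack.pop()
            for c, ln in node.children:
                total += ln
                stack.append(c)
        return total

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each canonicalised as the side not
        containing the lexicographically smallest leaf."""
        all_leaves = self.leaf_set
        anchor = min(all_leaves)
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf():
                return frozenset([node.label])
            below: set[str] = set()
            for c, _ in node.children:
                side = walk(c)
                below |= side
                if 1 < len(side) < len(all_leaves) - 1:
                    canon = side if anchor not in side else all_leaves - side
                    out.add(frozenset(canon))
            return frozenset(below)

        walk(self.root)
        return out

    def clades(self) -> list[frozenset[str]]:
        """Every leaf set obtainable as one side of an edge (both sides)."""
        all_leaves = self.leaf_set
        sides: list[frozenset[str]] = []

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf():
                return frozenset([node.label])
            below: set[str] = set()
            for c, _ in node.children:
                side = walk(c)
                below |= side
                sides.append(frozenset(side))
                sides.append(all_leaves - side)
            return frozenset(below)

        walk(self.root)
        return sides

    def newick(self) -> str:
        return self.root.newick()


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(D: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor joining.

    Q(i, j) = (n - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k); the argmin
    pair is joined, ties resolved by the lexicographically smallest pair of
    cluster representative labels (each cluster represented by its smallest
    leaf). Branch lengths follow the standard formulas; negative estimates
    are clamped to 0 and the deficit logged.
    """
    n = len(D.labels)
    if n < 3:
        raise SequenceError("neighbor joining needs >= 3 taxa")
    nodes: list[TreeNode] = [TreeNode(label=lb) for lb in D.labels]
    reps: list[str] = list(D.labels)  # representative (min leaf) per cluster
    d = D.d.astype(float).copy()
    active = list(range(n))
    clamped = 0.0

    while len(active) > 3:
        m = len(active)
        sums = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - sums[i] - sums[j]
                pair_key = tuple(sorted((reps[i], reps[j])))
                cand = (q, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = 0.5 * d[i, j] + (sums[i] - sums[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        if li < 0:
            clamped += -li
            li = 0.0
        if lj < 0:
            clamped += -lj
            lj = 0.0
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        # grow the matrix by one row/col for the new cluster
        k = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for h in active:
            if h in (i, j):
                continue
            d[k, h] = d[h, k] = 0.5 * (d[i, h] + d[j, h] - d[i, j])
        nodes.append(new)
        reps.append(min(reps[i], reps[j]))
        active = [h for h in active if h not in (i, j)] + [k]

    i, j, k = active
    # three-point formulas for the final star
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    lens = []
    for ln in (li, lj, lk):
        if ln < 0:
            clamped += -ln
            ln = 0.0
        lens.append(ln)
    if clamped:
        log.info("clamped %.3g of negative branch length to 0", clamped)
    # order final children deterministically by representative label
    order = sorted(range(3), key=lambda t: reps[[i, j, k][t]])
    root = TreeNode(
        children=[(nodes[[i, j, k][t]], lens[t]) for t in order]
    )
    return Tree(root)


def bootstrap_support(
    aln: Sequence[SequenceRecord],
    n_replicates: int = 1000,
    seed: int = 0,
    poisson_correct: bool = False,
) -> Tree:
    """NJ tree of the full alignment with bootstrap supports.

    Columns are resampled with replacement per replicate; support for each
    internal bipartition of the full-data tree is the percentage of
    replicate trees containing it. All supports are stored on the tree;
    display conventions (masking <= 50) are left to the writer.
    """
    if n_replicates < 1:
        raise SequenceError("n_replicates must be >= 1")
    L = len(aln[0])
    if L < 2:
        raise SequenceError("alignment shorter than 2 columns")
    tree = neighbor_joining(p_distance_matrix(aln, poisson_correct))
    target = tree.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    mat = _codes(aln)
    ids = tuple(r.id for r in aln)
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        try:
            rep_d = _p_dist(mat[:, cols], ids, poisson_correct)
            rep_tree = neighbor_joining(DistanceMatrix(ids, rep_d))
        except SequenceError:
            continue  # degenerate resample (e.g. all-gap column pair)
        rep_bips = rep_tree.bipartitions()
        for bp in target:
            if bp in rep_bips:
                counts[bp] += 1
    supports = {bp: 100.0 * c / n_replicates for bp, c in counts.items()}
    _attach_supports(tree, supports)
    return tree


def _attach_supports(tree: Tree, supports: dict[frozenset[str], float]) -> None:
    all_leaves = tree.leaf_set
    anchor = min(all_leaves)

    def walk(node: TreeNode) -> frozenset[str]:
        if node.is_leaf():
            return frozenset([node.label])
        below: set[str] = set()
        for c, _ in node.children:
            side = walk(c)
            below |= side
            if 1 < len(side) < len(all_leaves) - 1:
                canon = side if anchor not in side else all_leaves - side
                c.support = supports.get(frozenset(canon))
        return frozenset(below)

    walk(tree.root)


def masked_newick(tree: Tree, min_support: float = 50.0) -> str:
    """Newick with supports written as internal node labels, masking
    supports <= ``min_support`` (the display convention for figures)."""

    def nwk(node: TreeNode) -> str:
        if node.is_leaf():
            return node.label
        inner = ",".join(f"{nwk(c)}:{ln:.6g}" for c, ln in node.children)
        sup = ""
        if node.support is not None and node.support > min_support:
            sup = f"{node.support:g}"
        return f"({inner}){sup}"

    return nwk(tree.root) + ";"


# ---------------------------------------------------------------------------
# Host-range typing
# ---------------------------------------------------------------------------

def assign_host_range_type(
    asv: SequenceRecord,
    panel: ReferencePanel,
    tree: Tree,
    min_identity: float = 85.0,
) -> str:
    """UA/CY typing of an HcRNAV-derived ASV.

    The ASV is typed UA (resp. CY) when its nearest HcRNAV panel neighbour by
    identity is UA-typed (resp. CY), that identity exceeds ``min_identity``,
    and the ASV leaf attaches inside a clade whose panel references are all
    of that one type. Anything else is ``unknown``.
    """
    if asv.id not in tree.leaf_set:
        raise SequenceError(f"tree lacks leaf {asv.id!r}")
    hc = [e for e in panel.entries if e.group == "HcRNAV"]
    typed = [e for e in hc if e.host_range_type in ("UA", "CY")]
    if not typed:
        return "unknown"
    idents = sorted(
        ((percent_identity(asv.residues, e.record.residues), e) for e in typed),
        key=lambda t: (-t[0], t[1].accession),
    )
    best_pid, best = idents[0]
    if best_pid <= min_identity:
        return "unknown"
    t = best.host_range_type
    ref_ids = {e.record.id for e in hc if e.record.id in tree.leaf_set}
    same_type = {
        e.record.id for e in hc
        if e.host_range_type == t and e.record.id in tree.leaf_set
    }
    for side in tree.clades():
        if asv.id in side:
            refs_in = side & ref_ids
            if refs_in and refs_in <= same_type:
                return t
    return "unknown"
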