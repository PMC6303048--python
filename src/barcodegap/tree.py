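"""Neighbor-Joining trees with nonparametric bootstrap support.

Classic Saitou–Nei NJ on the K2P matrix: at each step join the pair
minimising

    Q(i, j) = (r - 2) d(i, j) - sum_k d(i, k) - sum_k d(j, k),

with the usual branch-length formulas, leaving an unrooted tree whose
root node is the final trifurcation. Ties in Q are broken by the lowest
(row, column) index pair so runs are bit-reproducible. Negative branch
estimates are clamped to zero for display (the raw value is kept on the
node and clamp events are counted).

Bootstrap support: alignment columns are resampled with replacement,
distances and the NJ tree are recomputed per pseudo-replicate, and each
internal edge of the original-data tree is labelled with the percentage
of replicates whose tree contains the same bipartition. Replicates whose
matrix has undefined (saturated / low-overlap) entries are dropped and
the denominator adjusted. Per-replicate randomness comes from streams
spawned off one master seed, so supports are reproducible bit-for-bit.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .distances import DistanceConfig, DistanceMatrix, count_matrices, k2p_matrix_from_counts
from .seq_io import Alignment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BootstrapConfig:
    replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class TreeNode:
    name: str | None = None  # leaf label; None for internal nodes
    children: list["TreeNode"] = field(default_factory=list)
    length: float = 0.0  # displayed branch length (clamped at 0)
    raw_length: float = 0.0  # NJ estimate before clamping
    support: float | None = None  # bootstrap %, internal edges only

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


class Tree:
    """Unrooted tree: the root is a trifurcation, not a biological root."""

    def __init__(self, root: TreeNode):
        self.root = root
        self.n_clamped = 0
        self.n_replicates_used: int | None = None
        self.n_replicates_dropped: int | None = None

    @property
    def leaf_names(self) -> list[str]:
        return [lf.name for lf in self.root.leaves()]

    def _iter_nonroot(self):
        stack = list(self.root.children)
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def splits(self) -> dict[frozenset, TreeNode]:
        """Internal-edge bipartitions, each normalised to the side that
        excludes the lexicographically smallest leaf."""
        all_leaves = frozenset(self.leaf_names)
        ref = min(all_leaves)
        out: dict[frozenset, TreeNode] = {}
        for node in self._iter_nonroot():
            if node.is_leaf:
                continue
            side = frozenset(lf.name for lf in node.leaves())
            if ref in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                out[side] = node
        return out

    def clamp_negative_lengths(self) -> int:
        n = 0
        for node in self._iter_nonroot():
            if node.raw_length < 0:
                n += 1
                logger.debug(
                    "negative branch length %.3g clamped to 0", node.raw_length
                )
        if n:
            logger.warning("%d negative branch lengths clamped to 0", n)
        self.n_clamped = n
        return n

    def total_length(self) -> float:
        return sum(n.length for n in self._iter_nonroot())

    def leaf_distance_matrix(self) -> DistanceMatrix:
        """Patristic (path-length) distances between leaves."""
        names = sorted(self.leaf_names)
        idx = {n: i for i, n in enumerate(names)}
        n = len(names)
        d = np.zeros((n, n))

        def below(node):
            # returns {leaf: depth}; adds cross-pair paths on the way up
            if node.is_leaf:
                return {node.name: 0.0}
            acc: dict[str, float] = {}
            for child in node.children:
                sub = {k: v + child.length for k, v in below(child).items()}
                for a, da in acc.items():
                    for b, db in sub.items():
                        d[idx[a], idx[b]] = d[idx[b], idx[a]] = da + db
                acc.update(sub)
            return acc

        below(self.root)
        return DistanceMatrix(names, d, np.full((n, n), -1.0))


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Standard NJ; requires >= 3 taxa and a fully defined matrix."""
    n = len(dm)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    if dm.n_undefined_pairs:
        bad = sorted(
            {
                dm.ids[i]
                for i in range(n)
                if np.isnan(np.delete(dm.values[i], i)).any()
            }
        )
        raise ValueError(
            "distance matrix has undefined entries; exclude the affected "
            f"specimens first: {bad}"
        )
    D = dm.values.astype(np.float64).copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]

    while len(nodes) > 3:
        r = len(nodes)
        s = D.sum(axis=1)
        Q = (r - 2) * D - s[:, None] - s[None, :]
        np.fill_diagonal(Q, np.inf)
        # argmin of the row-major flat index: ties resolve to the lowest
        # (i, j) with i < j because row i is scanned before row j
        flat = int(np.argmin(Q))
        i, j = divmod(flat, r)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = 0.5 * dij + (s[i] - s[j]) / (2.0 * (r - 2))
        lj = dij - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.raw_length, child_j.raw_length = li, lj
        child_i.length, child_j.length = max(li, 0.0), max(lj, 0.0)
        new = TreeNode(children=[child_i, child_j])
        d_new = 0.5 * (D[i, :] + D[j, :] - dij)
        D[i, :] = d_new
        D[:, i] = d_new
        D[i, i] = 0.0
        nodes[i] = new
        D = np.delete(np.delete(D, j, axis=0), j, axis=1)
        del nodes[j]

    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    for node, raw in zip(
        nodes,
        (
            0.5 * (dab + dac - dbc),
            0.5 * (dab + dbc - dac),
            0.5 * (dac + dbc - dab),
        ),
    ):
        node.raw_length = float(raw)
        node.length = max(float(raw), 0.0)
    tree = Tree(TreeNode(children=[a, b, c]))
    tree.clamp_negative_lengths()
    return tree


def bootstrap_support(
    aln: Alignment,
    config: BootstrapConfig = BootstrapConfig(),
    dist_config: DistanceConfig = DistanceConfig(),
) -> Tree:
    """NJ tree of the full data with bootstrap supports on internal edges."""
    codes = aln.codes()
    S, TS, TV = count_matrices(codes)
    d0 = k2p_matrix_from_counts(S, TS, TV, dist_config)
    tree = neighbor_joining(DistanceMatrix(aln.ids, d0, S))
    target = tree.splits()
    counts = {split: 0 for split in target}

    L = codes.shape[1]
    streams = np.random.SeedSequence(config.seed).spawn(config.replicates)
    used = dropped = 0
    for ss in streams:
        rng = np.random.default_rng(ss)
        weights = np.bincount(rng.integers(0, L, size=L), minlength=L)
        Sb, TSb, TVb = count_matrices(codes, weights)
        db = k2p_matrix_from_counts(Sb, TSb, TVb, dist_config)
        iu = np.triu_indices(len(aln), k=1)
        if np.isnan(db[iu]).any():
            dropped += 1
            continue
        rep = neighbor_joining(DistanceMatrix(aln.ids, db, Sb))
        used += 1
        for split in rep.splits():
            if split in counts:
                counts[split] += 1
    if dropped:
        logger.warning(
            "%d of %d bootstrap replicates dropped (undefined distances)",
            dropped,
            config.replicates,
        )
    if used == 0:
        raise RuntimeError("all bootstrap replicates had undefined distances")
    for split, node in target.items():
        node.support = 100.0 * counts[split] / used
    tree.n_replicates_used = used
    tree.n_replicates_dropped = dropped
    return tree


def _newick(node: TreeNode, top: bool) -> str:
    if node.is_leaf:
        return f"{node.name}:{node.length:.10g}"
    inner = ",".join(_newick(c, False) for c in node.children)
    if top:
        return f"({inner});"
    label = "" if node.support is None else str(int(round(node.support)))
    return f"({inner}){label}:{node.length:.10g}"


def to_newick(tree: Tree) -> str:
    """Newick string; bootstrap supports appear as integer internal-node
    labels, the convention most readers (dendropy, ape, FigTree) expect."""
    return _newick(tree.root, True)


def write_newick(tree: Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree) + "\n")
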