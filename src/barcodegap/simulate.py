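"""Synthetic COI-barcode datasets with known ground truth.

The generator emulates the statistical structure of a stream-fish
barcode survey — a few dozen species, 2–24 specimens each (mean ~8),
~600-bp sequences, shallow within-species divergence (~0.5%), deep
between-species divergence (~10%), and AT/CT-rich base composition — so
the whole analysis pipeline (distances, barcode gap, OTU clustering,
trees, delimitation) can be exercised offline with by-construction
expectations.

Genealogy. Species ancestors sit at the tips of a random-join species
tree whose node heights are spread over [0.5, 2.0] x inter_depth / 2,
so any two species are separated by at least 0.5 x inter_depth — a
floor that keeps interspecific divergence safely above OTU/NND
thresholds unless a construction deliberately violates it. Within a
species, specimens hang off the species ancestor (or off one of two
lineage anchors, for injected cryptic complexes) at independent
exponential depths with mean intra_depth / 2, truncated at
0.6 x intra_depth: deep intraspecific splits are a phenomenon this
generator models only through explicit cryptic injections, never as a
tail accident, so ground-truth flag counts are unambiguous. Two
injections create known violations:

* cryptic_species — (species index, lineage_divergence, proportion):
  the species gets two lineage anchors separated by lineage_divergence
  and a deterministic share of its specimens on each, producing a deep
  intraspecific split;
* discordant_pairs — (i, j): species j's ancestor is re-drawn a hair's
  breadth (0.005 subs/site) from species i's, so the two species fuse
  into one OTU at any ordinary threshold.

Sequences evolve along each branch under the Kimura two-parameter
process with transition/transversion rate ratio kappa, total rate one
substitution per site per unit branch length — the same model the
distance estimator assumes, so K2P estimates are unbiased for the true
path lengths and recovery tests are exact in expectation. The root is
drawn from base_freqs; K2P's stationary distribution is uniform, but at
the shallow depths simulated the composition drifts by well under one
percentage point.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .seq_io import Alignment, SequenceRecord, TaxonomyTable, write_fasta

_BASES = "ACGT"
_SITE_CODES = ("UDV", "ISB", "SRS", "IRU", "SJ1", "SJ2", "BRC", "CP16", "CP19", "CP22")


@dataclass(frozen=True)
class SimulationConfig:
    n_species: int = 29
    specimens_per_species: tuple[int, int] = (2, 24)
    seq_length: int = 600
    kappa: float = 3.0
    base_freqs: tuple[float, float, float, float] = (0.235, 0.278, 0.181, 0.307)
    intra_depth: float = 0.005
    inter_depth: float = 0.10
    cryptic_species: tuple[tuple[int, float, float], ...] = ()
    discordant_pairs: tuple[tuple[int, int], ...] = ()
    discordant_separation: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        lo, hi = self.specimens_per_species
        if not 1 <= lo <= hi:
            raise ValueError("invalid specimens_per_species range")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if abs(sum(self.base_freqs) - 1.0) > 0.01:
            raise ValueError("base_freqs must sum to 1")
        if not 0 <= self.intra_depth < self.inter_depth:
            raise ValueError("need 0 <= intra_depth < inter_depth")
        for idx, div, prop in self.cryptic_species:
            if not 0 <= idx < self.n_species:
                raise ValueError(f"cryptic species index {idx} out of range")
            if div <= 0 or not 0 < prop < 1:
                raise ValueError("cryptic lineage needs div > 0 and 0 < prop < 1")
            # beyond ~0.7 subs/site the K2P estimator saturates
            if div >= 0.7:
                raise ValueError(f"lineage_divergence {div} is saturating")
        for i, j in self.discordant_pairs:
            if i == j or not (0 <= i < self.n_species and 0 <= j < self.n_species):
                raise ValueError(f"invalid discordant pair ({i}, {j})")


@dataclass
class TruthTable:
    """Ground-truth labels and expected pairwise divergences."""

    frame: pd.DataFrame  # specimen_id, true_species, true_lineage
    ids: list[str] = field(default_factory=list)
    expected_divergence: np.ndarray | None = None  # true path lengths

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def expected_k2p(depth: float, kappa: float) -> tuple[float, float, float]:
    """Analytic (P, Q, d) between two sequences separated by total path
    length 2*depth under the simulator's K2P process.

    With transition rate a and per-target transversion rate b,
    a + 2b = 1 (one expected substitution per site per unit time) and
    a / b = kappa. The expected proportions after time t = 2*depth are

        P(t) = 1/4 + 1/4 e^{-4bt} - 1/2 e^{-2(a+b)t}
        Q(t) = 1/2 - 1/2 e^{-4bt}

    and plugging them into the K2P formula returns exactly t, which is
    what makes this the simulator's closed-form oracle.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    b = 1.0 / (kappa + 2.0)
    a = kappa * b
    t = 2.0 * depth
    if math.isinf(t):
        return 0.25, 0.5, math.nan
    P = 0.25 + 0.25 * math.exp(-4 * b * t) - 0.5 * math.exp(-2 * (a + b) * t)
    Q = 0.5 - 0.5 * math.exp(-4 * b * t)
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    d = math.nan if w1 <= 0 or w2 <= 0 else -0.5 * math.log(w1 * math.sqrt(w2))
    return P, Q, d


def _evolve(codes: np.ndarray, t: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """One K2P step of duration t for every site of a coded sequence."""
    if t <= 0:
        return codes.copy()
    P, Q, _ = expected_k2p(t / 2.0, kappa)  # P,Q for total path length t
    u = rng.random(codes.size)
    coin = rng.random(codes.size)  # picks between the two transversion targets
    out = codes.copy()
    ts = u < P
    tv = (u >= P) & (u < P + Q)
    out[ts] ^= 2  # A<->G, C<->T
    out[tv] ^= np.where(coin[tv] < 0.5, 1, 3).astype(np.uint8)
    return out


def _species_tree(
    n: int, inter_depth: float, rng: np.random.Generator
) -> tuple[list[tuple[int, int, float]], np.ndarray]:
    """Random sequential-join topology with bounded node heights.

    Returns the join list (left_node, right_node, height) over node
    indices (leaves 0..n-1, internals n..2n-2) and the n x n matrix of
    expected interspecific divergences (2 x MRCA height).
    """
    D = np.zeros((n, n))
    if n == 1:
        return [], D
    heights = (inter_depth / 2.0) * (0.5 + 1.5 * np.sort(rng.random(n - 1)))
    active = list(range(n))
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    joins = []
    nxt = n
    for h in heights:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        for x in members[a]:
            for y in members[b]:
                D[x, y] = D[y, x] = 2.0 * h
        joins.append((a, b, float(h)))
        members[nxt] = members.pop(a) + members.pop(b)
        active[i] = nxt
        del active[j]
        nxt += 1
    return joins, D


def _clade_labels(
    joins: list[tuple[int, int, float]], n: int, cut: float, prefix: str
) -> list[str]:
    """Group species into clades whose joining height is below ``cut``."""
    parent = list(range(2 * n - 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    node = n
    for a, b, h in joins:
        if h <= cut:
            ra, rb = find(a), find(b)
            parent[ra] = parent[rb] = node
        node += 1
    groups: dict[int, list[int]] = {}
    for sp in range(n):
        groups.setdefault(find(sp), []).append(sp)
    labels = [""] * n
    for k, (_, group) in enumerate(sorted((min(g), g) for g in groups.values()), 1):
        for sp in group:
            labels[sp] = f"{prefix}{k:02d}"
    return labels


def simulate(config: SimulationConfig) -> tuple[Alignment, TaxonomyTable, TruthTable]:
    """Generate (alignment, taxonomy, truth) reproducibly from the seed."""
    rng = np.random.default_rng(config.seed)
    L = config.seq_length
    n_sp = config.n_species
    freqs = np.asarray(config.base_freqs, dtype=np.float64)
    freqs = freqs / freqs.sum()

    # root sequence with the target composition built in exactly
    # (largest-remainder apportionment, then shuffled): a multinomial
    # draw at ~600 sites would blur the composition by >1% per base
    counts = np.floor(freqs * L).astype(int)
    remainder = freqs * L - counts
    for b in np.argsort(-remainder)[: L - counts.sum()]:
        counts[b] += 1
    root = np.repeat(np.arange(4, dtype=np.uint8), counts)
    rng.shuffle(root)
    joins, D_sp = _species_tree(n_sp, config.inter_depth, rng)

    # walk the species tree root-down to obtain ancestor sequences whose
    # pairwise path lengths equal D_sp
    n_nodes = 2 * n_sp - 1
    root_height = joins[-1][2] if joins else 0.0
    node_height = [0.0] * n_nodes
    children: dict[int, tuple[int, int]] = {}
    for k, (a, b, h) in enumerate(joins):
        node = n_sp + k
        node_height[node] = h
        children[node] = (a, b)
    node_seq: dict[int, np.ndarray] = {n_nodes - 1 if joins else 0: root}
    for node in range(n_nodes - 1, n_sp - 1, -1):
        a, b = children[node]
        h = node_height[node]
        for child in (a, b):
            node_seq[child] = _evolve(
                node_seq[node], h - node_height[child], config.kappa, rng
            )
    if not joins:
        node_seq[0] = root
    ancestors = [node_seq[i] for i in range(n_sp)]

    genus = _clade_labels(joins, n_sp, 0.45 * root_height, "Genus") if joins else ["Genus01"]
    family = _clade_labels(joins, n_sp, 0.80 * root_height, "Family") if joins else ["Family01"]

    # forced discordant pairs: species j re-anchored right next to species i
    for i, j in config.discordant_pairs:
        sep = config.discordant_separation
        ancestors[j] = _evolve(ancestors[i], sep, config.kappa, rng)
        D_sp[j, :] = D_sp[i, :]
        D_sp[:, j] = D_sp[:, i]
        D_sp[i, j] = D_sp[j, i] = sep
        D_sp[j, j] = 0.0
        genus[j] = genus[i]
        family[j] = family[i]

    cryptic = {idx: (div, prop) for idx, div, prop in config.cryptic_species}
    lo, hi = config.specimens_per_species

    records: list[SequenceRecord] = []
    tax_rows = []
    truth_rows = []
    anchor_id: list[int] = []  # per specimen: unique lineage-anchor index
    anchor_offset: list[float] = []  # anchor depth below the species ancestor
    tip_depth: list[float] = []
    species_idx: list[int] = []
    next_anchor = 0

    for sp in range(n_sp):
        if lo == hi:
            n_i = lo
        else:
            n_i = int(np.clip(lo + rng.poisson(6.0), lo, hi))
        species_name = f"Species{sp + 1:02d}"
        if sp in cryptic:
            div, prop = cryptic[sp]
            n_b = int(np.clip(round(n_i * prop), 1, n_i - 1))
            anchors = [
                (_evolve(ancestors[sp], div / 2.0, config.kappa, rng), div / 2.0),
                (_evolve(ancestors[sp], div / 2.0, config.kappa, rng), div / 2.0),
            ]
            lineage_of = [0] * (n_i - n_b) + [1] * n_b
        else:
            anchors = [(ancestors[sp], 0.0)]
            lineage_of = [0] * n_i
        anchor_base = next_anchor
        next_anchor += len(anchors)
        for k in range(n_i):
            lin = lineage_of[k]
            anchor_seq, offset = anchors[lin]
            if config.intra_depth > 0:
                t = min(rng.exponential(config.intra_depth / 2.0),
                        0.6 * config.intra_depth)
            else:
                t = 0.0
            seq_codes = _evolve(anchor_seq, t, config.kappa, rng)
            sid = f"SP{sp + 1:02d}-{k + 1:03d}"
            records.append(
                SequenceRecord(sid, "".join(_BASES[c] for c in seq_codes))
            )
            tax_rows.append(
                {
                    "specimen_id": sid,
                    "species": species_name,
                    "genus": genus[sp],
                    "family": family[sp],
                    "site": _SITE_CODES[int(rng.integers(0, len(_SITE_CODES)))],
                    "external_cluster_id": "",
                }
            )
            truth_rows.append(
                {
                    "specimen_id": sid,
                    "true_species": species_name,
                    "true_lineage": f"{species_name}.L{lin + 1}",
                }
            )
            anchor_id.append(anchor_base + lin)
            anchor_offset.append(offset)
            tip_depth.append(t)
            species_idx.append(sp)

    m = len(records)
    exp_div = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            if anchor_id[i] == anchor_id[j]:
                dist = tip_depth[i] + tip_depth[j]
            elif species_idx[i] == species_idx[j]:
                dist = (
                    tip_depth[i] + tip_depth[j] + anchor_offset[i] + anchor_offset[j]
                )
            else:
                dist = (
                    tip_depth[i]
                    + tip_depth[j]
                    + anchor_offset[i]
                    + anchor_offset[j]
                    + D_sp[species_idx[i], species_idx[j]]
                )
            exp_div[i, j] = exp_div[j, i] = dist

    aln = Alignment(records)
    tax = TaxonomyTable(pd.DataFrame(tax_rows))
    truth = TruthTable(
        pd.DataFrame(truth_rows), ids=aln.ids, expected_divergence=exp_div
    )
    return aln, tax, truth


def write_dataset(
    aln: Alignment, tax: TaxonomyTable, truth: TruthTable, outdir: str | Path
) -> dict[str, Path]:
    """Write the generator's outputs in the dialect ``seq_io`` reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "sequences.fasta",
        "metadata": outdir / "metadata.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(aln.records, paths["fasta"])
    tax.to_tsv(paths["metadata"])
    truth.to_tsv(paths["truth"])
    return paths
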