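"""Kimura two-parameter (K2P) distances with pairwise deletion.

The K2P model distinguishes transitions (A<->G, C<->T; proportion P of
comparable sites) from transversions (proportion Q) and estimates the
substitutions-per-site distance

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)].

Sites are deleted pairwise: a column drops out of a comparison only when
one of the two sequences carries a gap, an N or an IUPAC ambiguity there
(MEGA's default for distance summaries). Saturated pairs — where the log
argument leaves its domain — are marked undefined (NaN) by default rather
than aborting the run.

For whole-matrix work the transition/transversion/comparable-site counts
are computed for all pairs at once from one-hot base indicators via
matrix products, which also makes column-weighted (bootstrap) recounts
cheap.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .seq_io import Alignment, _ENCODE_TABLE

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairwiseCounts:
    """Comparable-site, transition and transversion counts for one pair."""

    n_sites: int
    n_transitions: int
    n_transversions: int

    def __post_init__(self) -> None:
        if min(self.n_sites, self.n_transitions, self.n_transversions) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_transitions + self.n_transversions > self.n_sites:
            raise ValueError("differences exceed comparable sites")


@dataclass(frozen=True)
class DistanceConfig:
    """Policy knobs for matrix computation.

    min_overlap: pairs sharing fewer comparable sites are undefined.
    on_saturation: "mark_undefined" (NaN + warning) or "error".
    """

    min_overlap: int = 100
    on_saturation: str = "mark_undefined"

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if self.on_saturation not in {"mark_undefined", "error"}:
            raise ValueError("on_saturation must be 'mark_undefined' or 'error'")


class SaturationError(ValueError):
    """A pair's divergence left the K2P log domain under the error policy."""


def _encode(seq: str) -> np.ndarray:
    return _ENCODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def count_differences(seq_a: str, seq_b: str) -> PairwiseCounts:
    """Count comparable sites, transitions and transversions for a pair.

    Only columns where both characters are concrete A/C/G/T are
    comparable. With bases coded A=0, C=1, G=2, T=3, two differing
    comparable bases are a transition exactly when they share parity
    (both purines or both pyrimidines).
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"sequence lengths differ ({len(seq_a)} vs {len(seq_b)})"
        )
    a = _encode(seq_a.upper())
    b = _encode(seq_b.upper())
    comparable = (a != 255) & (b != 255)
    diff = comparable & (a != b)
    ts = diff & ((a & 1) == (b & 1))
    return PairwiseCounts(
        n_sites=int(comparable.sum()),
        n_transitions=int(ts.sum()),
        n_transversions=int(diff.sum() - ts.sum()),
    )


def k2p(counts: PairwiseCounts, on_saturation: str = "mark_undefined") -> float:
    """K2P distance from pair counts; NaN when saturated (by policy)."""
    if counts.n_sites == 0:
        raise ValueError("no comparable sites: K2P distance undefined")
    n, ts, tv = counts.n_sites, counts.n_transitions, counts.n_transversions
    # integer numerators make the log-domain boundary test exact
    if n - 2 * ts - tv <= 0 or n - 2 * tv <= 0:
        if on_saturation == "error":
            raise SaturationError(
                f"saturated pair (P={ts / n:.4f}, Q={tv / n:.4f}): K2P undefined"
            )
        return float("nan")
    w1 = (n - 2 * ts - tv) / n
    w2 = (n - 2 * tv) / n
    return -0.5 * float(np.log(w1 * np.sqrt(w2))) + 0.0  # avoid -0.0


@dataclass
class DistanceMatrix:
    """Symmetric K2P distance matrix (substitutions/site; NaN = undefined)."""

    ids: list[str]
    values: np.ndarray
    n_comparable: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n) or self.n_comparable.shape != (n, n):
            raise ValueError("matrix shape does not match number of IDs")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_undefined_pairs(self) -> int:
        iu = np.triu_indices(len(self.ids), k=1)
        return int(np.isnan(self.values[iu]).sum())

    def get(self, id_a: str, id_b: str) -> float:
        i, j = self.ids.index(id_a), self.ids.index(id_b)
        return float(self.values[i, j])

    def subset(self, keep_ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in keep_ids]
        sel = np.ix_(idx, idx)
        return DistanceMatrix(list(keep_ids), self.values[sel], self.n_comparable[sel])

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(len(self.ids)):
            for j in range(i + 1, len(self.ids)):
                rows.append(
                    {
                        "id_a": self.ids[i],
                        "id_b": self.ids[j],
                        "k2p": self.values[i, j],
                        "n_sites": int(self.n_comparable[i, j]),
                    }
                )
        return pd.DataFrame(rows, columns=["id_a", "id_b", "k2p", "n_sites"])

    def write_square_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", float_format="%.8f"
        )

    def write_long_tsv(self, path: str | Path) -> None:
        self.to_long_frame().to_csv(path, sep="\t", index=False, float_format="%.8f")


def count_matrices(
    codes: np.ndarray, column_weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs (comparable, transition, transversion) count matrices.

    ``codes`` is the (n, L) uint8 matrix from :meth:`Alignment.codes`;
    ``column_weights`` gives each column an integer multiplicity (ones if
    omitted), which is how bootstrap resampling re-counts without
    rebuilding sequences. One-hot indicators turn the per-pair site scans
    into four rank-L matrix products.
    """
    n, L = codes.shape
    w = np.ones(L) if column_weights is None else column_weights.astype(np.float64)
    X = [(codes == b).astype(np.float64) for b in range(4)]
    Xw = [x * w for x in X]
    valid = X[0] + X[1] + X[2] + X[3]
    S = (valid * w) @ valid.T
    match = sum(Xw[b] @ X[b].T for b in range(4))
    TS = Xw[0] @ X[2].T + Xw[2] @ X[0].T + Xw[1] @ X[3].T + Xw[3] @ X[1].T
    TV = S - match - TS
    return np.rint(S), np.rint(TS), np.rint(TV)


def k2p_matrix_from_counts(
    S: np.ndarray,
    TS: np.ndarray,
    TV: np.ndarray,
    config: DistanceConfig = DistanceConfig(),
) -> np.ndarray:
    """Vectorised K2P over count matrices; applies overlap/saturation policy."""
    with np.errstate(divide="ignore", invalid="ignore"):
        # integer-valued numerators: the saturation boundary is exact
        w1 = (S - 2.0 * TS - TV) / S
        w2 = (S - 2.0 * TV) / S
        d = -0.5 * np.log(w1 * np.sqrt(w2)) + 0.0  # normalise -0.0
    bad = (w1 <= 0) | (w2 <= 0)
    low = S < config.min_overlap
    np.fill_diagonal(bad, False)
    np.fill_diagonal(low, False)
    if bad.any() and config.on_saturation == "error":
        raise SaturationError(f"{int(bad.sum()) // 2} saturated pairs")
    d[bad | low] = np.nan
    np.fill_diagonal(d, 0.0)
    return d


def distance_matrix(
    aln: Alignment, config: DistanceConfig = DistanceConfig()
) -> DistanceMatrix:
    """Symmetric pairwise K2P matrix for an alignment."""
    if len(aln) < 2:
        raise ValueError("distance matrix requires at least 2 sequences")
    codes = aln.codes()
    S, TS, TV = count_matrices(codes)
    d = k2p_matrix_from_counts(S, TS, TV, config)
    iu = np.triu_indices(len(aln), k=1)
    n_undef = int(np.isnan(d[iu]).sum())
    if n_undef:
        logger.warning(
            "%d of %d pairs undefined (saturation or < %d overlapping sites)",
            n_undef,
            len(iu[0]),
            config.min_overlap,
        )
    return DistanceMatrix(aln.ids, d, S)
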