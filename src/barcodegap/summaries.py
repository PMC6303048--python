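"""Distance summaries and barcode-gap / nearest-neighbour analysis.

Implements the descriptive layer of a barcoding survey:

* mean base composition across sequences (ambiguous sites excluded);
* distance summaries by taxonomic rank — intraspecific (same species),
  intrageneric (same genus, different species) and intrafamilial (same
  family, different genus), each strictly exclusive of the rank below,
  with unweighted means over specimen pairs;
* one report row per species: mean and maximum intraspecific distance,
  nearest-neighbour distance (NND — the minimum distance from any member
  to any specimen of another species), the nearest species, and whether
  a barcode gap exists (NND exceeds the maximum intraspecific distance);
* the deep-divergence flag used for cryptic-diversity screens.

All reported distances are percentages (K2P x 100), the convention of
barcoding papers; the matrices underneath stay in substitutions/site.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .distances import DistanceMatrix
from .seq_io import Alignment, TaxonomyTable, AMBIGUITY_CODES

logger = logging.getLogger(__name__)

RANKS = ("intraspecific", "intrageneric", "intrafamilial")


@dataclass(frozen=True)
class BaseComposition:
    pct_A: float
    pct_C: float
    pct_G: float
    pct_T: float

    def as_dict(self) -> dict[str, float]:
        return {"A": self.pct_A, "C": self.pct_C, "G": self.pct_G, "T": self.pct_T}


@dataclass(frozen=True)
class RankSummary:
    rank: str
    n_comparisons: int
    mean_pct: float
    min_pct: float
    max_pct: float


@dataclass(frozen=True)
class SpeciesReport:
    """One barcode-gap table row for a species."""

    species: str
    n: int
    mean_intra_pct: Optional[float]
    max_intra_pct: Optional[float]
    nnd_pct: Optional[float]
    nearest_species: Optional[str]
    has_barcode_gap: bool
    note: str = ""


def base_composition(aln: Alignment) -> BaseComposition:
    """Unweighted mean of per-sequence A/C/G/T percentages.

    Each sequence's composition is taken over its own unambiguous sites;
    sequences with no unambiguous site are excluded with a warning.
    """
    per_seq = []
    for rec in aln:
        counts = {b: 0 for b in "ACGT"}
        for ch in rec.sequence:
            if ch in counts:
                counts[ch] += 1
        total = sum(counts.values())
        if total == 0:
            logger.warning(
                "specimen %s has no unambiguous site; excluded from composition",
                rec.specimen_id,
            )
            continue
        per_seq.append([100.0 * counts[b] / total for b in "ACGT"])
    if not per_seq:
        raise ValueError("no sequence with unambiguous sites")
    mean = np.mean(per_seq, axis=0)
    return BaseComposition(*(float(x) for x in mean))


def _rank_masks(
    dm: DistanceMatrix, tax: TaxonomyTable
) -> dict[str, np.ndarray]:
    """Boolean matrices selecting pairs at each (exclusive) rank."""
    ids = dm.ids
    missing = [i for i in ids if i not in set(tax.ids)]
    if missing:
        raise ValueError(f"matrix IDs absent from taxonomy: {missing}")
    sp = np.array(tax.column("species", ids))
    ge = np.array(tax.column("genus", ids))
    fa = np.array(tax.column("family", ids))
    same_sp = sp[:, None] == sp[None, :]
    same_ge = ge[:, None] == ge[None, :]
    same_fa = fa[:, None] == fa[None, :]
    return {
        "intraspecific": same_sp,
        "intrageneric": same_ge & ~same_sp,
        "intrafamilial": same_fa & ~same_ge,
    }


def rank_summaries(dm: DistanceMatrix, tax: TaxonomyTable) -> list[RankSummary]:
    """Distance summaries at the three exclusive taxonomic ranks.

    Undefined (NaN) distances are dropped from both the counts and the
    statistics; means are unweighted over pairs.
    """
    masks = _rank_masks(dm, tax)
    iu = np.triu_indices(len(dm.ids), k=1)
    d = dm.values[iu] * 100.0
    defined = ~np.isnan(d)
    out = []
    for rank in RANKS:
        sel = masks[rank][iu] & defined
        vals = d[sel]
        if vals.size:
            out.append(
                RankSummary(
                    rank,
                    int(vals.size),
                    float(vals.mean()),
                    float(vals.min()),
                    float(vals.max()),
                )
            )
        else:
            out.append(RankSummary(rank, 0, math.nan, math.nan, math.nan))
    return out


def species_reports(dm: DistanceMatrix, tax: TaxonomyTable) -> list[SpeciesReport]:
    """Per-species intraspecific / nearest-neighbour report rows.

    NND is the minimum defined interspecific distance over all
    (member, non-member) specimen pairs; the nearest species is the
    species of the arg-min specimen, ties broken lexicographically.
    Singletons carry no intraspecific fields and a barcode gap by
    convention; with a single species in the dataset NND is undefined
    and flagged in the note.
    """
    ids = dm.ids
    sp = np.array(tax.column("species", ids))
    species = sorted(set(sp))
    d = dm.values * 100.0
    reports: list[SpeciesReport] = []
    for s in species:
        s = str(s)
        member = sp == s
        n = int(member.sum())
        mean_intra = max_intra = None
        if n >= 2:
            block = d[np.ix_(member, member)]
            iu = np.triu_indices(n, k=1)
            vals = block[iu]
            vals = vals[~np.isnan(vals)]
            if vals.size:
                mean_intra = float(vals.mean())
                max_intra = float(vals.max())
        nnd = None
        nearest = None
        note = ""
        if member.all():
            note = "single-species dataset: NND undefined"
        else:
            inter = d[np.ix_(member, ~member)]
            other_sp = sp[~member]
            inter = np.where(np.isnan(inter), np.inf, inter)
            if not np.isfinite(inter).any():
                note = "all interspecific distances undefined"
            else:
                nnd = float(inter.min())
                cols = np.where(inter.min(axis=0) == nnd)[0]
                nearest = min(str(other_sp[c]) for c in cols)
        if n < 2 or max_intra is None:
            gap = True
            if not note:
                note = "insufficient sampling for intraspecific distance"
        elif nnd is None:
            gap = False
        else:
            gap = nnd > max_intra
        reports.append(
            SpeciesReport(s, n, mean_intra, max_intra, nnd, nearest, gap, note)
        )
    return reports


def flag_divergent(
    reports: Sequence[SpeciesReport], threshold_pct: float = 2.0
) -> list[SpeciesReport]:
    """Species whose maximum intraspecific distance exceeds the threshold,
    sorted by descending divergence — the cryptic-diversity screen."""
    hits = [
        r
        for r in reports
        if r.max_intra_pct is not None and r.max_intra_pct > threshold_pct
    ]
    return sorted(hits, key=lambda r: -r.max_intra_pct)


def composition_frame(comp: BaseComposition) -> pd.DataFrame:
    return pd.DataFrame(
        [{"base": b, "mean_pct": v} for b, v in comp.as_dict().items()]
    )


def ranks_frame(summaries: Sequence[RankSummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in summaries])


def species_frame(reports: Sequence[SpeciesReport]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in reports])
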