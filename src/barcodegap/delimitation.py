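"""Candidate- and cryptic-species decision rules.

Two independent flags per morphospecies, following the common
BIN-concordance delimitation criteria:

* candidate species — none of the OTUs the species occupies is
  discordant (singletons are allowed; a species split across several
  concordant OTUs still qualifies) AND its nearest-neighbour distance
  exceeds the NND threshold (default 2%);
* cryptic complex — its maximum intraspecific distance exceeds the
  intraspecific threshold (default 2%) and no morphological
  distinctiveness between its specimens has been reported.

Morphological distinctiveness is an input (it was assessed by eye in the
source workflow); by default no species is marked distinct, so every
deeply divergent species is a cryptic candidate until overridden.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .clustering import DISCORDANT, SpeciesClusterProfile
from .summaries import SpeciesReport


@dataclass(frozen=True)
class DelimitationConfig:
    nnd_threshold_pct: float = 2.0
    intra_threshold_pct: float = 2.0
    morphology_distinct: Mapping[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.nnd_threshold_pct <= 0 or self.intra_threshold_pct <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class DelimitationResult:
    species: str
    candidate: bool
    cryptic_complex: bool
    n_otus: int
    otu_statuses: tuple[str, ...]
    max_intra_pct: Optional[float]
    nnd_pct: Optional[float]
    rationale: str


@dataclass(frozen=True)
class DelimitationSummary:
    n_species: int
    n_candidate: int
    n_cryptic: int
    n_neither: int
    candidates: tuple[str, ...]


def delimit(
    reports: Sequence[SpeciesReport],
    profiles: Mapping[str, SpeciesClusterProfile],
    config: DelimitationConfig = DelimitationConfig(),
) -> list[DelimitationResult]:
    """Apply both rules to every species; deterministic, auditable output."""
    report_by_species = {r.species: r for r in reports}
    if set(report_by_species) != set(profiles):
        only_r = sorted(set(report_by_species) - set(profiles))
        only_p = sorted(set(profiles) - set(report_by_species))
        raise ValueError(
            f"species sets differ between distance reports and cluster "
            f"profiles; reports-only: {only_r}, profiles-only: {only_p}"
        )
    results = []
    for species in sorted(report_by_species):
        rep = report_by_species[species]
        prof = profiles[species]
        reasons = []

        if not prof.all_non_discordant:
            bad = [o for o, s in zip(prof.otu_ids, prof.statuses) if s == DISCORDANT]
            candidate = False
            reasons.append(f"not candidate: discordant OTU {','.join(bad)}")
        elif rep.nnd_pct is None:
            candidate = False
            reasons.append("not candidate: NND undefined")
        elif rep.nnd_pct > config.nnd_threshold_pct:
            candidate = True
            reasons.append(
                f"candidate: no discordant OTU and NND {rep.nnd_pct:.2f}% > "
                f"{config.nnd_threshold_pct:.2f}%"
            )
        else:
            candidate = False
            reasons.append(
                f"not candidate: NND {rep.nnd_pct:.2f}% <= "
                f"{config.nnd_threshold_pct:.2f}%"
            )

        distinct = bool(config.morphology_distinct.get(species, False))
        if rep.max_intra_pct is None:
            cryptic = False
            reasons.append("not cryptic: no intraspecific distance (n<2)")
        elif rep.max_intra_pct <= config.intra_threshold_pct:
            cryptic = False
            reasons.append(
                f"not cryptic: max intra {rep.max_intra_pct:.2f}% <= "
                f"{config.intra_threshold_pct:.2f}%"
            )
        elif distinct:
            cryptic = False
            reasons.append(
                "not cryptic: deep divergence but morphological "
                "distinctiveness reported"
            )
        else:
            cryptic = True
            reasons.append(
                f"cryptic complex: max intra {rep.max_intra_pct:.2f}% > "
                f"{config.intra_threshold_pct:.2f}% and no morphological "
                "distinctiveness"
            )

        results.append(
            DelimitationResult(
                species=species,
                candidate=candidate,
                cryptic_complex=cryptic,
                n_otus=len(prof.otu_ids),
                otu_statuses=prof.statuses,
                max_intra_pct=rep.max_intra_pct,
                nnd_pct=rep.nnd_pct,
                rationale="; ".join(reasons),
            )
        )
    return results


def count_delimited(results: Sequence[DelimitationResult]) -> DelimitationSummary:
    candidates = tuple(r.species for r in results if r.candidate)
    n_cryptic = sum(r.cryptic_complex for r in results)
    n_neither = sum(1 for r in results if not r.candidate and not r.cryptic_complex)
    return DelimitationSummary(
        n_species=len(results),
        n_candidate=len(candidates),
        n_cryptic=n_cryptic,
        n_neither=n_neither,
        candidates=candidates,
    )


def delimitation_frame(results: Sequence[DelimitationResult]) -> pd.DataFrame:
    rows = [
        {
            "species": r.species,
            "candidate": r.candidate,
            "cryptic_complex": r.cryptic_complex,
            "n_otus": r.n_otus,
            "otu_statuses": ",".join(r.otu_statuses),
            "max_intra_pct": r.max_intra_pct,
            "nnd_pct": r.nnd_pct,
            "rationale": r.rationale,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
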