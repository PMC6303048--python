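"""Threshold OTU clustering and morphospecies concordance classes.

OTUs stand in for BOLD's Barcode Index Numbers (BINs). BOLD's RESL
algorithm (refined single linkage with Markov re-assignment) is not
published in reproducible form, so the internal clusterer is a documented
proxy: single-linkage connected components of the K2P graph at a fixed
threshold, defaulting to 2.2% — RESL's published seed threshold. Users
holding a BOLD export can instead pass the true BIN IDs through
``assignment_from_external`` and run concordance on those.

Each OTU is classified against the morphospecies labels:

* singleton  — exactly one specimen (takes precedence over concordant);
* concordant — >1 specimen, all of one species;
* discordant — specimens of more than one species.

Undefined (NaN) distances never merge: missing evidence is treated as
"above threshold".
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distances import DistanceMatrix
from .seq_io import TaxonomyTable

#: Single-linkage threshold (substitutions/site): RESL's 2.2% seed value.
DEFAULT_THRESHOLD = 0.022

CONCORDANT = "concordant"
DISCORDANT = "discordant"
SINGLETON = "singleton"


@dataclass(frozen=True)
class ClusterAssignment:
    """Specimen → OTU map; OTU IDs are each cluster's lexicographically
    smallest member ID, so identical input yields identical IDs."""

    otu_of: Mapping[str, str]
    threshold: float | None
    source: str  # "internal_single_linkage" or "external"

    def members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sid, otu in self.otu_of.items():
            out.setdefault(otu, []).append(sid)
        return {otu: sorted(m) for otu, m in sorted(out.items())}

    @property
    def n_otus(self) -> int:
        return len(set(self.otu_of.values()))


@dataclass(frozen=True)
class OtuClass:
    otu_id: str
    n_specimens: int
    species_set: tuple[str, ...]
    status: str


@dataclass(frozen=True)
class SpeciesClusterProfile:
    species: str
    otu_ids: tuple[str, ...]
    statuses: tuple[str, ...]
    all_non_discordant: bool


def cluster_single_linkage(
    dm: DistanceMatrix, threshold: float = DEFAULT_THRESHOLD
) -> ClusterAssignment:
    """Connected components of the ≤-threshold distance graph.

    Two specimens share an OTU iff a chain of pairs each at distance
    ≤ threshold connects them (single-linkage chaining). NaN distances
    contribute no edge.
    """
    if len(dm) == 0:
        raise ValueError("empty distance matrix")
    with np.errstate(invalid="ignore"):
        adj = dm.values <= threshold
    adj &= ~np.isnan(dm.values)
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(
        csr_matrix(adj), directed=False, return_labels=True
    )
    ids = np.array(dm.ids)
    otu_name = {}
    for comp in range(n_comp):
        otu_name[comp] = min(ids[labels == comp])
    otu_of = {sid: otu_name[lab] for sid, lab in zip(dm.ids, labels)}
    return ClusterAssignment(otu_of, threshold, "internal_single_linkage")


def assignment_from_external(tax: TaxonomyTable) -> ClusterAssignment:
    """Use externally assigned cluster IDs (e.g. BOLD BIN URIs) verbatim."""
    col = tax.frame["external_cluster_id"].astype(str)
    missing = sorted(tax.frame.index[(col == "") | col.isin(["nan", "<NA>"])])
    if missing:
        raise ValueError(f"specimens lacking external_cluster_id: {missing}")
    return ClusterAssignment(dict(zip(tax.ids, col)), None, "external")


def classify_otus(
    assignment: ClusterAssignment, tax: TaxonomyTable
) -> list[OtuClass]:
    """Concordance class per OTU, sorted by OTU ID."""
    out = []
    for otu, members in assignment.members().items():
        species = tuple(sorted({tax.species_of(m) for m in members}))
        if len(members) == 1:
            status = SINGLETON
        elif len(species) > 1:
            status = DISCORDANT
        else:
            status = CONCORDANT
        out.append(OtuClass(otu, len(members), species, status))
    return out


def census(classes: list[OtuClass]) -> dict[str, int]:
    """Counts of OTUs overall and per concordance class."""
    return {
        "n_otus": len(classes),
        CONCORDANT: sum(c.status == CONCORDANT for c in classes),
        DISCORDANT: sum(c.status == DISCORDANT for c in classes),
        SINGLETON: sum(c.status == SINGLETON for c in classes),
    }


def species_cluster_profile(
    assignment: ClusterAssignment, tax: TaxonomyTable
) -> dict[str, SpeciesClusterProfile]:
    """Per species: the OTUs its specimens occupy, with statuses, and
    whether none of those OTUs is discordant."""
    classes = {c.otu_id: c for c in classify_otus(assignment, tax)}
    per_species: dict[str, set[str]] = {}
    for sid, otu in assignment.otu_of.items():
        per_species.setdefault(tax.species_of(sid), set()).add(otu)
    out = {}
    for species in sorted(per_species):
        otus = tuple(sorted(per_species[species]))
        statuses = tuple(classes[o].status for o in otus)
        out[species] = SpeciesClusterProfile(
            species, otus, statuses, DISCORDANT not in statuses
        )
    return out


def otus_frame(
    assignment: ClusterAssignment, tax: TaxonomyTable
) -> pd.DataFrame:
    classes = {c.otu_id: c for c in classify_otus(assignment, tax)}
    rows = [
        {
            "otu_id": otu,
            "specimen_id": sid,
            "species": tax.species_of(sid),
            "status": classes[otu].status,
        }
        for otu, members in assignment.members().items()
        for sid in members
    ]
    return pd.DataFrame(rows, columns=["otu_id", "specimen_id", "species", "status"])


def profiles_frame(
    profiles: dict[str, SpeciesClusterProfile]
) -> pd.DataFrame:
    rows = [
        {
            "species": p.species,
            "otu_ids": ",".join(p.otu_ids),
            "statuses": ",".join(p.statuses),
            "all_non_discordant": p.all_non_discordant,
        }
        for p in profiles.values()
    ]
    return pd.DataFrame(
        rows, columns=["species", "otu_ids", "statuses", "all_non_discordant"]
    )
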