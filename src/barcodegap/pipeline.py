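"""End-to-end pipeline: QC -> distances -> summaries -> OTUs -> tree -> delimitation.

One call produces the full report bundle in an output directory:

    qc_report.tsv       per-sequence QC status and first failed criterion
    distance_matrix.tsv square K2P matrix (substitutions/site)
    distances_long.tsv  id_a, id_b, k2p, n_sites
    composition.tsv     mean base composition (%)
    ranks.tsv           intraspecific/intrageneric/intrafamilial summaries
    summary.tsv         per-species barcode-gap table
    otus.tsv            OTU membership and concordance status
    species_profile.tsv OTUs occupied per species
    tree.nwk            NJ tree with bootstrap supports
    delimitation.tsv    candidate / cryptic flags with rationale
    report.json         headline numbers + every threshold and seed used

All user-facing thresholds are percentages (the barcoding convention);
conversion to substitutions/site happens here and nowhere else.
report.json is written with sorted keys and no timestamps, so reruns
with the same inputs and seed are byte-identical.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import clustering, delimitation, summaries
from .clustering import DEFAULT_THRESHOLD
from .distances import DistanceConfig, DistanceMatrix, distance_matrix
from .seq_io import QCConfig, load_dataset
from .tree import BootstrapConfig, bootstrap_support, write_newick

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1

OUTPUT_FILES = (
    "qc_report.tsv",
    "distance_matrix.tsv",
    "distances_long.tsv",
    "composition.tsv",
    "ranks.tsv",
    "summary.tsv",
    "otus.tsv",
    "species_profile.tsv",
    "tree.nwk",
    "delimitation.tsv",
    "report.json",
)


@dataclass
class RunConfig:
    fasta: str | Path
    metadata: str | Path
    outdir: str | Path
    qc: QCConfig = field(default_factory=QCConfig)
    dist: DistanceConfig = field(default_factory=DistanceConfig)
    cluster_threshold_pct: float = DEFAULT_THRESHOLD * 100.0
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    delim: delimitation.DelimitationConfig = field(
        default_factory=delimitation.DelimitationConfig
    )
    use_external_clusters: bool = False

    def __post_init__(self) -> None:
        if self.cluster_threshold_pct <= 0:
            raise ValueError("cluster threshold must be positive")


@dataclass
class RunResult:
    outdir: Path
    files: dict[str, Path]
    report: dict


def _drop_undefined(dm: DistanceMatrix) -> tuple[DistanceMatrix, list[str]]:
    """Greedily drop the specimen with the most undefined pairs until the
    matrix is fully defined (needed by NJ)."""
    keep = list(dm.ids)
    sub = dm
    dropped: list[str] = []
    while sub.n_undefined_pairs:
        undef_counts = np.isnan(sub.values).sum(axis=1)
        worst = int(np.argmax(undef_counts))
        dropped.append(keep.pop(worst))
        sub = dm.subset(keep)
    return sub, dropped


def run_pipeline(config: RunConfig) -> RunResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {name: outdir / name for name in OUTPUT_FILES}

    logger.info("loading %s / %s", config.fasta, config.metadata)
    aln, tax, qc_report = load_dataset(config.fasta, config.metadata, config.qc)
    logger.info("%d sequences passed QC (length %d)", len(aln), aln.length)
    qc_report.to_csv(files["qc_report.tsv"], sep="\t", index=False)

    dm = distance_matrix(aln, config.dist)
    dm.write_square_tsv(files["distance_matrix.tsv"])
    dm.write_long_tsv(files["distances_long.tsv"])

    comp = summaries.base_composition(aln)
    summaries.composition_frame(comp).to_csv(
        files["composition.tsv"], sep="\t", index=False, float_format="%.4f"
    )
    ranks = summaries.rank_summaries(dm, tax)
    summaries.ranks_frame(ranks).to_csv(
        files["ranks.tsv"], sep="\t", index=False, float_format="%.4f"
    )
    reports = summaries.species_reports(dm, tax)
    summaries.species_frame(reports).to_csv(
        files["summary.tsv"], sep="\t", index=False, float_format="%.4f"
    )

    if config.use_external_clusters:
        assignment = clustering.assignment_from_external(tax)
    else:
        assignment = clustering.cluster_single_linkage(
            dm, config.cluster_threshold_pct / 100.0
        )
    classes = clustering.classify_otus(assignment, tax)
    cluster_census = clustering.census(classes)
    clustering.otus_frame(assignment, tax).to_csv(
        files["otus.tsv"], sep="\t", index=False
    )
    profiles = clustering.species_cluster_profile(assignment, tax)
    clustering.profiles_frame(profiles).to_csv(
        files["species_profile.tsv"], sep="\t", index=False
    )

    tree_dm, dropped_for_tree = _drop_undefined(dm)
    if dropped_for_tree:
        logger.warning(
            "excluded %d specimens with undefined distances from the tree: %s",
            len(dropped_for_tree),
            dropped_for_tree,
        )
    tree_aln = aln.subset(tree_dm.ids)
    tree = bootstrap_support(tree_aln, config.bootstrap, config.dist)
    write_newick(tree, files["tree.nwk"])

    results = delimitation.delimit(reports, profiles, config.delim)
    delimitation.delimitation_frame(results).to_csv(
        files["delimitation.tsv"], sep="\t", index=False, float_format="%.4f"
    )
    counts = delimitation.count_delimited(results)

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": {
            "qc": dataclasses.asdict(config.qc),
            "distance": dataclasses.asdict(config.dist),
            "cluster_threshold_pct": config.cluster_threshold_pct,
            "cluster_source": assignment.source,
            "bootstrap_replicates": config.bootstrap.replicates,
            "bootstrap_seed": config.bootstrap.seed,
            "nnd_threshold_pct": config.delim.nnd_threshold_pct,
            "intra_threshold_pct": config.delim.intra_threshold_pct,
        },
        "n_sequences_input": int(len(qc_report)),
        "n_sequences_passed_qc": len(aln),
        "alignment_length": aln.length,
        "n_undefined_pairs": dm.n_undefined_pairs,
        "base_composition_pct": comp.as_dict(),
        "rank_summaries": [dataclasses.asdict(r) for r in ranks],
        "otu_census": cluster_census,
        "n_species": counts.n_species,
        "n_candidate_species": counts.n_candidate,
        "n_cryptic_complexes": counts.n_cryptic,
        "n_neither": counts.n_neither,
        "candidate_species": list(counts.candidates),
        "tree": {
            "n_leaves": len(tree_dm.ids),
            "excluded_specimens": dropped_for_tree,
            "bootstrap_used": tree.n_replicates_used,
            "bootstrap_dropped": tree.n_replicates_dropped,
            "n_clamped_branches": tree.n_clamped,
        },
    }
    with open(files["report.json"], "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return RunResult(outdir, files, report)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    return obj
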