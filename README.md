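# barcodegap

DNA-barcode species delimitation for COI survey data: from aligned
barcode sequences plus specimen metadata to distance summaries,
barcode-gap / nearest-neighbour analysis, threshold OTU clustering with
morphospecies concordance, Neighbor-Joining trees with bootstrap
support, and candidate / cryptic species flags.

## Who this is for

Biodiversity surveys — for example of poorly documented Neotropical
stream fishes — routinely pair a morphological species list with COI
barcodes and ask two questions: which morphospecies are corroborated as
molecular clusters, and which hide deep divergences suggesting cryptic
species? The analysis behind those answers is standard (BOLD workbench
tools, MEGA), but not conveniently scriptable or reproducible offline.
`barcodegap` re-implements the whole chain as a Python library and CLI,
together with a ground-truth simulator so every stage can be validated
without any database download.

## The method

**K2P distance.** For a pair of sequences with proportion *P* of
transitions (A↔G, C↔T) and *Q* of transversions over their comparable
sites,

    d = -1/2 · ln[(1 - 2P - Q) · √(1 - 2Q)]

Sites with gaps, N or IUPAC ambiguities are deleted pairwise. Distances
are reported as percentages (d × 100).

**Barcode gap.** Per species: mean and maximum intraspecific distance
(I.D.), the nearest-neighbour distance NND = min distance from any
member to any specimen of another species, and the gap flag
NND > max I.D.

**OTUs.** Single-linkage connected components of the distance graph at
2.2% (a documented proxy for BOLD's BIN clusters; true BIN IDs can be
passed through instead). Each OTU is concordant (one species),
discordant (several species) or a singleton.

**Trees.** Saitou–Nei Neighbor-Joining on the K2P matrix with
deterministic tie-breaking; nonparametric bootstrap (column resampling)
maps per-bipartition support onto the tree; Newick output.

**Delimitation.** A species is a *candidate species* when none of its
OTUs is discordant and NND > 2%; it is a *cryptic complex* when its
maximum intraspecific distance exceeds 2% and no morphological
distinctiveness was reported. The two flags are independent.

## Worked example

Simulate a small survey with known ground truth, then analyse it:

```sh
$ barcodegap simulate --n-species 6 --seed 42 --out demo/data
simulated 52 specimens of 6 species -> demo/data

$ barcodegap run --fasta demo/data/sequences.fasta \
    --metadata demo/data/metadata.tsv --out demo/report \
    --no-stop-check --bootstrap 100 --seed 42
report bundle written to demo/report
6 species, 6 candidates, 0 cryptic complexes
```

(`--no-stop-check` because simulated sequences carry no reading frame.)
`demo/report/ranks.tsv` then contains

```
rank           n_comparisons  mean_pct  min_pct  max_pct
intraspecific  204            0.3861    0.0000   1.3494
intrageneric   99             7.9184    7.5794   9.0965
intrafamilial  0
```

— 204 within-species comparisons averaging 0.39% divergence against
7.9% between congeneric species, a clean barcode gap. The per-species
table (`summary.tsv`) shows it species by species:

```
species    n  mean_intra_pct  max_intra_pct  nnd_pct  nearest_species  has_barcode_gap
Species01  8  0.3767          0.8392         17.2616  Species03        True
Species02  8  0.5456          1.3494         16.7136  Species03        True
```

and `delimitation.tsv` / `report.json` aggregate the decision: all six
species sit in their own concordant OTU with NND far above 2%, so all
six are flagged candidate species and none as a cryptic complex. The
bundle also includes the K2P matrix, base composition, OTU membership,
the bootstrapped NJ tree (`tree.nwk`) and a machine-readable
`report.json` echoing every threshold and seed.

To analyse a real BOLD-style export instead, point `--fasta`/
`--metadata` at your files (metadata columns: `specimen_id`, `species`,
`genus`, `family`, `site`, optional `external_cluster_id`), drop
`--no-stop-check`, and add `--use-external-clusters` if you want
concordance computed on your BIN IDs rather than the internal proxy.

## Layout

- `src/barcodegap/seq_io.py` — FASTA/TSV reading, QC filters, validation
- `src/barcodegap/distances.py` — K2P distances, pairwise deletion
- `src/barcodegap/summaries.py` — composition, rank summaries, barcode gap
- `src/barcodegap/clustering.py` — threshold OTUs, concordance classes
- `src/barcodegap/tree.py` — Neighbor-Joining, bootstrap, Newick
- `src/barcodegap/delimitation.py` — candidate / cryptic decision rules
- `src/barcodegap/simulate.py` — ground-truth barcode simulator
- `src/barcodegap/pipeline.py`, `cli.py` — orchestration and CLI

See `docs/methods.md` for the models, defaults and design decisions.
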