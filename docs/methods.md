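# Methods

This note documents the models and procedures implemented in
`barcodegap`, the defaults they ship with, and the design decisions
taken where more than one reasonable choice existed.

## Input contract and quality control

The package analyses *pre-aligned* (or naturally equal-length) COI
barcode sequences; it deliberately contains no aligner, because barcode
workflows align upstream and an alignment step would import a large
method surface that the analysis itself does not depend on. Unequal
surviving lengths are a hard error instructing the user to align first.

QC mirrors barcode-compliance practice, in this order per record:

| filter | default | notes |
|---|---|---|
| minimum ungapped length | 500 sites | barcode-compliant fragment |
| ambiguous fraction | ≤ 0.01 | N + IUPAC codes over ungapped length |
| indels | none allowed | any `-` fails when enabled |
| stop codons | no open frame ⇒ fail | vertebrate mitochondrial code |

The stop-codon scan accepts a record if *any* of the three forward
frames is free of internal stops (the amplicon's frame offset is not
assumed; reverse frames are not scanned because standard fish-barcoding
primer pairs read the sense strand). The terminal codon of a frame is
exempt. Stops under the vertebrate mitochondrial code are TAA, TAG,
AGA, AGG; the standard nuclear code is available by configuration. The
scan can be disabled (`check_stop_codons=False`) — required for
synthetic data, which carries no reading-frame structure.

Ambiguities are *counted*, never stripped: a record passes or fails on
its ambiguous fraction, and downstream distance code excludes ambiguous
sites pairwise. This keeps coordinates stable and makes QC idempotent.

## K2P distances

Distances follow the Kimura two-parameter model,
`d = -1/2 ln[(1-2P-Q)√(1-2Q)]`, with `P` and `Q` the transition and
transversion proportions over the sites comparable for that specific
pair (pairwise deletion — MEGA's default for distance summaries, and
the choice that maximises usable sites). Partial IUPAC ambiguities are
treated as non-comparable rather than probabilistically resolved.

Numerical choices:

- The log-domain boundary is tested on integer numerators
  (`n - 2·ts - tv ≤ 0`), so exact saturation is detected without float
  slop.
- Saturated pairs are marked undefined (NaN) with a warning by default;
  a hard-error policy is available. Undefined entries never merge
  clusters and exclude a pair from summaries.
- Pairs overlapping in fewer than `min_overlap = 100` comparable sites
  are undefined — 100 sites is where a single difference already means
  1% distance, too coarse for a 2% decision threshold.
- Whole-matrix counts are computed as one-hot indicator matrix
  products, which also makes bootstrap re-counting a weighted product
  rather than a sequence rebuild.
- Internally all distances are substitutions/site; user-facing numbers
  are percentages. The conversion lives in exactly one place (the
  pipeline layer).

## Distance summaries and the barcode gap

Rank summaries are strictly exclusive: intraspecific (same species),
intrageneric (same genus, *different* species), intrafamilial (same
family, *different* genus). Means are unweighted over specimen pairs,
matching the "N comparisons" convention of barcoding reports.

Per species, the nearest-neighbour distance (NND) is the minimum
defined distance from any member to any specimen of another species —
the min-over-pairs estimator. The nearest species is the species of the
arg-min specimen, ties broken lexicographically so output is
deterministic. A species has a barcode gap when NND exceeds its maximum
intraspecific distance; singletons get the gap by convention (there is
no intraspecific distance to violate it) with an explicit
"insufficient sampling" note.

## OTU clustering and concordance

BOLD's RESL algorithm is not published in reproducible form, so the
internal OTU builder is a stated proxy: single-linkage connected
components at a fixed threshold, default 2.2% — RESL's published seed
threshold. Single linkage is the right proxy shape because RESL is
itself seeded by single linkage; no claim is made that the proxy
reproduces an external BIN census, and a pass-through mode runs all
concordance and delimitation logic on externally supplied cluster IDs
instead. OTU IDs are the lexicographically smallest member ID, so
clusterings are stable across runs.

Concordance classes per OTU: singleton (one specimen — takes precedence
over concordant), discordant (more than one species), concordant
(otherwise). A census counts all three; singletons count as clusters.

## Neighbor-Joining and bootstrap

Canonical Saitou–Nei NJ: join the pair minimising
`Q(i,j) = (r-2)d(i,j) - Σ_k d(i,k) - Σ_k d(j,k)`, standard branch
length and matrix-reduction formulas, unrooted result with a final
trifurcation. Ties in `Q` resolve to the lowest (row, column) index
pair — the first minimum in row-major order — so results are
bit-reproducible across platforms. Negative branch estimates (a known
NJ artefact on non-additive data) are clamped to zero for display; the
raw estimate is kept on the node and clamp events are counted in the
run report. On additive matrices the reconstruction is exact, which the
tests verify against independently generated random trees.

Bootstrap: alignment columns are resampled with replacement per
pseudo-replicate (default 1000, the conventional figure), distances and
the NJ tree recomputed, and each internal bipartition of the
original-data tree labelled with the percentage of replicates
containing it (supports on the original tree, not a consensus).
Replicates whose resampled matrix contains undefined distances are
dropped and the denominator adjusted; the drop count is reported.
Per-replicate randomness comes from child streams spawned off the
master seed, so supports are reproducible bit-for-bit and independent
of execution order. Newick output writes supports as integer internal
node labels, the convention dendropy/ape/FigTree parse natively.

## Delimitation rules

Per morphospecies, two independent flags:

- **candidate species** — no occupied OTU is discordant, and
  NND > 2%. "No discordant OTU" (rather than "exactly one concordant
  OTU") is the operative reading: a species split across several
  concordant OTUs or holding a singleton still qualifies, while sharing
  any OTU with another species disqualifies. This is also the reading
  under which the counts add up in published surveys of this design
  (total species minus discordant-BIN species = delimited species).
- **cryptic complex** — maximum intraspecific distance > 2% and no
  morphological distinctiveness reported. Distinctiveness is an input
  map (it is assessed by eye, not computed); the default "not
  distinct" makes every deeply divergent species a cryptic candidate
  until a user overrides it.

Both thresholds are configurable; every decision carries a rationale
string naming the rule that fired, so reports are auditable.

## The synthetic-data generator

The simulator produces datasets with the statistical shape of a
stream-fish barcode survey, with full ground truth:

| parameter | default | meaning |
|---|---|---|
| `n_species` | 29 | species count of a mid-sized survey |
| `specimens_per_species` | 2–24 | drawn as `clip(2 + Poisson(6), 2, 24)`, mean 8 |
| `seq_length` | 600 | barcode-compliant fragment length (sites) |
| `kappa` | 3.0 | transition/transversion rate ratio |
| `base_freqs` | A .235, C .278, G .181, T .307 | COI composition |
| `intra_depth` | 0.005 | expected conspecific pair divergence |
| `inter_depth` | 0.10 | scale of interspecific divergence |

A uniform draw over 2–24 would average 13 specimens; the shifted
Poisson reproduces the "2–24, mean ≈ 8" sampling profile instead.

Genealogy: a random-join species tree whose node heights are spread
uniformly over `[0.5, 2.0] · inter_depth/2`. Consequences: minimum
interspecific divergence `0.5 · inter_depth` (5% at defaults, safely
above the 2.2% OTU threshold), maximum `2 · inter_depth`, overall mean
near 1.5 × `inter_depth`. The floor is deliberate: with unbounded
(e.g. exponential) species depths, near-zero separations would merge
OTUs at random and no by-construction expectation about candidate
counts could hold. Genus and family labels come from cutting the
species tree at 45% and 80% of root height, giving the
intra < intrageneric < intrafamilial ordering of real surveys.

Within species, specimens hang off the species ancestor at exponential
depths (mean `intra_depth/2`) truncated at `0.6 · intra_depth`. The
truncation encodes a modelling stance: deep intraspecific splits exist
in the generator only as explicit **cryptic injections** (two lineage
anchors separated by a stated divergence, specimens apportioned
deterministically between them), never as tail accidents — so a test
asserting "exactly one cryptic complex" is meaningful. Likewise,
**discordant injections** re-anchor one species a fixed 0.005
subs/site from another, guaranteeing a merged OTU at any ordinary
threshold.

Sequences evolve along branches under the K2P continuous-time process
with ratio `kappa`, total rate 1 substitution/site/unit time — the same
model the estimator assumes, a deliberate self-consistency choice that
makes distance recovery exact in expectation (`expected_k2p` gives the
closed form: the K2P estimate of a pair at path length *t* has
expectation exactly *t*). The root sequence carries the target base
composition exactly (largest-remainder apportionment, shuffled), since
a multinomial draw at 600 sites would blur composition by over 1% per
base; K2P's stationary distribution is uniform, but at simulated depths
the drift is well under one percentage point.

What the generator does **not** emulate — and hence what passing tests
do not demonstrate about real data: reading-frame structure (simulated
sequences fail a stop-codon scan, so pipeline runs on them disable it),
rate heterogeneity across sites, composition bias in the substitution
process, alignment gaps and ambiguity calls, sequencing error, and
non-neutral or non-clocklike evolution. Tests on synthetic data
establish the *correctness of the computations*, not the field
performance of the thresholds.

One statistical subtlety matters when validating estimator recovery:
specimen pairs share genealogy branches, so their estimation errors are
strongly correlated and an iid standard error across pairs drastically
understates the fluctuation of the mean. The recovery checks therefore
bound the mean deviation by the realized-path fluctuation scale
`sqrt(d/L)` — the standard deviation of the realized substitution
fraction of a single path of expected length `d` over `L` sites —
rather than by a per-pair standard error.

## Problem sizes used in the acceptance script

`scripts/acceptance.py` analyses one study-scale simulation (29
species, ~230 specimens, 600 bp — the size of the surveys this package
targets) for distances, summaries, clustering and delimitation, and
measures bootstrap supports on a 5-species run at 200 replicates, where
support for true species clades is already saturated; the NJ exactness
check uses 12-taxon additive matrices, enough to exercise repeated
joins and the terminal trifurcation.

## Known limitations

- The internal OTU proxy is not RESL: external BIN censuses are only
  reproduced in pass-through mode.
- NND uses the min-pair estimator; platforms that report a different
  nearest-neighbour statistic may differ in the second decimal.
- Exact agreement with MEGA/BOLD distance tables further depends on
  their gap/ambiguity handling for specific records.
- Single-linkage OTUs at 2.2% chain: two species bridged by an
  intermediate specimen merge even if their extremes exceed the
  threshold. This matches the stated proxy, but is a known failure
  mode of threshold clustering.
- Bootstrap on hundreds of specimens at 1000 replicates is the
  expensive step (minutes); all other stages are effectively instant at
  survey scale.
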