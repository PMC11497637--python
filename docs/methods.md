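# Methods

## The model

`somstab` trains online Kohonen self-organizing maps: a rectangular
grid of `k = xdim × ydim` nodes, each carrying a weight (codebook)
vector in marker space. Training presents one cell per step; the
best-matching node (smallest Euclidean distance, ties to the lowest
node index) and every node within the current neighborhood radius on
the grid move toward the cell by the current learning rate:

```
w_j ← w_j + α(t) · (x − w_j)    for all j with griddist(bmu, j) ≤ r(t)
```

Choices the underlying algorithm family leaves open are fixed as
follows and are deliberate design decisions, not facts about any
particular reference implementation:

- **Presentation order** is cyclic: step *t* presents cell
  `t mod n_cells`. Together with seeded initialization this makes
  training bit-reproducible — identical (data, config, seed) gives
  identical codebooks — which the stability metrics require to be
  meaningful.
- **Initialization** samples `k` distinct cells (seeded) as the
  initial codebook. The initial codebook is retained on the model so
  an "untrained" outcome can be detected exactly.
- **Neighborhood** is a bubble: all nodes within radius move by the
  full α. Grid distance is Euclidean on integer grid coordinates.
- **Schedules**: α decays linearly from `alpha_start` to `alpha_end`
  over the `niter = rlen × n_cells` steps; the radius decays linearly
  from the 0.67 quantile of inter-node grid distances to zero.

### 64-bit scheduling and the 32-bit emulator

`schedule_iterations` computes `niter` in arbitrary-precision Python
integers and refuses products ≥ 2⁶³ explicitly. `emulate_niter_32bit`
models the historical failure in which the product is stored in a
signed 32-bit integer:

```
emulated = ((rlen · n + 2³¹) mod 2³²) − 2³¹
```

Training in `buggy_mode` replaces the exact count by this emulated
value, clamped below at zero — a wrapped-negative count therefore
returns the initialization untouched, reproducing the untrained-map
failure deterministically rather than as an undefined value. For
n = 27,531,842 (a 39-channel dataset filling a 2³⁰-element budget) the
wrapped product is negative for rlen ∈ {80–140}, {240–300}, 400 and
600 within the standard ladder; the audit reports all of them.

### Metaclustering

`metacluster_codebook` merges similar nodes by average-linkage
hierarchical clustering of the codebook vectors (Euclidean), cut at
`n_meta` clusters (default cap 80). This is a deliberately simple
single-pass scheme for annotation convenience; consensus-style
metaclustering is out of scope.

## Stability metrics

Between two runs over the same cells, the Jaccard matrix is computed
from the k×k contingency table. Conventions:

- Empty-vs-empty node pairs get Jaccard 0 **with a warning**: this
  keeps AMJI defined while biasing toward "unstable" rather than
  silently inflating similarity.
- PMJIOT uses a strict `> t` test, so a node whose best match is
  exactly at the threshold does not count.
- AMJI and PMJIOT are directional (rows = first run). The sweep always
  passes (earlier-rlen run, later-rlen run) in that order, and the
  pairwise series is indexed by the earlier rlen of each pair: the
  value at rlen *r* says whether *r* epochs already agree with the
  next rung of the ladder. "Stable from the first rlen" therefore
  recommends the first ladder value.
- `match_nodes` is per-row argmax (many-to-one allowed, ties to the
  lowest column index); optimal one-to-one assignment is deliberately
  not used.

## The parameter sweep

For each (grid, learning-rate pair), one SOM per ladder rlen is
trained from a single shared seeded initialization; AD is recorded per
run and AMJI/PMJIOT per consecutive pair. Curves are smoothed with
LOWESS (`statsmodels`, default `frac = 0.3` — the smoothing method is
standard, the span is a package default) and the plateau is the
earliest rlen from which the smoothed curve stays within `epsilon`
(default 0.05, on the [0, 1] scale; PMJIOT is divided by 100) of its
maximum. A band entered only within the final two ladder entries is
not called a plateau (`None`: stability was not reached inside the
ladder). The recommendation uses the PMJIOT(0.5) curve and falls back
to AMJI when PMJIOT never leaves zero (no plateau signal at all) or
yields no plateau.

Defaults mirror the standard optimization grid: ladder
1, 5, 10, 20, 40, …, 400, 600, 800, 1000; square grids 10–16; alpha
pairs (0.05, 0.01), (0.05, 0.001), (0.01, 0.001), (0.1, 0.05);
thresholds 0.5 and 0.7. The overflow audit is pure arithmetic on
(rlen, n) and never touches the data; `declared_n_cells` lets a sweep
on a down-sampled matrix audit the full dataset's size.

## Preprocessing

The standard chain is arcsinh (`asinh(x / cofactor)`, cofactor 5 — the
CyTOF convention) followed by per-channel standardization. The
standard deviation uses the sample convention (divisor n − 1), fixed
and documented here because either convention is defensible.
Zero-variance channels are mapped to all zeros with a warning instead
of NaN so downstream training stays finite. Scaling statistics are
computed over whatever matrix is given (pooled, if samples were
concatenated). Down-sampling is uniform without replacement,
seed-deterministic, preserving original row order so downstream
set-based metrics are order-independent.
`plan_downsample_for_limit(m, B)` returns `round(B / m)` — the cell
count whose `cells × channels` product fills an element budget, e.g.
`round(2³⁰ / 39) = 27,531,842`.

FCS 3.0/3.1 reading/writing is implemented directly (list-mode,
float/double data): no installed dependency covers the format, and
the reader deliberately indexes with 64-bit offsets so matrices with
more than 2³¹ − 1 elements load correctly. Compensation, bead
normalization and gating are out of scope; marker channels are chosen
by an explicit user-supplied list, never heuristically.

## Synthetic data

The generator draws Gaussian mixtures **directly in arcsinh space**
with diagonal covariance: population means are then known in closed
form and every metric has an exact oracle. The default panel has 13
PBMC-like populations over 39 channels — lineage markers
(CD3/CD4/CD8a/CD19/CD56) follow canonical phenotypes, each population
adds a fixed multi-marker signature on ~10 further channels, per-
channel sd 0.3, proportions from 22% down to two rare 0.5% subsets.
The multi-population signature structure is what anchors SOM nodes in
real cytometry data; a featureless blob would make node placement
arbitrary and stability unmeasurable.

The contamination scenario replaces the panel's naive CD4/CD8 T cells
with a pair separated by 4.5 sd on the two designated channels (CD4,
CD8a — each clearly bimodal in the pooled data) while the minor
channels carry most of the per-cell variance (sd 0.6 vs 0.4). An
untrained codebook of raw sampled cells attracts these cells by noise
rather than phenotype, so under-trained maps mix the pair inside
nodes; trained codebooks average the noise away and separate them.

What the generator does **not** emulate: ion-count statistics,
spillover, batch effects, acquisition-time drift, doublets, and the
density continua of real differentiation trajectories. Passing tests
show the algorithms behave correctly under known ground truth; they do
not certify stability levels on any real dataset — stability must be
re-measured per dataset with the sweep.

## Problem sizes and test design

Simulation-backed checks run at 10,000 cells (trend and matching
properties: 12 × 12 or 10 × 10/16 × 16 grids, rlen ladders up to 80),
with 5–10 fixed seeds per property; metric identities are verified
against brute-force set arithmetic on 30-cell instances across 100
seeds. These sizes were chosen as the smallest at which the
qualitative parameter dependences are reliably expressed. Trend
properties are asserted in ≥ 80% of seeds, because they are genuinely
stochastic orderings, not invariants. At 10,000 cells absolute
stability stays modest even at the ladder top (AMJI ≈ 0.3) — small
datasets are exactly the regime where default settings are unreliable,
and the package's recommendations are relative to a dataset's own
plateau, not to an absolute stability level.

## Known limitations

- Online (not batch) SOM only; no minimum-spanning-tree or further
  visualization.
- The plateau rule is a heuristic; on curves whose dynamic range is
  comparable to epsilon the recommendation degenerates to the first
  ladder value.
- Metacluster-count selection is not addressed (the cap is 80).
- FCS integer data types and FCS 2.0 dialects are unsupported.
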