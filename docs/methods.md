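# Methods

## The measurement being modelled

One GC→PC connectivity map is a grid of mean evoked EPSC amplitude
magnitudes (pA) over photostimulation sites in the granular layer: 6 rows of
20 × 20 µm sites (high resolution) or 4 rows of 40 × 40 µm sites (low
resolution), up to 1280 µm wide along the mediolateral axis. Each site is
stimulated 5–10 times; the per-site mean is the map entry. Spontaneous
activity measured at every site pools into a map-wide noise distribution
with mean `X` and SD `σ`, and a site is connected when
`z = (A − X)/σ ≥ 3`. At the default noise model this threshold corresponds
to ≈ 15 pA. Stimulating one 20 µm site excites ≈ 76.8 granule cells
(≈ 384 at 40 µm) at the granular-layer density of 1.92 × 10⁶ cells/mm³,
using the effective stimulated volumes of 4 × 10⁻⁵ and 2 × 10⁻⁴ mm³; an
explicit depth argument switches to the geometric `side² × depth` volume.

Maps from different animals are aligned in a zebrin coordinate frame: seven
parasagittal bands (P2−, P2+, P1− contralateral, P1+, then P1−, P2+, P2−
ipsilateral) whose widths are sampled from printed adult means ± SD (e.g.
P1+ 34.63 ± 16.18 µm, ipsilateral P1− 320.46 ± 60.54 µm). The origin is the
centre of P1+ (the band straddling the midline), ipsilateral positive, and
positions are reported as % of the ipsilateral P1− width. Positions exactly
on a band boundary belong to the band on the ipsilateral side.

## Profiles, group summaries, numerical choices

* **Profiles** are per-column maxima: maximum z (connectivity flags) or
  maximum significant amplitude (weight-bearing outputs: cumulative curves,
  zone weights). A column is connected iff any of its sites reaches z ≥ 3.
* **Median profiles**: each profile is linearly interpolated to a 1 µm grid,
  convolved with a unit-area triangular kernel (half-width 9 µm high-res /
  18 µm low-res; edges padded by replication so constants pass through
  exactly), mapped to normalised coordinates, then the pointwise median and
  MAD are taken where at least half the maps overlap.
* **Averaged maps** pool site values in 30 µm (high-res) or 60 µm (low-res)
  bins on the normalised axis, per row. Empty bins are missing (NaN), never
  zero, to avoid biasing group means. Any display smoothing is excluded
  from numeric outputs.
* **Cumulative strength** is the running sum of connected-column maximal
  weights from the contralateral end, in nA; non-connected columns add 0,
  so curves are non-decreasing by construction.
* **Downsampling** 20 µm → 40 µm is a 2×2 block mean (odd shapes
  edge-replicated), which conserves block sums exactly (×4).
* **Group-level profile CIs** resample maps with replacement (percentile
  bootstrap of the pointwise median); the resampling unit is the map. A
  position is group-connected when the CI lower bound exceeds 0. This is a
  design choice — other resampling units would be defensible.

## Graph representation and metrics

Edges are Pearson correlations between raw column amplitude vectors,
clipped: negatives and undefined correlations (constant columns) become 0,
self-links are 0. Because z-scoring is affine per map, building the graph
from z maps would give the identical adjacency (tested). At least 3 rows per
column are required for a meaningful correlation.

Modules come from seeded Louvain (resolution 1, best of 20 restarts)
followed by a deterministic greedy single-node-move refinement: Louvain's
aggregation can lock a node into a community that a single reassignment
would improve, and the refinement removes exactly that residue (on all
tested ≤ 8-node map-derived graphs the refined result equals the exhaustive
optimum). Ties between restarts break toward fewer modules, then the
lexicographically smallest assignment, so results are reproducible.

The four weighted metrics use the ordered-pair convention (`l^w` = total
double-counted weight):

* modularity `Q^w = (1/l^w) Σ_ij [w_ij − k_i k_j / l^w] δ(m_i, m_j)`;
* module-degree z-score, with z = 0 for singleton or zero-spread modules so
  homogeneous modules contribute neutrally to medians;
* participation `y_i = 1 − Σ_m (k_i(m)/k_i)²`, 0 for isolated nodes;
* assortativity as the weighted degree–degree correlation over links,
  returned as NaN (not an exception) on regular graphs where the variance
  term vanishes. Lateralised values evaluate the same formula on the
  induced ipsi-/contralateral subgraphs.

Null models rewire edge pairs (a,b),(c,d) → (a,d),(c,b) when the target
slots are empty, 10 attempts per edge, carrying weights along; the binary
degree sequence is preserved exactly and total weight conserved. Ensembles
default to ≥ 10 instances; Δ% divides by the ensemble median with a 1e−12
guard (NaN when degenerate). Graphs with < 2 edges return unchanged with a
warning flag.

Feature schemes: `g_global` = [Q, median z, median y, r] (4-dim);
`g_bilateral` = [Q, (median z, median y, r) per side] (7-dim);
`g_zonewise` = per-zone medians of z and y plus per-zone subgraph
assortativity (the zone-wise reduction is not uniquely pinned down by a
stated dimension, so the flattening is configurable); `g_weights_zonewise`
= per-zone mean significant weight normalised by the map-wide mean
significant weight (8 structural zones). Empty zones yield missing entries,
imputed downstream by training-split medians.

## Zoning and mutual information

Structural zones label each column by its zebrin band; the default template
is the seven printed bands, with an optional eight-zone template splitting
the ipsilateral P1− band at its midpoint into medial/lateral halves (the
exact split underlying an eight-zone anatomical parcellation is not fully
specified, so the template is configuration-driven). Functional zones come
from the module partition either as maximal contiguous runs (α1, β1, α2, …)
or as bare module labels (α, β, …). MI uses natural logarithms and plug-in
frequencies, normalised by max(H(X), H(Y)) so 1 means identity up to
relabeling. Chance permutes structural labels per column (a block-rotating
variant is available for contiguity-preserving nulls) and reports the 95%
percentile interval.

## Behavior

Per-trial balance index is `log10(∫left/∫right)` (base 10 chosen as the
convention; all identities are base-covariant). Trials need ≥ 5 strides and
positive integrals; a session needs ≥ 3 valid trials, else it is a missing
datapoint. Time courses are baseline-subtracted (mean pre-surgery BI) and
summarised by the value nearest day 15 and trapezoidal AUCs over half-open
phase windows; both the 0–9/9–21/>21-day and the 0–4/4–21/>21-day
conventions ship as options, defaulting to the former. Wheel training
reduces to total distance and the OLS slope of distance vs session. The
logistic group-curve fit is a display helper only.

## Classification and GLM protocols

Random forest: 150 trees, max depth 30, 100 stratified 80:20 trials;
features are standardised on the training split (missing entries imputed by
the training median). The chance baseline permutes training labels on the
identical split (a global-permutation option exists; the within-fold
variant is the default). Confusion matrices aggregate held-out predictions,
rows normalised.

GLM: Gaussian family, identity link, design `[1 | G | T·G]`, 100 random
75:25 trials, scoring held-out Pearson r and MSE, with a shuffled-target
baseline on shared splits. GLM features are rescaled but **not** centred:
centring a feature that also enters the `T·G` interaction would introduce a
bare group-offset term outside the model class and break exact noise-free
recovery. Rank-deficient training designs are fitted (pinv) and flagged.

A note on chance levels: with seven groups sized 14/13/11/11/25/14/17 the
prior-matching oracle is Σ(nᵢ/N)² ≈ 0.156. The measured protocol chance
sits slightly higher (≈ 0.17–0.19) because deep forests trained on permuted
labels skew predictions toward the majority class; this is a property of
the protocol itself, reproduced by `scripts/acceptance.py`, not a defect of
the implementation.

## Synthetic cohorts: what they emulate, and what they do not

Defaults mirror the high-resolution study conditions: seven locomotor groups
with 14/13/11/11/25/14/17 maps (105 total), 6 × 64 grids at 20 µm,
zebrin geometries from the printed band statistics, PC positions from
52.42 ± 29.8 µm clipped to [0, 130] µm. Patches are jittered ellipses whose
centres follow a Gaussian-mixture prior along the mediolateral axis (one
component is the recurrent hotspot ≈ 500 µm ipsilateral); patches are added
until the condition's target active fraction (9.9–16.5%) is reached.
Active-site amplitudes are drawn from a left-truncated lognormal (floor at
the ≈ 15 pA significance threshold) whose truncated mean is solved to match
the condition's printed significant-weight mean (e.g. control 72.3 ± 50 pA)
— lognormal because the printed distributions are strongly right-skewed
(mean ≫ median). Noise is i.i.d. Normal per site (mean 4.5 pA, SD 3.5 pA,
trial-to-trial evoked SD 8 pA), placing z = 3 at ≈ 15 pA. Behavior couples
to four deterministic map summaries through the planted interaction GLM
with configurable coefficients and noise.

The generator does **not** emulate: temporal current waveforms, per-site
noise heteroscedasticity, spatial correlation of noise, multi-map animals,
or any true dependence of patch geometry on condition beyond amplitude and
active-fraction differences (the empirical patch-size distribution is
unknown; defaults are tunable, not fitted). Passing tests therefore show
that the estimators recover planted structure under the stated statistical
assumptions — not that real maps satisfy those assumptions, and not that
real-data effect sizes (e.g. the 0.51 actual-label classification accuracy,
or the 50–57% structural/functional overlap) are reproduced, since those
depend on the original recordings.

## Problem sizes used by the test suite and acceptance script

Cohort-level tests run on 9–15-map cohorts; oracle-equivalence suites use
100 random weighted graphs (n ≤ 12) and exhaustive partition searches on
8-node map windows; null-model self-consistency uses one 64-node map graph
with 50 rewired instances (leave-one-out Δ%); GLM recovery uses n = 30 maps,
6 features, 50 replicates; the chance-level protocol uses the full 105-map
group structure with 6 independent permuted cohorts. These sizes keep every
stage's statistics interpretable while the whole suite remains quick to run.
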