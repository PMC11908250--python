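# Methods

## The model and what it is for

`momirf` selects *cross-correlated* features across two or more omics
matrices measured on the same samples — the variables in each layer that
load on structure shared between layers.  The engine is a multivariate
random forest (MRF): one omics matrix plays the predictor role `X` (n × p),
another the response role `Y` (n × q), and each node split is chosen to
maximize the summed per-response statistic

    Gq*(s, t) = Σ_j G_j,
    G_j = (Σ_{i∈L} y*_ij)² / n_L + (Σ_{i∈R} y*_ij)² / n_R,

where `y*` is the response standardized *within the node* to mean 0 and
mean-square 1.  Maximizing `Gq*` is algebraically identical to minimizing
the summed within-daughter sums of squares of the standardized responses;
the per-node standardization keeps every response on the same scale so that
no single outcome dominates the split.  The response achieving the largest
`G_j` at a split is recorded as that node's **maximal splitting response
variable (MSRV)**.  MSRV labels are the device that lets *response*
variables be ranked by tree topology, exactly as split variables rank
predictors.

**Inverse minimal depth (IMD).**  A variable's minimal depth in a tree is
the shallowest depth at which it appears (as split variable or as MSRV);
its IMD is `1/(depth+1)`, and exactly 0 when it never appears.  The forest
IMD is the mean over trees (zeros included).  Strong variables have high
IMD; in high dimension the IMD of noise variables piles up just above 0,
which is what the three selection rules exploit.  The reference
distributions of minimal depth for a weak variable under balanced-tree
assumptions (`weak_md_pmf`, `md_pmf`) are provided for analysis; they are
not used by the selectors, because with p ≫ number of nodes all their
probabilities vanish.

**t-score IMD.**  `t_v = (IMD_v − μ) / SE_v`, with μ the mean forest IMD
over all variables of the same side and `SE_v` the standard error of the
per-tree IMDs (s.d. across trees divided by √B).  Variables with zero SE
get t = 0 when they sit at μ and ±∞ otherwise (they are decisively
classified).  Predictor-side and response-side profiles are never pooled
into one μ.

## Selection rules

* **filter** — keep variables with forest IMD > τ·σ, σ being the s.d. of
  forest IMD across the variables of that side.  τ is tuned on the grid
  0.1, 0.2, …, 3.0: for each τ the forest is refitted on the kept
  variables (`k_repeats` times, default 5; fresh seeds) and the mean OOB
  error recorded.  The kept-set mean OOB error *decreases monotonically in
  τ* — stricter filtering conditions on ever more predictable variables —
  so the curve's minimum cannot locate the right model.  τ is instead
  chosen at the **knee** of the curve (the grid point with the largest
  vertical drop below the chord joining the first and last evaluated
  points): beyond the knee, pruning buys no real error reduction.  Two cost
  controls exist: tuning refits may use a smaller forest (`tuning_ntree`),
  and τ values keeping more than `refit_max_frac` (default one half) of all
  variables reuse the base model's error, since that part of the curve is
  flat and its refits are by far the most expensive.

* **mixture** — a zero-inflated two-component Gaussian mixture is fitted to
  the forest IMD of one side: a point mass `p0` at 0 (the exact empirical
  zero fraction) plus densities `p·f1 + (1−p)·f2` on the nonzeros, fitted
  by EM (tolerance 1e-6, ≤1000 iterations, deterministic initialization by
  a 75th-percentile split of the nonzeros).  Components are relabelled so
  component 1 has the smaller mean (noise).  Variables whose posterior
  probability of the noise component is below `pr` (default 0.05) are
  selected; zero-IMD variables belong to the zero atom and are never
  selected.  A truncated-normal variant (noise density renormalized on
  (0, ∞)) is available; its likelihood is mechanically a little higher
  whenever μ1 ≈ 0, but both variants land on near-identical components and
  the plain Gaussian is the default.

* **transformation** — select variables with t-score IMD above the
  magnitude of the Student-t 0.05-level quantile with `ntree − 1` degrees
  of freedom (≈1.66 at B = 100).  The literal lower-tail cut (which keeps
  nearly everything) is available via `tail="lower"` for comparison.

## Out-of-bag errors

Responses: a sample's OOB prediction is the bootstrap-weighted terminal
mean of the in-bag members, averaged over the trees where the sample is
out-of-bag.  Predictors have no direct prediction path and are scored
through *forest weights*: each OOB tree contributes a distribution over its
in-bag samples proportional to bootstrap multiplicity within the OOB
sample's terminal node; pooled over trees and row-normalized, these weights
give `X̂_i = Σ_k w_ik X_k`.  Per-variable errors are mean squared
differences over covered samples; the mean OOB error averages all p + q of
them and drives both τ tuning and direction ranking.  Samples never OOB
(possible at very small B) are dropped, not imputed.

## Multi-dataset orchestration

With K datasets the model collection M contains exactly one model per
response dataset.  For K = 2 the only candidates are the two directions, so
both are fitted on full features.  For K ≥ 3 every ordered pair is first
scored on PCA-reduced matrices (components up to 80% cumulative variance by
default) by mean OOB error, and the best predictor per response is refitted
on full features — PCA is a screening device only; selection always runs on
full-feature forests.

A dataset's aggregated profile pools the per-tree IMD matrices of every
model it appears in (response side in one, predictor side possibly in
others), so the mean IMD is the mean over appearances and the t-score SE is
taken across the pooled trees.  Filter and mixture run on this pooled
profile; the transformation rule also thresholds the pooled profile by
default — a per-model majority vote (`trans_vote=True`) is available, but
at K = 2 a strict majority degenerates to the intersection of two
selections and is far too conservative, while the pooled t-score uses the
same evidence coherently.

## Synthetic data

Two generators define the benchmark conditions.

*Latent model.*  One latent vector `u ~ N(0, σ_u²)` (σ_u = 2) is shared by
all datasets; dataset m is `g_m(u) w_mᵀ + ε` with kernels `u²`, `exp(u)`,
`u` for datasets 1–3, weights with only the first `p_c[m]` entries nonzero
(U(−1,1), normalized to unit sum of squares), and i.i.d. Gaussian noise
with s.d. 0.3.  Columns are standardized to mean 0 / s.d. 1 (ddof = 1, the
R convention).  The truth mask is the first `p_c[m]` columns.  `p_c = 0`
yields a pure-noise dataset (the latent term is dropped), used for null
calibration.

*Non-linear regression model.*  `p_l = 2·p2c` standard-normal basis
variables; each spawns g predictor copies `U_i + (0.01 + 0.5(j−1)/(g−1))·ε`
(plain `U_i + ε` at g = 1), and each response combines a basis pair through
`0.25·exp(4u_a) + 4/(1+exp(−20u_b)) − 0.5`.  Basis pairs are consecutive
(`u_{2k−1}, u_{2k}`) by default; a 3k-strided indexing is available but
inconsistent with `p_l = 2·p2c` and therefore not the default.  Independent
N(0,1) noise columns are appended to both sides.

What the generators do *not* emulate: within-layer correlation beyond the
shared latent factor, heavy-tailed or count-valued measurements,
batch/technical effects, and missingness.  Passing benchmarks here shows
the machinery recovers planted cross-layer structure at realistic
dimensions — not that it is robust to every artifact of real assays (real
inputs must be complete; validation rejects missing values).

## Defaults and numerical choices

| parameter | default | why |
|---|---|---|
| ntree (B) | 100 | forest size used throughout the benchmarks |
| mtry | ⌈p/3⌉ | regression-forest convention |
| nodesize | 5 | regression-forest convention |
| nsplit | 10 | random cut points per candidate, the rfsrc-style default; `0` = exhaustive search (used by the oracle tests) |
| resp_frac | 1.0 | score all responses per split; lowering it trades fidelity of MSRV labels for speed in very wide response matrices |
| τ grid | 0.1 … 3.0 step 0.1 | filter tuning range |
| k_repeats | 5 | tuning refits per τ (benchmarks use 3, see below) |
| pr | 0.05 | mixture posterior cutoff |
| alpha | 0.05 | t-score tail level |
| var_threshold | 0.8 | PCA cumulative-variance cut for direction screening |

Tie-breaks are deterministic everywhere: candidate predictors are scanned
in ascending index order, cut points left to right, MSRV argmax takes the
smallest index.  Per-tree seeds derive from the forest seed via
`SeedSequence.spawn`, so forests are schedule-independent and two fits with
the same parameters are bit-identical.  Within-node standardization treats
columns with within-node sum of squares below 1e-24·m as inert (zero
contribution).  EM convergence is |Δloglik| < 1e-6 with a σ floor of 1e-6;
the truncated M-step is a generalized EM step (Nelder–Mead on the weighted
truncated-normal likelihood, never accepted if it degrades the objective).

## Benchmark problem sizes

The built-in benchmark scenarios are the two-omics latent settings
S1 (n = 100, p = q = 200, 20 true per dataset) and S2 (n = 200,
p = q = 500, 30 true per dataset), run at 20 and 10 replicates with
B = 100.  Benchmark runs use `k_repeats = 3` and `tuning_ntree = 50` for
the filter's τ-tuning refits: the knee of the error curve is stable under
both choices, and they keep a full benchmark run on one core in the tens of
minutes.  Metrics: recall, precision (both averaged over datasets), PR-AUC
(average precision of the ranking each rule actually thresholds — mean IMD
for filter/mixture, t-score for transformation — averaged over datasets),
and model size (selected variables summed over datasets).

## Known limitations

* The filter's τ rule (knee detection) is this package's operationalization
  of "a tolerable error deviation"; other stopping rules move the selected
  model size by ±20%.
* Predictor-side IMD from a single direction model is noticeably less
  stable than response-side IMD; per-dataset rankings should always come
  from the pooled profile over M, never from one side of one model.
* OOB forest weights are pooled over trees before normalization; a
  per-tree-region restriction would be a different (also defensible)
  estimator.
* No missing-value handling, no survival or classification splitting.
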