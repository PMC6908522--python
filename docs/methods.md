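# Methods

This note documents the models implemented in `coexmeta`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic data
do and do not establish about real data.

## Normalization

**QC.** Per-sample medians, IQRs and missing fractions are summarized; a
sample is flagged when its median lies outside the Tukey fence
(Q1 − 1.5·IQR, Q3 + 1.5·IQR) of all sample medians. The matrix is guessed
to be on a log-like scale when its maximum is below 30 (log2 microarray
data rarely exceed ~20); log-like input skips calibration and the glog and
is passed through, which is logged. The threshold is overridable.

**Between-sample calibration.** The reference profile is the per-feature
median across samples. Each sample is regressed on the reference
(`y ≈ a_j + b_j·ref`) over features whose reference value lies in the
[5th, 95th] percentile band, and replaced by `(y − a_j)/b_j`. The fit is an
iteratively trimmed least squares (3 passes, trimming the 20% largest
absolute residuals): with a plain fit, a minority of strongly differential
genes acts as high-leverage points, drags the slope of the affected group's
samples, and imprints a spurious group-coherent shift on *every* gene —
measured here as hundreds of false DEG calls on a planted simulation, and
the reason production variance-stabilization methods use robust (least
trimmed squares) regression in exactly this place. On exactly affine data
the trimming is a no-op and (a, b) are recovered to machine precision.
Slopes must be positive and finite; a constant reference is rejected.

**Generalized log.** `h(y) = log2((y + √(y² + c²))/2)` is strictly
increasing, finite for all real y (including small negatives produced by
calibration), equals `log2(c/2)` at 0, and converges to `log2(y)` for
y ≫ c (|h − log2 y| ≤ 1e−3 at y/c ≥ 100). The constant c is auto-selected
as `σ_add/σ_mult`: the scaled MAD of per-feature-centered intensities among
the bottom-decile features (additive noise scale) divided by the median
per-feature SD of log intensities among the top-decile features
(multiplicative scale). This is the intensity at which the two noise
regimes cross — the canonical glog crossover — and on the additive +
multiplicative simulation it reduces the max/min per-decile SD ratio from
> 5 to ≈ 1.1, where an additive-scale-only choice (a plain MAD of the
low intensities) leaves it at ≈ 2. The full maximum-likelihood
variance-stabilizing fit is deliberately replaced by this closed-form
calibration + glog procedure: it targets the same error model with fully
specified, testable arithmetic.

## SAM differential expression

Per feature, `d_i = (x̄_case − x̄_ctrl)/(s_i + s0)` with the pooled
two-group standard error `s_i = √(a·(SS_case + SS_ctrl))`,
`a = (1/n₁ + 1/n₂)/(n₁ + n₂ − 2)`; with s0 = 0, d is exactly the pooled
two-sample t statistic (tested to 1e−12). The fudge factor s0 is the
s-quantile α ∈ {0, 0.05, …, 1} minimizing the coefficient of variation of
window-wise scaled MADs of d(α) over up to 100 equal-count windows of s;
ties break to the smallest α, and if all s are equal s0 = 0 with a warning
(the choice is vacuous there). A user-supplied s0 bypasses estimation.

The null is a pooled permutation null: B distinct group-label assignments
(the identity excluded; reduced to the exhaustive count when
C(n, n₁) − 1 ≤ B, which is logged), and
`p_i = (1 + #{(b,j): |d_jb| ≥ |d_i|})/(1 + mB)`. The +1 smoothing avoids
zero p-values; |d| values are rounded to 12 decimals before comparison so
exact ties (e.g. the complement of the identity assignment) are counted
consistently. Pooling across features gives resolution 1/(mB) and matches
standard SAM practice. B defaults to 1000 stand-alone and 200 in the
pipeline and calibration simulations — the permutation p floor 1/(mB) is
then far below the q-threshold at m = 800–1000 genes, and null-calibration
checks (call rate under the global null, KS distance of p from uniform)
pass at that resolution.

Storey q-values use a single λ = 0.5: `π0 = min(1, #{p > λ}/(m(1 − λ)))`,
not floored, with the step-up `q_(i) = min_{j≥i} π0·m·p_(j)/j` capped at 1;
with π0 = 1 this reduces to Benjamini–Hochberg. Genes are called at
q < 0.01. The called set additionally carries a study-level estimated FDR,
`π0 · median_b #{|d_null| ≥ cutoff} / #called` with the cutoff at the
smallest called |d|; a set whose estimate exceeds the 15% ceiling is kept
but flagged non-conforming, since a hard joint rule is not well defined
when the two criteria disagree.

## Consensus winner genes

Probe-level results collapse to gene level by the probe with maximum |d|
(ties to the lexicographically smallest probe label). The direction matrix
holds {+1, −1, 0} per gene × study (0 = not called); genes absent from a
study's platform count 0 — non-support, not missing-excluded — and are
tracked in a separate mask. A gene wins in direction σ iff it carries σ in
≥ `min_total` (7) studies overall and ≥ `min_lc` (5) LC studies. Under the
6 LC + 4 LD design this forces ≥ 1 LD study at 6 LC supports and ≥ 2 at 5,
i.e. the "total plus LC quota" arithmetic subsumes any separate LD quota;
the two readings coincide for this design. `min_total` > #studies/2
guarantees the up/down winner sets are disjoint. The rule is verified
exhaustively against a brute-force restatement over all 3¹⁰ patterns.

## Coexpression networks and CCPs

Similarity is |Pearson r| over all samples of a study; zero-variance genes
are dropped with a warning. Edges use the closed rule |r| ≥ τ so τ = 1
keeps perfectly correlated pairs; network nodes are edge endpoints only
(isolated genes excluded). C(τ) is the mean local (Watts–Strogatz)
clustering coefficient over nodes of degree ≥ 2 — common coexpression
practice; global transitivity is not used. The random expectation is the
G(N, p) edge density C₀ = 2E/(N(N−1)). The scan covers τ ∈ [0.50, 0.99]
in 0.01 steps; τ* is the smallest grid point that is a local maximum of
D = C − C₀ within ±5 grid steps and whose network keeps ≥ 10 edges,
falling back to the global argmax subject to the edge minimum, then to an
error. Window, grid and edge minimum are all configurable; the selection
rule itself is fixed here because only the comparison (observed vs random
clustering) is canonical, not the decision rule. On planted-block data D
is unimodal with its peak between the between- and within-block
correlation levels, and the network at τ* recovers the planted
within-block edges with Jaccard ≥ 0.8.

A CCP is the label-matched edge intersection of two networks; its nodes
are the shared edges' endpoints (degree-0 shared genes are not CCP nodes).
In the pipeline each network is built at its own study's τ*, the network
study defaults to the first LC study, and one CCP is computed against each
LD network. Hub ranking is by descending degree with lexicographic ties.

## Enrichment

Over-representation uses the upper-tail hypergeometric probability
(computed by scipy in log space) of overlap k between an n-gene list and a
K-gene set in an N-gene universe. The universe defaults to the genes
present after filtering, not the whole genome. Sets with k = 0 are
omitted from the output and from the BH family (mirroring common
annotation-service behavior); BH adjustment is applied over the emitted
rows and significance is flagged at p_adj ≤ 0.05. An optional EASE-style
variant substitutes k − 1 for k (more conservative); it is off by default.

## Survival

Patients split at the median of a gene's expression; strictly greater
values are "high", ties go to "low" (a fixed, documented cutoff policy —
no "best cutoff" search, which inflates type-I error). Kaplan–Meier
estimation and the log-rank test delegate to lifelines. The Cox model is
fit by Newton–Raphson on the Breslow-ties partial likelihood (Efron
available behind a flag), with step halving, tolerance 1e−8 on the
coefficient change, at most 50 iterations, covariate centering, and
detection of rank-deficient designs and monotone likelihood (perfect
separation). Inference is Wald: SEs from the observed information,
HR = exp(β) with 95% CI exp(β ± 1.96·SE) — matching the HR (CI) reporting
convention of survival-lookup services. The implementation agrees with an
independent score-equation solution to 1e−6 and with lifelines to ~1e−3
(the residual is Efron-vs-Breslow tie handling).

## Synthetic data

`gen_expression_study` draws raw intensities `y = α + μ·e^η + ε` with
per-gene log-normal baselines μ (meanlog 6, sdlog 1), background α = 30,
multiplicative noise η ~ N(0, 0.25²), additive noise ε ~ N(0, 15²), and a
positive clipping floor of 0.5 mimicking scanner output. Planted winners
receive a case-group fold change 2^(±effect_size) (→ a ±effect_size shift
in glog2 units at high intensity); the direction of each winner is fixed
globally so cross-study consistency is by construction, and each study
perturbs a winner with probability `winner_penetrance`. Default study
sizes follow a typical published ten-study lung design (six LC pairs
60/60, 49/58, 5/5, 9/54, 18/22, 30/30; four LD pairs 12/42, 12/18, 11/13,
11/15). Defaults are effect_size = 2.0 (a 4-fold change) at penetrance 1.
The SAM operating characteristics are measured at effect 1.5 with 10%
non-null genes. Effect sizes in real meta-analyses are heterogeneous and
unknown; these values were chosen once for testability, not fitted to any
dataset.

The end-to-end exact-recovery check runs the collection in an
*effect ≫ noise* regime (the 4-fold change against reduced noise,
additive sd 5 and multiplicative sd 0.1), where recovery measures the
correctness of the pipeline plumbing rather than per-study power. At the
default noise levels the smallest study (5 + 5 samples) is power-limited
for down-regulated genes whose shifted intensities sit near the additive
floor, so a few such genes can miss the consensus quota depending on the
seed. Notably, raising the effect size does not help: at 8–16-fold the
planted genes remain strongly bimodal under label permutation and fatten
the pooled permutation null, which then drowns the weaker calls — a known
property of pooled-null moderated statistics under many strong signals.

`gen_coexpression_pair` uses a latent-factor block model on the glog2
scale: gene i in block b is `x = μ_i + λ·f_b + e`, with
λ = σ·√(r/(1−r)) hitting the target within-block correlation r and block
factors sharing a common component so between-block correlation targets
its configured value. Non-shared blocks lose their factor in the second
study (genes become independent noise), so only shared blocks can
contribute CCP edges.

`gen_survival_cohort` assigns exponential event times with hazard ratio
`true_hr` between the high and low expression halves (baseline rate 0.1)
and independent uniform(0, c) censoring with c solved numerically per
group so the expected censored fraction equals `censor_rate`.

One root seed spawns per-study child seeds through
`numpy.random.SeedSequence.spawn`, so generation is a pure function of
seeds and appending a study never changes earlier ones.

**What the synthetic data omit.** Per-sample global scale effects,
batch/platform effects, probe-level artifacts, correlated noise between
genes outside the planted blocks, non-exponential hazards and informative
censoring. Passing tests therefore establish the *statistical machinery*
(calibration under the null, recovery under planted signal, exact
agreement with brute-force oracles), not performance on any real cohort;
in particular the normalization's robustness margin is only exercised
against the simulated DEG fraction (~9%), and heavier contamination would
require a larger trim fraction.

## Numerical choices and degenerate inputs

- Writers emit 6 significant digits, fixed ordering: byte-identical files
  for identical objects; the pipeline manifest records SHA-256 of every
  output, and re-runs from the same seed reproduce all hashes.
- d = 0 is reported (not an error) when both the mean difference and the
  pooled spread vanish; a non-zero difference over a zero denominator is
  an error naming the features.
- Down-regulated genes with small baselines approach the additive noise
  floor where the glog compresses differences; detecting them needs more
  samples than equally-shifted up-regulated genes. This is a property of
  the intensity model, not a defect, and sets the sample sizes used in the
  end-to-end tests (≥ 15 per group at 200 genes).
- Empty DEG call sets have estimated FDR 0; empty CCPs are legal; an empty
  similarity scan or a scan whose every network is below the edge minimum
  raises with advice.
- The log-rank test requires at least one event; Cox fits require ≥ 1
  event and a full-rank design.

## Known limitations

- The consensus step is vote counting; no effect-size pooling or p-value
  combination across studies.
- Only two-class unpaired SAM; no Wilcoxon variant, multi-class or paired
  designs.
- Enrichment is set-based over-representation; no ontology-graph
  propagation, no motif/PSSM scanning for TF-binding evidence — TF
  regulons enter as user-supplied GMT target sets.
- Survival handles right censoring only; no time-dependent covariates or
  competing risks.
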