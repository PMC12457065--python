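# Methods

This note documents the statistical models the package implements, the
choices made where the underlying methodology leaves room, and what the
synthetic-data world does and does not establish.

## 1. Growth mixture model

### Model and parameter structure

Subject trajectories over T = 3 annual waves follow a K-class linear
growth mixture: given class k, y_i ~ N(Xμ_k, XΣXᵀ + diag(θ)) with
X = [1 | t], t = 0, 1, 2 (the intercept is wave-1 status). The
random-effect covariance Σ (2×2) and the wave-specific residual variances
θ are shared across classes, so each extra class adds exactly three
parameters (α_k, β_k, π_k): p = 3K + 5. This structure is not an arbitrary
choice — inverting AIC − aBIC = 2p − p·ln((n+2)/24) on the published
1-class and 2-class fit-index pairs at n = 1277 yields p = 8 and
p = 11 to within rounding, which identifies the class-invariant-variance
model uniquely among the usual alternatives. Class-specific variance
structures are deliberately not implemented (they would change the
parameter count the enumeration logic relies on).

### Estimation

ECM over the full latent structure (class indicator + subject random
effects):

* E-step: class posteriors r_ik from the marginal Gaussian mixture;
  random-effect conditional moments m_ik = ΣXᵀV⁻¹(y_i − Xμ_k) and shared
  conditional covariance C = Σ − ΣXᵀV⁻¹XΣ (these forms stay valid when Σ
  is singular, which matters in near-noise-free limits).
* CM steps: π from posterior means; μ_k by θ-weighted GLS of the
  random-effect-adjusted class means; Σ as the posterior-weighted second
  moment of random effects plus C; θ from residuals under the updated μ.

The observed-data log-likelihood is computed every iteration and asserted
non-decreasing (tolerance 1e-6 relative); a decrease raises immediately
rather than returning a silently wrong fit. Convergence is relative
log-likelihood change below 1e-8 (default), at most 500 iterations.
Because ECM converges linearly, oracle comparisons against a generic
optimizer of the same closed-form likelihood use a tightened tolerance.

Starts: a deterministic Lloyd k-means on per-subject OLS (intercept,
slope) pairs seeds the first start; subsequent starts re-assign each
subject with probability 0.2. The reference procedure uses 200 random
starts; that is the default, but the default synthetic world is separated
enough that a handful of starts always reaches the same optimum, and the
tests/scripts use 2–20 starts accordingly. Degenerate starts (a component
expecting fewer than one subject) are dropped and refit from the next
start. Class labels are canonicalized by descending intercept, so class 1
is always the high-starting ("high-risk") class.

Floors: θ ≥ 1e-10; Σ symmetrized each iteration (it is PSD by
construction of its update).

### Fit battery and enumeration

AIC = −2ℓ + 2p; aBIC = −2ℓ + p·ln((n+2)/24) (the standard sample-size
adjustment); entropy = 1 − Σ_ik(−p_ik ln p_ik)/(n ln K), reported only for
K ≥ 2; smallest-class size from modal assignment. BLRT: 2(ℓ_K − ℓ_{K−1})
referred to its parametric-bootstrap null (data simulated from the fitted
K−1 model, both models refit per replicate with the same settings),
add-one p-value (1 + #{T_b ≥ T_obs})/(B + 1). Because add-one p-values
reach exactly 1/(B+1), significance is judged as p ≤ α.

The LMR adjusted LRT is implemented as a documented approximation:
statistic 2Δℓ / (1 + 1/(d·ln n)) with d = 3 extra parameters, referred to
χ²_d. The true limit is a weighted chi-square mixture; the chi-square
reference is known to be liberal, so the BLRT — fully specified by its
resampling definition — is the authoritative test here, and the LMR value
is reported for completeness only.

Model selection: recommended K is the largest K whose solution converged,
whose BLRT against K−1 is significant, whose aBIC improves on the
(K−1)-class model, and whose smallest class holds at least 5% of the
sample (configurable); K = 1 is the always-admissible baseline. This
encodes the reference logic (substantial information-criterion reductions
backed by BLRT, interpretable class sizes, parsimony). The aBIC condition
matters in practice: the BLRT p-value for K vs K−1 is uniform when K−1 is
the truth, so on its own it admits a spurious extra class in ~5% of
datasets; requiring the likelihood gain to also beat the aBIC parameter
cost suppresses those accidental acceptances. Classification is modal (hard) assignment; ties break to the
lower class index. No three-step correction for classify-analyze bias is
applied, matching the hard-classification practice the pipeline mirrors.

## 2. Cross-lagged panel network

Within one trajectory group and wave pair (t, t+1), each of the six
cluster scores at t+1 is regressed on all six scores at t plus three
covariates (gender, age, trauma count), every variable z-scored within the
group × analysis sample (so edge weights are comparable across the two
wave-pair networks). The objective per outcome is

    (1/2n)‖y − Xb‖² + λ Σ_{j penalized} |b_j|

with the six node predictors penalized and covariates unpenalized —
"controlling for" means adjustment, not network membership, so covariate
coefficients are stored separately and never enter W. Autoregressive
coefficients are penalized uniformly with the cross-lagged ones (the
methodology leaves this open; uniform treatment avoids privileging the
diagonal).

The solver is scikit-learn coordinate descent for the final per-outcome
fits; cross-validation paths run on an in-package Gram-matrix coordinate
descent (numba-compiled) that solves the identical objective — verified
against scikit-learn's path to ~1e-11 in the tests — because re-selecting
λ inside every bootstrap replicate requires sub-millisecond paths.
Partially-penalized designs are profiled exactly: minimizing over the
unpenalized block first reduces the problem to an ordinary lasso on
residualized y and predictors (Frisch–Waugh), and the unpenalized
coefficients are recovered by least squares afterwards. λ = 0 falls back
to a direct least-squares solve.

λ selection: per outcome, 10-fold cross-validation over a 100-point log
grid spanning four decades below the full-sample λ_max = max|Xᵀy|/n (after
residualization), seeded fold split. Two rules: `min` (CV-MSE minimizer,
the default — the common convention when edge weights are the quantity of
interest) and `1se` (largest λ within one standard error of the minimum —
appropriate when support recovery is the goal; the support-recovery
acceptance check uses it for exactly that reason).

Display thresholding (|W| < 0.05 → 0, strict inequality) produces a
separate copy used only for plots/GraphML export; centrality and
bootstrap functions refuse thresholded networks.

## 3. Centrality and robustness

Expected influence retains edge signs: in-EI(j) = Σ_{i≠j} W[i,j],
out-EI(i) = Σ_{j≠i} W[i,j]. Self-loops are excluded by default —
centrality is meant to capture cross-symptom influence — with a flag to
include them (the reference description does not state its convention).
Σ in-EI = Σ out-EI holds exactly in off-diagonal mode and is asserted.
Ranking is by signed value, ties broken by the canonical cluster order
(RE, AV, TH, AD, NSC, DR). A z-scored view is provided for plotting; raw
values are always retained.

Edge bootstrap: subjects resampled with replacement, network re-estimated
per replicate, 95% percentile bounds per edge plus the fraction of
replicates in which the edge is nonzero. λ is re-selected per replicate by
default (faithful to the estimator); a fixed-λ mode reuses the
full-sample λs and is used by the scaled pipeline/acceptance runs for
speed. Edge-difference tests use paired per-replicate differences and the
percentile interval at level α.

Case-drop CS: for each drop proportion p in 0.10–0.75 (step 0.05),
B subsamples of ⌈(1−p)n⌉ subjects are drawn without replacement, the
network and centrality recomputed, and the Spearman correlation with the
full-sample centrality recorded; CS is the largest p retaining correlation
≥ 0.7 with probability ≥ 0.95 (B defaults to 250; the reference
methodology's count is unstated). A constant centrality vector has no rank
order, so degenerate correlations count as unstable — this makes an empty
(all-zero) network correctly score CS = 0 rather than spuriously stable.
With only six nodes, Spearman correlations are coarse; CS outputs carry a
small-network caveat flag and should be read as order-of-magnitude
statements.

Known limitation: percentile intervals of cross-validated lasso estimates
inherit shrinkage bias of order λ, which for moderately sized edges at
n ≈ 500 is comparable to one standard error. In fixed-λ bootstrap mode
their empirical coverage of true large-edge values falls to the mid-80s;
with λ re-selected per replicate (the default), the added selection
variability widens the intervals and coverage returns to approximately
90%. Edge intervals from penalized estimators should in general be read
as stability summaries rather than exact confidence statements.

## 4. Synthetic world

The generator emulates the cohort the pipeline targets: n = 1277 subjects,
three waves, two severity classes (22.63% high-risk: intercept 0.45,
slope +1.90; 77.37% resistance: −0.14, −0.59) on a standardized severity
scale — the near-zero weighted mean of the printed intercepts implies the
original severity was standardized before trajectory modeling, so the
generator works on that scale and offers an affine map to the raw 0–4
mean-item scale (anchor mean 0.98, SD 0.84 at wave 1) for display only.
Unprinted nuisance parameters default to Σ = diag(0.04, 0.04) and
θ_t = 0.10; these make the two classes widely separated (entropy ≈ 1),
so green trajectory tests establish correctness of the machinery, not
performance under weak separation. Covariates: gender ~ Bernoulli(0.475),
age ~ N(20.34, 2.80²) truncated at 17, trauma count ~ Poisson(2.32).

Cluster scores are the subject's total plus VAR(1)-structured deviations
with class-specific transition matrices (high-risk: DR-dominant outgoing
influence with NSC secondary; resistance: AD-dominant), innovation SD
0.25, spectral radii well below 1; wave-1 deviations are drawn from the
VAR's stationary distribution, and covariate effects (trauma +, age −,
applied to z-scored covariates) shift every wave. Score bounding into
[0, 4] is hard clamping by default (the instrument is a bounded Likert
scale); a logistic squash is available.

Not emulated: item-level responses, missingness/attrition (the design
models completers of a platform that rejected incomplete submissions),
floor effects of the raw scale on the analysis path (the analysis runs on
the unbounded standardized scale), and any weak-separation regime. Green
tests on this world therefore validate estimator correctness and the
published-parameter recovery path, not robustness to messy real data.

## 5. Reproducibility

Every stochastic operation takes an explicit seed; the pipeline derives
per-stage seeds from one master seed via `SeedSequence` (folded below
2³¹). Identical configuration + seed yields byte-identical panels and
report JSON; the run manifest records SHA-256 hashes of every artifact the
report cites, and a failed stage still writes the manifest with the stage
named.
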