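# trajnet

Latent symptom-severity trajectories and cross-lagged panel networks (CLPN)
for short longitudinal panels, built around the six ICD-11 complex-PTSD
symptom clusters (RE re-experiencing, AV avoidance, TH sense of threat,
AD affective dysregulation, NSC negative self-concept, DR disturbed
relationships) measured at three annual waves.

The package is aimed at researchers in psychiatric epidemiology who want to
answer two questions about a trauma-exposed cohort: *do subjects follow
distinct severity trajectories over time?* and, *within each trajectory
group, which symptoms drive which over time?*

## The model

**Stage 1 — growth mixture model.** Total severity y_i = (y_i1, y_i2, y_i3)
belongs to one of K latent classes; given class k,

    y_i ~ N( X μ_k , X Σ Xᵀ + diag(θ) ),   X = [1 | t], t = 0, 1, 2

with class-specific mean intercept/slope μ_k = (α_k, β_k), shared
random-effect covariance Σ and wave-specific residual variances θ_t
(3K + 5 free parameters). Estimation is restarted ECM over the full latent
structure; class enumeration uses AIC, sample-size-adjusted BIC
(p·ln((n+2)/24)), normalized entropy, an approximate Lo–Mendell–Rubin
adjusted LRT, and a parametric-bootstrap likelihood ratio test (BLRT),
with classes under 5% of the sample flagged as potentially spurious.

**Stage 2 — cross-lagged panel network.** Within each trajectory group and
for each consecutive wave pair, every cluster score at wave t+1 is
regressed on all six z-scored cluster scores at wave t (LASSO, per-outcome
λ by 10-fold cross-validation) with gender, age and lifetime trauma count
as unpenalized controls. The 6×6 coefficient matrix W is a directed signed
network; node centrality is expected influence (in-EI = signed column sum,
out-EI = signed row sum, self-loops excluded). Robustness comes from a
nonparametric edge bootstrap (95% percentile intervals, paired
edge-difference tests) and case-drop correlation-stability (CS)
coefficients.

Because the motivating study's raw survey data are not public, a
synthetic-data module generates panels with the published generating
structure (two classes: 22.63% "high-risk", intercept 0.45, slope +1.90;
77.37% "resistance", intercept −0.14, slope −0.59; standardized severity
scale) plus class-specific VAR(1) cross-lagged dynamics over the six
clusters; every downstream stage is validated against this stated world.

## Worked example

```bash
python analysis/01_simulate.py --seed 0          # writes results/panel.csv
python analysis/02_trajectories.py --seed 0      # fit indices + assignments
python analysis/03_networks.py --seed 0          # four CLPNs + centrality
python analysis/04_stability.py --seed 0         # bootstrap + CS
```

`02_trajectories.py` prints the enumeration battery and the selected model
(this is the verbatim `--seed 0` output):

```
K=1: AIC    8247.8  aBIC    8263.6  entropy -  smallest 100.00%  blrt None
K=2: AIC    5916.5  aBIC    5938.3  entropy 1.000  smallest 21.61%  blrt 0.05
K=3: AIC    5920.8  aBIC    5948.5  entropy 0.593  smallest 15.35%  blrt 0.5
selected K = 2
class 1: intercept +0.455, slope +1.897, share 21.61%, avg posterior 1.000
class 2: intercept -0.146, slope -0.584, share 78.39%, avg posterior 1.000
agreement with simulation ground truth: 100.00%
```

The two recovered classes match the generating parameters (0.45/1.90 and
−0.14/−0.59) and the 22.63% high-risk share (21.61% realized in this
draw); a third class is rejected (BLRT p = 0.5, aBIC worsens). Entropy is
≈1 because the default synthetic classes are widely separated.
`03_networks.py` then reports, per group × wave pair, the nonzero
cross-lagged edge count, the strongest directed edges, and the top
expected-influence nodes — for `--seed 0`, the high-risk T1→T2 network has
10 nonzero cross-lagged edges led by `DR -> AV: +0.229` with DR the top
out-EI node, while the resistance networks are led by AD
(`AD -> DR: +0.220`), reproducing the generator's class-specific dynamics.
`04_stability.py` prints edge-difference tests and CS coefficients per
centrality metric (e.g. CS(out_EI) = 0.55 for the resistance T1→T2
network; the small high-risk group yields CS values near 0, illustrating
the small-subgroup instability the method is known for).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the complete pipeline from scratch at a single-CPU scale —
simulation, class enumeration with BLRT, classification, the four
trajectory-stratified networks with centrality, and scaled bootstrap/CS
diagnostics — writing its artifacts under `results/acceptance_run/` and the
target report to the given path.
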