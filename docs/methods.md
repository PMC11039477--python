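# Methods

## Model

A multivariate multiple linear profile relates `p` correlated responses to
`q` explanatory variables: for the `k`-th sample of size `n`,

    Y_k = X B + E_k,

where `X` is the `n × (q+1)` design matrix with a leading column of ones,
`B` the `(q+1) × p` coefficient matrix, and the rows of `E_k` are i.i.d.
multivariate normal with covariance `Σ`.  Phase-II monitoring assumes `B`
and `Σ` known (established in a stable Phase-I period).  Out-of-control
conditions are an additive coefficient shift `B → B + ΔB` and/or a variance
inflation `Σ → τΣ` applied to every element of `Σ`.  Shifts are raw
additive increments; in the benchmark scenario the error standard
deviations are 1, so raw and σ-scaled shifts coincide.

The least-squares estimator `B̂_k = (XᵀX)⁻¹XᵀY_k` is vectorized
response-major, `β̂ = (β̂_01, β̂_11, …, β̂_q1, …, β̂_0p, …, β̂_qp)ᵀ`, with
covariance `Σ_β̂ = Σ ⊗ (XᵀX)⁻¹`.  Residual summaries against the known `B`
are the mean residual vector `ē_k` and
`f_k = W_k = Σ_i e_ik Σ⁻¹ e_ikᵀ ~ χ²(np)` in control.

## Chart statistics

All four charts share the probability integral transform
`x → Φ⁻¹(H_df(x))` (chi-square CDF to standard-normal quantile), with the
CDF value clamped to `[ε, 1−ε]`, `ε = 1e−12`, so the transform is finite at
0 and +∞.  The clamp only matters for the first few updates of a fresh
state, where EWMA quadratic forms start at exactly zero.

* **Max-MEWMA** (coefficients): `z_k = λ(β̂_k − β) + (1−λ)z_{k−1}`,
  `C_k = Φ⁻¹[H_{(q+1)p}{((2−λ)/λ) z_kᵀ Σ_β̂⁻¹ z_k}]`;
  `g_k = (1−λ)g_{k−1} + λΦ⁻¹[H_np{W_k}]`, `S_k = √((2−λ)/λ) g_k`;
  plot `ME_k = max(|C_k|, |S_k|)`.
* **Max-MCUSUM** (coefficients): `U_k = max(0, U_{k−1} + Z_k − D/2)` with
  `Z_k = a(β̂_k − β_g)ᵀ`, `a` the `Σ_β̂⁻¹`-unit direction from `β_g` to a
  reference out-of-control vector `β_b`, `D` the corresponding Mahalanobis
  distance; `L_k = max(0, L_{k−1} + (β̂_k−β_g)Σ_β̂⁻¹(β̂_k−β_g)ᵀ − v)` with
  `v = ln(τ_d)·τ_d/(τ_d−1)` (natural log, consistent with the
  likelihood-ratio derivation of variance CUSUMs; `v ≈ 1.0484` at the
  default `τ_d = 1.1`); plot `MC_k = max(U_k, L_k)`.
* **SS-EWMAe** (residuals): `z_k = λē_k + (1−λ)z_{k−1}`,
  `T_k = Φ⁻¹[H_p{z_kᵀ[(λ/(2−λ))·Σ/n]⁻¹z_k}]`, `P_k = λT_k + (1−λ)P_{k−1}`;
  `F_k = Φ⁻¹[H_np{f_k}]`, `V_k = λF_k + (1−λ)V_{k−1}`; plot
  `EWe_k = P_k² + V_k²`.
* **SS-CUSUMe** (residuals): two-sided CUSUMs of `T_k` (allowance `k1 = 1`)
  and `F_k` (allowance `k2 = 1.5`), `M_k = max(D_k⁻, D_k⁺)`,
  `N_k = max(B_k⁻, B_k⁺)`; plot `CUe_k = M_k² + N_k²`.

All memory states start at zero; every plotting statistic is nonnegative,
so each chart needs only an upper control limit.

Design choices worth flagging:

* **SS-EWMAe mean standardization.** Applying `Σ_β̂⁻¹` (dimension
  `p(q+1)`) to the `p`-vector `z_k` is dimensionally inconsistent, so the
  quadratic form standardizes `z_k` by its asymptotic in-control EWMA
  covariance `(λ/(2−λ))·(Σ/n)`, making the argument of `H_p`
  asymptotically `χ²(p)` — the same construction the Max-MEWMA mean
  statistic uses explicitly.  This is the package's reading, documented,
  not asserted as the original authors' code.
* **Asymptotic EWMA variance.** The factor `(2−λ)/λ` is the asymptotic
  one; the exact finite-`k` factor is not used.  Calibrated limits absorb
  early-run behaviour.
* **Max-MCUSUM variability accumulator.** `L_k` accumulates the
  coefficient-vector Mahalanobis deviation (mean about `p(q+1)` per step in
  control against an allowance `v ≈ 1.05`), so it drifts upward and its
  calibrated limit is large and its in-control run length nearly
  deterministic.  It is implemented exactly as specified; its
  out-of-control behaviour also depends on `β_b`, which has no canonical
  published value — the default is `β_g` plus a unit shift in every
  intercept.
* **Sample-size dependence.**  `Σ_β̂`, the `np` degrees of freedom and
  `Σ/n` all depend on the current sample's design, so every update takes
  the sample's own `X`; VP schemes with `n1 ≠ n2` are handled per sample.

## VP scheme

Two parameter settings: relaxed `(n1, t1, UCL1, UWL1)` (region 1) after a
safe-zone statistic (`stat ≤ UWL`, boundary inclusive) and tightened
`(n2, t2, UCL2, UWL2)` (region 2) after a warning-zone statistic
(`UWL < stat ≤ UCL`); `stat > UCL` signals.  The free parameters are tied
to target expectations through the in-control safe-zone probability `P0`:

    P0 = (E(n) − n2)/(n1 − n2),
    t1 = (E(t)(n1 − n2) − t2(n1 − E(n)))/(E(n) − n2),
    α2 = (E(α)(n1 − n2) − α1(E(n) − n2))/(n1 − E(n)).

Memory statistics are split into two region tracks: only the active
region's track advances; the other is frozen (not reset) and resumes when
its region is re-entered, so statistics from one region never contaminate
the other (mixing them inflates the false-alarm rate).

Time-accounting conventions (the literature leaves both open; these were
fixed by requiring internal consistency with the published benchmark
performance numbers, which they reproduce):

* **Performance simulation.**  Runs start relaxed (region 1, both tracks
  zero).  The interval chosen after sample `k−1` elapses before sample
  `k`; no zone information exists before the first sample, so its
  preceding interval is the expected interval `E(t)` (overridable to the
  starting region's interval; a randomized initial region with probability
  `P0` is also available).
* **Stream monitoring.**  Decision tables start the clock at the first
  sample (its preceding interval is zero), matching how monitoring periods
  are reported in practice.

## Limit calibration

`UCL`: the starting value is the `⌈reps(1−α)⌉`-th order statistic of
`reps` first-update statistics from fresh in-control states; the search
then adjusts the limit until the simulated zero-state in-control ARL equals
`1/α`.  The search is a bracketing grid refinement with common random
numbers: with a shared seed the chart trajectories do not depend on the
candidate limit, so each replication's run length is exactly nondecreasing
in the limit and a whole candidate grid is evaluated in one vectorized
simulation pass.  Convergence is declared at
`|ARL − 1/α| ≤ min(tol·(1/α), max(SE, 1e−3/α))` — relative to the
Monte-Carlo SE when that is tighter, since near-deterministic run lengths
(Max-MCUSUM) permit and require finer placement.  Search passes truncate
runs at ~10× the target ARL (`P(RL > cap) ≈ e⁻¹⁰` at the solution, so the
bias is negligible); performance evaluation uses a cap of `50/α` with
truncations counted at the cap and logged.

`UWL`: with the UCL fixed, the warning limit is the `P0`-quantile of the
pooled in-control non-signal statistics (the VSI-style construction, one
warning limit per `(α, n, UCL)` triple).  The simultaneous conditions
(`P0`, ARL, ATS) are over-determined given a fixed UCL; the implemented
order matches `P0` and re-verifies ARL/ATS, which the property suite
checks (safe-zone fraction ≈ `P0`, mean sample size ≈ `E(n)`, mean
interval ≈ `E(t)`).

For the benchmark design (`α1 = 0.004, α2 = 0.006, n1 = 4, n2 = 8,
P0 = 0.5`) the calibrated Max-MEWMA limits come out at
`UCL1 ≈ 3.01, UCL2 ≈ 2.88, UWL1 ≈ 1.02, UWL2 ≈ 1.03`.

## Performance measures

Zero-state run lengths: the shift is present from the first monitored
sample and all memory starts at zero.  ARL/SDRL count samples; ATS/SDTS
accumulate sampling intervals.  For FP, `ATS = t·ARL` and `SDTS = t·SDRL`
exactly.  Summaries report means, SDs (denominator `reps − 1`) and
Monte-Carlo standard errors `SD/√reps`.  Replications are independent
given the seed, and results are reproducible bit-for-bit from it.

The Monte-Carlo kernels are vectorized across replications in a private
engine; the test suite replays the engine's documented draw order through
the public scalar recursions and requires agreement to machine precision,
so the scalar classes act as the oracle for the vectorized path.

## Synthetic data

The Phase-II stream generator draws error rows from `N(0, τΣ)` via a
Cholesky factor and applies the scheduled coefficient shifts; covariates
come from the scenario's fixed designs.  For the stroke-care scenario
(log10 onset-to-needle and door-to-needle times vs age, sex, severity) the
patient-level register data are restricted, so design matrices are
synthetic stand-ins drawn once from documented distributions: age ~
Normal(72, 10²) truncated to [18, 100], sex ~ Bernoulli(0.5), severity ~
Gamma(shape 2, scale 4) truncated to [0, 42].  These affect only the
synthetic demonstrations, not the chart mathematics.  The generator does
not emulate hospital-level clustering, missingness, registration delays or
covariate drift, so passing tests say nothing about those features of real
register data; responses are generated on the log10 scale on which the
profiles are defined, with an optional back-transformed convenience
column.

## Problem sizes and tolerances

Calibration and evaluation default to 10000 replications (ARL tolerance
1%); the test suite uses 10000 for calibration-sensitive checks and
1000–5000 for directional and property checks, sizes chosen so the whole
suite runs in a few minutes on one core.  Monte-Carlo comparisons against
published simulation results use the combined standard error of both sides
(the published tables are themselves 10000-replication simulations, with
their per-replication spread estimated by ours).  Known limitations: no
steady-state run lengths (zero-state only), no Markov-chain/integral-
equation ARL evaluation, no Phase-I estimation effects (parameters are
treated as known), and the six-response benchmark scenario ships without
design matrices (they are unpublished), so its tables are not reproduced.
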