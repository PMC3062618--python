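# Methods

This note records the statistical choices in stageloop precisely enough to
re-derive every number the package prints.

## 1. Design

`build_double_loop(S)` constructs the double loop over `S` stages:

- forward loop: arrays `(1→2), (2→3), …, (S→1)` with Cy3 on the arrow's tail
  stage and Cy5 on its head;
- reverse loop: arrays `(S→S−1), …, (1→S)`, same dye rule.

This uses `2S` arrays and `4S` biological pools (each channel its own pool, no
technical replication). Every stage appears exactly twice per dye; replicate
slots are assigned deterministically (forward-Cy3 → rep 1, forward-Cy5 → rep 2,
reverse-Cy3 → rep 3, reverse-Cy5 → rep 4). The design graph is connected
(checked by union–find), so all pairwise stage contrasts are estimable.

A consequence worth knowing: in a loop design the variance of a stage contrast
grows with the separation of the two stages along the loop. Adjacent-stage
contrasts are the best-estimated; smooth long-range trends are partially
confounded with the chain of array effects and need larger amplitudes to
detect.

## 2. Simulation

`simulate_experiment` generates raw spot intensities as
`2^(baseline_g + tau[g, stage] + dye·[Cy5] + a_array + b(x,y)·sign + c(A0)·sign/2 + e)`
with `a ~ N(0, array_sd²)` shared within array, `e ~ N(0, noise_sd²)` per
channel, an optional spatial bias field `b` and intensity-dependent dye bias
`c` (sign = +1 for Cy5). Herring-sperm control spots draw non-specific signal
from `N(100, 15²)` clipped at zero. Default magnitudes (baseline
`N(9.5, 2²)`, dye 0.3, array SD 0.3, noise SD 0.25 on the log2 scale) put a
few percent of genes below the detection threshold so the filter is exercised;
they emulate the error structure the models assume, not any particular
platform's physics.

## 3. Preprocessing

- **Detection**: threshold = mean + 1 sample SD of all pooled control signals
  (both channels, all arrays). A gene is retained if its raw signal strictly
  exceeds the threshold in at least one channel of at least one array.
- **Normalization** per array in (M, A) coordinates, `M = log2(Cy5/Cy3)`,
  `A = ½ log2(Cy5·Cy3)`: (1) Lowess of M on A within each subgrid
  (span 0.2) removes regional intensity-dependent dye bias; (2) a separable
  spatial pass — Lowess of the residual M on x, then on y (span 0.3) —
  removes slide-position trends. Only M is adjusted; A is preserved exactly,
  so corrected channels are `A ± M_corr/2`. Zero-signal spots are dropped
  with a logged warning.

## 4. Mixed models

**Global normalization** fits `y = μ + Array + Dye + (Array×Dye) + ε` over
all genes jointly. With complete balance this reduces to channel means: dye
effects are dye-mean deviations, array effects are shrunken array-mean BLUPs
(method-of-moments variance components from within-array dye differences),
and the Array×Dye interaction BLUP is shrunk by `σ²_AD / (σ²_AD + σ²_ε/G)`.
Residuals keep each gene's own level and stage signal.

**Per-gene model**: `r = μ + Dye + Array + Stage + ε`, Array random. Fixed
effects use sum-to-zero coding (dye ±1; stage columns `I(k) − I(S)`), and the
stage least-squares mean is `μ + Stage_k`.

*Variance components* are REML estimates obtained in closed form per gene:
transforming each array's two channels to sums and differences makes the
covariance diagonal (differences: `σ²_ε`; sums: `σ²_ε + 2σ²_a`), and a
generalized eigendecomposition of the sum-stratum cross-products reduces the
profiled REML criterion to a 1-D search in `w = 1/(1 + 2λ)`, `λ = σ²_a/σ²_ε`
(coarse grid + golden section, with the `λ = 0` boundary checked explicitly).
The engine is validated against a dense grid search over the unprofiled REML
log-likelihood.

*Fixed-effect inference* deliberately does **not** use Wald statistics on the
REML variance estimate. The REML `σ̂²_ε` pools information across strata
(~119 d.f. on the full design), so an F referenced to the 40-d.f. residual
would be far too conservative (measured null rejection rate 0.00075 at
α = 0.01; KS p ≈ 3·10⁻⁹). Instead, tests condition on arrays as fixed
blocks: with `W = [X | sum-to-zero array dummies]`, the residual mean square
`MS = RSS_W / df_resid` has exactly `df_resid = n_channels − n_arrays −
n_levels` degrees of freedom — 40 for the stage model, 78 for the pre/post
model — and

- overall stage test: `F = (RSS₀ − RSS)/q / MS ~ F(S−1, S)` exactly under
  normality (measured null rate 0.0103, KS p = 0.27);
- contrasts: `t = ĉ/se(ĉ)` with `df_resid` d.f. `delta` is the earlier minus
  the later stage's lsmean, so a rise over time gives a negative delta;
  `log2_fc_post_pre = −delta` is also reported for the pre/post model.

The reported degrees-of-freedom record for the full design is therefore
dye 1 / array 79 / stage 39 / residual 40 (pre/post: residual 78), and the
reported variance components (`sigma2_array`, `sigma2_resid`) remain the REML
estimates.

## 5. Trajectories

Stage lsmean vectors are standardized per gene ((x − mean)/sample SD; constant
profiles are flagged and excluded from correlations). **Peak calling**: the
maximum stage `k*` is always a peak; candidate stages are local maxima whose
lsmean is at least `lsmean[k*] − z₀.₉₅ · se[k*]` (the lower bound of the 90%
CI of the maximum; normal quantile by default, `t(df_resid)` optional);
candidates are accepted greedily in decreasing height (ties to the earlier
stage), rejecting any within 2 stages (`|Δ| < 3`) of an accepted peak. Genes
are ordered by primary (tallest) peak stage.

**Correlations** are Pearson r over the `S` stage means for every unordered
gene pair; the two-tailed critical value is `critical_r(n, α) =
t / √(n − 2 + t²)` with `t = t₁₋α/₂(n−2)` — 0.4026 for n = 40, α = 0.01.
**Clustering** is average linkage on `1 − r` distance for genes or stages,
with Newick export using cophenetic branch lengths.

## 6. Enrichment

For a stage's peak gene set versus a functional category, the 2×2 table
`[[a, b], [c, d]]` is tested conditional on its margins: `p_right = P(X ≥ a)`
(over-representation), `p_left = P(X ≤ a)`, and the two-tailed p sums the
probabilities of all tables no more likely than the observed one
(point-probability method, with a `1 + 10⁻⁷` tolerance against floating-point
ties). Degenerate tables (a zero margin) return p = 1 in all tails.

## 7. Determinism and numerics

All randomness flows from one root seed through named substreams
(`SeedSequence` keyed by a CRC-32 of the step name; every derived seed
< 2³¹), so any step can be re-run in isolation and identical configs give
bit-identical outputs. Lowess uses statsmodels with `delta = 0.01 · range(x)`
for speed; the REML search is fully vectorized across genes (≈1 s for 4,000
genes on the 80-array design).

## 8. Limitations

- The simulator shares one spot layout and bias structure across arrays of an
  experiment; it is a calibration instrument, not a scanner model.
- Exact F/t distributions rely on Gaussian residuals; heavy-tailed data would
  need permutation references, which the code does not implement.
- The normalization model assumes complete balance (every array has both
  dyes, every stage measured equally often); unbalanced designs are rejected
  rather than approximated.
- Channel-mean global normalization absorbs any expression change shared by
  essentially all genes at a stage; stage effects are identified only
  relative to the per-channel average.
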