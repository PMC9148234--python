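# Methods

## Model and assumptions

The BPEEC distribution is specified through its conditionals: a
geometric-type "Poisson exponential" law for the count given the
duration, and an exponential law for the duration given the count.
Solving the compatibility functional equation yields the joint density

    f(x, y) = N(α)⁻¹ exp[α₁(x+1) − (α₂ − α₃(x+1)) y],
    x ∈ {0, 1, 2, …}, y > 0,

with normalizing series N(α) = Σ_x e^{α₁(x+1)} / (α₂ − α₃(x+1)).

**Parameter region.** The package enforces α₁ < 0, α₂ > 0, α₃ ≤ 0.
This is the exact set on which (i) the normalizing series converges,
(ii) the conditional exponential rate β(x) = α₂ − α₃(x+1) is positive
for all x ≥ 0, and (iii) the conditional geometric parameter
λ(y) = e^{−α₁−α₃y} − 1 is positive for all y ≥ 0. Some applied accounts
of this family state α₁ > 0; no joint density exists there, because the
series defining N diverges for any α₁ ≥ 0 with α₃ ≤ 0, and fitted values
reported under that convention cannot correspond to a normalized model.
A practical consequence: the family only expresses *negative* (or zero)
count–duration dependence. On positively associated data the dependence
estimate is pinned at the independence boundary α₃ = 0, which the fit
result flags via its boundary note.

**Support conventions.** The count support starts at 0 (both bundled
datasets contain zeros). The duration support is y > 0, but density and
likelihood evaluation accept y = 0 at the boundary (the exponential
density there equals its rate, finite); the sampler never emits an exact
zero. The discrete BPEC reference model keeps its canonical lattice
starting at 1, with an explicit `support_start=0` variant for data
containing zeros; the choice is always recorded in the fit result.

## Series evaluation

All infinite series (N, its parameter derivatives, and the moment
series) share the shape Σ_x (x+1)^a x^b e^{α₁(x+1)} / β(x)^c and are
summed in blocks with a certified geometric tail bound: for indices
beyond X every term is at most (x+1)^{a+b} e^{α₁(x+1)} / α₂^c and
consecutive bounds shrink by at least ρ = ((X+2)/(X+1))^{a+b} e^{α₁}.
Summation stops when the bound falls below `rel_tol` times the partial
sum (default 1e-12) and errors out — never silently truncates — if
`max_terms` (default 1e5; 1e6 for the slower-decaying gradient series)
is exhausted first. Densities are computed in log space and
exponentiated at the interface; `log(e^w − 1)` uses the stable form
`w + log1p(−e^{−w})`.

**Derivative-form expansion.** N can be rewritten as a power series in
α₃/α₂ whose k-th coefficient is the k-th α₁-derivative of the geometric
sum e^{α₁}/(1−e^{α₁}), i.e. Σ_m m^k e^{α₁ m}. Those coefficients grow
factorially, so the expansion is *asymptotic*: useful to near machine
precision for |α₃/α₂| of order 0.01, only to ~1e-3 at 0.1, and useless
beyond. It is implemented with optimal truncation plus divergence
detection (five consecutive growing terms) and serves strictly as an
independent cross-check of the direct series, never as the primary
route. The product moment E(XY) is likewise computed by its direct
series, with a generalized-hypergeometric (₃F₂) closed form — verified
algebraically to be the same sum — evaluated through mpmath as a
cross-check for α₃ < 0.

## Sampling

The sampler is exact up to a 1e-15 relative truncation of the X-marginal
CDF table: X by inverse CDF with the half-open convention
[F(x−1), F(x)), then Y | X = x exponential with rate β(x). BPEC sampling
works the same way on its lattice (geometric conditional); BEC sampling
draws X by rejection from an Exp(λ₂) envelope with exact acceptance
probability λ₁/(λ₁ − λ₃x), then the exponential conditional. A single
numpy Generator, seeded per call, drives every stochastic operation, and
dataset labels record (model, params, n, seed).

## Estimation

**MLE.** The log-likelihood is ℓ = −n log N(α) + Σ[α₁(xᵢ+1) − β(xᵢ)yᵢ],
with analytic score using the three derivative series of N. **MPLE**
maximizes Σ[log f(xᵢ|yᵢ) + log f(yᵢ|xᵢ)], which cancels N entirely (an
instrumentation counter lets tests assert this). Both objectives are
maximized by L-BFGS-B on the log scale u with α₁ = −e^{u₁}, α₂ = e^{u₂},
α₃ = −e^{u₃}, so the optimizer cannot leave the valid region; box
bounds on u (e.g. u₁ ≥ −7, i.e. |α₁| ≥ 9·10⁻⁴) keep every series
evaluable within its term budget. Three jittered starts (σ = 0.25 in
u-space, seed recorded) guard against local optima, and the best point
is polished by a Powell-hybrid root solve of the analytic
(pseudo-)score, judged by the gradient norm it achieves rather than the
solver's own status flag. A fit is declared converged when the
natural-scale score sup-norm is below 1e-6 (or the estimate sits on the
search boundary, which is noted).

**Inference.** Standard errors come from the inverse observed
information, a central-difference Hessian of the maximized objective on
the natural scale (relative step 1e-4, one-sided stencils when a
parameter sits within a step of the region boundary). Confidence
intervals are symmetric Wald intervals; for MPLE they are likewise
inverse-pseudo-information intervals, adequate here (coverage is
verified by simulation for the MLE) but not sandwich-corrected — a known
limitation. Degenerate data (all x or all y equal) still fit, with weak
identifiability of α₃.

**Information criteria.** Both conventions are computed and labelled:
standard AIC = 2k − 2ℓ / BIC = k ln n − 2ℓ (smaller is better) and the
legacy larger-is-better variants ℓ − 2k and ℓ − (k/2) ln n found in some
applied reports. Rankings agree by construction (the variants are −½
times the standard values), so the comparison table is
convention-invariant.

## Reference models

BPEC: P(x, y) ∝ exp(θ₁y − θ₃xy + θ₂x) on the lattice, convergent for
θ₁, θ₂ < 0, θ₃ ≥ 0 (θ₃ < 0 is rejected as divergent — the inner
geometric sum is closed-form, reducing N to one certified series). BEC
(Arnold–Strauss): f(x, y) ∝ exp(−λ₁y − λ₂x + λ₃xy) on the positive
quadrant, λ₃ ≤ 0; its normalizing constant is the smooth 1-D integral
∫ e^{−λ₂x}/(λ₁ − λ₃x) dx evaluated by adaptive quadrature (rel. error
1e-12) — simpler to certify than exponential-integral closed forms.
These models are fitted with finite-difference gradients; only the
BPEEC objectives carry analytic scores.

## Synthetic data and the simulation harness

The generator draws from the exact samplers above. Defaults for the
recovery study: true parameters (−0.5, 1.0, −0.3), n = 200 per
replicate, 200 replicates, seed 20220521, reporting mean estimate, bias
and MSE (mean squared deviation from the truth) per parameter and
method, with failed replicates counted and excluded, never silently.
The default truth was chosen as a moderately dependent, well-identified
interior point; recovery studies at true values outside the convergence
region are impossible by construction, which is why positive-α₃ "true
values" seen in some reports cannot be simulated from. Synthetic data
share every feature of the model by construction — what passing
recovery and coverage tests show is correctness of the estimators under
the model, not robustness to misspecification, censoring, or the
positive dependence real recurrence data often exhibit.

Problem sizes used by the shipped study and checks — 200 replicates at
n ∈ {200, 2000}, 300 replicates at n = 1000 for interval calibration,
10⁵–10⁶ draws for sampler-based moment checks — were chosen so each
Monte-Carlo comparison has standard error comfortably below the effect
it measures.

## Numerical defaults

| quantity | default | rationale |
|---|---|---|
| series rel_tol | 1e-12 | certified truncation near machine precision |
| series max_terms | 1e5 (1e6 for score series) | covers \|α₁\| ≥ 9·10⁻⁴ |
| sampler CDF tail | 1e-15 | inverse-CDF exactness to double precision |
| optimizer | L-BFGS-B, ftol 1e-13, gtol 1e-9, ≤500 iters | tight enough for 1e-6 score norms after polish |
| multi-start | 3 jittered (σ = 0.25, seeded) | cheap insurance against local optima |
| Hessian step | 1e-4 relative, boundary-aware | balances truncation vs. round-off |
| CI level | 0.95 | convention |

## Known limitations

- Only non-positive dependence is representable; positively associated
  pairs are fitted at the independence boundary.
- MPLE interval widths use the naive inverse pseudo-information, not a
  robust sandwich.
- The derivative-form expansion of N is asymptotic and cross-check-only.
- BPEC requires an integer lattice; datasets with non-integer durations
  skip that comparison (noted in the output).
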