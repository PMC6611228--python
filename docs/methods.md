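# Methods

## Dosimetry of a decaying, evaporating source

Cells growing as a 15 µm monolayer are irradiated by a physically separate
Y-90 source dish (half-life `T_phys = 64.1 h`). The absorbed dose rate per
unit activity is an S-value in the MIRD sense, tabulated per dish position
and formulation (`constants.S_INITIAL_CGY_PER_MBQ_DAY`). Because up to a
third of the medium evaporates over a 6-day exposure, the S-value is not
constant: it is modelled as drifting linearly from `S_initial` at the start
to `S_final` at the end of the exposure. The cumulated dose is the exact
integral of `A0 e^{-λt} S(t)`:

    D(T) = (A0/λ) [ (S_f − S_i)/(λT) (1 − (1+λT)e^{−λT}) + S_i (1 − e^{−λT}) ]

Numerical choices: the factor `(1 − (1+x)e^{−x})/x` is evaluated by its
series `x/2 − x²/3 + x³/8` for `x < 1e-6` to avoid catastrophic
cancellation at short exposures; `1 − e^{−x}` always goes through `expm1`;
`T = 0` returns 0 Gy rather than an error. Internal canonical units are
hours, MBq and Gy; S-values cross the API boundary in the conventional
cGy MBq⁻¹ d⁻¹ and are converted once.

End-of-exposure S-values are dish-specific measurements that are not
tabulated, so the package parameterises them as
`S_final = evaporation_factor × S_initial` (default 1.2, configurable per
run). A consequence of tying the drift to the exposure end is that `D(T)` is
not globally monotone in `T` when `S_final > S_initial`: stretching the
exposure also stretches the S ramp past the time when most activity has
decayed, so `D(T)` peaks and relaxes toward `A0 S_initial/λ`. Monotonicity
holds exactly for a constant S-value, and the closed form agrees with
adaptive quadrature of the defining integral to 1e-8 relative everywhere
tested.

## Mixed-effects linear-quadratic fitting

Surviving fractions are `SF = (colonies/plated)/PE`, with the plating
efficiency `PE` of each replicate set (biological repeat) estimated from its
own 0 Gy control wells as pooled colonies over pooled plated cells; controls
therefore normalise to SF = 1 by construction and only irradiated wells
enter the regression. Zero-colony wells have no log-scale image and are
excluded with a warning (no continuity correction); the fit reports them.

The model `−ln(SF) = αD + βD² + b_i + ε` has no fixed intercept (the
population curve satisfies SF(0) = 1 exactly), a random intercept per
replicate set, and is estimated by REML. Implementation: for
`V₀ = I + γ ZZ'` with `γ = σ_b²/σ_e²`, the coefficients and σ_e² have
closed-form profiles, so the REML criterion

    (n−p) log σ̂_e²(γ) + log|V₀(γ)| + log|X'V₀(γ)⁻¹X|

is minimised over the single scalar γ (coarse log-spaced grid, then bounded
scalar refinement; ties resolve to the γ = 0 boundary). Group structure
makes every term computable from per-group sums via the Woodbury identity,
so the fit is deterministic and costs microseconds. The fixed-effect
covariance is the conditional generalised-least-squares form
`σ̂_e² (X'V₀⁻¹X)⁻¹` evaluated at the REML variance estimates — the same
convention as the standard mixed-model packages for this design. With a
single replicate set the random intercept is inestimable and the fit
degrades, with a warning, to fixed-effects least squares through the origin.

β is deliberately not constrained non-negative (protracted exposures push it
toward, and legitimately below, zero within noise); an explicit `alpha_only`
refit drops the quadratic column instead. Wald p-values use the normal
reference; 95% intervals are ±1.96 SE. The delta-method SE of α/β is

    SE² = var(α)/β² − 2α cov(α,β)/β³ + α² var(β)/β⁴.

This first-order expansion is accurate to better than 5% against brute-force
bivariate-normal propagation while CV(β) ≲ 13%; beyond that the heavy tail
of a normal ratio inflates the Monte-Carlo SD by roughly `3·CV(β)²`
relative, which is a property of the approximation itself, not of the
implementation. Ratios from a β that is consistent with zero should be read
as undefined (the package raises rather than reporting one for alpha-only
fits).

## Lea–Catcheside protraction and equivalence

For dose rate proportional to `e^{−λt}` over a finite exposure `T`, the
Lea–Catcheside factor (repair rate `μ = ln2/T_rep`) integrates to

    G_T = 2λ² / ((1−e^{−λT})² (μ−λ)) · [ (1−e^{−2λT})/(2λ) − (1−e^{−(λ+μ)T})/(λ+μ) ]

with the exact `μ = λ` limit `(1 − (1+2λT)e^{−2λT}) / (2(1−e^{−λT})²)`
used when `|μ−λ| < 1e−9 λ` (the two branches agree to ~1e−10 across the
switch). The closed form is validated against double numerical quadrature of
the defining integral to 1e-8 relative, and satisfies the acute limit
(G → 1 as T → 0), the no-repair limit (G → 1 as T_rep → ∞) and the
fully decayed limit `G∞ = T_rep/(T_rep + T_phys)`.

G is strictly increasing in `T_rep`, so the inversion used to infer the
repair half-time from a β ratio (`G_T = β_Y90/β_EBRT`) is a bracketed
monotone root find on `T_rep ∈ [1e−4, 1e4] h`, converged to |ΔG| < 1e−10.

Equivalence calculators implement `BED_EBRT = nd(1 + d/(α/β))`,
`BED_Y90 = D(RBE_max + G∞ D/(α/β))` and `EQDd = BED_Y90/(1 + d/(α/β))`,
plus the inverse map from a target log-survival effect to the Y-90 dose
(positive quadratic root). EQD curves flag doses above 32 Gy as
extrapolated, the upper end of the measured survival range. No repopulation
term and no LET dependence of β are modelled.

Note on published comparisons: the published per-cell-line assignment of the
EQD10 values (17.6 vs 19.3 Gy) is swapped relative to direct evaluation of
the equivalence formula with the published parameters, so comparison reports
treat EQD10 as an unordered pair. Repair half-times printed to two decimals
(0.21 h) limit forward reproductions of G to ~2%.

## Synthetic assay generator

`simulate_clonogenic` draws, for replicate set *i* and dose *D*,

    colonies ~ Poisson( cells_plated · PE · exp(−(αD + βD² + b_i)) ),
    b_i ~ N(0, σ_b²),

i.e. exactly the data-generating process the fitter assumes, with Poisson
counting noise in place of the Gaussian residual. Defaults emulate the
laboratory design: triplicate wells × three biological repeats, acute doses
0–10 Gy (7 levels), PE = 0.6, 4000 cells per well (within the reported
plating range), σ_b = 0.1 on the −ln SF scale as a modest repeat-to-repeat
variability (no measured value exists). The protracted variant builds its
dose ladder from the dosimetry module over (activity × dish position) pairs
— 10/15/20 MBq across four positions gives twelve doses spanning ≈0.7–31 Gy
— and is labelled modality `Y90`.

What the generator does *not* emulate: the ≥50-cell colony threshold and
image-level counting (absorbed into PE), overdispersion beyond the shared
replicate intercept, cell-cycle or bystander effects, and any dose-rate
dependence of α within an exposure. Passing recovery tests therefore show
that the estimation chain is correct for data satisfying the model's
assumptions, not that real assays are free of these additional effects.

Because the applied random intercept also shifts the control wells, control
normalisation removes most of `b_i` from the response and leaves a shared
normalisation noise per set, which the random intercept of the fit absorbs;
measured over 200 seeded runs at the triplicate design the 95% Wald CI for α
covers the truth 96% of the time with a mean bias of about −1%.

## Problem sizes used in the validation suite

Oracle comparisons run 1000 random dosimetry configurations and a 40-point
randomized (T_rep, T) grid for G; recovery uses 200 simulated experiments
of 63 wells each; Monte-Carlo propagation uses 1e5 bivariate-normal draws.
These sizes give sampling error comfortably below the tolerances they
check while keeping the full suite in the tens of seconds.
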