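# Methods

This note documents the models implemented in `photocap`, the parameter
defaults and why they were chosen, the numerical decisions, and what the
synthetic experiments do and do not demonstrate.

## 1. Temperature kinetics

V<sub>c,max</sub> measured at leaf temperature T_meas is converted to the
growing-season temperature T_g and to 25 °C with the peaked Arrhenius scalar

    f(T0, T1) = exp[Ha (T1−T0) / (R Tk0 Tk1)]
              · (1 + exp[(Tk0 ΔS − Hd)/(R Tk0)]) / (1 + exp[(Tk1 ΔS − Hd)/(R Tk1)])

with Tk = T + 273.15 exactly, Ha = 71,513 J mol⁻¹, Hd = 200,000 J mol⁻¹,
R = 8.314 J mol⁻¹ K⁻¹, and an entropy term acclimating linearly to the
growing season, ΔS = −1.07·T_g + 668.39 J mol⁻¹ K⁻¹.  The same ΔS(T_g) is
used for both conversion steps, so T_meas → 25 → T_g chains exactly
(multiplicative consistency f(a,b)f(b,c) = f(a,c) holds to machine
precision).  The response peaks at

    T_opt(K) = Hd / (ΔS − R ln[Ha/(Hd−Ha)])

≈ 36.2 °C for a 25 °C growing season; warmer T_g (smaller ΔS) pushes the
optimum upward — the acclimation direction.  Temperatures outside
(−50, 60) °C raise an error rather than extrapolate, because the
deactivation exponential overflows silently beyond that range.

## 2. Optimality model

Two nested optimisations predict V<sub>c,max</sub>(T_g) from five
aboveground drivers.

**Least-cost χ.**  The internal/ambient CO₂ ratio balances the unit costs of
transpiration and carboxylation:

    ξ = sqrt(β (K + Γ*) / (1.6 η*)),   χ = Γ*/ca + (1 − Γ*/ca) ξ/(ξ + √D)

with D the VPD in Pa (floored at 1 Pa to avoid the χ → 1 singularity),
ca the CO₂ partial pressure (ppm × site atmospheric pressure, barometric
formula with standard lapse rate), Γ* the photorespiratory compensation
point, K = K_c(1 + pO₂/K_o) the effective Michaelis coefficient, and η* the
water viscosity relative to 25 °C (Vogel–Fulcher–Tammann form, normalised so
η*(25) = 1).  Biochemical constants (Arrhenius base rates at 25 °C and
activation energies): Γ*₂₅ = 4.332 Pa (scaled by pressure; 37,830 J mol⁻¹),
K_c25 = 41.03 Pa (79,430), K_o25 = 28,210 Pa (36,380), O₂ mole fraction
0.2095 × pressure, β = 146.  All are config-exposed
(`OptimalityConstants`).

**Coordination and the unit cost c.**  J_max maximises light-limited
assimilation minus a linear cost c·J_max, where the electron-transport rate
follows a non-rectangular hyperbola with curvature θ = 0.85 and intrinsic
quantum yield φ₀ = 0.257/4.  Writing g = 4c/m:

    ω  = −(1 − 2θ) + sqrt((1 − θ)(1/(g(1 − θg)) − 4θ))
    ω* = 1 + ω − sqrt((1 + ω)² − 4θω)
    J_max = φ₀ I ω,    V_c,max = φ₀ I (m/m_c) ω* / (8θ)

with m = (c_i − Γ*)/(c_i + 2Γ*) and m_c = (c_i − Γ*)/(c_i + K).  V_c,max is
exactly linear in absorbed light I and increases with VPD (stomatal closure
compensated by more carboxylation capacity).  The closed form agrees with
brute-force maximisation of the objective on a dense J_max grid to < 0.1%
over random global environments (this is a standing test).  Costs for which
ω is complex or non-positive raise a typed `CostInfeasibleError` — the
calibrator treats them as a penalty signal rather than clamping, which
would bias the search.

**Dynamic cost.**  c is either the global constant 0.053 or a linear
function of site covariates, c_i = β₀ + Σ_j β_j x_ij, under three covariate
scenarios: the ten edaphic variables; all climate + edaphic variables plus
LMA and N_a; or the five empirically most important variables (N_a, VPD,
soil pH, precipitation, elevation).  Setting β₀ = 0.053 with all β_j = 0
reproduces the constant model bit-for-bit (a standing test).

## 3. Calibration

Covariates are z-scored with means/SDs of the **calibration folds only**
(no validation leakage), so one bound set works across scenarios:
β₀ ∈ [0.005, 0.3], β_j ∈ [−0.2, 0.2] on the standardised scale.  The
coefficients minimise the RMSE between observed and modelled
V<sub>c,max</sub>(T_g) — not V<sub>c,max25</sub> — inside a 5-fold
cross-validation repeated 100 times (fold assignment is a fresh seeded
permutation per repetition, unstratified); per-site predictions are the
mean over repetitions ("out-of-fold ensemble").

The optimiser is a real-coded genetic algorithm: population 100, tournament
selection (size 3), blend crossover (BLX-0.5, rate 0.7), per-gene Gaussian
mutation (probability 0.2), elitism 1, 800 generations.  Three refinements
matter in practice and are all config-exposed:

- **Annealed mutation.**  σ decays geometrically from 10% of the bound range
  to 0.02% of that over the run.  A fixed σ of 0.04 cannot resolve
  coefficients of order 0.005, and without annealing the GA stalls an order
  of magnitude above the attainable RMSE.
- **Restarts and a seeded null.**  The RMSE surface is multimodal: a
  mirrored basin with inflated intercept fits deceptively well.  Three
  independent runs (best final fitness wins), each with one initial
  individual at the constant-cost null (β₀ = 0.053, β = 0), reliably select
  the correct basin.
- **Simplex polish.**  A Nelder–Mead refinement of the final best individual
  sharpens convergence along flat valleys.

With these, the GA matches an exact Levenberg–Marquardt least-squares
solution of the same folds (latent-cost recovery r = 0.92–0.97 across
generator seeds).  Sites with infeasible candidate costs contribute a large
fixed squared-error penalty (10⁶) during fitness evaluation; a fold whose
best individual still sits at the penalty level is marked failed, and more
than 10% failed folds aborts the calibration.

## 4. Statistical track

Level 1: the global mean of site V<sub>c,max25</sub> times f(25, T_g,i).
Level 2: OLS of site V<sub>c,max25</sub> on unstandardised covariates under
the same repeated CV; out-of-fold V<sub>c,max25</sub> ensembles are
multiplied by f(25, T_g,i).  Exactly collinear predictors (the three soil
texture fractions sum to 100) are dropped greedily in listed order with a
warning.  With zero predictors and no CV the regression reduces exactly to
level 1.  The default predictor list is all 18 covariates after VIF pruning.

## 5. Assessment machinery

Metrics: r² (squared Pearson), bias = mean(pred − obs), RMSE, and
AIC = 2k + n·ln(RMSE²) with the **natural** logarithm — the convention is
pinned by the self-consistency check n = 281, k = 1, RMSE = 17.17 → AIC ≈
1600 (base-10 would give ≈ 696).  k counts regression coefficients including
the intercept; the kinetics-only model has k = 1.

Collinearity pruning removes the largest-VIF variable until all VIF < 10
(exact ties — e.g. all infinite under perfect collinearity — drop the
later-listed variable), then repeatedly finds the strongest remaining pair
with |r| ≥ 0.7 and drops the member with the larger mean |r| to the other
survivors (ties keep the earlier-listed variable).

Variable importance enumerates all 2^p predictor subsets (p ≤ 20) by OLS,
ranks them by AICc = AIC + 2k(k+1)/(n−k−1) on the RMSE-based AIC (a
`count_sigma` switch reproduces the convention of likelihood-based selection
tools; the two agree to three decimals on test data), converts to Akaike
weights w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2), and scores each variable by the
summed weight of models containing it, with 0.8 as the important/unimportant
cut-off.  Note an intrinsic property of this statistic: a pure-noise
variable whose full-model |t| reaches ≈ 2.2 attains importance 0.8, which
happens for ~3–5% of noise variables per dataset at n = 200; claims about
noise variables staying below the cut-off therefore hold per candidate, not
for the maximum over many candidates.  Partial-regression slopes equal the
full-model coefficients (Frisch–Waugh) and their intervals use the full
model's residual degrees of freedom.

## 6. Sensitivity analysis

First-order Sobol' indices of the constant-cost model's
V<sub>c,max25</sub> over the five drivers, by the Saltelli radial design:
one scrambled 2d-dimensional Sobol' sequence supplies matrices A and B
(n_base = 2¹⁴ by default, N(d+2) model runs), and
V_i = mean(f(B)(f(A_B^i) − f(A))).  Indices are reported raw and normalised
to sum to 100% ("relative contribution").  The estimator reproduces the
closed-form Ishigami indices to ±0.02 and splits an additive
equal-variance model 50/50 ± 2% (standing tests).  Default input ranges
(T_g 0–30 °C, PAR 100–2400 µmol m⁻² s⁻¹, VPD 0.1–4 kPa, C_a 360–420 ppm,
elevation 0–4500 m) are demo placeholders for a global dataset's spans and
config-exposed; under them PAR (≈ 55%) and T_g (≈ 44%) dominate.

## 7. Synthetic data generator

Covariates are drawn from a Gaussian copula over 17 latents with fixed
cross-correlations (e.g. T_g–VPD +0.5, VPD–α −0.5, soil C–N +0.8,
LMA–N_a +0.5) and mixed marginals: truncated normal T_g(16, 7) on [0, 30],
lognormal PAR/VPD/precipitation/elevation/soil C/N/CEC/LMA/N_a, uniform soil
pH (4–8.5) and α (0.3–1.3); texture fractions are exponentiated latents
normalised to sum to exactly 100; C:N is the ratio of the generated C and N.

Two ground-truth modes:

- `regression_truth`: V<sub>c,max25,i</sub> = γ₀ + Σγ_j z_ij + ε with
  standardised-scale defaults γ = {N_a +16, VPD −10, soil pH +8,
  precipitation +7, elevation −8} µmol per SD, γ₀ = 70, site noise SD 10.
  These give V<sub>c,max25</sub> a CV of ≈ 35% with the covariate signal
  carrying ≈ 84% of its variance — chosen so the kinetics-only model
  explains ≈ 0.69 and the covariate regression ≈ 0.91 of
  V<sub>c,max</sub>(T_g), the qualitative two-level structure seen in global
  compilations.  A floor at 5 µmol m⁻² s⁻¹ guards against negative draws
  (rarely binding; it introduces a slight nonlinearity at the extreme left
  tail).
- `optimality_truth`: c_i = β₀ + Σβ_j z_ij with β₀ = 0.053 and edaphic
  defaults {soil pH −0.008, α +0.005, soil N −0.004, CEC +0.003} (c CV ≈
  20%); V<sub>c,max</sub>(T_g) from the optimality model, multiplicative
  site noise (5% default), back-converted to the measurement temperature.
  If > 1% of sites draw an infeasible cost the β are halved with a warning.

Measurement level: T_meas = T_g + N(2, 3²) jitter, replicate multiplicative
noise 5%, three replicates per site by default.  The truth table records
every latent (true V<sub>c,max25</sub>, true cost, the generating
coefficients on both standardised and raw scales).

What the generator does **not** emulate: geographic/species structure,
non-linear covariate responses (the pH hump is represented by a linear
stand-in), heteroscedastic measurement error, shared-site pseudo-replication
across species.  Passing tests therefore demonstrate that the machinery
recovers truth under the assumed data-generating processes, not that those
processes describe any real dataset.

## 8. Problem sizes and determinism

Default experiment sizes — 200 sites, 5 × 100 CV for the statistical track,
5 × 10 CV for GA calibration experiments, n_base = 2¹⁴ for sensitivity —
keep a full comparison run near a minute on one CPU.  A single top-level
seed fans out to per-stage seeds by fixed offsets; every reported number is
regenerable from the logged config, and all stochastic components
(generator, CV folds, GA, Sobol' scrambling) take explicit seeds.

## 9. Known limitations

- The cost model is purely phenomenological; nothing constrains β to a
  mechanistic interpretation of nutrient-acquisition costs.
- Exhaustive selection is limited to 20 candidates (2^p fits).
- The optimality module covers C₃ leaves only; no soil-moisture stress on
  φ₀, no J_max temperature response, no canopy upscaling.
- Importance and sensitivity analyses assume independent sampling of the
  inputs within their ranges; correlated real-world drivers make
  "relative contribution" range-dependent.
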