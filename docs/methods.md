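# Methods

This note documents the model, the numerical choices and the design
decisions behind `qspvct`, and states what the synthetic-data-driven tests
do and do not demonstrate.

## 1. The reduced QSP-IO model

### Structure

Four compartments: tumor, tumor-draining lymph node (TDLN), central
(blood) and peripheral (rest of body). 24 state variables:

| block | states | compartments |
|---|---|---|
| tumor | cancer cells, CD8 Teff, CD4 Th, Treg, mature APC, M1, M2, cytokine | tumor |
| priming | mature APC, CD8, CD4, Treg | TDLN |
| circulation | CD8, CD4, Treg | central |
| antibody | intact and cleaved pools | all four |
| bookkeeping | cumulative cleaved amount | — |

Cell amounts are counts, the cytokine pool is in arbitrary units, and
antibody amounts are mol. T cells are modeled in tumor/TDLN/central only;
the peripheral compartment carries antibody alone — it exists to account
for off-target drug exposure, not immune dynamics. Cancer cells and
macrophages are tumor-resident.

### Tumor and immune dynamics

Cancer cells grow logistically (rate `growth_rate`, capacity `c_max`,
default 3·10¹¹ cells ≈ a 10-cm sphere at the default geometry) and are
killed at

```
kill = k_kill · Teff · C/(C + K_C) · (1 − η·s) · 1/(1 + Treg/K_T) · 1/(1 + M2/K_M2)
```

where `s` is the PD-1 engagement by unblocked PD-L1 (below). Killing
releases cytokine; cytokine matures APCs from a tumor-resident pool; APCs
migrate to the TDLN and prime T cells at rates proportional to

```
ψ(TCC) = TCC/(TCC + K_TCC)      (clonal breadth; TMB proxy)
φ(Kd)  = Kd_ref/(Kd_ref + Kd)   (neoantigen presentation strength)
```

Primed cells egress to blood and infiltrate the tumor at a rate that
saturates with tumor volume. CD8 cells in the tumor are additionally
exhausted at `k_exh · C/(C+K_C) · (c₀ + (1−c₀)·s)` — checkpoint engagement
accelerates exhaustion, and blockade relieves it down to the fraction
`c₀ = 0.2`. Tregs and M2 macrophages suppress killing through the
saturating factors above; M1 recruitment follows cytokine, M2 recruitment
and M1→M2 polarization follow tumor burden.

### Checkpoint pharmacology (quasi-static)

Receptor amounts (~10⁻¹² mol of PD-L1) are negligible against the dose
(~10⁻⁵ mol at 10 mg/kg), so binding does not deplete the antibody and the
out-of-synapse PD-L1 occupancy is taken at mass-action equilibrium,

```
occ = A_act / (A_act + Kd_ab),   A_act = (f_open·A_intact + A_cleaved)/V_tumor
```

Synapse PD-1 engagement is `s = (1−occ)/((1−occ) + K_s)`. This
quasi-static treatment removes the fastest rates from the system (binding
at diffusion-limited on-rates would add ~10⁴/day eigenvalues) and is the
reason an explicit integrator suffices. Bound species are reported as
derived pools (occupancy × total PD-L1, split between open- and
cleaved-antibody complexes). Synapse occupancies of the remaining ligands
(PD-L2, CTLA4, CD28, TCR, MHC, CD80) are reported as fixed competitive
equilibrium values; they do not feed back into the reduced dynamics.

### Masked-antibody kinetics

Each antibody carries two masks on cleavable linkers. Each mask is an
independent two-state (closed/open) unit with equilibrium constant
`K_M = k_open/k_close`; at equilibrium the probability that both masks are
closed is `(1+K_M)⁻²`, so the binding-competent ("≥ 1 site exposed")
fraction of the *intact* pool is

```
f_open(K_M) = 1 − (1 + K_M)⁻²
```

Mask exchange is fast relative to PK, so the open/closed split is treated
as an algebraic fraction of the intact pool rather than as separate slow
states (the tests verify `f_open` against a brute-force integration of
the full per-mask kinetics). Cleavage is a first-order, irreversible
conversion intact → cleaved at rate `k_cvg`, *in the tumor compartment
only* (tumor-resident proteases); a cumulative-cleaved state provides the
irreversibility audit. The unmasked comparator arm injects the same
molecule with `f_open` forced to 1 — identical PK constants — which makes
the masked arm converge exactly to the unmasked arm as `K_M → ∞`.

### Antibody PK

Linear disposition: clearance from central (`k_clear_ab`), flow-limited
exchange with TDLN and peripheral, and permeability-limited exchange with
the tumor (`k_perm_tumor` per mL of tumor). The peripheral flux carries a
vascular partition factor `sigma_peripheral = 0.02` (antibodies penetrate
peripheral tissue poorly), which produces the strong
central ≫ peripheral exposure gradient. Boluses add
`dose·body_mass/MW` mol to the central intact pool at each dose time.

## 2. Numerical integration

The right-hand side and a Dormand–Prince 5(4) adaptive stepper are
numba-compiled. Defaults: `rtol = 1e-8` and a per-state absolute
tolerance vector (1e-3 for cell counts, 1e-9 for cytokine, 1e-18 for
molar amounts) — state magnitudes span ~20 orders, so a single scalar
atol would be meaningless for part of the vector. Steps land exactly on
the output grid (1 day in trials, 5 days during pre-treatment growth);
dosing is handled by integrating between dose times and applying state
jumps, so no discontinuity ever sits inside a step. Tiny negative
undershoots are clipped to zero after each accepted step. Because the
quasi-static treatment caps all rates at a few per day, the explicit pair
is stable at ~1-day steps; a full patient trial integrates in
milliseconds, which is what makes 10⁴–10⁵-simulation analyses (TCC
stratification, cohort scans) tractable on one CPU.

Pre-treatment growth stops at the first grid point past the patient's
target diameter; the crossing state is interpolated linearly in diameter
between the bracketing grid points and the cancer-cell count is pinned to
the exact target.

## 3. Virtual-patient selection

Ratios are clamped to `[ε, 1−ε]` (default ε = 0.01, exposed in config;
the ε-diagnostic reports the relative change of the sample median as a
function of ε, which is zero until ε crosses the median). Densities are
Gaussian KDEs with Silverman bandwidth on `log(x/(1−x))` — the log of the
underlying cell-count ratio (log(M1/M2), log(Treg/CD8), log(CD4/CD8)),
which the ε clamp bounds symmetrically. By default one 1-D KDE per active
ratio is fitted and multiplied (product mode); a joint-KDE mode is
available. Identical-sample degeneracies fall back to a narrow Gaussian
atom. Density values below 1e-12 are floored before forming the ratio
`f_ref/f_pla`, and inclusion probabilities are clipped to [0, 1].

β is calibrated by simulated annealing on log β (500 iterations,
geometric cooling 0.99 from T₀ = 0.1, step 0.5): the objective is the
*expected selected fraction* minus `λ` times the sum over active ratios
of the Kolmogorov–Smirnov distance between the probability-weighted
plausible distribution and the reference sample (λ = 5 by default). The
two terms are balanced so that, when the distributions overlap, the
optimum sits just below the clipping regime: β as large as possible
(cohort size) without `min(1, β·r)` saturating and dragging the selected
distribution back toward the plausible one. At temperature 0 the walk
reduces to a greedy hill-climb. The objective is a documented design
choice: it is declared in the annealing config and logged with every run.

A structural caveat: selection can only *thin* the plausible cohort.
When the reference distribution has mass where the plausible cohort has
none (support deficit), no β can remove the resulting KS floor; the
synthetic shifted-cohort generator therefore applies its location shift
on the logit scale, which preserves support.

## 4. Trial readouts

Percent change is evaluated at the final trial day (best-response mode is
available but off by default). RECIST classes: PD at ≥ +20 %, PR at
≤ −30 %, CR when the final diameter is below 0.2 cm, SD otherwise.
Progression for PFS is +20 % over the running nadir (baseline included);
a baseline-referenced mode is available. The Kaplan–Meier estimate and
its exponential-Greenwood log(−log) 95 % CI come from `lifelines`; the
tests check the estimator against a brute-force product-limit
computation. Exposure is the trapezoidal AUC of active antibody
(`f_open`·intact + cleaved) per compartment in %dose/g, with tumor mass
tracking the simulated volume at 1 g/mL and fixed masses (equal to the
distribution volumes at unit density) for the other compartments.

## 5. Analyses

- **PRCC**: rank-transform all columns, residualize each parameter's and
  the output's ranks on all other parameters (linear regression with
  intercept), correlate residuals. Constant columns are dropped with a
  warning. For a single parameter this reduces exactly to Spearman
  correlation; the tests cross-check against an independent
  partial-Spearman implementation.
- **Responder contrasts**: two-sided Mann–Whitney rank-sum by default
  (the distribution-free choice; Welch's t by config), stars at
  0.05/0.01/0.001. Identical samples are reported as p = 1.
- **Median split**: ties label as "≥ median".
- **TCC stratification**: the TCC marginal is cut at its own quantiles
  into 10 equal-probability bands; each band re-runs the full
  generate → select → treat pipeline with only the TCC truncation
  changed. ORR CIs are Wilson score intervals (a CI method had to be
  chosen; Wilson behaves well at small counts).

## 6. Synthetic data and study conditions

The omics reference emulates an iAtlas-style export: per-sample
proportions of M1, M2, Treg, CD8, CD4 in leukocytes, generated as beta
marginals coupled by a Gaussian copula with a specified rank-correlation
matrix. Default marginals are right-skewed and put mass at both clamp
regions so every branch of the ratio definition is exercised; defaults
include mild positive rank correlations within the T-cell and macrophage
lineages. What it does *not* emulate: deconvolution noise, batch
structure, cancer-type composition, or any real iAtlas marginal — so
passing selection tests demonstrates the machinery (density ratio,
annealing, thinning) on realistic *shapes*, not agreement with any real
cohort.

Patient-level parameter distributions (the study conditions) are:
growth rate lognormal(median 0.015/day, σ 0.35), initial diameter
uniform 2–4 cm, neoantigen Kd log-uniform 0.3–30 nM, TCC lognormal with
geometric median 93 clones (σ 0.8; the NSCLC-like setting used
throughout), cleavage rate lognormal(median 0.1/day), masking constant
K_M log-uniform 10⁻³–10⁻¹, exhaustion rate lognormal(median 0.08/day),
killing rate lognormal(median 5/day), antibody clearance
lognormal(median 0.25/day), body mass normal(70, 10) kg, plus lognormal
heterogeneity in CD4/Treg priming and M1/M2 recruitment that spreads the
pre-treatment immune ratios across patients. The fixed physiological
constants and these medians are this package's own calibration of the
reduced model, chosen so that (i) proposed tumors reach 2–4 cm within
the 8000-day horizon, (ii) the 10 mg/kg Q2W masked arm produces a mixed
RECIST spread with a response rate in the mid-teens, (iii) reversible
unmasking alone saturates PD-L1 at high dose (antibody Kd 0.1 nM), so
masked and unmasked efficacy are similar while the cleaved pool still
dominates tumor exposure, and (iv) exposure is strongly
tumor-localized (tumor ≈ 10× central; peripheral ~2 orders below tumor).

## 7. Known limitations

- The reduced system is structurally faithful (compartments, cell types,
  mask states, checkpoint logic) but not numerically calibrated to any
  clinical dataset; absolute ORR/PFS values are illustrative of the
  workflow, not predictions.
- No cancer-associated fibroblasts, no metastatic lesions, no
  toxicity/organ-resolved PBPK, no masking of ligands other than PD-L1
  out of synapse — all out of scope by design.
- The annealing objective is a declared stand-in; any calibration that
  maximizes cohort size subject to distribution fidelity could be
  substituted behind `calibrate_beta`.
- Bernoulli selection at small cohort sizes leaves few virtual patients
  (selection rates of a few percent are expected when three constraints
  are active), so cohort-level statistics carry binomial noise; scale
  `n_proposed` accordingly.
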