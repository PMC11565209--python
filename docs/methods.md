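# Methods

This note documents the models gasxkit fits, the numerical choices behind
them, what the synthetic-data generator does and does not emulate, and the
known limits of the estimators.

## Gas-exchange data model

A `GasxSeries` is one plant measured under one protocol: elapsed time `t`
(seconds from the first record of the protocol segment, strictly
increasing), irradiance `Q` (PPFD, µmol m⁻² s⁻¹), net assimilation `A`
(µmol m⁻² s⁻¹), stomatal conductance to water vapour `gs` (mol m⁻² s⁻¹),
and the CO₂ mole fractions `Ci`/`Ca` (µmol mol⁻¹).  Readers accept comma- or
tab-delimited text with configurable column mapping (defaults cover the
common IRGA export dialects, e.g. `Photo`/`Cond`/`PARi`); unknown columns
are carried through untouched, and floats are parsed with correctly-rounded
(`round_trip`) conversion so write→read round trips preserve every bit.
`Ca` more than 5% off the 400 µmol mol⁻¹ cuvette set-point triggers a
warning, not an error: it marks an off-protocol run, not invalid data.

Windowed means use closed intervals on both ends, so "the last 5 min" of a
10 s grid includes both boundary samples.  Protocol validation is
reporting-only: it checks the twelve nominal light-curve set-points (±5%,
with a 10 µmol m⁻² s⁻¹ floor for the dim levels) in non-increasing order,
or the two step-change plateaus and near-10 s sampling, and never mutates
data.

## Light-response model

`A(Q) = φ·Q·A_max/(φ·Q + A_max) − R_d` — a rectangular hyperbola
(Michaelis–Menten form) with dark respiration offset.  Parameterising by
(φ, A_max, R_d) makes the apparent quantum yield an analytic property of the
fit: dA/dQ at Q = 0 equals φ exactly, so no post-hoc slope regression over
an arbitrary "low-light" subset is needed (that alternative is still easy to
compute from the stored points; the parameter form is the default and the
one reported).

Fitting is trust-region least squares with positivity bounds and a
deterministic multi-start: φ₀ from the OLS slope of the three lowest
nonzero-Q points, R_d₀ from the dark records (0.5 µmol m⁻² s⁻¹ if absent),
A_max₀ = max(A) + R_d₀, each also perturbed ×0.5/×2 (9 starts).  Tolerances
are 1e-14 so noiseless synthetic curves recover their truth to machine
precision.  At least four distinct irradiance levels are required.

A_sat and g_ssat are deliberately *measured* means at the nominal
2000 µmol m⁻² s⁻¹ level (matching tolerance ±5%), not the model asymptote:
A_max is a gross-assimilation asymptote the protocol never reaches, while
the saturating-light means are the quantities a screen compares across
genotypes.

## Induction model

Both channels of the step response are fitted with the same time-lagged
sigmoid (Gompertz form), `y(t) = y0 + (yf − y0)·exp(−exp((λ − t)/k))`, with
time measured from the step.  The reported time constant τ is `k`; λ is the
initial delay and is reported separately rather than folded into τ.  A
single functional family for A and g_s keeps τ_ai and τ_i directly
comparable, and the sigmoid subsumes a simple exponential rise (λ → 0).
Decreasing steps (stomatal closure) are fitted by the same machinery with
yf < y0.

Numerical choices:

* the step is located by thresholding Q at the midpoint of its range
  (robust to lamp set-point jitter); exactly one upward crossing is
  required;
* multi-start grid λ ∈ {0, 30, 60, 120, 300} s × k ∈ {30, 100, 300, 1000} s
  (τ spans two orders of magnitude across genotypes), ranked by raw SSE,
  best six refined by bounded least squares (λ ∈ [0, t_max],
  k ∈ (0, 20·t_max]);
* y0 initialised from the baseline mean, yf from the final 120 s;
* a trace whose apparent amplitude |yf − y0| is below 3× the baseline
  standard deviation is flagged `no_response` instead of fitted — a time
  constant for a flat trace is meaningless;
* W_i = A/g_s is masked (NaN) where g_s < 0.005 mol m⁻² s⁻¹, below typical
  instrument resolution, rather than letting ratios explode.

**Limitation — slow responders.**  With a 30 min post-step window, time
constants approaching 900–1200 s leave the final plateau unobserved; yf and
k then trade off, and λ̂–k̂ trade-off also widens single-fit scatter.  All
fits still land on the global SSE optimum (verified against refinement from
the true parameters), so this is estimator statistics, not an optimisation
artifact: single-fit errors of 10–30% occur at the slow extreme, medians
over ~20 replicates stay within ~10% (±15% at the extremes), and a mild
negative bias in k̂ appears as τ approaches the window length.  Trait
medians over replicate plants are the recommended panel-level quantity.

## Anatomical maximum stomatal conductance

`g_smax = d·SD·a_max / (v·(l + (π/2)·√(a_max/π)))`, the standard
diffusion-limited ceiling: d (24.6×10⁻⁶ m² s⁻¹) is the diffusivity of water
vapour in air and v (24.4×10⁻³ m³ mol⁻¹) the molar volume of air, both at
25 °C and overridable.  The pore is an ellipse with major axis the pore
length p and minor axis p/2 (a_max = π·p²/8); pore depth l is a quarter of
the guard-cell length; √(a_max/π) is the radius of the equal-area circle
(the end-correction term, without which the expression is dimensionally
inconsistent).  All computation is in SI; densities below 10⁶ m⁻² are
rejected with a hint because they almost always mean a mm⁻² value was
passed unconverted.

Per plant and surface, geometry is averaged over the measured stomata
*before* applying the equation (the equation is applied to the mean
stoma, not averaged over per-stoma conductances), and density pools counts
over all fields of view (Σcounts/Σareas, weighting fields by area).
Leaf-level g_smax is the sum of the two surfaces: the abaxial and adaxial
stomatal populations are diffusion pathways in parallel.

## Panel statistics

ANOVA uses sequential (type I) sums of squares via an OLS fit, which keeps
unbalanced accession panels well-defined; a zero-residual decomposition is
flagged `degenerate` with p reported as 0 for separated groups.  Tukey HSD
computes q = |Δmean|/√(MS_within/2·(1/nᵢ + 1/nⱼ)) — the Tukey–Kramer
harmonic-mean correction, exact for balanced data — with adjusted p from
the studentized-range distribution.  The compact letter display uses
insert-and-absorb: start with one column holding all groups, split every
column containing a significantly different pair, absorb columns that are
subsets of others, assign letters in group-sort order.  The construction is
deterministic and guarantees the defining biconditional: two groups share a
letter iff they are not significantly different at α.

## Synthetic-data generator

The generator is the package's test bed: it emulates the measurement
protocols exactly (12 descending light levels with three steady records
each; a 5 min/10 s baseline at Q = 100 then 30 min/10 s at Q = 1000,
endpoints inclusive — 211 records) and draws accession truths from ranges a
diverse sorghum panel spans:

| parameter | default range | notes |
|---|---|---|
| φ | 0.045–0.065 | apparent quantum yield, C₄ leaves |
| A_max | 20–55 µmol m⁻² s⁻¹ | asymptotic gross assimilation |
| R_d | 0.5–2.5 µmol m⁻² s⁻¹ | dark respiration |
| coupling slope b | 150–220 | A = a + b·g_s within accession |
| τ_i (k_gs) | 42–1062 s | log-uniform |
| τ_ai (k_A) | 92–1235 s | log-uniform, copula-correlated with τ_i (ρ = 0.6) |
| λ | 10–120 s | shared between channels per accession |
| SD abaxial / adaxial | 51–185 / 28–121 mm⁻² | abaxial denser on average |
| guard-cell length | 30–50 µm | pore length 0.40–0.60 of it |
| σ_A / σ_gs | 0.3 / 0.005 | typical IRGA channel noise |

Structural choices:

* **g_s is derived from A** through the inverted per-accession coupling
  line (floored at 0.005 mol m⁻² s⁻¹), not simulated independently — tight
  A–g_s coupling is the structure the pipeline is designed to detect, so
  the generator embodies it rather than hoping it emerges.
* **Accessions share a panel-level anchor line.**  Each accession's
  saturating point (A_sat*, g_ssat*) is placed on a common line
  (slope 150, intercept 1.3) and its own intercept a is derived from that
  placement (±0.5 jitter, clamped to [−17, −1.7] so a < 0 and W_i rises
  with irradiance).  Independent draws of (a, b) would scatter the
  cross-accession A_sat–g_ssat relation far below the near-perfect coupling
  such panels actually show; the anchor makes the tight panel regression a
  property of the generator, which the pipeline then verifies end to end.
* **C_i is back-filled** from a target C_i:C_a ratio (0.30 at saturating
  light, relaxing toward 0.95 in darkness with an 80 µmol m⁻² s⁻¹
  e-folding, ±0.01 jitter) rather than from a mesophyll model: the pipeline
  consumes only the ratio, and a mechanistic C₄ biochemistry model is out
  of scope.
* Anatomy: field counts ~ Poisson(SD × 0.29 mm²) — the field-of-view area
  of a ×10 objective is an assumption, exposed in config — and geometry
  ~ Normal with 5% CV truncated so 0 < pore < guard-cell length.
* τ_ai–τ_i correlation ρ = 0.6 is a modelling choice for the copula; the
  induced Pearson correlation of log-τ is ≈ (6/π)·asin(ρ/2) ≈ 0.59.

Determinism: every stream is derived from the user seed through
`SeedSequence([seed, stream])`, so identical seed + config give
byte-identical output files.

What the generator does **not** emulate — and hence what passing recovery
tests do not establish about instrument data: drift and autocorrelated
noise (noise is i.i.d. Gaussian per channel), leaf-temperature and VPD
covariation, C_i transients during induction (the ratio profile is
irradiance-indexed only), plant-to-plant variation in true parameters
within an accession (replicates differ only by noise realisation and
anatomy sampling), and any linkage between quantum yield and capacity
(φ and A_max are drawn independently, so the generator does not reproduce
the strong QY–A_sat correlation real panels can show).

## Pipeline

`run_pipeline` is a pure function of (inputs, config): simulate or load →
validate → fit both protocols per plant → anatomy → accession-level ANOVA +
Tukey letters per trait → Pearson correlations across accession means
(accession values are means of plant values; ANOVA runs on plant-level
replicates).  The manifest records the config hash, seed, package version
and every plant id; no timestamps or other wall-clock state enter any
output.  A stage failure aborts with the stage name and offending plant id.

Problem sizes: the default generator panel is 43 accessions; recovery
experiments in the tests and the acceptance script use 20 replicate fits
per condition, 200 random datasets for letter-display validity, 2000
simulations for the null family-wise error rate, and two plants per
accession for the panel-structure check — sizes at which all reported
medians and rates are stable.
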