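# gasxkit

Trait extraction and panel statistics for leaf gas-exchange screens of
photosynthesis and stomatal behaviour — built for studies that phenotype many
genotypes (e.g. a C₄ cereal accession panel) with two standard infra-red
gas-analyser protocols and a stomatal-anatomy survey, and then ask how
assimilation, stomatal conductance and water-use efficiency covary across the
panel.

## What it computes

**Steady-state light responses.** Net CO₂ assimilation over a 12-step
irradiance series (2000 → 0 µmol m⁻² s⁻¹) is fitted with a rectangular
hyperbola

```
A(Q) = φ·Q·A_max / (φ·Q + A_max) − R_d
```

so the apparent quantum yield QY = φ (the initial slope dA/dQ at Q = 0) is a
fitted parameter.  A_sat and g_ssat are the *measured* means at the nominal
2000 µmol m⁻² s⁻¹ level; C_i:C_a ratios are profiled per level.

**Induction kinetics.**  After a 100 → 1000 µmol m⁻² s⁻¹ step (10 s
sampling; 5 min baseline, 30 min response), both A and g_s are fitted with
the time-lagged sigmoid

```
y(t) = y0 + (yf − y0)·exp(−exp((λ − t)/k))
```

giving the time constants τ_ai (assimilation) and τ_i (stomatal opening),
the lag λ, and the steady end-points.  Intrinsic water-use efficiency
W_i = A/g_s is averaged over the last 5 min at each light level.

**Anatomical g_smax.**  From stomatal density SD, pore length p (elliptical
pore, a_max = π·p²/8) and guard-cell length (pore depth l = GCL/4):

```
g_smax = d·SD·a_max / ( v·( l + (π/2)·√(a_max/π) ) )
```

with d = 24.6×10⁻⁶ m² s⁻¹ and v = 24.4×10⁻³ m³ mol⁻¹ (25 °C).  Leaf-level
g_smax sums the abaxial and adaxial surfaces (parallel conductances).

**Panel statistics.**  One-/two-way ANOVA (sequential SS), Tukey HSD with
the Tukey–Kramer correction for unequal replication, compact letter
displays, and Pearson correlations across accession means.

**Synthetic panels.**  A deterministic generator emulates both measurement
protocols and the anatomy survey for panels of accessions with configurable,
field-realistic parameter ranges and a built-in A–g_s coupling line per
accession — so every estimator can be validated by parameter recovery.

## Worked example

```python
from gasxkit import fit_induction, split_step, steady_state_wi
from gasxkit.synthetic_data import AccessionTruth, simulate_step_response

truth = AccessionTruth(
    accession="DEMO", phi=0.055, Amax=45.0, Rd=1.8,
    coupling_slope=200.0, coupling_intercept=-10.0,
    k_gs=250.0, k_A=140.0, lam=50.0,
    SD_ab=120.0, SD_ad=70.0, gcl=40.0, pore=20.0,
    noise_A=0.3, noise_gs=0.005,
)
phases = split_step(simulate_step_response(truth, seed=3))
print(fit_induction(phases, "gs").k, fit_induction(phases, "A").k)
print(steady_state_wi(phases))
```

prints (`examples/02_induction_kinetics.py` shows the full script):

```
step detected at t = 300 s (30 baseline + 181 response samples)
tau_i  (gs)  :   279.2 s   (truth 250.0)   lag 0.0 s
tau_ai (A)   :   137.6 s   (truth 140.0)   lag 48.2 s
gs: 0.0551 -> 0.1648 mol m-2 s-1
A : 2.65 -> 22.93 umol m-2 s-1
Wi low/high  : 47.0 / 139.2 umol CO2 / mol H2O (n=30/31) — higher at high light
```

The stomatal time constant is recovered within ~12% at realistic channel
noise (τ̂ and λ̂ trade off; medians over replicates are tighter — see
`docs/methods.md`), the assimilation time constant within 2%, and W_i roughly
triples between the low- and high-light steady states, as expected when A
rises faster than g_s along a coupling line with a negative intercept.

The other scripts under `examples/` cover the light-response fit, the
anatomical g_smax calculation (the reference geometry 100 mm⁻², 20 µm pore,
40 µm guard cell gives 0.7503 mol m⁻² s⁻¹), and the panel pipeline with
Tukey letters.

A thin CLI mirrors the pipeline stages:

```
gasxkit simulate --seed 1 --out panel/
gasxkit run-all --seed 1 --out results/
gasxkit recover --truths results/dataset/truths.tsv --traits results/traits.tsv --out rec.tsv
```

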