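"""Synthetic accession panels with the statistical structure the analysis assumes.

The generator emulates the two gas-exchange measurement protocols (a 12-step
light-response curve and a 100→1000 µmol m⁻² s⁻¹ step change sampled every
10 s) and the stomatal-anatomy survey (Poisson field counts, near-normal
guard-cell and pore lengths), for a panel of accessions whose ground-truth
parameters are drawn from ranges anchored to what diverse sorghum panels
actually span:

* A–g_s coupling lines A = a + b·g_s with slopes b in 150–220 µmol CO₂ per
  mol H₂O and intercepts a in −17…−1.7 µmol m⁻² s⁻¹;
* time constants τ for stomatal opening in 42–1062 s and for assimilation in
  92–1235 s, drawn log-uniformly with positive cross-correlation (ρ = 0.6);
* abaxial stomatal densities 51–185 mm⁻², adaxial 28–121 mm⁻² (abaxial
  higher on average).

g_s is derived from A through the inverted coupling line rather than
simulated independently — tight A–g_s coupling is the structural assumption
the pipeline is built to detect, so the generator must embody it.  C_i is
back-filled from a target C_i:C_a ratio (≈0.30 above 250 µmol m⁻² s⁻¹,
rising toward C_a in dim light) rather than from a mesophyll model.

Everything is deterministic given the seed; identical seed and config produce
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data_model import (
    AnatomyRecord,
    GasxSeries,
    LIGHT_CURVE_LEVELS,
    Protocol,
    STEP_HIGH_PPFD,
    STEP_LOW_PPFD,
    write_anatomy_table,
    write_gasx_table,
)
from .induction_kinetics import sigmoid_response
from .light_response import rectangular_hyperbola

__all__ = [
    "AccessionTruth",
    "GeneratorConfig",
    "PanelData",
    "sample_panel",
    "simulate_light_curve",
    "simulate_step_response",
    "simulate_anatomy",
    "simulate_panel",
    "write_dataset",
    "read_truths",
]


@dataclass(frozen=True)
class AccessionTruth:
    """Ground-truth parameter set for one synthetic accession."""

    accession: str
    phi: float                 # apparent quantum yield
    Amax: float                # µmol m⁻² s⁻¹ (asymptotic gross assimilation)
    Rd: float                  # µmol m⁻² s⁻¹
    coupling_slope: float      # b in A = a + b·gs, µmol CO₂ per mol H₂O
    coupling_intercept: float  # a, µmol m⁻² s⁻¹ (may be negative)
    k_gs: float                # s, stomatal time constant (τ_i)
    k_A: float                 # s, assimilation time constant (τ_ai)
    lam: float                 # s, shared induction lag
    SD_ab: float               # mm⁻²
    SD_ad: float               # mm⁻²
    gcl: float                 # µm, guard-cell length
    pore: float                # µm, pore length
    noise_A: float             # µmol m⁻² s⁻¹
    noise_gs: float            # mol m⁻² s⁻¹

    def __post_init__(self) -> None:
        for name in ("phi", "Amax", "Rd", "coupling_slope", "k_gs", "k_A",
                     "SD_ab", "SD_ad", "gcl", "pore"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not (30.0 <= self.k_gs <= 1500.0 and 30.0 <= self.k_A <= 1500.0):
            raise ValueError("time constants must lie within [30, 1500] s")
        if not self.pore < self.gcl:
            raise ValueError("pore length must be shorter than guard-cell length")


@dataclass(frozen=True)
class GeneratorConfig:
    """Panel generator settings (all ranges inclusive; units as in AccessionTruth)."""

    n_accessions: int = 43
    n_plants: int = 4
    phi_range: tuple[float, float] = (0.045, 0.065)
    amax_range: tuple[float, float] = (20.0, 55.0)
    rd_range: tuple[float, float] = (0.5, 2.5)
    slope_range: tuple[float, float] = (150.0, 220.0)
    # shared panel-level Asat–gssat anchor line; per-accession intercepts are
    # derived from it so the cross-accession coupling is tight by construction
    panel_slope: float = 150.0
    panel_intercept: float = 1.3
    intercept_sd: float = 0.5
    intercept_clip: tuple[float, float] = (-17.0, -1.7)
    k_gs_range: tuple[float, float] = (42.0, 1062.0)
    k_a_range: tuple[float, float] = (92.0, 1235.0)
    tau_rho: float = 0.6               # copula correlation between k_A and k_gs
    lam_range: tuple[float, float] = (10.0, 120.0)
    sd_ab_range: tuple[float, float] = (51.0, 185.0)
    sd_ad_range: tuple[float, float] = (28.0, 121.0)
    gcl_range: tuple[float, float] = (30.0, 50.0)
    pore_frac_range: tuple[float, float] = (0.40, 0.60)  # pore length / gcl
    noise_A: float = 0.3               # IRGA-typical channel noise
    noise_gs: float = 0.005
    ci_ca_target: float = 0.30         # ratio at saturating light
    ci_ca_dark: float = 0.95           # ratio approached as Q → 0
    ci_ca_decay_q: float = 80.0        # e-folding PPFD of the dim-light rise
    ci_ca_jitter: float = 0.01
    Ca: float = 400.0
    gs_floor: float = 0.005
    # protocol timing
    sample_dt: float = 10.0            # s
    light_dwell: float = 180.0         # s per light-curve level
    light_records_per_level: int = 3
    baseline_duration: float = 300.0   # s at Q=100 before the step
    response_duration: float = 1800.0  # s at Q=1000 after the step
    # anatomy survey
    n_fields: int = 9
    n_stomata: int = 9
    field_area_mm2: float = 0.29       # ×10-objective field of view (assumed)
    geometry_cv: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown generator config keys: {sorted(unknown)}")
        for key, val in raw.items():
            if isinstance(val, list):
                raw[key] = tuple(val)
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = {
            k: list(v) if isinstance(v, tuple) else v
            for k, v in dataclasses.asdict(self).items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


def _uniform(rng: np.random.Generator, lo_hi: tuple[float, float], size=None):
    lo, hi = lo_hi
    return rng.uniform(lo, hi, size=size)


def sample_panel(
    n_accessions: int | None = None,
    n_plants: int | None = None,
    seed: int = 0,
    config: GeneratorConfig | None = None,
) -> list[AccessionTruth]:
    """Draw ground-truth parameters for a panel of accessions.

    Deterministic given ``seed``.  τ_ai and τ_gs are drawn log-uniformly over
    their ranges through a Gaussian copula with correlation ``tau_rho``, so
    accessions with fast stomata also tend to have fast assimilation — the
    cross-trait association the panel analysis looks for.  ``n_plants`` only
    fixes the replicate count recorded with the panel; plant-to-plant
    variation comes from measurement noise at simulation time.
    """
    cfg = config or GeneratorConfig()
    if n_accessions is None:
        n_accessions = cfg.n_accessions
    if n_plants is None:
        n_plants = cfg.n_plants
    if n_accessions < 1 or n_plants < 1:
        raise ValueError("need at least one accession and one plant")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EED]))

    # correlated uniforms for the two time constants (Gaussian copula)
    cov = np.array([[1.0, cfg.tau_rho], [cfg.tau_rho, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n_accessions, method="cholesky")
    from scipy.stats import norm

    u = norm.cdf(z)

    def _loguniform(u_col, lo_hi):
        lo, hi = lo_hi
        return np.exp(np.log(lo) + u_col * (np.log(hi) - np.log(lo)))

    k_A = _loguniform(u[:, 0], cfg.k_a_range)
    k_gs = _loguniform(u[:, 1], cfg.k_gs_range)

    truths = []
    width = max(3, len(str(n_accessions)))
    for i in range(n_accessions):
        gcl = float(_uniform(rng, cfg.gcl_range))
        phi = float(_uniform(rng, cfg.phi_range))
        amax = float(_uniform(rng, cfg.amax_range))
        rd = float(_uniform(rng, cfg.rd_range))
        slope = float(_uniform(rng, cfg.slope_range))
        # pin each accession near the shared panel-level Asat–gssat line:
        # its saturating point (Asat*, gssat*) sits on that line, so the
        # cross-accession coupling is tight while within-accession slopes vary
        asat_star = float(rectangular_hyperbola(2000.0, phi, amax, rd))
        gssat_star = (asat_star - cfg.panel_intercept) / cfg.panel_slope
        intercept_raw = asat_star - slope * gssat_star + float(
            rng.normal(0.0, cfg.intercept_sd)
        )
        intercept = float(np.clip(intercept_raw, *cfg.intercept_clip))
        truths.append(
            AccessionTruth(
                accession=f"ACC{i + 1:0{width}d}",
                phi=phi,
                Amax=amax,
                Rd=rd,
                coupling_slope=slope,
                coupling_intercept=intercept,
                k_gs=float(k_gs[i]),
                k_A=float(k_A[i]),
                lam=float(_uniform(rng, cfg.lam_range)),
                SD_ab=float(_uniform(rng, cfg.sd_ab_range)),
                SD_ad=float(_uniform(rng, cfg.sd_ad_range)),
                gcl=gcl,
                pore=float(_uniform(rng, cfg.pore_frac_range)) * gcl,
                noise_A=cfg.noise_A,
                noise_gs=cfg.noise_gs,
            )
        )
    return truths


def _ci_ca_ratio(Q, cfg: GeneratorConfig):
    """Target C_i:C_a per irradiance: ≈ the saturating-light target above
    ~250 µmol m⁻² s⁻¹, rising toward C_a in dim light and darkness."""
    Q = np.asarray(Q, dtype=float)
    return cfg.ci_ca_target + (cfg.ci_ca_dark - cfg.ci_ca_target) * np.exp(-Q / cfg.ci_ca_decay_q)


def _steady_state(truth: AccessionTruth, Q: np.ndarray):
    """Noise-free steady A and g_s at irradiance Q via the coupling line."""
    A = rectangular_hyperbola(Q, truth.phi, truth.Amax, truth.Rd)
    gs = (A - truth.coupling_intercept) / truth.coupling_slope
    return A, gs


def simulate_light_curve(
    truth: AccessionTruth,
    seed: int,
    plant_id: str = "P1",
    config: GeneratorConfig | None = None,
) -> GasxSeries:
    """One plant's 12-step light-response measurement.

    Each nominal level contributes ``light_records_per_level`` steady-state
    records (taken at the end of the dwell, 10 s apart); A comes from the
    rectangular hyperbola plus Gaussian noise, g_s from the inverted coupling
    line (floored), and C_i from the target C_i:C_a profile with jitter.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x11647]))
    levels = np.asarray(LIGHT_CURVE_LEVELS, dtype=float)
    nrec = cfg.light_records_per_level
    t, Q = [], []
    for idx, level in enumerate(levels):
        dwell_end = (idx + 1) * cfg.light_dwell
        for j in range(nrec):
            t.append(dwell_end - (nrec - 1 - j) * cfg.sample_dt)
            Q.append(level)
    t = np.asarray(t)
    Q = np.asarray(Q)
    A_clean, gs_clean = _steady_state(truth, Q)
    A = A_clean + rng.normal(0.0, truth.noise_A, size=len(t))
    gs = np.maximum(gs_clean + rng.normal(0.0, truth.noise_gs, size=len(t)), cfg.gs_floor)
    ratio = _ci_ca_ratio(Q, cfg) + rng.normal(0.0, cfg.ci_ca_jitter, size=len(t))
    ratio = np.clip(ratio, 0.01, 0.99)
    Ca = np.full(len(t), cfg.Ca)
    return GasxSeries(
        plant_id=plant_id, accession=truth.accession, protocol=Protocol.LIGHT_CURVE,
        t=t, Q=Q, A=A, gs=gs, Ci=ratio * Ca, Ca=Ca,
    )


def simulate_step_response(
    truth: AccessionTruth,
    seed: int,
    plant_id: str = "P1",
    config: GeneratorConfig | None = None,
) -> GasxSeries:
    """One plant's 100→1000 µmol m⁻² s⁻¹ step-change measurement.

    Baseline samples every 10 s for 5 min at Q=100 (steady model values),
    then the response sampled every 10 s for 30 min inclusive of both
    endpoints (30 + 181 = 211 records under default timing).  A and g_s each
    follow the induction sigmoid toward their own steady targets with their
    own time constants and a shared lag; channel noise is independent.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x57E9]))
    t_base = np.arange(0.0, cfg.baseline_duration, cfg.sample_dt)
    t_resp = np.arange(
        cfg.baseline_duration,
        cfg.baseline_duration + cfg.response_duration + 0.5 * cfg.sample_dt,
        cfg.sample_dt,
    )
    t = np.concatenate([t_base, t_resp])
    Q = np.concatenate(
        [np.full(len(t_base), STEP_LOW_PPFD), np.full(len(t_resp), STEP_HIGH_PPFD)]
    )
    A_lo_arr, gs_lo_arr = _steady_state(truth, np.array([STEP_LOW_PPFD]))
    A_hi_arr, gs_hi_arr = _steady_state(truth, np.array([STEP_HIGH_PPFD]))
    A_lo, gs_lo = float(A_lo_arr[0]), float(gs_lo_arr[0])
    A_hi, gs_hi = float(A_hi_arr[0]), float(gs_hi_arr[0])

    tr = t_resp - cfg.baseline_duration
    A_clean = np.concatenate(
        [np.full(len(t_base), A_lo), sigmoid_response(tr, A_lo, A_hi, truth.lam, truth.k_A)]
    )
    gs_clean = np.concatenate(
        [np.full(len(t_base), gs_lo), sigmoid_response(tr, gs_lo, gs_hi, truth.lam, truth.k_gs)]
    )
    A = A_clean + rng.normal(0.0, truth.noise_A, size=len(t))
    gs = np.maximum(gs_clean + rng.normal(0.0, truth.noise_gs, size=len(t)), cfg.gs_floor)
    ratio = _ci_ca_ratio(Q, cfg) + rng.normal(0.0, cfg.ci_ca_jitter, size=len(t))
    ratio = np.clip(ratio, 0.01, 0.99)
    Ca = np.full(len(t), cfg.Ca)
    return GasxSeries(
        plant_id=plant_id, accession=truth.accession, protocol=Protocol.STEP_CHANGE,
        t=t, Q=Q, A=A, gs=gs, Ci=ratio * Ca, Ca=Ca,
    )


def simulate_anatomy(
    truth: AccessionTruth,
    n_fields: int | None = None,
    n_stomata: int | None = None,
    seed: int = 0,
    plant_id: str = "P1",
    config: GeneratorConfig | None = None,
) -> list[AnatomyRecord]:
    """Stomatal-anatomy survey of one plant: both surfaces, Poisson field counts.

    Field counts ~ Poisson(SD_surface × field_area); guard-cell and pore
    lengths ~ Normal(truth, 5% CV) truncated so 0 < pore < guard-cell length.
    Geometry measurements ride on the first ``n_stomata`` field records of
    each surface.
    """
    cfg = config or GeneratorConfig()
    if n_fields is None:
        n_fields = cfg.n_fields
    if n_stomata is None:
        n_stomata = cfg.n_stomata
    if n_fields < 1 or n_stomata < 1:
        raise ValueError("need at least one field and one stoma")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA4A7]))
    records = []
    for surface, sd in (("abaxial", truth.SD_ab), ("adaxial", truth.SD_ad)):
        counts = rng.poisson(sd * cfg.field_area_mm2, size=n_fields)
        gcls = truth.gcl * (1.0 + cfg.geometry_cv * rng.standard_normal(n_stomata))
        pores = truth.pore * (1.0 + cfg.geometry_cv * rng.standard_normal(n_stomata))
        gcls = np.maximum(gcls, 0.2 * truth.gcl)
        pores = np.clip(pores, 0.1 * truth.pore, 0.95 * gcls)
        n_rows = max(n_fields, n_stomata)
        for i in range(n_rows):
            count = int(counts[i]) if i < n_fields else int(counts[-1])
            records.append(
                AnatomyRecord(
                    plant_id=plant_id,
                    accession=truth.accession,
                    surface=surface,
                    field_count=count,
                    field_area=cfg.field_area_mm2,
                    guard_cell_length=float(gcls[i]) if i < n_stomata else None,
                    pore_length=float(pores[i]) if i < n_stomata else None,
                )
            )
    return records


@dataclass
class PanelData:
    """A fully simulated panel: truths plus every series and anatomy record."""

    truths: list[AccessionTruth]
    n_plants: int
    light: list[GasxSeries] = field(default_factory=list)
    step: list[GasxSeries] = field(default_factory=list)
    anatomy: list[AnatomyRecord] = field(default_factory=list)

    def truths_frame(self) -> pd.DataFrame:
        """One row per (accession, plant) carrying the accession's truth."""
        rows = []
        for truth in self.truths:
            for p in range(self.n_plants):
                row = dataclasses.asdict(truth)
                row["plant_id"] = f"{truth.accession}-P{p + 1}"
                rows.append(row)
        df = pd.DataFrame(rows)
        cols = ["accession", "plant_id"] + [c for c in df.columns if c not in ("accession", "plant_id")]
        return df[cols]


def simulate_panel(
    truths: list[AccessionTruth],
    n_plants: int | None = None,
    seed: int = 0,
    config: GeneratorConfig | None = None,
) -> PanelData:
    """Simulate all measurements for a panel (deterministic per seed).

    Each plant gets its own derived random stream, so panels are reproducible
    and plants are independent noise realisations of their accession's truth.
    """
    cfg = config or GeneratorConfig()
    if n_plants is None:
        n_plants = cfg.n_plants
    panel = PanelData(truths=truths, n_plants=n_plants)
    for acc_idx, truth in enumerate(truths):
        for p in range(n_plants):
            pid = f"{truth.accession}-P{p + 1}"
            sub = int(np.random.SeedSequence([int(seed), acc_idx, p]).generate_state(1)[0])
            panel.light.append(simulate_light_curve(truth, sub, plant_id=pid, config=cfg))
            panel.step.append(simulate_step_response(truth, sub + 1, plant_id=pid, config=cfg))
            panel.anatomy.extend(
                simulate_anatomy(truth, seed=sub + 2, plant_id=pid, config=cfg)
            )
    return panel


def write_dataset(panel: PanelData, out_dir) -> dict[str, list[Path]]:
    """Write a panel in the layout the readers expect.

    ``gasx/light/<plant>.csv`` and ``gasx/step/<plant>.csv`` (one file per
    plant-protocol, long columns), ``anatomy.tsv`` and ``truths.tsv`` for
    recovery scoring.  Returns the written paths by category.
    """
    out = Path(out_dir)
    (out / "gasx" / "light").mkdir(parents=True, exist_ok=True)
    (out / "gasx" / "step").mkdir(parents=True, exist_ok=True)
    written: dict[str, list[Path]] = {"light": [], "step": [], "anatomy": [], "truths": []}
    for series in panel.light:
        path = out / "gasx" / "light" / f"{series.plant_id}.csv"
        write_gasx_table(series, path, sep=",")
        written["light"].append(path)
    for series in panel.step:
        path = out / "gasx" / "step" / f"{series.plant_id}.csv"
        write_gasx_table(series, path, sep=",")
        written["step"].append(path)
    anatomy_path = out / "anatomy.tsv"
    write_anatomy_table(panel.anatomy, anatomy_path)
    written["anatomy"].append(anatomy_path)
    truths_path = out / "truths.tsv"
    panel.truths_frame().to_csv(truths_path, sep="\t", index=False)
    written["truths"].append(truths_path)
    return written


def read_truths(path) -> pd.DataFrame:
    """Read a truths table written by :func:`write_dataset`."""
    return pd.read_csv(path, sep="\t")
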