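"""Steady-state light-response (A/Q) curve fitting and derived traits.

Net assimilation as a function of irradiance is modelled as a rectangular
hyperbola (Michaelis–Menten form) offset by dark respiration:

    A(Q) = φ·Q·A_max / (φ·Q + A_max) − R_d

parameterised so the apparent quantum yield φ (the initial slope dA/dQ at
Q = 0) is a fitted parameter rather than a post-hoc slope estimate, A_max is
the asymptotic light-saturated *gross* assimilation, and R_d ≥ 0 the dark
respiration rate.  A_sat and g_ssat — the traits used for the panel-level
coupling analysis — are *measured* means at the nominal 2000 µmol m⁻² s⁻¹
level, not model asymptotes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .data_model import (
    GasxSeries,
    LIGHT_CURVE_LEVELS,
    assign_nominal_levels,
    nominal_level_tolerance,
)

__all__ = [
    "LightResponseFit",
    "LightCurveSummary",
    "RegressionResult",
    "fit_light_response",
    "summarize_light_curve",
    "a_gs_regression",
    "rectangular_hyperbola",
]


def rectangular_hyperbola(Q, phi, Amax, Rd):
    """A(Q) = φ·Q·A_max/(φ·Q + A_max) − R_d (vectorised)."""
    Q = np.asarray(Q, dtype=float)
    return phi * Q * Amax / (phi * Q + Amax) - Rd


@dataclass(frozen=True)
class LightResponseFit:
    """Fitted rectangular-hyperbola parameters for one plant.

    ``phi`` is the apparent quantum yield (mol CO₂ mol⁻¹ photons), ``Amax``
    the asymptotic gross assimilation and ``Rd`` dark respiration (both
    µmol m⁻² s⁻¹); ``sse`` the residual sum of squares over ``n`` points.
    """

    phi: float
    Amax: float
    Rd: float
    sse: float
    n: int

    def __post_init__(self) -> None:
        if not (self.phi > 0 and self.Amax > 0 and self.Rd >= 0):
            raise ValueError(
                f"invalid light-response parameters phi={self.phi}, "
                f"Amax={self.Amax}, Rd={self.Rd}"
            )

    def predict(self, Q) -> np.ndarray:
        return rectangular_hyperbola(Q, self.phi, self.Amax, self.Rd)


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; carries the best attempt found."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


def _initial_guesses(Q: np.ndarray, A: np.ndarray) -> list[tuple[float, float, float]]:
    """Deterministic multi-start seeds.

    Base seed: φ₀ from the OLS slope of the three lowest nonzero-Q points, R_d₀
    from A at Q≈0 (0.5 if absent), A_max₀ = max(A) + R_d₀; plus scale
    perturbations to escape bad basins.
    """
    dark = Q <= nominal_level_tolerance(0.0)
    Rd0 = float(-A[dark].mean()) if dark.any() else 0.5
    Rd0 = max(Rd0, 0.0)
    nz = np.flatnonzero(~dark)
    order = nz[np.argsort(Q[nz])]
    low = order[:3]
    if len(low) >= 2 and np.ptp(Q[low]) > 0:
        slope = float(np.polyfit(Q[low], A[low], 1)[0])
    else:
        slope = 0.05
    phi0 = slope if slope > 0 else 0.05
    Amax0 = float(A.max()) + Rd0
    Amax0 = max(Amax0, 1e-3)
    seeds = []
    for fp in (1.0, 0.5, 2.0):
        for fa in (1.0, 0.5, 2.0):
            seeds.append((phi0 * fp, Amax0 * fa, Rd0))
    return seeds


def fit_light_response(series: GasxSeries) -> LightResponseFit:
    """Least-squares rectangular-hyperbola fit of A on Q.

    Requires ≥ 4 distinct irradiance levels.  Deterministic multi-start local
    optimisation; raises :class:`FitError` (carrying the best attempt) if no
    start converges.
    """
    Q, A = series.Q, series.A
    if len(np.unique(np.round(Q, 6))) < 4:
        raise ValueError(
            f"series {series.plant_id!r}: need ≥4 distinct Q levels to fit a light response"
        )
    best = None
    for p0 in _initial_guesses(Q, A):
        try:
            res = optimize.least_squares(
                lambda p: rectangular_hyperbola(Q, *p) - A,
                x0=np.asarray(p0),
                bounds=([1e-8, 1e-8, 0.0], [np.inf, np.inf, np.inf]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:
            continue
        sse = float(2 * res.cost)
        if res.success and (best is None or sse < best[0]):
            best = (sse, res.x)
    if best is None:
        raise FitError(f"series {series.plant_id!r}: light-response fit did not converge")
    sse, (phi, Amax, Rd) = best
    return LightResponseFit(phi=float(phi), Amax=float(Amax), Rd=float(Rd),
                            sse=sse, n=len(Q))


@dataclass(frozen=True)
class LightCurveSummary:
    """Traits read off one plant's light-response curve.

    QY is the fitted quantum yield; Asat/gssat are measured means at the
    nominal 2000 µmol m⁻² s⁻¹ level (±5% matching tolerance);
    ``ci_ca_by_level`` lists (nominal Q, mean C_i/C_a) per level.
    """

    QY: float
    Asat: float
    gssat: float
    ci_ca_by_level: tuple[tuple[float, float], ...]


def summarize_light_curve(series: GasxSeries, fit: LightResponseFit) -> LightCurveSummary:
    """Derive QY, A_sat, g_ssat and the per-level C_i:C_a profile."""
    assigned = assign_nominal_levels(series.Q)
    sat = assigned == 2000
    if not sat.any():
        raise ValueError(
            f"series {series.plant_id!r}: no samples at the nominal 2000 µmol m⁻² s⁻¹ level"
        )
    ratios = series.Ci / series.Ca
    by_level = []
    for level in LIGHT_CURVE_LEVELS:
        mask = assigned == level
        if mask.any():
            by_level.append((float(level), float(ratios[mask].mean())))
    return LightCurveSummary(
        QY=fit.phi,
        Asat=float(series.A[sat].mean()),
        gssat=float(series.gs[sat].mean()),
        ci_ca_by_level=tuple(by_level),
    )


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p: float
    n: int


def a_gs_regression(A, gs) -> RegressionResult:
    """OLS regression of A on g_s with Pearson R and two-sided p.

    The A–g_s coupling line (slope in µmol CO₂ per mol H₂O) is the central
    steady-state descriptor of stomatal–mesophyll coordination.
    """
    A = np.asarray(A, dtype=float)
    gs = np.asarray(gs, dtype=float)
    if len(A) != len(gs):
        raise ValueError("A and gs must have equal length")
    if len(A) < 3:
        raise ValueError("need at least 3 (A, gs) pairs")
    if np.ptp(gs) == 0:
        raise ValueError("gs has zero variance; regression undefined")
    if np.ptp(A) == 0:
        raise ValueError("A has zero variance; correlation undefined")
    res = stats.linregress(gs, A)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p=float(res.pvalue),
        n=len(A),
    )
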