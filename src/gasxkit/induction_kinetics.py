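"""Induction kinetics: time constants of A and g_s after a light step.

After a step increase in irradiance (here 100 → 1000 µmol m⁻² s⁻¹), both net
assimilation and stomatal conductance relax sigmoidally toward a new steady
state.  Both channels are fitted with the same time-lagged sigmoid

    y(t) = y0 + (yf − y0) · exp(−exp((λ − t)/k))

with ``t`` measured from the step, lag ``λ`` (s) and time constant ``k`` (s).
The reported time constant τ — τ_ai for assimilation, τ_i for stomatal
opening — is ``k``; λ is exposed separately.  The same machinery fits closing
responses (yf < y0).

Intrinsic water-use efficiency W_i = A/g_s (µmol CO₂ mol⁻¹ H₂O) is computed
pointwise with a conductance floor below which samples are masked rather than
divided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import optimize

from .data_model import GasxSeries, Protocol, ProtocolWarning

__all__ = [
    "SigmoidFit",
    "StepPhases",
    "SteadyStateWi",
    "sigmoid_response",
    "split_step",
    "fit_induction",
    "wi_timecourse",
    "steady_state_wi",
    "EPS_GS_DEFAULT",
]

#: Conductance floor for W_i; below instrument resolution the ratio explodes.
EPS_GS_DEFAULT: float = 0.005

#: Multi-start grid for the sigmoid fit — τ spans two orders of magnitude
#: across accessions, so a single start is not robust.
LAM_GRID: tuple[float, ...] = (0.0, 30.0, 60.0, 120.0, 300.0)
K_GRID: tuple[float, ...] = (30.0, 100.0, 300.0, 1000.0)


def sigmoid_response(t, y0, yf, lam, k):
    """Time-lagged sigmoid y(t) = y0 + (yf−y0)·exp(−exp((λ−t)/k))."""
    t = np.asarray(t, dtype=float)
    z = np.clip((lam - t) / k, -700.0, 50.0)
    return y0 + (yf - y0) * np.exp(-np.exp(z))


@dataclass(frozen=True)
class SigmoidFit:
    """Fitted induction parameters for one channel (A or g_s).

    ``k`` is the time constant τ in seconds; ``lam`` the lag.  When the step
    amplitude is below the noise floor no kinetics are fitted and
    ``no_response`` is True (``lam``/``k`` are NaN).
    """

    variable: str
    y0: float
    yf: float
    lam: float
    k: float
    sse: float
    n: int
    no_response: bool = False

    def __post_init__(self) -> None:
        if not self.no_response:
            if not self.k > 0:
                raise ValueError(f"time constant must be positive, got k={self.k}")
            if not self.lam >= 0:
                raise ValueError(f"lag must be non-negative, got lam={self.lam}")

    @property
    def tau(self) -> float:
        """Reported time constant (= k), seconds."""
        return self.k

    def predict(self, t) -> np.ndarray:
        if self.no_response:
            return np.full_like(np.asarray(t, dtype=float), self.y0)
        return sigmoid_response(t, self.y0, self.yf, self.lam, self.k)


@dataclass
class StepPhases:
    """A step-change series split at the irradiance transition.

    ``baseline`` holds the low-light samples (t < t_step), ``response`` the
    samples from the step onward; together they partition the parent series.
    """

    baseline: GasxSeries
    response: GasxSeries
    t_step: float

    def __post_init__(self) -> None:
        if self.baseline.t[-1] >= self.response.t[0]:
            raise ValueError("baseline must end before the response begins")
        dur = self.response.t[-1] - self.response.t[0]
        if dur < 600.0:
            warnings.warn(
                f"response phase only {dur:g} s (<10 min); kinetic fits may be unreliable",
                ProtocolWarning,
                stacklevel=2,
            )


def split_step(series: GasxSeries) -> StepPhases:
    """Locate the single upward irradiance step and split the series there.

    The transition is detected by thresholding Q at the midpoint of its range,
    which tolerates set-point jitter (Q≈98–103 then 995–1005).  Exactly one
    upward crossing and no downward crossing is required.
    """
    if series.protocol is not Protocol.STEP_CHANGE:
        raise ValueError(f"series {series.plant_id!r}: not a step-change series")
    Q = series.Q
    qlo, qhi = float(Q.min()), float(Q.max())
    if qlo <= 0 or qhi / max(qlo, 1e-12) < 5.0:
        raise ValueError(
            f"series {series.plant_id!r}: no ≥5-fold irradiance step found "
            f"(Q range {qlo:g}–{qhi:g})"
        )
    above = Q > 0.5 * (qlo + qhi)
    flips = np.diff(above.astype(int))
    ups = np.flatnonzero(flips == 1)
    downs = np.flatnonzero(flips == -1)
    if len(ups) != 1 or len(downs) != 0:
        raise ValueError(
            f"series {series.plant_id!r}: expected exactly one upward step, "
            f"found {len(ups)} up / {len(downs)} down transitions"
        )
    i_step = int(ups[0]) + 1  # first sample at the high level
    mask = np.zeros(len(series), dtype=bool)
    mask[i_step:] = True
    return StepPhases(
        baseline=series.subset(~mask),
        response=series.subset(mask),
        t_step=float(series.t[i_step]),
    )


def fit_induction(phases: StepPhases, variable: str) -> SigmoidFit:
    """Fit the sigmoid induction model to one channel of a step response.

    Time is measured from the step.  y0 is initialised from the baseline mean
    and yf from the final 120 s of the response; a deterministic (λ, k) grid
    seeds local least-squares refinement.  If the apparent amplitude is below
    3× the baseline standard deviation the trace is flagged ``no_response``
    instead of fitted.
    """
    if variable not in ("A", "gs"):
        raise ValueError(f"variable must be 'A' or 'gs', got {variable!r}")
    resp = phases.response
    if len(resp) < 60:
        raise ValueError(
            f"series {resp.plant_id!r}: response phase has {len(resp)} samples, need ≥60"
        )
    t = resp.t - phases.t_step
    y = getattr(resp, variable)
    base = getattr(phases.baseline, variable)
    y0_init = float(base.mean())
    tail = t >= t[-1] - 120.0
    yf_init = float(y[tail].mean())
    noise_floor = 3.0 * float(base.std(ddof=1)) if len(base) > 1 else 0.0
    if abs(yf_init - y0_init) < noise_floor:
        return SigmoidFit(
            variable=variable, y0=y0_init, yf=yf_init,
            lam=float("nan"), k=float("nan"),
            sse=float(np.sum((y - y0_init) ** 2)), n=len(y), no_response=True,
        )

    t_max = float(t[-1])
    bounds = (
        [-np.inf, -np.inf, 0.0, 1e-3],
        [np.inf, np.inf, t_max, 20.0 * t_max],
    )

    def residuals(p):
        return sigmoid_response(t, *p) - y

    # rank grid seeds by their raw SSE, refine the best few
    seeds = []
    for lam0 in LAM_GRID:
        for k0 in K_GRID:
            p0 = (y0_init, yf_init, min(lam0, t_max), k0)
            seeds.append((float(np.sum(residuals(p0) ** 2)), p0))
    seeds.sort(key=lambda s: s[0])

    best = None
    for _, p0 in seeds[:6]:
        try:
            res = optimize.least_squares(
                residuals, x0=np.asarray(p0), bounds=bounds,
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except Exception:
            continue
        sse = float(2 * res.cost)
        if res.success and (best is None or sse < best[0]):
            best = (sse, res.x)
    if best is None:
        raise RuntimeError(
            f"series {resp.plant_id!r}: induction fit for {variable!r} did not converge "
            f"(grid of {len(seeds)} starts exhausted)"
        )
    sse, (y0, yf, lam, k) = best
    return SigmoidFit(
        variable=variable, y0=float(y0), yf=float(yf),
        lam=float(lam), k=float(k), sse=sse, n=len(y),
    )


def wi_timecourse(series: GasxSeries, eps_gs: float = EPS_GS_DEFAULT) -> np.ndarray:
    """Pointwise intrinsic water-use efficiency W_i = A/g_s.

    Samples with g_s below ``eps_gs`` are returned as NaN (masked, not an
    error): below instrument resolution the ratio is meaningless.
    """
    wi = np.full(len(series), np.nan)
    ok = series.gs >= eps_gs
    wi[ok] = series.A[ok] / series.gs[ok]
    return wi


class SteadyStateWi(NamedTuple):
    wi_low: float
    wi_high: float
    n_low: int
    n_high: int


def steady_state_wi(phases: StepPhases, eps_gs: float = EPS_GS_DEFAULT,
                    window_s: float = 300.0) -> SteadyStateWi:
    """Steady-state W_i at each light level: mean over the last 5 min of each phase."""
    out = []
    for phase in (phases.baseline, phases.response):
        # a phase of n samples at spacing dt covers n·dt of measurement even
        # though its endpoints span only (n−1)·dt
        dt = float(np.median(np.diff(phase.t)))
        dur = phase.t[-1] - phase.t[0] + dt
        if dur < window_s:
            raise ValueError(
                f"series {phase.plant_id!r}: phase covers {dur:g} s, shorter than "
                f"the {window_s:g} s steady-state window"
            )
        wi = wi_timecourse(phase, eps_gs)
        mask = (phase.t >= phase.t[-1] - window_s) & np.isfinite(wi)
        n = int(mask.sum())
        if n == 0:
            raise ValueError(
                f"series {phase.plant_id!r}: no valid W_i samples in the steady-state window"
            )
        out.append((float(wi[mask].mean()), n))
    (wi_low, n_low), (wi_high, n_high) = out
    return SteadyStateWi(wi_low, wi_high, n_low, n_high)
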