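"""Domain types and table I/O for leaf gas-exchange and stomatal-anatomy data.

The central container is :class:`GasxSeries` — one plant measured under one
protocol (a 12-step light-response curve or a 100→1000 µmol m⁻² s⁻¹ step
change), holding elapsed time, irradiance, net assimilation ``A``, stomatal
conductance ``g_s`` and the CO₂ mole fractions ``C_i``/``C_a``.  Readers accept
delimited text in the dialects common to infra-red gas-analyser exports; the
column mapping is configurable because different instrument generations name
the same quantity differently (``Photo`` vs ``A``, ``Cond`` vs ``gsw`` …).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Protocol",
    "Constants",
    "GasxSeries",
    "AnatomyRecord",
    "ProtocolWarning",
    "ValidationCheck",
    "ValidationReport",
    "WindowMean",
    "LIGHT_CURVE_LEVELS",
    "STEP_LOW_PPFD",
    "STEP_HIGH_PPFD",
    "read_gasx_table",
    "write_gasx_table",
    "read_anatomy_table",
    "write_anatomy_table",
    "window_mean",
    "validate_protocol",
]

#: Nominal PPFD set-points of the 12-step light-response protocol, in
#: measurement order (saturating light first, darkness last), µmol m⁻² s⁻¹.
LIGHT_CURVE_LEVELS: tuple[float, ...] = (
    2000, 1500, 1250, 1000, 750, 500, 300, 200, 100, 50, 20, 0,
)

#: Nominal PPFD of the two plateaus of the step-change protocol.
STEP_LOW_PPFD: float = 100.0
STEP_HIGH_PPFD: float = 1000.0

#: Nominal cuvette CO₂ set-point, µmol mol⁻¹.
NOMINAL_CA: float = 400.0


class Protocol(str, enum.Enum):
    """Measurement protocol a series was collected under."""

    LIGHT_CURVE = "light_curve"
    STEP_CHANGE = "step_change"


class ProtocolWarning(UserWarning):
    """A series departs from the nominal measurement protocol (non-fatal)."""


@dataclass(frozen=True)
class Constants:
    """Physical constants for diffusive conductance calculations.

    Parameters
    ----------
    d : float
        Diffusivity of water vapour in air, m² s⁻¹.  Default 24.6e-6 (25 °C).
    v : float
        Molar volume of air, m³ mol⁻¹.  Default 24.4e-3 (25 °C, 101.3 kPa).
    """

    d: float = 24.6e-6
    v: float = 24.4e-3

    def __post_init__(self) -> None:
        if not (self.d > 0 and self.v > 0):
            raise ValueError(f"constants must be positive, got d={self.d}, v={self.v}")


def _as_float_array(name: str, values: Sequence[float]) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


@dataclass
class GasxSeries:
    """One plant × one protocol gas-exchange time series.

    All vectors have equal length ≥ 2; ``t`` is elapsed seconds from the first
    record of the protocol segment and must be strictly increasing.
    """

    plant_id: str
    accession: str
    protocol: Protocol
    t: np.ndarray
    Q: np.ndarray
    A: np.ndarray
    gs: np.ndarray
    Ci: np.ndarray
    Ca: np.ndarray
    #: extra columns from the source table, carried through untouched
    extra: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.protocol = Protocol(self.protocol)
        for name in ("t", "Q", "A", "gs", "Ci", "Ca"):
            setattr(self, name, _as_float_array(name, getattr(self, name)))
        n = len(self.t)
        if n < 2:
            raise ValueError(f"series {self.plant_id!r}: needs at least 2 records, got {n}")
        for name in ("Q", "A", "gs", "Ci", "Ca"):
            if len(getattr(self, name)) != n:
                raise ValueError(
                    f"series {self.plant_id!r}: column {name!r} has length "
                    f"{len(getattr(self, name))}, expected {n}"
                )
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            row = int(np.argmax(dt <= 0)) + 1
            raise ValueError(
                f"series {self.plant_id!r}: time not strictly increasing at row {row} "
                f"(t={self.t[row]!r})"
            )
        if np.any(self.Q < 0):
            raise ValueError(f"series {self.plant_id!r}: negative PPFD")
        if np.any(self.gs < 0):
            raise ValueError(f"series {self.plant_id!r}: negative stomatal conductance")
        if np.any(self.Ca <= 0):
            raise ValueError(f"series {self.plant_id!r}: non-positive Ca")
        if np.any(np.abs(self.Ca - NOMINAL_CA) > 0.05 * NOMINAL_CA):
            warnings.warn(
                f"series {self.plant_id!r}: Ca departs >5% from the nominal "
                f"{NOMINAL_CA:g} µmol mol⁻¹ set-point",
                ProtocolWarning,
                stacklevel=2,
            )
        if self.extra is not None and len(self.extra) != n:
            raise ValueError(f"series {self.plant_id!r}: extra columns length mismatch")

    def __len__(self) -> int:
        return len(self.t)

    def subset(self, mask: np.ndarray) -> "GasxSeries":
        """Return a copy restricted to the boolean ``mask`` (order preserved)."""
        mask = np.asarray(mask, dtype=bool)
        extra = self.extra.loc[mask].reset_index(drop=True) if self.extra is not None else None
        return replace(
            self,
            t=self.t[mask], Q=self.Q[mask], A=self.A[mask],
            gs=self.gs[mask], Ci=self.Ci[mask], Ca=self.Ca[mask],
            extra=extra,
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame with canonical column names."""
        df = pd.DataFrame(
            {
                "plant_id": self.plant_id,
                "accession": self.accession,
                "protocol": self.protocol.value,
                "t": self.t,
                "Q": self.Q,
                "A": self.A,
                "gs": self.gs,
                "Ci": self.Ci,
                "Ca": self.Ca,
            }
        )
        if self.extra is not None:
            df = pd.concat([df, self.extra.reset_index(drop=True)], axis=1)
        return df


@dataclass(frozen=True)
class AnatomyRecord:
    """One microscope field of view on one leaf surface of one plant.

    ``field_count`` stomata were counted in ``field_area`` mm²; guard-cell and
    pore lengths (µm) are present only for records where individual stomata
    were measured.
    """

    plant_id: str
    accession: str
    surface: str  # "abaxial" | "adaxial"
    field_count: int
    field_area: float
    guard_cell_length: float | None = None
    pore_length: float | None = None

    def __post_init__(self) -> None:
        if self.surface not in ("abaxial", "adaxial"):
            raise ValueError(f"surface must be 'abaxial' or 'adaxial', got {self.surface!r}")
        if self.field_count < 0 or int(self.field_count) != self.field_count:
            raise ValueError(f"field_count must be a non-negative integer, got {self.field_count}")
        if not self.field_area > 0:
            raise ValueError(f"field_area must be positive, got {self.field_area}")
        for name in ("guard_cell_length", "pore_length"):
            val = getattr(self, name)
            if val is not None and not val > 0:
                raise ValueError(f"{name} must be positive, got {val}")
        if (
            self.guard_cell_length is not None
            and self.pore_length is not None
            and not self.pore_length < self.guard_cell_length
        ):
            raise ValueError(
                f"pore_length ({self.pore_length}) must be shorter than "
                f"guard_cell_length ({self.guard_cell_length})"
            )


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

#: Canonical column → accepted header aliases (case-insensitive), covering the
#: export dialects of the two instrument generations plus our own canonical
#: long format.
DEFAULT_COLUMN_ALIASES: Mapping[str, tuple[str, ...]] = {
    "t": ("t", "time", "elapsed", "elapsed_s", "secs"),
    "Q": ("q", "ppfd", "qin", "pari", "par"),
    "A": ("a", "photo", "anet"),
    "gs": ("gs", "gsw", "cond"),
    "Ci": ("ci",),
    "Ca": ("ca", "co2s", "co2_s", "co2r"),
    "plant_id": ("plant_id", "plant", "obs_id"),
    "accession": ("accession", "genotype", "line"),
    "protocol": ("protocol",),
}

_MANDATORY = ("t", "Q", "A", "gs", "Ci", "Ca")


def _resolve_columns(
    header: Sequence[str], column_map: Mapping[str, str] | None
) -> dict[str, str]:
    """Map canonical names to actual header names; explicit map wins."""
    resolved: dict[str, str] = {}
    lower = {h.lower(): h for h in header}
    for canon, aliases in DEFAULT_COLUMN_ALIASES.items():
        if column_map and canon in column_map:
            if column_map[canon] in header:
                resolved[canon] = column_map[canon]
            continue
        for alias in aliases:
            if alias in lower:
                resolved[canon] = lower[alias]
                break
    return resolved


def _detect_sep(path) -> str:
    """Comma/tab auto-detection from the header line."""
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_gasx_table(
    path,
    *,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
    plant_id: str | None = None,
    accession: str = "",
    protocol: Protocol | str | None = None,
) -> list[GasxSeries]:
    """Read a delimited gas-exchange table into one series per plant×protocol.

    Parameters
    ----------
    path
        Delimited text file (comma or tab; auto-detected unless ``sep`` given)
        with a header naming at least the t, Q, A, gs, Ci and Ca columns.
    column_map
        Optional explicit mapping from canonical names (``"t"``, ``"Q"`` …) to
        the file's header names; falls back to built-in instrument aliases.
    plant_id, accession, protocol
        Metadata used when the table has no such columns (single-plant files
        exported directly from the instrument).

    Returns
    -------
    list of GasxSeries, one per (plant_id, protocol) group, rows sorted by t.
    """
    if sep is None:
        sep = _detect_sep(path)
    # round_trip: the default float parser can be off by one ulp
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    resolved = _resolve_columns(df.columns, column_map)
    missing = [c for c in _MANDATORY if c not in resolved]
    if missing:
        raise ValueError(
            f"{path}: missing mandatory column(s) {missing}; header is {list(df.columns)}"
        )

    for canon in _MANDATORY:
        col = resolved[canon]
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r} at data row {row}"
            )
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna().to_numpy())[0])
            raise ValueError(f"{path}: missing value in column {col!r} at data row {row}")
        df[col] = numeric

    known = set(resolved.values())
    extra_cols = [c for c in df.columns if c not in known]

    if "plant_id" in resolved:
        plant_col = df[resolved["plant_id"]].astype(str)
    else:
        if plant_id is None:
            raise ValueError(f"{path}: no plant id column and no plant_id argument given")
        plant_col = pd.Series([plant_id] * len(df))
    if "accession" in resolved:
        acc_col = df[resolved["accession"]].astype(str)
    else:
        acc_col = pd.Series([accession] * len(df))
    if "protocol" in resolved:
        proto_col = df[resolved["protocol"]].astype(str)
    else:
        if protocol is None:
            raise ValueError(f"{path}: no protocol column and no protocol argument given")
        proto_col = pd.Series([Protocol(protocol).value] * len(df))

    out: list[GasxSeries] = []
    work = df.assign(_plant=plant_col.values, _proto=proto_col.values, _acc=acc_col.values)
    for (pid, proto), grp in work.groupby(["_plant", "_proto"], sort=True):
        grp = grp.sort_values(resolved["t"], kind="stable").reset_index(drop=True)
        extra = grp[extra_cols].copy() if extra_cols else None
        out.append(
            GasxSeries(
                plant_id=str(pid),
                accession=str(grp["_acc"].iloc[0]),
                protocol=Protocol(proto),
                t=grp[resolved["t"]].to_numpy(),
                Q=grp[resolved["Q"]].to_numpy(),
                A=grp[resolved["A"]].to_numpy(),
                gs=grp[resolved["gs"]].to_numpy(),
                Ci=grp[resolved["Ci"]].to_numpy(),
                Ca=grp[resolved["Ca"]].to_numpy(),
                extra=extra,
            )
        )
    return out


def write_gasx_table(series: Iterable[GasxSeries] | GasxSeries, path, *, sep: str = "\t") -> None:
    """Write one or more series as a long-format delimited table."""
    if isinstance(series, GasxSeries):
        series = [series]
    frames = [s.to_frame() for s in series]
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)


_ANATOMY_COLS = {
    "plant_id": "plant_id",
    "accession": "accession",
    "surface": "surface",
    "field_count": "field_count",
    "field_area": "field_area_mm2",
    "guard_cell_length": "gcl_um",
    "pore_length": "pore_um",
}


def read_anatomy_table(path, *, sep: str = "\t") -> list[AnatomyRecord]:
    """Read a stomatal-anatomy table (one row per field of view)."""
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = [c for c in ("plant_id", "accession", "surface", "field_count", "field_area_mm2")
               if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing anatomy column(s) {missing}")
    records = []
    for _, row in df.iterrows():
        def _opt(col):
            if col not in df.columns:
                return None
            val = row[col]
            return None if pd.isna(val) else float(val)

        records.append(
            AnatomyRecord(
                plant_id=str(row["plant_id"]),
                accession=str(row["accession"]),
                surface=str(row["surface"]),
                field_count=int(row["field_count"]),
                field_area=float(row["field_area_mm2"]),
                guard_cell_length=_opt("gcl_um"),
                pore_length=_opt("pore_um"),
            )
        )
    return records


def write_anatomy_table(records: Iterable[AnatomyRecord], path, *, sep: str = "\t") -> None:
    """Write anatomy records as a delimited table (one row per field)."""
    df = pd.DataFrame(
        {
            "plant_id": [r.plant_id for r in records],
            "accession": [r.accession for r in records],
            "surface": [r.surface for r in records],
            "field_count": [r.field_count for r in records],
            "field_area_mm2": [r.field_area for r in records],
            "gcl_um": [r.guard_cell_length for r in records],
            "pore_um": [r.pore_length for r in records],
        }
    )
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Windowed summaries and protocol validation
# ---------------------------------------------------------------------------


class WindowMean(NamedTuple):
    mean: float
    n: int


def window_mean(series: GasxSeries, variable: str, t_start: float, t_end: float) -> WindowMean:
    """Arithmetic mean of ``variable`` over the closed time window [t_start, t_end].

    Closed at both ends so that e.g. "the last 5 min" includes both boundary
    samples of a 10 s grid.
    """
    if not t_start < t_end:
        raise ValueError(f"t_start ({t_start}) must be < t_end ({t_end})")
    values = getattr(series, variable)
    mask = (series.t >= t_start) & (series.t <= t_end)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(
            f"series {series.plant_id!r}: no samples in window [{t_start}, {t_end}] s"
        )
    return WindowMean(float(values[mask].mean()), n)


@dataclass(frozen=True)
class ValidationCheck:
    name: str
    status: str  # "pass" | "warn"
    message: str


@dataclass
class ValidationReport:
    plant_id: str
    protocol: Protocol
    checks: list[ValidationCheck]

    @property
    def ok(self) -> bool:
        return all(c.status == "pass" for c in self.checks)

    @property
    def warnings(self) -> list[ValidationCheck]:
        return [c for c in self.checks if c.status == "warn"]

    def __str__(self) -> str:
        lines = [f"{self.plant_id} [{self.protocol.value}]"]
        lines += [f"  {c.status.upper():4s} {c.name}: {c.message}" for c in self.checks]
        return "\n".join(lines)


def nominal_level_tolerance(level: float, rel: float = 0.05, floor: float = 10.0) -> float:
    """Matching half-width for a nominal PPFD set-point (±5%, floor for dim levels)."""
    return max(rel * level, floor)


def assign_nominal_levels(Q: np.ndarray, levels: Sequence[float] = LIGHT_CURVE_LEVELS) -> np.ndarray:
    """Nearest nominal level per sample; NaN where no level matches within tolerance."""
    levels_arr = np.asarray(levels, dtype=float)
    idx = np.argmin(np.abs(Q[:, None] - levels_arr[None, :]), axis=1)
    nearest = levels_arr[idx]
    tol = np.array([nominal_level_tolerance(l) for l in nearest])
    out = np.where(np.abs(Q - nearest) <= tol, nearest, np.nan)
    return out


def validate_protocol(series: GasxSeries) -> ValidationReport:
    """Check a series against its nominal measurement protocol (reporting only).

    For light curves: all 12 nominal PPFD set-points present, first occurring
    in non-increasing order.  For step changes: a low plateau near 100, a high
    plateau near 1000, and near-10 s sampling.  Never mutates the data.
    """
    checks: list[ValidationCheck] = []

    def _add(name: str, ok: bool, msg: str, warn_msg: str) -> None:
        checks.append(
            ValidationCheck(name, "pass" if ok else "warn", msg if ok else warn_msg)
        )

    if series.protocol is Protocol.LIGHT_CURVE:
        assigned = assign_nominal_levels(series.Q)
        present = [l for l in LIGHT_CURVE_LEVELS if np.any(assigned == l)]
        _add(
            "levels",
            len(present) == len(LIGHT_CURVE_LEVELS),
            f"all {len(LIGHT_CURVE_LEVELS)} nominal levels present",
            f"incomplete protocol: {len(present)}/{len(LIGHT_CURVE_LEVELS)} nominal levels found",
        )
        first_seen = []
        for l in present:
            first_seen.append((np.flatnonzero(assigned == l)[0], l))
        order = [l for _, l in sorted(first_seen)]
        _add(
            "order",
            all(a >= b for a, b in zip(order, order[1:])),
            "levels appear in non-increasing order",
            f"levels out of order: {order}",
        )
        _add(
            "unmatched",
            not np.any(np.isnan(assigned)),
            "every sample matches a nominal level",
            f"{int(np.isnan(assigned).sum())} sample(s) match no nominal level",
        )
    elif series.protocol is Protocol.STEP_CHANGE:
        lo_tol = nominal_level_tolerance(STEP_LOW_PPFD, rel=0.2)
        hi_tol = nominal_level_tolerance(STEP_HIGH_PPFD, rel=0.2)
        low = np.abs(series.Q - STEP_LOW_PPFD) <= lo_tol
        high = np.abs(series.Q - STEP_HIGH_PPFD) <= hi_tol
        _add(
            "plateaus",
            low.any() and high.any(),
            f"low (~{STEP_LOW_PPFD:g}) and high (~{STEP_HIGH_PPFD:g}) plateaus present",
            "missing low and/or high plateau",
        )
        if low.any() and high.any():
            _add(
                "step_order",
                int(np.flatnonzero(low)[0]) < int(np.flatnonzero(high)[0]),
                "low plateau precedes high plateau",
                "high plateau precedes low plateau",
            )
        dt = np.diff(series.t)
        med = float(np.median(dt))
        _add(
            "sampling",
            abs(med - 10.0) <= 1.0,
            f"median sampling interval {med:g} s (~10 s)",
            f"median sampling interval {med:g} s departs from 10 s",
        )
    return ValidationReport(series.plant_id, series.protocol, checks)
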