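"""Phenotype-microarray kinetic curve analysis.

Biolog OmniLog phenotype microarray (PM) plates record tetrazolium-dye
reduction — a proxy for cellular respiration — in 96 wells over time, each
well presenting a single candidate nutrient. This module fits a smoothing
spline to each well's trace and extracts the four standard respiration-curve
parameters:

* ``A``      — maximum height of the curve (maximum respiration),
* ``mu``     — maximum slope (respiration rate),
* ``lambda`` — lag time, by the tangent-intercept convention: the time at
  which the tangent at the steepest point crosses the baseline,
* ``AUC``    — area under the fitted curve over the observed interval.

A well is called *positive* when its maximum height exceeds the summed
abiotic background — the negative-control well plus the corresponding blank
well — by more than a configurable threshold ``theta`` (strictly greater;
ties are negative). Replicate plates are compared by pairing per-well maxima.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import trapezoid
from scipy.interpolate import CubicSpline, make_smoothing_spline

__all__ = [
    "Role",
    "WellTimeSeries",
    "CurveParams",
    "PositiveCall",
    "ConcordanceReport",
    "MissingRoleError",
    "fit_curve",
    "call_positive",
    "call_plate",
    "replicate_concordance",
    "export_plate_matrix",
    "plate_level_matrix",
    "read_plate_csv",
    "write_plate_csv",
]

#: canonical 96-well layout
ROWS = "ABCDEFGH"
COLS = range(1, 13)
WELL_IDS = tuple(f"{r}{c}" for r in ROWS for c in COLS)

# number of points on the dense evaluation grid used for maxima/derivatives
_GRID = 2001
_MU_TINY = 1e-9


class Role(str, enum.Enum):
    TEST = "test"
    NEGATIVE_CONTROL = "negative_control"
    BLANK = "blank"


class MissingRoleError(ValueError):
    """A positive call was requested without the named reference role."""

    def __init__(self, role: str):
        self.role = role
        super().__init__(f"missing required reference curve: {role}")


@dataclass(frozen=True)
class WellTimeSeries:
    """One well's kinetic trace.

    ``times`` are hours (strictly increasing, >= 0); ``values`` are OmniLog
    units — instrument-arbitrary absorbance-like units, treated as
    dimensionless. At least four points are required for curve fitting.
    """

    plate_id: str
    well_id: str
    compound: str
    role: Role
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.ndim != 1 or len(t) != len(v):
            raise ValueError("times and values must be 1-D and the same length")
        if len(t) < 4:
            raise ValueError(f"well {self.well_id}: need >= 4 time points, got {len(t)}")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(v)):
            raise ValueError(f"well {self.well_id}: non-finite data")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"well {self.well_id}: times must be strictly increasing")
        if t[0] < 0:
            raise ValueError(f"well {self.well_id}: negative time")
        if isinstance(self.role, str) and not isinstance(self.role, Role):
            object.__setattr__(self, "role", Role(self.role))


@dataclass(frozen=True)
class CurveParams:
    """Fitted respiration-curve parameters for one well."""

    lag_lambda: float  # hours; NaN when the curve has no rising phase
    rate_mu: float  # units per hour
    max_A: float  # units
    auc: float  # units * hours

    def as_dict(self) -> dict:
        return {
            "lag_lambda": self.lag_lambda,
            "rate_mu": self.rate_mu,
            "max_A": self.max_A,
            "auc": self.auc,
        }


@dataclass(frozen=True)
class PositiveCall:
    compound: str
    plate_id: str
    delta_A: float
    is_positive: bool
    threshold_theta: float = 0.0
    well_id: str = ""


@dataclass(frozen=True)
class ConcordanceReport:
    """Replicate agreement on per-well maximum heights."""

    paired_max_values: list  # [(well_id, rep1_A, rep2_A), ...]
    max_abs_deviation: float
    n_deviating: int
    deviation_cutoff: float = 50.0


#: candidate roughness penalties for cross-validated smoothing; spans
#: near-interpolation to near-linear fits on hour/OmniLog-unit scales
_LAM_GRID = np.logspace(-6.0, 6.0, 13)


def select_smoothing(times: np.ndarray, values: np.ndarray) -> float:
    """Choose the spline roughness penalty by hold-out cross-validation.

    Fits each candidate penalty on the even-indexed observations and scores
    it by squared prediction error on the odd-indexed ones; the best
    penalty is returned. Falls back to the smallest candidate for very
    short series (the held-in half must keep >= 5 points).
    """
    if len(times) < 10:
        return float(_LAM_GRID[0])
    t_fit, v_fit = times[::2], values[::2]
    t_val, v_val = times[1::2], values[1::2]
    best_lam, best_err = float(_LAM_GRID[0]), np.inf
    for lam in _LAM_GRID:
        spline = make_smoothing_spline(t_fit, v_fit, lam=lam)
        err = float(np.mean((spline(t_val) - v_val) ** 2))
        if err < best_err:
            best_lam, best_err = float(lam), err
    return best_lam


def _smooth(series: WellTimeSeries, smoothing: float | None):
    """Fit a cubic smoothing spline (cross-validated penalty by default).

    Fewer than five points fall back to an interpolating cubic spline:
    the smoothing-penalty criterion needs at least five observations.
    """
    t, v = series.times, series.values
    if len(t) < 5:
        return CubicSpline(t, v)
    if smoothing is None:
        smoothing = select_smoothing(t, v)
    return make_smoothing_spline(t, v, lam=smoothing)


def fit_curve(series: WellTimeSeries, smoothing: float | None = None) -> CurveParams:
    """Extract (lambda, mu, A, AUC) from one well's trace.

    ``smoothing`` is the spline roughness penalty ``lam``; ``None`` selects it
    by generalized cross-validation. The maximum height and maximum slope are
    read off a dense grid over the observed interval; the lag is the
    baseline-crossing of the tangent at the steepest point, where the
    baseline is the fitted value at the first observation. The AUC is the
    trapezoidal integral of the fitted curve at the observed times.
    """
    spline = _smooth(series, smoothing)
    t = series.times
    grid = np.linspace(t[0], t[-1], _GRID)
    fitted = spline(grid)
    max_A = float(fitted.max())
    deriv = spline.derivative()(grid)
    i = int(np.argmax(deriv))
    mu = float(deriv[i])
    baseline = float(spline(t[0]))
    if mu > _MU_TINY:
        lag = float(grid[i] - (fitted[i] - baseline) / mu)
    else:
        lag = float("nan")  # flat or falling trace: no rising phase
    auc = float(trapezoid(spline(t), t))
    return CurveParams(lag_lambda=lag, rate_mu=mu, max_A=max_A, auc=auc)


def call_positive(
    test: CurveParams,
    neg_control: CurveParams | None,
    blank: CurveParams | None,
    theta: float = 0.0,
    subtract_mode: str = "both",
    compound: str = "",
    plate_id: str = "",
    well_id: str = "",
) -> PositiveCall:
    """Background-subtract a test well and call it positive/negative.

    ``subtract_mode="both"`` (default) treats the abiotic signal as the sum
    of the negative-control and blank maxima:
    ``delta_A = A_test - A_neg - A_blank``. ``"control_only"`` subtracts only
    the negative control. Positivity is strict: ``delta_A > theta``.
    """
    if neg_control is None:
        raise MissingRoleError(Role.NEGATIVE_CONTROL.value)
    if subtract_mode == "both":
        if blank is None:
            raise MissingRoleError(Role.BLANK.value)
        delta = test.max_A - neg_control.max_A - blank.max_A
    elif subtract_mode == "control_only":
        delta = test.max_A - neg_control.max_A
    else:
        raise ValueError(f"unknown subtract_mode: {subtract_mode!r}")
    return PositiveCall(
        compound=compound,
        plate_id=plate_id,
        well_id=well_id,
        delta_A=float(delta),
        is_positive=bool(delta > theta),
        threshold_theta=theta,
    )


def call_plate(
    wells: Iterable[WellTimeSeries],
    theta: float = 0.0,
    subtract_mode: str = "both",
    smoothing: float | None = None,
) -> pd.DataFrame:
    """Fit every well of a plate and call test wells against the controls.

    Expects one negative-control well per plate and, for ``subtract_mode
    "both"``, a blank trace per test well (same ``well_id``, role ``blank``)
    or a single plate-level blank. Returns a tidy frame with the fitted
    parameters and the call for each test well.

    With ``smoothing=None`` one shared roughness penalty is cross-validated
    on a deterministic sample of wells and applied plate-wide (noise is a
    property of the instrument run, not of individual wells).
    """
    wells = list(wells)
    if smoothing is None:
        sample = sorted(
            (w for w in wells if w.role == Role.TEST),
            key=lambda w: _well_sort_key(w.well_id),
        )
        step = max(1, len(sample) // 5)
        lams = [
            select_smoothing(w.times, w.values) for w in sample[::step][:5]
        ]
        if lams:
            smoothing = float(np.median(lams))
    tests, blanks, negs = {}, {}, {}
    for w in wells:
        if w.role == Role.TEST:
            tests[w.well_id] = w
        elif w.role == Role.BLANK:
            blanks[w.well_id] = w
        else:
            negs[w.well_id] = w
    if not negs:
        raise MissingRoleError(Role.NEGATIVE_CONTROL.value)
    neg_params = fit_curve(next(iter(negs.values())), smoothing)
    plate_blank = fit_curve(next(iter(blanks.values())), smoothing) if len(blanks) == 1 else None

    rows = []
    for well_id in sorted(tests, key=_well_sort_key):
        w = tests[well_id]
        p = fit_curve(w, smoothing)
        if subtract_mode == "both":
            if well_id in blanks:
                blank_params = fit_curve(blanks[well_id], smoothing)
            elif plate_blank is not None:
                blank_params = plate_blank
            else:
                raise MissingRoleError(Role.BLANK.value)
        else:
            blank_params = None
        call = call_positive(
            p, neg_params, blank_params, theta, subtract_mode,
            compound=w.compound, plate_id=w.plate_id, well_id=well_id,
        )
        rows.append(
            {
                "plate_id": w.plate_id,
                "well_id": well_id,
                "compound": w.compound,
                **p.as_dict(),
                "delta_A": call.delta_A,
                "is_positive": call.is_positive,
            }
        )
    return pd.DataFrame(rows)


def _well_sort_key(well_id: str):
    return (well_id[0], int(well_id[1:]))


def replicate_concordance(
    rep1: Mapping[str, CurveParams],
    rep2: Mapping[str, CurveParams],
    deviation_cutoff: float = 50.0,
) -> ConcordanceReport:
    """Pair per-well maximum heights of two replicate plates.

    Raises ``ValueError`` listing the symmetric difference when the two
    replicates do not cover the same wells.
    """
    k1, k2 = set(rep1), set(rep2)
    if k1 != k2:
        only1 = sorted(k1 - k2)
        only2 = sorted(k2 - k1)
        raise ValueError(
            f"replicate well sets differ: only in rep1 {only1}, only in rep2 {only2}"
        )
    pairs = []
    for well in sorted(k1, key=_well_sort_key):
        pairs.append((well, rep1[well].max_A, rep2[well].max_A))
    devs = np.array([abs(a - b) for _, a, b in pairs]) if pairs else np.array([0.0])
    return ConcordanceReport(
        paired_max_values=pairs,
        max_abs_deviation=float(devs.max()) if pairs else 0.0,
        n_deviating=int((devs > deviation_cutoff).sum()) if pairs else 0,
        deviation_cutoff=deviation_cutoff,
    )


# ---------------------------------------------------------------------------
# plate serialisation


def export_plate_matrix(wells: Iterable[WellTimeSeries]) -> pd.DataFrame:
    """Serialise a plate losslessly as a long-format table.

    Columns: plate_id, well_id, compound, role, time_h, value — the same
    layout the CSV reader consumes, so export -> import is the identity.
    Duplicate (well_id, role) pairs are an error.
    """
    seen = set()
    frames = []
    for w in wells:
        key = (w.well_id, w.role)
        if key in seen:
            raise ValueError(f"duplicate well id {w.well_id} (role {w.role.value})")
        seen.add(key)
        frames.append(
            pd.DataFrame(
                {
                    "plate_id": w.plate_id,
                    "well_id": w.well_id,
                    "compound": w.compound,
                    "role": w.role.value,
                    "time_h": w.times,
                    "value": w.values,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["plate_id", "well_id", "compound", "role", "time_h", "value"]
        )
    return pd.concat(frames, ignore_index=True)


def plate_level_matrix(
    wells: Iterable[WellTimeSeries], time_h: float
) -> pd.DataFrame:
    """8x12 level-plot grid of signal values at (nearest observed) ``time_h``.

    Missing wells appear as NaN — the explicit gap marker.
    """
    grid = pd.DataFrame(np.nan, index=list(ROWS), columns=list(COLS))
    seen = set()
    for w in wells:
        if w.role != Role.TEST and w.role != Role.NEGATIVE_CONTROL:
            continue
        if w.well_id in seen:
            raise ValueError(f"duplicate well id {w.well_id}")
        seen.add(w.well_id)
        row, col = w.well_id[0], int(w.well_id[1:])
        i = int(np.argmin(np.abs(w.times - time_h)))
        grid.loc[row, col] = w.values[i]
    return grid


def write_plate_csv(wells: Iterable[WellTimeSeries], path: str | Path) -> None:
    export_plate_matrix(wells).to_csv(path, index=False)


def read_plate_csv(path: str | Path) -> list[WellTimeSeries]:
    """Read long-format plate CSV (header required) into well traces."""
    df = pd.read_csv(path)
    required = {"plate_id", "well_id", "compound", "role", "time_h", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate CSV missing columns: {sorted(missing)}")
    out = []
    for (plate, well, role), grp in df.groupby(
        ["plate_id", "well_id", "role"], sort=False
    ):
        grp = grp.sort_values("time_h")
        out.append(
            WellTimeSeries(
                plate_id=str(plate),
                well_id=str(well),
                compound=str(grp["compound"].iloc[0]),
                role=Role(role),
                times=grp["time_h"].to_numpy(float),
                values=grp["value"].to_numpy(float),
            )
        )
    return out


def plate_summary_json(calls: pd.DataFrame, path: str | Path) -> None:
    """Per-plate JSON summary of positive calls."""
    summary = {
        "plates": {
            str(p): {
                "n_wells": int(len(g)),
                "n_positive": int(g["is_positive"].sum()),
                "positives": sorted(g.loc[g["is_positive"], "compound"].tolist()),
            }
            for p, g in calls.groupby("plate_id")
        }
    }
    Path(path).write_text(json.dumps(summary, indent=2))
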