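"""Turbidity calibration, kinetic parameter estimation, sensitivity scans.

Ties the sensor layer back to physical quantities: an ordinary
least-squares line maps FAU readings to total cell concentration; the
exponential-phase slope of log viable cells estimates the maximum
growth rate; a maintenance-corrected regression of cell growth on
glucose consumption estimates the biomass-on-glucose yield; and a
one-at-a-time parameter scan quantifies how strongly the simulated
trajectory depends on a kinetic parameter (the maximum growth rate
being the canonical case).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.stats import linregress

from .fedbatch import FeedEvent, SimulationError, Trajectory, simulate
from .kinetics import PER_CELL_TO_BULK, CultureState, KineticParameters, e5_per_ml_to_e9_per_l
from .sensors import OfflineAssay, TurbiditySeries

__all__ = [
    "LinearCalibration", "SensitivityResult", "calibrate_turbidity",
    "divergence_flag", "estimate_mu_max", "estimate_yield_X_glc",
    "sensitivity_scan",
]


@dataclass
class LinearCalibration:
    """OLS line: total cell concentration (1e9 cells/L) = slope*FAU + intercept."""

    slope: float
    intercept: float
    r_squared: float
    n: int
    residual_sd: float
    window: tuple | None = None

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("calibration needs at least 3 points")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError(f"R^2 out of [0, 1]: {self.r_squared}")

    def predict(self, fau) -> np.ndarray:
        """Total cell concentration (1e9 cells/L) implied by FAU readings."""
        return self.slope * np.asarray(fau, dtype=float) + self.intercept

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "slope_E9_L_per_FAU": self.slope,
                "intercept_E9_L": self.intercept,
                "r_squared": self.r_squared,
                "n": self.n,
                "residual_sd": self.residual_sd,
                "window_h": list(self.window) if self.window else None,
            }, fh, indent=1, sort_keys=True)


@dataclass
class SensitivityResult:
    """One-at-a-time scan: per-value trajectory summaries as a tidy frame.

    ``table`` columns: parameter, value, peak_Xv_E9_L, t_glc_depletion_h,
    final_mAb_g_L, ok (False when that simulation failed).
    """

    parameter: str
    values: np.ndarray
    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, lineterminator="\n")


def _ols(x: np.ndarray, y: np.ndarray):
    res = linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    dof = max(len(x) - 2, 1)
    return res.slope, res.intercept, res.rvalue ** 2, float(np.sqrt(resid @ resid / dof))


def _match_times(t_sparse, t_dense, tol):
    """Index into t_dense of the nearest neighbor per sparse time, within tol."""
    t_dense = np.asarray(t_dense, dtype=float)
    out = []
    for i, ts in enumerate(np.asarray(t_sparse, dtype=float)):
        j = int(np.argmin(np.abs(t_dense - ts)))
        if abs(t_dense[j] - ts) <= tol:
            out.append((i, j))
    return out


def calibrate_turbidity(
    assay: OfflineAssay,
    turb: TurbiditySeries,
    window: tuple | None = None,
    match_tol_h: float = 0.5,
) -> LinearCalibration:
    """OLS of offline total cell concentration on the turbidity signal.

    Offline sampling times are matched to the nearest online reading
    within ``match_tol_h`` hours (unmatched samples dropped); an
    optional time window restricts the fit, e.g. to exclude fouled
    late-culture data.
    """
    t_off = assay.times
    xt_off = e5_per_ml_to_e9_per_l(assay.replicate_mean("Xt_E5_mL"))
    if window is not None:
        keep = (t_off >= window[0]) & (t_off <= window[1])
        t_off, xt_off = t_off[keep], xt_off[keep]
    pairs = _match_times(t_off, turb.times, match_tol_h)
    if len(pairs) < 3:
        raise ValueError(f"insufficient data: only {len(pairs)} matched pairs")
    fau = np.array([turb.signal[j] for _, j in pairs])
    cells = np.array([xt_off[i] for i, _ in pairs])
    slope, intercept, r2, resid_sd = _ols(fau, cells)
    return LinearCalibration(slope, intercept, r2, len(pairs), resid_sd, window)


def divergence_flag(
    times: np.ndarray,
    turb_implied_Xt: np.ndarray,
    Xv_ref: np.ndarray,
    threshold: float = 0.10,
) -> np.ndarray:
    """Times where the turbidity-implied cell concentration departs from
    the viable reference by at least ``threshold`` (relative).

    Flags |implied - ref| / ref >= threshold; this is the operating
    criterion for when a total-cell proxy stops representing viable
    cells (viability decline or probe fouling).
    """
    times = np.asarray(times, dtype=float)
    implied = np.asarray(turb_implied_Xt, dtype=float)
    ref = np.asarray(Xv_ref, dtype=float)
    if not (times.shape == implied.shape == ref.shape):
        raise ValueError("series must be aligned")
    if np.any(ref <= 0):
        raise ValueError("reference viable cell concentration must be > 0")
    rel = np.abs(implied - ref) / ref
    return times[rel >= threshold]


def estimate_mu_max(
    times: np.ndarray,
    Xv: np.ndarray,
    window: tuple | None = None,
) -> float:
    """Maximum growth rate from the exponential phase (h^-1).

    Least-squares slope of log(Xv) versus time over the user-declared
    window.  Recovers the generating mu_max when substrates saturate
    and inhibitors are absent.
    """
    times = np.asarray(times, dtype=float)
    Xv = np.asarray(Xv, dtype=float)
    if window is not None:
        keep = (times >= window[0]) & (times <= window[1])
        times, Xv = times[keep], Xv[keep]
    if len(times) < 3:
        raise ValueError("need at least 3 samples in the window")
    if np.any(Xv <= 0):
        raise ValueError("viable cell concentration must be > 0 for log fit")
    if np.ptp(np.log(Xv)) == 0:
        return 0.0
    slope, *_ = _ols(times, np.log(Xv))
    return float(slope)


def estimate_yield_X_glc(
    times: np.ndarray,
    Xv: np.ndarray,
    GLC: np.ndarray,
    m_glc: float | None = None,
    p: KineticParameters | None = None,
) -> float:
    """Biomass-on-glucose yield (1e9 cells/mmol) from batch samples.

    Regresses cell growth (Xv - Xv0) on maintenance-corrected glucose
    consumption (GLC0 - GLC) - integral(m_glc * Xv dt), the integral by
    the trapezoid rule on the sample grid.  ``m_glc`` in the table's
    1e-12 mmol/cell/h units (taken from ``p`` if omitted).
    """
    if m_glc is None:
        m_glc = (p or KineticParameters()).m_glc
    times = np.asarray(times, dtype=float)
    Xv = np.asarray(Xv, dtype=float)
    GLC = np.asarray(GLC, dtype=float)
    if len(times) < 3:
        raise ValueError("need at least 3 samples")
    maint = cumulative_trapezoid(m_glc * PER_CELL_TO_BULK * Xv, times, initial=0.0)
    consumption = (GLC[0] - GLC) - maint
    growth = Xv - Xv[0]
    if np.ptp(consumption) == 0:
        raise ValueError("no measurable glucose consumption")
    slope, *_ = _ols(consumption, growth)
    return float(slope)


def _summarize(traj: Trajectory, depletion_threshold: float = 0.05) -> dict:
    glc = traj.column("GLC_mM")
    below = np.nonzero(glc <= depletion_threshold)[0]
    return {
        "peak_Xv_E9_L": float(traj.Xv.max()),
        "t_glc_depletion_h": float(traj.t[below[0]]) if len(below) else np.nan,
        "final_mAb_g_L": float(traj.column("mAb_g_L")[-1]),
    }


def sensitivity_scan(
    p: KineticParameters,
    name: str,
    values,
    initial: CultureState,
    feeds=(),
    t_end: float = 240.0,
    dt_out: float = 1.0,
    depletion_threshold: float = 0.05,
) -> SensitivityResult:
    """Re-simulate the scenario once per parameter value.

    All other settings are held fixed; each trajectory is reduced to
    peak viable cell concentration, glucose depletion time (first time
    GLC falls below ``depletion_threshold`` mM) and final antibody
    titer.  A failed simulation is recorded (ok=False) and the scan
    continues.
    """
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise ValueError("scan values must be positive")
    rows = []
    for v in values:
        row = {"parameter": name, "value": float(v)}
        try:
            pv = p.replace(**{name: float(v)})
            traj = simulate(initial, pv, feeds=feeds, t_end=t_end, dt_out=dt_out)
            row.update(_summarize(traj, depletion_threshold))
            row["ok"] = True
        except (SimulationError, ValueError) as exc:
            row.update(peak_Xv_E9_L=np.nan, t_glc_depletion_h=np.nan,
                       final_mAb_g_L=np.nan, ok=False)
            row["error"] = str(exc)
        rows.append(row)
    table = pd.DataFrame(rows)
    return SensitivityResult(name, values, table,
                             meta={"t_end": t_end, "dt_out": dt_out,
                                   "depletion_threshold_mM": depletion_threshold})
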