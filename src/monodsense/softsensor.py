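"""Model-based soft sensor: substrate estimation from a cell signal.

The estimator integrates the substrate/metabolite balances of the
kinetic model with the viable cell concentration replaced by an online
measured signal (turbidity-calibrated, Raman/PLS-predicted, or ground
truth), so glucose and lactate become observable without an analyzer:

    d[GLC]/dt = -((mu - mu_d)/Y_X_glc + m_glc') Xv_meas(t)
    d[GLN]/dt, d[LAC]/dt, d[AMM]/dt analogously

with mu and mu_d closed-loop from the *estimated* concentrations (not
from differentiating the noisy signal).  Bolus feeds are applied as in
the forward simulator; glucose is pinned at zero on depletion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import LinearCalibration, _match_times
from .chemometrics import r_squared, rmse
from .fedbatch import FeedEvent, Trajectory, integrate_piecewise
from .kinetics import PER_CELL_TO_BULK, KineticParameters, _m_gln, _mu, _mu_d
from .sensors import TurbiditySeries

__all__ = ["CellSignal", "SubstrateEstimate", "estimate_substrates", "evaluate_estimate"]


@dataclass
class CellSignal:
    """Online viable-cell-concentration signal (1e9 cells/L)."""

    times: np.ndarray
    Xv: np.ndarray
    source: str = "ground-truth"  # turbidity-calibrated | raman-pls | ground-truth
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.Xv = np.asarray(self.Xv, dtype=float)
        if self.times.shape != self.Xv.shape:
            raise ValueError("times and Xv must align")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("signal times must be increasing")
        if np.any(self.Xv < 0):
            raise ValueError("negative cell concentration in signal")
        if self.valid is None:
            self.valid = np.ones(self.times.shape, dtype=bool)

    @classmethod
    def from_turbidity(cls, turb: TurbiditySeries, calib: LinearCalibration) -> "CellSignal":
        """Calibrated turbidity as a cell signal (clipped at zero).

        The probe reads total cells; using it as a viable-cell signal
        assumes high viability (see divergence_flag).
        """
        xv = np.maximum(calib.predict(turb.signal), 0.0)
        return cls(turb.times, xv, source="turbidity-calibrated")

    @classmethod
    def from_trajectory(cls, traj: Trajectory, times=None) -> "CellSignal":
        if times is None:
            # keep the raw rows: interpolating onto the trajectory's own
            # grid would collapse the pre/post bolus duplicates
            return cls(traj.t.copy(), traj.Xv.copy(), source="ground-truth")
        times = np.asarray(times, dtype=float)
        return cls(times, traj.interp("Xv_E9_L", times), source="ground-truth")

    def smoothed(self, window: int) -> "CellSignal":
        """Centered moving-average smoothing (odd window length)."""
        if window < 3 or window % 2 == 0:
            raise ValueError("window must be an odd integer >= 3")
        kernel = np.ones(window) / window
        pad = window // 2
        padded = np.pad(self.Xv, pad, mode="edge")
        sm = np.convolve(padded, kernel, mode="valid")
        return CellSignal(self.times, sm, source=self.source, valid=self.valid)

    def to_csv(self, path) -> None:
        pd.DataFrame({"t_h": self.times, "Xv_E9_L": self.Xv,
                      "valid": self.valid.astype(int)}).to_csv(
            path, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path, source="turbidity-calibrated") -> "CellSignal":
        df = pd.read_csv(path)
        valid = df["valid"].to_numpy().astype(bool) if "valid" in df else None
        return cls(df["t_h"].to_numpy(), df["Xv_E9_L"].to_numpy(),
                   source=source, valid=valid)


@dataclass
class SubstrateEstimate:
    """Soft-sensor output: estimated concentration trajectories."""

    data: pd.DataFrame  # t_h, GLC_mM, GLN_mM, LAC_mM, AMM_mM, V_L, glc_pinned
    initial: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    source: str = ""
    diagnostics: dict = field(default_factory=dict)

    @property
    def times(self) -> np.ndarray:
        return self.data["t_h"].to_numpy()

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def interp(self, column: str, times) -> np.ndarray:
        return np.interp(np.asarray(times, dtype=float), self.times, self.column(column))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, lineterminator="\n")


def _dedupe(times: np.ndarray, values: np.ndarray):
    """Keep the first row of any run of identical timestamps."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    keep = np.ones(len(times), dtype=bool)
    keep[1:] = np.diff(times) > 0
    return times[keep], values[keep]


_GLC, _GLN, _LAC, _AMM, _V = range(5)


def estimate_substrates(
    signal: CellSignal,
    initial: dict,
    p: KineticParameters,
    feeds=(),
    t_end: float | None = None,
    dt_out: float = 1.0,
    max_gap_h: float | None = None,
    smooth_window: int | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> SubstrateEstimate:
    """Estimate GLC/GLN/LAC/AMM by driving the balances with the signal.

    ``initial`` must contain GLC, GLN, LAC, AMM (mM) and V (L); the
    volume is needed to dilute the estimates across bolus feeds.  The
    estimation horizon defaults to the signal span.  ``max_gap_h``
    rejects signals with larger sampling gaps; ``smooth_window``
    applies centered moving-average smoothing first (default off).
    """
    required = {"GLC", "GLN", "LAC", "AMM", "V"}
    missing = required - set(initial)
    if missing:
        raise ValueError(f"initial conditions missing {sorted(missing)}")
    if any(initial[k] < 0 for k in ("GLC", "GLN", "LAC", "AMM")):
        raise ValueError("initial concentrations must be >= 0")
    if not initial["V"] > 0:
        raise ValueError("initial volume must be > 0")
    if smooth_window:
        signal = signal.smoothed(smooth_window)
    if max_gap_h is not None:
        gaps = np.diff(signal.times)
        if len(gaps) and gaps.max() > max_gap_h:
            raise ValueError(
                f"signal gap {gaps.max():.3g} h exceeds maximum {max_gap_h} h")

    t0 = float(signal.times[0])
    if t_end is None:
        t_end = float(signal.times[-1])
    if t_end > signal.times[-1] + 1e-9:
        raise ValueError("signal does not span the estimation horizon")
    feeds = sorted(feeds, key=lambda f: f.t_feed)
    feeds = [f for f in feeds if t0 < f.t_feed < t_end]

    st, sx = signal.times.astype(float).copy(), signal.Xv
    # a signal sampled across a bolus carries duplicated timestamps
    # (pre/post); break the tie so integrating up to the bolus instant
    # interpolates the pre-feed value, not the diluted one
    dup = np.nonzero(np.diff(st) == 0)[0] + 1
    st[dup] += 1e-9

    def rhs(t, y, pinned):
        Xv = np.interp(t, st, sx)
        GLC = 0.0 if _GLC in pinned else max(y[_GLC], 0.0)
        GLN = 0.0 if _GLN in pinned else max(y[_GLN], 0.0)
        LAC = max(y[_LAC], 0.0)
        AMM = 0.0 if _AMM in pinned else max(y[_AMM], 0.0)
        mu = _mu(GLC, GLN, LAC, AMM, p)
        mu_d = _mu_d(LAC, AMM, p)
        net = mu - mu_d
        glc_uptake = (net / p.Y_X_glc + p.m_glc * PER_CELL_TO_BULK) * Xv
        gln_uptake = (net / p.Y_X_gln + _m_gln(GLN, p) * PER_CELL_TO_BULK) * Xv
        d = np.empty(5)
        d[_GLC] = -glc_uptake
        d[_GLN] = -gln_uptake
        d[_LAC] = p.Y_lac_glc * glc_uptake
        d[_AMM] = (p.Y_amm_gln * net / p.ammonium_yield_denominator
                   - p.r_amm * PER_CELL_TO_BULK) * Xv
        d[_V] = 0.0
        for i in pinned:
            d[i] = max(d[i], 0.0)
        return d

    def apply_feed(k, y):
        f = feeds[k]
        V = y[_V]
        V2 = V + f.V_feed
        y2 = y.copy()
        for i, c_feed in ((_GLC, f.GLC), (_GLN, f.GLN), (_LAC, f.LAC), (_AMM, f.AMM)):
            y2[i] = (max(y[i], 0.0) * V + c_feed * f.V_feed) / V2
        y2[_V] = V2
        return y2

    y0 = np.array([initial["GLC"], initial["GLN"], initial["LAC"],
                   initial["AMM"], initial["V"]], dtype=float)
    times, Y = integrate_piecewise(
        rhs, y0, t0, t_end, [f.t_feed for f in feeds], apply_feed,
        (_GLC, _GLN, _AMM), dt_out, rtol=rtol, atol=atol,
    )
    Y[:4] = np.maximum(Y[:4], 0.0)
    df = pd.DataFrame({
        "t_h": times,
        "GLC_mM": Y[_GLC], "GLN_mM": Y[_GLN],
        "LAC_mM": Y[_LAC], "AMM_mM": Y[_AMM],
        "V_L": Y[_V],
        "glc_pinned": (Y[_GLC] <= 0.0).astype(int),
    })
    return SubstrateEstimate(df, initial=dict(initial), params=p.to_dict(),
                             source=signal.source)


def evaluate_estimate(
    est: SubstrateEstimate,
    reference_times: np.ndarray,
    reference: dict,
    phase: tuple | None = None,
    match_tol_h: float = 0.5,
) -> dict:
    """R^2 and RMSE of the estimate against a reference series.

    ``reference`` maps analyte column names (e.g. ``GLC_mM``) to values
    on ``reference_times``.  ``phase`` restricts the evaluation window
    (e.g. the pre-feed phase).  Needs >= 3 time-matched pairs per
    analyte.
    """
    reference_times = np.asarray(reference_times, dtype=float)
    out = {}
    for analyte, ref_vals in reference.items():
        ref_vals = np.asarray(ref_vals, dtype=float)
        # bolus instants appear twice (pre/post feed); keep the pre-feed
        # row on both sides so jumps cannot be paired across the bolus
        et, ev = _dedupe(est.times, est.column(analyte))
        t, v = _dedupe(reference_times, ref_vals)
        if phase is not None:
            keep = (t >= phase[0]) & (t <= phase[1])
            t, v = t[keep], v[keep]
        pairs = _match_times(t, et, match_tol_h)
        if len(pairs) < 3:
            raise ValueError(f"fewer than 3 matched pairs for {analyte}")
        yhat = np.array([ev[j] for _, j in pairs])
        yref = np.array([v[i] for i, _ in pairs])
        out[analyte] = {"R2": r_squared(yhat, yref), "RMSE": rmse(yhat, yref),
                        "n": len(pairs)}
    est.diagnostics.update(out)
    return out
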