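"""Fed-batch simulation: piecewise ODE integration with bolus feeds.

Daily bolus feed additions make the trajectory piecewise smooth: the
kinetic ODEs are integrated between feed times with a stiff-capable
adaptive solver, and each bolus is applied as an instantaneous,
perfectly mixed state jump (mass balance over the enlarged volume).
Substrates that reach zero are pinned there by event detection so that
maintenance terms cannot drive them negative.

Trajectories are thin wrappers around a pandas DataFrame using the
column convention ``t_h, Xv_E9_L, Xt_E9_L, GLC_mM, GLN_mM, LAC_mM,
AMM_mM, mAb_g_L, V_L``.  Feed instants appear twice (state immediately
before and after the bolus).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .kinetics import (
    PER_CELL_TO_BULK,
    CultureState,
    KineticParameters,
    _m_gln,
    _mu,
    _mu_d,
)

__all__ = ["FeedEvent", "Trajectory", "SimulationError", "apply_bolus_feed",
           "simulate", "total_cell_track", "read_feed_schedule", "write_feed_schedule"]

TRAJ_COLUMNS = ["t_h", "Xv_E9_L", "Xt_E9_L", "GLC_mM", "GLN_mM", "LAC_mM",
                "AMM_mM", "mAb_g_L", "V_L"]
FEED_COLUMNS = ["t_feed_h", "V_feed_L", "GLC_mM", "GLN_mM", "LAC_mM", "AMM_mM", "mAb_g_L"]


class SimulationError(RuntimeError):
    """Integration failure; carries the last valid state reached."""

    def __init__(self, message: str, last_state: CultureState | None = None):
        super().__init__(message)
        self.last_state = last_state


@dataclass(frozen=True)
class FeedEvent:
    """One bolus addition: volume ``V_feed`` (L) of cell-free feed medium.

    Composition concentrations are those of the feed medium itself
    (mM; antibody g/L), not amounts.
    """

    t_feed: float
    V_feed: float
    GLC: float = 0.0
    GLN: float = 0.0
    LAC: float = 0.0
    AMM: float = 0.0
    mAb: float = 0.0

    def __post_init__(self) -> None:
        if not self.V_feed > 0:
            raise ValueError(f"V_feed must be > 0, got {self.V_feed}")
        for name in ("GLC", "GLN", "LAC", "AMM", "mAb"):
            if getattr(self, name) < 0:
                raise ValueError(f"feed {name} must be >= 0")


@dataclass
class Trajectory:
    """Time-gridded culture states plus provenance metadata."""

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in TRAJ_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"trajectory missing columns {missing}")
        t = self.data["t_h"].to_numpy()
        if np.any(np.diff(t) < 0):
            raise ValueError("trajectory times must be non-decreasing")

    # -- array accessors ------------------------------------------------
    @property
    def t(self) -> np.ndarray:
        return self.data["t_h"].to_numpy()

    @property
    def Xv(self) -> np.ndarray:
        return self.data["Xv_E9_L"].to_numpy()

    @property
    def Xt(self) -> np.ndarray:
        return self.data["Xt_E9_L"].to_numpy()

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def interp(self, column: str, times) -> np.ndarray:
        """Linear interpolation of a trajectory column onto new times."""
        return np.interp(np.asarray(times, dtype=float), self.t, self.column(column))

    def state_at(self, i: int) -> CultureState:
        row = self.data.iloc[i]
        return CultureState(t=row["t_h"], Xv=row["Xv_E9_L"], Xt=row["Xt_E9_L"],
                            GLC=row["GLC_mM"], GLN=row["GLN_mM"], LAC=row["LAC_mM"],
                            AMM=row["AMM_mM"], mAb=row["mAb_g_L"], V=row["V_L"])

    @property
    def viability(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            v = np.where(self.Xt > 0, self.Xv / np.maximum(self.Xt, 1e-300), 1.0)
        return v

    def to_csv(self, path) -> None:
        header = "# meta: " + json.dumps(self.meta, sort_keys=True) + "\n"
        with open(path, "w") as fh:
            fh.write(header)
            self.data.to_csv(fh, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        with open(path) as fh:
            first = fh.readline()
            meta = {}
            if first.startswith("# meta: "):
                meta = json.loads(first[len("# meta: "):])
                body = fh.read()
            else:
                body = first + fh.read()
        return cls(pd.read_csv(io.StringIO(body)), meta)


def read_feed_schedule(path) -> list[FeedEvent]:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in FEED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feed schedule missing columns {missing}")
    feeds = [
        FeedEvent(t_feed=r.t_feed_h, V_feed=r.V_feed_L, GLC=r.GLC_mM, GLN=r.GLN_mM,
                  LAC=r.LAC_mM, AMM=r.AMM_mM, mAb=r.mAb_g_L)
        for r in df.itertuples()
    ]
    _check_feed_order(feeds)
    return feeds


def write_feed_schedule(feeds: Sequence[FeedEvent], path) -> None:
    df = pd.DataFrame(
        [(f.t_feed, f.V_feed, f.GLC, f.GLN, f.LAC, f.AMM, f.mAb) for f in feeds],
        columns=FEED_COLUMNS,
    )
    df.to_csv(path, index=False, lineterminator="\n")


def _check_feed_order(feeds: Sequence[FeedEvent]) -> None:
    times = [f.t_feed for f in feeds]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("feed events must be strictly ordered in time")


def apply_bolus_feed(state: CultureState, feed: FeedEvent) -> CultureState:
    """Instantaneous, perfectly mixed bolus addition.

    Every species obeys the mass balance C' = (C V + C_feed V_feed)/V';
    the feed is cell-free, so viable and total cells are simply diluted.
    """
    state.validate()
    V2 = state.V + feed.V_feed

    def mix(c, c_feed=0.0):
        return (c * state.V + c_feed * feed.V_feed) / V2

    return CultureState(
        t=state.t,
        Xv=mix(state.Xv),
        Xt=mix(state.Xt),
        GLC=mix(state.GLC, feed.GLC),
        GLN=mix(state.GLN, feed.GLN),
        LAC=mix(state.LAC, feed.LAC),
        AMM=mix(state.AMM, feed.AMM),
        mAb=mix(state.mAb, feed.mAb),
        V=V2,
    )


# ---------------------------------------------------------------------------
# Generic piecewise integration with feed jumps and zero-pinning events.
# Shared by the forward simulator and the soft sensor.
# ---------------------------------------------------------------------------

def integrate_piecewise(
    rhs: Callable[[float, np.ndarray, frozenset], np.ndarray],
    y0: np.ndarray,
    t0: float,
    t_end: float,
    feed_times: Sequence[float],
    apply_feed: Callable[[int, np.ndarray], np.ndarray],
    depletable: Sequence[int],
    dt_out: float,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    pin_threshold: float = 1e-9,
):
    """Integrate ``rhs`` with state jumps at feed times and zero-pinning.

    ``rhs(t, y, pinned)`` must return derivatives with consumption of any
    index in ``pinned`` suppressed (non-negative derivative at zero).
    ``apply_feed(k, y)`` maps the state across the k-th feed.  Components
    listed in ``depletable`` trigger a terminal event when they cross
    zero from above; they are then pinned at zero until either a feed or
    production lifts them above ``pin_threshold``.

    Returns ``(times, Y)`` where feed instants appear twice (pre/post)
    and the output grid is ``t0 + k*dt_out`` plus segment boundaries.
    """
    y0 = np.asarray(y0, dtype=float)
    feed_times = list(feed_times)
    if any(ft <= t0 or ft >= t_end for ft in feed_times):
        raise ValueError("feed times must lie strictly inside (t0, t_end)")

    grid = np.arange(t0, t_end + 0.5 * dt_out, dt_out)
    grid = grid[grid <= t_end + 1e-12]
    if grid[-1] < t_end - 1e-12:
        grid = np.append(grid, t_end)

    out_t: list[float] = [t0]
    out_y: list[np.ndarray] = [y0.copy()]
    pinned: set[int] = set()

    def refresh_pins(t, y):
        # unpin anything a feed/production pushed above threshold; pin
        # anything at (or numerically below) zero that is being consumed
        for i in list(pinned):
            if y[i] > pin_threshold:
                pinned.discard(i)
        for i in depletable:
            if i in pinned:
                continue
            if y[i] <= 0.0:
                y[i] = 0.0
                if rhs(t, y, frozenset())[i] < 0:
                    pinned.add(i)

    segments = [t0] + feed_times + [t_end]
    y = y0.copy()
    for k in range(len(segments) - 1):
        a, b = segments[k], segments[k + 1]
        t_cur = a
        while t_cur < b - 1e-12:
            refresh_pins(t_cur, y)
            frozen = frozenset(pinned)

            def f(t, yy, _frozen=frozen):
                return rhs(t, yy, _frozen)

            events = []
            ev_idx = []
            for i in depletable:
                if i in pinned:
                    continue

                def ev(t, yy, _i=i):
                    return yy[_i]

                ev.terminal = True
                ev.direction = -1.0
                events.append(ev)
                ev_idx.append(i)

            sol = solve_ivp(f, (t_cur, b), y, method=method, rtol=rtol, atol=atol,
                            events=events, dense_output=True)
            if not sol.success:
                last = out_y[-1]
                raise SimulationError(
                    f"integrator failed at t={sol.t[-1]:.4g}: {sol.message}",
                    last_state=None if last is None else _last_state_hint(out_t[-1], last),
                )
            t_reached = sol.t[-1]
            mask = (grid > t_cur + 1e-12) & (grid < t_reached - 1e-12)
            if np.any(mask):
                ys = np.atleast_2d(sol.sol(grid[mask]))
                out_t.extend(float(tg) for tg in grid[mask])
                out_y.extend(np.ascontiguousarray(ys.T))
            out_t.append(float(t_reached))
            out_y.append(sol.y[:, -1].copy())
            y = sol.y[:, -1].copy()
            if sol.status == 1:  # depletion event fired
                for j, te in enumerate(sol.t_events):
                    if len(te):
                        i = ev_idx[j]
                        y[i] = 0.0
                        pinned.add(i)
                out_y[-1] = y.copy()
            t_cur = t_reached
        if k < len(segments) - 2:  # a feed sits at b
            y = apply_feed(k, y)
            out_t.append(float(b))
            out_y.append(y.copy())

    return np.asarray(out_t), np.asarray(out_y).T


def _last_state_hint(t, y):
    try:
        return CultureState(t=t, Xv=max(y[0], 0), Xt=max(y[0] + y[1], 0),
                            GLC=y[2], GLN=y[3], LAC=y[4], AMM=y[5], mAb=y[6],
                            V=y[7])
    except Exception:
        return None


# state vector layout for the forward simulation
_XV, _XD, _GLC, _GLN, _LAC, _AMM, _MAB, _V = range(8)
_DEPLETABLE = (_GLC, _GLN, _AMM)


def simulate(
    initial: CultureState,
    p: KineticParameters,
    feeds: Iterable[FeedEvent] = (),
    t_end: float = 240.0,
    dt_out: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    lysis_rate: float = 0.0,
) -> Trajectory:
    """Integrate the kinetic model from ``initial`` to ``t_end``.

    Dead cells are tracked alongside the model states (dXd/dt =
    mu_d Xv - lysis_rate Xd, default no lysis) so that the total cell
    concentration Xt = Xv + Xd is available to the sensor layer.  Bolus
    feeds are applied as instantaneous perfectly mixed jumps; the output
    reports the state both before and after each feed.

    Output is sampled every ``dt_out`` hours plus all segment
    boundaries.  Default tolerances rtol=1e-8, atol=1e-10.
    """
    initial.validate()
    if not t_end > initial.t:
        raise ValueError("t_end must exceed the initial time")
    feeds = sorted(feeds, key=lambda f: f.t_feed)
    _check_feed_order(feeds)
    if any(f.t_feed <= initial.t for f in feeds):
        raise ValueError("feed events must lie after the initial time")
    # a shorter horizon is a view of the same campaign: later feeds are moot
    feeds = [f for f in feeds if f.t_feed < t_end]

    def rhs(t, y, pinned):
        Xv = max(y[_XV], 0.0)
        GLC = 0.0 if _GLC in pinned else max(y[_GLC], 0.0)
        GLN = 0.0 if _GLN in pinned else max(y[_GLN], 0.0)
        LAC = max(y[_LAC], 0.0)
        AMM = 0.0 if _AMM in pinned else max(y[_AMM], 0.0)
        mu = _mu(GLC, GLN, LAC, AMM, p)
        mu_d = _mu_d(LAC, AMM, p)
        net = mu - mu_d
        glc_uptake = (net / p.Y_X_glc + p.m_glc * PER_CELL_TO_BULK) * Xv
        gln_uptake = (net / p.Y_X_gln + _m_gln(GLN, p) * PER_CELL_TO_BULK) * Xv
        dAMM = (p.Y_amm_gln * net / p.ammonium_yield_denominator
                - p.r_amm * PER_CELL_TO_BULK) * Xv
        d = np.empty(8)
        d[_XV] = net * Xv
        d[_XD] = mu_d * Xv - lysis_rate * y[_XD]
        d[_GLC] = -glc_uptake
        d[_GLN] = -gln_uptake
        d[_LAC] = p.Y_lac_glc * glc_uptake
        d[_AMM] = dAMM
        d[_MAB] = p.Q_mAb * PER_CELL_TO_BULK * Xv * (1.0 - mu / p.mu_max)
        d[_V] = 0.0
        for i in pinned:
            d[i] = max(d[i], 0.0)
        return d

    def apply_feed(k, y):
        f = feeds[k]
        state = CultureState(t=f.t_feed, Xv=max(y[_XV], 0.0),
                             Xt=max(y[_XV], 0.0) + max(y[_XD], 0.0),
                             GLC=max(y[_GLC], 0.0), GLN=max(y[_GLN], 0.0),
                             LAC=max(y[_LAC], 0.0), AMM=max(y[_AMM], 0.0),
                             mAb=max(y[_MAB], 0.0), V=y[_V])
        mixed = apply_bolus_feed(state, f)
        y2 = y.copy()
        dilution = state.V / mixed.V
        y2[_XV] = mixed.Xv
        y2[_XD] = max(y[_XD], 0.0) * dilution
        y2[_GLC], y2[_GLN] = mixed.GLC, mixed.GLN
        y2[_LAC], y2[_AMM] = mixed.LAC, mixed.AMM
        y2[_MAB], y2[_V] = mixed.mAb, mixed.V
        return y2

    Xd0 = max(initial.Xt - initial.Xv, 0.0)
    y0 = np.array([initial.Xv, Xd0, initial.GLC, initial.GLN, initial.LAC,
                   initial.AMM, initial.mAb, initial.V])
    times, Y = integrate_piecewise(
        rhs, y0, initial.t, t_end, [f.t_feed for f in feeds], apply_feed,
        _DEPLETABLE, dt_out, rtol=rtol, atol=atol, method=method,
    )
    Y = np.maximum(Y, 0.0)  # strip solver-tolerance-level negatives
    df = pd.DataFrame({
        "t_h": times,
        "Xv_E9_L": Y[_XV],
        "Xt_E9_L": Y[_XV] + Y[_XD],
        "GLC_mM": Y[_GLC],
        "GLN_mM": Y[_GLN],
        "LAC_mM": Y[_LAC],
        "AMM_mM": Y[_AMM],
        "mAb_g_L": Y[_MAB],
        "V_L": Y[_V],
    })
    meta = {
        "params": p.to_dict(),
        "ammonium_yield_basis": p.ammonium_yield_basis,
        "feeds": [[float(x) for x in (f.t_feed, f.V_feed, f.GLC, f.GLN, f.LAC,
                                      f.AMM, f.mAb)] for f in feeds],
        "rtol": rtol,
        "atol": atol,
        "method": method,
        "lysis_rate": lysis_rate,
    }
    return Trajectory(df, meta)


def total_cell_track(traj: Trajectory, p: KineticParameters, Xd0: float = 0.0) -> Trajectory:
    """Reconstruct total cells from a viable-cell trajectory.

    Dead cells accumulate as the quadrature of mu_d(LAC, AMM) * Xv
    (trapezoid rule on the trajectory grid, no lysis); across a bolus
    row (duplicated timestamp) the accumulated dead cells are diluted by
    the same factor as the viable cells.  Returns a copy with
    ``Xt_E9_L = Xv + Xd``.
    """
    t = traj.t
    Xv = traj.Xv
    mu_d = _mu_d(traj.column("LAC_mM"), traj.column("AMM_mM"), p)
    integrand = mu_d * Xv
    Xd = np.empty_like(Xv)
    Xd[0] = Xd0
    for i in range(1, len(t)):
        dt = t[i] - t[i - 1]
        if dt == 0.0 and Xv[i - 1] > 0:
            Xd[i] = Xd[i - 1] * (Xv[i] / Xv[i - 1])  # bolus dilution
        else:
            Xd[i] = Xd[i - 1] + 0.5 * (integrand[i] + integrand[i - 1]) * dt
    df = traj.data.copy()
    df["Xt_E9_L"] = Xv + Xd
    return Trajectory(df, dict(traj.meta, total_cell_track="quadrature"))
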