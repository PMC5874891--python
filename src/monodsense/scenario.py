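"""End-to-end scenario runs: simulate -> sense -> calibrate -> PLS -> soft-sense.

A Scenario bundles everything needed to replay a synthetic fed-batch
campaign: the kinetic parameter set, initial state, feed schedule,
sensor settings and a single root seed (all stochastic stages draw
named substreams from it).  ``run_scenario`` executes the full chain
and writes a report bundle; ``make_fixtures`` materializes the bundled
defaults as plain files for tests and the CLI.

Default scenario
----------------
Seeding at 0.3e9 viable cells/L (98% viability), 30 mM glucose and
4 mM glutamine in 1.5 L; daily cell-free bolus feeds (75 mL at 250 mM
glucose / 40 mM glutamine) from 72 h to 216 h; 240 h horizon.  The
turbidity probe reads every 15 min at 0.75% relative error with a gain
of 25 FAU per 1e9 cells/L; offline double determinations every 12 h;
40 ex-situ Raman spectra across the run with a 0.5 h sampling-loop
hold-up.  The pre-feed phase is everything before the first bolus.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import chemometrics
from .calibration import calibrate_turbidity, divergence_flag, estimate_mu_max, sensitivity_scan
from .fedbatch import FeedEvent, Trajectory, simulate, write_feed_schedule
from .kinetics import CultureState, KineticParameters, e5_per_ml_to_e9_per_l
from .rng import substream
from .sensors import (RamanLibrary, default_raman_library, generate_offline,
                      generate_raman, generate_turbidity)
from .softsensor import CellSignal, estimate_substrates, evaluate_estimate

__all__ = ["Scenario", "default_scenario", "run_scenario", "make_fixtures"]


@dataclass
class Scenario:
    """Complete configuration of one synthetic campaign."""

    params: KineticParameters
    initial: CultureState
    feeds: list
    t_end: float = 240.0
    dt_out: float = 1.0
    seed: int = 0
    # turbidity probe
    turbidity_gain: float = 25.0        # FAU per 1e9 cells/L
    turbidity_noise_rel: float = 0.0075
    turbidity_dt: float = 0.25          # h between readings
    fouling_onset: float | None = None
    fouling_rate: float | None = None
    # offline assays
    offline_dt: float = 12.0
    cv_count: float = 0.05
    cv_assay: float = 0.02
    # Raman
    n_spectra: int = 40
    raman_noise_sd: float = 0.02
    raman_baseline_order: int = 2
    raman_baseline_scale: float = 0.3
    holdup_lag_h: float = 0.5
    pls_max_factors: int = 6
    n_holdout: int = 10
    outdir: str | None = None

    @property
    def pre_feed_end(self) -> float:
        return min((f.t_feed for f in self.feeds), default=self.t_end)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["params"] = self.params.to_dict()
        d["params"]["ammonium_yield_basis"] = self.params.ammonium_yield_basis
        d["initial"] = dataclasses.asdict(self.initial)
        d["feeds"] = [dataclasses.asdict(f) for f in self.feeds]
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def default_feed_schedule() -> list:
    """Daily cell-free boluses: 75 mL of 250 mM GLC / 40 mM GLN feed."""
    return [FeedEvent(t_feed=float(t), V_feed=0.075, GLC=250.0, GLN=40.0)
            for t in np.arange(72.0, 217.0, 24.0)]


def default_scenario(seed: int = 0, **overrides) -> Scenario:
    sc = Scenario(
        params=KineticParameters(),
        initial=CultureState(t=0.0, Xv=0.3, Xt=0.306, GLC=30.0, GLN=4.0,
                             LAC=0.0, AMM=0.0, mAb=0.0, V=1.5),
        feeds=default_feed_schedule(),
        seed=seed,
    )
    return dataclasses.replace(sc, **overrides) if overrides else sc


def scenario_from_yaml(path) -> Scenario:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    params = KineticParameters.from_dict(d.get("params", {}))
    initial = CultureState(**d["initial"])
    feeds = [FeedEvent(**f) for f in d.get("feeds", [])]
    keys = {f.name for f in dataclasses.fields(Scenario)} - {"params", "initial", "feeds"}
    extra = {k: v for k, v in d.items() if k in keys}
    return Scenario(params=params, initial=initial, feeds=feeds, **extra)


def scenario_to_yaml(sc: Scenario, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(sc.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------

def _spectra_times(sc: Scenario) -> np.ndarray:
    return np.linspace(sc.initial.t + sc.holdup_lag_h, sc.t_end, sc.n_spectra)


def run_scenario(sc: Scenario, outdir=None) -> dict:
    """Execute the full pipeline; write a report bundle if outdir given.

    Returns the summary dict (also written as ``summary.json``):
    calibration R^2, PLS factor count and held-out R^2, soft-sensor
    glucose/lactate R^2 and RMSE, recovered mu_max, and the mu_max
    sensitivity orderings.  Identical seeds give identical bundles; a
    stage failure is recorded and the bundle marked partial.
    """
    outdir = Path(outdir) if outdir is not None else (
        Path(sc.outdir) if sc.outdir else None)
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    summary: dict = {"seed": sc.seed, "config_hash": sc.config_hash(),
                     "partial": False, "errors": {}}

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # a stage failure must not kill the bundle
            summary["partial"] = True
            summary["errors"][name] = f"{type(exc).__name__}: {exc}"
            return None

    # 1. ground truth
    traj = simulate(sc.initial, sc.params, feeds=sc.feeds, t_end=sc.t_end,
                    dt_out=sc.dt_out)
    if outdir is not None:
        traj.to_csv(outdir / "trajectory.csv")

    # 2. sensors
    turb_times = np.arange(sc.initial.t, sc.t_end + 1e-9, sc.turbidity_dt)
    turb = generate_turbidity(traj, gain=sc.turbidity_gain,
                              noise_rel=sc.turbidity_noise_rel,
                              fouling_onset=sc.fouling_onset,
                              fouling_rate=sc.fouling_rate,
                              seed=sc.seed, times=turb_times)
    offline_times = np.arange(sc.initial.t, sc.t_end + 1e-9, sc.offline_dt)
    assay = generate_offline(traj, offline_times, cv_count=sc.cv_count,
                             cv_assay=sc.cv_assay, seed=sc.seed)
    library = default_raman_library()
    spectra = generate_raman(traj, library, times=_spectra_times(sc),
                             baseline_order=sc.raman_baseline_order,
                             baseline_scale=sc.raman_baseline_scale,
                             noise_sd=sc.raman_noise_sd,
                             holdup_lag_h=sc.holdup_lag_h, seed=sc.seed)
    if outdir is not None:
        turb.to_csv(outdir / "turbidity.csv")
        assay.to_csv(outdir / "offline.csv")
        spectra.to_csv(outdir / "spectra.csv", outdir / "spectra_timestamps.csv")

    # 3. turbidity calibration + divergence check
    def _calibrate():
        calib = calibrate_turbidity(assay, turb)
        implied = calib.predict(turb.signal)
        xv_ref = traj.interp("Xv_E9_L", turb.times)
        flags = divergence_flag(turb.times, implied, np.maximum(xv_ref, 1e-9))
        if outdir is not None:
            calib.to_json(outdir / "calibration.json")
        summary["turbidity"] = {
            "R2": calib.r_squared, "slope_E9_L_per_FAU": calib.slope,
            "intercept_E9_L": calib.intercept, "n": calib.n,
            "first_divergence_h": float(flags[0]) if len(flags) else None,
        }
        return calib

    calib = stage("calibration", _calibrate)

    # 4. mu_max recovery from offline viable counts (exponential phase)
    def _mu_max():
        xv = e5_per_ml_to_e9_per_l(assay.replicate_mean("Xv_E5_mL"))
        window = (sc.initial.t, 0.75 * sc.pre_feed_end)
        est = estimate_mu_max(assay.times, np.maximum(xv, 1e-9), window=window)
        summary["mu_max_estimate_h-1"] = est
        return est

    stage("mu_max", _mu_max)

    # 5. Raman PLS for viable cells
    def _pls():
        y = traj.interp("Xv_E9_L", spectra.timestamps - sc.holdup_lag_h)
        rng = substream(sc.seed, "pls_split")
        idx = rng.permutation(len(y))
        test, train = idx[:sc.n_holdout], idx[sc.n_holdout:]
        model = chemometrics.fit_pls(spectra.intensities[train], y[train],
                                     max_factors=sc.pls_max_factors)
        yhat = chemometrics.predict(model, spectra.intensities[test])
        summary["raman_pls"] = {
            "n_factors": model.n_factors,
            "rmse_cv": model.rmse_cv.tolist(),
            "explained_y_variance": model.explained_y_variance.tolist(),
            "holdout_R2": chemometrics.r_squared(yhat, y[test]),
            "holdout_RMSE": chemometrics.rmse(yhat, y[test]),
        }
        if outdir is not None:
            model.to_json(outdir / "pls_model.json")
        return model

    stage("pls", _pls)

    # 6. soft sensor driven by the calibrated turbidity signal
    def _soft():
        signal = (CellSignal.from_turbidity(turb, calib) if calib is not None
                  else CellSignal.from_trajectory(traj, turb.times))
        initial = {"GLC": sc.initial.GLC, "GLN": sc.initial.GLN,
                   "LAC": sc.initial.LAC, "AMM": sc.initial.AMM,
                   "V": sc.initial.V}
        est = estimate_substrates(signal, initial, sc.params, feeds=sc.feeds,
                                  dt_out=sc.dt_out)
        ref = {"GLC_mM": traj.column("GLC_mM"), "LAC_mM": traj.column("LAC_mM")}
        full = evaluate_estimate(est, traj.t, ref, match_tol_h=0.25 * sc.dt_out)
        pre = evaluate_estimate(est, traj.t, {"GLC_mM": ref["GLC_mM"]},
                                phase=(sc.initial.t, sc.pre_feed_end),
                                match_tol_h=0.25 * sc.dt_out)
        summary["soft_sensor"] = {
            "signal_source": signal.source,
            "glucose_R2_pre_feed": pre["GLC_mM"]["R2"],
            "glucose_RMSE_pre_feed_mM": pre["GLC_mM"]["RMSE"],
            "glucose_R2_full": full["GLC_mM"]["R2"],
            "lactate_R2_full": full["LAC_mM"]["R2"],
            "lactate_RMSE_full_mM": full["LAC_mM"]["RMSE"],
        }
        if outdir is not None:
            est.to_csv(outdir / "estimate.csv")
        return est

    stage("soft_sensor", _soft)

    # 7. mu_max sensitivity scan (+/-5%, +/-10%)
    def _scan():
        base = sc.params.mu_max
        values = base * np.array([0.90, 0.95, 1.0, 1.05, 1.10])
        res = sensitivity_scan(sc.params, "mu_max", values, sc.initial,
                               feeds=sc.feeds, t_end=sc.t_end, dt_out=sc.dt_out)
        tab = res.table
        peaks = tab["peak_Xv_E9_L"].to_numpy()
        depl = tab["t_glc_depletion_h"].to_numpy()
        summary["mu_max_scan"] = {
            "values": values.tolist(),
            "peak_Xv_E9_L": peaks.tolist(),
            "t_glc_depletion_h": depl.tolist(),
            "peak_Xv_strictly_increasing": bool(np.all(np.diff(peaks) > 0)),
            "glc_depletion_strictly_decreasing": bool(
                np.all(np.isfinite(depl)) and np.all(np.diff(depl) < 0)),
        }
        if outdir is not None:
            res.to_csv(outdir / "sensitivity_mu_max.csv")
        return res

    stage("sensitivity", _scan)

    if outdir is not None:
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return summary


def make_fixtures(outdir, seed: int = 0) -> dict:
    """Write the bundled defaults as plain files (for tests and the CLI).

    Produces the published parameter set as YAML, the default feed
    schedule and Raman library as CSV, a scenario YAML, a soft-sensor
    initials YAML, and a short golden batch trajectory.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sc = default_scenario(seed=seed)
    paths = {}

    paths["params"] = outdir / "table_params.yaml"
    sc.params.to_yaml(paths["params"])

    paths["feeds"] = outdir / "feeds.csv"
    write_feed_schedule(sc.feeds, paths["feeds"])

    paths["scenario"] = outdir / "scenario.yaml"
    scenario_to_yaml(sc, paths["scenario"])

    paths["initials"] = outdir / "initials.yaml"
    with open(paths["initials"], "w") as fh:
        yaml.safe_dump({"GLC": sc.initial.GLC, "GLN": sc.initial.GLN,
                        "LAC": sc.initial.LAC, "AMM": sc.initial.AMM,
                        "V": sc.initial.V}, fh, sort_keys=False)

    lib = default_raman_library()
    paths["raman_library"] = outdir / "raman_library.csv"
    import pandas as pd
    wide = pd.DataFrame({"channel": lib.channels})
    for name, s in lib.components.items():
        wide[name] = s
    wide.to_csv(paths["raman_library"], index=False, lineterminator="\n")

    golden = simulate(sc.initial, sc.params, feeds=(), t_end=48.0, dt_out=4.0)
    paths["golden_trajectory"] = outdir / "golden_batch_48h.csv"
    golden.to_csv(paths["golden_trajectory"])

    return {k: str(v) for k, v in paths.items()}
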