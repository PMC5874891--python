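"""Synthetic raw-data layer: turbidity, ex-situ Raman spectra, offline assays.

These generators emulate the instrument chain around a bioreactor run,
taking a ground-truth :class:`~monodsense.fedbatch.Trajectory` and a
seed and producing the raw signals a process historian would hold:

* an in-situ transmission turbidity series (formazine attenuation
  units, FAU) proportional to the *total* cell concentration with 0.75%
  relative probe error and an optional late-culture fouling drift
  (cells accumulating in the probe gap);
* ex-situ Raman spectra whose intensities are linear mixtures of
  per-analyte pure-component spectra (viable cells, glucose, lactate)
  plus a random polynomial baseline and white noise, optionally lagged
  by the sampling-loop hold-up;
* sparse offline assays with double determination (two replicates per
  analyte per sampling time).

All generators are bit-reproducible given (inputs, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fedbatch import Trajectory
from .kinetics import e9_per_l_to_e5_per_ml
from .rng import substream

__all__ = [
    "TurbiditySeries", "SpectraSet", "OfflineAssay", "RamanLibrary",
    "default_raman_library", "generate_turbidity", "generate_raman",
    "generate_offline",
]


@dataclass
class TurbiditySeries:
    """Online turbidity signal in FAU with its noise/fouling provenance."""

    times: np.ndarray
    signal: np.ndarray
    noise_rel: float = 0.0075
    fouling_onset: float | None = None
    fouling_rate: float | None = None
    gain: float | None = None  # FAU per 1e9 cells/L used at generation

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.shape != self.signal.shape:
            raise ValueError("times and signal must have equal length")
        if np.any(self.signal < 0):
            raise ValueError("turbidity signal must be >= 0")

    def to_csv(self, path) -> None:
        pd.DataFrame({"t_h": self.times, "FAU": self.signal}).to_csv(
            path, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path, **kw) -> "TurbiditySeries":
        df = pd.read_csv(path)
        return cls(df["t_h"].to_numpy(), df["FAU"].to_numpy(), **kw)


@dataclass
class SpectraSet:
    """Matrix of spectra (rows) over a common channel axis (columns)."""

    channels: np.ndarray
    intensities: np.ndarray  # (n_spectra, n_channels)
    timestamps: np.ndarray   # h, one per spectrum
    seed: int | None = None

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.intensities.shape != (len(self.timestamps), len(self.channels)):
            raise ValueError("intensity matrix must be (n_spectra, n_channels)")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    def to_csv(self, path, timestamps_path) -> None:
        wide = pd.DataFrame({"channel": self.channels})
        for i in range(self.intensities.shape[0]):
            wide[f"spectrum_{i}"] = self.intensities[i]
        wide.to_csv(path, index=False, lineterminator="\n")
        pd.DataFrame({"spectrum": np.arange(len(self.timestamps)),
                      "t_h": self.timestamps}).to_csv(
            timestamps_path, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path, timestamps_path) -> "SpectraSet":
        wide = pd.read_csv(path)
        ts = pd.read_csv(timestamps_path)
        channels = wide["channel"].to_numpy()
        X = wide.drop(columns="channel").to_numpy().T
        return cls(channels, X, ts["t_h"].to_numpy())


@dataclass
class OfflineAssay:
    """Sparse offline reference data with double determination.

    ``data`` columns: t_h, then ``<analyte>_1``/``<analyte>_2`` replicate
    pairs for Xv_E5_mL, Xt_E5_mL, GLC_mM, LAC_mM.
    """

    data: pd.DataFrame
    cv_count: float = 0.05
    cv_assay: float = 0.02

    ANALYTES = ("Xv_E5_mL", "Xt_E5_mL", "GLC_mM", "LAC_mM")

    @property
    def times(self) -> np.ndarray:
        return self.data["t_h"].to_numpy()

    def replicate_mean(self, analyte: str) -> np.ndarray:
        return 0.5 * (self.data[f"{analyte}_1"].to_numpy()
                      + self.data[f"{analyte}_2"].to_numpy())

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path, **kw) -> "OfflineAssay":
        return cls(pd.read_csv(path), **kw)


def generate_turbidity(
    traj: Trajectory,
    gain: float = 25.0,
    noise_rel: float = 0.0075,
    fouling_onset: float | None = None,
    fouling_rate: float | None = None,
    seed: int = 0,
    times: np.ndarray | None = None,
) -> TurbiditySeries:
    """Turbidity proportional to total cell concentration.

    FAU(t) = gain * Xt(t) * (1 + eps), eps ~ N(0, noise_rel), plus an
    additive linear drift ``fouling_rate * (t - onset)`` after the
    fouling onset (probe-gap cell accumulation).  ``gain`` is in FAU per
    1e9 cells/L.
    """
    if not gain > 0:
        raise ValueError("gain must be > 0")
    if times is None:
        times = traj.t
    times = np.asarray(times, dtype=float)
    Xt = traj.interp("Xt_E9_L", times)
    rng = substream(seed, "turbidity")
    eps = rng.normal(0.0, noise_rel, size=times.shape) if noise_rel > 0 else 0.0
    fau = gain * Xt * (1.0 + eps)
    if fouling_onset is not None:
        rate = 0.0 if fouling_rate is None else fouling_rate
        fau = fau + rate * np.clip(times - fouling_onset, 0.0, None)
    fau = np.maximum(fau, 0.0)
    return TurbiditySeries(times, fau, noise_rel=noise_rel,
                           fouling_onset=fouling_onset, fouling_rate=fouling_rate,
                           gain=gain)


@dataclass(frozen=True)
class RamanLibrary:
    """Pure-component spectra on a common channel axis.

    ``components`` maps analyte name -> spectrum per unit concentration
    (1e9 cells/L for Xv, mM for solutes).  The bundled default library
    is synthetic: Gaussian peak sets at plausible band positions with
    partial overlap between analytes.
    """

    channels: np.ndarray
    components: dict = field(default_factory=dict)

    def spectrum(self, name: str) -> np.ndarray:
        return self.components[name]


# (center cm^-1, width cm^-1, amplitude per unit concentration)
_DEFAULT_PEAKS = {
    # viable cells: protein/lipid bands (per 1e9 cells/L)
    "Xv_E9_L": [(1004, 8, 1.00), (1250, 25, 0.45), (1320, 30, 0.30),
                (1450, 18, 0.70), (1660, 22, 0.85)],
    # glucose (per mM)
    "GLC_mM": [(911, 12, 0.040), (1060, 14, 0.055), (1125, 13, 0.045),
               (1365, 16, 0.025)],
    # lactate (per mM); 1045/1090 overlap the glucose ring modes
    "LAC_mM": [(830, 11, 0.035), (1045, 13, 0.050), (1090, 12, 0.030),
               (1420, 15, 0.025)],
}


def default_raman_library(n_channels: int = 400, lo: float = 400.0,
                          hi: float = 1800.0) -> RamanLibrary:
    """Synthetic Gaussian-peak library for viable cells, glucose, lactate."""
    channels = np.linspace(lo, hi, n_channels)
    comps = {}
    for name, peaks in _DEFAULT_PEAKS.items():
        s = np.zeros_like(channels)
        for center, width, amp in peaks:
            s += amp * np.exp(-0.5 * ((channels - center) / width) ** 2)
        comps[name] = s
    return RamanLibrary(channels, comps)


def generate_raman(
    traj: Trajectory,
    library: RamanLibrary | None = None,
    times: np.ndarray | None = None,
    baseline_order: int = 2,
    baseline_scale: float = 0.3,
    noise_sd: float = 0.02,
    holdup_lag_h: float = 0.5,
    seed: int = 0,
) -> SpectraSet:
    """Synthetic ex-situ Raman spectra from a ground-truth trajectory.

    Each spectrum at acquisition time t is the linear mixture
    ``sum_a c_a(t - lag) * s_a`` over the library analytes, plus a
    random polynomial baseline of the given order (-1 disables it) and
    iid Gaussian noise.  The hold-up lag emulates the sampling loop:
    spectra reflect the culture ``holdup_lag_h`` hours before their
    timestamp.
    """
    if library is None:
        library = default_raman_library()
    if times is None:
        times = traj.t
    times = np.asarray(times, dtype=float)
    if holdup_lag_h < 0:
        raise ValueError("holdup_lag_h must be >= 0")
    sample_times = times - holdup_lag_h
    if np.any(sample_times < traj.t[0] - 1e-9) or np.any(times > traj.t[-1] + 1e-9):
        raise ValueError("acquisition times minus lag fall outside the trajectory span")

    rng = substream(seed, "raman")
    n = len(times)
    nchan = len(library.channels)
    X = np.zeros((n, nchan))
    for name, s in library.components.items():
        conc = traj.interp(name, sample_times)
        X += conc[:, None] * s[None, :]
    if baseline_order >= 0:
        x01 = np.linspace(0.0, 1.0, nchan)
        coeffs = rng.normal(0.0, baseline_scale, size=(n, baseline_order + 1))
        for j in range(baseline_order + 1):
            X += coeffs[:, [j]] * x01[None, :] ** j
    if noise_sd > 0:
        X += rng.normal(0.0, noise_sd, size=X.shape)
    return SpectraSet(library.channels, X, times, seed=seed)


def generate_offline(
    traj: Trajectory,
    schedule: np.ndarray,
    cv_count: float = 0.05,
    cv_assay: float = 0.02,
    seed: int = 0,
) -> OfflineAssay:
    """Sparse offline double determinations of cells, glucose and lactate.

    Two replicate draws per analyte per scheduled time, multiplicative
    Gaussian noise with coefficient of variation ``cv_count`` for the
    hemocytometer counts (applied on the E5 cells/mL scale) and
    ``cv_assay`` for the glucose/lactate analyzer.
    """
    schedule = np.asarray(schedule, dtype=float)
    if schedule.size and (schedule.min() < traj.t[0] - 1e-9
                          or schedule.max() > traj.t[-1] + 1e-9):
        raise ValueError("offline schedule outside trajectory span")
    rng = substream(seed, "offline")
    cols = {"t_h": schedule}
    truths = {
        "Xv_E5_mL": e9_per_l_to_e5_per_ml(traj.interp("Xv_E9_L", schedule)),
        "Xt_E5_mL": e9_per_l_to_e5_per_ml(traj.interp("Xt_E9_L", schedule)),
        "GLC_mM": traj.interp("GLC_mM", schedule),
        "LAC_mM": traj.interp("LAC_mM", schedule),
    }
    for name, truth in truths.items():
        cv = cv_count if name.endswith("E5_mL") else cv_assay
        for rep in (1, 2):
            noise = rng.normal(0.0, cv, size=schedule.shape) if cv > 0 else 0.0
            cols[f"{name}_{rep}"] = np.maximum(truth * (1.0 + noise), 0.0)
    return OfflineAssay(pd.DataFrame(cols), cv_count=cv_count, cv_assay=cv_assay)
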