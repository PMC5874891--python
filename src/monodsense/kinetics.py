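"""Macroscopic Monod-type kinetic core for fed-batch CHO cell culture.

This module holds the culture state, the published parameter set, and the
rate laws of the macroscopic model as pure functions.  The model tracks
viable cells, glucose, glutamine, lactate, ammonium and monoclonal
antibody; growth follows a multiplicative Monod law with substrate
limitation (glucose, glutamine) and metabolite inhibition (lactate,
ammonium), death follows a saturable law in the two inhibitory
metabolites, and antibody production is growth-decoupled (maximal when
the culture stops growing).

Canonical units
---------------
time            h
concentrations  mM (antibody in g/L)
cells           1e9 cells/L  (the display unit "E5 cells/mL" equals
                0.1e9 cells/L; see :func:`e5_per_ml_to_e9_per_l`)
volume          L

Per-cell rates (``m_glc``, ``r_amm``, ``a1``, ``Q_mAb``) are stored in
1e-12 mmol (or g) per cell per hour, the convention of the published
parameter table.  Multiplying such a rate by a cell concentration in
1e9 cells/L yields 1e-3 mmol/L/h, so the bulk contribution in mM/h is
``rate * PER_CELL_TO_BULK * Xv`` with ``PER_CELL_TO_BULK = 1e-3``.
Yield coefficients ``Y_X_glc``/``Y_X_gln`` (1e9 cells per mmol) need no
bridge: ``mu / Y * Xv`` is already in mM/h.

Integration of these rate laws lives in :mod:`monodsense.fedbatch`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import yaml

__all__ = [
    "PER_CELL_TO_BULK",
    "CultureState",
    "KineticParameters",
    "StateDerivatives",
    "specific_growth_rate",
    "death_rate",
    "glutamine_maintenance",
    "state_derivatives",
    "e5_per_ml_to_e9_per_l",
    "e9_per_l_to_e5_per_ml",
]

#: Bridge from per-cell rates (1e-12 mmol cell^-1 h^-1) times a cell
#: concentration (1e9 cells/L) to a bulk rate in mM/h.
PER_CELL_TO_BULK = 1e-3

_TABLE_KEYS = (
    "mu_max", "k_d", "K_glc", "K_gln", "K_Ilac", "K_Iamm", "K_Dlac",
    "K_Damm", "Y_X_glc", "Y_X_gln", "Y_lac_glc", "Y_amm_gln", "r_amm",
    "m_glc", "a1", "a2", "Q_mAb",
)


def e5_per_ml_to_e9_per_l(x):
    """Convert a cell concentration from E5 cells/mL to 1e9 cells/L."""
    return np.asarray(x, dtype=float) * 0.1


def e9_per_l_to_e5_per_ml(x):
    """Convert a cell concentration from 1e9 cells/L to E5 cells/mL."""
    return np.asarray(x, dtype=float) * 10.0


@dataclass(frozen=True)
class KineticParameters:
    """Parameter set of the macroscopic model (published defaults).

    Defaults reproduce the experimentally determined / literature values
    for a CHO DG44 fed-batch culture.  Units: rates h^-1; Monod and
    inhibition constants mM; cell yields 1e9 cells/mmol; metabolite
    yields mmol/mmol; per-cell rates 1e-12 mmol (g for ``Q_mAb``) per
    cell per hour.

    ``ammonium_yield_basis`` selects the yield dividing (mu - mu_d) in
    the ammonium balance: ``"as_printed"`` uses ``Y_X_glc`` (faithful to
    the published equation), ``"glutamine"`` uses ``Y_X_gln`` (the
    dimensionally conventional choice).
    """

    mu_max: float = 0.039
    k_d: float = 0.004
    K_glc: float = 1.00
    K_gln: float = 0.047
    K_Ilac: float = 43.00
    K_Iamm: float = 6.51
    K_Dlac: float = 45.8
    K_Damm: float = 6.51
    Y_X_glc: float = 0.357
    Y_X_gln: float = 0.974
    Y_lac_glc: float = 0.70
    Y_amm_gln: float = 0.67
    r_amm: float = 6.3
    m_glc: float = 69.2
    a1: float = 3.2
    a2: float = 2.1
    Q_mAb: float = 1.51
    ammonium_yield_basis: str = "as_printed"

    def __post_init__(self) -> None:
        for key in _TABLE_KEYS:
            value = getattr(self, key)
            if not (np.isfinite(value) and value > 0):
                raise ValueError(f"parameter {key} must be strictly positive, got {value!r}")
        if self.ammonium_yield_basis not in ("as_printed", "glutamine"):
            raise ValueError(
                "ammonium_yield_basis must be 'as_printed' or 'glutamine', "
                f"got {self.ammonium_yield_basis!r}"
            )

    @property
    def ammonium_yield_denominator(self) -> float:
        return self.Y_X_glc if self.ammonium_yield_basis == "as_printed" else self.Y_X_gln

    def replace(self, **changes) -> "KineticParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in _TABLE_KEYS}

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParameters":
        unknown = set(d) - set(_TABLE_KEYS) - {"ammonium_yield_basis"}
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "KineticParameters":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class CultureState:
    """Instantaneous state of the culture and reactor.

    Xv/Xt are viable/total cell concentration in 1e9 cells/L; GLC, GLN,
    LAC, AMM in mM; mAb in g/L; V in L.
    """

    t: float = 0.0
    Xv: float = 0.0
    Xt: float = 0.0
    GLC: float = 0.0
    GLN: float = 0.0
    LAC: float = 0.0
    AMM: float = 0.0
    mAb: float = 0.0
    V: float = 1.0

    def validate(self) -> "CultureState":
        for name in ("Xv", "Xt", "GLC", "GLN", "LAC", "AMM", "mAb"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not self.V > 0:
            raise ValueError(f"V must be > 0, got {self.V}")
        if self.Xt < self.Xv - 1e-12 * max(1.0, self.Xv):
            raise ValueError(f"Xt ({self.Xt}) must be >= Xv ({self.Xv})")
        return self

    @property
    def viability(self) -> float:
        if self.Xt == 0:
            return 1.0
        return self.Xv / self.Xt


class StateDerivatives(NamedTuple):
    """Time derivatives in native units per hour."""

    dXv: float   # 1e9 cells/L/h
    dGLC: float  # mM/h
    dGLN: float  # mM/h
    dLAC: float  # mM/h
    dAMM: float  # mM/h
    dmAb: float  # g/L/h


def _check_nonneg(clamp: bool, **concs):
    out = {}
    for name, c in concs.items():
        if c < 0:
            if clamp:
                c = 0.0
            else:
                raise ValueError(f"negative concentration {name}={c}")
        out[name] = c
    return out


def _mu(GLC, GLN, LAC, AMM, p: KineticParameters):
    """Specific growth rate from raw concentrations (array-friendly)."""
    return (
        p.mu_max
        * GLC / (p.K_glc + GLC)
        * GLN / (p.K_gln + GLN)
        * p.K_Ilac / (p.K_Ilac + LAC)
        * p.K_Iamm / (p.K_Iamm + AMM)
    )


def _mu_d(LAC, AMM, p: KineticParameters):
    """Specific death rate from raw concentrations (array-friendly)."""
    return p.k_d * LAC / (p.K_Dlac + LAC) * AMM / (p.K_Damm + AMM)


def _m_gln(GLN, p: KineticParameters):
    return p.a1 * GLN / (p.a2 + GLN)


def specific_growth_rate(state: CultureState, p: KineticParameters, *, clamp: bool = False) -> float:
    """Specific growth rate mu (h^-1).

    Multiplicative Monod law: glucose and glutamine limit growth,
    lactate and ammonium inhibit it.  Bounded by [0, mu_max].
    Negative concentrations raise unless ``clamp`` is set (then they
    are treated as zero).
    """
    c = _check_nonneg(clamp, GLC=state.GLC, GLN=state.GLN, LAC=state.LAC, AMM=state.AMM)
    return float(_mu(c["GLC"], c["GLN"], c["LAC"], c["AMM"], p))


def death_rate(state: CultureState, p: KineticParameters, *, clamp: bool = False) -> float:
    """Specific death rate mu_d (h^-1), driven by lactate and ammonium.

    Bounded by [0, k_d]; zero when either metabolite is absent.
    """
    c = _check_nonneg(clamp, LAC=state.LAC, AMM=state.AMM)
    return float(_mu_d(c["LAC"], c["AMM"], p))


def glutamine_maintenance(GLN: float, p: KineticParameters, *, clamp: bool = False) -> float:
    """Glutamine maintenance coefficient m_gln (1e-12 mmol/cell/h).

    Saturable in glutamine: m_gln = a1 * GLN / (a2 + GLN).
    """
    c = _check_nonneg(clamp, GLN=GLN)
    return float(_m_gln(c["GLN"], p))


def state_derivatives(state: CultureState, p: KineticParameters, *, clamp: bool = False) -> StateDerivatives:
    """All balance-equation right-hand sides for the current state.

    dXv/dt  = (mu - mu_d) Xv
    dGLC/dt = -((mu - mu_d)/Y_X_glc + m_glc') Xv
    dGLN/dt = -((mu - mu_d)/Y_X_gln + m_gln') Xv
    dLAC/dt = Y_lac_glc ((mu - mu_d)/Y_X_glc + m_glc') Xv
    dAMM/dt = Y_amm_gln (mu - mu_d)/Y_basis Xv - r_amm' Xv
    dmAb/dt = Q_mAb' Xv (1 - mu/mu_max)

    where primes denote per-cell rates bridged to bulk units
    (``PER_CELL_TO_BULK``) and Y_basis is selected by
    ``p.ammonium_yield_basis``.  Lactate production is stoichiometrically
    coupled to glucose consumption: dLAC/dt = -Y_lac_glc * dGLC/dt.
    """
    c = _check_nonneg(
        clamp, Xv=state.Xv, GLC=state.GLC, GLN=state.GLN, LAC=state.LAC, AMM=state.AMM
    )
    Xv = c["Xv"]
    mu = _mu(c["GLC"], c["GLN"], c["LAC"], c["AMM"], p)
    mu_d = _mu_d(c["LAC"], c["AMM"], p)
    net = mu - mu_d

    glc_uptake = (net / p.Y_X_glc + p.m_glc * PER_CELL_TO_BULK) * Xv  # mM/h
    gln_uptake = (net / p.Y_X_gln + _m_gln(c["GLN"], p) * PER_CELL_TO_BULK) * Xv

    dXv = net * Xv
    dGLC = -glc_uptake
    dGLN = -gln_uptake
    dLAC = p.Y_lac_glc * glc_uptake
    dAMM = (p.Y_amm_gln * net / p.ammonium_yield_denominator - p.r_amm * PER_CELL_TO_BULK) * Xv
    dmAb = p.Q_mAb * PER_CELL_TO_BULK * Xv * (1.0 - mu / p.mu_max)
    return StateDerivatives(dXv, dGLC, dGLN, dLAC, dAMM, dmAb)
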