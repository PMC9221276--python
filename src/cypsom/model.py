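"""Rapid-equilibrium two-site occupancy model of CYP3A4.

CYP3A4 accommodates the probe substrate midazolam (MDZ) at a high-affinity
productive position inside the substrate-binding pocket and, at higher
concentrations, a second ligand at a peripheral allosteric site between the
F-F' and G-G' loops and the membrane interface.  Regioselectivity is
state-dependent: the singly-bound enzyme hydroxylates MDZ exclusively at C1,
while occupancy of the allosteric site (by a second MDZ or by an effector
such as progesterone) switches on formation of the minor 4OH product.

The model is a strictly stepwise, rapid-equilibrium partition function over
the occupancy grid {productive site} x {allosteric site}: the allosteric
site only carries ligand when the productive site is occupied, matching the
stepwise dissociation constants resolved experimentally (5.1 uM for the
productive position, 14.7 uM for the allosteric site for MDZ).  With
substrate S at concentration ``s`` and effector X at ``x``::

    Z = 1 + sum over occupied-productive states of
        w_prod(L1) * (1 + w_allo(S) + w_allo(X))

where ``w_prod(S) = s/Kd_prod_S`` etc., and disabled binding modes
contribute zero weight.

Rates follow from occupancy: each productive state (substrate at the
productive site) turns over with its own kcat and splits product between
1OH and 4OH according to its 4OH fraction ``f4oh``.  The site-of-metabolism
(SOM) ratio is v_1OH / v_4OH.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "DISABLED",
    "NOBIND",
    "OccupancyModelParams",
    "StateOccupancy",
    "RatePrediction",
    "compute_occupancy",
    "predict_rates",
    "som_curve",
    "langmuir_response",
]

#: Sentinel spellings used in config files for absent binding modes.
DISABLED = "disabled"
NOBIND = "nobind"

# Site occupancy labels: E = empty, S = substrate, X = effector.
_PROD_STATES = ("E", "S", "X")
_ALLO_STATES = ("E", "S", "X")


class InputError(ValueError):
    """Invalid user input (concentration, grid, dataset shape ...)."""


class ConfigurationError(ValueError):
    """Model configuration leaves no thermodynamically allowed state."""


@dataclass(frozen=True)
class OccupancyModelParams:
    """Binding constants and state-specific catalytic parameters.

    Parameters
    ----------
    kd_prod_s : float
        Stepwise dissociation constant of the substrate at the productive
        site (uM).
    kd_allo_s : float
        Stepwise dissociation constant of the substrate at the allosteric
        site (uM).
    kd_allo_x : float or None
        Effector dissociation constant at the allosteric site (uM); ``None``
        disables effector binding there (config spelling ``disabled``).
    kd_prod_x : float or None
        Effector dissociation constant at the productive site (uM); ``None``
        means the effector cannot enter the active site (config spelling
        ``nobind``).  A finite value models competitive inhibition.
    kcat_s, kcat_ss, kcat_sx : float
        Turnover (min^-1) of the productive states with the allosteric site
        empty, substrate-occupied, or effector-occupied, respectively.
    f4oh_s, f4oh_ss, f4oh_sx : float
        Fraction of total product that is 4OH in each productive state.
        The singly-bound enzyme makes C1 product only (``f4oh_s = 0``).
    """

    kd_prod_s: float = 5.1
    kd_allo_s: float = 14.7
    kd_allo_x: Optional[float] = None
    kd_prod_x: Optional[float] = None
    kcat_s: float = 1.0
    kcat_ss: float = 1.0
    kcat_sx: float = 1.0
    f4oh_s: float = 0.0
    f4oh_ss: float = 0.35
    f4oh_sx: float = 0.35

    def __post_init__(self) -> None:
        for name in ("kd_prod_s", "kd_allo_s"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise InputError(f"{name} must be a positive finite number, got {v!r}")
        for name in ("kd_allo_x", "kd_prod_x"):
            v = getattr(self, name)
            if v is not None and not (np.isfinite(v) and v > 0):
                raise InputError(f"{name} must be positive, None, or sentinel; got {v!r}")
        for name in ("kcat_s", "kcat_ss", "kcat_sx"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise InputError(f"{name} must be >= 0, got {v!r}")
        for name in ("f4oh_s", "f4oh_ss", "f4oh_sx"):
            v = getattr(self, name)
            if not (np.isfinite(v) and 0.0 <= v <= 1.0):
                raise InputError(f"{name} must lie in [0, 1], got {v!r}")

    def with_updates(self, **kwargs) -> "OccupancyModelParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        """Flat dict with sentinels spelled out, for config serialization."""
        d = {
            "kd_prod_s": self.kd_prod_s,
            "kd_allo_s": self.kd_allo_s,
            "kd_allo_x": DISABLED if self.kd_allo_x is None else self.kd_allo_x,
            "kd_prod_x": NOBIND if self.kd_prod_x is None else self.kd_prod_x,
            "kcat_s": self.kcat_s,
            "kcat_ss": self.kcat_ss,
            "kcat_sx": self.kcat_sx,
            "f4oh_s": self.f4oh_s,
            "f4oh_ss": self.f4oh_ss,
            "f4oh_sx": self.f4oh_sx,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "OccupancyModelParams":
        kw = dict(d)
        for key, sentinel in (("kd_allo_x", DISABLED), ("kd_prod_x", NOBIND)):
            v = kw.get(key)
            if isinstance(v, str):
                if v not in (DISABLED, NOBIND):
                    raise InputError(f"unknown sentinel {v!r} for {key}")
                kw[key] = None
        return cls(**kw)


@dataclass(frozen=True)
class StateOccupancy:
    """Equilibrium fractions over the 3x3 occupancy grid.

    ``fractions[(p, a)]`` is the population of the state with ``p`` at the
    productive site and ``a`` at the allosteric site, where each label is
    one of ``"E"`` (empty), ``"S"`` (substrate), ``"X"`` (effector).
    """

    fractions: dict = field(default_factory=dict)

    def __getitem__(self, key) -> float:
        return self.fractions[key]

    @property
    def total(self) -> float:
        return sum(self.fractions.values())

    @property
    def productive_substrate(self) -> float:
        """Population with substrate at the productive site (catalytic states)."""
        return sum(v for (p, _a), v in self.fractions.items() if p == "S")


@dataclass(frozen=True)
class RatePrediction:
    """Predicted product-formation rates (min^-1 per enzyme).

    ``som_ratio`` is NaN when no 4OH product is formed; use
    :attr:`som_defined` to test for the sentinel.
    """

    v_1oh: float
    v_4oh: float
    som_ratio: float

    @property
    def som_defined(self) -> bool:
        return not math.isnan(self.som_ratio)

    @property
    def v_total(self) -> float:
        return self.v_1oh + self.v_4oh


def _state_weights(params: OccupancyModelParams, s: float, x: float) -> dict:
    """Statistical weights of the 9 occupancy states (unnormalized).

    Stepwise scheme: the allosteric site binds only when the productive site
    is occupied, so (E, S) and (E, X) carry zero weight; a disabled binding
    mode zeroes every state requiring it.
    """
    w_prod = {"E": 1.0, "S": s / params.kd_prod_s}
    w_prod["X"] = 0.0 if params.kd_prod_x is None else x / params.kd_prod_x
    w_allo = {"E": 1.0, "S": s / params.kd_allo_s}
    w_allo["X"] = 0.0 if params.kd_allo_x is None else x / params.kd_allo_x

    weights = {}
    for p in _PROD_STATES:
        for a in _ALLO_STATES:
            if p == "E" and a != "E":
                weights[(p, a)] = 0.0
            else:
                weights[(p, a)] = w_prod[p] * w_allo[a]
    return weights


def compute_occupancy(
    params: OccupancyModelParams, s_conc: float, x_conc: float = 0.0
) -> StateOccupancy:
    """Equilibrium populations of the two-site occupancy grid.

    Parameters
    ----------
    params : OccupancyModelParams
    s_conc, x_conc : float
        Free substrate and effector concentrations (uM).  The model is
        rapid-equilibrium in the ligand-excess regime, so total and free
        concentrations are identified.

    Returns
    -------
    StateOccupancy
        Fractions summing to 1 (within 1e-12); states whose binding mode is
        disabled are exactly 0.
    """
    if not (np.isfinite(s_conc) and s_conc >= 0):
        raise InputError(f"substrate concentration must be >= 0, got {s_conc!r}")
    if not (np.isfinite(x_conc) and x_conc >= 0):
        raise InputError(f"effector concentration must be >= 0, got {x_conc!r}")

    weights = _state_weights(params, s_conc, x_conc)
    z = sum(weights.values())
    if z <= 0:
        raise ConfigurationError("all occupancy states are disabled")
    return StateOccupancy({k: w / z for k, w in weights.items()})


def predict_rates(
    params: OccupancyModelParams, s_conc: float, x_conc: float = 0.0
) -> RatePrediction:
    """Predict 1OH/4OH formation rates and the SOM ratio.

    Each productive state contributes ``kcat_state * fraction`` to the total
    rate and splits it ``(1 - f4oh) : f4oh`` between the C1 and C4 products.
    """
    occ = compute_occupancy(params, s_conc, x_conc)
    contributions = (
        (occ[("S", "E")], params.kcat_s, params.f4oh_s),
        (occ[("S", "S")], params.kcat_ss, params.f4oh_ss),
        (occ[("S", "X")], params.kcat_sx, params.f4oh_sx),
    )
    v_1oh = sum(f * k * (1.0 - q) for f, k, q in contributions)
    v_4oh = sum(f * k * q for f, k, q in contributions)
    som = v_1oh / v_4oh if v_4oh > 0 else math.nan
    return RatePrediction(v_1oh=v_1oh, v_4oh=v_4oh, som_ratio=som)


def som_curve(
    params: OccupancyModelParams,
    s_grid: Iterable[float],
    x_levels: Iterable[float] = (0.0,),
) -> pd.DataFrame:
    """Tabulate rates and SOM ratio over a substrate grid at effector levels.

    Returns a tidy frame with one row per (s, x) pair and columns
    ``s_um, x_um, v1oh, v4oh, som_ratio``; SOM is NaN where no 4OH product
    is formed.
    """
    s_grid = list(s_grid)
    x_levels = list(x_levels)
    if not s_grid or not x_levels:
        raise InputError("substrate grid and effector levels must be non-empty")
    rows = []
    for x in x_levels:
        for s in s_grid:
            pred = predict_rates(params, s, x)
            rows.append((s, x, pred.v_1oh, pred.v_4oh, pred.som_ratio))
    return pd.DataFrame(rows, columns=["s_um", "x_um", "v1oh", "v4oh", "som_ratio"])


def langmuir_response(ks: float, bmax: float, l: float) -> float:
    """Non-cooperative Langmuir isotherm ``bmax * l / (ks + l)``.

    Models the fractional high-spin shift of the heme iron upon ligand
    binding, as read from optical titrations.
    """
    if not (np.isfinite(ks) and ks > 0):
        raise InputError(f"ks must be > 0, got {ks!r}")
    if not (np.isfinite(bmax) and 0.0 <= bmax <= 1.0):
        raise InputError(f"bmax must lie in [0, 1], got {bmax!r}")
    l = np.asarray(l, dtype=float)
    if np.any(~np.isfinite(l)) or np.any(l < 0):
        raise InputError("ligand concentration must be finite and >= 0")
    out = bmax * l / (ks + l)
    return float(out) if out.ndim == 0 else out
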