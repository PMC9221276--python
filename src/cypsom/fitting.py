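"""Weighted least-squares fitting of the occupancy model and titrations.

Fitting the kinetic model is a joint weighted nonlinear least-squares
problem on the observed (v_1OH, v_4OH) pairs.  Dissociation constants are
fitted on a log10 scale (they span orders of magnitude and must remain
positive); product fractions are box-bounded to [0, 1].  Because the
surface is multimodal for small designs, the fit restarts from seeded
perturbations of the initial guess and keeps the best optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import lmfit
import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .model import (
    InputError,
    OccupancyModelParams,
    langmuir_response,
    predict_rates,
)

__all__ = [
    "RateDataset",
    "TitrationCurve",
    "TitrationFit",
    "FitResult",
    "FREE_PARAM_NAMES",
    "fit_rate_data",
    "fit_titration",
    "classify_effector_mode",
    "EFFECTOR_MODES",
]

#: OccupancyModelParams fields that may be freed in a fit.
FREE_PARAM_NAMES = (
    "kd_prod_s",
    "kd_allo_s",
    "kd_allo_x",
    "kd_prod_x",
    "kcat_s",
    "kcat_ss",
    "kcat_sx",
    "f4oh_s",
    "f4oh_ss",
    "f4oh_sx",
)

_KD_NAMES = ("kd_prod_s", "kd_allo_s", "kd_allo_x", "kd_prod_x")
_F4OH_NAMES = ("f4oh_s", "f4oh_ss", "f4oh_sx")

EFFECTOR_MODES = (
    "no-effect",
    "competitive-inhibition",
    "allosteric-4OH-favoring",
    "allosteric-4OH-suppressing",
    "mixed",
)


class ConvergenceError(RuntimeError):
    """Raised when a fit fails on every start."""


class IdentifiabilityError(ValueError):
    """Raised when the data carry no information about the fitted model."""


@dataclass
class RateDataset:
    """Tabular kinetic measurements: rates versus (substrate, effector).

    ``data`` has columns ``s_um, x_um, v1oh, v4oh`` and optionally ``sd``
    (per-row noise standard deviation used as fit weights).
    """

    data: pd.DataFrame
    effector: str = "none"
    true_params: Optional[OccupancyModelParams] = None

    REQUIRED = ("s_um", "x_um", "v1oh", "v4oh")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise InputError(f"rate dataset missing columns: {missing}")
        if (self.data["s_um"] < 0).any() or (self.data["x_um"] < 0).any():
            raise InputError("concentrations must be >= 0")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_distinct_s(self) -> int:
        return self.data["s_um"].nunique()

    @classmethod
    def from_csv(cls, path, effector: str = "none") -> "RateDataset":
        df = pd.read_csv(path, comment="#")
        return cls(data=df, effector=effector)

    def to_csv(self, path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.data.to_csv(fh, index=False)


@dataclass
class TitrationCurve:
    """Spin-shift titration: fractional response versus ligand concentration."""

    data: pd.DataFrame  # columns: ligand_um, response
    ligand: str = "ligand"

    def __post_init__(self) -> None:
        for c in ("ligand_um", "response"):
            if c not in self.data.columns:
                raise InputError(f"titration curve missing column {c!r}")
        if (self.data["ligand_um"] < 0).any():
            raise InputError("ligand concentrations must be >= 0")
        r = self.data["response"]
        if ((r < 0) | (r > 1)).any():
            raise InputError("responses must lie in [0, 1]")

    @classmethod
    def from_csv(cls, path, ligand: str = "ligand") -> "TitrationCurve":
        return cls(data=pd.read_csv(path, comment="#"), ligand=ligand)


@dataclass
class TitrationFit:
    ks: float
    bmax: float
    ks_stderr: float
    bmax_stderr: float
    rss: float


@dataclass
class FitResult:
    """Result of a multi-start occupancy-model fit."""

    params: OccupancyModelParams
    stderr: Dict[str, Optional[float]] = field(default_factory=dict)
    rss: float = math.nan
    converged: bool = False
    identifiable: Dict[str, bool] = field(default_factory=dict)
    n_starts: int = 0

    @property
    def non_identifiable(self) -> list:
        return sorted(k for k, v in self.identifiable.items() if not v)

    def to_report(self) -> dict:
        return {
            "estimates": self.params.to_dict(),
            "stderr": self.stderr,
            "rss": self.rss,
            "converged": self.converged,
            "identifiable": self.identifiable,
            "n_starts": self.n_starts,
        }


def _make_lmfit_params(
    init: OccupancyModelParams, free: Sequence[str]
) -> lmfit.Parameters:
    pars = lmfit.Parameters()
    d = {name: getattr(init, name) for name in FREE_PARAM_NAMES}
    for name in FREE_PARAM_NAMES:
        is_free = name in free
        val = d[name]
        if name in _KD_NAMES:
            if val is None:
                if is_free:
                    raise InputError(
                        f"{name} is free but initialized to a disabled sentinel"
                    )
                continue  # sentinel stays disabled; no lmfit parameter
            pars.add(f"log10_{name}", value=math.log10(val), vary=is_free,
                     min=-4.0, max=5.0)
        elif name in _F4OH_NAMES:
            pars.add(name, value=val, vary=is_free, min=0.0, max=1.0)
        else:  # kcat
            pars.add(name, value=val, vary=is_free, min=0.0)
    return pars


def _params_from_lmfit(pars: lmfit.Parameters, init: OccupancyModelParams
                       ) -> OccupancyModelParams:
    kw = {}
    for name in FREE_PARAM_NAMES:
        if name in _KD_NAMES:
            key = f"log10_{name}"
            kw[name] = 10.0 ** pars[key].value if key in pars else None
        else:
            kw[name] = float(pars[name].value)
    return OccupancyModelParams(**kw)


def _residuals(pars: lmfit.Parameters, init: OccupancyModelParams,
               s: np.ndarray, x: np.ndarray, v1: np.ndarray, v4: np.ndarray,
               sd: np.ndarray) -> np.ndarray:
    p = _params_from_lmfit(pars, init)
    pred = [predict_rates(p, si, xi) for si, xi in zip(s, x)]
    r1 = (v1 - np.array([q.v_1oh for q in pred])) / sd
    r4 = (v4 - np.array([q.v_4oh for q in pred])) / sd
    return np.concatenate([r1, r4])


def fit_rate_data(
    data: RateDataset,
    init: OccupancyModelParams,
    free: Sequence[str] = ("kd_prod_s", "kd_allo_s"),
    seed: int = 0,
    n_starts: int = 10,
) -> FitResult:
    """Fit free occupancy-model parameters to a kinetic dataset.

    Parameters
    ----------
    data : RateDataset
        Observed rates; an optional ``sd`` column provides weights
        (defaults to unit weights).
    init : OccupancyModelParams
        Initial guess; fields not listed in ``free`` are held fixed.
    free : sequence of str
        Names of the OccupancyModelParams fields to fit.
    seed : int
        Seeds the multi-start perturbations.
    n_starts : int
        Number of restarts; the first start is the unperturbed guess.

    Returns
    -------
    FitResult
        Best optimum by (residual sum of squares, parameter norm);
        ``identifiable[name]`` is False for any free parameter to which the
        residuals are insensitive at the optimum (e.g. effector parameters
        when the dataset has no effector).
    """
    free = list(free)
    bad = [f for f in free if f not in FREE_PARAM_NAMES]
    if bad:
        raise InputError(f"unknown free parameters: {bad}")
    if data.n_distinct_s < 4:
        raise InputError("need at least 4 distinct substrate concentrations")
    if len(data) < len(free):
        raise InputError(
            f"{len(data)} rows cannot constrain {len(free)} free parameters"
        )

    df = data.data
    s = df["s_um"].to_numpy(float)
    x = df["x_um"].to_numpy(float)
    v1 = df["v1oh"].to_numpy(float)
    v4 = df["v4oh"].to_numpy(float)
    sd = (df["sd"].to_numpy(float) if "sd" in df.columns
          else np.ones_like(s))
    if np.any(sd <= 0):
        raise InputError("sd weights must be positive")

    rng = np.random.default_rng(seed)
    args = (init, s, x, v1, v4, sd)

    best = None
    n_done = 0
    for start in range(n_starts):
        pars = _make_lmfit_params(init, free)
        if start > 0:  # jittered restarts around the initial guess
            for name in pars:
                par = pars[name]
                if not par.vary:
                    continue
                if name.startswith("log10_"):
                    par.value = np.clip(par.value + rng.normal(0, 0.5),
                                        par.min, par.max)
                elif name in _F4OH_NAMES:
                    par.value = float(np.clip(par.value + rng.normal(0, 0.15),
                                              1e-3, 1 - 1e-3))
                else:
                    par.value = abs(par.value * (1 + rng.normal(0, 0.3))) + 1e-6
        try:
            res = lmfit.minimize(_residuals, pars, args=args,
                                 method="least_squares")
        except Exception:
            continue
        n_done += 1
        rss = float(np.sum(res.residual ** 2))
        pnorm = float(np.linalg.norm([res.params[n].value for n in res.params
                                      if res.params[n].vary]))
        key = (rss, pnorm)
        if best is None or key < best[0]:
            best = (key, res)

    if best is None:
        return FitResult(params=init, converged=False, n_starts=0,
                         identifiable={f: False for f in free})

    _, res = best
    fitted = _params_from_lmfit(res.params, init)

    stderr: Dict[str, Optional[float]] = {}
    for name in free:
        key = f"log10_{name}" if name in _KD_NAMES else name
        se = res.params[key].stderr
        if se is not None and name in _KD_NAMES:
            # delta-method back-transform from log10 scale
            se = se * math.log(10) * getattr(fitted, name)
        stderr[name] = None if se is None else float(se)

    identifiable = _sensitivity_flags(res.params, free, args)

    return FitResult(
        params=fitted,
        stderr=stderr,
        rss=float(np.sum(res.residual ** 2)),
        converged=bool(res.success),
        identifiable=identifiable,
        n_starts=n_done,
    )


def _sensitivity_flags(pars: lmfit.Parameters, free: Sequence[str], args
                       ) -> Dict[str, bool]:
    """Flag free parameters whose perturbation leaves the residuals unchanged."""
    base = _residuals(pars, *args)
    flags = {}
    for name in free:
        key = f"log10_{name}" if name in _KD_NAMES else name
        perturbed = pars.copy()
        p = perturbed[key]
        step = 0.05 * max(abs(p.value), 1e-3)
        p.set(value=p.value + step, min=-np.inf, max=np.inf)
        delta = _residuals(perturbed, *args) - base
        flags[name] = bool(np.max(np.abs(delta)) > 1e-10)
    return flags


def fit_titration(curve: TitrationCurve, init_ks: Optional[float] = None,
                  init_bmax: Optional[float] = None) -> TitrationFit:
    """Least-squares Langmuir fit of a spin-shift titration.

    Requires at least 4 concentration points.  Raises
    :class:`IdentifiabilityError` when the response carries no signal.
    """
    df = curve.data
    if len(df) < 4:
        raise InputError("titration fit needs at least 4 points")
    l = df["ligand_um"].to_numpy(float)
    r = df["response"].to_numpy(float)
    if np.ptp(r) < 1e-9:
        raise IdentifiabilityError("flat titration response: ks not identifiable")

    bmax0 = init_bmax if init_bmax is not None else min(max(r.max(), 1e-3), 1.0)
    ks0 = init_ks if init_ks is not None else max(np.median(l[l > 0]), 1e-3)

    popt, pcov = curve_fit(
        lambda lc, ks, bmax: bmax * lc / (ks + lc),
        l, r, p0=[ks0, bmax0],
        bounds=([1e-9, 0.0], [np.inf, 1.0]),
        maxfev=10000,
    )
    perr = np.sqrt(np.diag(pcov))
    resid = r - langmuir_response(popt[0], popt[1], l)
    return TitrationFit(
        ks=float(popt[0]), bmax=float(popt[1]),
        ks_stderr=float(perr[0]), bmax_stderr=float(perr[1]),
        rss=float(np.sum(resid ** 2)),
    )


def classify_effector_mode(
    fit_base: FitResult,
    data_with_x: RateDataset,
    threshold_som: float = 0.2,
    threshold_rate: float = 0.2,
    min_4oh_share: float = 0.05,
) -> str:
    """Classify an effector by its signature on SOM ratio and total rate.

    Compares the observed rates at effector-present rows against the
    baseline model (fitted at x = 0) evaluated at the same substrate
    concentrations.  SOM shifts are only meaningful where the baseline
    minor product is quantifiable, so the comparison is restricted to
    matched concentrations where the baseline 4OH share is at least
    ``min_4oh_share``; among those, the largest-magnitude relative shift
    decides the direction.  (At very low substrate the baseline forms
    almost no 4OH, so any allosteric occupancy registers as 4OH-favoring
    regardless of the effector's own regioselectivity.)  The total-rate
    shift is the median over matched concentrations.

    Returns one of ``no-effect``, ``competitive-inhibition``,
    ``allosteric-4OH-favoring``, ``allosteric-4OH-suppressing``, ``mixed``.
    """
    df = data_with_x.data
    obs = df[df["x_um"] > 0]
    if obs.empty:
        raise InputError("dataset contains no effector-present rows")

    som_shifts = []  # shifts where the baseline 4OH share is quantifiable
    rate_shifts = []
    appeared = False  # 4OH formed under effector where baseline makes none
    for s_val, grp in obs.groupby("s_um"):
        base = predict_rates(fit_base.params, float(s_val), 0.0)
        v1 = grp["v1oh"].mean()
        v4 = grp["v4oh"].mean()
        if base.v_total > 0:
            rate_shifts.append((v1 + v4 - base.v_total) / base.v_total)
        obs_som = v1 / v4 if v4 > 0 else math.nan
        base_share = base.v_4oh / base.v_total if base.v_total > 0 else 0.0
        if base_share >= min_4oh_share and not math.isnan(obs_som):
            som_shifts.append((obs_som - base.som_ratio) / base.som_ratio)
        elif base_share < min_4oh_share and not math.isnan(obs_som):
            obs_share = v4 / (v1 + v4)
            if obs_share >= min_4oh_share:
                appeared = True
    if not som_shifts and not rate_shifts and not appeared:
        raise InputError("no matched substrate concentrations with defined rates")

    if som_shifts:
        som_shift = max(som_shifts, key=abs)
    else:
        som_shift = -math.inf if appeared else 0.0
    rate_shift = float(np.median(rate_shifts)) if rate_shifts else 0.0

    som_down = som_shift < -threshold_som
    som_up = som_shift > threshold_som
    rate_down = rate_shift < -threshold_rate

    if (som_down or som_up) and rate_down:
        return "mixed"
    if som_down:
        return "allosteric-4OH-favoring"
    if som_up:
        return "allosteric-4OH-suppressing"
    if rate_down:
        return "competitive-inhibition"
    return "no-effect"
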