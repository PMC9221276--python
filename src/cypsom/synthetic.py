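"""Seeded generators for kinetic, titration, and toy-trajectory data.

These generators emulate the statistical structure of the study conditions:
substrate-saturation rate panels with and without allosteric effectors,
non-cooperative Langmuir spin-shift titrations, and minimal coordinate
trajectories whose C1/C4-to-oxidant distance distributions and
residue-contact probabilities follow prescribed mixtures.  Every generator
is deterministic under a fixed seed, and embeds (or emits alongside) its
ground truth so the analysis modules can be validated by round-trip.

The toy trajectory contains no full protein: a heme pseudo-residue (Fe,
four pyrrole N, axial S), a two-carbon ligand (C1, C4), and one pseudo-atom
per protein residue of interest.  The residue ids are real CYP3A4 positions
in the B-C loop (106, 108), the F-F' loop (213-221) and the active site
(304, 309), so contact reports read like the real analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

import MDAnalysis as mda
from MDAnalysis.coordinates.memory import MemoryReader

from .fitting import RateDataset, TitrationCurve
from .model import InputError, OccupancyModelParams, langmuir_response, predict_rates

__all__ = [
    "RateDesign",
    "TrajectorySpec",
    "ScenarioPreset",
    "generate_rate_dataset",
    "generate_titration",
    "generate_toy_trajectory",
    "scenario_presets",
]

NOISE_MODELS = ("none", "additive", "proportional")


@dataclass(frozen=True)
class RateDesign:
    """Design of a synthetic kinetic experiment.

    ``noise_model`` is one of ``none``, ``additive`` (Gaussian sd =
    ``noise_scale`` in rate units) or ``proportional`` (Gaussian cv =
    ``noise_scale``).  ``replicates`` emits that many rows per design
    point, never averaged.
    """

    s_grid: Tuple[float, ...]
    x_levels: Tuple[float, ...] = (0.0,)
    noise_model: str = "none"
    noise_scale: float = 0.0
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "s_grid", tuple(float(s) for s in self.s_grid))
        object.__setattr__(self, "x_levels", tuple(float(x) for x in self.x_levels))
        if not self.s_grid or not self.x_levels:
            raise InputError("s_grid and x_levels must be non-empty")
        if any(s < 0 for s in self.s_grid) or any(x < 0 for x in self.x_levels):
            raise InputError("concentrations must be >= 0")
        if self.noise_model not in NOISE_MODELS:
            raise InputError(f"noise_model must be one of {NOISE_MODELS}")
        if self.noise_scale < 0:
            raise InputError("noise_scale must be >= 0")
        if self.replicates < 1:
            raise InputError("replicates must be >= 1")

    def to_dict(self) -> dict:
        return {
            "s_grid": list(self.s_grid),
            "x_levels": list(self.x_levels),
            "noise_model": self.noise_model,
            "noise_scale": self.noise_scale,
            "replicates": self.replicates,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RateDesign":
        return cls(**{**d, "s_grid": tuple(d["s_grid"]),
                      "x_levels": tuple(d["x_levels"])})


def _default_s_grid() -> Tuple[float, ...]:
    """12 substrate points, 0.5-100 uM, log-spaced."""
    return tuple(np.round(np.geomspace(0.5, 100.0, 12), 4))


def generate_rate_dataset(
    true_params: OccupancyModelParams, design: RateDesign,
    effector: str = "synthetic",
) -> RateDataset:
    """Generate a kinetic dataset from the occupancy model plus noise.

    Noiseless rows equal :func:`~cypsom.model.predict_rates` outputs
    exactly; seeded noise is bit-reproducible.  The generating parameters
    travel with the dataset as ground truth.
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    for x in design.x_levels:
        for s in design.s_grid:
            pred = predict_rates(true_params, s, x)
            for _rep in range(design.replicates):
                v1, v4 = pred.v_1oh, pred.v_4oh
                if design.noise_model == "additive":
                    v1 += rng.normal(0.0, design.noise_scale)
                    v4 += rng.normal(0.0, design.noise_scale)
                    sd = design.noise_scale
                elif design.noise_model == "proportional":
                    v1 *= 1.0 + rng.normal(0.0, design.noise_scale)
                    v4 *= 1.0 + rng.normal(0.0, design.noise_scale)
                    sd = design.noise_scale * max(pred.v_total / 2, 1e-9)
                else:
                    sd = 1.0
                rows.append((s, x, max(v1, 0.0), max(v4, 0.0), sd))
    df = pd.DataFrame(rows, columns=["s_um", "x_um", "v1oh", "v4oh", "sd"])
    if design.noise_model == "none":
        df = df.drop(columns="sd")
    return RateDataset(data=df, effector=effector, true_params=true_params)


def generate_titration(
    ks: float, bmax: float, grid: Sequence[float],
    noise_sd: float = 0.0, seed: int = 0, ligand: str = "ligand",
) -> TitrationCurve:
    """Langmuir titration curve with additive Gaussian noise, clipped to [0, 1]."""
    grid = np.asarray(list(grid), float)
    if grid.size == 0 or np.any(grid < 0):
        raise InputError("titration grid must be non-empty and >= 0")
    if noise_sd < 0:
        raise InputError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    resp = np.array([langmuir_response(ks, bmax, l) for l in grid])
    if noise_sd > 0:
        resp = resp + rng.normal(0.0, noise_sd, size=resp.shape)
    resp = np.clip(resp, 0.0, 1.0)
    return TitrationCurve(
        data=pd.DataFrame({"ligand_um": grid, "response": resp}), ligand=ligand,
    )


#: CYP3A4 residue ids carried by the toy system's pseudo-atoms.
TOY_RESIDUE_IDS = (106, 108, 213, 214, 215, 216, 217, 218, 219, 220, 221, 304, 309)


@dataclass(frozen=True)
class TrajectorySpec:
    """Specification of a toy trajectory's label and distance statistics.

    Distances (A) are measured to the analytically known virtual oxygen.
    Mixture components are truncated normals kept a ``margin`` clear of
    the classification thresholds so every generated frame's label is
    unambiguous and exactly recoverable.
    """

    n_frames: int = 1000
    productive_probability: float = 0.52
    selective_probability: float = 0.8  # P(selective | productive)
    contact_probabilities: Dict[int, float] = field(default_factory=dict)
    condition: str = "baseline"
    seed: int = 0
    # distance mixture parameters (A)
    c1_in_mean: float = 3.8
    c1_out_mean: float = 5.2
    c4_near_mean: float = 4.8
    c4_far_mean: float = 6.3
    distance_sd: float = 0.3
    productive_cutoff: float = 4.5
    selective_cutoff: float = 5.5
    contact_cutoff: float = 4.0
    margin: float = 0.05

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise InputError("n_frames must be >= 1")
        for name in ("productive_probability", "selective_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} must lie in [0, 1]")
        for rid, p in self.contact_probabilities.items():
            if not 0.0 <= p <= 1.0:
                raise InputError(f"contact probability for resid {rid} not in [0, 1]")
        if self.margin <= 0:
            raise InputError("margin must be > 0")

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "n_frames", "productive_probability", "selective_probability",
            "condition", "seed", "c1_in_mean", "c1_out_mean", "c4_near_mean",
            "c4_far_mean", "distance_sd", "productive_cutoff",
            "selective_cutoff", "contact_cutoff", "margin")}
        d["contact_probabilities"] = {int(k): float(v) for k, v in
                                      self.contact_probabilities.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrajectorySpec":
        kw = dict(d)
        kw["contact_probabilities"] = {int(k): float(v) for k, v in
                                       kw.get("contact_probabilities", {}).items()}
        return cls(**kw)


def _trunc_sample(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                         random_state=rng)


def _random_unit_vectors(rng, n):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


# Idealized heme frame: Fe at origin, pyrrole N's in the z=0 plane, axial S
# proximal (negative z).  Virtual oxygen sits at (0, 0, fe_o_distance).
_HEME_COORDS = np.array([
    [0.0, 0.0, 0.0],      # FE
    [2.0, 0.0, 0.0],      # N1
    [0.0, 2.0, 0.0],      # N2
    [-2.0, 0.0, 0.0],     # N3
    [0.0, -2.0, 0.0],     # N4
    [0.0, 0.0, -2.3],     # SG
])
_FE_O_DISTANCE = 1.65
_O_VIRTUAL = np.array([0.0, 0.0, _FE_O_DISTANCE])
_FAR_AWAY = np.array([40.0, 40.0, 40.0])  # non-contact parking position


def generate_toy_trajectory(
    spec: TrajectorySpec,
    topology_path,
    trajectory_path,
    labels_path=None,
) -> pd.DataFrame:
    """Write a toy PDB topology + DCD/XTC trajectory with known labels.

    Per frame, productive and (conditionally) selective labels are sampled,
    C1 and C4 are placed at distances from the virtual oxygen drawn from
    the matching truncated-normal mixture component, and each residue
    pseudo-atom is placed in or out of contact range of the ligand
    according to its Bernoulli contact indicator.

    Returns the ground-truth label table (columns ``frame, productive,
    selective, d_c1_o, d_c4_o, contact_<resid>...``); also written to
    ``labels_path`` as CSV when given.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    resids = sorted(spec.contact_probabilities) or list(TOY_RESIDUE_IDS)
    probs = {rid: spec.contact_probabilities.get(rid, 0.0) for rid in resids}

    productive = rng.random(n) < spec.productive_probability
    selective_draw = rng.random(n) < spec.selective_probability
    selective = productive & selective_draw

    m = spec.margin
    d_c1 = np.where(
        productive,
        _trunc_sample(rng, spec.c1_in_mean, spec.distance_sd,
                      2.5, spec.productive_cutoff - m, n),
        _trunc_sample(rng, spec.c1_out_mean, spec.distance_sd,
                      spec.productive_cutoff + m, 8.0, n),
    )
    d_c4 = np.where(
        selective,
        _trunc_sample(rng, spec.c4_far_mean, spec.distance_sd,
                      spec.selective_cutoff + m, 9.0, n),
        _trunc_sample(rng, spec.c4_near_mean, spec.distance_sd,
                      2.5, spec.selective_cutoff - m, n),
    )

    contacts = {rid: rng.random(n) < probs[rid] for rid in resids}

    # Assemble coordinates: heme(6) + ligand C1,C4 + one CA per residue.
    n_atoms = 6 + 2 + len(resids)
    coords = np.empty((n, n_atoms, 3), dtype=np.float32)
    u1 = _random_unit_vectors(rng, n)
    u4 = _random_unit_vectors(rng, n)
    contact_dirs = {rid: _random_unit_vectors(rng, n) for rid in resids}
    for i in range(n):
        coords[i, :6] = _HEME_COORDS
        c1 = _O_VIRTUAL + d_c1[i] * u1[i]
        c4 = _O_VIRTUAL + d_c4[i] * u4[i]
        coords[i, 6] = c1
        coords[i, 7] = c4
        for j, rid in enumerate(resids):
            if contacts[rid][i]:
                # 3.2 A from C1: inside any positive cutoff >= margin-safe 4.0
                coords[i, 8 + j] = c1 + 3.2 * contact_dirs[rid][i]
            else:
                coords[i, 8 + j] = _FAR_AWAY + 5.0 * contact_dirs[rid][i]

    u = _build_toy_universe(resids, coords)
    with warnings.catch_warnings():
        # toy system has no cell/chain metadata; writer defaults are fine
        warnings.simplefilter("ignore", UserWarning)
        u.atoms.write(str(topology_path))
        with mda.Writer(str(trajectory_path), n_atoms=n_atoms) as w:
            for _ts in u.trajectory:
                w.write(u.atoms)

    labels = pd.DataFrame({
        "frame": np.arange(n),
        "productive": productive,
        "selective": np.where(productive, selective, np.array(None)),
        "d_c1_o": d_c1,
        "d_c4_o": d_c4,
    })
    for rid in resids:
        labels[f"contact_{rid}"] = contacts[rid]
    if labels_path is not None:
        labels.to_csv(labels_path, index=False)
    return labels


def _build_toy_universe(resids: List[int], coords: np.ndarray) -> mda.Universe:
    n_res = 2 + len(resids)
    n_atoms = coords.shape[1]
    atom_resindex = [0] * 6 + [1] * 2 + list(range(2, n_res))
    u = mda.Universe.empty(n_atoms, n_residues=n_res,
                           atom_resindex=atom_resindex, trajectory=True)
    names = ["FE", "N1", "N2", "N3", "N4", "SG", "C1", "C4"] + ["CA"] * len(resids)
    elements = ["Fe", "N", "N", "N", "N", "S", "C", "C"] + ["C"] * len(resids)
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("elements", elements)
    u.add_TopologyAttr("types", elements)
    u.add_TopologyAttr("resnames", ["HEM", "MDZ"] + ["GLY"] * len(resids))
    u.add_TopologyAttr("resids", [900, 901] + list(resids))
    u.load_new(coords, format=MemoryReader)
    return u


@dataclass(frozen=True)
class ScenarioPreset:
    """A named, fully-specified synthetic scenario.

    Bundles the generating occupancy-model parameters with a kinetic
    design; trajectory presets additionally carry a pair of
    :class:`TrajectorySpec` conditions, and titration presets the Langmuir
    ground truth.
    """

    name: str
    params: OccupancyModelParams
    design: RateDesign
    description: str = ""
    titration: Optional[Tuple[float, float]] = None  # (ks uM, bmax)
    trajectory_pair: Optional[Tuple[TrajectorySpec, TrajectorySpec]] = None

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "params": self.params.to_dict(),
            "design": self.design.to_dict(),
            "description": self.description,
        }
        if self.titration is not None:
            d["titration"] = {"ks": self.titration[0], "bmax": self.titration[1]}
        if self.trajectory_pair is not None:
            d["trajectory_pair"] = [t.to_dict() for t in self.trajectory_pair]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioPreset":
        titration = None
        if "titration" in d:
            titration = (d["titration"]["ks"], d["titration"]["bmax"])
        pair = None
        if "trajectory_pair" in d:
            pair = tuple(TrajectorySpec.from_dict(t) for t in d["trajectory_pair"])
        return cls(
            name=d["name"],
            params=OccupancyModelParams.from_dict(d["params"]),
            design=RateDesign.from_dict(d["design"]),
            description=d.get("description", ""),
            titration=titration,
            trajectory_pair=pair,
        )


# Contact probabilities emulating the reported per-residue signature:
# with the effector bound, contacts with 106/108 (B-C loop) and 215/218/220
# (F-F' loop) drop by >= 50%, 217 and 309 drop by < 50%, 214 gains >= 50%,
# 304 gains < 50%.
_BASE_CONTACTS = {
    106: 0.60, 108: 0.55, 213: 0.30, 214: 0.25, 215: 0.50, 216: 0.30,
    217: 0.35, 218: 0.45, 219: 0.30, 220: 0.40, 221: 0.30, 304: 0.30,
    309: 0.35,
}
_EFFECTOR_CONTACTS = {
    106: 0.25, 108: 0.20, 213: 0.30, 214: 0.55, 215: 0.20, 216: 0.30,
    217: 0.25, 218: 0.18, 219: 0.30, 220: 0.15, 221: 0.30, 304: 0.39,
    309: 0.25,
}


def _pgs_trajectory_pair(seed: int = 0) -> Tuple[TrajectorySpec, TrajectorySpec]:
    base = TrajectorySpec(
        n_frames=2000, productive_probability=0.52,
        selective_probability=0.8, contact_probabilities=_BASE_CONTACTS,
        condition="no-effector", seed=seed,
    )
    with_pgs = TrajectorySpec(
        n_frames=2000, productive_probability=0.52,
        selective_probability=0.6, contact_probabilities=_EFFECTOR_CONTACTS,
        condition="with-pgs", seed=seed + 1,
    )
    return base, with_pgs


def scenario_presets(seed: int = 0) -> Dict[str, ScenarioPreset]:
    """Named synthetic scenarios mirroring the experimental designs.

    * ``pgs_15um`` — progesterone at a single 15 uM level; its allosteric
      Kd is set to 14.7 uM so that the substrate outcompetes 15 uM effector
      above ~15 uM substrate; carries the two-condition trajectory pair.
    * ``steroid_20_50um`` — generic steroid panel at 20 and 50 uM.
    * ``medroxyprogesterone_2_8um`` — tight binder probed at 2 and 8 uM.
    * ``anf_gefitinib_opposite`` — effector that suppresses 4OH formation
      (f4oh_sx below the homotropic doubly-bound value), shifting SOM up.
    * ``schisandrin_weak`` — steroid-like direction but weaker amplitude;
      carries the Langmuir titration truth (Ks 10 uM, 70% spin shift).
    """
    s_grid = _default_s_grid()

    def design(x_levels, offset):
        return RateDesign(s_grid=s_grid, x_levels=(0.0, *x_levels),
                          noise_model="none", seed=seed + offset)

    presets = {
        "pgs_15um": ScenarioPreset(
            name="pgs_15um",
            params=OccupancyModelParams(kd_allo_x=14.7, f4oh_sx=0.35),
            design=design((15.0,), 0),
            description="progesterone, 15 uM, allosteric 4OH-favoring",
            trajectory_pair=_pgs_trajectory_pair(seed),
        ),
        "steroid_20_50um": ScenarioPreset(
            name="steroid_20_50um",
            params=OccupancyModelParams(kd_allo_x=25.0, f4oh_sx=0.35),
            design=design((20.0, 50.0), 1),
            description="generic steroid panel, 20/50 uM",
        ),
        "medroxyprogesterone_2_8um": ScenarioPreset(
            name="medroxyprogesterone_2_8um",
            params=OccupancyModelParams(kd_allo_x=2.0, f4oh_sx=0.35),
            design=design((2.0, 8.0), 2),
            description="tight-binding steroid, 2/8 uM",
        ),
        "anf_gefitinib_opposite": ScenarioPreset(
            name="anf_gefitinib_opposite",
            params=OccupancyModelParams(kd_allo_x=10.0, f4oh_sx=0.05),
            design=design((5.0, 15.0), 3),
            description="ANF/Gefitinib-like effector suppressing 4OH",
            titration=(10.0, 0.25),
        ),
        "schisandrin_weak": ScenarioPreset(
            name="schisandrin_weak",
            params=OccupancyModelParams(kd_allo_x=20.0, f4oh_sx=0.15),
            design=design((5.0, 13.0), 4),
            description="weak steroid-like effector, large spin shift",
            titration=(10.0, 0.70),
        ),
    }
    return presets


def get_preset(name: str, seed: int = 0) -> ScenarioPreset:
    presets = scenario_presets(seed)
    if name not in presets:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(presets)}"
        )
    return presets[name]
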