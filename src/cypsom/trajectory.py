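"""Geometric regioselectivity analysis of CYP3A4-ligand MD trajectories.

The reactive species of the P450 catalytic cycle is Compound I, a ferryl
(Fe=O) intermediate.  Hydroxylation proceeds by hydrogen-atom abstraction,
so a trajectory frame can only lead to product when the metabolized carbon
sits close to the ferryl oxygen.  Trajectories rarely model Compound I
explicitly; instead a *virtual oxygen* is constructed 1.65 A above the heme
iron along the distal normal of the pyrrole-nitrogen plane (a typical
ferryl bond length), and frames are classified by the distances from the
substrate carbons C1 (major site of metabolism) and C4 (minor site) to that
point:

* **productive** — d(C1, O) <= 4.5 A ("within" is inclusive);
* **selective** — productive and d(C4, O) > 5.5 A (strictly): only C1 is in
  reach, so only the major 1OH product can form;
* **non-selective** — productive but C4 also near the oxidant, permitting
  the minor 4OH product.

Productive frames are further analyzed for residue-ligand contacts (any
heavy-atom pair within 4.0 A) and contact frequencies are compared between
conditions (e.g. with/without an allosteric effector), flagging residues
whose contact frequency changes by 50% or more.

All coordinates are in Angstrom; MDAnalysis converts nm-based trajectory
formats (e.g. XTC) on read.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

import MDAnalysis as mda
from MDAnalysis.lib.distances import distance_array

from .model import InputError

__all__ = [
    "HemeGeometry",
    "ClassificationThresholds",
    "FrameClassification",
    "ScanSummary",
    "ContactTable",
    "ContactDifferential",
    "GeometryError",
    "SelectionError",
    "build_virtual_oxygen",
    "classify_frame",
    "scan_trajectory",
    "distance_histogram",
    "contact_counts",
    "contact_differential",
    "classifications_to_frame",
]


class GeometryError(ValueError):
    """Degenerate heme geometry (collinear pyrrole nitrogens, in-plane axial S)."""


class SelectionError(ValueError):
    """An atom selection resolved to the wrong number of atoms."""


@dataclass(frozen=True)
class ClassificationThresholds:
    """Distance cutoffs (A) for frame classification and contacts."""

    productive_cutoff: float = 4.5
    selective_cutoff: float = 5.5
    contact_cutoff: float = 4.0

    def __post_init__(self) -> None:
        for name in ("productive_cutoff", "selective_cutoff", "contact_cutoff"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be > 0")
        if self.selective_cutoff < self.productive_cutoff:
            raise InputError("selective_cutoff must be >= productive_cutoff")


@dataclass(frozen=True)
class HemeGeometry:
    """Positions (A) defining the heme reference frame.

    ``fe``: iron; ``pyrrole_n``: the four pyrrole nitrogens (4 x 3 array);
    ``axial_s``: the proximal cysteine thiolate sulfur, which identifies the
    proximal face so the virtual oxygen can be placed distally.
    """

    fe: np.ndarray
    pyrrole_n: np.ndarray
    axial_s: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "fe", np.asarray(self.fe, dtype=float))
        object.__setattr__(self, "pyrrole_n", np.asarray(self.pyrrole_n, dtype=float))
        object.__setattr__(self, "axial_s", np.asarray(self.axial_s, dtype=float))
        if self.pyrrole_n.shape != (4, 3):
            raise InputError("pyrrole_n must be a 4x3 coordinate array")
        if self.fe.shape != (3,) or self.axial_s.shape != (3,):
            raise InputError("fe and axial_s must be 3-vectors")


def _pyrrole_plane_normal(pyrrole_n: np.ndarray) -> np.ndarray:
    """Unit normal of the least-squares plane through the pyrrole nitrogens."""
    centered = pyrrole_n - pyrrole_n.mean(axis=0)
    _u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # Collinear (or coincident) nitrogens: no unique plane.
    if s[1] < 1e-6 * max(s[0], 1e-12):
        raise GeometryError("pyrrole nitrogens are collinear; plane undefined")
    return vt[2]


def build_virtual_oxygen(heme: HemeGeometry, fe_o_distance: float = 1.65
                         ) -> np.ndarray:
    """Place the virtual Compound-I oxygen above the heme iron.

    The point is ``fe + fe_o_distance * n`` where ``n`` is the unit normal
    of the least-squares pyrrole-nitrogen plane oriented away from the
    proximal axial sulfur (i.e. toward the distal, substrate-facing side).

    Raises
    ------
    GeometryError
        If the nitrogens are collinear or the axial sulfur lies in the
        pyrrole plane (orientation ambiguous).
    """
    normal = _pyrrole_plane_normal(heme.pyrrole_n)
    center = heme.pyrrole_n.mean(axis=0)
    side = float(np.dot(heme.axial_s - center, normal))
    if abs(side) < 1e-6:
        raise GeometryError("axial sulfur lies in the pyrrole plane; "
                            "distal orientation undefined")
    if side > 0:  # normal currently points proximally; flip distal
        normal = -normal
    return heme.fe + fe_o_distance * normal


@dataclass(frozen=True)
class FrameClassification:
    """Per-frame geometric verdict.

    ``selective`` is None for non-productive frames (undefined).
    """

    frame_index: int
    d_c1_o: float
    d_c4_o: float
    productive: bool
    selective: Optional[bool]


def classify_frame(
    c1: np.ndarray,
    c4: np.ndarray,
    o_virtual: np.ndarray,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
    frame_index: int = 0,
) -> FrameClassification:
    """Classify one frame from the C1/C4 positions and the virtual oxygen.

    Boundary convention: productive is inclusive (d_C1 <= cutoff, "within");
    selective is strict (d_C4 > cutoff, "more than").
    """
    c1 = np.asarray(c1, float)
    c4 = np.asarray(c4, float)
    o = np.asarray(o_virtual, float)
    if not (np.all(np.isfinite(c1)) and np.all(np.isfinite(c4))
            and np.all(np.isfinite(o))):
        raise InputError("coordinates must be finite")
    d1 = float(np.linalg.norm(c1 - o))
    d4 = float(np.linalg.norm(c4 - o))
    productive = d1 <= thresholds.productive_cutoff
    selective = (d4 > thresholds.selective_cutoff) if productive else None
    return FrameClassification(frame_index, d1, d4, productive, selective)


@dataclass(frozen=True)
class ScanSummary:
    n_total: int
    n_productive: int
    n_selective: int
    n_nonselective: int

    @property
    def productive_fraction(self) -> float:
        return self.n_productive / self.n_total if self.n_total else math.nan

    @property
    def selective_fraction(self) -> float:
        """Fraction of productive frames where only C1 is in reach."""
        return self.n_selective / self.n_productive if self.n_productive else math.nan

    @property
    def nonselective_fraction(self) -> float:
        return (self.n_nonselective / self.n_productive
                if self.n_productive else math.nan)


#: Default atom selections (MDAnalysis selection grammar).
DEFAULT_SELECTIONS = {
    "c1": "resname MDZ and name C1",
    "c4": "resname MDZ and name C4",
    "fe": "resname HEM and name FE",
    "axial_s": "resname HEM and name SG",
    "pyrrole_n": "resname HEM and name N1 N2 N3 N4",
}


def _resolve(universe: mda.Universe, selections: Dict[str, str]):
    """Resolve the five named selections, enforcing atom counts."""
    sel = dict(DEFAULT_SELECTIONS)
    sel.update(selections or {})
    groups = {}
    expected = {"c1": 1, "c4": 1, "fe": 1, "axial_s": 1, "pyrrole_n": 4}
    for key, n_exp in expected.items():
        try:
            g = universe.select_atoms(sel[key])
        except Exception as exc:
            raise SelectionError(f"selection {key}={sel[key]!r} failed: {exc}")
        if len(g) != n_exp:
            raise SelectionError(
                f"selection {key}={sel[key]!r} resolved to {len(g)} atoms, "
                f"expected {n_exp}"
            )
        groups[key] = g
    return groups


def scan_trajectory(
    topology,
    trajectory=None,
    selections: Optional[Dict[str, str]] = None,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
    stride: int = 1,
    fe_o_distance: float = 1.65,
) -> Tuple[List[FrameClassification], ScanSummary]:
    """Scan a trajectory, classifying every ``stride``-th frame.

    Parameters
    ----------
    topology : path or MDAnalysis.Universe
        PDB topology (or a pre-built Universe, in which case ``trajectory``
        is ignored).
    trajectory : path, optional
        DCD or XTC coordinates.
    selections : dict, optional
        Overrides for the atom selections ``c1, c4, fe, axial_s,
        pyrrole_n`` (MDAnalysis grammar); each must resolve to exactly one
        atom (four for ``pyrrole_n``).
    stride : int
        Classify every ``stride``-th frame, starting from frame 0.

    Returns
    -------
    (list of FrameClassification, ScanSummary)
        Frame indices refer to the trajectory as read (0-based, pre-stride
        numbering).
    """
    if stride < 1:
        raise InputError("stride must be >= 1")
    if isinstance(topology, mda.Universe):
        u = topology
    else:
        try:
            u = (mda.Universe(str(topology)) if trajectory is None
                 else mda.Universe(str(topology), str(trajectory)))
        except (OSError, ValueError) as exc:
            raise IOError(f"cannot read topology/trajectory: {exc}")
    groups = _resolve(u, selections)

    classifications: List[FrameClassification] = []
    for ts in u.trajectory[::stride]:
        heme = HemeGeometry(
            fe=groups["fe"].positions[0],
            pyrrole_n=groups["pyrrole_n"].positions,
            axial_s=groups["axial_s"].positions[0],
        )
        o = build_virtual_oxygen(heme, fe_o_distance)
        fc = classify_frame(groups["c1"].positions[0], groups["c4"].positions[0],
                            o, thresholds, frame_index=ts.frame)
        classifications.append(fc)
    return classifications, summarize(classifications)


def summarize(classifications: Sequence[FrameClassification]) -> ScanSummary:
    n_total = len(classifications)
    n_prod = sum(1 for c in classifications if c.productive)
    n_sel = sum(1 for c in classifications if c.productive and c.selective)
    return ScanSummary(
        n_total=n_total,
        n_productive=n_prod,
        n_selective=n_sel,
        n_nonselective=n_prod - n_sel,
    )


def classifications_to_frame(classifications: Sequence[FrameClassification]
                             ) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.frame_index, c.d_c1_o, c.d_c4_o, c.productive,
          "" if c.selective is None else c.selective)
         for c in classifications],
        columns=["frame", "d_c1_o", "d_c4_o", "productive", "selective"],
    )


def distance_histogram(
    classifications: Sequence[FrameClassification],
    which: str = "c1",
    bin_edges: Sequence[float] = tuple(np.arange(2.0, 10.5, 0.5)),
    productive_only: bool = False,
) -> pd.DataFrame:
    """Histogram of C1-O or C4-O distances over (optionally productive) frames.

    Distances outside the edge range are clipped into the terminal bins so
    the counts always sum to the number of frames selected.  Returns a
    frame with columns ``bin_lo, bin_hi, count``.
    """
    if which not in ("c1", "c4"):
        raise InputError("which must be 'c1' or 'c4'")
    edges = np.asarray(bin_edges, float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise InputError("bin edges must be strictly increasing, length >= 2")
    sel = [c for c in classifications if (c.productive or not productive_only)]
    if not sel:
        warnings.warn("no frames selected for histogram", stacklevel=2)
        counts = np.zeros(len(edges) - 1, dtype=int)
    else:
        d = np.array([c.d_c1_o if which == "c1" else c.d_c4_o for c in sel])
        d = np.clip(d, edges[0], edges[-1] - 1e-12)
        counts, _ = np.histogram(d, bins=edges)
    return pd.DataFrame({
        "bin_lo": edges[:-1], "bin_hi": edges[1:], "count": counts.astype(int),
    })


@dataclass
class ContactTable:
    """Per-residue contact counts over a set of analyzed frames.

    ``counts[resid]`` is the number of analyzed frames in which any ligand
    heavy atom lies within ``cutoff`` of any heavy atom of that residue.
    """

    condition: str
    n_frames: int
    counts: Dict[int, int]
    cutoff: float

    def frequency(self, resid: int) -> float:
        return self.counts[resid] / self.n_frames if self.n_frames else math.nan

    def to_frame(self) -> pd.DataFrame:
        rows = [(r, c, self.frequency(r)) for r, c in sorted(self.counts.items())]
        return pd.DataFrame(rows, columns=["resid", "count", "frequency"])


def contact_counts(
    topology,
    trajectory=None,
    ligand_selection: str = "resname MDZ",
    residue_ids: Sequence[int] = (),
    productive_mask: Optional[Sequence[bool]] = None,
    contact_cutoff: float = 4.0,
    stride: int = 1,
    condition: str = "",
) -> ContactTable:
    """Count residue-ligand contacts over masked (typically productive) frames.

    A residue is in contact in a frame iff the minimum heavy-atom pair
    distance between it and the ligand is <= ``contact_cutoff``.  Hydrogens
    are excluded.  ``productive_mask`` selects which of the strided frames
    to analyze (length must match the strided frame count); ``None``
    analyzes all frames.
    """
    if not residue_ids:
        raise InputError("residue list must be non-empty")
    if contact_cutoff < 0:
        raise InputError("contact_cutoff must be >= 0")
    if isinstance(topology, mda.Universe):
        u = topology
    else:
        u = (mda.Universe(str(topology)) if trajectory is None
             else mda.Universe(str(topology), str(trajectory)))

    heavy = "not (name H* or name [123]H*)"
    ligand = u.select_atoms(f"({ligand_selection}) and {heavy}")
    if len(ligand) == 0:
        raise SelectionError(f"ligand selection {ligand_selection!r} is empty")
    res_groups = {}
    for rid in residue_ids:
        g = u.select_atoms(f"resid {rid} and protein and {heavy}")
        if len(g) == 0:
            g = u.select_atoms(f"resid {rid} and {heavy} and not "
                               f"({ligand_selection})")
        if len(g) == 0:
            raise InputError(f"residue id {rid} not found in topology")
        res_groups[rid] = g

    frames = u.trajectory[::stride]
    n_strided = len(range(0, len(u.trajectory), stride))
    if productive_mask is not None:
        mask = np.asarray(productive_mask, bool)
        if len(mask) != n_strided:
            raise InputError(
                f"mask length {len(mask)} != strided frame count {n_strided}"
            )
    else:
        mask = np.ones(n_strided, bool)

    counts = {rid: 0 for rid in residue_ids}
    n_analyzed = 0
    for i, _ts in enumerate(frames):
        if not mask[i]:
            continue
        n_analyzed += 1
        lig_pos = ligand.positions
        for rid, g in res_groups.items():
            dmin = distance_array(lig_pos, g.positions).min()
            if dmin <= contact_cutoff:
                counts[rid] += 1
    return ContactTable(condition=condition, n_frames=n_analyzed,
                        counts=counts, cutoff=contact_cutoff)


NEW_CONTACT = "new-contact"


@dataclass
class ContactDifferential:
    """Per-residue relative change in contact frequency between conditions.

    ``table`` columns: ``resid, freq_a, freq_b, rel_change, category,
    flag_major_loss, flag_major_gain``.  Residues absent from the baseline
    (zero frequency in A but contacted in B) fall in the ``new-contact``
    category with an undefined (NaN) relative change.
    """

    condition_a: str
    condition_b: str
    major_threshold: float
    table: pd.DataFrame

    @property
    def major_losses(self) -> list:
        return self.table.loc[self.table["flag_major_loss"], "resid"].tolist()

    @property
    def major_gains(self) -> list:
        t = self.table
        return t.loc[t["flag_major_gain"] | (t["category"] == NEW_CONTACT),
                     "resid"].tolist()


def contact_differential(
    table_a: ContactTable,
    table_b: ContactTable,
    major_threshold: float = 0.5,
) -> ContactDifferential:
    """Relative change in per-residue contact frequency from A to B.

    ``rel_change = (freq_b - freq_a) / freq_a``; losses at or beyond
    ``-major_threshold`` and gains at or beyond ``+major_threshold`` are
    flagged as major (the 50% criterion separating major from minor contact
    changes between conditions).
    """
    if set(table_a.counts) != set(table_b.counts):
        raise InputError("contact tables cover different residue lists")
    if not math.isclose(table_a.cutoff, table_b.cutoff):
        raise InputError("contact tables used different cutoffs")
    if major_threshold <= 0:
        raise InputError("major_threshold must be > 0")

    rows = []
    for rid in sorted(table_a.counts):
        fa = table_a.frequency(rid)
        fb = table_b.frequency(rid)
        if fa > 0:
            change = (fb - fa) / fa
            category = "changed" if not math.isclose(fb, fa) else "unchanged"
            loss = change <= -major_threshold
            gain = change >= major_threshold
        elif fb > 0:
            change = math.nan
            category = NEW_CONTACT
            loss = False
            gain = False
        else:
            change = 0.0
            category = "absent"
            loss = gain = False
        rows.append((rid, fa, fb, change, category, loss, gain))
    table = pd.DataFrame(rows, columns=[
        "resid", "freq_a", "freq_b", "rel_change", "category",
        "flag_major_loss", "flag_major_gain",
    ])
    return ContactDifferential(
        condition_a=table_a.condition, condition_b=table_b.condition,
        major_threshold=major_threshold, table=table,
    )
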