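"""End-to-end workflows tying the model, fitting and trajectory stages together.

Each workflow reads plain CSV/PDB/DCD inputs, runs the corresponding
analysis, and writes provenance-stamped CSV/JSON outputs into an output
directory.  All randomness (fit restarts, synthetic generation) flows from
a single integer seed so reruns are byte-reproducible apart from file
timestamps.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import config as _config
from .fitting import (
    ConvergenceError,
    FitResult,
    RateDataset,
    TitrationCurve,
    classify_effector_mode,
    fit_rate_data,
    fit_titration,
)
from .model import InputError, OccupancyModelParams, som_curve
from .synthetic import (
    generate_rate_dataset,
    generate_titration,
    generate_toy_trajectory,
    get_preset,
)
from .trajectory import (
    ClassificationThresholds,
    classifications_to_frame,
    contact_counts,
    contact_differential,
    distance_histogram,
    scan_trajectory,
)

logger = logging.getLogger("cypsom")

DEFAULT_FREE_BASELINE = ("kd_prod_s", "kd_allo_s", "f4oh_ss")
DEFAULT_FREE_EFFECTOR = ("kd_allo_x", "f4oh_sx")


def run_kinetics_workflow(
    rates_csv,
    out_dir,
    seed: int = 0,
    init: Optional[OccupancyModelParams] = None,
    free_baseline: Sequence[str] = DEFAULT_FREE_BASELINE,
    free_effector: Sequence[str] = DEFAULT_FREE_EFFECTOR,
    threshold_som: float = 0.2,
    threshold_rate: float = 0.2,
    cfg: Optional[dict] = None,
) -> dict:
    """Fit the occupancy model to a rate table and classify each effector level.

    The baseline model is fitted to the effector-free rows; effector
    parameters are then fitted on the effector rows with the baseline
    fixed.  Writes ``fit_report.json`` and ``som_curve.csv`` into
    ``out_dir`` and returns the report dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data = RateDataset.from_csv(rates_csv)
    if data.data.empty:
        raise InputError(f"rate table {rates_csv} is empty")
    init = init or OccupancyModelParams(kd_allo_x=10.0)

    base_rows = data.data[data.data["x_um"] == 0]
    if base_rows.empty:
        raise InputError("rate table has no effector-free (x_um = 0) rows")
    base_ds = RateDataset(data=base_rows.reset_index(drop=True),
                          effector=data.effector)
    fit_base = fit_rate_data(base_ds, init, free=free_baseline, seed=seed)
    if not fit_base.converged:
        raise ConvergenceError("baseline fit did not converge")
    logger.info("baseline fit: rss=%.3g params=%s", fit_base.rss,
                fit_base.params.to_dict())

    x_levels = sorted(data.data["x_um"].unique())
    verdicts: Dict[str, str] = {}
    fit_eff = None
    eff_rows = data.data[data.data["x_um"] > 0]
    if not eff_rows.empty:
        eff_ds = RateDataset(data=data.data.reset_index(drop=True),
                             effector=data.effector)
        fit_eff = fit_rate_data(eff_ds, fit_base.params, free=free_effector,
                                seed=seed + 1)
        for x in x_levels:
            if x == 0:
                continue
            level = data.data[data.data["x_um"] == x]
            level_ds = RateDataset(data=level.reset_index(drop=True),
                                   effector=data.effector)
            verdicts[f"{x:g}"] = classify_effector_mode(
                fit_base, level_ds, threshold_som, threshold_rate)

    curve_params = fit_eff.params if fit_eff is not None else fit_base.params
    s_grid = sorted(data.data["s_um"].unique())
    curve = som_curve(curve_params, s_grid, x_levels)
    _config.write_csv(curve, out_dir / "som_curve.csv", seed=seed, cfg=cfg)

    report = {
        "effector": data.effector,
        "baseline_fit": fit_base.to_report(),
        "effector_fit": None if fit_eff is None else fit_eff.to_report(),
        "verdicts": verdicts,
        "seed": seed,
    }
    _config.write_json(report, out_dir / "fit_report.json", seed=seed, cfg=cfg)
    return report


def run_titration_workflow(titration_csv, out_dir, seed: int = 0,
                           cfg: Optional[dict] = None) -> dict:
    """Fit a Langmuir isotherm to a spin-shift titration table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    curve = TitrationCurve.from_csv(titration_csv)
    fit = fit_titration(curve)
    report = {
        "ks_um": fit.ks, "bmax": fit.bmax,
        "ks_stderr": fit.ks_stderr, "bmax_stderr": fit.bmax_stderr,
        "rss": fit.rss,
    }
    _config.write_json(report, out_dir / "titration_fit.json", seed=seed, cfg=cfg)
    return report


def run_trajectory_workflow(
    conditions: List[dict],
    out_dir,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
    selections: Optional[dict] = None,
    residue_ids: Sequence[int] = (),
    stride: int = 1,
    seed: int = 0,
    cfg: Optional[dict] = None,
) -> dict:
    """Scan one or more trajectory conditions and compare the first two.

    ``conditions`` is a list of dicts with keys ``label, topology,
    trajectory``.  Per condition, writes ``frames_<label>.csv``,
    ``hist_c4_<label>.csv`` and (when ``residue_ids`` given)
    ``contacts_<label>.csv``; with two or more conditions, writes
    ``contact_differential.csv`` comparing the first two and a comparison
    summary.  Returns the summary dict.
    """
    if not conditions:
        raise InputError("at least one trajectory condition required")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    summaries = {}
    tables = {}
    for cond in conditions:
        label = cond["label"]
        classifications, summary = scan_trajectory(
            cond["topology"], cond["trajectory"], selections=selections,
            thresholds=thresholds, stride=stride)
        _config.write_csv(classifications_to_frame(classifications),
                          out_dir / f"frames_{label}.csv", seed=seed, cfg=cfg)
        for which in ("c1", "c4"):
            hist = distance_histogram(classifications, which=which,
                                      productive_only=(which == "c4"))
            _config.write_csv(hist, out_dir / f"hist_{which}_{label}.csv",
                              seed=seed, cfg=cfg)
        summaries[label] = {
            "n_total": summary.n_total,
            "n_productive": summary.n_productive,
            "productive_fraction": summary.productive_fraction,
            "n_selective": summary.n_selective,
            "n_nonselective": summary.n_nonselective,
            "selective_fraction": summary.selective_fraction,
            "nonselective_fraction": summary.nonselective_fraction,
        }
        if residue_ids:
            mask = [c.productive for c in classifications]
            table = contact_counts(
                cond["topology"], cond["trajectory"],
                residue_ids=residue_ids, productive_mask=mask,
                contact_cutoff=thresholds.contact_cutoff, stride=stride,
                condition=label)
            tables[label] = table
            _config.write_csv(table.to_frame(),
                              out_dir / f"contacts_{label}.csv",
                              seed=seed, cfg=cfg)

    report = {"conditions": summaries}
    if len(conditions) >= 2 and len(tables) >= 2:
        a, b = conditions[0]["label"], conditions[1]["label"]
        diff = contact_differential(tables[a], tables[b])
        _config.write_csv(diff.table, out_dir / "contact_differential.csv",
                          seed=seed, cfg=cfg)
        report["differential"] = {
            "condition_a": a, "condition_b": b,
            "major_losses": diff.major_losses,
            "major_gains": diff.major_gains,
        }
    elif len(conditions) < 2:
        logger.info("single condition: differential step skipped")
    _config.write_json(report, out_dir / "trajectory_summary.json",
                       seed=seed, cfg=cfg)
    return report


def make_synthetic(preset_name: str, out_dir, seed: int = 0,
                   cfg: Optional[dict] = None) -> dict:
    """Materialize a named scenario preset as files plus a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    preset = get_preset(preset_name, seed=seed)

    paths = {}
    dataset = generate_rate_dataset(preset.params, preset.design,
                                    effector=preset.name)
    rates_path = out_dir / f"rates_{preset.name}.csv"
    _config.write_csv(dataset.data, rates_path, seed=seed, cfg=cfg)
    paths["rates"] = str(rates_path)

    if preset.titration is not None:
        ks, bmax = preset.titration
        grid = np.round(np.geomspace(ks / 10, ks * 10, 10), 3)
        tc = generate_titration(ks, bmax, grid, noise_sd=0.0,
                                seed=preset.design.seed, ligand=preset.name)
        tit_path = out_dir / f"titration_{preset.name}.csv"
        _config.write_csv(tc.data, tit_path, seed=seed, cfg=cfg)
        paths["titration"] = str(tit_path)

    truth: dict = {"params": preset.params.to_dict()}
    if preset.trajectory_pair is not None:
        for spec in preset.trajectory_pair:
            top = out_dir / f"toy_{spec.condition}.pdb"
            trj = out_dir / f"toy_{spec.condition}.dcd"
            lab = out_dir / f"labels_{spec.condition}.csv"
            generate_toy_trajectory(spec, top, trj, lab)
            paths[f"trajectory_{spec.condition}"] = str(trj)
            paths[f"topology_{spec.condition}"] = str(top)
            paths[f"labels_{spec.condition}"] = str(lab)
        truth["trajectory_pair"] = [t.to_dict() for t in preset.trajectory_pair]
    if preset.titration is not None:
        truth["titration"] = {"ks": preset.titration[0],
                              "bmax": preset.titration[1]}

    manifest = {"preset": preset.name, "seed": seed, "paths": paths,
                "truth": truth}
    _config.write_json(manifest, out_dir / "manifest.json", seed=seed, cfg=cfg)
    return manifest
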