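"""Config parsing and provenance-stamped output helpers."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def dump_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: Optional[dict]) -> str:
    payload = json.dumps(cfg or {}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def provenance_lines(seed: Optional[int], cfg: Optional[dict] = None
                     ) -> Sequence[str]:
    from . import __version__
    return (
        f"cypsom {__version__}",
        f"config_sha256={config_hash(cfg)}",
        f"seed={'none' if seed is None else seed}",
    )


def write_csv(df: pd.DataFrame, path, seed: Optional[int] = None,
              cfg: Optional[dict] = None) -> None:
    """Write a CSV with a commented provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in provenance_lines(seed, cfg):
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def write_json(obj: dict, path, seed: Optional[int] = None,
               cfg: Optional[dict] = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"provenance": list(provenance_lines(seed, cfg)), **obj}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_jsonify)
        fh.write("\n")


def _jsonify(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
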