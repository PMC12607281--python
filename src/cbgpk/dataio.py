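"""Dataset dialect, configuration files, and run logging.

The on-disk dataset is a plain CSV in a NONMEM-like long format with the
exact header ``ID,OCC,TIME,DVID,DV,AMT,DUR,FORM,BW,BLQ`` (decimal point,
UTF-8).  Units are fixed at the dialect level: hours, nmol/L for
concentrations, nmol/kg for dose amounts; the mg <-> nmol bridge is applied
only at configuration boundaries.  Configuration (population parameters,
design, regimen, estimation settings) travels as YAML whose keys mirror the
reported parameter-table names.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .population_model import PopulationModel
from .synthetic_data import COLUMNS, PKDataset, StudyDesign

log = logging.getLogger("cbgpk")


def read_dataset(path) -> PKDataset:
    """Load and validate a dialect CSV; errors name the offending row."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    unknown = [c for c in df.columns if c not in COLUMNS]
    if unknown:
        raise ValueError(f"unknown column(s) {unknown} in {path.name}")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s) {missing} in {path.name}")
    neg = df.index[df["TIME"] < 0]
    if len(neg):
        raise ValueError(f"negative TIME at row {neg[0] + 2} of {path.name}")
    ds = PKDataset(df)
    if ds.n_quantifiable() == 0:
        raise ValueError("no quantifiable data (every observation is missing or BLOQ)")
    return ds


def write_dataset(ds: PKDataset, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ds.df.to_csv(path, index=False)
    return path


def write_truth(truth: dict, path) -> Path:
    """Sidecar with the generating parameters (never part of a fit input)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(truth), fh, sort_keys=False)
    return path


def write_population(pop: PopulationModel, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(pop.to_dict()), fh, sort_keys=False)
    return path


def read_population(path) -> PopulationModel:
    with open(path) as fh:
        return PopulationModel.from_dict(yaml.safe_load(fh))


def read_design(path) -> StudyDesign:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if "occasions" in d:
        d["occasions"] = tuple(tuple(o) for o in d["occasions"])
    if "sampling_times" in d:
        d["sampling_times"] = tuple(d["sampling_times"])
    return StudyDesign(**d)


def _plain(obj):
    """Recursively convert numpy scalars/arrays so YAML stays readable."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration, recorded with every artifact."""
    text = yaml.safe_dump(_plain(config), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def log_run(artifact: str, seed, config: dict):
    from . import __version__

    log.info(
        "%s: seed=%s version=%s config=%s", artifact, seed, __version__, config_hash(config)
    )
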