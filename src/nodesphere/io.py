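"""Readers and writers for the pipeline's plain-text formats.

Node tables and imaging calls travel as CSV, models as JSON, masks as
NIfTI, configuration as YAML. Writers can stamp a run id as a leading
``#`` comment line; readers skip comments, so round-trips are exact.

Node CSV dialect: ``patient_id, node_id, a_mm, b_mm, c_mm`` plus the
optional ``node_label, patient_label, nac`` columns (0/1). Axis rows are
canonicalized to a <= b <= c on read (a logged warning if any row needed
sorting); rows with non-numeric or non-positive axes are rejected with
their CSV line numbers logged.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterator, Optional, Union

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from nodesphere.classifiers import Model, model_from_json, model_to_json
from nodesphere.simulate import CohortConfig, ShapeClassParams
from nodesphere.types import MIN_DIAMETER_MM

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

AXIS_COLUMNS = ("a_mm", "b_mm", "c_mm")
NODE_COLUMNS = ("patient_id", "node_id", *AXIS_COLUMNS)
OPTIONAL_NODE_COLUMNS = ("node_label", "patient_label", "nac")
IMAGING_COLUMNS = ("patient_id", "method", "call")


def _write_csv(df: pd.DataFrame, path: PathLike, run_id: Optional[str]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if run_id:
            fh.write(f"# run_id={run_id}\n")
        df.to_csv(fh, index=False)


def read_nodes(path: PathLike) -> pd.DataFrame:
    """Read and validate a node axis table."""
    df = pd.read_csv(path, comment="#")
    missing = set(NODE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")

    axes = df[list(AXIS_COLUMNS)].apply(pd.to_numeric, errors="coerce")
    # CSV line numbers: +2 for the header row and 1-based counting
    # (comment stripping happens before parsing, so this is exact for
    # files without leading data comments beyond the run-id line)
    bad = axes.isna().any(axis=1) | (axes <= MIN_DIAMETER_MM / 2).any(axis=1)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()
        logger.error(
            "%s: rejected %d malformed rows (non-numeric or non-positive "
            "axes) at CSV lines %s", path, int(bad.sum()), lines,
        )
        df = df[~bad].copy()
        axes = axes[~bad]
    if df.empty:
        raise ValueError(f"{path}: no valid node rows")

    sorted_axes = np.sort(axes.to_numpy(dtype=float), axis=1)
    needed_sort = ~np.all(np.isclose(sorted_axes, axes.to_numpy(dtype=float)), axis=1)
    if needed_sort.any():
        logger.warning(
            "%s: %d rows had unsorted axis columns; canonicalized to a<=b<=c",
            path, int(needed_sort.sum()),
        )
    df = df.copy()
    df[list(AXIS_COLUMNS)] = sorted_axes
    for col in OPTIONAL_NODE_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    return df.reset_index(drop=True)


def write_nodes(df: pd.DataFrame, path: PathLike, run_id: Optional[str] = None) -> None:
    missing = set(NODE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"node table lacks columns {sorted(missing)}")
    _write_csv(df, path, run_id)


def read_imaging(path: PathLike) -> pd.DataFrame:
    """Read per-patient imaging calls (patient_id, method, call)."""
    df = pd.read_csv(path, comment="#")
    missing = set(IMAGING_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    calls = pd.to_numeric(df["call"], errors="coerce")
    bad = ~calls.isin([0, 1])
    if bad.any():
        lines = (df.index[bad] + 2).tolist()
        logger.error(
            "%s: rejected %d imaging rows with non-binary calls at CSV lines %s",
            path, int(bad.sum()), lines,
        )
        df = df[~bad].copy()
    df["call"] = df["call"].astype(int)
    return df.reset_index(drop=True)


def write_imaging(
    df: pd.DataFrame, path: PathLike, run_id: Optional[str] = None
) -> None:
    missing = set(IMAGING_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"imaging table lacks columns {sorted(missing)}")
    _write_csv(df, path, run_id)


def write_calls(df: pd.DataFrame, path: PathLike, run_id: Optional[str] = None) -> None:
    _write_csv(df, path, run_id)


def read_calls(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# -- masks ------------------------------------------------------------------

def write_mask(
    mask: np.ndarray, voxel_mm: np.ndarray, path: PathLike
) -> None:
    """Write a binary mask as NIfTI with the spacing in the header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag([*np.asarray(voxel_mm, dtype=float), 1.0])
    img = nib.Nifti1Image(mask.astype(np.uint8), affine)
    nib.save(img, str(path))


def read_mask(path: PathLike) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI mask; returns (binary array, spacing in mm)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj) > 0
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return data, spacing


def iter_masks(directory: PathLike) -> Iterator[tuple[str, np.ndarray, np.ndarray]]:
    """Yield (node id from filename, mask, spacing) for each NIfTI in a dir."""
    directory = Path(directory)
    paths = sorted(
        p for p in directory.iterdir()
        if p.name.endswith((".nii", ".nii.gz"))
    )
    if not paths:
        raise FileNotFoundError(f"no NIfTI masks found under {directory}")
    for p in paths:
        name = p.name
        for suffix in (".nii.gz", ".nii"):
            if name.endswith(suffix):
                name = name[: -len(suffix)]
        mask, spacing = read_mask(p)
        yield name, mask, spacing


# -- models -----------------------------------------------------------------

def save_model(model: Model, path: PathLike) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(model_to_json(model))


def load_model(path: PathLike) -> Model:
    return model_from_json(Path(path).read_text())


# -- configuration ----------------------------------------------------------

def cohort_config_from_dict(d: dict) -> CohortConfig:
    """Build a CohortConfig from a parsed YAML mapping."""
    d = dict(d)
    if "class_params" in d:
        d["class_params"] = {
            key: ShapeClassParams(**params)
            for key, params in d["class_params"].items()
        }
    if "imaging_specs" in d:
        d["imaging_specs"] = {
            m: (float(v[0]), float(v[1])) for m, v in d["imaging_specs"].items()
        }
    if "nodes_per_patient" in d:
        lo, hi = d["nodes_per_patient"]
        d["nodes_per_patient"] = (int(lo), int(hi))
    config = CohortConfig(**d)
    config.validate()
    return config


def load_yaml(path: PathLike) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a YAML mapping at top level")
    return data
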