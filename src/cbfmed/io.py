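"""Reading and writing study inputs/outputs.

Volumes are NIfTI-1 (via nibabel), frame labels a one-label-per-line text
sidecar, cohort tables CSV, configs YAML, reports JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .config import AcquisitionConfig
from .synthetic import ASLSeries

__all__ = [
    "write_series",
    "read_series",
    "write_cbf_map",
    "read_map",
    "write_cohort",
    "read_cohort",
    "REQUIRED_COHORT_COLUMNS",
]

REQUIRED_COHORT_COLUMNS = (
    "id", "age", "gender_code", "bmi", "resting_heart_rate",
    "activity_score", "systolic_bp", "diastolic_bp",
)


def _nifti(data: np.ndarray) -> nib.Nifti1Image:
    return nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine=np.eye(4))


def write_series(series: ASLSeries, directory, prefix: str = "asl") -> dict[str, Path]:
    """Write a series as NIfTI + label sidecar + mask volumes + acquisition YAML."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["data"] = directory / f"{prefix}.nii.gz"
    nib.save(_nifti(series.data), paths["data"])
    paths["labels"] = directory / f"{prefix}_labels.txt"
    paths["labels"].write_text("\n".join(series.frame_labels) + "\n")
    for name, mask in series.masks.items():
        p = directory / f"{prefix}_mask_{name}.nii.gz"
        nib.save(_nifti(mask.astype(np.uint8)), p)
        paths[f"mask_{name}"] = p
    paths["acquisition"] = directory / f"{prefix}_acq.yaml"
    with open(paths["acquisition"], "w") as fh:
        yaml.safe_dump(asdict(series.acquisition), fh, sort_keys=False)
    return paths


def read_series(directory, prefix: str = "asl") -> ASLSeries:
    """Inverse of :func:`write_series`."""
    directory = Path(directory)
    data_path = directory / f"{prefix}.nii.gz"
    if not data_path.exists():
        raise FileNotFoundError(f"missing ASL volume {data_path}")
    img = nib.load(data_path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{data_path}: expected a 4-D series, got shape {data.shape}")

    labels_path = directory / f"{prefix}_labels.txt"
    if not labels_path.exists():
        raise FileNotFoundError(f"missing label sidecar {labels_path}")
    labels = [ln.strip() for ln in labels_path.read_text().splitlines() if ln.strip()]
    if len(labels) != data.shape[3]:
        raise ValueError(
            f"{labels_path}: {len(labels)} labels for {data.shape[3]} frames")

    acq_path = directory / f"{prefix}_acq.yaml"
    if acq_path.exists():
        with open(acq_path) as fh:
            raw = yaml.safe_load(fh)
        for k, v in raw.items():
            if isinstance(v, list):
                raw[k] = tuple(v)
        acq = AcquisitionConfig(**raw)
    else:
        acq = AcquisitionConfig()

    masks = {}
    for p in sorted(directory.glob(f"{prefix}_mask_*.nii.gz")):
        name = p.name[len(f"{prefix}_mask_"):-len(".nii.gz")]
        masks[name] = np.asarray(nib.load(p).dataobj) > 0
    return ASLSeries(data=data, frame_labels=labels, acquisition=acq, masks=masks)


def write_cbf_map(cbf_map: np.ndarray, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(_nifti(cbf_map), path)
    return path


def read_map(path) -> np.ndarray:
    return np.asarray(nib.load(path).dataobj, dtype=float)


def write_cohort(cohort: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(path, index=False)
    return path


def read_cohort(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing cohort table {path}")
    cohort = pd.read_csv(path)
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table {path} missing required columns: {missing}")
    return cohort


def write_report(report: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
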