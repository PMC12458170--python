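"""File formats and ROI extraction.

DWI volumes are NIfTI-1 (via nibabel); gradient tables use the FSL dialect
(one whitespace-separated row of b-values; three rows of x/y/z direction
components).  Metric maps are written as one float32 NIfTI per metric with
NaN marking invalid voxels.  ROI label images are integer NIfTI volumes
(FreeSurfer-style segmentations); hemisphere label pairs are merged by
voxel-count-weighted averaging where the ROI specification says so.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .rsi_core import AcquisitionScheme

__all__ = [
    "read_bvals_bvecs",
    "write_bvals_bvecs",
    "read_dwi",
    "write_dwi",
    "write_metric_maps",
    "read_label_volume",
    "extract_roi_means",
    "RunConfig",
    "write_manifest",
]


def read_bvals_bvecs(bval_path, bvec_path) -> tuple[np.ndarray, np.ndarray]:
    """Read FSL-dialect bval/bvec text files -> (bvals (n,), bvecs (n, 3))."""
    bvals = np.loadtxt(bval_path, ndmin=2).ravel()
    bvecs = np.loadtxt(bvec_path, ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape[1] != 3:
        raise ValueError(f"bvec file must have 3 rows or 3 columns, got {bvecs.shape}")
    if len(bvals) != len(bvecs):
        raise ValueError(
            f"bval count ({len(bvals)}) != bvec count ({len(bvecs)})"
        )
    return bvals, bvecs


def write_bvals_bvecs(bval_path, bvec_path, scheme: AcquisitionScheme) -> None:
    # %.17g keeps the text round-trip bit-exact for doubles
    np.savetxt(bval_path, scheme.bvals[None, :], fmt="%.17g")
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.17g")


def read_dwi(
    nifti_path, bval_path, bvec_path, renorm_tol: float = 1e-3
) -> tuple[np.ndarray, AcquisitionScheme]:
    """Load a 4D DWI NIfTI with its gradient table.

    Direction norms within ``renorm_tol`` of 1 are silently renormalised;
    larger deviations (including zero vectors at b > 0) are format errors.
    Volume count and gradient-table length must agree.
    """
    img = nib.load(str(nifti_path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"expected 4D DWI, got {data.ndim}D")
    bvals, bvecs = read_bvals_bvecs(bval_path, bvec_path)
    if data.shape[3] != len(bvals):
        raise ValueError(
            f"NIfTI has {data.shape[3]} volumes but gradient table has "
            f"{len(bvals)} entries"
        )
    norms = np.linalg.norm(bvecs, axis=1)
    dwi_rows = bvals > 0
    off = np.abs(norms - 1.0)
    if np.any(dwi_rows & (off > renorm_tol)):
        bad = int(np.sum(dwi_rows & (off > renorm_tol)))
        raise ValueError(
            f"{bad} gradient direction(s) with b > 0 deviate from unit norm "
            f"beyond tolerance {renorm_tol}"
        )
    fix = dwi_rows & (off > 1e-12)
    bvecs = bvecs.copy()
    bvecs[fix] = bvecs[fix] / norms[fix, None]
    return data, AcquisitionScheme(bvals=bvals, bvecs=bvecs)


def write_dwi(nifti_path, bval_path, bvec_path, data, scheme, affine=None) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(nifti_path))
    write_bvals_bvecs(bval_path, bvec_path, scheme)


def write_metric_maps(out_dir, maps: dict[str, np.ndarray], affine=None) -> dict[str, Path]:
    """One float32 NIfTI per metric; returns the written paths."""
    affine = np.eye(4) if affine is None else affine
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, vol in maps.items():
        p = out_dir / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine), str(p))
        paths[name] = p
    return paths


def read_label_volume(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj).astype(np.int32)


def extract_roi_means(
    metric_map: np.ndarray,
    label_map: np.ndarray,
    label_spec: dict[str, list[int]],
) -> pd.Series:
    """Mean metric per ROI from an integer label volume.

    ``label_spec`` maps ROI name -> list of integer labels; multi-label ROIs
    (e.g. left+right hemisphere pairs of a subcortical structure) are merged
    by pooling their voxels, i.e. a voxel-count-weighted average.  Only
    finite voxels contribute; an ROI with no voxels yields NaN and a warning.
    """
    metric_map = np.asarray(metric_map, dtype=float)
    label_map = np.asarray(label_map)
    if metric_map.shape != label_map.shape:
        raise ValueError(
            f"metric map shape {metric_map.shape} != label map shape {label_map.shape}"
        )
    out = {}
    for roi, labels in label_spec.items():
        sel = np.isin(label_map, labels) & np.isfinite(metric_map)
        if not sel.any():
            warnings.warn(f"ROI {roi!r}: no finite voxels for labels {labels}")
            out[roi] = np.nan
        else:
            out[roi] = float(metric_map[sel].mean())
    return pd.Series(out, name="roi_mean")


@dataclasses.dataclass
class RunConfig:
    """Resolved run options; round-trips losslessly through YAML."""

    seed: int = 0
    norm_mode: str = "sum"
    ridge_lambda: float = 1e-6
    m_imputations: int = 20
    n_chains: int = 2
    n_iter: int = 50
    alpha: float = 0.05
    motion_threshold_mm: float = 1.7
    obesity_cutoff_percentile: float = 85.0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def write_manifest(path, config: RunConfig, extra: dict | None = None) -> None:
    """JSON manifest recording the resolved config and seed for reproduction."""
    import rsipipe

    payload = {
        "config": dataclasses.asdict(config),
        "package_version": rsipipe.__version__,
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
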