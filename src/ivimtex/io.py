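"""NIfTI / table I/O for the pipeline.

Conventions: NIfTI-1 (optionally gzipped), 4D volumes ordered (x, y, z,
b); the input affine is carried through to every derived map; voxel
indices are 0-based and nothing is resampled in world space. CSV files
have a header row, UTF-8, '.' decimal; JSON reports are pretty-printed
with sorted keys for diffability.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .fitting import FitResult, ParamMaps
from .models import BValueScheme

logger = logging.getLogger(__name__)

__all__ = [
    "read_dwi",
    "read_mask",
    "write_param_maps",
    "write_fit_report",
    "read_manifest",
]

MAP_SUFFIXES = {"adc": "_ADC", "d": "_D", "dstar": "_Dstar",
                "f": "_f", "k": "_k", "adj_r2": "_adjR2"}


def read_dwi(path: str | Path, bvals_path: str | Path):
    """Load a 4D DWI volume and its b-value table.

    Returns (volume4d float array, BValueScheme, affine).
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D volume (x,y,z,b), got ndim={data.ndim}")
    scheme = BValueScheme.from_file(bvals_path)
    if data.shape[3] != len(scheme):
        raise ValueError(
            f"volume has {data.shape[3]} b-frames but the table lists "
            f"{len(scheme)} b-values"
        )
    return data, scheme, img.affine


def read_mask(path: str | Path, reference_shape, reference_affine=None,
              atol: float = 1e-4) -> np.ndarray:
    """Load a binary 3D ROI mask and check geometry against the reference."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"mask must be 3D, got ndim={data.ndim}")
    if tuple(data.shape) != tuple(reference_shape):
        raise ValueError(
            f"mask shape {data.shape} != reference {tuple(reference_shape)}"
        )
    if reference_affine is not None and not np.allclose(
        img.affine, reference_affine, atol=atol
    ):
        raise ValueError("mask affine differs from the reference affine")
    uniq = np.unique(data)
    if not set(uniq.tolist()) <= {0, 1}:
        logger.warning("mask values %s coerced to binary (nonzero -> 1)",
                       uniq[:5])
    mask = data != 0
    if mask.sum() == 0:
        logger.warning("mask %s selects no voxels", path)
    return mask


def write_param_maps(maps: ParamMaps, affine: np.ndarray, out_dir: str | Path,
                     stem: str = "maps") -> dict[str, Path]:
    """Write one 3D NIfTI per parametric map, preserving the affine."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for attr, suffix in MAP_SUFFIXES.items():
        arr = getattr(maps, attr).astype(np.float32)
        p = out_dir / f"{stem}{suffix}.nii.gz"
        nib.save(nib.Nifti1Image(arr, affine), str(p))
        written[attr] = p
    return written


def write_fit_report(result: FitResult, path: str | Path) -> None:
    report = {
        "mean_adjusted_r2": None if np.isnan(result.mean_adj_r2)
        else float(result.mean_adj_r2),
        "outer_iterations_run": int(result.outer_iterations_run),
        "n_voxels_fitted": int(result.maps.mask.sum()),
        "n_voxels_converged": int(result.converged.sum()),
    }
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_manifest(path: str | Path, base_dir: str | Path | None = None
                  ) -> pd.DataFrame:
    """Load a case manifest CSV and verify the referenced files exist."""
    df = pd.read_csv(path)
    if "case_id" not in df.columns or "label" not in df.columns:
        raise ValueError("manifest needs 'case_id' and 'label' columns")
    bad = set(df["label"]) - {"PDAC", "pNET", "MFCP", "SPEN"}
    if bad:
        raise ValueError(f"unknown class labels in manifest: {sorted(bad)}")
    base = Path(base_dir) if base_dir else Path(path).parent
    for col in df.columns:
        if col.endswith("_path"):
            for rel in df[col]:
                if not (base / rel).exists():
                    raise FileNotFoundError(base / rel)
    return df
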