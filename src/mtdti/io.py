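"""Volume, gradient-table and table I/O with provenance sidecars.

NIfTI-1 for all volumes (plain or gzipped), FSL-style text bval/bvec for
diffusion gradients, TSV/JSON for the evolution tables.  Every artifact
written by a pipeline stage gets a ``.json`` sidecar recording the
stage, seed, config hash and package version, so any map on disk can be
traced to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Tuple

import nibabel as nib
import numpy as np

__all__ = [
    "read_volume",
    "write_volume",
    "read_bvals_bvecs",
    "write_bvals_bvecs",
    "write_sidecar",
    "config_hash",
    "check_same_grid",
]


def read_volume(path) -> Tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns (data, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def write_volume(data: np.ndarray, affine: np.ndarray, path,
                 sidecar: Optional[dict] = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(data), np.asarray(affine)), str(path))
    if sidecar is not None:
        write_sidecar(path, sidecar)


def write_sidecar(artifact_path, meta: dict) -> None:
    p = Path(str(artifact_path))
    side = p.with_suffix("").with_suffix("") if p.name.endswith(".nii.gz") else p.with_suffix("")
    side = side.parent / (side.name + ".json")
    with open(side, "w") as fh:
        json.dump(meta, fh, indent=1, default=str)


def config_hash(config) -> str:
    """Stable short hash of a pipeline config (for provenance sidecars)."""
    blob = json.dumps(config.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def check_same_grid(*named_volumes) -> None:
    """Raise with both shapes named on any mismatch among (name, array) pairs."""
    ref_name, ref = named_volumes[0]
    for name, vol in named_volumes[1:]:
        if np.asarray(vol).shape != np.asarray(ref).shape:
            raise ValueError(
                f"grid mismatch: {name} has shape {np.asarray(vol).shape} "
                f"but {ref_name} has shape {np.asarray(ref).shape}"
            )


def write_bvals_bvecs(bvals, bvecs, bval_path, bvec_path) -> None:
    """FSL text dialect: bvals on one row; bvecs as three rows (x, y, z)."""
    bvals = np.asarray(bvals, dtype=float)
    bvecs = np.asarray(bvecs, dtype=float)
    np.savetxt(bval_path, bvals[None, :], fmt="%.1f")
    np.savetxt(bvec_path, bvecs.T, fmt="%.8f")


def read_bvals_bvecs(bval_path, bvec_path) -> Tuple[np.ndarray, np.ndarray]:
    bvals = np.loadtxt(bval_path).reshape(-1)
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    if bvecs.shape != (bvals.size, 3):
        raise ValueError(
            f"bvec table {bvecs.shape} inconsistent with {bvals.size} b-values"
        )
    return bvals, bvecs
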