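"""NIfTI-1 volume I/O and provenance helpers."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["read_volume", "write_volume", "write_complex", "read_complex",
           "write_provenance"]


def write_volume(volume: np.ndarray, path, voxel_size_mm=(1.5, 1.5, 3.0),
                 affine: np.ndarray | None = None) -> Path:
    """Write a volume as NIfTI-1 (float32), voxel size encoded in the affine."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"target directory does not exist: {path.parent}")
    if affine is None:
        affine = np.diag([*voxel_size_mm, 1.0])
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine)
    nib.save(img, str(path))
    return path


def read_volume(path):
    """Read a NIfTI-1 volume; returns (data float32, affine, voxel size mm).

    Raises FileNotFoundError for missing paths and a format error naming the
    offending field for malformed headers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float32)
    except Exception as exc:  # nibabel raises various header errors
        raise ValueError(f"malformed NIfTI file {path}: {exc}") from exc
    voxel = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, img.affine, voxel


def write_complex(volume: np.ndarray, prefix, voxel_size_mm=(1.5, 1.5, 3.0)):
    """Write a complex series as paired magnitude/phase NIfTI files."""
    prefix = Path(prefix)
    write_volume(np.abs(volume), prefix.with_name(prefix.name + "_mag.nii.gz"),
                 voxel_size_mm)
    write_volume(np.angle(volume), prefix.with_name(prefix.name + "_phase.nii.gz"),
                 voxel_size_mm)


def read_complex(prefix):
    prefix = Path(prefix)
    mag, affine, voxel = read_volume(prefix.with_name(prefix.name + "_mag.nii.gz"))
    phase, _, _ = read_volume(prefix.with_name(prefix.name + "_phase.nii.gz"))
    return mag * np.exp(1j * phase.astype(np.float64)), affine, voxel


def write_provenance(out_dir, config: dict) -> Path:
    """Write the resolved configuration and library versions next to outputs."""
    import nibabel
    import numpy
    import pandas
    import scipy

    out_dir = Path(out_dir)
    payload = {
        "config": config,
        "versions": {
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "nibabel": nibabel.__version__,
        },
    }
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
    return path
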