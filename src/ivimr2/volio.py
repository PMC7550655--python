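"""NIfTI volume I/O.

Thin wrappers over nibabel enforcing the package's conventions: volume
axes are (x, y, z[, measurement]), the 4th dimension must match the
protocol length when one is given, masks share the spatial grid exactly,
and NaN is the missing-value sentinel in parameter maps.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .acquisition import ValidationError

__all__ = ["read_volume", "write_volume"]


def read_volume(path: str | Path, expected_length: int | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI volume; returns (data, affine).

    ``expected_length`` checks the 4th dimension against a protocol.
    Plain and gzipped files both load.
    """
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if expected_length is not None:
        if data.ndim != 4 or data.shape[3] != expected_length:
            raise ValidationError(
                f"volume: 4th dimension {data.shape[3] if data.ndim == 4 else None} "
                f"does not match protocol length {expected_length}")
    return data, np.asarray(img.affine)


def write_volume(data: np.ndarray, path: str | Path,
                 affine: np.ndarray | None = None) -> None:
    """Write an array as NIfTI-1 (identity affine by default)."""
    if affine is None:
        affine = np.eye(4)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    nib.save(img, str(path))
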