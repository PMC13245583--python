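"""Unit dipole kernel and forward field convolution used by QSM routines.

The magnetic field perturbation (in ppm) produced by a susceptibility
distribution chi (ppm) is, in k-space, D(k) * FFT(chi) with the unit dipole
kernel D(k) = 1/3 - kz^2/|k|^2 (k = 0 term set to 0, i.e. the mean field
offset is not attributed to chi).
"""

from __future__ import annotations

import numpy as np

__all__ = ["dipole_kernel", "forward_field"]


def dipole_kernel(shape: tuple[int, ...], voxel_size_mm=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Unit dipole kernel on the FFT grid for a volume of ``shape``.

    B0 is along the third (z) axis. Anisotropic voxel sizes enter through the
    physical spatial frequencies.
    """
    if len(shape) != 3:
        raise ValueError("dipole kernel requires a 3D shape")
    kx = np.fft.fftfreq(shape[0], d=voxel_size_mm[0])
    ky = np.fft.fftfreq(shape[1], d=voxel_size_mm[1])
    kz = np.fft.fftfreq(shape[2], d=voxel_size_mm[2])
    kx, ky, kz = np.meshgrid(kx, ky, kz, indexing="ij")
    k2 = kx ** 2 + ky ** 2 + kz ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 / 3.0 - kz ** 2 / k2
    d[0, 0, 0] = 0.0
    return d


def forward_field(chi_ppm: np.ndarray, voxel_size_mm=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Field perturbation (ppm) from a susceptibility volume (ppm)."""
    d = dipole_kernel(chi_ppm.shape, voxel_size_mm)
    return np.real(np.fft.ifftn(d * np.fft.fftn(chi_ppm)))
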