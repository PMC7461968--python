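"""Fourier-domain unit dipole kernel and the shared k-space grid.

The magnetic field perturbation induced by a susceptibility distribution
chi (in ppm) is, to first order, a convolution with the field of a unit
dipole.  In the Fourier domain the convolution is a pointwise product with

    D(k) = 1/3 - kz^2 / |k|^2

where kz is the frequency component along the main-field (B0) axis.
D vanishes on the magic-angle cone kz^2 = |k|^2 / 3, which is what makes
the field-to-susceptibility inverse problem ill posed.  Every forward
simulation and every inversion algorithm in this package shares the kernel
built here, so the forward and inverse operators are exactly consistent.

The kernel uses the continuous-k expression evaluated on the discrete
frequency grid of the volume.  D(0) is set to 0: the dipole convolution
carries no information about the spatial mean of chi, so reconstructed
maps are defined only up to a constant and are referenced to zero mean
over the mask downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["KSpaceGrid", "DipoleKernel", "make_dipole_kernel", "kernel_cone_mask"]


@dataclass(frozen=True)
class KSpaceGrid:
    """Discrete Fourier frequency grid of a 3-D volume.

    Frequencies are in cycles/mm (``numpy.fft.fftfreq`` convention: DC at
    index 0, positive frequencies first, Nyquist in the middle for even
    sizes).  Anisotropic voxels are honored, so non-cubic acquisition
    matrices produce physically correct frequency coordinates.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 2 for n in self.shape):
            raise ValueError(f"grid shape must be 3-D with sides >= 2, got {self.shape}")
        if len(self.voxel_size) != 3 or any(h <= 0 for h in self.voxel_size):
            raise ValueError(f"voxel size must be 3 positive reals, got {self.voxel_size}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(h) for h in self.voxel_size))

    def axis_frequencies(self) -> list[np.ndarray]:
        """Per-axis frequency coordinates (cycles/mm), DC at index 0."""
        return [np.fft.fftfreq(n, d=h) for n, h in zip(self.shape, self.voxel_size)]

    def k_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable 3-D frequency coordinate arrays."""
        fx, fy, fz = self.axis_frequencies()
        return (
            fx[:, None, None],
            fy[None, :, None],
            fz[None, None, :],
        )

    def k_squared(self) -> np.ndarray:
        kx, ky, kz = self.k_coords()
        return kx**2 + ky**2 + kz**2


@dataclass(frozen=True)
class DipoleKernel:
    """Unit dipole field response D(k) on a :class:`KSpaceGrid`.

    ``values`` lies in [-2/3, 1/3]; ``dc_value`` records the D(0)
    convention (0 here).  ``b0_axis`` is the array axis along B0.
    """

    grid: KSpaceGrid
    values: np.ndarray = field(repr=False)
    b0_axis: int = 2
    dc_value: float = 0.0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape


def make_dipole_kernel(grid: KSpaceGrid, b0_axis: int = 2) -> DipoleKernel:
    """Build D(k) = 1/3 - kz^2/|k|^2 on ``grid``, with D(0) = 0.

    Parameters
    ----------
    grid
        Frequency grid of the target volume.
    b0_axis
        Array axis aligned with the main field (default: last axis).
    """
    if b0_axis not in (0, 1, 2):
        raise ValueError(f"b0_axis must be 0, 1 or 2, got {b0_axis}")
    coords = grid.k_coords()
    kz = coords[b0_axis]
    k2 = grid.k_squared()
    with np.errstate(divide="ignore", invalid="ignore"):
        values = 1.0 / 3.0 - (kz**2) / k2
    values = np.where(k2 > 0, values, 0.0)
    # enforce the analytic range against one-ULP rounding excursions
    values = np.clip(values, -2.0 / 3.0, 1.0 / 3.0)
    return DipoleKernel(grid=grid, values=values, b0_axis=b0_axis, dc_value=0.0)


def kernel_cone_mask(kernel: DipoleKernel, delta: float) -> np.ndarray:
    """Binary mask of ill-conditioned k-space voxels, |D(k)| <= delta.

    The marked region contains the magic-angle cone (including DC) and
    grows monotonically with ``delta``; at delta = 2/3 it covers all of
    k-space since D is bounded by [-2/3, 1/3].
    """
    if delta < 0:
        raise ValueError(f"threshold must be >= 0, got {delta}")
    return np.abs(kernel.values) <= delta
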