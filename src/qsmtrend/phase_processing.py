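"""Local-field recovery from wrapped phase.

Two stages stand between a wrapped GRE phase image and the tissue field
that dipole inversion needs:

1. *Laplacian unwrapping.*  The unwrapped phase is estimated as
   inv_Laplacian(cos(theta) * Laplacian(sin(theta))
                 - sin(theta) * Laplacian(cos(theta))),
   which is insensitive to the 2*pi jumps of the wrapped input and
   recovers the true phase up to an additive harmonic component (that
   component is removed by the next stage anyway, since background
   fields are harmonic inside the brain).  Both Laplacians are Fourier
   multipliers -(2*pi*|k|)^2; before transforming, the volume is
   extended by even (mirror) symmetry so that non-periodic phase
   topographies — a linear ramp in particular — are representable.

2. *V-SHARP background removal.*  A field generated by sources outside
   the mask is harmonic inside it and therefore equals its spherical
   mean over any sphere contained in the mask.  Filtering with
   (delta - SMV) kernels annihilates such fields; V-SHARP uses, at each
   voxel, the largest sphere radius that still fits inside the mask, so
   the usable region extends closer to the brain surface than with a
   single large kernel.  The surviving local field is deconvolved by
   the largest-radius kernel with truncated inversion, and is only
   trusted (and nonzero) inside the mask eroded by that largest radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import AcquisitionParams, WrappedPhaseVolume

__all__ = [
    "UnwrapResult",
    "VSharpConfig",
    "TissueField",
    "laplacian_unwrap",
    "vsharp",
    "phase_to_ppm",
]


@dataclass
class UnwrapResult:
    """Unwrapped phase in radians, zero mean, with provenance tag."""

    unwrapped_phase: np.ndarray
    voxel_size: tuple[float, float, float]
    acq: AcquisitionParams | None = None
    method_tag: str = "laplacian-fourier"


@dataclass(frozen=True)
class VSharpConfig:
    """Radius schedule and truncation threshold for V-SHARP.

    ``radii`` are sphere radii in mm, strictly decreasing, largest
    first; the default walks from 4 mm down to 1 mm in unit steps.
    ``tsvd_threshold`` truncates the deconvolution of the
    largest-radius kernel where its spectrum magnitude falls below the
    threshold.
    """

    radii: tuple[float, ...] = (4.0, 3.0, 2.0, 1.0)
    tsvd_threshold: float = 0.05

    def __post_init__(self) -> None:
        r = self.radii
        if len(r) == 0 or any(b >= a for a, b in zip(r, r[1:])):
            raise ValueError(f"radii must be non-empty and strictly decreasing, got {r}")
        if r[-1] <= 0:
            raise ValueError("smallest radius must be positive")
        if not (0.0 < self.tsvd_threshold < 1.0):
            raise ValueError("tsvd_threshold must lie in (0, 1)")


@dataclass
class TissueField:
    """Local tissue field (radians or ppm) supported on the eroded mask."""

    data: np.ndarray
    mask: np.ndarray  # eroded mask; data is zero outside
    voxel_size: tuple[float, float, float]
    units: str = "rad"
    acq: AcquisitionParams | None = None


def _laplacian_multiplier(shape, voxel_size) -> np.ndarray:
    k2 = sum(
        np.fft.fftfreq(n, d=h)[_axis_slice(i)] ** 2
        for i, (n, h) in enumerate(zip(shape, voxel_size))
    )
    return -((2.0 * np.pi) ** 2) * k2


def _axis_slice(axis: int):
    idx = [None, None, None]
    idx[axis] = slice(None)
    return tuple(idx)


def _fourier_laplacian(vol: np.ndarray, mult: np.ndarray) -> np.ndarray:
    return np.real(np.fft.ifftn(mult * np.fft.fftn(vol)))


def _fourier_inv_laplacian(vol: np.ndarray, mult: np.ndarray) -> np.ndarray:
    spec = np.fft.fftn(vol)
    with np.errstate(divide="ignore", invalid="ignore"):
        spec = np.where(mult != 0, spec / mult, 0.0)
    return np.real(np.fft.ifftn(spec))


def laplacian_unwrap(
    wrapped: WrappedPhaseVolume,
    mirror_pad: bool = True,
    integer_correction: bool = True,
) -> UnwrapResult:
    """Unwrap phase via the Laplacian identity; output has zero mean.

    ``mirror_pad`` extends the volume by even symmetry before the FFTs.
    This matters for phase patterns that are not periodic on the box
    (e.g. linear ramps, whose mirror extension is a triangle wave);
    for fields produced by the package's own periodic forward model it
    is a no-op in effect but is kept on for uniformity.

    ``integer_correction`` snaps the continuous Laplacian estimate back
    onto the measured phase modulo 2*pi (adding the nearest multiple of
    2*pi of the estimate-measurement difference to the measurement).
    Wherever the Laplacian estimate is within pi of the true phase this
    makes the unwrap exact instead of merely approximate; the estimate
    alone smooths sharp phase transitions at structure boundaries.
    """
    theta = np.asarray(wrapped.phase, dtype=np.float64)
    pad = tuple((0, n) for n in theta.shape) if mirror_pad else None
    work = np.pad(theta, pad, mode="symmetric") if mirror_pad else theta
    mult = _laplacian_multiplier(work.shape, wrapped.voxel_size)
    s, c = np.sin(work), np.cos(work)
    src = c * _fourier_laplacian(s, mult) - s * _fourier_laplacian(c, mult)
    unwrapped = _fourier_inv_laplacian(src, mult)
    if mirror_pad:
        unwrapped = unwrapped[tuple(slice(0, n) for n in theta.shape)]
    if integer_correction:
        offset = unwrapped - theta
        # center the offset by its circular mean so the rounding below
        # never sits on a half-cycle boundary (the estimate is defined
        # only up to an additive constant anyway)
        center = float(np.angle(np.mean(np.exp(1j * offset))))
        unwrapped = theta + center + 2.0 * np.pi * np.round(
            (offset - center) / (2.0 * np.pi)
        )
    unwrapped = unwrapped - unwrapped.mean()
    return UnwrapResult(
        unwrapped_phase=unwrapped,
        voxel_size=wrapped.voxel_size,
        acq=wrapped.acq,
        method_tag="laplacian-fourier" + ("-snap" if integer_correction else ""),
    )


def _ball_element(radius_mm: float, voxel_size) -> np.ndarray:
    """Odd-sized binary ball of physical radius ``radius_mm``."""
    half = [int(np.floor(radius_mm / h)) for h in voxel_size]
    coords = [np.arange(-m, m + 1) * h for m, h in zip(half, voxel_size)]
    d2 = (
        coords[0][:, None, None] ** 2
        + coords[1][None, :, None] ** 2
        + coords[2][None, None, :] ** 2
    )
    return d2 <= radius_mm**2 + 1e-9


def _smv_spectrum(element: np.ndarray, shape) -> np.ndarray:
    """Fourier spectrum of the normalized spherical-mean kernel on ``shape``."""
    if any(e > n for e, n in zip(element.shape, shape)):
        raise ValueError("SMV sphere does not fit inside the volume")
    kern = np.zeros(shape, dtype=np.float64)
    start = [n // 2 - e // 2 for n, e in zip(shape, element.shape)]
    sl = tuple(slice(s, s + e) for s, e in zip(start, element.shape))
    kern[sl] = element / element.sum()
    return np.fft.fftn(np.fft.ifftshift(kern))


def vsharp(unwrapped: UnwrapResult | np.ndarray, mask: np.ndarray, cfg: VSharpConfig | None = None) -> TissueField:
    """Remove the background (harmonic) field with variable-radius SMV filtering.

    At each voxel the (identity - spherical mean) filter with the
    largest radius whose sphere fits inside ``mask`` is applied; the
    result is deconvolved by the largest-radius filter using truncated
    inversion at ``cfg.tsvd_threshold`` and zeroed outside the mask
    eroded by the largest radius.

    Adding a constant to the input does not change the output
    (constants are harmonic and SMV-filtering removes them exactly).
    """
    cfg = cfg or VSharpConfig()
    if isinstance(unwrapped, UnwrapResult):
        phase = unwrapped.unwrapped_phase
        voxel_size = unwrapped.voxel_size
        acq = unwrapped.acq
    else:
        phase = np.asarray(unwrapped, dtype=np.float64)
        voxel_size = (1.0, 1.0, 1.0)
        acq = None
    mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    shape = phase.shape

    elements = [_ball_element(r, voxel_size) for r in cfg.radii]
    if not ndimage.binary_erosion(mask, structure=elements[-1]).any():
        raise ValueError("mask too small for the smallest V-SHARP radius")

    phase_spec = np.fft.fftn(phase)
    filtered = np.zeros(shape, dtype=np.float64)
    assigned = np.zeros(shape, dtype=bool)
    eroded_largest: np.ndarray | None = None
    for element in elements:
        supported = ndimage.binary_erosion(mask, structure=element)
        if eroded_largest is None:
            eroded_largest = supported
        smv = _smv_spectrum(element, shape)
        highpass = np.real(np.fft.ifftn((1.0 - smv) * phase_spec))
        fresh = supported & ~assigned
        filtered[fresh] = highpass[fresh]
        assigned |= supported

    # deconvolve the largest-radius filter; truncate near its spectral zeros
    h1 = 1.0 - _smv_spectrum(elements[0], shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.where(np.abs(h1) > cfg.tsvd_threshold, 1.0 / h1, 0.0)
    tissue = np.real(np.fft.ifftn(inv * np.fft.fftn(filtered)))
    tissue = np.where(eroded_largest, tissue, 0.0)
    return TissueField(
        data=tissue,
        mask=eroded_largest,
        voxel_size=voxel_size,
        units="rad",
        acq=acq,
    )


def phase_to_ppm(tissue: TissueField, acq: AcquisitionParams | None = None) -> TissueField:
    """Convert a tissue field from radians to ppm of B0.

    ppm = theta / (2*pi * f0 * TE) * 1e6; doubling TE halves the ppm
    value for a fixed phase.
    """
    acq = acq or tissue.acq
    if acq is None:
        raise ValueError("acquisition parameters required for ppm conversion")
    if acq.TE <= 0:
        raise ValueError("TE must be positive")
    if tissue.units == "ppm":
        return tissue
    data = tissue.data / acq.rad_per_ppm
    return TissueField(
        data=data,
        mask=tissue.mask,
        voxel_size=tissue.voxel_size,
        units="ppm",
        acq=acq,
    )
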