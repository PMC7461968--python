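"""Synthetic susceptibility phantoms for deep-gray-nucleus aging studies.

The generator emulates the structure of an ex vivo primate gradient-echo
susceptibility study: an ellipsoidal brain-shaped mask containing four
bilateral ellipsoidal nuclei — caudate (Cd), putamen (Pt), globus
pallidus (Gp), substantia nigra (Sn) — whose susceptibility follows a
linear model in age (iron accumulates roughly linearly over the rhesus
monkey lifespan).  Out-of-mask spherical sources emulate the strong
background field from the air/container interface, and an optional
contamination step flips a fraction of Gp/Sn voxels to diamagnetic
values, emulating the diamagnetic voxels seen ex vivo in those nuclei.

The forward chain is: susceptibility -> dipole field (ppm) -> GRE phase
accrual at B0 and TE -> complex Gaussian noise at a stated SNR -> wrapped
phase in (-pi, pi].  Every step is deterministic given the seed.

Default age models (ppm vs years):

    Cd: chi = 0.00300*age + 0.00377
    Pt: chi = 0.00260*age + 0.00246
    Gp: chi = 0.00452*age + 0.00242
    Sn: chi = 0.00619*age - 0.00216
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dipole import DipoleKernel, KSpaceGrid, make_dipole_kernel

__all__ = [
    "AgeModel",
    "NucleusSpec",
    "AcquisitionParams",
    "PhantomSpec",
    "SusceptibilityVolume",
    "LabelVolume",
    "WrappedPhaseVolume",
    "SubjectDataset",
    "DEFAULT_AGE_MODELS",
    "default_phantom_spec",
    "synthesize_phantom",
    "forward_field",
    "field_to_wrapped_phase",
    "synthesize_cohort",
]

#: Proton gyromagnetic ratio over 2*pi, Hz per tesla.
PROTON_LARMOR_HZ_PER_T = 42.577e6

#: Standard SNR of the noisy synthetic acquisition: representative of
#: high-resolution ex vivo gradient-echo imaging, where reconstruction
#: error near the dipole cone is dominated by amplified noise streaks.
DEFAULT_NOISY_SNR = 20.0

NUCLEUS_NAMES = ("Cd", "Pt", "Gp", "Sn")


class PhantomConfigError(ValueError):
    """Invalid phantom geometry (nucleus outside mask, overlap, ...)."""


@dataclass(frozen=True)
class AgeModel:
    """Linear susceptibility-vs-age model, chi(age) = slope*age + intercept."""

    slope: float  # ppm / year
    intercept: float  # ppm

    def chi(self, age: float) -> float:
        return self.slope * float(age) + self.intercept


#: Age models of the four analyzed nuclei (ppm per year, ppm).
DEFAULT_AGE_MODELS: dict[str, AgeModel] = {
    "Cd": AgeModel(slope=0.00300, intercept=0.00377),
    "Pt": AgeModel(slope=0.00260, intercept=0.00246),
    "Gp": AgeModel(slope=0.00452, intercept=0.00242),
    "Sn": AgeModel(slope=0.00619, intercept=-0.00216),
}


@dataclass(frozen=True)
class NucleusSpec:
    """One ellipsoidal nucleus; mirrored across the mid-sagittal plane if bilateral."""

    name: str
    center: tuple[float, float, float]  # mm, relative to volume center
    semi_axes: tuple[float, float, float]  # mm
    age_model: AgeModel
    bilateral: bool = True

    def __post_init__(self) -> None:
        if self.name not in NUCLEUS_NAMES:
            raise ValueError(f"unknown nucleus {self.name!r}; expected one of {NUCLEUS_NAMES}")
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError(f"semi-axes must be positive, got {self.semi_axes}")


@dataclass(frozen=True)
class AcquisitionParams:
    """Gradient-echo acquisition constants entering the phase model.

    B0 in tesla, TE in seconds.  ``snr`` is the per-channel SNR of the
    complex signal (magnitude / noise sigma); ``None`` disables noise.
    """

    B0: float = 9.4
    TE: float = 0.013
    larmor_frequency_per_tesla: float = PROTON_LARMOR_HZ_PER_T
    snr: float | None = None

    def __post_init__(self) -> None:
        if self.B0 <= 0 or self.TE <= 0:
            raise ValueError("B0 and TE must be positive")
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be positive or None")

    @property
    def f0(self) -> float:
        """Larmor frequency at B0, Hz."""
        return self.larmor_frequency_per_tesla * self.B0

    @property
    def rad_per_ppm(self) -> float:
        """Phase accrued at TE per ppm of field shift, radians."""
        return 2.0 * np.pi * self.f0 * self.TE * 1e-6


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and contamination parameters of the synthetic brain."""

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    brain_mask_semi_axes: tuple[float, float, float] = (20.0, 17.0, 15.0)
    nuclei: tuple[NucleusSpec, ...] = ()
    #: (center mm, radius mm, chi ppm) spheres strictly outside the brain mask
    background_sources: tuple[tuple[tuple[float, float, float], float, float], ...] = ()
    diamagnetic_fraction: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(int(n) < 16 for n in self.grid_shape):
            raise ValueError(f"grid_shape components must be >= 16, got {self.grid_shape}")
        if not (0.0 <= self.diamagnetic_fraction < 1.0):
            raise ValueError("diamagnetic_fraction must lie in [0, 1)")

    @property
    def grid(self) -> KSpaceGrid:
        return KSpaceGrid(shape=self.grid_shape, voxel_size=self.voxel_size)


@dataclass
class SusceptibilityVolume:
    """3-D susceptibility field in ppm with voxel geometry and brain mask."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    mask: np.ndarray

    @property
    def grid(self) -> KSpaceGrid:
        return KSpaceGrid(shape=self.data.shape, voxel_size=self.voxel_size)


@dataclass
class LabelVolume:
    """Integer nucleus labels; 0 is background.  ``legend`` maps label -> name.

    Bilateral nuclei carry distinct labels per side that map to the same
    name, so pooling left and right is a name-level operation.
    """

    data: np.ndarray
    legend: dict[int, str]


@dataclass
class WrappedPhaseVolume:
    """Wrapped GRE phase in (-pi, pi] plus the acquisition that produced it."""

    phase: np.ndarray
    voxel_size: tuple[float, float, float]
    acq: AcquisitionParams


@dataclass
class SubjectDataset:
    """One synthetic subject: ground truth plus simulated measurements."""

    subject_id: str
    age: float
    chi_truth: SusceptibilityVolume
    labels: LabelVolume
    field: np.ndarray  # forward dipole field, ppm
    wrapped_phase: WrappedPhaseVolume
    magnitude: np.ndarray


def default_phantom_spec(
    grid_shape: tuple[int, int, int] = (48, 48, 48),
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    diamagnetic_fraction: float = 0.0,
    rng_seed: int = 0,
    with_background: bool = True,
) -> PhantomSpec:
    """Standard four-nucleus bilateral phantom used throughout the package.

    Geometry is expressed in mm around the volume center, so the same
    anatomy is reproduced at any grid size large enough to contain it.
    The two background spheres sit above and below/behind the brain,
    mimicking residual susceptibility sources near the specimen
    container (+0.5 ppm relative to tissue; strong enough to dominate
    the internal field near the brain surface while keeping the
    accrued phase spatially sampled at desk-scale voxels).
    """
    nuclei = tuple(
        NucleusSpec(name=name, center=center, semi_axes=axes, age_model=DEFAULT_AGE_MODELS[name])
        for name, center, axes in (
            ("Cd", (7.0, 6.0, 4.0), (2.5, 3.0, 3.5)),
            ("Pt", (11.0, 1.0, 1.0), (2.5, 3.0, 4.5)),
            ("Gp", (6.5, 0.5, 0.0), (2.0, 2.5, 3.5)),
            ("Sn", (4.0, -5.0, -6.0), (1.8, 2.2, 3.0)),
        )
    )
    background = (
        ((0.0, 2.0, 20.0), 2.5, 0.5),
        ((0.0, -19.0, -10.0), 2.5, 0.5),
    ) if with_background else ()
    return PhantomSpec(
        grid_shape=grid_shape,
        voxel_size=voxel_size,
        nuclei=nuclei,
        background_sources=background,
        diamagnetic_fraction=diamagnetic_fraction,
        rng_seed=rng_seed,
    )


def _mm_coords(shape, voxel_size):
    """Per-axis voxel-center coordinates in mm, origin at the volume center."""
    return [
        (np.arange(n) - (n - 1) / 2.0) * h
        for n, h in zip(shape, voxel_size)
    ]


def _ellipsoid_mask(shape, voxel_size, center, semi_axes) -> np.ndarray:
    x, y, z = _mm_coords(shape, voxel_size)
    q = (
        ((x[:, None, None] - center[0]) / semi_axes[0]) ** 2
        + ((y[None, :, None] - center[1]) / semi_axes[1]) ** 2
        + ((z[None, None, :] - center[2]) / semi_axes[2]) ** 2
    )
    return q <= 1.0


def _sphere_mask(shape, voxel_size, center, radius) -> np.ndarray:
    return _ellipsoid_mask(shape, voxel_size, center, (radius, radius, radius))


def synthesize_phantom(spec: PhantomSpec, age: float) -> tuple[SusceptibilityVolume, LabelVolume]:
    """Generate ground-truth susceptibility and label volumes at a given age.

    Every voxel of nucleus n takes chi = n.age_model(age); in-mask
    background tissue is 0 ppm; out-of-mask sources take their stated
    chi.  If ``diamagnetic_fraction`` > 0, that fraction of Gp and Sn
    voxels (chosen reproducibly from ``spec.rng_seed``) is flipped to
    -|chi|.

    Raises
    ------
    PhantomConfigError
        If a nucleus pokes outside the brain mask, two nuclei overlap,
        or a background source intersects the mask.
    """
    if age < 0:
        raise ValueError(f"age must be >= 0, got {age}")
    shape, voxel = spec.grid_shape, spec.voxel_size
    brain = _ellipsoid_mask(shape, voxel, (0.0, 0.0, 0.0), spec.brain_mask_semi_axes)

    chi = np.zeros(shape, dtype=np.float64)
    labels = np.zeros(shape, dtype=np.int16)
    legend: dict[int, str] = {}
    next_label = 1
    for nuc in spec.nuclei:
        sides = [nuc.center]
        if nuc.bilateral:
            cx, cy, cz = nuc.center
            sides.append((-cx, cy, cz))
        for center in sides:
            m = _ellipsoid_mask(shape, voxel, center, nuc.semi_axes)
            if np.any(m & ~brain):
                raise PhantomConfigError(f"nucleus {nuc.name} at {center} extends outside the brain mask")
            if np.any(labels[m] != 0):
                raise PhantomConfigError(f"nucleus {nuc.name} at {center} overlaps another nucleus")
            if not m.any():
                raise PhantomConfigError(f"nucleus {nuc.name} at {center} contains no voxels at this resolution")
            chi[m] = nuc.age_model.chi(age)
            labels[m] = next_label
            legend[next_label] = nuc.name
            next_label += 1

    if spec.diamagnetic_fraction > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(spec.rng_seed), 7]))
        target_labels = [lab for lab, name in legend.items() if name in ("Gp", "Sn")]
        for lab in target_labels:
            idx = np.flatnonzero(labels.ravel() == lab)
            n_flip = int(round(spec.diamagnetic_fraction * idx.size))
            if n_flip:
                flip = rng.choice(idx, size=n_flip, replace=False)
                flat = chi.ravel()
                flat[flip] = -np.abs(flat[flip])

    for center, radius, source_chi in spec.background_sources:
        m = _sphere_mask(shape, voxel, center, radius)
        if np.any(m & brain):
            raise PhantomConfigError(f"background source at {center} intersects the brain mask")
        chi[m] = source_chi

    vol = SusceptibilityVolume(data=chi, voxel_size=tuple(voxel), mask=brain)
    return vol, LabelVolume(data=labels, legend=legend)


def forward_field(chi: SusceptibilityVolume, kernel: DipoleKernel) -> np.ndarray:
    """Induced field shift (ppm) of a susceptibility distribution.

    Computes the dipole convolution in the Fourier domain; since
    D(0) = 0, the output has zero spatial mean, and the operation is
    linear in chi.
    """
    if kernel.shape != chi.data.shape:
        raise ValueError(f"kernel shape {kernel.shape} does not match volume shape {chi.data.shape}")
    return np.real(np.fft.ifftn(kernel.values * np.fft.fftn(chi.data)))


def field_to_wrapped_phase(
    field_ppm: np.ndarray,
    acq: AcquisitionParams,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    rng_seed: int | None = None,
) -> tuple[WrappedPhaseVolume, np.ndarray]:
    """Convert a field map into a wrapped, optionally noisy GRE phase image.

    The true phase is theta = 2*pi * f0 * TE * field * 1e-6 with
    f0 = larmor_frequency_per_tesla * B0.  A unit-magnitude complex
    signal exp(i*theta) receives i.i.d. complex Gaussian noise with
    per-channel sigma = 1/snr when ``acq.snr`` is set; the returned
    phase is its angle (in (-pi, pi]) and the magnitude its modulus.
    """
    theta = acq.rad_per_ppm * np.asarray(field_ppm, dtype=np.float64)
    signal = np.exp(1j * theta)
    if acq.snr is not None:
        rng = np.random.default_rng(rng_seed)
        sigma = 1.0 / acq.snr
        signal = signal + rng.normal(scale=sigma, size=theta.shape) + 1j * rng.normal(
            scale=sigma, size=theta.shape
        )
    wrapped = np.angle(signal)
    magnitude = np.abs(signal)
    return WrappedPhaseVolume(phase=wrapped, voxel_size=tuple(voxel_size), acq=acq), magnitude


def synthesize_cohort(
    spec: PhantomSpec,
    ages: list[float],
    acq: AcquisitionParams,
    rng_seed: int = 0,
) -> list[SubjectDataset]:
    """Simulate one subject per age through the full forward chain.

    Per-subject seeds are spawned deterministically from ``rng_seed``
    and the subject index, so identical calls produce bit-identical
    cohorts and any subject can be regenerated in isolation.
    """
    if len(ages) == 0:
        raise ValueError("ages must be non-empty")
    kernel = make_dipole_kernel(spec.grid)
    root = np.random.SeedSequence(int(rng_seed))
    children = root.spawn(len(ages))
    subjects = []
    for i, (age, child) in enumerate(zip(ages, children)):
        sub_seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        sub_spec = replace(spec, rng_seed=sub_seed)
        chi, labels = synthesize_phantom(sub_spec, age)
        fld = forward_field(chi, kernel)
        wrapped, mag = field_to_wrapped_phase(fld, acq, voxel_size=spec.voxel_size, rng_seed=sub_seed)
        subjects.append(
            SubjectDataset(
                subject_id=f"S{i:02d}",
                age=float(age),
                chi_truth=chi,
                labels=labels,
                field=fld,
                wrapped_phase=wrapped,
                magnitude=mag,
            )
        )
    return subjects
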