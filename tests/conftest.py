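"""Shared fixtures: standard phantom, kernel, and processed tissue fields.

Session-scoped where the object is expensive and read-only, so the
forward simulation and V-SHARP run once per grid size.
"""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import settings

from qsmtrend import (
    AcquisitionParams,
    VSharpConfig,
    default_phantom_spec,
    field_to_wrapped_phase,
    forward_field,
    laplacian_unwrap,
    make_dipole_kernel,
    phase_to_ppm,
    synthesize_phantom,
    vsharp,
)

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

STANDARD_AGE = 19.0


class _Truth:
    """Ground-truth bundle for one phantom realization."""

    def __init__(self, grid_side: int, age: float = STANDARD_AGE):
        self.spec = default_phantom_spec(grid_shape=(grid_side,) * 3)
        self.kernel = make_dipole_kernel(self.spec.grid)
        self.chi, self.labels = synthesize_phantom(self.spec, age)
        spec_internal = replace(self.spec, background_sources=())
        self.chi_internal, _ = synthesize_phantom(spec_internal, age)
        self.field_internal = forward_field(self.chi_internal, self.kernel)
        self.field_total = forward_field(self.chi, self.kernel)
        self.mask = self.chi.mask


@pytest.fixture(scope="session")
def truth48() -> _Truth:
    return _Truth(48)


@pytest.fixture(scope="session")
def truth64() -> _Truth:
    return _Truth(64)


@pytest.fixture(scope="session")
def tissue48(truth48):
    """Noiseless wrapped phase at 48^3, unwrapped + V-SHARP + ppm."""
    acq = AcquisitionParams()
    wrapped, _ = field_to_wrapped_phase(truth48.field_total, acq)
    unwrapped = laplacian_unwrap(wrapped)
    return phase_to_ppm(vsharp(unwrapped, truth48.mask, VSharpConfig()))


@pytest.fixture(scope="session")
def tissue64(truth64):
    """Noiseless wrapped phase at 64^3, unwrapped + V-SHARP + ppm."""
    acq = AcquisitionParams()
    wrapped, _ = field_to_wrapped_phase(truth64.field_total, acq)
    unwrapped = laplacian_unwrap(wrapped)
    return phase_to_ppm(vsharp(unwrapped, truth64.mask, VSharpConfig()))
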