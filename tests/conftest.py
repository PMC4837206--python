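"""Shared fixtures: small phantom configurations and toy stacks."""

import numpy as np
import pytest

from ramanstack.phantom import PhantomConfig, generate_stack
from ramanstack.stack import PlaneImage, Spectrum, ZStack


@pytest.fixture
def axis918():
    """The default fixed-dialect acquisition grid (449–3200 cm⁻¹, 3 cm⁻¹)."""
    return 449.0 + 3.0 * np.arange(918)


@pytest.fixture
def tiny_config():
    """Small but otherwise default fixed-dialect phantom (6×6 px, 3 planes)."""
    return PhantomConfig(plane_grid=(6, 6), seed=0)


@pytest.fixture
def noiseless_config():
    """Deterministic phantom: no noise, no spikes, zero baseline."""
    return PhantomConfig(
        plane_grid=(4, 4),
        noise_sd=0.0,
        spike_rate=0.0,
        baseline_coeffs_range=((0.0, 0.0), (0.0, 0.0), (0.0, 0.0)),
        seed=0,
    )


@pytest.fixture
def tiny_stack(tiny_config):
    stack, _ = generate_stack(tiny_config, "control")
    return stack


def make_toy_stack(h=2, w=2, n_ch=3, n_planes=2, z_step=0.5, seed=0):
    """Tiny arbitrary stack for I/O and container tests."""
    rng = np.random.default_rng(seed)
    axis = 100.0 + 10.0 * np.arange(n_ch)
    planes = [
        PlaneImage(axis, rng.normal(1.0, 0.3, size=(h, w, n_ch)), z=z_step * k)
        for k in range(n_planes)
    ]
    return ZStack(planes, z_step, {"dialect": "fixed", "condition": "control"})


def gaussian_spectrum(axis, center, sigma, amplitude=1.0, offset=0.0):
    axis = np.asarray(axis, dtype=float)
    return Spectrum(axis, offset + amplitude * np.exp(-0.5 * ((axis - center) / sigma) ** 2))
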