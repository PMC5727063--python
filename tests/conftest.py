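"""Shared fixtures: geometries, shapes, synthetic pulses and small
simulated datasets used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from porescope import pipeline
from porescope.features import NormalizedPulse
from porescope.pulse_sim import CocciChain, PoreGeometry, RoundedRod


@pytest.fixture(scope="session")
def geom() -> PoreGeometry:
    """Reference device: 3 um pore, 40 nm SiN membrane, diluted PBS."""
    return PoreGeometry()


@pytest.fixture(scope="session")
def strep_geom() -> PoreGeometry:
    """Bacterium-sized pore used for the cocci-chain measurements."""
    return PoreGeometry(d_pore=1.4e-6, L_pore=40e-9)


@pytest.fixture(scope="session")
def rod() -> RoundedRod:
    return RoundedRod(D=800e-9, Lb=2.6e-6, R=200e-9)


@pytest.fixture(scope="session")
def chain() -> CocciChain:
    return CocciChain(n_cocci=2, b=400e-9, a=500e-9, neck_diameter=280e-9)


def make_triangle(n: int = 2001) -> NormalizedPulse:
    """Symmetric triangular pulse peaking at t_norm = 0.5."""
    t = np.linspace(0.0, 1.0, n)
    return NormalizedPulse(1.0 - 2.0 * np.abs(t - 0.5), t)


def make_rectangle(n: int = 2001) -> NormalizedPulse:
    """Near-rectangular (flat-top) pulse with single-sample edges."""
    t = np.linspace(0.0, 1.0, n)
    i = np.ones(n)
    i[0] = i[-1] = 0.0
    return NormalizedPulse(i, t)


def make_needle(n: int = 2001, width: float = 1e-3) -> NormalizedPulse:
    """Sharp spike at t_norm = 0.5 with near-zero crossing spread."""
    t = np.linspace(0.0, 1.0, n)
    return NormalizedPulse(np.exp(-0.5 * ((t - 0.5) / width) ** 2), t)


def random_pulse(rng: np.random.Generator, n: int = 1500) -> NormalizedPulse:
    """Random smooth positive pulse: 1-3 Gaussian bumps, apex normalized."""
    t = np.linspace(0.0, 1.0, n)
    i = np.zeros(n)
    for _ in range(rng.integers(1, 4)):
        center = rng.uniform(0.2, 0.8)
        width = rng.uniform(0.03, 0.2)
        amp = rng.uniform(0.3, 1.0)
        i += amp * np.exp(-0.5 * ((t - center) / width) ** 2)
    return NormalizedPulse(i / i.max(), t)


@pytest.fixture(scope="session")
def small_dataset():
    """Small two-class rod dataset (8 traces/class) with its features."""
    dataset = pipeline.simulate_two_class_dataset(n_per_class=8, seed=7)
    featurized = pipeline.featurize_dataset(dataset)
    return dataset, featurized
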