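"""Feature tests: closed-form pulses (triangle, rectangle, needle),
dense-resampling oracles, invariance and bound properties, and the
60-vector catalog."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from porescope import features as ft
from porescope.features import NormalizedPulse
from porescope.pulse_detect import DetectedPulse

from conftest import make_needle, make_rectangle, make_triangle, random_pulse


def make_pulse(samples: np.ndarray, fs: float = 1e6, pulse_id: int = 0
               ) -> DetectedPulse:
    samples = np.asarray(samples, dtype=float)
    peak = int(np.argmax(samples))
    return DetectedPulse(pulse_id=pulse_id, t_s=0.0, t_e=(len(samples) - 1) / fs,
                         peak_time=peak / fs, I_p=float(samples.max()),
                         samples=samples, sigma=0.0, sampling_rate=fs)


# ---------------------------------------------------------------------------
# dense-resampling oracles (independent recomputation)
# ---------------------------------------------------------------------------

DENSE_N = 10 ** 5


def oracle_beta(np_pulse: NormalizedPulse, y_th: float) -> float:
    t = np.linspace(0.0, 1.0, DENSE_N)
    i = np.interp(t, np_pulse.t_norm, np_pulse.i_norm)
    level = 1.0 - y_th / 100.0
    sign = np.sign(i - level)
    idx = np.flatnonzero(sign[:-1] * sign[1:] < 0)
    crossings = []
    for k in idx:
        frac = (level - i[k]) / (i[k + 1] - i[k])
        crossings.append(t[k] + frac * (t[k + 1] - t[k]))
    crossings = np.array(crossings)
    return float(np.mean((crossings - crossings.mean()) ** 2))


def oracle_area(np_pulse: NormalizedPulse) -> float:
    t = np.linspace(0.0, 1.0, DENSE_N)
    return float(np.trapezoid(np.interp(t, np_pulse.t_norm, np_pulse.i_norm), t))


def oracle_inertia(np_pulse: NormalizedPulse) -> tuple[float, float]:
    # continuum identities: I_m = int t^2 i dt;
    # I_w = int h^2 w(h) dh = int i(t)^3/3 dt by Fubini
    t = np.linspace(0.0, 1.0, DENSE_N)
    i = np.interp(t, np_pulse.t_norm, np_pulse.i_norm)
    i_m = float(np.trapezoid(t * t * i, t))
    i_w = float(np.trapezoid(i ** 3 / 3.0, t))
    return i_m, i_w


# ---------------------------------------------------------------------------
# closed-form pulses
# ---------------------------------------------------------------------------

class TestClosedForms:
    def test_triangle_crossings_at_30_percent(self):
        m, t_i, t_ave = ft.crossing_times(make_triangle(), 30.0)
        assert m == 2
        assert t_i == pytest.approx([0.35, 0.65], abs=1e-3)
        assert t_ave == pytest.approx(0.5, abs=1e-3)

    def test_triangle_bluntness_closed_form(self):
        # crossings at {0.35, 0.65} deviate +-0.15 -> beta = 0.15^2 = 0.0225
        assert ft.bluntness(make_triangle(), 30.0) == pytest.approx(0.0225, rel=1e-3)

    def test_rectangle_bluntness_approaches_quarter(self):
        assert ft.bluntness(make_rectangle(), 30.0) == pytest.approx(0.25, rel=5e-3)

    def test_needle_bluntness_approaches_zero(self):
        assert ft.bluntness(make_needle(), 30.0) < 1e-4

    def test_monotone_single_peak_has_two_crossings(self):
        m, _, _ = ft.crossing_times(make_needle(width=0.1), 50.0)
        assert m == 2

    def test_symmetric_pulse_onset_angle(self):
        assert ft.onset_angle(make_triangle()) == pytest.approx(math.atan(2.0))

    def test_peak_at_end_gives_pi_over_4(self):
        t = np.linspace(0, 1, 101)
        assert ft.onset_angle(NormalizedPulse(t.copy(), t)) == pytest.approx(
            math.pi / 4)

    def test_peak_at_onset_gives_pi_over_2(self):
        t = np.linspace(0, 1, 101)
        assert ft.onset_angle(NormalizedPulse(1.0 - t, t)) == pytest.approx(
            math.pi / 2)

    def test_rectangle_area_is_one(self):
        a, a_l, a_r, r_m, _ = ft.areas(make_rectangle())
        assert a == pytest.approx(1.0, rel=5e-3)
        assert a == pytest.approx(a_l + a_r, abs=1e-12)

    def test_triangle_area_is_half(self):
        a, *_ = ft.areas(make_triangle(), n_partitions=50)
        assert a == pytest.approx(0.5, abs=1.0 / 50)

    def test_symmetric_pulse_area_ratio_unity(self):
        *_, r_m, _ = ft.areas(make_triangle())
        assert r_m == pytest.approx(1.0, rel=5e-2)

    def test_rectangle_inertia_thirds(self):
        n = 50
        i_m, i_w = ft.inertia(make_rectangle(), n)
        assert i_m == pytest.approx(1.0 / 3.0, abs=2.0 / n ** 2)
        assert i_w == pytest.approx(1.0 / 3.0, abs=2.0 / n)

    def test_needle_transverse_inertia_vanishes(self):
        _, i_w = ft.inertia(make_needle())
        assert i_w < 5e-3


# ---------------------------------------------------------------------------
# oracle equivalence on random pulses
# ---------------------------------------------------------------------------

class TestOracleEquivalence:
    def test_beta_area_inertia_against_dense_recomputation(self):
        rng = np.random.default_rng(2024)
        checked = 0
        for _ in range(50):
            pulse = random_pulse(rng)
            beta = ft.bluntness(pulse, 30.0)
            assert beta == pytest.approx(oracle_beta(pulse, 30.0), rel=1e-3,
                                         abs=1e-7)
            a, *_ = ft.areas(pulse, 200)
            assert a == pytest.approx(oracle_area(pulse), rel=1e-3)
            i_m, i_w = ft.inertia(pulse, 200)
            om, ow = oracle_inertia(pulse)
            assert i_m == pytest.approx(om, rel=1e-3)
            assert i_w == pytest.approx(ow, rel=2e-3, abs=1e-4)
            checked += 1
        assert checked == 50


# ---------------------------------------------------------------------------
# invariances and bounds
# ---------------------------------------------------------------------------

class TestInvariances:
    def test_depth_scaling_leaves_normalized_features_unchanged(self):
        rng = np.random.default_rng(5)
        base = 1e-10 * random_pulse(rng).i_norm
        p1, p2 = make_pulse(base), make_pulse(2.0 * base)
        r1, n1 = ft.compute_features(p1)
        r2, n2 = ft.compute_features(p2)
        assert r2.I_p == pytest.approx(2 * r1.I_p)
        for name in ("beta_apex_30", "theta", "A", "r_m", "I_m", "I_w"):
            assert r1.scalar(name) == pytest.approx(r2.scalar(name), rel=1e-12)

    def test_time_stretch_preserves_t_norm_features(self):
        rng = np.random.default_rng(8)
        base = random_pulse(rng, n=1001).i_norm
        p1 = make_pulse(1e-10 * base, fs=1e6)
        p2 = make_pulse(1e-10 * base, fs=5e5)    # same samples, 2x duration
        r1, _ = ft.compute_features(p1)
        r2, _ = ft.compute_features(p2)
        assert r2.t_d == pytest.approx(2 * r1.t_d)
        assert r1.beta[30.0] == pytest.approx(r2.beta[30.0], rel=1e-12)

    def test_apex_maps_to_one(self):
        p = make_pulse(np.array([0, 1e-11, 5e-11, 2e-11, 0]))
        np_pulse = ft.normalize(p)
        assert np_pulse.i_norm.max() == 1.0

    def test_zero_depth_pulse_rejected(self):
        p = make_pulse(np.array([0, 1e-11, 5e-11, 2e-11, 0]))
        p.I_p = 0.0
        with pytest.raises(ValueError):
            ft.normalize(p)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6), st.floats(10.0, 90.0))
    def test_beta_bounds(self, seed, y_th):
        pulse = random_pulse(np.random.default_rng(seed))
        beta = ft.bluntness(pulse, y_th)
        m, _, _ = ft.crossing_times(pulse, y_th)
        assert beta >= 0.0
        if m == 2:
            assert beta <= 0.25

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_crossing_width_shrinks_toward_apex(self, seed):
        # on single-peak pulses the crossing span narrows as Y_th
        # decreases toward the apex
        rng = np.random.default_rng(seed)
        t = np.linspace(0, 1, 1500)
        center = rng.uniform(0.3, 0.7)
        width = rng.uniform(0.05, 0.2)
        i = np.exp(-0.5 * ((t - center) / width) ** 2)
        pulse = NormalizedPulse(i / i.max(), t)
        spans = []
        for y_th in (50.0, 30.0, 15.0, 5.0):
            _, t_i, _ = ft.crossing_times(pulse, y_th)
            spans.append(t_i.max() - t_i.min())
        assert all(a >= b - 1e-12 for a, b in zip(spans, spans[1:]))

    def test_level_above_apex_errors(self):
        t = np.linspace(0, 1, 101)
        pulse = NormalizedPulse(np.interp(t, [0, 0.5, 1], [0.95, 1.0, 0.95]), t)
        with pytest.raises(ValueError, match="never crosses"):
            ft.crossing_times(pulse, 10.0)


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------

class TestCatalog:
    def test_default_catalog_has_sixty_specs(self):
        catalog = ft.default_catalog()
        assert len(catalog) == 60
        assert len({s.name for s in catalog}) == 60

    def test_vector_lengths_and_determinism(self):
        rng = np.random.default_rng(3)
        p = make_pulse(1e-10 * random_pulse(rng).i_norm)
        record, np_pulse = ft.compute_features(p)
        v1 = ft.build_feature_vectors(record, np_pulse)
        v2 = ft.build_feature_vectors(record, np_pulse)
        for spec in ft.default_catalog():
            assert v1[spec.name].shape == (spec.length,)
            assert np.array_equal(v1[spec.name], v2[spec.name])

    def test_scalar_only_spec_has_length_one(self):
        spec = ft.FeatureVectorSpec(name="I_p", scalar="I_p")
        assert spec.length == 1

    def test_unknown_scalar_rejected(self):
        rng = np.random.default_rng(3)
        p = make_pulse(1e-10 * random_pulse(rng).i_norm)
        record, np_pulse = ft.compute_features(p)
        bad = [ft.FeatureVectorSpec(name="x", scalar="nope")]
        with pytest.raises(KeyError, match="nope"):
            ft.build_feature_vectors(record, np_pulse, bad)

    def test_catalog_hash_stable_and_sensitive(self):
        catalog = ft.default_catalog()
        h1 = ft.catalog_hash(catalog)
        h2 = ft.catalog_hash(catalog)
        assert h1 == h2
        assert ft.catalog_hash(catalog[:59]) != h1
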