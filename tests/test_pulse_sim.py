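"""Simulator tests: geometry profiles, pore resistance against independent
quadrature, pulse properties, corrugation counts and dataset generation."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.signal import find_peaks

from porescope import pulse_sim as ps
from porescope.pulse_sim import (CocciChain, NoiseModel, PoreGeometry,
                                 RoundedRod, TraceSpec, TranslocationEvent,
                                 Variability)


# ---------------------------------------------------------------------------
# radial profiles
# ---------------------------------------------------------------------------

class TestRadialProfile:
    def test_rod_body_is_half_diameter(self, rod):
        assert ps.radial_profile(rod, 0.0) == pytest.approx(400e-9)

    def test_rod_vanishes_beyond_half_length(self, rod):
        assert ps.radial_profile(rod, 2.0e-6) == 0.0

    def test_chain_neck_radius_at_midpoint(self, chain):
        # spacing s = 2a sqrt(1 - (neck/2b)^2); the junction plane sits at s/2
        s = 2 * 500e-9 * math.sqrt(1 - (140 / 400) ** 2)
        assert chain.spacing == pytest.approx(s)
        # centers sit at +-s/2, so the junction mid-plane is zeta = 0
        assert ps.radial_profile(chain, 0.0) == pytest.approx(140e-9, rel=1e-9)

    def test_chain_has_n_local_maxima(self):
        for n in range(1, 5):
            chain = CocciChain(n_cocci=n)
            z = np.linspace(-chain.half_extent, chain.half_extent, 20001)
            r = ps.radial_profile(chain, z)
            peaks, _ = find_peaks(r, prominence=0.05 * r.max())
            assert len(peaks) == n

    def test_rejects_non_finite_zeta(self, rod):
        with pytest.raises(ValueError):
            ps.radial_profile(rod, np.nan)

    def test_profile_never_exceeds_half_diameter(self, rod):
        z = np.linspace(-3e-6, 3e-6, 5001)
        assert np.all(ps.radial_profile(rod, z) <= rod.D / 2 + 1e-18)

    def test_volume_matching_conserves_volume(self):
        reference = RoundedRod(R=10e-9)
        for R in (200e-9, 600e-9, 1100e-9):
            matched = RoundedRod(R=R, volume_matched=True)
            assert matched.volume == pytest.approx(reference.volume, rel=1e-3)


# ---------------------------------------------------------------------------
# resistance model
# ---------------------------------------------------------------------------

def oracle_blocked_resistance(geom, shape, z_c, refine: int = 10) -> float:
    """Independent brute-force quadrature: kink-split midpoint rule at
    ``refine``-times the default slice density."""
    half_l = geom.L_pore / 2.0
    z_max = half_l + ps.ACCESS_EXTENT * geom.d_pore
    regions = [
        np.linspace(-z_max, -half_l, refine * ps.N_ACCESS + 1),
        np.linspace(-half_l, half_l, refine * ps.N_MEMBRANE + 1),
        np.linspace(half_l, z_max, refine * ps.N_ACCESS + 1),
    ]
    brk = z_c + shape.breakpoints()
    total = ps.open_pore_resistance(geom)
    lo = max(z_c - shape.half_extent, -z_max)
    hi = min(z_c + shape.half_extent, z_max)
    if hi <= lo:
        return total
    for edges in regions:
        a, b = edges[0], edges[-1]
        if hi <= a or lo >= b:
            continue
        e = np.unique(np.concatenate((
            [max(lo, a)], edges[(edges > lo) & (edges < hi)],
            brk[(brk > max(lo, a)) & (brk < min(hi, b))], [min(hi, b)])))
        for k in range(len(e) - 1):
            mid = 0.5 * (e[k] + e[k + 1])
            r = float(shape.profile(np.array([mid - z_c]))[0])
            a_part = math.pi * r * r
            radius = geom.d_pore / 2 + max(0.0, abs(mid) - half_l)
            a_open = math.pi * radius * radius
            total += (e[k + 1] - e[k]) * (
                1.0 / (a_open - a_part) - 1.0 / a_open) / geom.kappa
    return total


class TestResistance:
    def test_open_pore_closed_form(self, geom):
        # access 2.083 MOhm + pore 35.4 kOhm for the 3 um x 40 nm device
        r = ps.open_pore_resistance(geom)
        assert r == pytest.approx(2.083e6 + 35.4e3, rel=2e-3)

    def test_open_pore_thin_membrane_limit(self):
        g = PoreGeometry(L_pore=1e-15)
        assert ps.open_pore_resistance(g) == pytest.approx(
            1.0 / (g.kappa * g.d_pore), rel=1e-6)

    def test_open_pore_inverse_in_conductivity(self, geom):
        doubled = PoreGeometry(kappa=2 * geom.kappa)
        assert ps.open_pore_resistance(doubled) == pytest.approx(
            ps.open_pore_resistance(geom) / 2)

    def test_far_field_limit(self, geom, rod):
        r_open = ps.open_pore_resistance(geom)
        r_far = ps.blocked_resistance(geom, rod, 100 * geom.d_pore)
        assert abs(r_far - r_open) / r_open < 1e-9

    def test_blocked_exceeds_open_everywhere(self, geom, rod):
        for z in np.linspace(-10e-6, 10e-6, 21):
            assert ps.blocked_resistance(geom, rod, z) >= ps.open_pore_resistance(geom)

    def test_monotone_in_diameter(self, geom):
        thin = RoundedRod(D=400e-9, Lb=2.6e-6, R=200e-9)
        thick = RoundedRod(D=800e-9, Lb=2.6e-6, R=200e-9)
        assert ps.blocked_resistance(geom, thick, 0.0) > \
            ps.blocked_resistance(geom, thin, 0.0)

    def test_matches_fine_quadrature_oracle(self, geom):
        rng = np.random.default_rng(42)
        for _ in range(20):
            if rng.random() < 0.5:
                shape = RoundedRod(D=rng.uniform(3e-7, 9e-7),
                                   Lb=rng.uniform(1.5e-6, 3e-6),
                                   R=rng.uniform(1e-8, 1.2e-6))
            else:
                shape = CocciChain(n_cocci=int(rng.integers(1, 5)),
                                   b=rng.uniform(2e-7, 4.5e-7),
                                   a=rng.uniform(3e-7, 6e-7),
                                   neck_diameter=2e-7)
            z_c = rng.uniform(-8e-6, 8e-6)
            ours = ps.blocked_resistance(geom, shape, z_c)
            oracle = oracle_blocked_resistance(geom, shape, z_c)
            assert ours == pytest.approx(oracle, rel=1e-6)

    def test_profile_agrees_with_scalar_path(self, geom, rod):
        z = np.linspace(-12e-6, 12e-6, 49)
        prof = ps.resistance_profile(geom, rod, z)
        scalar = np.array([ps.blocked_resistance(geom, rod, zi) for zi in z])
        assert np.max(np.abs(prof - scalar) / scalar) < 1e-4

    def test_plugged_pore_raises(self):
        g = PoreGeometry(d_pore=700e-9)   # pore narrower than the rod
        with pytest.raises(ps.PluggedPoreError):
            ps.blocked_resistance(g, RoundedRod(), 0.0)


# ---------------------------------------------------------------------------
# pulse simulation
# ---------------------------------------------------------------------------

class TestSimulatePulse:
    def test_noise_free_baseline_is_exactly_open_pore(self, geom, rod):
        spec = TraceSpec(duration=0.03)
        event = TranslocationEvent(velocity=3e-3, t0=0.015)
        trace = ps.simulate_pulse(geom, rod, event, spec, NoiseModel(rms=0.0))
        i_open = geom.v_b / ps.open_pore_resistance(geom)
        zone = ps.influence_half_width(geom, rod)
        t = trace.times
        far = np.abs(event.velocity * (t - event.t0)) > zone
        assert np.all(trace.samples[far] == i_open)

    def test_rod_pulse_single_minimum_deeper_than_threshold(self, geom, rod):
        t, depth = ps.theoretical_pulse(geom, rod)
        assert depth.max() > 60e-12
        peaks, _ = find_peaks(depth, prominence=0.05 * depth.max())
        assert len(peaks) == 1

    def test_cocci_chain_corrugations(self, strep_geom):
        for n in (1, 2, 3, 4):
            t, depth = ps.theoretical_pulse(strep_geom, CocciChain(n_cocci=n))
            peaks, _ = find_peaks(depth, prominence=0.05 * depth.max())
            assert len(peaks) == n

    def test_pre_entry_depth_fraction(self, geom, rod):
        # access-dominated sensing: >10% of the depth accrues before the
        # particle tip reaches the membrane
        _, depth = ps.theoretical_pulse(geom, rod)
        z_tip = -(geom.L_pore / 2 + rod.half_extent)
        at_entry = geom.v_b / ps.open_pore_resistance(geom) \
            - geom.v_b / ps.blocked_resistance(geom, rod, z_tip)
        assert at_entry > 0.10 * depth.max()

    def test_transit_must_fit_duration(self, geom, rod):
        with pytest.raises(ValueError):
            ps.simulate_pulse(geom, rod, TranslocationEvent(velocity=3e-3, t0=0.001),
                              TraceSpec(duration=0.005), NoiseModel(rms=0.0))

    def test_seeded_noise_reproducible(self, geom, rod):
        spec = TraceSpec(duration=0.03)
        event = TranslocationEvent(t0=0.015)
        a = ps.simulate_pulse(geom, rod, event, spec, NoiseModel(seed=5))
        b = ps.simulate_pulse(geom, rod, event, spec, NoiseModel(seed=5))
        assert a.samples.tobytes() == b.samples.tobytes()

    def test_noise_rms_matches_spec(self):
        noise = NoiseModel(rms=13e-12, seed=3)
        samples = noise.sample(10 ** 5)
        assert samples.std() == pytest.approx(13e-12, rel=0.05)


class TestBluntnessCurve:
    def test_reference_is_unity_and_strictly_monotone(self, geom):
        rod = RoundedRod(R=10e-9)
        curve = ps.bluntness_curve(geom, rod, [10e-9, 200e-9, 600e-9, 1100e-9])
        values = [b for _, b in curve]
        assert values[0] == pytest.approx(1.0)
        diffs = np.diff(values)
        assert np.all(diffs > 0) or np.all(diffs < 0)

    def test_deterministic_for_equal_roundness(self, geom):
        rod = RoundedRod(R=10e-9)
        curve = ps.bluntness_curve(geom, rod, [10e-9, 400e-9, 400e-9])
        assert curve[1][1] == curve[2][1]

    def test_requires_reference_in_grid(self, geom):
        with pytest.raises(ValueError):
            ps.bluntness_curve(geom, RoundedRod(), [200e-9, 600e-9])


# ---------------------------------------------------------------------------
# dataset / mixture generation
# ---------------------------------------------------------------------------

class TestGenerateDataset:
    def test_class_counts(self):
        specs = [("a", RoundedRod(R=200e-9), Variability()),
                 ("b", RoundedRod(R=1100e-9), Variability())]
        ds = ps.generate_dataset(specs, n_per_class=3, seed=0)
        assert len(ds) == 6
        assert ds.labels == ["a"] * 3 + ["b"] * 3

    def test_same_seed_bit_identical(self):
        specs = [("a", RoundedRod(R=200e-9), Variability())]
        d1 = ps.generate_dataset(specs, 2, seed=11)
        d2 = ps.generate_dataset(specs, 2, seed=11)
        for r1, r2 in zip(d1.records, d2.records):
            assert r1.trace.samples.tobytes() == r2.trace.samples.tobytes()

    def test_zero_jitter_zero_noise_identical_pulses(self):
        specs = [("a", RoundedRod(R=200e-9),
                  Variability(size_cv=0.0, velocity_cv=0.0))]
        ds = ps.generate_dataset(specs, 2, noise=NoiseModel(rms=0.0), seed=0)
        a, b = ds.records
        assert np.array_equal(a.trace.samples, b.trace.samples)

    def test_invalid_variability_rejected(self):
        with pytest.raises(ValueError):
            Variability(size_cv=-0.1)


class TestGenerateMixture:
    def test_zero_concentration_all_first_class(self):
        specs = [("E", RoundedRod(R=200e-9), Variability()),
                 ("B", RoundedRod(R=1100e-9), Variability())]
        _, hidden = ps.generate_mixture(specs, c_b=0.0, n_total=10, seed=0)
        assert hidden == ["E"] * 10

    def test_equal_rates_binomial_fraction(self):
        # label-draw model at n = 10^4: fraction 0.5 within 3 standard errors
        rng = np.random.default_rng(123)
        p = ps.mixture_class_probability(1.0)
        draws = rng.random(10 ** 4) < p
        se = math.sqrt(0.25 / 10 ** 4)
        assert abs(draws.mean() - 0.5) < 3 * se

    def test_halved_capture_rate_closed_form(self):
        # C_B = 2 with B's capture rate halved: p_B = (2*0.5)/(2*0.5 + 1) = 0.5
        assert ps.mixture_class_probability(2.0, rate_e=1.0, rate_b=0.5) == \
            pytest.approx(0.5)

    def test_hidden_labels_match_record_count(self):
        specs = [("E", RoundedRod(R=200e-9), Variability()),
                 ("B", RoundedRod(R=1100e-9), Variability())]
        mix, hidden = ps.generate_mixture(specs, c_b=1.0, n_total=6, seed=2)
        assert len(mix) == len(hidden) == 6
        assert all(r.label == "" for r in mix.records)


class TestSizingArithmetic:
    def test_sensitivity_and_resolution(self):
        # (800 - 280) nm across the ~250 pA per-cocci step ~= 2 nm/pA;
        # with 13 pA rms noise the implied resolution is 2 x 13 = 26 nm
        sens = ps.current_size_sensitivity(800e-9, 280e-9, 250e-12)
        nm_per_pa = sens * 1e-12 / 1e-9
        assert round(nm_per_pa) == 2
        res = ps.size_resolution(round(nm_per_pa) * 1e-9 / 1e-12, 13e-12)
        assert res == pytest.approx(26e-9)
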