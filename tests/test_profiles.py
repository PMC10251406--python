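"""Depth-profile handling: normalization, per-spot replacement,
quadrature, photic partitioning and diel loss."""

import numpy as np
import pytest

import dielmat as dm
from dielmat import profiles as prof
from dielmat.errors import (
    DegenerateProfileError,
    NoBoundaryError,
    UndefinedLossError,
    UndefinedPartitionError,
)


def make_profile(depths, deltas, **kw):
    return dm.DepthProfile("p1", np.asarray(depths, float),
                           np.asarray(deltas, float), **kw)


class TestNormalizeDepth:
    def test_affine_map(self):
        p = dm.normalize_depth(make_profile([0, 4500, 9000], [0, 0, 0]))
        np.testing.assert_allclose(p.normalized_depths, [0, 0.5, 1])

    def test_offset_top(self):
        p = dm.normalize_depth(make_profile([100, 5100], [0, 0]))
        np.testing.assert_allclose(p.normalized_depths, [0, 1])

    def test_affine_invariance(self):
        d = np.array([120.0, 800.0, 2300.0, 9000.0])
        p1 = dm.normalize_depth(make_profile(d, np.zeros(4)))
        p2 = dm.normalize_depth(make_profile(3.7 * d + 55.0, np.zeros(4)))
        np.testing.assert_allclose(p1.normalized_depths,
                                   p2.normalized_depths, atol=1e-12)

    def test_degenerate(self):
        with pytest.raises(DegenerateProfileError):
            dm.normalize_depth(make_profile([500.0], [0.0]))


class TestReplacementProfile:
    def test_control_profile_gives_zero(self, substrates):
        p = make_profile([0, 1000, 2000], [-20.0, -20.0, -20.0])
        rp = dm.replacement_profile(p, -20.0, substrates["bicarbonate"])
        np.testing.assert_allclose(rp.percent, 0.0, atol=1e-12)
        assert not rp.flags.any()

    def test_end_member_spot_reads_100(self, substrates):
        d_top = dm.atom_fraction_to_delta(0.5 - 1e-15)
        p = make_profile([0, 1000], [d_top, -20.0])
        rp = dm.replacement_profile(p, -20.0, substrates["bicarbonate"])
        np.testing.assert_allclose(rp.percent, [100.0, 0.0], atol=1e-6)

    def test_matches_pointwise_scalar_oracle(self, rng, substrates):
        # exponential-uptake profile, checked spot by spot
        z = np.sort(rng.uniform(0, 9000, 30))
        u_true = 3.0 * np.exp(-z / 2000.0)
        f_ctrl = dm.delta_to_atom_fraction(-20.0)
        f_sample = u_true / 100 * 0.5 + (1 - u_true / 100) * f_ctrl
        deltas = dm.atom_fraction_to_delta(f_sample)
        rp = dm.replacement_profile(make_profile(z, deltas), -20.0,
                                    substrates["bicarbonate"])
        oracle = [dm.percent_replacement(
            dm.delta_to_atom_fraction(float(d)), f_ctrl, 0.5)
            for d in deltas]
        np.testing.assert_allclose(rp.percent, oracle, atol=1e-12)

    def test_interpolated_control_profile(self, substrates):
        sample = make_profile([0, 500, 1000], [-10.0, -10.0, -10.0])
        control = make_profile([0, 1000], [-10.0, -10.0])
        rp = dm.replacement_profile(sample, control,
                                    substrates["bicarbonate"])
        np.testing.assert_allclose(rp.percent, 0.0, atol=1e-12)

    def test_negative_spots_flagged_not_clipped(self, substrates):
        p = make_profile([0, 1000], [-120.0, -20.0])
        rp = dm.replacement_profile(p, -20.0, substrates["bicarbonate"])
        assert rp.percent[0] < 0 and rp.flags[0]
        assert not rp.flags[1]


def linear_interp_riemann(depths, values, n=100_000):
    """Midpoint Riemann oracle for the piecewise-linear profile."""
    xs = np.linspace(depths[0], depths[-1], n + 1)
    mid = 0.5 * (xs[:-1] + xs[1:])
    return float(np.sum(np.interp(mid, depths, values)) * np.diff(xs)[0])


class TestMeanReplacement:
    def test_uniform_profile(self):
        rp = prof.ReplacementProfile("p", np.linspace(0, 1, 7),
                                     np.full(7, 2.46), np.zeros(7, bool))
        m = dm.mean_replacement(rp)
        assert m.integrated == pytest.approx(2.46, abs=1e-12)
        assert m.spot_mean == pytest.approx(2.46, abs=1e-12)

    def test_linear_ramp(self):
        z = np.linspace(0, 1, 11)
        rp = prof.ReplacementProfile("p", z, 10 * z, np.zeros(11, bool))
        assert dm.mean_replacement(rp).integrated == pytest.approx(5.0)

    def test_matches_riemann_oracle(self, rng):
        z = np.sort(np.concatenate(([0, 1], rng.uniform(0, 1, 28))))
        y = rng.uniform(-0.5, 5.0, 30)
        rp = prof.ReplacementProfile("p", z, y, np.zeros(30, bool))
        assert dm.mean_replacement(rp).integrated == pytest.approx(
            linear_interp_riemann(z, y), abs=1e-6)


class TestPartition:
    def test_uniform_profile(self):
        rp = prof.ReplacementProfile("p", np.linspace(0, 1, 21),
                                     np.ones(21), np.zeros(21, bool))
        part = dm.partition_at_boundary(rp, 0.1)
        assert part.fraction_below == pytest.approx(0.9, abs=1e-12)
        assert part.fraction_below + part.fraction_above == pytest.approx(
            1.0, abs=1e-9)

    def test_surface_concentrated_profile(self):
        z = np.array([0.0, 0.05, 0.0500001, 1.0])
        y = np.array([10.0, 10.0, 0.0, 0.0])
        part = dm.partition_at_boundary(
            prof.ReplacementProfile("p", z, y, np.zeros(4, bool)), 0.1)
        assert part.fraction_below == pytest.approx(0.0, abs=1e-6)

    def test_matches_fine_grid_oracle(self, rng):
        z = np.sort(np.concatenate(([0, 1], rng.uniform(0, 1, 18))))
        y = rng.uniform(0.1, 4.0, 20)
        rp = prof.ReplacementProfile("p", z, y, np.zeros(20, bool))
        b = 0.37
        part = dm.partition_at_boundary(rp, b)
        total = linear_interp_riemann(z, y)
        xs = np.linspace(b, 1, 100_001)
        mid = 0.5 * (xs[:-1] + xs[1:])
        below = float(np.sum(np.interp(mid, z, y)) * np.diff(xs)[0])
        assert part.fraction_below == pytest.approx(below / total,
                                                    abs=1e-6)

    def test_boundary_monotonicity(self, rng):
        z = np.linspace(0, 1, 25)
        y = rng.uniform(0.0, 3.0, 25)
        rp = prof.ReplacementProfile("p", z, y, np.zeros(25, bool))
        fb = [dm.partition_at_boundary(rp, b).fraction_below
              for b in np.linspace(0.05, 0.95, 19)]
        assert np.all(np.diff(fb) <= 1e-12)

    def test_noise_floor_flagged(self):
        rp = prof.ReplacementProfile("p", np.array([0.0, 1.0]),
                                     np.array([1e-12, -2e-12]),
                                     np.zeros(2, bool))
        part = dm.partition_at_boundary(rp, 0.5)
        assert part.flagged and np.isnan(part.fraction_below)

    def test_negative_total_raises(self):
        rp = prof.ReplacementProfile("p", np.array([0.0, 1.0]),
                                     np.array([-5.0, -5.0]),
                                     np.zeros(2, bool))
        with pytest.raises(UndefinedPartitionError):
            dm.partition_at_boundary(rp, 0.5)


class TestBoundaryFromIrradiance:
    def test_exponential_attenuation(self):
        z = np.linspace(0, 1, 2001)
        b = dm.boundary_from_irradiance(z, 100 * np.exp(-z / 0.1), 10.0)
        assert b == pytest.approx(0.1 * np.log(10.0), abs=5e-4)

    def test_surface_already_dark(self):
        assert dm.boundary_from_irradiance([0, 1], [5.0, 1.0], 10.0) == 0.0

    def test_linear_interpolation_between_points(self):
        b = dm.boundary_from_irradiance([0.0, 0.2, 0.3], [100, 12, 8], 10.0)
        assert b == pytest.approx(0.25, abs=1e-12)

    def test_never_reaching_threshold(self):
        with pytest.raises(NoBoundaryError):
            dm.boundary_from_irradiance([0, 1], [100.0, 50.0], 10.0)

    def test_non_monotone_warns(self):
        with pytest.warns(UserWarning):
            b = dm.boundary_from_irradiance([0, 0.5, 1], [100, 5, 20], 10.0)
        assert 0 < b < 0.5


class TestDielLoss:
    @pytest.mark.parametrize("earlier, later, expected", [
        (1.0, 0.56, 44.0),
        (2.0, 2.0, 0.0),
        (1.0, 1.2, -20.0),  # net gain, reported negative
    ])
    def test_arithmetic(self, earlier, later, expected):
        assert dm.diel_loss(earlier, later) == pytest.approx(expected)

    def test_undefined_for_nonpositive_earlier(self):
        with pytest.raises(UndefinedLossError):
            dm.diel_loss(0.0, 1.0)


class TestCombineProfiles:
    def test_per_profile_then_average(self):
        m1 = prof.MeanReplacement(2.0, 2.2)
        m2 = prof.MeanReplacement(3.0, 2.8)
        combined = prof.combine_profile_means([m1, m2])
        assert combined.integrated == pytest.approx(2.5)
        assert combined.spot_mean == pytest.approx(2.5)
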