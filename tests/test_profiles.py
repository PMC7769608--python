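import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paracable.profiles import (
    IntensityProfile,
    NoParanodeError,
    ProfileFormatError,
    overlap_points,
    paranode_length_from_profile,
    proportion_overlapping_axons,
    read_profiles_csv,
    regrid_channels,
    threshold_sweep,
    write_profiles_csv,
)


def make_profile(r, g, axon_id="a"):
    n = len(r)
    return IntensityProfile(axon_id, np.arange(n) * 0.05, np.asarray(r, float), np.asarray(g, float))


def brute_force_overlap(profile, T, B):
    """Independent per-point re-implementation of the overlap rule."""
    out = []
    for i in range(len(profile.positions_um)):
        r, g = profile.red[i], profile.green[i]
        if abs(r - g) < T and r >= B and g >= B:
            out.append(i)
    return out


class TestOverlapPoints:
    def test_identical_channels_all_overlap(self):
        p = make_profile([100] * 20, [100] * 20)
        res = overlap_points(p, threshold=1.0, background_floor=0.0)
        assert res.has_overlap
        assert len(res.overlapping_indices) == 20

    def test_disjoint_channels_no_overlap(self):
        r = [200] * 10 + [0] * 10
        g = [0] * 10 + [200] * 10
        res = overlap_points(make_profile(r, g), threshold=50.0)
        assert not res.has_overlap

    def test_matches_brute_force_on_random_profiles(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            r = rng.integers(0, 256, 100)
            g = rng.integers(0, 256, 100)
            p = make_profile(r, g)
            T = float(rng.integers(1, 120))
            B = float(rng.integers(0, 60))
            res = overlap_points(p, T, B)
            assert list(res.overlapping_indices) == brute_force_overlap(p, T, B)

    def test_symmetric_in_channels(self):
        rng = np.random.default_rng(7)
        p = make_profile(rng.integers(0, 256, 50), rng.integers(0, 256, 50))
        a = overlap_points(p, 40.0)
        b = overlap_points(p.swapped(), 40.0)
        assert a.overlapping_indices == b.overlapping_indices

    def test_common_offset_invariance_with_shifted_floor(self):
        rng = np.random.default_rng(11)
        r = rng.integers(0, 150, 60).astype(float)
        g = rng.integers(0, 150, 60).astype(float)
        base = overlap_points(make_profile(r, g), 30.0, background_floor=20.0)
        shifted = overlap_points(
            make_profile(r + 40, g + 40), 30.0, background_floor=60.0
        )
        assert base.overlapping_indices == shifted.overlapping_indices

    def test_background_guard_excludes_mutual_background(self):
        p = make_profile([0] * 10, [0] * 10)
        assert overlap_points(p, 50.0, background_floor=20.0).has_overlap is False
        # the literal rule (B = 0) marks mutual background as overlap
        assert overlap_points(p, 50.0, background_floor=0.0).has_overlap is True

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ProfileFormatError):
            IntensityProfile("x", np.arange(3.0), np.zeros(3), np.zeros(4))


class TestCohortProportions:
    def test_all_and_none(self):
        same = [make_profile([100] * 5, [100] * 5, f"s{i}") for i in range(4)]
        disjoint = [
            make_profile([200, 0], [0, 200], f"d{i}") for i in range(4)
        ]
        assert proportion_overlapping_axons(same, 10.0, 0.0) == 1.0
        assert proportion_overlapping_axons(disjoint, 50.0, 0.0) == 0.0

    def test_known_dislocated_fraction_recovered(self):
        from paracable.synthetic import gen_profile_cohort

        q = 0.3
        profiles = gen_profile_cohort(40, q, noise_sd=0.0, seed=3)
        prop = proportion_overlapping_axons(profiles, 50.0, 20.0)
        assert prop == pytest.approx(q, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            proportion_overlapping_axons([], 10.0)


class TestThresholdSweep:
    def test_endpoints(self):
        rng = np.random.default_rng(5)
        profiles = [
            make_profile(rng.integers(30, 256, 50), rng.integers(30, 256, 50), f"p{i}")
            for i in range(10)
        ]
        curve = threshold_sweep(profiles, [0.0, 300.0], background_floor=0.0)
        assert curve["proportion_overlapping"].iloc[0] == 0.0  # strict inequality
        assert curve["proportion_overlapping"].iloc[-1] == 1.0

    def test_monotone_nondecreasing(self):
        rng = np.random.default_rng(9)
        profiles = [
            make_profile(rng.integers(0, 256, 80), rng.integers(0, 256, 80), f"p{i}")
            for i in range(30)
        ]
        curve = threshold_sweep(profiles, list(np.arange(0, 260, 10.0)))
        props = curve["proportion_overlapping"].to_numpy()
        assert np.all(np.diff(props) >= 0)

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValueError):
            threshold_sweep([make_profile([1], [1])], [50.0, 10.0])


class TestParanodeLength:
    def test_gaussian_band_fwhm(self):
        x = np.arange(-5, 5, 0.01)
        sigma = 0.85
        v = 200.0 * np.exp(-(x**2) / (2 * sigma**2))
        m = paranode_length_from_profile(x, v)
        assert m.length_um == pytest.approx(2.3548 * sigma, rel=1e-3)

    def test_rectangular_band_width(self):
        x = np.arange(0, 10, 0.005)
        v = np.where((x >= 3.0) & (x <= 5.3), 200.0, 0.0)
        m = paranode_length_from_profile(x, v)
        assert m.length_um == pytest.approx(2.3, abs=0.01)

    def test_all_zero_profile_raises(self):
        x = np.arange(0, 5, 0.05)
        with pytest.raises(NoParanodeError):
            paranode_length_from_profile(x, np.zeros_like(x))

    def test_fixed_level_rule(self):
        x = np.arange(0, 10, 0.005)
        v = np.where((x >= 2.0) & (x <= 6.0), 100.0, 0.0)
        m = paranode_length_from_profile(x, v, rule="fixed", fixed_level=50.0)
        assert m.length_um == pytest.approx(4.0, abs=0.01)
        with pytest.raises(ValueError):
            paranode_length_from_profile(x, v, rule="fixed")


def test_regrid_channels_aligns_different_sampling():
    xr = np.linspace(0, 10, 101)
    xg = np.linspace(0, 10, 173)
    r = np.interp(xr, [0, 5, 10], [0, 200, 0])
    g = np.interp(xg, [0, 5, 10], [0, 200, 0])
    p = regrid_channels(xr, r, xg, g, step_um=0.05)
    assert np.allclose(p.red, p.green, atol=3.0)


def test_profiles_csv_roundtrip(tmp_path):
    rng = np.random.default_rng(1)
    profiles = [
        make_profile(rng.integers(0, 256, 30), rng.integers(0, 256, 30), f"ax{i}")
        for i in range(3)
    ]
    path = tmp_path / "profiles.csv"
    write_profiles_csv(profiles, path)
    back = read_profiles_csv(path)
    assert [p.axon_id for p in back] == ["ax0", "ax1", "ax2"]
    for a, b in zip(profiles, back):
        assert np.allclose(a.red, b.red)
        assert np.allclose(a.positions_um, b.positions_um)
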