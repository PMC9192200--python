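"""Synthetic-cohort generator: grids, distributions, spectra, determinism."""

import numpy as np
import pytest

from endospec.cohort import (
    Band,
    CohortConfig,
    GroupSpec,
    ParameterError,
    BandConfigError,
    DEFAULT_BAND_LIBRARY,
    GROUP_PANEL_STATS,
    PARAM_NAMES,
    apply_group_effects,
    add_instrument_noise,
    default_config,
    default_groups,
    generate_base_spectrum,
    generate_cohort,
    lognormal_moment_matched,
    sample_biochem,
)
from endospec.grid import GridError, build_grid


class TestGrid:
    def test_default_instrument_axis(self):
        g = build_grid(400, 4000, 7469)
        assert g.n_points == 7469
        assert g.values[0] == 400 and g.values[-1] == 4000
        assert g.spacing == pytest.approx(0.48206, abs=5e-6)

    @pytest.mark.parametrize(
        "lo,hi,n,expected",
        [
            (0, 10, 11, np.arange(11.0)),
            (700, 1450, 4, np.array([700.0, 950.0, 1200.0, 1450.0])),
        ],
    )
    def test_uniform_values(self, lo, hi, n, expected):
        np.testing.assert_allclose(build_grid(lo, hi, n).values, expected)

    @pytest.mark.parametrize("lo,hi,n", [(400, 400, 5), (500, 400, 5), (0, 1, 1)])
    def test_invalid_grid_rejected(self, lo, hi, n):
        with pytest.raises(GridError):
            build_grid(lo, hi, n)


class TestLognormal:
    def test_moment_matching_against_brute_force(self, rng):
        # (m=1, s=1): sigma^2 = ln 2, mu = -ln2/2; empirical moments at 1e6
        x = lognormal_moment_matched(1.0, 1.0, 10**6, rng)
        assert x.mean() == pytest.approx(1.0, abs=0.01)
        assert x.std(ddof=1) == pytest.approx(1.0, abs=0.05)
        # direct draw with the closed-form parameters agrees
        sigma = np.sqrt(np.log(2.0))
        y = np.random.default_rng(0).lognormal(-np.log(2.0) / 2, sigma, 10**6)
        assert x.mean() == pytest.approx(y.mean(), abs=0.01)

    def test_heavy_tailed_marker_mean_recovered(self, rng):
        m, s = GROUP_PANEL_STATS["CA 125 (U/mL)"]["E"]
        x = lognormal_moment_matched(m, s, 200_000, rng)
        se = s / np.sqrt(x.size)
        assert abs(x.mean() - m) < 3 * se
        assert (x > 0).all()

    def test_zero_sd_degenerates_to_constant(self, rng):
        x = lognormal_moment_matched(5.0, 0.0, 100, rng)
        assert (x == 5.0).all()

    def test_nonpositive_mean_rejected(self, rng):
        with pytest.raises(ParameterError):
            lognormal_moment_matched(0.0, 1.0, 10, rng)


class TestBaseSpectrum:
    def test_single_band_peaks_at_nearest_grid_point(self, small_grid):
        spec = generate_base_spectrum(small_grid, [Band(1645.0, 30.0, 1.0)])
        assert np.argmax(spec) == small_grid.index_of(1645.0)

    def test_out_of_grid_band_skipped_with_warning(self, small_grid):
        with pytest.warns(UserWarning, match="outside grid"):
            spec = generate_base_spectrum(small_grid, [Band(3290.0, 60.0, 1.0)])
        assert np.all(spec == 0.0)

    def test_two_bands_integral_additive(self, small_grid):
        b1, b2 = Band(800.0, 10.0, 0.5), Band(1600.0, 10.0, 0.3)
        dx = small_grid.spacing
        i1 = np.trapezoid(generate_base_spectrum(small_grid, [b1]), dx=dx)
        i2 = np.trapezoid(generate_base_spectrum(small_grid, [b2]), dx=dx)
        i12 = np.trapezoid(generate_base_spectrum(small_grid, [b1, b2]), dx=dx)
        assert i12 == pytest.approx(i1 + i2, rel=1e-6)

    def test_nonnegative(self, small_grid):
        assert (generate_base_spectrum(small_grid, DEFAULT_BAND_LIBRARY) >= 0).all()


class TestGroupEffects:
    def test_unit_factors_are_identity(self, small_grid):
        lib = [Band(1000.0, 10.0, 0.5), Band(1200.0, 10.0, 0.2)]
        base = generate_base_spectrum(small_grid, lib)
        out = apply_group_effects(small_grid, lib, {1000.0: 1.0, 1200.0: 1.0})
        np.testing.assert_array_equal(out, base)

    def test_factor_scales_isolated_band(self, small_grid):
        lib = [Band(1000.0, 10.0, 0.5), Band(1600.0, 10.0, 0.2)]
        out = apply_group_effects(small_grid, lib, {1000.0: 2.0})
        base = generate_base_spectrum(small_grid, lib)
        # difference equals one extra copy of the single scaled band
        single = generate_base_spectrum(small_grid, [Band(1000.0, 10.0, 0.5)])
        np.testing.assert_allclose(out - base, single, atol=1e-12)

    def test_zero_factor_removes_band(self, small_grid):
        lib = [Band(1000.0, 10.0, 0.5)]
        out = apply_group_effects(small_grid, lib, {1000.0: 0.0})
        assert out[small_grid.index_of(1000.0)] == 0.0

    def test_unknown_center_rejected(self, small_grid):
        with pytest.raises(BandConfigError):
            apply_group_effects(small_grid, [Band(1000.0, 10.0, 0.5)], {999.0: 1.1})

    def test_effect_monotonicity(self, small_grid):
        lib = [Band(1000.0, 10.0, 0.5), Band(1100.0, 10.0, 0.3)]
        idx = small_grid.index_of(1000.0)
        prev = -np.inf
        for f in (0.8, 1.0, 1.3, 2.0):
            val = apply_group_effects(small_grid, lib, {1000.0: f})[idx]
            assert val > prev
            prev = val


class TestInstrumentNoise:
    def test_all_zero_noise_is_identity(self, rng):
        spec = np.linspace(0, 1, 100)
        out = add_instrument_noise(spec, 2, 0.0, 0.0, 0.0, rng)
        np.testing.assert_array_equal(out, spec)

    def test_white_noise_sd_recovered(self):
        rng = np.random.default_rng(3)
        spec = np.zeros(100)
        draws = np.stack([
            add_instrument_noise(spec, 0, 0.0, 0.0, 1e-3, rng) for _ in range(10_000)
        ])
        assert np.median(draws.std(axis=0)) == pytest.approx(1e-3, rel=0.05)

    def test_constant_baseline_offset_sd(self):
        rng = np.random.default_rng(4)
        spec = np.zeros(50)
        offsets = np.array([
            add_instrument_noise(spec, 0, 0.02, 0.0, 0.0, rng)[0]
            for _ in range(10_000)
        ])
        assert offsets.std(ddof=1) == pytest.approx(0.02, rel=0.05)


class TestCohortGeneration:
    def test_default_shapes(self):
        cohort = generate_cohort(default_config(seed=0))
        assert cohort.biochem.shape == (71, 29)
        assert cohort.spectra.shape == (71, 7469)
        assert len(cohort.labels) == 71

    def test_same_seed_bitwise_identical(self, small_grid):
        cfg = CohortConfig(groups=default_groups(sizes={"E": 3, "NE": 3, "C": 3}),
                           grid=small_grid, seed=11)
        a, b = generate_cohort(cfg), generate_cohort(cfg)
        np.testing.assert_array_equal(a.biochem, b.biochem)
        np.testing.assert_array_equal(a.spectra, b.spectra)

    def test_singleton_groups(self, small_grid):
        cfg = CohortConfig(groups=default_groups(sizes={"E": 1, "NE": 1, "C": 1}),
                           grid=small_grid, seed=1)
        cohort = generate_cohort(cfg)
        assert list(cohort.labels) == ["E", "NE", "C"]

    def test_biochem_strictly_positive(self, small_cohort):
        assert (small_cohort.biochem > 0).all()

    def test_rows_aligned(self, small_cohort):
        n = small_cohort.n_samples
        assert small_cohort.spectra.shape[0] == n == len(small_cohort.labels)

    def test_missing_parameter_rejected(self, small_grid, rng):
        g = GroupSpec("E", 2, {"CA 125 (U/mL)": 10.0}, {"CA 125 (U/mL)": 1.0})
        with pytest.raises(ParameterError, match="lacks parameter"):
            sample_biochem([g], rng)

    def test_group_moment_recovery_all_printed_markers(self):
        """Empirical mean/SD of every printed marker matches its target."""
        rng = np.random.default_rng(5)
        groups = default_groups()
        n = 100_000
        for g in groups:
            for p in GROUP_PANEL_STATS:
                m, s = g.biochem_mean[p], g.biochem_sd[p]
                x = lognormal_moment_matched(m, s, n, rng)
                assert abs(x.mean() - m) < 4 * s / np.sqrt(n), (g.name, p)

    def test_param_names_complete(self):
        assert len(PARAM_NAMES) == 29
        assert len(set(PARAM_NAMES)) == 29
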