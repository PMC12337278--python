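import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from micromrs.biomarkers import (
    DEFAULT_REGISTRY,
    build_feature_table,
    compare_cohorts,
    extract_biomarkers,
    lilliefors_mc,
    lorentzian_fit,
    mannwhitney_exact,
    region_intensity,
    region_moment_stat,
    snr,
)
from micromrs.spectra import DEFAULT_REGIONS, Spectrum
from micromrs.synthdata import CohortEffect, SynthConfig, generate_cohort, preset_config

from conftest import lorentzian

SAT = DEFAULT_REGIONS["Saturate"]


def spec_from(axis, y, **meta):
    return Spectrum(ppm=axis, intensity=y, metadata=meta, referenced=True)


class TestRegionIntensity:
    def test_unit_rectangle_integrates_to_width(self, axis):
        y = np.where((axis >= 1.15) & (axis <= 1.45), 1.0, 0.0)
        got = region_intensity(spec_from(axis, y), SAT)
        assert got == pytest.approx(0.30, abs=2 * (axis[1] - axis[0]))

    def test_zero_spectrum(self, axis):
        assert region_intensity(spec_from(axis, np.zeros_like(axis)), SAT) == 0.0

    def test_matches_truncated_lorentzian_closed_form(self, axis):
        """Trapezoidal integral agrees with A*g*[atan((hi-c)/g)+atan((c-lo)/g)]."""
        A, fwhm, c = 1.0, 0.12, 1.30
        g = fwhm / 2
        y = lorentzian(axis, c, fwhm, A)
        expected = A * g * (np.arctan((SAT[1] - c) / g) + np.arctan((c - SAT[0]) / g))
        assert region_intensity(spec_from(axis, y), SAT) == pytest.approx(expected, rel=0.005)

    def test_too_few_bins_rejected(self):
        axis = np.linspace(0, 10, 40)  # 0.26 ppm spacing -> <4 bins in Saturate
        with pytest.raises(ValueError, match="bins"):
            region_intensity(spec_from(axis, np.ones_like(axis)), SAT)


class TestRegionMoments:
    def test_symmetric_peak_has_zero_skew(self, axis):
        # tolerance covers grid discretization (peak center off-bin)
        y = lorentzian(axis, 1.30, 0.10, 2.0)
        assert region_moment_stat(spec_from(axis, y), SAT, "Skew") == pytest.approx(0.0, abs=0.01)

    def test_uniform_region_kurtosis_is_nine_fifths(self, axis):
        y = np.ones_like(axis)
        got = region_moment_stat(spec_from(axis, y), SAT, "Kurt")
        assert got == pytest.approx(1.8, abs=1e-3)

    def test_kurtosis_increases_as_line_narrows(self, axis):
        """Sharper Lorentzians give larger lineshape kurtosis over the region."""
        kurts = [
            region_moment_stat(
                spec_from(axis, lorentzian(axis, 1.30, f, 1.0)), SAT, "Kurt")
            for f in (0.20, 0.15, 0.10, 0.06)
        ]
        assert all(a < b for a, b in zip(kurts, kurts[1:]))

    def test_all_zero_region_is_error(self, axis):
        with pytest.raises(ValueError, match="all-zero"):
            region_moment_stat(spec_from(axis, np.zeros_like(axis)), SAT, "Skew")


class TestScaleAndShiftEquivariance:
    """Multiplying by s>0 scales Int/Ampl by s and leaves shape stats fixed;
    a rigid ppm shift (regions shifted too) changes nothing."""

    @pytest.fixture
    def noisy_spec(self, axis):
        rng = np.random.default_rng(8)
        y = (lorentzian(axis, 1.30, 0.12, 2.0)
             + lorentzian(axis, 0.90, 0.10, 1.0)
             + np.abs(rng.normal(0, 0.01, axis.size)))
        return spec_from(axis, y)

    def test_scale_equivariance(self, noisy_spec):
        s = 3.7
        scaled = noisy_spec.copy(intensity=noisy_spec.intensity * s)
        for region in ("Saturate", "PLC"):
            r = DEFAULT_REGIONS[region]
            assert region_intensity(scaled, r) == pytest.approx(
                s * region_intensity(noisy_spec, r), rel=1e-9)
            for kind in ("Skew", "Kurt"):
                assert region_moment_stat(scaled, r, kind) == pytest.approx(
                    region_moment_stat(noisy_spec, r, kind), rel=1e-9)
        a0, f0, *_ = lorentzian_fit(noisy_spec, DEFAULT_REGIONS["Saturate"])
        a1, f1, *_ = lorentzian_fit(scaled, DEFAULT_REGIONS["Saturate"])
        assert a1 == pytest.approx(s * a0, rel=1e-6)
        assert f1 == pytest.approx(f0, rel=1e-6)

    def test_shift_equivariance(self, noisy_spec):
        eps = 0.237
        shifted = noisy_spec.copy(ppm=noisy_spec.ppm + eps)
        for region in ("Saturate", "S1"):
            lo, hi = DEFAULT_REGIONS[region]
            assert region_intensity(shifted, (lo + eps, hi + eps)) == pytest.approx(
                region_intensity(noisy_spec, (lo, hi)), rel=1e-9)
            for kind in ("Skew", "Kurt"):
                assert region_moment_stat(shifted, (lo + eps, hi + eps), kind) == (
                    pytest.approx(region_moment_stat(noisy_spec, (lo, hi), kind),
                                  rel=1e-9))


class TestLorentzianFit:
    def test_noiseless_exact_recovery(self, axis):
        y = lorentzian(axis, 1.30, 0.12, 3.0)
        amp, fwhm, center, offset, ok = lorentzian_fit(spec_from(axis, y), SAT)
        assert ok
        assert amp == pytest.approx(3.0, rel=1e-6)
        assert fwhm == pytest.approx(0.12, rel=1e-6)
        assert center == pytest.approx(1.30, abs=1e-6)
        assert offset == pytest.approx(0.0, abs=1e-6)

    def test_noiseless_with_offset(self, axis):
        y = lorentzian(axis, 1.25, 0.08, 2.0) + 0.5
        amp, fwhm, center, offset, ok = lorentzian_fit(spec_from(axis, y), SAT)
        assert ok and offset == pytest.approx(0.5, abs=1e-4)
        assert fwhm == pytest.approx(0.08, rel=1e-4)

    def test_pure_noise_flagged(self, axis):
        rng = np.random.default_rng(3)
        y = rng.normal(0, 1.0, axis.size)
        *_, ok = lorentzian_fit(spec_from(axis, y), SAT)
        # may converge to a junk width at a bound or fail outright; never
        # silently reports a plausible converged fit of pure noise
        amp, fwhm, *_rest = lorentzian_fit(spec_from(axis, y), SAT)
        assert (not ok) or not (0.02 < fwhm < 1.0 and amp > 3.0)

    def test_noisy_recovery_within_10pct(self):
        cfg = SynthConfig(cohort_effects={"A": CohortEffect()},
                          n_per_class={"A": 20}, seed=3)
        spectra, _ = generate_cohort(cfg)
        errs = []
        for s in spectra:
            truth = {p["assignment"]: p for p in s.metadata["truth"]["peaks"]}
            tb = build_feature_table([s], ["A"])
            fitted = tb["Saturate-Width"].iloc[0]
            errs.append(abs(fitted - truth["bulk (CH2)n"]["fwhm_ppm"]))
        # median error across draws within 10% of the typical linewidth
        assert np.median(errs) < 0.1 * 0.12 + 0.01


class TestSNR:
    def test_peak_over_noise_sd(self, axis):
        rng = np.random.default_rng(1)
        noise = rng.normal(0, 1.0, axis.size)
        y = lorentzian(axis, 1.30, 0.12, 22.0) + noise
        got = snr(spec_from(axis, y))
        assert got == pytest.approx(22.0, rel=0.1)

    def test_zero_spectrum_is_error(self, axis):
        with pytest.raises(ValueError, match="SNR undefined"):
            snr(spec_from(axis, np.zeros_like(axis)))

    def test_noiseless_is_infinite_with_warning(self, axis):
        y = lorentzian(axis, 1.30, 0.12, 5.0)
        y[axis > 9.0] = 0.0
        with pytest.warns(UserWarning, match="infinite"):
            assert snr(spec_from(axis, y)) == np.inf


class TestExtraction:
    def test_identical_spectra_identical_vectors(self, water_spectrum):
        a = extract_biomarkers(water_spectrum)
        b = extract_biomarkers(water_spectrum)
        for k in DEFAULT_REGISTRY.names:
            assert a[k] == b[k]

    def test_vector_has_all_registry_entries_in_order(self, water_spectrum):
        v = extract_biomarkers(water_spectrum)
        assert [k for k in v if k in set(DEFAULT_REGISTRY.names)] == DEFAULT_REGISTRY.names

    def test_embryo_preset_table_shape(self, embryo_table):
        assert embryo_table.shape[0] == 61
        assert list(embryo_table.columns[1:15]) == DEFAULT_REGISTRY.names
        assert embryo_table["label"].value_counts().to_dict() == {"ARR": 54, "DEV": 7}

    def test_undefined_stat_is_nan_not_zero(self, axis):
        # all-negative region -> clipped to zero -> moment stats undefined
        y = np.full(axis.size, -1.0)
        y[axis > 4.6] = lorentzian(axis, 4.70, 0.08, 30.0)[axis > 4.6]
        v = extract_biomarkers(spec_from(axis, y), preprocess=False)
        assert np.isnan(v["Saturate-Skew"])
        assert "Saturate-Skew" in v["_missing"]


class TestMannWhitney:
    def test_identical_groups_p_one(self):
        assert mannwhitney_exact([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]) == 1.0

    def test_canonical_example(self):
        """{1,2,3} vs {4,5,6}: 2 of the 20 rank splits are as extreme."""
        assert mannwhitney_exact([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    @pytest.mark.parametrize("nx,ny", [(3, 3), (4, 5), (5, 5), (6, 7), (7, 7)])
    def test_matches_scipy_exact_on_tie_free_data(self, nx, ny):
        rng = np.random.default_rng(nx * 10 + ny)
        x, y = rng.normal(size=nx), rng.normal(0.5, 1, size=ny)
        ours = mannwhitney_exact(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_matches_brute_force_permutation_with_ties(self):
        """Tie-aware enumeration equals an independent label-permutation oracle."""
        x = np.array([1.0, 2.0, 2.0, 3.0])
        y = np.array([2.0, 3.0, 4.0])
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)

        def u_of(idx):
            return ranks[list(idx)].sum() - len(x) * (len(x) + 1) / 2

        mean_u = len(x) * len(y) / 2
        obs = abs(u_of(range(len(x))) - mean_u)
        hits = total = 0
        for idx in itertools.combinations(range(pooled.size), len(x)):
            total += 1
            hits += abs(u_of(idx) - mean_u) >= obs - 1e-12
        assert mannwhitney_exact(x, y) == pytest.approx(hits / total)


class TestLilliefors:
    def test_normal_data_not_rejected(self):
        rng = np.random.default_rng(0)
        p = lilliefors_mc(rng.normal(size=80), seed=1)
        assert p > 0.05

    def test_exponential_data_rejected(self):
        rng = np.random.default_rng(0)
        p = lilliefors_mc(rng.exponential(size=80), seed=1)
        assert p < 0.01

    def test_agrees_with_statsmodels_direction(self):
        """Cross-check against the table-based implementation."""
        from statsmodels.stats.diagnostic import lilliefors as sm_lf
        rng = np.random.default_rng(5)
        for data in (rng.normal(size=50), rng.uniform(size=50)):
            ours = lilliefors_mc(data, seed=2)
            _, theirs = sm_lf(data, dist="norm")
            assert (ours < 0.05) == (theirs < 0.05)


class TestCompareCohorts:
    def _table(self, a, b):
        return pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(len(a) + len(b))],
            "X": list(a) + list(b),
            "label": ["A"] * len(a) + ["B"] * len(b),
        })

    def test_tiny_groups_use_exact_mannwhitney(self):
        cmp_ = compare_cohorts(self._table([1, 2, 3], [4, 5, 6]), "X")
        assert cmp_.test_used == "Mann-Whitney-U"
        assert cmp_.p_value == pytest.approx(0.1)

    def test_normal_groups_use_welch(self):
        rng = np.random.default_rng(4)
        cmp_ = compare_cohorts(
            self._table(rng.normal(0, 1, 40), rng.normal(1, 2, 35)), "X", seed=9)
        assert cmp_.test_used == "Welch-t"
        assert cmp_.p_value < 0.05

    def test_nonnormal_group_forces_mannwhitney(self):
        rng = np.random.default_rng(4)
        cmp_ = compare_cohorts(
            self._table(rng.exponential(1, 60), rng.normal(1, 1, 60)), "X", seed=9)
        assert cmp_.test_used == "Mann-Whitney-U"

    def test_insufficient_n_is_error(self):
        with pytest.raises(ValueError, match="n >= 3"):
            compare_cohorts(self._table([1, 2], [3, 4, 5]), "X")

    def test_oocyte_preset_saturate_intensity_highly_significant(self):
        """MAT oocytes show higher saturate intensity at p < 1e-4."""
        spectra, labels = generate_cohort(preset_config("oocyte102", seed=5))
        table = build_feature_table(spectra, labels)
        cmp_ = compare_cohorts(table, "Saturate-Int", seed=5)
        mat_mean = cmp_.mean_b if cmp_.group_b == "MAT" else cmp_.mean_a
        imm_mean = cmp_.mean_a if cmp_.group_b == "MAT" else cmp_.mean_b
        assert mat_mean > imm_mean
        assert cmp_.p_value < 1e-4


class TestWaterNormalization:
    def test_water_normalization_divides_scale_carrying_values(self, water_spectrum):
        from micromrs.biomarkers import WATER_REGION, region_intensity
        raw = extract_biomarkers(water_spectrum, preprocess=False)
        norm = extract_biomarkers(water_spectrum, preprocess=False, normalize="water")
        w = region_intensity(water_spectrum, WATER_REGION)
        assert w > 0
        for name in ("PLC-Int", "Saturate-Int", "Saturate-Ampl"):
            assert norm[name] == pytest.approx(raw[name] / w, rel=1e-9)
        # shape statistics are untouched
        for name in ("PLC-Skew", "SaturateR-Kurt", "Saturate-Width"):
            assert norm[name] == pytest.approx(raw[name], rel=1e-12)

    def test_unknown_normalization_rejected(self, water_spectrum):
        with pytest.raises(ValueError, match="normalize"):
            extract_biomarkers(water_spectrum, normalize="tsp")
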