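"""Robust z-scores, group PCA, modulation index, trait statistics."""

import numpy as np
import pandas as pd
import pytest

from metapac import (
    MultichannelSeries,
    gen_trait_scores,
    modified_zscore,
    modulation_index_course,
    state_group_pca,
    trait_correlation_suite,
    two_proportion_z,
)
from metapac.stats import fdr_bh, partial_pearson, posthoc_regression


class TestModifiedZscore:
    def test_closed_form_small_example(self):
        np.testing.assert_allclose(
            modified_zscore([1.0, 2.0, 3.0]), [-0.6745, 0.0, 0.6745]
        )

    def test_median_of_output_is_zero_and_scale_invariant(self, rng):
        x = rng.standard_normal(101)
        z = modified_zscore(x)
        assert np.median(z) == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(modified_zscore(7.3 * x), z, atol=1e-10)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="deviation"):
            modified_zscore(np.ones(10))


class TestStateGroupPca:
    def test_planar_rows_have_two_nonzero_components(self, rng):
        basis = rng.standard_normal((2, 20))
        rows = rng.standard_normal((30, 2)) @ basis
        res = state_group_pca(rows, n_perm=50, robust=False, seed=0)
        assert np.all(res.explained_variance[2:] < 1e-20)

    def test_variances_sum_to_total(self, rng):
        rows = rng.standard_normal((25, 10))
        res = state_group_pca(rows, n_perm=50, robust=False, seed=0)
        centered = rows - rows.mean(axis=0)
        total = (centered**2).sum() / (rows.shape[0] - 1)
        assert res.explained_variance.sum() == pytest.approx(total)

    def test_grouped_spatial_structure_detected(self, rng):
        # two families of state topographies; after centering, the
        # between-group axis dominates and survives the channel-shuffle null
        chan = np.linspace(0, 3 * np.pi, 40)
        t1, t2 = np.sin(chan), np.cos(2 * chan)
        rows = np.vstack(
            [t1 + 0.2 * rng.standard_normal(40) for _ in range(15)]
            + [t2 + 0.2 * rng.standard_normal(40) for _ in range(15)]
        )
        res = state_group_pca(rows, n_perm=100, seed=1)
        assert res.significant[0]
        assert res.cumulative_significant_ratio > 0.5

    def test_structureless_rows_rarely_significant(self, rng):
        rows = rng.standard_normal((40, 30))
        res = state_group_pca(rows, n_perm=100, robust=False, seed=2)
        # Bonferroni makes false positives rare
        assert res.significant.sum() <= 2

    def test_too_few_permutations_rejected(self, rng):
        with pytest.raises(ValueError):
            state_group_pca(rng.standard_normal((5, 4)), n_perm=5)


class TestModulationIndex:
    @pytest.fixture(scope="class")
    def pac_channel(self):
        fs = 200.0
        t = np.arange(0, 80, 1 / fs)
        b = np.where(t < 40, 0.85, 0.15)
        slow = np.cos(2 * np.pi * t)
        x = slow + 0.5 * (1 + b * slow) * np.sin(2 * np.pi * 10 * t)
        return MultichannelSeries(x[None, :], fs), t

    def test_strong_modulation_segment_has_larger_mi(self, pac_channel):
        x, t = pac_channel
        mi, t0 = modulation_index_course(x, f_slow=1.0, f_fast=10.0)
        times = t0 + np.arange(mi.size) / x.sample_rate
        early = mi[(times > 5) & (times < 35)].mean()
        late = mi[(times > 45) & (times < 75)].mean()
        assert early > late

    def test_unmodulated_signal_has_small_mi(self, rng):
        fs = 200.0
        t = np.arange(0, 60, 1 / fs)
        x = MultichannelSeries(
            (np.cos(2 * np.pi * t) + 0.5 * np.sin(2 * np.pi * 10 * t))[None, :], fs
        )
        mi, _ = modulation_index_course(x, f_slow=1.0, f_fast=10.0, window=10.0)
        xm, _ = modulation_index_course(x, f_slow=1.0, f_fast=10.0, window=1.0)
        # phasor cancellation: longer windows drive the MI toward zero
        assert mi.mean() < xm.mean()

    def test_window_and_channel_validation(self, pac_channel, rng):
        x, _ = pac_channel
        with pytest.raises(ValueError, match="window"):
            modulation_index_course(x, 1.0, 10.0, window=1000.0)
        multi = MultichannelSeries(rng.standard_normal((2, 500)), 100.0)
        with pytest.raises(ValueError, match="single channel"):
            modulation_index_course(multi, 1.0, 10.0)


class TestTraitSuite:
    @staticmethod
    def _table(rng, n=200):
        stats = {f"x{i}": rng.standard_normal(n) for i in range(6)}
        df = pd.DataFrame(stats)
        df["y_corr"] = gen_trait_scores(df["x0"].to_numpy(), 0.6, seed=1)
        df["y_null"] = rng.standard_normal(n)
        return df

    def test_planted_partial_correlation_recovered(self, rng):
        df = self._table(rng)
        out = trait_correlation_suite(
            df, [f"x{i}" for i in range(6)], ["y_corr", "y_null"]
        )
        row = out[(out.statistic == "x0") & (out.trait == "y_corr")].iloc[0]
        assert abs(row.r - 0.6) < 0.15
        assert row.p_bonferroni >= row.p

    def test_identical_variable_has_unit_partial_r(self, rng):
        n = 60
        x = rng.standard_normal(n)
        covs = rng.standard_normal((n, 3))
        r, p = partial_pearson(x, x.copy(), covs)
        assert r == pytest.approx(1.0)
        assert p < 1e-12

    def test_posthoc_regression_degrees_of_freedom(self, rng):
        n = 52
        df = pd.DataFrame(
            {
                "k": rng.standard_normal(n),
                "alpha": rng.standard_normal(n),
                "y": rng.standard_normal(n),
            }
        )
        res = posthoc_regression(df, "y", ["k", "alpha"])
        assert res["df"] == (2, 49)
        assert set(res["loadings"]) == {"k", "alpha"}
        assert 0.0 <= res["multiple_r"] <= 1.0

    def test_collinear_predictors_rejected(self, rng):
        n = 30
        x = rng.standard_normal(n)
        df = pd.DataFrame({"a": x, "b": 2 * x, "y": rng.standard_normal(n)})
        with pytest.raises(ValueError, match="collinear"):
            posthoc_regression(df, "y", ["a", "b"])

    def test_row_order_invariance(self, rng):
        df = self._table(rng, n=80)
        cols_x = [f"x{i}" for i in range(6)]
        out1 = trait_correlation_suite(df, cols_x, ["y_corr"])
        out2 = trait_correlation_suite(
            df.sample(frac=1.0, random_state=3), cols_x, ["y_corr"]
        )
        np.testing.assert_allclose(out1.r.to_numpy(), out2.r.to_numpy(), atol=1e-12)


class TestModulationIndexTracksStates:
    def test_clean_toy_channels_significant_after_fdr(self, clean_toy):
        from scipy import stats as sstats

        spec, series, _, b = clean_toy
        pvalues = []
        for ch in range(series.n_channels):
            x = MultichannelSeries(series.data[ch : ch + 1], spec.sample_rate)
            mi, t0 = modulation_index_course(x, spec.f_slow, spec.f_fast)
            offset = int(round(t0 * spec.sample_rate))
            truth = b[offset : offset + mi.size]
            n = min(mi.size, truth.size)
            # correlate on a decimated grid so samples are roughly independent
            step = int(spec.sample_rate)  # one per second
            r, p = sstats.pearsonr(mi[:n:step], truth[:n:step])
            assert r > 0.8
            pvalues.append(p)
        assert fdr_bh(np.array(pvalues), q=0.05).all()


class TestMultipleComparisons:
    def test_bh_rejections_superset_of_bonferroni(self, rng):
        p = np.concatenate([rng.uniform(0, 0.002, 5), rng.uniform(0.2, 1, 45)])
        bh = fdr_bh(p, q=0.05)
        bonf = p < 0.05 / p.size
        assert np.all(bh[bonf])


class TestTwoProportionZ:
    def test_equal_proportions_give_zero(self):
        z, p = two_proportion_z(30, 60, 25, 50)
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_model_rejection_contrast_arithmetic(self):
        # pooled z for 74/95 vs 45/95 (direct arithmetic oracle: pooled
        # p = 119/190, se = sqrt(p(1-p)*2/95), z = (74-45)/95 / se)
        z, p = two_proportion_z(74, 95, 45, 95)
        pool = 119 / 190
        se = np.sqrt(pool * (1 - pool) * 2 / 95)
        assert z == pytest.approx((29 / 95) / se)
        assert z == pytest.approx(4.35, abs=0.01)
        assert p < 1e-4

    def test_antisymmetry_and_validation(self):
        za, _ = two_proportion_z(10, 20, 15, 20)
        zb, _ = two_proportion_z(15, 20, 10, 20)
        assert za == pytest.approx(-zb)
        with pytest.raises(ValueError):
            two_proportion_z(21, 20, 5, 20)
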