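"""Genome scans: Mahalanobis RDA scan, random-forest scan, whitening,
outlier selection."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import localadapt as la
from localadapt._forest import forest_oob_r2


class TestRDAScan:
    def test_null_lambda_and_uniform_pvalues(self, null_freqs, null_climate):
        s = la.rda_scan(null_freqs, null_climate, K=2)
        assert 0.8 <= s.lambda_ <= 1.2
        assert stats.kstest(s.pvalues_, "uniform").pvalue > 0.01

    def test_identical_loci_identical_statistic(self, null_freqs, null_climate):
        f = null_freqs.copy()
        f["dup"] = f.iloc[:, 0]
        s = la.rda_scan(f, null_climate, K=2)
        assert s.d2_.iloc[0] == pytest.approx(s.d2_["dup"])
        assert s.pvalues_.iloc[0] == pytest.approx(s.pvalues_["dup"])

    def test_k_bounds(self, null_freqs, null_climate):
        with pytest.raises(ValueError):
            la.rda_scan(null_freqs, null_climate, K=0)
        with pytest.raises(ValueError):
            la.rda_scan(null_freqs, null_climate, K=12)

    def test_lambda_variants_agree_on_null(self, null_freqs, null_climate):
        med = la.RDAGenomeScan(n_axes=2).fit(null_freqs, null_climate)
        mean = la.RDAGenomeScan(n_axes=2, lambda_method="mean").fit(
            null_freqs, null_climate)
        robust = la.RDAGenomeScan(n_axes=2, robust=True).fit(
            null_freqs, null_climate)
        for s in (med, mean, robust):
            assert 0.8 <= s.lambda_ <= 1.2
        # same loadings, different covariance: rankings nearly coincide
        assert med.d2_.corr(robust.d2_, method="spearman") > 0.95

    def test_pvalues_in_unit_interval(self, small_freqs, small_truth):
        s = la.rda_scan(small_freqs, small_truth.climate, K=2)
        assert ((s.pvalues_ > 0) & (s.pvalues_ <= 1)).all()
        assert len(s.d2_) == small_freqs.shape[1]


class TestRandomForestScan:
    def test_monotone_signal_high_r2(self, rng):
        clim = pd.DataFrame(rng.normal(size=(64, 11)), columns=la.CLIMATE_VARS)
        f = pd.DataFrame({
            "signal": 0.5 + 0.4 * np.tanh(clim["DD_0"]),
            "noise": rng.uniform(0.2, 0.8, 64)})
        s = la.RandomForestScan(n_trees=300, mtry=6, random_state=1).fit(f, clim)
        assert s.r2_["signal"] > 0.8
        assert s.r2_["noise"] < 0.35

    def test_pure_noise_r2_near_zero(self, rng):
        clim = pd.DataFrame(rng.normal(size=(64, 11)), columns=la.CLIMATE_VARS)
        means = []
        for rep in range(20):
            f = pd.DataFrame({"l": np.random.default_rng(rep).uniform(0.2, 0.8, 64)})
            s = la.rf_scan(f, clim, n_trees=100, seed=rep)
            means.append(s.r2_["l"])
        assert np.mean(means) <= 0.1

    def test_same_seed_identical(self, null_freqs, null_climate):
        f = null_freqs.iloc[:, :50]
        s1 = la.rf_scan(f, null_climate, n_trees=100, seed=9)
        s2 = la.rf_scan(f, null_climate, n_trees=100, seed=9)
        pd.testing.assert_series_equal(s1.r2_, s2.r2_)

    def test_matches_sklearn_oob_behaviour(self, rng):
        """Cross-check against sklearn's RandomForestRegressor OOB score on
        matched signal/noise inputs (both stochastic; compare coarsely)."""
        from sklearn.ensemble import RandomForestRegressor
        X = rng.normal(size=(64, 11))
        y_sig = 0.9 * X[:, 0] + 0.2 * rng.normal(size=64)
        y_noise = rng.normal(size=64)
        for y in (y_sig, y_noise):
            skl = RandomForestRegressor(n_estimators=500, oob_score=True,
                                        max_features=3, min_samples_leaf=5,
                                        random_state=0).fit(X, y).oob_score_
            ours = forest_oob_r2(X, y, n_trees=500, seed=1)[0]
            assert abs(skl - ours) < 0.15

    def test_too_few_localities_rejected(self, rng):
        clim = pd.DataFrame(rng.normal(size=(5, 11)), columns=la.CLIMATE_VARS)
        f = pd.DataFrame(rng.uniform(0.2, 0.8, size=(5, 3)))
        with pytest.raises(ValueError, match="localities"):
            la.rf_scan(f, clim)

    def test_min_trees_enforced(self, null_freqs, null_climate):
        with pytest.raises(ValueError, match="n_trees"):
            la.rf_scan(null_freqs.iloc[:, :5], null_climate, n_trees=50)


class TestWhitening:
    def test_independent_localities_nearly_unchanged(self, rng):
        """With no shared structure the whitener is close to the identity:
        output stays near the centred/scaled input."""
        # Bernoulli-sampled locality frequencies: per-locus variance equals
        # pbar(1-pbar), so the standardized covariance is ~identity
        p = rng.uniform(0.3, 0.7, 10_000)
        f = pd.DataFrame(rng.binomial(1, p, size=(64, 10_000)).astype(float))
        poly = (f.mean() > 0) & (f.mean() < 1)
        f = f.loc[:, poly]
        corrected, omega = la.standardize_freqs(f, shrinkage=0.1)
        pbar = f.mean()
        z = (f - pbar) / np.sqrt(pbar * (1 - pbar))
        # per-locus centring leaves a -1/(n-1) structural covariance between
        # localities, so exact identity is out of reach; the whitener must
        # still leave values essentially unchanged
        diff = np.abs(corrected.to_numpy() - z.to_numpy())
        assert np.median(diff) < 0.1
        off = omega.to_numpy() - np.diag(np.diag(omega))
        assert np.abs(off).max() < 0.1
        assert np.abs(np.diag(omega) - 1).max() < 0.15

    def test_block_structure_whitened_to_identity(self, rng):
        """Whitening property: the non-degenerate spectrum of the output
        covariance is within 0.1 of 1 (per-locus centring fixes one linear
        combination exactly, so one eigenvalue is structurally zero)."""
        n, L = 64, 10_000
        blocks = np.repeat(np.arange(4), 16)
        sigma = 0.2 * np.eye(n) + 0.8 * (blocks[:, None] == blocks[None, :])
        a = np.linalg.cholesky(sigma)
        z = a @ rng.normal(size=(n, L)) * 0.08
        f = pd.DataFrame(np.clip(0.5 + z, 0.01, 0.99))
        corrected, _ = la.standardize_freqs(f, shrinkage=0.01)
        ev = np.linalg.eigvalsh(np.cov(corrected.to_numpy()))
        assert np.abs(ev[1:] - 1).max() < 0.1

    def test_not_positive_definite_advises_shrinkage(self, rng):
        f = pd.DataFrame(rng.uniform(0.3, 0.7, size=(30, 10)))  # loci < localities
        with pytest.raises(ValueError, match="shrinkage"):
            la.standardize_freqs(f, shrinkage=0.0)

    def test_correction_reduces_structure_driven_r2(self, small_freqs, small_truth):
        """On a collinear landscape, whitening lowers the strongest
        per-locus climate R-squared (raw-vs-corrected contrast)."""
        clim = small_truth.climate
        loci = list(small_truth.loci_with_label("clinal"))[:20]
        raw = la.rf_scan(small_freqs[loci], clim, n_trees=100, seed=3)
        fw = la.FrequencyWhitener(shrinkage=0.1).fit(small_freqs)
        corr = la.RandomForestScan(n_trees=100, random_state=3,
                                   correction="corrected").fit(
            fw.transform(small_freqs)[loci], clim)
        assert corr.r2_.max() < raw.r2_.max()


class TestSelectOutliers:
    def test_study_scale_count(self, rng):
        stats_ser = pd.Series(rng.normal(size=335_588))
        out = la.select_outliers({"m1": stats_ser, "m2": stats_ser}, q=0.002, m=2)
        assert all(c == 671 for c in out.counts.values())

    def test_enumeration_intersection(self):
        loci = list("abcd")
        scans = {
            "s1": pd.Series([4.0, 3.0, 0.0, 0.0], index=loci),  # top2 {a,b}
            "s2": pd.Series([0.0, 4.0, 3.0, 0.0], index=loci),  # top2 {b,c}
            "s3": pd.Series([3.0, 0.0, 4.0, 0.0], index=loci),  # top2 {c,a}
            "s4": pd.Series([0.0, 0.0, 0.0, 4.0], index=loci),  # top2 {d,...}
        }
        out = la.select_outliers(scans, q=0.5, m=2)
        assert set(out.intersection) == {"a", "b", "c"}

    def test_q_selecting_everything(self, rng):
        s = pd.Series(rng.normal(size=10))
        out = la.select_outliers({"m": s}, q=1.0, m=1)
        assert len(out.per_method["m"]) == 10

    def test_ties_broken_by_locus_order(self):
        s = pd.Series([1.0, 1.0, 1.0, 0.0], index=list("abcd"))
        out = la.select_outliers({"m": s}, q=0.5, m=1)
        assert list(out.per_method["m"]) == ["a", "b"]

    def test_mismatched_locus_sets_rejected(self):
        s1 = pd.Series([1.0, 2.0], index=["a", "b"])
        s2 = pd.Series([1.0, 2.0], index=["a", "c"])
        with pytest.raises(ValueError, match="locus set"):
            la.select_outliers({"s1": s1, "s2": s2}, q=0.5, m=1)

    def test_all_neutral_fraction_and_intersection(self, rng):
        """False-positive control: each method picks exactly floor(qN) loci
        and the >= 2-method intersection is far smaller on independent
        null statistics."""
        n = 5000
        idx = pd.RangeIndex(n)
        scans = {f"m{i}": pd.Series(rng.normal(size=n), index=idx) for i in range(4)}
        out = la.select_outliers(scans, q=0.01, m=2)
        assert all(c == 50 for c in out.counts.values())
        assert len(out.intersection) < 10
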