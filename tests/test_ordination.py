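"""RDA engine, permutation tests, variance partitioning, dbMEM, genetic PCA."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import localadapt as la


def brute_force_rda(Y, X, condition=None):
    """Independent oracle: explicit least squares, then eigendecomposition
    of the fitted-value cross-product."""
    Yc = Y - Y.mean(axis=0)
    Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    if condition is not None:
        Zs = (condition - condition.mean(axis=0)) / condition.std(axis=0, ddof=1)
        Hz = Zs @ np.linalg.pinv(Zs)
        Yc = Yc - Hz @ Yc
        Xs = Xs - Hz @ Xs
    Yhat = Xs @ np.linalg.pinv(Xs) @ Yc
    eig, vec = np.linalg.eigh(Yhat.T @ Yhat)
    order = np.argsort(eig)[::-1]
    return eig[order], vec[:, order], float((Yhat**2).sum()), float((Yc**2).sum())


class TestRDA:
    def test_identical_response_and_predictors(self, rng):
        X = rng.normal(size=(8, 3))
        m = la.RDA().fit(X, X.copy())
        assert m.constrained_inertia_ == pytest.approx(m.total_inertia_)
        assert m.r2_ == pytest.approx(1.0)

    def test_condition_equal_to_predictors_kills_pure_model(self, rng):
        X = rng.normal(size=(10, 3))
        Y = rng.normal(size=(10, 5))
        m = la.RDA().fit(X, Y, condition=X)
        assert m.constrained_inertia_ == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("trial", range(50))
    def test_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = rng.integers(6, 12)
        p = rng.integers(1, 4)
        q = rng.integers(2, 7)
        Y = rng.normal(size=(n, q))
        X = rng.normal(size=(n, p))
        m = la.RDA().fit(X, Y)
        eig, _, cons, tot = brute_force_rda(Y, X)
        k = m.n_components_
        np.testing.assert_allclose(m.eigenvalues_, eig[:k], atol=1e-8)
        assert m.constrained_inertia_ == pytest.approx(cons, abs=1e-8)
        assert m.total_inertia_ == pytest.approx(tot, abs=1e-8)
        # site scores equal X_std @ coefs by construction; check vs oracle
        recon = m.site_scores_.to_numpy()
        assert np.allclose((recon**2).sum(), m.eigenvalues_.sum(), atol=1e-8)

    def test_partial_matches_oracle(self, rng):
        Y = rng.normal(size=(12, 6))
        X = rng.normal(size=(12, 2))
        Z = rng.normal(size=(12, 2))
        m = la.RDA().fit(X, Y, condition=Z)
        eig, _, cons, _ = brute_force_rda(Y, X, condition=Z)
        np.testing.assert_allclose(m.eigenvalues_, eig[: m.n_components_], atol=1e-8)
        assert m.constrained_inertia_ == pytest.approx(cons, abs=1e-8)

    def test_eigenvalues_nonincreasing_and_bounds(self, small_freqs, small_truth):
        m = la.RDA().fit(small_truth.climate, small_freqs)
        assert (np.diff(m.eigenvalues_) <= 1e-9).all()
        assert (m.eigenvalues_ >= 0).all()
        assert m.constrained_inertia_ <= m.total_inertia_ + 1e-9

    def test_constant_predictor_named(self, rng):
        X = np.column_stack([rng.normal(size=6), np.ones(6)])
        with pytest.raises(ValueError, match="x1"):
            la.RDA().fit(X, rng.normal(size=(6, 3)))

    def test_more_predictors_than_rows(self, rng):
        with pytest.raises(ValueError, match="predictors"):
            la.RDA().fit(rng.normal(size=(5, 7)), rng.normal(size=(5, 3)))

    def test_matches_vegan(self, rng, tmp_path):
        """Cross-check constrained eigenvalues against vegan::rda (R)."""
        Y = rng.normal(size=(8, 4))
        X = rng.normal(size=(8, 2))
        np.savetxt(tmp_path / "Y.csv", Y, delimiter=",")
        np.savetxt(tmp_path / "X.csv", X, delimiter=",")
        script = textwrap.dedent(f"""
            suppressMessages(library(vegan))
            Y <- as.matrix(read.csv("{tmp_path}/Y.csv", header=FALSE))
            X <- scale(as.matrix(read.csv("{tmp_path}/X.csv", header=FALSE)))
            m <- rda(Y ~ X)
            cat(m$CCA$eig, sep="\\n")
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=120)
        assert out.returncode == 0, out.stderr
        vegan_eig = np.array([float(v) for v in out.stdout.split()])
        m = la.RDA().fit(X, Y)
        # vegan reports variance-scaled eigenvalues (sum of squares / (n-1))
        np.testing.assert_allclose(m.eigenvalues_ / (len(Y) - 1), vegan_eig,
                                   rtol=1e-6)


class TestPermutationTest:
    def test_perfect_association_minimum_p(self, rng):
        X = rng.normal(size=(12, 2))
        p = la.permutation_test(pd.DataFrame(X), X, n_perm=99, seed=0)
        assert p == pytest.approx(1 / 100)

    def test_same_seed_same_p(self, rng):
        Y = rng.normal(size=(15, 4))
        X = rng.normal(size=(15, 2))
        p1 = la.permutation_test(Y, X, n_perm=99, seed=5)
        p2 = la.permutation_test(Y, X, n_perm=99, seed=5)
        assert p1 == p2

    def test_type_i_error_calibration(self):
        """Null rejection rate at alpha=0.05 within the binomial CI over
        200 seeded replicates."""
        hits = 0
        n_rep = 200
        for rep in range(n_rep):
            rng = np.random.default_rng(20_000 + rep)
            Y = rng.normal(size=(18, 5))
            X = rng.normal(size=(18, 2))
            if la.permutation_test(Y, X, n_perm=99, seed=rep) <= 0.05:
                hits += 1
        lo, hi = stats.binom.interval(0.999, n_rep, 0.05)
        assert lo <= hits <= hi


class TestVariancePartition:
    def test_printed_inertia_bookkeeping(self):
        t = la.partition_from_inertias(1154.8, 394.5, 143.1, 94.3, 2812.6)
        assert round(100 * t.loc["full", "prop_total"]) == 41
        assert round(100 * t.loc["pure_climate", "prop_explainable"]) == 34
        assert round(100 * t.loc["confounded", "prop_explainable"]) == 45
        assert round(100 * t.loc["pure_geography", "prop_explainable"]) == 12
        assert round(100 * t.loc["pure_ancestry", "prop_explainable"]) == 8

    def test_orthogonal_groups_no_confounding(self):
        # predictor groups built on disjoint orthonormal centred directions
        # (centring first keeps them orthogonal after internal standardization)
        a = np.random.default_rng(3).normal(size=(12, 6))
        q, _ = np.linalg.qr(a - a.mean(axis=0))
        clim, geog, anc = q[:, :2], q[:, 2:4], q[:, 4:6]
        Y = (clim @ np.ones((2, 4)) + 2 * geog @ np.ones((2, 4))
             + 3 * anc @ np.ones((2, 4)))
        t = la.variance_partition(Y, clim, geog, anc, n_perm=0)
        assert abs(t.loc["confounded", "inertia"]) < 1e-8

    def test_duplicated_group_fully_confounded(self, rng):
        clim = rng.normal(size=(10, 2))
        anc = rng.normal(size=(10, 1))
        Y = rng.normal(size=(10, 5))
        t = la.variance_partition(Y, clim, clim.copy(), anc, n_perm=0)
        assert t.loc["pure_climate", "inertia"] == pytest.approx(0.0, abs=1e-8)
        assert t.loc["pure_geography", "inertia"] == pytest.approx(0.0, abs=1e-8)

    def test_decomposition_identities_on_simulaccording(self, small_freqs, small_truth):
        mems = la.dbmem(small_truth.localities, n_keep=3)
        pca = la.genetic_pca(small_truth.dosages, small_truth.membership)
        t = la.variance_partition(small_freqs, small_truth.climate,
                                  mems.vectors, pca.locality_scores, n_perm=0)
        pure = t.loc[["pure_climate", "pure_geography", "pure_ancestry"], "inertia"].sum()
        assert pure + t.loc["confounded", "inertia"] == pytest.approx(
            t.loc["full", "inertia"], abs=1e-6)
        assert t.loc["full", "inertia"] + t.loc["unexplained", "inertia"] == pytest.approx(
            t.loc["total", "inertia"], abs=1e-6)
        assert ((t["prop_total"].dropna() >= -1e-9)
                & (t["prop_total"].dropna() <= 1 + 1e-9)).all()

    def test_collinearity_knob_monotone(self):
        """Stronger drift alignment with the gradient -> larger confounded
        fraction of explainable inertia."""
        fracs = []
        for align in (0.0, 0.3, 0.6):
            cfg = la.SimulationConfig(n_neutral_loci=1500, n_clinal_loci=0,
                                      n_threshold_loci=0, n_families=128,
                                      n_effect_loci=0, drift_alignment=align,
                                      seed=11)
            truth = la.simulate_landscape(cfg)
            mems = la.dbmem(truth.localities, n_keep=3)
            zc = truth.freqs - truth.freqs.mean()
            u, s, _ = np.linalg.svd(zc.to_numpy(), full_matrices=False)
            anc = pd.DataFrame(u[:, :2] * s[:2], index=truth.freqs.index)
            t = la.variance_partition(truth.freqs, truth.climate,
                                      mems.vectors, anc, n_perm=0)
            fracs.append(t.loc["confounded", "prop_explainable"])
        assert fracs[0] < fracs[1] < fracs[2]


class TestDbmem:
    def test_transect_first_vector_one_sign_change(self):
        coords = pd.DataFrame({"longitude": np.zeros(10),
                               "latitude": np.arange(10.0)})
        mem = la.dbmem(coords)
        signs = np.sign(mem.vectors.iloc[:, 0].to_numpy())
        changes = int((np.diff(signs[signs != 0]) != 0).sum())
        assert changes == 1

    def test_orthogonality(self, small_truth):
        mem = la.dbmem(small_truth.localities)
        v = mem.vectors.to_numpy()
        g = v.T @ v
        off = g - np.diag(np.diag(g))
        assert np.abs(off).max() < 1e-10

    def test_n_keep_three(self, small_truth):
        mem = la.dbmem(small_truth.localities, n_keep=3)
        assert mem.vectors.shape[1] == 3
        assert (np.diff(mem.eigenvalues) <= 1e-12).all()

    def test_coincident_points_rejected(self):
        coords = pd.DataFrame({"longitude": [1.0] * 4, "latitude": [2.0] * 4})
        with pytest.raises(ValueError, match="coincide"):
            la.dbmem(coords)


class TestGeneticPCA:
    def test_two_groups_separate_on_pc1(self):
        d = pd.DataFrame(np.vstack([np.tile([0.0, 0.0, 2.0], (5, 1)),
                                    np.tile([2.0, 2.0, 0.0], (5, 1))]),
                         index=[f"i{j}" for j in range(10)])
        res = la.genetic_pca(d)
        pc1 = res.scores["PC1"]
        assert pc1.iloc[:5].std() == pytest.approx(0.0, abs=1e-10)
        assert abs(pc1.iloc[0] - pc1.iloc[-1]) > 0.1

    def test_locality_score_is_member_mean(self, small_truth):
        res = la.genetic_pca(small_truth.dosages, small_truth.membership)
        manual = res.scores.groupby(small_truth.membership).mean()
        pd.testing.assert_frame_equal(
            res.locality_scores, manual.loc[res.locality_scores.index])

    def test_eigenvalues_nonnegative(self, small_truth):
        res = la.genetic_pca(small_truth.dosages)
        assert (res.eigenvalues >= -1e-10).all()

    def test_single_locus_rejected(self):
        d = pd.DataFrame({"l1": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError, match="locus"):
            la.genetic_pca(d)
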