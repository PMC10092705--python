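"""Constrained ordination: RDA, partial RDA, permutation tests, variance
partitioning, dbMEM spatial eigenvectors and genetic PCA.

Redundancy analysis (RDA) is a PCA of the fitted values of a multivariate
least-squares regression of a response matrix ``Y`` (here: locality allele
frequencies, centred but never standardized) on a predictor matrix ``X``
(standardized internally).  A *partial* RDA first residualizes both ``Y``
and ``X`` on a conditioning matrix, so the constrained axes capture only
variation independent of the condition.  Inertia is the sum of squared
centred values; the constrained inertia is the part captured by the
predictors.

Variance partitioning decomposes the explainable inertia of a full model
``Y ~ climate + geography + ancestry`` into the three pure (conditioned)
contributions and a confounded remainder — the quantity of interest when
demography, geography and climate covary along an expansion route.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator

__all__ = [
    "RDA", "rda", "permutation_test", "variance_partition",
    "partition_from_inertias", "dbmem", "SpatialEigenvectors",
    "genetic_pca", "GeneticPCAResult",
]

_EIG_TOL = 1e-9


def _as_matrix(x, name):
    if isinstance(x, (pd.DataFrame, pd.Series)):
        cols = list(x.columns) if isinstance(x, pd.DataFrame) else [x.name]
        return np.asarray(x, dtype=float).reshape(len(x), -1), cols
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"{name}{i}" for i in range(arr.shape[1])]


def _standardize_columns(x, names):
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    const = np.flatnonzero(sd == 0)
    if const.size:
        raise ValueError(f"constant predictor column: {names[const[0]]!r}")
    return (x - mean) / sd, mean, sd


class RDA(BaseEstimator):
    """Redundancy analysis of a response matrix on predictors.

    Parameters
    ----------
    n_components : int or None
        Number of constrained axes to retain (default: all with eigenvalue
        above numerical tolerance).
    scale_predictors : bool
        Standardize predictor (and conditioning) columns to unit variance.
        The response is always centred and never scaled.

    Attributes
    ----------
    eigenvalues_ : ndarray — per-axis constrained eigenvalues (sum of squares
        of fitted values along the axis), non-increasing.
    site_scores_ : DataFrame — rows of ``Y`` in constrained-axis space
        (linear-combination scores, ``X @ coefs_``).
    loadings_ : DataFrame — response-column (locus) loadings; orthonormal
        right singular vectors of the fitted values.
    predictor_coefs_ : DataFrame — coefficients of each constrained axis on
        the standardized predictors; site scores equal
        ``X_std @ predictor_coefs_`` exactly, which is what landscape
        projection uses.
    biplot_scores_ : DataFrame — correlations of standardized predictors with
        site scores, for interpreting which variables drive each axis.
    constrained_inertia_, conditioned_inertia_, total_inertia_ : float
    proportion_explained_ : ndarray — eigenvalues / constrained inertia.
    """

    def __init__(self, n_components: int | None = None, scale_predictors: bool = True):
        self.n_components = n_components
        self.scale_predictors = scale_predictors

    def fit(self, X, Y, condition=None):
        Ymat, y_names = _as_matrix(Y, "y")
        Xmat, x_names = _as_matrix(X, "x")
        self.feature_names_in_ = list(x_names)
        n = Ymat.shape[0]
        if Xmat.shape[0] != n:
            raise ValueError("X and Y row counts differ")
        self._y_index = Y.index if isinstance(Y, pd.DataFrame) else pd.RangeIndex(n)

        Yc = Ymat - Ymat.mean(axis=0)
        self.total_inertia_ = float(np.sum(Yc**2))

        if self.scale_predictors:
            Xs, self.x_mean_, self.x_scale_ = _standardize_columns(Xmat, x_names)
        else:
            self.x_mean_ = Xmat.mean(axis=0)
            self.x_scale_ = np.ones(Xmat.shape[1])
            Xs = Xmat - self.x_mean_

        self.conditioned_inertia_ = 0.0
        if condition is not None:
            Zmat, z_names = _as_matrix(condition, "z")
            if Zmat.shape[0] != n:
                raise ValueError("condition and Y row counts differ")
            if self.scale_predictors:
                Zs, _, _ = _standardize_columns(Zmat, z_names)
            else:
                Zs = Zmat - Zmat.mean(axis=0)
            qz, _ = np.linalg.qr(Zs)
            Yfit_cond = qz @ (qz.T @ Yc)
            Yc = Yc - Yfit_cond
            Xs = Xs - qz @ (qz.T @ Xs)
            self.conditioned_inertia_ = float(np.sum(Yfit_cond**2))

        n_pred = np.linalg.matrix_rank(Xs)
        if Xs.shape[1] >= n:
            raise ValueError(
                f"more predictors ({Xs.shape[1]}) than rows ({n}); RDA is underdetermined"
            )

        # least squares with an absolute rank cutoff: predictor columns
        # annihilated by the conditioning step must not resurface as noise
        ux, sx, vtx = np.linalg.svd(Xs, full_matrices=False)
        keep = sx > 1e-8 * np.sqrt(n)
        coef = (vtx[keep].T / sx[keep]) @ (ux[:, keep].T @ Yc)
        Yhat = Xs @ coef
        u, s, vt = np.linalg.svd(Yhat, full_matrices=False)
        rank = min(n_pred, Ymat.shape[1], int(np.sum(s > _EIG_TOL * max(s[0], 1.0))))
        k = rank if self.n_components is None else min(self.n_components, rank)

        # reproducible axis orientation: largest-|loading| entry positive
        for j in range(k):
            i = np.argmax(np.abs(vt[j]))
            if vt[j, i] < 0:
                vt[j] *= -1
                u[:, j] *= -1

        eig = s**2
        self.n_components_ = k
        self.eigenvalues_ = eig[:k]
        self.constrained_inertia_ = float(np.sum(Yhat**2))
        self.proportion_explained_ = (
            self.eigenvalues_ / self.constrained_inertia_
            if self.constrained_inertia_ > 0 else np.zeros(k)
        )
        axes = [f"RDA{i + 1}" for i in range(k)]
        self.loadings_ = pd.DataFrame(vt[:k].T, index=y_names, columns=axes)
        self.site_scores_ = pd.DataFrame(
            u[:, :k] * s[:k], index=self._y_index, columns=axes)
        self.predictor_coefs_ = pd.DataFrame(
            coef @ vt[:k].T, index=x_names, columns=axes)
        with np.errstate(invalid="ignore", divide="ignore"):
            bip = np.corrcoef(Xs, u[:, :k] * s[:k], rowvar=False)[: Xs.shape[1], Xs.shape[1]:]
        self.biplot_scores_ = pd.DataFrame(bip, index=x_names, columns=axes)
        return self

    def transform(self, X) -> pd.DataFrame:
        """Project new predictor rows onto the constrained axes.

        Standardization uses the training means/sds; only valid for
        unconditioned models (the condition residualization is not
        transferable to new sites).
        """
        if self.conditioned_inertia_ != 0:
            raise ValueError("transform is only defined for unconditioned RDA")
        Xmat, _ = _as_matrix(X, "x")
        Xs = (Xmat - self.x_mean_) / self.x_scale_
        out = Xs @ self.predictor_coefs_.to_numpy()
        idx = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(Xmat))
        return pd.DataFrame(out, index=idx, columns=self.predictor_coefs_.columns)

    @property
    def r2_(self) -> float:
        denom = self.total_inertia_ - self.conditioned_inertia_
        return self.constrained_inertia_ / denom if denom > 0 else 0.0


def rda(Y, X, condition=None, n_components=None) -> RDA:
    """Functional wrapper around :class:`RDA` (note the Y-first signature)."""
    return RDA(n_components=n_components).fit(X, Y, condition=condition)


def _prep_perm(Y, X, condition):
    """Precompute projection bases for fast permutation of constrained inertia."""
    Ymat, _ = _as_matrix(Y, "y")
    Xmat, x_names = _as_matrix(X, "x")
    Yc = Ymat - Ymat.mean(axis=0)
    Xs, _, _ = _standardize_columns(Xmat, x_names)
    if condition is not None:
        Zmat, z_names = _as_matrix(condition, "z")
        Zs, _, _ = _standardize_columns(Zmat, z_names)
        qz, _ = np.linalg.qr(Zs)
        Yfit = qz @ (qz.T @ Yc)
        Yres = Yc - Yfit
        Xs = Xs - qz @ (qz.T @ Xs)
    else:
        Yfit = np.zeros_like(Yc)
        Yres = Yc
    ux, sx, _ = np.linalg.svd(Xs, full_matrices=False)
    qx = ux[:, sx > 1e-8 * np.sqrt(Xs.shape[0])]
    return Yfit, Yres, qx


def permutation_test(Y, X, condition=None, n_perm: int = 999, seed=None) -> float:
    """Permutation p-value for the constrained inertia of a (partial) RDA.

    Rows of ``Y`` are permuted freely; for partial models the residuals of
    the conditioned fit are permuted and added back to the conditional
    fitted values (residual permutation under the reduced model).
    ``p = (1 + #{permuted >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    rng = np.random.default_rng(seed)
    Yfit, Yres, qx = _prep_perm(Y, X, condition)
    n = Yres.shape[0]

    def stat(resid):
        Ytot = Yfit + resid
        Ytot = Ytot - Ytot.mean(axis=0)
        return float(np.sum((qx.T @ Ytot) ** 2))

    observed = stat(Yres)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if stat(Yres[perm]) >= observed - 1e-12 * max(observed, 1.0):
            hits += 1
    return (1 + hits) / (1 + n_perm)


def partition_from_inertias(full, pure_climate, pure_geography, pure_ancestry,
                            total, p_values=None) -> pd.DataFrame:
    """Variance-partition bookkeeping from already-computed inertias.

    Confounded inertia = full - (pure climate + pure geography + pure
    ancestry); unexplained = total - full.  Reports each term as a
    proportion of the explainable (full-model) inertia and of the total.
    """
    confounded = full - (pure_climate + pure_geography + pure_ancestry)
    unexplained = total - full
    rows = {
        "full": full,
        "pure_climate": pure_climate,
        "pure_geography": pure_geography,
        "pure_ancestry": pure_ancestry,
        "confounded": confounded,
        "unexplained": unexplained,
        "total": total,
    }
    out = pd.DataFrame({"inertia": pd.Series(rows, dtype=float)})
    out["prop_explainable"] = out["inertia"] / full
    out.loc[["unexplained", "total"], "prop_explainable"] = np.nan
    out.loc["full", "prop_explainable"] = 1.0
    out["prop_total"] = out["inertia"] / total
    out["p_value"] = np.nan
    if p_values:
        for key, p in p_values.items():
            out.loc[key, "p_value"] = p
    return out


def variance_partition(Y, climate, geography, ancestry, n_perm: int = 999,
                       seed=None) -> pd.DataFrame:
    """Decompose explainable inertia via a series of partial RDAs.

    Fits the full model ``Y ~ climate + geography + ancestry`` and the three
    pure models, each conditioning on the other two predictor groups, then
    delegates the bookkeeping to :func:`partition_from_inertias`.
    Collinearity between groups is expected (it is the object of study) and
    surfaces as the confounded fraction, not as an error.
    """
    for name, grp in (("climate", climate), ("geography", geography),
                      ("ancestry", ancestry)):
        mat, _ = _as_matrix(grp, name)
        if mat.shape[1] == 0:
            raise ValueError(f"empty predictor group: {name}")
    c, _ = _as_matrix(climate, "clim")
    g, _ = _as_matrix(geography, "geog")
    a, _ = _as_matrix(ancestry, "anc")
    everything = np.hstack([c, g, a])

    full = RDA().fit(everything, Y)
    pure_c = RDA().fit(c, Y, condition=np.hstack([g, a]))
    pure_g = RDA().fit(g, Y, condition=np.hstack([c, a]))
    pure_a = RDA().fit(a, Y, condition=np.hstack([c, g]))

    rng = np.random.default_rng(seed)
    pvals = {}
    if n_perm:
        sub = rng.integers(0, 2**31 - 1, size=4)
        pvals["full"] = permutation_test(Y, everything, n_perm=n_perm, seed=int(sub[0]))
        pvals["pure_climate"] = permutation_test(
            Y, c, condition=np.hstack([g, a]), n_perm=n_perm, seed=int(sub[1]))
        pvals["pure_geography"] = permutation_test(
            Y, g, condition=np.hstack([c, a]), n_perm=n_perm, seed=int(sub[2]))
        pvals["pure_ancestry"] = permutation_test(
            Y, a, condition=np.hstack([c, g]), n_perm=n_perm, seed=int(sub[3]))

    return partition_from_inertias(
        full.constrained_inertia_,
        pure_c.constrained_inertia_,
        pure_g.constrained_inertia_,
        pure_a.constrained_inertia_,
        full.total_inertia_,
        p_values=pvals,
    )


@dataclass
class SpatialEigenvectors:
    """dbMEM spatial eigenfunctions of a set of localities."""

    vectors: pd.DataFrame
    eigenvalues: np.ndarray
    truncation: float

    def __post_init__(self):
        order = np.argsort(self.eigenvalues)[::-1]
        self.eigenvalues = np.asarray(self.eigenvalues)[order]
        self.vectors = self.vectors.iloc[:, order]
        self.vectors.columns = [f"MEM{i + 1}" for i in range(self.vectors.shape[1])]


def dbmem(coords, n_keep: int | None = None, truncation: float | None = None) -> SpatialEigenvectors:
    """Distance-based Moran's Eigenvector Maps from locality coordinates.

    The pairwise Euclidean distance matrix is truncated (distances beyond
    the threshold replaced by 4x the threshold), double-centred as in
    principal coordinates analysis, and eigendecomposed; eigenvectors with
    positive eigenvalues model positive spatial autocorrelation, broadest
    scales first.  The default truncation threshold is the longest edge of
    the minimum spanning tree of the locality graph, the smallest value
    keeping the graph connected.
    """
    if isinstance(coords, pd.DataFrame):
        cols = [c for c in ("longitude", "latitude") if c in coords.columns]
        xy = coords[cols].to_numpy(dtype=float) if cols else coords.to_numpy(dtype=float)
        index = coords.index
    else:
        xy = np.asarray(coords, dtype=float)
        index = pd.RangeIndex(len(xy))
    if len(xy) < 3:
        raise ValueError("dbMEM needs at least 3 localities")
    d = squareform(pdist(xy))
    if d.max() == 0:
        raise ValueError("all localities coincide")
    if truncation is None:
        mst = minimum_spanning_tree(d)
        truncation = float(mst.data.max())
    dt = np.where(d > truncation, 4.0 * truncation, d)
    np.fill_diagonal(dt, 0.0)
    a = -0.5 * dt**2
    a = a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()
    w, v = linalg.eigh(a)
    pos = w > max(1e-10, 1e-12 * abs(w).max())
    w, v = w[pos], v[:, pos]
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    if n_keep is not None:
        if n_keep > v.shape[1]:
            raise ValueError(
                f"requested {n_keep} dbMEMs but only {v.shape[1]} positive eigenvectors")
        w, v = w[:n_keep], v[:, :n_keep]
    for j in range(v.shape[1]):  # orientation: largest-|entry| positive
        if v[np.argmax(np.abs(v[:, j])), j] < 0:
            v[:, j] *= -1
    vectors = pd.DataFrame(v, index=index,
                           columns=[f"MEM{i + 1}" for i in range(v.shape[1])])
    return SpatialEigenvectors(vectors=vectors, eigenvalues=w, truncation=truncation)


@dataclass
class GeneticPCAResult:
    """Individual and locality-averaged scores of a dosage PCA."""

    scores: pd.DataFrame
    locality_scores: pd.DataFrame | None
    eigenvalues: np.ndarray
    loadings: pd.DataFrame = field(repr=False, default=None)


def genetic_pca(d: pd.DataFrame, membership=None, n_components: int = 2) -> GeneticPCAResult:
    """PCA of mean-imputed, centred genotype dosages.

    Individual scores are the principal components of the individual x
    individual covariance of centred dosages; the locality score on each
    axis is the arithmetic mean of its member individuals' scores, used
    downstream as a conditioning proxy for neutral ancestry.
    """
    if d.shape[0] < 2:
        raise ValueError("genetic PCA needs at least 2 individuals")
    if d.shape[1] < 2:
        raise ValueError("genetic PCA needs more than one locus")
    vals = d.to_numpy(dtype=float)
    if np.isnan(vals).any():
        col_means = np.nanmean(vals, axis=0)
        vals = np.where(np.isnan(vals), col_means, vals)
    vals = vals - vals.mean(axis=0)
    u, s, vt = np.linalg.svd(vals, full_matrices=False)
    k = min(n_components, len(s))
    for j in range(k):
        if vt[j, np.argmax(np.abs(vt[j]))] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    axes = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(u[:, :k] * s[:k], index=d.index, columns=axes)
    loadings = pd.DataFrame(vt[:k].T, index=d.columns, columns=axes)
    eig = s[:k] ** 2 / (len(d) - 1)
    loc_scores = None
    if membership is not None:
        groups = pd.Series(membership).reindex(d.index)
        if groups.isna().any():
            raise ValueError("individuals without locality assignment")
        loc_scores = scores.groupby(groups, sort=False).mean()
    return GeneticPCAResult(scores=scores, locality_scores=loc_scores,
                            eigenvalues=eig, loadings=loadings)
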