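"""Multivariate genotype-environment genome scans and outlier selection.

Two per-locus statistics are implemented:

* :class:`RDAGenomeScan` — an RDA of locality allele frequencies on the
  climate variables (optionally conditioned on neutral-ancestry scores);
  each locus's loadings on the first ``K`` constrained axes are scored by
  their Mahalanobis distance from the centre of the loading cloud.  The
  squared distances are rescaled by a median-based genomic inflation
  factor lambda and converted to upper-tail chi-squared(K) p-values.
* :class:`RandomForestScan` — per locus, a random-forest regression of its
  locality frequencies on the climate variables; the statistic is the
  out-of-bag R-squared (negative values truncated to zero).

Either scan can be run on raw frequencies or on structure-corrected
(whitened) frequencies from :class:`~localadapt.freqs.FrequencyWhitener`.
Candidate loci are the top fraction ``q`` of each scan's ranking;
the final candidate set keeps loci found by at least ``m`` scans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.covariance import MinCovDet

from ._forest import forest_oob_r2
from .ordination import RDA

__all__ = ["RDAGenomeScan", "RandomForestScan", "rda_scan", "rf_scan",
           "select_outliers", "OutlierSet"]


class RDAGenomeScan(BaseEstimator):
    """RDA genome scan with a Mahalanobis outlier statistic.

    Parameters
    ----------
    n_axes : int
        K, the number of constrained axes whose locus loadings enter the
        Mahalanobis distance.
    robust : bool
        Estimate the loading-cloud covariance with the minimum covariance
        determinant instead of the classical estimator.
    lambda_method : {"median", "mean"}
        Genomic-control definition: median(d2)/median(chi2_K) (standard)
        or mean(d2)/K.

    Attributes
    ----------
    d2_ : Series — squared Mahalanobis distance per locus.
    pvalues_ : Series — chi-squared(K) upper-tail p at ``d2 / lambda``.
    lambda_ : float — genomic inflation factor, median(d2) / median chi2(K).
    correction_ : str — ``"corrected"`` if a condition was given else ``"raw"``.
    rda_ : fitted :class:`~localadapt.ordination.RDA`.
    """

    method = "rda"

    def __init__(self, n_axes: int = 2, robust: bool = False,
                 lambda_method: str = "median", random_state: int | None = 0):
        self.n_axes = n_axes
        self.robust = robust
        self.lambda_method = lambda_method
        self.random_state = random_state

    def fit(self, f: pd.DataFrame, climate: pd.DataFrame, condition=None):
        n_pred = climate.shape[1] if hasattr(climate, "shape") else np.asarray(climate).shape[1]
        if not 1 <= self.n_axes <= n_pred:
            raise ValueError(f"n_axes must lie in [1, {n_pred}]")
        self.rda_ = RDA().fit(climate, f, condition=condition)
        if self.n_axes > self.rda_.n_components_:
            raise ValueError(
                f"n_axes={self.n_axes} exceeds the {self.rda_.n_components_} "
                "available constrained axes")
        load = self.rda_.loadings_.iloc[:, : self.n_axes].to_numpy()
        if self.robust:
            mcd = MinCovDet(random_state=self.random_state).fit(load)
            center, cov = mcd.location_, mcd.covariance_
        else:
            center, cov = load.mean(axis=0), np.cov(load, rowvar=False)
        cov = np.atleast_2d(cov)
        dev = load - center
        d2 = np.einsum("ij,jk,ik->i", dev, np.linalg.inv(cov), dev)
        k = self.n_axes
        if self.lambda_method == "median":
            self.lambda_ = float(np.median(d2) / stats.chi2.median(k))
        elif self.lambda_method == "mean":
            self.lambda_ = float(np.mean(d2) / k)
        else:
            raise ValueError(f"unknown lambda_method {self.lambda_method!r}")
        self.d2_ = pd.Series(d2, index=self.rda_.loadings_.index, name="d2")
        self.pvalues_ = pd.Series(stats.chi2.sf(d2 / self.lambda_, k),
                                  index=self.d2_.index, name="p")
        self.correction_ = "raw" if condition is None else "corrected"
        return self

    @property
    def statistic_(self) -> pd.Series:
        return self.d2_


class RandomForestScan(BaseEstimator):
    """Per-locus random-forest R-squared scan of frequencies on climate.

    Attributes
    ----------
    r2_ : Series — out-of-bag R-squared per locus, truncated below at 0.
    r2_raw_ : Series — untruncated out-of-bag R-squared.
    """

    method = "rf"

    def __init__(self, n_trees: int = 500, mtry: int | None = None,
                 min_samples_leaf: int = 5, random_state: int | None = 0,
                 correction: str = "raw"):
        self.n_trees = n_trees
        self.mtry = mtry
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state
        self.correction = correction

    def fit(self, f: pd.DataFrame, climate: pd.DataFrame, y=None):
        if self.n_trees < 100:
            raise ValueError("n_trees must be at least 100")
        if len(f) < 10:
            raise ValueError("need at least 10 localities for stable "
                             "out-of-bag estimates")
        r2 = forest_oob_r2(np.asarray(climate, dtype=float), f.to_numpy(),
                           n_trees=self.n_trees, mtry=self.mtry,
                           min_leaf=self.min_samples_leaf,
                           seed=self.random_state)
        self.r2_raw_ = pd.Series(r2, index=f.columns, name="r2_raw")
        self.r2_ = self.r2_raw_.clip(lower=0.0).rename("r2")
        self.correction_ = self.correction
        return self

    @property
    def statistic_(self) -> pd.Series:
        return self.r2_


def rda_scan(f, climate, condition=None, K: int = 2, robust: bool = False) -> RDAGenomeScan:
    return RDAGenomeScan(n_axes=K, robust=robust).fit(f, climate, condition=condition)


def rf_scan(f, climate, n_trees: int = 500, seed=0) -> RandomForestScan:
    return RandomForestScan(n_trees=n_trees, random_state=seed).fit(f, climate)


@dataclass
class OutlierSet:
    """Top-q locus sets per scan and their >= m-methods intersection."""

    per_method: dict[str, pd.Index]
    intersection: pd.Index
    q: float
    m: int

    @property
    def counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.per_method.items()}

    def membership_table(self) -> pd.DataFrame:
        """Locus x method boolean table plus the number of methods."""
        loci = sorted(set().union(*map(set, self.per_method.values())))
        out = pd.DataFrame(
            {name: [l in set(sel) for l in loci]
             for name, sel in self.per_method.items()},
            index=pd.Index(loci, name="locus"))
        out["n_methods"] = out.sum(axis=1)
        out["candidate"] = out["n_methods"] >= self.m
        return out


def _statistic_of(scan, name):
    if isinstance(scan, pd.Series):
        return scan
    if hasattr(scan, "statistic_"):
        return scan.statistic_
    raise TypeError(f"scan {name!r} has no statistic")


def select_outliers(scans, q: float = 0.002, m: int = 2) -> OutlierSet:
    """Rank-based outlier selection and intersection across scans.

    ``scans`` is a mapping name -> fitted scan (or Series of statistics).
    Each method contributes its ``floor(q * N)`` highest-statistic loci
    (ties at the cutoff broken by ascending locus index); the candidate set
    keeps loci present in at least ``m`` per-method sets.
    """
    if not 0 < q <= 1:
        raise ValueError("q must lie in (0, 1]")
    if isinstance(scans, (list, tuple)):
        scans = {getattr(s, "method", f"scan{i}") + f"_{getattr(s, 'correction_', i)}": s
                 for i, s in enumerate(scans)}
    if not 1 <= m <= len(scans):
        raise ValueError(f"m must lie in [1, {len(scans)}]")
    stats_by_method = {name: _statistic_of(s, name) for name, s in scans.items()}
    first = next(iter(stats_by_method.values()))
    for name, s in stats_by_method.items():
        if not s.index.equals(first.index):
            raise ValueError(f"scan {name!r} covers a different locus set")
    n_top = int(np.floor(q * len(first)))
    per_method = {}
    for name, s in stats_by_method.items():
        order = np.lexsort((np.arange(len(s)), -s.to_numpy()))
        per_method[name] = s.index[order[:n_top]]
    tally = pd.Series(0, index=first.index)
    for sel in per_method.values():
        tally[sel] += 1
    intersection = first.index[tally >= m]
    return OutlierSet(per_method=per_method, intersection=intersection, q=q, m=m)
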