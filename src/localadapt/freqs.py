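"""Dosage-to-frequency conversion, MAF filtering and structure correction.

Locality allele frequencies are the response variable of every downstream
ordination and scan: per locality, genotype dosages are averaged over member
individuals and divided by two.  The minor-allele-frequency filter operates
on the pooled individual-level frequency ("across the complete sampling"),
not on locality means, so unequal locality sizes are weighted by membership.

:class:`FrequencyWhitener` removes shared demographic covariance among
localities: per-locus frequencies are centred and scaled by the binomial
standard deviation ``sqrt(pbar (1 - pbar))``, the locality x locality
covariance of those standardized frequencies (the "omega" matrix) is
estimated across loci with ridge shrinkage toward its diagonal, and the
standardized matrix is whitened by the inverse Cholesky factor of omega.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator, TransformerMixin

from .io import validate_dosage, validate_freqs

logger = logging.getLogger(__name__)


def dosages_to_freqs(d: pd.DataFrame, membership, impute_missing: bool = True) -> pd.DataFrame:
    """Average dosages within localities and divide by two.

    Parameters
    ----------
    d : DosageMatrix (individuals x loci)
    membership : mapping or Series, individual id -> locality id
        Every individual in ``d`` must be assigned.
    impute_missing : bool
        Replace missing dosages by the locus mean (over all non-missing
        individuals) before averaging; otherwise localities average over
        their non-missing members only.

    Returns
    -------
    FreqMatrix (localities x loci), locality order = first appearance.
    """
    validate_dosage(d)
    membership = pd.Series(membership)
    unassigned = d.index.difference(membership.index)
    if len(unassigned):
        raise ValueError(f"individuals without locality assignment: {list(unassigned[:5])}")
    groups = membership.reindex(d.index)
    vals = d.to_numpy(dtype=float)
    if impute_missing and np.isnan(vals).any():
        n_imputed = int(np.isnan(vals).sum())
        col_means = np.nanmean(vals, axis=0)
        vals = np.where(np.isnan(vals), col_means, vals)
        logger.info("imputed %d missing dosages with locus means", n_imputed)
    imputed = pd.DataFrame(vals, index=d.index, columns=d.columns)
    counts = groups.value_counts()
    if (counts == 0).any():  # pragma: no cover - value_counts drops zeros
        raise ValueError("locality with zero members")
    freqs = imputed.groupby(groups, sort=False).mean() / 2.0
    if freqs.isna().any().any():
        raise ValueError("locality with no non-missing dosages at some locus")
    return validate_freqs(freqs)


def global_frequencies(d: pd.DataFrame) -> pd.Series:
    """Pooled per-locus allele frequency: mean dosage over individuals / 2."""
    return d.mean(axis=0, skipna=True) / 2.0


def filter_maf(x: pd.DataFrame, threshold: float = 0.10, kind: str = "auto"):
    """Remove loci whose minor allele frequency is strictly below ``threshold``.

    For a DosageMatrix the frequency is pooled over individuals; for a
    FreqMatrix it is the unweighted mean of locality frequencies.  Loci with
    ``min(f, 1 - f)`` exactly at the threshold are retained.

    Returns ``(filtered, kept)`` where ``kept`` is the boolean index of
    retained loci.
    """
    if not 0 <= threshold <= 0.5:
        raise ValueError("MAF threshold must lie in [0, 0.5]")
    if kind == "auto":
        kind = "dosage" if np.nanmax(x.to_numpy(dtype=float)) > 1 else "freq"
    if kind == "dosage":
        f = global_frequencies(x)
    elif kind == "freq":
        f = x.mean(axis=0)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    maf = np.minimum(f, 1 - f)
    kept = maf >= threshold
    return x.loc[:, kept], kept


class FrequencyWhitener(BaseEstimator, TransformerMixin):
    """Standardize locality allele frequencies and whiten them by the
    locality covariance ("omega") matrix.

    Parameters
    ----------
    shrinkage : float in [0, 1]
        Ridge weight pulling the across-loci covariance estimate toward its
        diagonal: ``omega = (1 - shrinkage) * S + shrinkage * diag(S)``.

    Attributes
    ----------
    omega_ : DataFrame (localities x localities)
        Shrunk covariance estimate of standardized frequencies.
    mean_ : Series, per-locus mean frequency used for centring.
    scale_ : Series, per-locus ``sqrt(pbar (1 - pbar))``.
    whitener_ : ndarray, inverse Cholesky factor applied to rows.
    """

    def __init__(self, shrinkage: float = 0.1):
        self.shrinkage = shrinkage

    def _standardize(self, f: pd.DataFrame) -> pd.DataFrame:
        z = (f - self.mean_) / self.scale_
        return z

    def fit(self, f: pd.DataFrame, y=None):
        validate_freqs(f)
        if f.shape[1] < 2:
            raise ValueError("need at least 2 loci to estimate omega")
        pbar = f.mean(axis=0)
        scale = np.sqrt(pbar * (1 - pbar))
        if (scale == 0).any():
            raise ValueError("monomorphic locus (pbar in {0,1}); filter first")
        self.mean_, self.scale_ = pbar, scale
        z = self._standardize(f).to_numpy()
        s = np.cov(z)  # localities x localities, loci as observations
        omega = (1 - self.shrinkage) * s + self.shrinkage * np.diag(np.diag(s))
        try:
            chol = linalg.cholesky(omega, lower=True)
        except linalg.LinAlgError as e:
            raise ValueError(
                "omega not positive definite; increase shrinkage"
            ) from e
        self.omega_ = pd.DataFrame(omega, index=f.index, columns=f.index)
        self.whitener_ = linalg.solve_triangular(chol, np.eye(len(f)), lower=True)
        return self

    def transform(self, f: pd.DataFrame) -> pd.DataFrame:
        z = self._standardize(f)
        out = self.whitener_ @ z.to_numpy()
        return pd.DataFrame(out, index=f.index, columns=f.columns)


def standardize_freqs(f: pd.DataFrame, shrinkage: float = 0.1):
    """Functional wrapper: returns ``(corrected frequencies, omega)``."""
    w = FrequencyWhitener(shrinkage=shrinkage).fit(f)
    return w.transform(f), w.omega_
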