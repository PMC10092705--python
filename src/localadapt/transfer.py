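"""Climate transfer distances and transfer functions.

A climate transfer distance is the multivariate difference between the
climate normals of a seed-source locality and the climate of a common
garden: both tables are standardized jointly, rotated by PCA, and the
Euclidean distance over *all* principal components is taken per
(source, garden) pair — which equals the Euclidean distance between the
z-scored climate vectors.  A declining (typically quadratic) regression of
garden performance on transfer distance is the classical signature of
local adaptation in provenance trials.

Family trait values are BLUPs from a linear mixed model with bed-rack and
family random intercepts (REML), fitted per garden; the locality value is
the unweighted mean of its member family values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .io import validate_climate, validate_traits

__all__ = ["climate_transfer_distance", "family_values", "FamilyValues",
           "TransferFunction", "fit_transfer_function"]

logger = logging.getLogger(__name__)


def climate_transfer_distance(sources: pd.DataFrame,
                              gardens: pd.DataFrame) -> pd.DataFrame:
    """Euclidean climate distance in full PC space, sources x gardens.

    The PCA is computed on the standardized joint matrix of source and
    garden climates; distances use all principal components and are
    therefore invariant to the rotation and to affine rescaling of any raw
    variable.
    """
    validate_climate(sources)
    mismatch = set(sources.columns) ^ set(gardens.columns)
    if mismatch:
        raise ValueError(f"variable mismatch between tables: {sorted(mismatch)}")
    gardens = validate_climate(gardens[sources.columns])
    joint = pd.concat([sources, gardens])
    z = (joint - joint.mean()) / joint.std(ddof=1)
    # full-rank PCA rotation; distances on all PCs
    zc = z - z.mean()
    _, _, vt = np.linalg.svd(zc.to_numpy(), full_matrices=False)
    scores = zc.to_numpy() @ vt.T
    zs = scores[: len(sources)]
    zg = scores[len(sources):]
    d = np.sqrt(((zs[:, None, :] - zg[None, :, :]) ** 2).sum(axis=2))
    return pd.DataFrame(d, index=sources.index, columns=gardens.index)


@dataclass
class FamilyValues:
    """Family- and locality-level trait values for one garden."""

    garden: str
    family_values: pd.Series
    locality_values: pd.Series
    intercept: float
    variance_components: dict
    converged: bool


def family_values(traits: pd.DataFrame, garden: str,
                  method: str = "blup") -> FamilyValues:
    """Family trait values for one garden: REML BLUPs or raw means.

    The BLUP model is ``height_growth ~ 1 + (1 | bed_rack) + (1 | family)``;
    the per-family value is the intercept plus the family random effect.
    With ``method="mean"`` raw family means are used instead.  If the trait
    is constant or REML fails to converge the function falls back with a
    warning (full shrinkage / raw means respectively).
    """
    validate_traits(traits)
    sub = traits[traits["garden"] == garden]
    if sub.empty:
        raise ValueError(f"no rows for garden {garden!r}")
    if sub["family"].nunique() < 2:
        raise ValueError("need at least 2 families")
    fam_loc = sub.groupby("family")["locality"].first()

    def _package(fam_vals, intercept, vc, converged):
        loc_vals = fam_vals.groupby(fam_loc).mean()
        return FamilyValues(garden=garden, family_values=fam_vals,
                            locality_values=loc_vals, intercept=intercept,
                            variance_components=vc, converged=converged)

    y = sub["height_growth"].to_numpy(dtype=float)
    if method == "mean" or np.var(y) == 0:
        if np.var(y) == 0 and method != "mean":
            warnings.warn("zero trait variance: all family values equal the intercept")
            flat = pd.Series(float(y[0]), index=fam_loc.index)
            return _package(flat, float(y[0]),
                            {"family": 0.0, "bed_rack": 0.0, "residual": 0.0}, True)
        means = sub.groupby("family")["height_growth"].mean().reindex(fam_loc.index)
        return _package(means, float(np.mean(y)), {}, True)

    model = sm.MixedLM.from_formula(
        "height_growth ~ 1", data=sub, groups=np.ones(len(sub)),
        vc_formula={"family": "0 + C(family)", "bed_rack": "0 + C(bed_rack)"})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=True)
            converged = bool(res.converged)
        except Exception:
            res, converged = None, False
    if not converged:
        logger.warning("REML failed to converge for garden %s; raw means used", garden)
        means = sub.groupby("family")["height_growth"].mean().reindex(fam_loc.index)
        return _package(means, float(np.mean(y)), {}, False)

    re = res.random_effects[1.0]
    # vc effects are named like "family[C(family)[<category>]]"
    fam_eff = pd.Series({name.split("[C(family)[", 1)[1][:-2]: float(val)
                         for name, val in re.items()
                         if name.startswith("family[")})
    intercept = float(res.fe_params.iloc[0])
    fam_vals = pd.Series(intercept, index=fam_loc.index, dtype=float)
    for fam in fam_vals.index:
        key = str(fam)
        if key in fam_eff.index:
            fam_vals[fam] += fam_eff[key]
    vc = {"family": float(res.vcomp[list(model.exog_vc.names).index("family")]),
          "bed_rack": float(res.vcomp[list(model.exog_vc.names).index("bed_rack")]),
          "residual": float(res.scale)}
    return _package(fam_vals, intercept, vc, True)


class TransferFunction(BaseEstimator):
    """OLS regression of locality trait values on climate transfer distance.

    Parameters
    ----------
    form : {"linear", "quadratic"}

    Attributes
    ----------
    coef_ : Series — intercept and distance (and distance^2) coefficients.
    r2_ : float
    pvalue_ : float — p of the highest-order term.
    fitted_ : Series — fitted values per locality.
    n_ : int — number of localities.
    """

    def __init__(self, form: str = "quadratic"):
        self.form = form

    def fit(self, distances, values):
        if self.form not in ("linear", "quadratic"):
            raise ValueError(f"unknown form {self.form!r}")
        d = pd.Series(distances, dtype=float)
        v = pd.Series(values, dtype=float).reindex(d.index)
        if v.isna().any():
            raise ValueError("locality values missing for some distances")
        if len(d) < 5:
            raise ValueError("need at least 5 localities")
        cols = {"intercept": np.ones(len(d)), "distance": d.to_numpy()}
        if self.form == "quadratic":
            cols["distance2"] = d.to_numpy() ** 2
        X = pd.DataFrame(cols, index=d.index)
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            raise ValueError("rank-deficient design (constant distances?)")
        res = sm.OLS(v.to_numpy(), X.to_numpy()).fit()
        self.result_ = res
        self.coef_ = pd.Series(res.params, index=X.columns)
        self.r2_ = float(res.rsquared)
        self.pvalue_ = float(res.pvalues[-1])
        self.fitted_ = pd.Series(res.fittedvalues, index=d.index)
        self.n_ = len(d)
        return self


def fit_transfer_function(distances, locality_values,
                          form: str = "quadratic") -> TransferFunction:
    return TransferFunction(form=form).fit(distances, locality_values)
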