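"""Adaptively-enriched ordination and its landscape projection.

After the genome scans have produced a candidate set, an ordinary RDA of
the candidate-locus frequencies on the climate variables summarizes the
main gradients of adaptive variation.  Its predictor coefficients project
any climate grid onto the constrained axes (the per-pixel *adaptive
index*), candidate loci cluster into co-varying modules in
(|RDA1|, |RDA2|) loading space, and per-module allele-frequency clines
along a focal variable are summarized by a four-parameter logistic fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .ordination import RDA

__all__ = ["enriched_rda", "adaptive_index", "AdaptiveIndexMap",
           "LocusClusterer", "cluster_loci", "ModuleAssignment",
           "cline_summary", "silhouette_profile"]


def enriched_rda(f_outliers: pd.DataFrame, climate: pd.DataFrame) -> RDA:
    """Unconditioned RDA of candidate-locus frequencies on climate."""
    if f_outliers.shape[1] < 2:
        raise ValueError("need at least 2 outlier loci")
    return RDA().fit(climate, f_outliers)


@dataclass
class AdaptiveIndexMap:
    """Per-cell adaptive indices of a climate grid."""

    index: pd.DataFrame     # raw per-axis index
    rescaled: pd.DataFrame  # per-axis min-max rescaled to [0, 1]
    degenerate: bool        # grid climatically constant on some axis


def adaptive_index(o: RDA, grid: pd.DataFrame) -> AdaptiveIndexMap:
    """Project a climate grid onto the constrained axes of a fitted RDA.

    Per cell and axis the index is the sum over predictors of the axis
    coefficient times the cell value standardized with the training
    means/sds, so a cell with the climate of a training locality receives
    exactly that locality's fitted site score.  A min-max rescaled copy
    (the 0-1 map scale) is included; if the grid is climatically constant
    along an axis the rescaled copy is flagged degenerate.
    """
    missing = [v for v in o.feature_names_in_ if v not in grid.columns]
    if missing:
        raise ValueError(f"grid lacks climate variables: {missing}")
    raw = o.transform(grid[list(o.feature_names_in_)])
    span = raw.max() - raw.min()
    degenerate = bool((span == 0).any())
    with np.errstate(invalid="ignore", divide="ignore"):
        rescaled = (raw - raw.min()) / span.replace(0, np.nan)
    return AdaptiveIndexMap(index=raw, rescaled=rescaled, degenerate=degenerate)


@dataclass
class ModuleAssignment:
    """k-means module labels of candidate loci in |loading| space."""

    labels: pd.Series          # locus -> cluster label (0..k-1)
    centroids: pd.DataFrame    # cluster x (|RDA1|, |RDA2|)
    loadings: pd.DataFrame     # signed loadings used, locus x axes
    inertia: float

    @property
    def k(self) -> int:
        return len(self.centroids)

    def dominant_axis(self, label: int) -> str:
        return self.centroids.columns[int(np.argmax(self.centroids.loc[label]))]


class LocusClusterer(BaseEstimator):
    """Euclidean k-means on absolute locus loadings of the first two axes.

    Clustering on absolute values makes the assignment invariant to axis
    sign flips: a locus loading -0.3 and one loading +0.3 belong to the
    same module (the allele coding is arbitrary).
    """

    def __init__(self, k: int = 2, n_restarts: int = 50, random_state: int = 0):
        self.k = k
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, o: RDA):
        n_axes = min(2, o.n_components_)
        load = o.loadings_.iloc[:, :n_axes]
        if len(load) < self.k:
            raise ValueError(f"fewer loci ({len(load)}) than clusters ({self.k})")
        absload = load.abs()
        if self.k > 1 and np.allclose(absload.to_numpy(),
                                      absload.to_numpy()[0], atol=1e-12):
            raise ValueError("degenerate clustering: all loading vectors identical")
        km = KMeans(n_clusters=self.k, n_init=self.n_restarts,
                    random_state=self.random_state).fit(absload.to_numpy())
        # stable label order: cluster 0 = largest |axis-1| centroid
        order = np.argsort(-km.cluster_centers_[:, 0])
        relabel = np.empty_like(order)
        relabel[order] = np.arange(self.k)
        labels = pd.Series(relabel[km.labels_], index=load.index, name="module")
        centroids = pd.DataFrame(km.cluster_centers_[order],
                                 index=pd.RangeIndex(self.k, name="module"),
                                 columns=absload.columns)
        self.assignment_ = ModuleAssignment(labels=labels, centroids=centroids,
                                            loadings=load, inertia=float(km.inertia_))
        return self


def cluster_loci(o: RDA, k: int = 2, seed: int = 0,
                 n_restarts: int = 50) -> ModuleAssignment:
    return LocusClusterer(k=k, n_restarts=n_restarts,
                          random_state=seed).fit(o).assignment_


def silhouette_profile(o: RDA, ks=(2, 3, 4, 5), seed: int = 0) -> pd.Series:
    """Mean silhouette width of the |loading| clustering for each k."""
    absload = o.loadings_.iloc[:, : min(2, o.n_components_)].abs().to_numpy()
    out = {}
    for k in ks:
        if k >= len(absload):
            continue
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(absload)
        out[k] = float(silhouette_score(absload, km.labels_))
    return pd.Series(out, name="silhouette")


def _logistic4(x, lo, hi, slope, inflection):
    return lo + (hi - lo) / (1.0 + np.exp(-slope * (x - inflection)))


def cline_summary(f: pd.DataFrame, modules: ModuleAssignment,
                  env: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Per-module allele-frequency cline along one climate variable.

    Within each module, loci whose loading on the module's dominant axis is
    negative are polarized (p -> 1 - p) so frequencies aggregate
    coherently; the locality mean frequency is then fit with a
    four-parameter logistic in the focal variable.  Reports the fitted
    inflection point and slope with 95% confidence intervals.
    """
    if variable not in env.columns:
        raise ValueError(f"variable {variable!r} not in climate table")
    x = env.loc[f.index, variable].to_numpy(dtype=float)
    if len(np.unique(x)) < 5:
        raise ValueError("logistic fit underdetermined: need >= 5 distinct "
                         "environment values")
    rows = []
    for label in modules.centroids.index:
        loci = modules.labels.index[modules.labels == label]
        if len(loci) < 2:
            warnings.warn(f"module {label} has fewer than 2 loci; skipped")
            continue
        axis = modules.dominant_axis(label)
        signs = np.sign(modules.loadings.loc[loci, axis].to_numpy())
        signs[signs == 0] = 1
        sub = f[loci].to_numpy()
        polarized = np.where(signs[None, :] > 0, sub, 1.0 - sub)
        mean_freq = polarized.mean(axis=1)

        lo0, hi0 = float(mean_freq.min()), float(mean_freq.max())
        span = max(x.max() - x.min(), 1e-9)
        # start the slope on the empirically right side: a decreasing cline
        # is otherwise stuck on the wrong branch of the lo/hi-slope ridge
        trend = np.corrcoef(x, mean_freq)[0, 1] if np.std(mean_freq) > 0 else 0.0
        s0 = (4.0 / span) * (1.0 if trend >= 0 else -1.0)
        p0 = [lo0, hi0, s0, float(np.median(x))]
        bounds = ([0, 0, -np.inf, x.min() - span], [1, 1, np.inf, x.max() + span])
        try:
            popt, pcov = curve_fit(_logistic4, x, mean_freq, p0=p0,
                                   bounds=bounds, maxfev=20000)
            se = np.sqrt(np.diag(pcov))
        except RuntimeError:
            warnings.warn(f"logistic fit failed for module {label}")
            continue
        z = stats.norm.ppf(0.975)
        rows.append({
            "module": label, "n_loci": len(loci), "dominant_axis": axis,
            "lower_plateau": popt[0], "upper_plateau": popt[1],
            "slope": popt[2], "slope_lo": popt[2] - z * se[2],
            "slope_hi": popt[2] + z * se[2],
            "inflection": popt[3], "inflection_lo": popt[3] - z * se[3],
            "inflection_hi": popt[3] + z * se[3],
        })
    return pd.DataFrame(rows).set_index("module") if rows else pd.DataFrame()
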