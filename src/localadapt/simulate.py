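"""Synthetic landscape generator with full ground truth.

The generator emulates the statistical structure of a range-edge conifer
sampled along a south-to-north post-glacial expansion route:

* localities are arrayed on a latitudinal transect with random elevations,
  so climate, geography and neutral ancestry are strongly collinear;
* neutral loci follow a serial-founder random walk along the expansion
  order, optionally with a per-locus directional bias (the collinearity
  knob) that aligns drift with the climate gradient;
* clinal adaptive loci follow a logistic cline in allele frequency along a
  cold gradient (degree-days below 0C), with the inflection mid-gradient;
* threshold adaptive loci switch between two plateau frequencies across an
  extreme-heat threshold driven mostly by elevation;
* genotype dosages are binomial draws from locality frequencies (mother
  trees, one per family);
* common-garden seedling height declines quadratically with the
  multivariate climate transfer distance between seed source and garden,
  on top of family, bed-rack, per-locus genotype and residual effects, with
  dead seedlings scored zero.

All randomness flows from one seed through named substreams (landscape,
dosages, design, garden) so each stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CLIMATE_VARS, locus_id, validate_freqs

__all__ = [
    "SimulationConfig", "SyntheticTruth", "simulate_landscape",
    "sample_dosages", "make_design", "simulate_common_garden",
    "simulate_study", "climate_from_geography", "transfer_distances_z",
]

#: climate variable -> (intercept, latitude coefficient, elevation
#: coefficient, noise sd); latitude in decimal degrees, elevation in m.
DEFAULT_CLIMATE_COEFS: dict[str, tuple[float, float, float, float]] = {
    "DD_0": (-3200.0, 100.0, 0.05, 30.0),
    "DD18": (3000.0, -60.0, -0.25, 25.0),
    "MAR": (35.5, -0.5, 0.001, 0.3),
    "PAS": (-680.0, 20.0, 0.08, 10.0),
    "MSP": (225.0, 5.0, 0.05, 15.0),
    "RH": (54.5, 0.3, 0.002, 1.0),
    "EXT": (48.25, -0.35, -0.0045, 0.4),
    "CMD": (720.0, -12.0, -0.1, 10.0),
    "TD": (-6.5, 0.9, 0.001, 0.5),
    "eFFP": (420.0, -4.0, -0.02, 3.0),
    "PET": (1400.0, -20.0, -0.15, 10.0),
}

#: (name, latitude, elevation) of the three common gardens, south to north.
DEFAULT_GARDENS: tuple[tuple[str, float, float], ...] = (
    ("garden_south", 35.6, 650.0),
    ("garden_mid", 39.7, 700.0),
    ("garden_north", 44.5, 120.0),
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic landscape; defaults are the study
    conditions exercised by the test suite."""

    # geography
    n_localities: int = 64
    lat_range: tuple[float, float] = (35.0, 47.0)
    lon_range: tuple[float, float] = (-84.0, -70.0)
    elev_range: tuple[float, float] = (0.0, 1500.0)
    # neutral drift
    n_neutral_loci: int = 49_900
    drift_sd: float = 0.02           # per expansion step
    drift_alignment: float = 0.25    # collinearity knob; 0 = pure random walk
    # clinal loci (logistic in DD_0)
    n_clinal_loci: int = 60
    cline_variable: str = "DD_0"
    cline_steepness: float = 0.02    # per degree-day below 0C
    cline_inflection: float = 700.0  # degree-days below 0C
    cline_inflection_jitter: float = 25.0
    # threshold loci (step in EXT)
    n_threshold_loci: int = 40
    threshold_variable: str = "EXT"
    threshold_location: float = 30.5  # deg C extreme maximum temperature
    threshold_low: float = 0.15
    threshold_high: float = 0.85
    # climate construction
    climate_coefs: dict = field(default_factory=lambda: dict(DEFAULT_CLIMATE_COEFS))
    gardens: tuple = DEFAULT_GARDENS
    # sampling
    n_families: int = 340            # mother trees, one dosage row each
    # common garden
    blocks_per_garden: int = 5
    seedlings_per_family_per_block: int = 1
    baseline_height: float = 25.0    # cm height growth over the experiment
    transfer_beta: float = 0.5       # cm per squared z-space distance unit
    n_effect_loci: int = 10          # loci with a direct phenotypic effect
    effect_variance_fraction: float = 0.02  # per-locus share of total variance
    effect_locus_label: str = "neutral"  # label class hosting the effects
    family_sd: float = 2.0
    bed_rack_sd: float = 1.0
    residual_sd: float = 3.0
    p_mortality: float = 0.02
    seed: int = 0

    def __post_init__(self):
        for name in ("drift_sd", "family_sd", "bed_rack_sd", "residual_sd",
                     "cline_steepness"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("threshold_low", "threshold_high", "p_mortality"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """Generated landscape with ground truth for recovery testing."""

    localities: pd.DataFrame
    climate: pd.DataFrame          # localities x 11 variables
    garden_climate: pd.DataFrame   # gardens x 11 variables
    freqs: pd.DataFrame            # generating locality frequencies, all loci
    labels: pd.DataFrame           # locus id -> label + generative parameters
    config: SimulationConfig
    dosages: pd.DataFrame | None = None
    membership: pd.Series | None = None
    design: pd.DataFrame | None = None
    traits: pd.DataFrame | None = None

    def loci_with_label(self, label: str) -> pd.Index:
        return self.labels.index[self.labels["label"] == label]


def _streams(seed):
    names = ("landscape", "dosages", "design", "garden")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def climate_from_geography(lat, elev, coefs, rng=None, noise: bool = True) -> pd.DataFrame:
    """Evaluate the deterministic climate surfaces (plus noise) at points."""
    lat = np.asarray(lat, dtype=float)
    elev = np.asarray(elev, dtype=float)
    out = {}
    for var, (a, b_lat, b_elev, sd) in coefs.items():
        vals = a + b_lat * lat + b_elev * elev
        if noise and sd > 0:
            if rng is None:
                raise ValueError("rng required for climate noise")
            vals = vals + rng.normal(0.0, sd, size=lat.shape)
        out[var] = vals
    return pd.DataFrame(out)


def simulate_landscape(cfg: SimulationConfig) -> SyntheticTruth:
    """Generate localities, climate and locality allele frequencies."""
    if cfg.n_localities < 2:
        raise ValueError("need at least 2 localities (degenerate geometry)")
    rng = _streams(cfg.seed)["landscape"]
    n = cfg.n_localities

    lat = np.linspace(*cfg.lat_range, n)
    lon = np.linspace(*cfg.lon_range, n) + rng.normal(0, 0.4, n)
    elev = rng.uniform(*cfg.elev_range, n)
    ids = [f"L{i:02d}" for i in range(n)]
    localities = pd.DataFrame(
        {"longitude": lon, "latitude": lat, "elevation": elev}, index=pd.Index(ids, name="locality"))

    climate = climate_from_geography(lat, elev, cfg.climate_coefs, rng)
    climate.index = localities.index
    g_names = [g[0] for g in cfg.gardens]
    g_lat = np.array([g[1] for g in cfg.gardens])
    g_elev = np.array([g[2] for g in cfg.gardens])
    garden_climate = climate_from_geography(g_lat, g_elev, cfg.climate_coefs, rng)
    garden_climate.index = pd.Index(g_names, name="garden")

    # expansion order = south to north along the transect
    blocks, labels_rows = [], []
    env_c = climate[cfg.cline_variable].to_numpy()
    env_t = climate[cfg.threshold_variable].to_numpy()

    if cfg.n_neutral_loci:
        p0 = rng.uniform(0.1, 0.9, cfg.n_neutral_loci)
        bias = rng.normal(0.0, cfg.drift_sd * cfg.drift_alignment, cfg.n_neutral_loci)
        steps = rng.normal(bias, cfg.drift_sd, size=(n - 1, cfg.n_neutral_loci))
        walk = np.empty((n, cfg.n_neutral_loci))
        walk[0] = p0
        for i in range(1, n):
            walk[i] = np.clip(walk[i - 1] + steps[i - 1], 0.01, 0.99)
        blocks.append(walk)
        for j in range(cfg.n_neutral_loci):
            labels_rows.append({"locus": locus_id(f"ctg{j // 100:04d}", 1000 + (j % 100) * 137),
                                "label": "neutral", "p0": p0[j],
                                "inflection": np.nan, "steepness": np.nan,
                                "polarity": 1, "effect": 0.0})

    if cfg.n_clinal_loci:
        infl = cfg.cline_inflection + rng.normal(0, cfg.cline_inflection_jitter,
                                                 cfg.n_clinal_loci)
        pol = rng.choice([-1, 1], cfg.n_clinal_loci)
        logi = 1.0 / (1.0 + np.exp(-cfg.cline_steepness * (env_c[:, None] - infl[None, :])))
        logi = np.where(pol[None, :] == 1, logi, 1.0 - logi)
        noise = rng.normal(0, cfg.drift_sd, size=logi.shape)
        blocks.append(np.clip(logi + noise, 0.01, 0.99))
        for j in range(cfg.n_clinal_loci):
            labels_rows.append({"locus": locus_id(f"clin{j:04d}", 500 + j * 61),
                                "label": "clinal", "p0": np.nan,
                                "inflection": infl[j], "steepness": cfg.cline_steepness,
                                "polarity": int(pol[j]), "effect": 0.0})

    if cfg.n_threshold_loci:
        pol = rng.choice([-1, 1], cfg.n_threshold_loci)
        above = (env_t[:, None] > cfg.threshold_location)
        step = np.where(above, cfg.threshold_high, cfg.threshold_low)
        step = np.where(pol[None, :] == 1, step, cfg.threshold_high + cfg.threshold_low - step)
        noise = rng.normal(0, cfg.drift_sd, size=step.shape)
        blocks.append(np.clip(step + noise, 0.01, 0.99))
        for j in range(cfg.n_threshold_loci):
            labels_rows.append({"locus": locus_id(f"thr{j:04d}", 750 + j * 83),
                                "label": "threshold", "p0": np.nan,
                                "inflection": cfg.threshold_location, "steepness": np.nan,
                                "polarity": int(pol[j]), "effect": 0.0})

    if not blocks:
        raise ValueError("no loci requested")
    labels = pd.DataFrame(labels_rows).set_index("locus")
    freqs = pd.DataFrame(np.hstack(blocks), index=localities.index,
                         columns=labels.index)
    validate_freqs(freqs)
    return SyntheticTruth(localities=localities, climate=climate,
                          garden_climate=garden_climate, freqs=freqs,
                          labels=labels, config=cfg)


def sample_dosages(f: pd.DataFrame, n_per_locality, seed=None) -> tuple[pd.DataFrame, pd.Series]:
    """Draw diploid genotype dosages ~ Binomial(2, p) per individual.

    ``n_per_locality`` is an int or a mapping locality -> count.  Returns
    the DosageMatrix and the individual -> locality membership Series.
    """
    rng = np.random.default_rng(seed)
    if np.isscalar(n_per_locality):
        counts = {loc: int(n_per_locality) for loc in f.index}
    else:
        counts = {loc: int(n_per_locality[loc]) for loc in f.index}
    if min(counts.values()) < 1:
        raise ValueError("n_per_locality must be >= 1")
    rows, ids, members = [], [], []
    p = f.to_numpy()
    for i, loc in enumerate(f.index):
        k = counts[loc]
        rows.append(rng.binomial(2, p[i], size=(k, f.shape[1])))
        ids.extend(f"{loc}_f{j}" for j in range(k))
        members.extend([loc] * k)
    d = pd.DataFrame(np.vstack(rows).astype(float), index=pd.Index(ids, name="individual"),
                     columns=f.columns)
    return d, pd.Series(members, index=d.index, name="locality")


def make_design(n_families: int, family_to_locality, gardens,
                blocks_per_garden: int = 5, seedlings_per_family_per_block: int = 1,
                seed=None) -> pd.DataFrame:
    """Randomized-block common-garden design table, one row per seedling.

    Every family contributes ``seedlings_per_family_per_block`` seedlings to
    every block of every garden; planting order within a block is
    randomized with ``seed``.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    fam_map = pd.Series(family_to_locality)
    families = list(fam_map.index[:n_families])
    if len(families) < n_families:
        raise ValueError("family_to_locality covers fewer families than n_families")
    rng = np.random.default_rng(seed)
    rows = []
    counter = 0
    for garden in gardens:
        for block in range(1, blocks_per_garden + 1):
            block_rows = []
            for fam in families:
                for _ in range(seedlings_per_family_per_block):
                    block_rows.append((fam, fam_map[fam], garden,
                                       f"{garden}:rack{block}"))
            order = rng.permutation(len(block_rows))
            for k in order:
                fam, loc, gar, rack = block_rows[k]
                rows.append({"seedling": f"s{counter:05d}", "family": fam,
                             "locality": loc, "garden": gar, "bed_rack": rack})
                counter += 1
    return pd.DataFrame(rows)


def transfer_distances_z(source_climate: pd.DataFrame,
                         garden_climate: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distance between z-scored climate vectors (sources and
    gardens standardized jointly); rows = sources, columns = gardens."""
    joint = pd.concat([source_climate, garden_climate])
    z = (joint - joint.mean()) / joint.std(ddof=1)
    zs = z.loc[source_climate.index].to_numpy()
    zg = z.loc[garden_climate.index].to_numpy()
    d = np.sqrt(((zs[:, None, :] - zg[None, :, :]) ** 2).sum(axis=2))
    return pd.DataFrame(d, index=source_climate.index, columns=garden_climate.index)


def simulate_common_garden(design: pd.DataFrame, truth: SyntheticTruth,
                           cfg: SimulationConfig | None = None,
                           seed=None) -> pd.DataFrame:
    """Simulate seedling height growth for a planting design.

    height = baseline - beta * (transfer distance)^2 + genotype effects
    + family effect + bed-rack effect + residual, truncated at zero; with
    probability ``p_mortality`` the seedling dies and is scored zero.

    Per-locus genotype effect sizes are calibrated so that each designated
    effect locus accounts for ``effect_variance_fraction`` of the total
    phenotypic variance (mortality inflation included analytically).
    """
    cfg = cfg or truth.config
    rng = np.random.default_rng(seed) if seed is not None else _streams(cfg.seed)["garden"]
    missing = set(design["garden"]) - set(truth.garden_climate.index)
    if missing:
        raise ValueError(f"garden missing from ClimateTable: {sorted(missing)}")
    if truth.dosages is None and cfg.n_effect_loci:
        raise ValueError("truth.dosages required to apply genotype effects")

    dist = transfer_distances_z(truth.climate, truth.garden_climate)
    d2 = np.array([dist.loc[loc, gar] ** 2
                   for loc, gar in zip(design["locality"], design["garden"])])
    penalty = cfg.transfer_beta * d2

    fams = design["family"].unique()
    fam_eff = pd.Series(rng.normal(0, cfg.family_sd, len(fams)), index=fams)
    racks = design["bed_rack"].unique()
    rack_eff = pd.Series(rng.normal(0, cfg.bed_rack_sd, len(racks)), index=racks)

    # analytic variance calibration for the planted per-locus effects: each
    # effect locus accounts for `effect_variance_fraction` of the total
    # within-garden phenotypic variance, averaged over gardens, with the
    # mortality inflation ((1-p) Var + p (1-p) mu^2) included.  Solved by
    # fixed-point iteration because the total itself contains the effects.
    pen_ser = pd.Series(penalty)
    var_quad_g = pen_ser.groupby(design["garden"].to_numpy()).var(ddof=0)
    mu_g = cfg.baseline_height - pen_ser.groupby(design["garden"].to_numpy()).mean()
    base_g = (cfg.family_sd**2 + cfg.bed_rack_sd**2 + cfg.residual_sd**2
              + var_quad_g)
    p, f_eff, k_eff = cfg.p_mortality, cfg.effect_variance_fraction, cfg.n_effect_loci
    geno_term = np.zeros(len(design))
    effect_loci = []
    if k_eff:
        if k_eff * f_eff >= 1:
            raise ValueError("total planted effect variance must stay below 1")
        hosts = list(truth.loci_with_label(cfg.effect_locus_label))
        if len(hosts) < k_eff:
            raise ValueError(
                f"not enough {cfg.effect_locus_label!r} loci to host the effects")
        effect_loci = list(rng.choice(hosts, size=k_eff, replace=False))
        g = truth.dosages.loc[design["family"], effect_loci].to_numpy()
        var_g = g.var(axis=0, ddof=0)
        var_g[var_g == 0] = np.nan
        s_tot = 0.0
        for _ in range(4):
            total_g = (1 - p) * (base_g + s_tot) + p * (1 - p) * mu_g**2
            beta_sq_varg = f_eff / ((1 - p) * float(np.mean(1.0 / total_g)))
            s_tot = k_eff * beta_sq_varg
        beta = np.nan_to_num(np.sqrt(beta_sq_varg / var_g))
        signs = rng.choice([-1.0, 1.0], k_eff)
        beta = beta * signs
        geno_term = (g - g.mean(axis=0)) @ beta
        truth.labels.loc[effect_loci, "effect"] = beta

    height = (cfg.baseline_height - penalty + geno_term
              + fam_eff.loc[design["family"]].to_numpy()
              + rack_eff.loc[design["bed_rack"]].to_numpy()
              + rng.normal(0, cfg.residual_sd, len(design)))
    height = np.maximum(height, 0.0)
    dead = rng.random(len(design)) < p
    height[dead] = 0.0

    traits = design.copy()
    traits["height_growth"] = height
    return traits


def simulate_study(cfg: SimulationConfig | None = None) -> SyntheticTruth:
    """Run the full generator: landscape, mother-tree dosages, design and
    common-garden traits.  Families are the genotyped mother trees,
    distributed round-robin over localities."""
    cfg = cfg or SimulationConfig()
    truth = simulate_landscape(cfg)
    streams = _streams(cfg.seed)

    n_loc = cfg.n_localities
    base, extra = divmod(cfg.n_families, n_loc)
    if base < 1:
        raise ValueError("need at least one family per locality")
    counts = {loc: base + (1 if i < extra else 0)
              for i, loc in enumerate(truth.freqs.index)}
    dosages, membership = sample_dosages(
        truth.freqs, counts, seed=streams["dosages"].integers(2**31 - 1))
    truth.dosages, truth.membership = dosages, membership

    design = make_design(cfg.n_families, membership,
                         gardens=list(truth.garden_climate.index),
                         blocks_per_garden=cfg.blocks_per_garden,
                         seedlings_per_family_per_block=cfg.seedlings_per_family_per_block,
                         seed=streams["design"].integers(2**31 - 1))
    truth.design = design
    truth.traits = simulate_common_garden(design, truth, cfg)
    return truth
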