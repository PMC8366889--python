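"""Synthetic forest scenes with known ground truth.

The generator emulates the airborne campaign over a mixed conifer-angiosperm
stand: ~1,300 circular crowns of 13 species with fixed relative abundances,
a 2-m 284-band reflectance cube (400-2,424 nm), a terrain-normalised lidar
point cloud, and per-pixel environmental rasters spanning the stated
gradients (elevation 655-810 m, PAR 525-8,414 W m-2 day-1, ...).

Each crown's true trait vector follows the additive generative model

    trait = species mean
          + sum_c slope(species, c) * z_c          (environment + interaction)
          + G90 cell effect + G40 cell effect      (spatial random effects)
          + residual noise

with z_c the covariate standardised to its configured range.  The spectral
and lidar forward models are built to be exactly invertible by the retrieval
stage in the noise-free limit: index-band reflectances are solved
analytically from the target trait values, the top lidar return is pinned at
the true canopy height, and ground returns follow the Beer-Lambert gap
fraction exp(-k*PAI).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq
from shapely.geometry import Point

from .datatypes import (BIOCHEMICAL_TRAITS, ENV_CATEGORICAL, ENV_NUMERIC,
                        TRAITS, ConfigurationError, CrownRecord, EnvRasters,
                        GenerationError, PointCloud, SpectralCube,
                        empty_trait_table)
from .retrieval import FHD_LAYER_HEIGHT, PAI_K, assign_env_to_crowns

# ------------------------------------------------------------- configuration

#: Stand composition: species, class, relative abundance (fraction of the
#: 1,307 mapped canopy trees).
SPECIES_TABLE = [
    ("Fagus sylvatica", "angiosperm", 0.396),
    ("Fraxinus excelsior", "angiosperm", 0.193),
    ("Acer pseudoplatanus", "angiosperm", 0.129),
    ("Abies alba", "conifer", 0.083),
    ("Tilia platyphyllos", "angiosperm", 0.080),
    ("Picea abies", "conifer", 0.040),
    ("Ulmus glabra", "angiosperm", 0.033),
    ("Acer platanoides", "angiosperm", 0.030),
    ("Quercus petrea", "angiosperm", 0.007),
    ("Carpinus betulus", "angiosperm", 0.006),
    ("Acer campestre", "angiosperm", 0.002),
    ("Pinus sylvestris", "conifer", 0.001),
    ("Sorbus aria", "angiosperm", 0.001),
]

#: Site environmental ranges (min, max) for the numeric covariates.
ENV_RANGES = {
    "PAR": (525.0, 8414.0),        # W m-2 day-1
    "elevation": (655.0, 810.0),   # m
    "slope": (3.9, 58.4),          # degrees
    "curvature": (-0.387, 0.287),
}

#: Number of levels per categorical covariate.
ENV_LEVELS = {"aspect": 8, "soil_type": 3, "soil_depth": 3,
              "soil_rocks": 3, "understory": 9, "herbs": 9}

DEFAULT_WAVELENGTHS = np.linspace(400.0, 2424.0, 284)


@dataclass
class SpeciesSpec:
    """One species: abundance, trait means and environmental slopes.

    ``slopes[trait][covariate]`` is the species' full response slope per unit
    of the standardised covariate z in [-1, 1]; species-specific deviations
    of the PAR slope encode the taxonomy x environment interaction.
    """

    name: str
    tree_class: str
    abundance: float
    trait_means: dict
    slopes: dict


@dataclass
class SimConfig:
    n_crowns: int = 1307
    species_table: list = field(default_factory=list)
    env_ranges: dict = field(default_factory=lambda: dict(ENV_RANGES))
    env_levels: dict = field(default_factory=lambda: dict(ENV_LEVELS))
    grid_sd_90: dict = field(default_factory=dict)   # trait -> SD
    grid_sd_40: dict = field(default_factory=dict)
    resid_sd: dict = field(default_factory=dict)
    spectral_noise_sd: float = 0.0
    shadow_fraction: float = 0.0
    shadow_scale: float = 0.2
    scene_extent: tuple = (260.0, 260.0)   # m
    pixel_size: float = 2.0
    points_per_m2: float = 40.0
    crown_radius_log_mean: float = math.log(2.4)
    crown_radius_log_sd: float = 0.20
    crown_radius_bounds: tuple = (1.8, 4.5)
    overlap: float = 0.10     # permitted fractional crown-circle overlap
    seed: int = 0

    def validate(self):
        if not self.species_table:
            raise ConfigurationError("species_table is empty")
        ab = np.array([s.abundance for s in self.species_table])
        if abs(ab.sum() - 1.0) > 0.01:
            raise ConfigurationError(
                f"species abundances sum to {ab.sum():.4f}, not 1")
        if (ab < 0).any():
            raise ConfigurationError("negative abundance")
        for d in (self.grid_sd_90, self.grid_sd_40, self.resid_sd):
            if any(v < 0 for v in d.values()):
                raise ConfigurationError("SDs must be >= 0")
        if self.pixel_size <= 0:
            raise ConfigurationError("pixel_size must be > 0")
        if self.scene_extent[0] <= 0 or self.scene_extent[1] <= 0:
            raise ConfigurationError("scene area must be positive")
        if self.spectral_noise_sd < 0:
            raise ConfigurationError("spectral_noise_sd must be >= 0")


@dataclass
class SyntheticScene:
    crowns: list
    truth: pd.DataFrame                 # generator-assigned TraitTable
    cube: SpectralCube | None
    cloud: PointCloud | None
    env_rasters: EnvRasters
    truth_partition: pd.DataFrame       # expected %SS per aggregated term
    shadow_labels: np.ndarray | None    # True where pixel generated shaded
    config: SimConfig
    components: dict | None = None      # trait -> {category -> array}


# Qualitative variance structure for the default demonstration stand:
# aggregated share of total trait variance per component (taxonomy higher
# for biochemical traits, environment dominating the architectural ones).
DEFAULT_SHARES = {
    #        taxonomy  env  interaction  spatial  residual
    "CHL": (0.15, 0.11, 0.03, 0.12, 0.59),
    "CAR": (0.18, 0.10, 0.03, 0.12, 0.57),
    "LWC": (0.28, 0.10, 0.02, 0.12, 0.48),
    "PAI": (0.05, 0.30, 0.03, 0.13, 0.49),
    "FHD": (0.04, 0.06, 0.01, 0.13, 0.76),
    "CH":  (0.07, 0.40, 0.03, 0.13, 0.37),
}

#: Overall trait level and total SD the default stand is calibrated to.
TRAIT_BASE = {"CHL": 0.55, "CAR": 4.5, "LWC": 0.25,
              "PAI": 4.0, "FHD": 1.10, "CH": 27.0}
TRAIT_TOTAL_SD = {"CHL": 0.08, "CAR": 0.90, "LWC": 0.06,
                  "PAI": 1.00, "FHD": 0.28, "CH": 6.0}

# Fixed per-species patterns (standardised below to abundance-weighted mean
# 0, variance 1).  Conifers (indices 3, 5, 11) sit low in CHL/CAR and high
# in LWC, mirroring the class contrast in the field data.
_SPECIES_PATTERN = {
    "CHL": [0.8, 0.4, 0.9, -1.6, 0.2, -1.4, 0.6, 1.0, -0.2, 0.3, 0.5, -1.8, 0.1],
    "CAR": [0.7, 0.9, 0.3, -1.5, 0.5, -1.7, 0.2, 0.8, 0.0, -0.3, 0.6, -1.4, 0.4],
    "LWC": [-0.7, -0.4, -0.9, 1.6, -0.3, 1.8, -0.6, -0.8, 0.2, -0.1, -0.5, 1.5, 0.0],
    "PAI": [1.0, -0.5, 0.3, 0.8, -0.9, 1.2, -0.4, 0.6, -1.1, 0.2, -0.8, 0.9, -0.6],
    "FHD": [-0.6, 0.9, -0.3, 1.1, 0.4, 0.8, -1.0, 0.2, 0.6, -1.2, 0.3, 1.0, -0.8],
    "CH":  [1.1, 0.6, -0.2, 0.9, -0.7, 1.3, -0.9, -0.4, -1.2, 0.1, -1.0, 0.8, -0.3],
}
# Species deviations of the PAR response (taxonomy x environment).
_PAR_DEV_PATTERN = [1.2, 0.8, -0.6, -1.1, 0.3, -1.4, 0.5, 1.0,
                    -0.2, 0.4, -0.8, -1.2, 0.6]

# Allocation of the environment share across covariates, with response signs
# (PAI and CH increase with light, CH decreases with elevation).
_ENV_WEIGHTS = {"PAR": 0.55, "elevation": 0.30, "slope": 0.10,
                "curvature": 0.05}
_ENV_SIGNS = {
    "CHL": {"PAR": -1, "elevation": -1, "slope": 1, "curvature": 1},
    "CAR": {"PAR": 1, "elevation": -1, "slope": -1, "curvature": 1},
    "LWC": {"PAR": -1, "elevation": 1, "slope": -1, "curvature": -1},
    "PAI": {"PAR": 1, "elevation": -1, "slope": -1, "curvature": 1},
    "FHD": {"PAR": 1, "elevation": -1, "slope": 1, "curvature": -1},
    "CH":  {"PAR": 1, "elevation": -1, "slope": -1, "curvature": 1},
}
_Z_SD = 1.0 / math.sqrt(3.0)   # SD of a standardised covariate ~U(-1, 1)


def _weighted_standardise(raw, weights):
    raw = np.asarray(raw, dtype=float)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    mu = float(w @ raw)
    var = float(w @ (raw - mu) ** 2)
    return (raw - mu) / math.sqrt(var)


def default_config(n_crowns: int = 1307, seed: int = 0,
                   shares: dict | None = None, **overrides) -> SimConfig:
    """The default demonstration stand (13 species, Table-like abundances).

    ``shares`` optionally replaces the per-trait aggregated variance
    structure (taxonomy, environment, interaction, spatial, residual).
    """
    shares = dict(DEFAULT_SHARES if shares is None else shares)
    weights = [a for (_, _, a) in SPECIES_TABLE]
    species = []
    grid90, grid40, resid = {}, {}, {}
    means_by_trait = {}
    devs = _weighted_standardise(_PAR_DEV_PATTERN, weights)
    for t in TRAITS:
        tax, env, inter, spat, res = shares[t]
        sd = TRAIT_TOTAL_SD[t]
        offs = _weighted_standardise(_SPECIES_PATTERN[t], weights)
        means_by_trait[t] = TRAIT_BASE[t] + offs * sd * math.sqrt(tax)
        grid90[t] = sd * math.sqrt(spat / 2.0)
        grid40[t] = sd * math.sqrt(spat / 2.0)
        resid[t] = sd * math.sqrt(res)
    for i, (name, cls, ab) in enumerate(SPECIES_TABLE):
        trait_means = {t: float(means_by_trait[t][i]) for t in TRAITS}
        slopes = {}
        for t in TRAITS:
            tax, env, inter, spat, res = shares[t]
            sd = TRAIT_TOTAL_SD[t]
            s = {}
            for c, w in _ENV_WEIGHTS.items():
                s[c] = _ENV_SIGNS[t][c] * sd * math.sqrt(env * w) / _Z_SD
            # interaction: species deviation of the PAR response
            s["PAR"] += devs[i] * sd * math.sqrt(inter) / _Z_SD
            slopes[t] = s
        species.append(SpeciesSpec(name, cls, ab, trait_means, slopes))
    cfg = SimConfig(n_crowns=n_crowns, species_table=species,
                    grid_sd_90=grid90, grid_sd_40=grid40, resid_sd=resid,
                    seed=seed, **overrides)
    cfg.validate()
    return cfg


# ------------------------------------------------------------ forward models

# Smooth "base leaf" reflectance templates (wavelength nm, reflectance);
# index-band values are overwritten analytically per crown.
_TEMPLATE_ANGIO = [(400, 0.03), (500, 0.05), (550, 0.12), (680, 0.04),
                   (705, 0.10), (750, 0.42), (780, 0.46), (860, 0.46),
                   (1000, 0.44), (1240, 0.38), (1450, 0.12), (1650, 0.22),
                   (1950, 0.05), (2200, 0.12), (2424, 0.04)]
_TEMPLATE_CONIFER = [(400, 0.025), (500, 0.04), (550, 0.09), (680, 0.035),
                     (705, 0.08), (750, 0.35), (780, 0.39), (860, 0.39),
                     (1000, 0.37), (1240, 0.31), (1450, 0.10), (1650, 0.18),
                     (1950, 0.04), (2200, 0.10), (2424, 0.035)]
_TEMPLATE_SOIL = [(400, 0.08), (700, 0.18), (1300, 0.30), (2424, 0.25)]


def _template(control, wavelengths):
    w, r = zip(*control)
    return np.interp(wavelengths, w, r)


def base_leaf_spectrum(wavelengths, tree_class="angiosperm"):
    ctrl = _TEMPLATE_CONIFER if tree_class == "conifer" else _TEMPLATE_ANGIO
    return _template(ctrl, np.asarray(wavelengths, dtype=float))


def soil_spectrum(wavelengths):
    return _template(_TEMPLATE_SOIL, np.asarray(wavelengths, dtype=float))


def _nearest_band(wavelengths, target, tol=10.0):
    i = int(np.argmin(np.abs(wavelengths - target)))
    if abs(wavelengths[i] - target) > tol:
        raise KeyError(f"wavelength grid has no band within {tol} nm of "
                       f"{target} nm required by the index forward model")
    return i


def synthesize_spectrum(traits, wavelengths=DEFAULT_WAVELENGTHS,
                        noise_sd: float = 0.0, shadowed: bool = False,
                        tree_class: str = "angiosperm",
                        shadow_scale: float = 0.2, rng=None) -> np.ndarray:
    """Reflectance spectrum whose index bands invert to the given traits.

    ``traits`` maps at least CHL, CAR, LWC to target values.  Band
    reflectances at the index wavelengths are solved in closed form so the
    default retrieval indices recover the inputs exactly when ``noise_sd=0``
    and ``shadowed=False``.
    """
    wl = np.asarray(wavelengths, dtype=float)
    refl = base_leaf_spectrum(wl, tree_class).copy()
    chl, car, lwc = (float(traits[k]) for k in BIOCHEMICAL_TRAITS)
    if not -1.0 < chl < 1.0:
        raise ValueError("CHL index target must lie in (-1, 1)")
    if not -1.0 < lwc < 1.0:
        raise ValueError("LWC index target must lie in (-1, 1)")
    i750 = _nearest_band(wl, 750.0)
    i705 = _nearest_band(wl, 705.0)
    s = refl[i750] + refl[i705]
    refl[i750] = s * (1.0 + chl) / 2.0
    refl[i705] = s * (1.0 - chl) / 2.0
    i510 = _nearest_band(wl, 510.0)
    i550 = _nearest_band(wl, 550.0)
    if car + 1.0 / refl[i550] <= 0:
        raise ValueError("CAR target below the invertible range")
    refl[i510] = 1.0 / (car + 1.0 / refl[i550])
    i860 = _nearest_band(wl, 860.0)
    i1240 = _nearest_band(wl, 1240.0)
    s = refl[i860] + refl[i1240]
    refl[i860] = s * (1.0 + lwc) / 2.0
    refl[i1240] = s * (1.0 - lwc) / 2.0
    if shadowed:
        refl = refl * shadow_scale
    if noise_sd > 0:
        rng = np.random.default_rng() if rng is None else rng
        refl = refl + rng.normal(0.0, noise_sd, refl.shape)
    return refl


def fhd_layer_weights(fhd: float, ch: float,
                      layer_height: float = FHD_LAYER_HEIGHT) -> np.ndarray:
    """5-m layer occupancy proportions with Shannon entropy ``fhd``.

    Uses the one-parameter geometric family p_i proportional to exp(-lam*i),
    whose entropy decreases monotonically from ln(L) (uniform, lam=0) to 0.
    """
    n_layers = max(1, int(math.ceil(ch / layer_height)))
    if n_layers == 1:
        return np.ones(1)
    hmax = math.log(n_layers)
    if not 0.0 <= fhd <= hmax + 1e-9:
        raise ValueError(f"FHD target {fhd} outside [0, ln {n_layers}]")

    def entropy(lam):
        w = np.exp(-lam * np.arange(n_layers))
        p = w / w.sum()
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    if fhd >= hmax - 1e-9:
        return np.ones(n_layers) / n_layers
    hi = 1.0
    while entropy(hi) > fhd:
        hi *= 2.0
        if hi > 1e4:
            break
    lam = brentq(lambda L: entropy(L) - fhd, 0.0, hi, xtol=1e-12)
    w = np.exp(-lam * np.arange(n_layers))
    return w / w.sum()


def synthesize_pointcloud(ch: float, pai: float, layer_weights,
                          density: float, crown_area: float,
                          seed=None, rng=None, k: float = PAI_K,
                          center=(0.0, 0.0), radius: float | None = None,
                          canopy_floor: float = 2.0,
                          layer_height: float = FHD_LAYER_HEIGHT) -> PointCloud:
    """Lidar returns for one crown.

    One return is pinned exactly at ``ch``; ground returns occur with the
    Beer-Lambert probability exp(-k*PAI); the remaining canopy returns are
    drawn from the 5-m layer mixture (heights kept above ``canopy_floor`` so
    the gap-fraction PAI estimator sees only true ground returns below its
    cutoff).
    """
    if ch <= canopy_floor:
        raise ValueError(f"canopy height must exceed {canopy_floor} m")
    w = np.asarray(layer_weights, dtype=float)
    if (w < 0).any() or abs(w.sum() - 1.0) > 1e-8:
        raise ValueError("layer_weights must be non-negative and sum to 1")
    expected = int(math.ceil(ch / layer_height))
    if w.size != expected:
        raise ValueError(f"need {expected} layer weights for ch={ch}")
    n = int(round(density * crown_area))
    if n < 2:
        raise ValueError("density x crown_area < 2: cannot represent both "
                         "canopy top and ground")
    rng = np.random.default_rng(seed) if rng is None else rng
    p_ground = math.exp(-k * pai)
    n_ground = rng.binomial(n - 1, p_ground)
    n_canopy = n - 1 - n_ground
    z = np.empty(n)
    is_ground = np.zeros(n, dtype=bool)
    z[0] = ch                                   # pinned top return
    z[1:1 + n_ground] = rng.uniform(0.0, 0.3, n_ground)
    is_ground[1:1 + n_ground] = True
    if n_canopy:
        layers = rng.choice(w.size, size=n_canopy, p=w)
        lo = np.maximum(layers * layer_height, canopy_floor)
        hi = np.minimum((layers + 1) * layer_height, ch)
        z[1 + n_ground:] = rng.uniform(lo, hi)
    if radius is None:
        x = np.full(n, center[0])
        y = np.full(n, center[1])
    else:
        r = radius * np.sqrt(rng.uniform(0.0, 1.0, n))
        th = rng.uniform(0.0, 2.0 * math.pi, n)
        x = center[0] + r * np.cos(th)
        y = center[1] + r * np.sin(th)
    return PointCloud(x, y, z, is_ground)


# ----------------------------------------------------------- DNA alignment

#: Synthetic phylogeny for the 13 species (invented topology; only the deep
#: conifer/angiosperm split is meaningful).  Branch lengths in subs/site.
DEFAULT_TREE_NEWICK = (
    "(((((((Acer_pseudoplatanus:0.02,Acer_platanoides:0.02):0.02,"
    "Acer_campestre:0.04):0.04,Tilia_platyphyllos:0.09):0.03,"
    "((Fagus_sylvatica:0.06,Quercus_petrea:0.06):0.03,"
    "Carpinus_betulus:0.09):0.03):0.02,"
    "(Ulmus_glabra:0.10,Sorbus_aria:0.10):0.02):0.02,"
    "Fraxinus_excelsior:0.14):0.25,"
    "((Abies_alba:0.05,Picea_abies:0.05):0.04,"
    "Pinus_sylvestris:0.09):0.25);")

_ALIGN_FREQS = np.array([0.30, 0.20, 0.20, 0.30])   # ACGT


def synthesize_alignment(n_sites: int = 2000, seed: int | None = None,
                         newick: str = DEFAULT_TREE_NEWICK,
                         freqs=_ALIGN_FREQS, kappa: float = 2.0):
    """Evolve a synthetic concatenated alignment along the species tree.

    Sequences evolve site-independently under F84 (transition/transversion
    parameter ``kappa``, stationary frequencies ``freqs``); the returned
    :class:`~crowntraits.phylo.Alignment` has one taxon per tree leaf.
    """
    import dendropy
    from scipy.linalg import expm

    from .phylo import Alignment, f84_rate_matrix

    rng = np.random.default_rng(seed)
    tree = dendropy.Tree.get(data=newick, schema="newick")
    Q = f84_rate_matrix(freqs, kappa)
    seqs = {}
    root = tree.seed_node
    root_seq = rng.choice(4, size=n_sites, p=np.asarray(freqs))
    states = {root: root_seq}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        P = expm(Q * (node.edge.length or 0.0))
        cum = P.cumsum(axis=1)
        parent = states[node.parent_node]
        u = rng.random(n_sites)
        child = (u[:, None] > cum[parent]).sum(axis=1)
        states[node] = child
        if node.is_leaf():
            seqs[node.taxon.label] = child
    names = sorted(seqs)
    codes = np.vstack([seqs[n] for n in names]).astype(np.int8)
    return Alignment(names, codes)


# --------------------------------------------------------------- the scene

def _place_crowns(cfg: SimConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    """Poisson-disk style dart throwing with permitted fractional overlap."""
    W, H = cfg.scene_extent
    rlo, rhi = cfg.crown_radius_bounds
    sep = 1.0 - cfg.overlap
    xs, ys, rs = [], [], []
    attempts, max_attempts = 0, 400 * cfg.n_crowns
    while len(xs) < cfg.n_crowns:
        attempts += 1
        if attempts > max_attempts:
            raise GenerationError(
                f"could not place {cfg.n_crowns} crowns in "
                f"{W:.0f}x{H:.0f} m after {max_attempts} attempts")
        r = float(np.clip(rng.lognormal(cfg.crown_radius_log_mean,
                                        cfg.crown_radius_log_sd), rlo, rhi))
        x = rng.uniform(r, W - r)
        y = rng.uniform(r, H - r)
        if xs:
            d = np.hypot(np.array(xs) - x, np.array(ys) - y)
            if (d < sep * (np.array(rs) + r)).any():
                continue
        xs.append(x); ys.append(y); rs.append(r)
    return np.array(xs), np.array(ys), np.array(rs)


def _smooth_field(shape, rng, sigma_px=8.0):
    f = gaussian_filter(rng.standard_normal(shape), sigma_px)
    lo, hi = f.min(), f.max()
    return (f - lo) / (hi - lo)     # in [0, 1]


def _env_rasters(cfg: SimConfig, rng) -> EnvRasters:
    W, H = cfg.scene_extent
    px = cfg.pixel_size
    rows = int(round(H / px))
    cols = int(round(W / px))
    layers = {}
    yy = (np.arange(rows) + 0.5)[:, None] * px / H    # 0 south -> 1 north
    lo, hi = cfg.env_ranges["elevation"]
    layers["elevation"] = np.broadcast_to(lo + yy * (hi - lo),
                                          (rows, cols)).copy()
    for name in ("PAR", "slope", "curvature"):
        lo, hi = cfg.env_ranges[name]
        layers[name] = lo + _smooth_field((rows, cols), rng) * (hi - lo)
    block = max(1, int(round(30.0 / px)))   # ~30 m categorical patches
    for name, n_levels in cfg.env_levels.items():
        coarse = rng.integers(1, n_levels + 1,
                              (rows // block + 1, cols // block + 1))
        layers[name] = np.kron(coarse, np.ones((block, block),
                                               dtype=int))[:rows, :cols]
    return EnvRasters(layers, origin=(0.0, 0.0), pixel_size=px)


def _standardise_env(value, name, env_ranges):
    lo, hi = env_ranges[name]
    return (value - (lo + hi) / 2.0) / ((hi - lo) / 2.0)


def simulate_forest(config: SimConfig, traits_only: bool = False,
                    assign_truth_ids: bool = False) -> SyntheticScene:
    """Generate a full synthetic scene (crowns, truth, cube, cloud, env).

    With ``traits_only=True`` the expensive imagery and point cloud are
    skipped (``cube``/``cloud`` are None) — sufficient for variance
    partitioning and classification studies.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    xs, ys, rs = _place_crowns(config, rng)
    ab = np.array([s.abundance for s in config.species_table])
    sp_idx = rng.choice(len(config.species_table), size=config.n_crowns,
                        p=ab / ab.sum())
    crowns = []
    for i in range(config.n_crowns):
        sp = config.species_table[sp_idx[i]]
        poly = Point(xs[i], ys[i]).buffer(rs[i], quad_segs=12)
        crowns.append(CrownRecord(i, sp.name, sp.tree_class, poly))

    env = _env_rasters(config, rng)
    assign_env_to_crowns(env, crowns)

    # standardised covariates per crown
    z = {c: np.array([_standardise_env(cr.env[c], c, config.env_ranges)
                      for cr in crowns]) for c in ENV_NUMERIC}

    # Environmental design used to orthogonalise the grid effects: the
    # spatial grids model spatial variation NOT explained by environment,
    # and the smooth/blocky covariate fields are themselves spatially
    # structured, so raw cell effects would leak into the (earlier-fitted)
    # environment terms.
    # Only the numeric covariates are used: they carry real effects and are
    # always retained by elimination, whereas orthogonalising against the
    # (null) categorical dummies would park spatial energy in directions
    # that leave the model when those terms are eliminated.
    E = np.column_stack([np.ones(config.n_crowns)]
                        + [z[c] for c in ENV_NUMERIC])

    def _orthogonalise(v):
        beta, *_ = np.linalg.lstsq(E, v, rcond=None)
        return v - E @ beta

    # spatial random effects keyed by occupied grid cell
    def grid_effects(cell_size, sd_by_trait):
        cells = [(int(x // cell_size), int(y // cell_size))
                 for x, y in zip(xs, ys)]
        uniq = sorted(set(cells))
        eff = {}
        for t in TRAITS:
            draw = {c: rng.normal(0.0, sd_by_trait.get(t, 0.0))
                    for c in uniq}
            eff[t] = _orthogonalise(np.array([draw[c] for c in cells]))
        return eff

    eff90 = grid_effects(90.0, config.grid_sd_90)
    eff40 = grid_effects(40.0, config.grid_sd_40)

    mean_slopes = {}
    for t in TRAITS:
        mean_slopes[t] = {c: float(sum(s.abundance * s.slopes[t].get(c, 0.0)
                                       for s in config.species_table) / ab.sum())
                          for c in ENV_NUMERIC}

    truth = empty_trait_table([c.crown_id for c in crowns])
    parts = {t: {} for t in TRAITS}
    for t in TRAITS:
        means = np.array([config.species_table[j].trait_means[t]
                          for j in sp_idx])
        env_part = np.zeros(config.n_crowns)
        int_part = np.zeros(config.n_crowns)
        for c in ENV_NUMERIC:
            full = np.array([config.species_table[j].slopes[t].get(c, 0.0)
                             for j in sp_idx])
            env_part += mean_slopes[t][c] * z[c]
            int_part += (full - mean_slopes[t][c]) * z[c]
        spat = eff90[t] + eff40[t]
        resid = rng.normal(0.0, config.resid_sd.get(t, 0.0), config.n_crowns)
        vals = means + env_part + int_part + spat + resid
        # keep traits inside the physically invertible range
        if t == "CHL" or t == "LWC":
            clipped = np.clip(vals, -0.95, 0.95)
        elif t == "CAR":
            clipped = np.clip(vals, 0.2, None)
        elif t == "CH":
            clipped = np.clip(vals, 2.5, None)
        elif t == "PAI":
            clipped = np.clip(vals, 0.1, None)
        else:
            clipped = vals
        resid = resid + (clipped - vals)   # fold clipping into residual
        truth[t] = clipped
        parts[t] = {"taxonomy": means, "environment": env_part,
                    "interaction": int_part, "spatial": spat,
                    "residual": resid}
    # FHD must respect its entropy bound given the realised CH
    hmax = np.log(np.maximum(np.ceil(truth["CH"] / FHD_LAYER_HEIGHT), 1.0))
    bounded = np.clip(truth["FHD"], 0.0, np.maximum(hmax - 1e-3, 0.0))
    parts["FHD"]["residual"] = (parts["FHD"]["residual"]
                                + (bounded - truth["FHD"].to_numpy()))
    truth["FHD"] = bounded

    truth_partition = _truth_partition(parts)

    cube = cloud = shadow_labels = None
    if not traits_only:
        cube, shadow_labels = _build_cube(config, crowns, truth, rng)
        cloud = _build_cloud(config, crowns, truth, xs, ys, rs, rng,
                             assign_truth_ids)
    return SyntheticScene(crowns, truth, cube, cloud, env, truth_partition,
                          shadow_labels, config, components=parts)


def _truth_partition(parts) -> pd.DataFrame:
    """Expected aggregated %SS from the realised generative components.

    Sequential projection of the trait vector onto the spans of the
    generative components in fitting order (taxonomy, environment,
    interaction, spatial); the residual takes the remainder, so the shares
    are additive exactly like a Type-I decomposition.
    """
    cats = ("taxonomy", "environment", "interaction", "spatial")
    rows = {}
    for t in TRAITS:
        y = np.asarray(sum(parts[t][c] for c in cats + ("residual",)),
                       dtype=float)
        n = y.size
        ybar = y.mean()
        total = float(((y - ybar) ** 2).sum())
        Q = np.ones((n, 1)) / math.sqrt(n)
        shares = []
        for c in cats:
            v = parts[t][c].astype(float)[:, None]
            r = v - Q @ (Q.T @ v)
            norm = np.linalg.norm(r)
            if norm < 1e-12 * max(1.0, np.linalg.norm(v)):
                shares.append(0.0)
                continue
            q = r / norm
            shares.append(float(((q.T @ y) ** 2).item()))
            Q = np.hstack([Q, q])
        shares.append(max(total - sum(shares), 0.0))
        rows[t] = 100.0 * np.array(shares) / total
    df = pd.DataFrame(rows, index=list(cats) + ["residual"]).T
    df.loc["multivariate"] = df.loc[list(TRAITS)].mean()
    return df


def _build_cube(config, crowns, truth, rng):
    W, H = config.scene_extent
    px = config.pixel_size
    rows, cols = int(round(H / px)), int(round(W / px))
    wl = DEFAULT_WAVELENGTHS
    refl = np.broadcast_to(soil_spectrum(wl), (rows, cols, wl.size)).copy()
    cube = SpectralCube(refl, wl, origin=(0.0, 0.0), pixel_size=px)
    shadow_labels = np.zeros((rows, cols), dtype=bool)
    from .retrieval import pixels_in_crown
    for crown in crowns:
        rr, cc = pixels_in_crown(cube, crown)
        if rr.size == 0:
            raise GenerationError(
                f"crown {crown.crown_id} contains no pixel centroid")
        shaded = rng.random(rr.size) < config.shadow_fraction
        if shaded.all():
            shaded[0] = False      # every crown keeps >=1 sun-lit pixel
        tr = truth.loc[crown.crown_id, list(TRAITS)]
        sunlit = synthesize_spectrum(tr, wl, tree_class=crown.tree_class)
        block = np.where(shaded[:, None], sunlit * config.shadow_scale,
                         sunlit)
        if config.spectral_noise_sd > 0:
            block = block + rng.normal(0.0, config.spectral_noise_sd,
                                       block.shape)
        cube.reflectance[rr, cc, :] = block
        shadow_labels[rr[shaded], cc[shaded]] = True
    return cube, shadow_labels


def _build_cloud(config, crowns, truth, xs, ys, rs, rng, assign_ids=True):
    pieces = []
    ids = []
    for i, crown in enumerate(crowns):
        ch = float(truth.loc[crown.crown_id, "CH"])
        pai = float(truth.loc[crown.crown_id, "PAI"])
        fhd = float(truth.loc[crown.crown_id, "FHD"])
        weights = fhd_layer_weights(fhd, ch)
        pc = synthesize_pointcloud(
            ch, pai, weights, config.points_per_m2, crowns[i].polygon.area,
            rng=rng, center=(xs[i], ys[i]), radius=0.99 * rs[i])
        pieces.append(pc)
        ids.append(np.full(len(pc), crown.crown_id))
    x = np.concatenate([p.x for p in pieces])
    y = np.concatenate([p.y for p in pieces])
    z = np.concatenate([p.z for p in pieces])
    g = np.concatenate([p.is_ground for p in pieces])
    cid = np.concatenate(ids) if assign_ids else None
    return PointCloud(x, y, z, g, cid)
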