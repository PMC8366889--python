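"""Species-mean distance matrices and permutation Mantel tests.

Species means (traits and crown-mean spectra) are computed over the
abundance-filtered species set; trait distances are Euclidean on min-max
rescaled traits, spectral distances Euclidean over wavelength windows
(VIS 400-700, NIR 700-1,300, SWIR 1,300-2,500 nm, half-open on the right
edge so shared endpoints count once).  All matrices are min-max rescaled to
[0, 1] before correlation.  The Mantel statistic is the Pearson correlation
of the lower-triangle vectors; its p-value comes from jointly permuting the
rows and columns of the second matrix, one-sided (greater) with the +1
correction p = (1 + #{r_perm >= r_obs}) / (1 + n_permutations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .datatypes import (ARCHITECTURAL_TRAITS, BIOCHEMICAL_TRAITS, TRAITS)
from .phylo import DistanceMatrix, rescale_distance

SPECTRAL_WINDOWS = {
    "full": (400.0, 2500.0),
    "VIS": (400.0, 700.0),
    "NIR": (700.0, 1300.0),
    "SWIR": (1300.0, 2500.0),
}

TRAIT_SUBSETS = {
    "all": TRAITS,
    "biochemical": BIOCHEMICAL_TRAITS,
    "architectural": ARCHITECTURAL_TRAITS,
}


@dataclass
class SpeciesMeans:
    """Per-species trait means and mean crown spectra."""

    traits: pd.DataFrame            # species x traits
    spectra: pd.DataFrame | None    # species x bands (columns = wavelengths)
    n_individuals: pd.Series


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    seed: int | None
    label_a: str = ""
    label_b: str = ""

    def __str__(self):
        return (f"Mantel[{self.label_a} ~ {self.label_b}]: "
                f"r={self.r:.3f}, p={self.p:.4g} "
                f"({self.n_permutations} permutations)")


def filter_species(trait_table: pd.DataFrame, crowns,
                   spectra: dict | None = None,
                   min_n: int = 10) -> SpeciesMeans:
    """Species means for species with at least ``min_n`` individuals.

    ``spectra`` maps crown_id -> Spectrum (crown-mean reflectance); species
    mean spectra average crown spectra with equal weight per crown.
    """
    species = pd.Series({c.crown_id: c.species for c in crowns},
                        name="species")
    counts = species.value_counts()
    kept = counts[counts >= min_n].index.tolist()
    if len(kept) < 3:
        raise ValueError(f"only {len(kept)} species have n >= {min_n}; "
                         "need at least 3 for distance analyses")
    df = trait_table.join(species)
    df = df[df["species"].isin(kept)]
    means = df.groupby("species")[list(TRAITS)].mean()
    means = means.loc[sorted(kept)]
    spec_df = None
    if spectra is not None:
        rows = {}
        wavelengths = None
        for sp in means.index:
            ids = df.index[df["species"] == sp]
            mats = [spectra[i].reflectance for i in ids
                    if spectra.get(i) is not None]
            if mats:
                rows[sp] = np.mean(mats, axis=0)
                wavelengths = next(spectra[i].wavelengths for i in ids
                                   if spectra.get(i) is not None)
        if rows:
            spec_df = pd.DataFrame.from_dict(rows, orient="index",
                                             columns=wavelengths)
            spec_df = spec_df.loc[means.index]
    return SpeciesMeans(means, spec_df, counts.loc[means.index])


def trait_distance(species_means: SpeciesMeans,
                   trait_subset: str | tuple = "all") -> DistanceMatrix:
    """Euclidean distance on min-max rescaled species trait means."""
    traits = (TRAIT_SUBSETS[trait_subset]
              if isinstance(trait_subset, str) else tuple(trait_subset))
    if not traits:
        raise ValueError("empty trait subset")
    tm = species_means.traits[list(traits)]
    if len(tm) < 2:
        raise ValueError("need at least two species")
    lo, hi = tm.min(), tm.max()
    constant = hi == lo
    if constant.any():
        import warnings
        warnings.warn(f"dropping constant traits: "
                      f"{list(tm.columns[constant])}")
        tm = tm.loc[:, ~constant]
        if tm.shape[1] == 0:
            raise ValueError("all traits constant across species")
        lo, hi = tm.min(), tm.max()
    scaled = (tm - lo) / (hi - lo)
    d = squareform(pdist(scaled.to_numpy()))
    dm = DistanceMatrix(list(tm.index), d)
    if len(tm) == 2:
        # a single off-diagonal value: min-max rescaling is undefined, so
        # the degenerate pair maps to the maximal distance 1 with a warning
        import warnings
        warnings.warn("two-species distance matrix: rescaling is "
                      "degenerate, off-diagonal set to 1")
        v = (d > 0).astype(float)
        return DistanceMatrix(list(tm.index), v, rescaled=True)
    return rescale_distance(dm)


def spectral_distance(species_means: SpeciesMeans,
                      band_window: str = "full",
                      rescale: bool = True,
                      standardize: bool = False) -> DistanceMatrix:
    """Euclidean distance on species mean spectra within a window [lo, hi).

    ``standardize`` centres and scales each band across species before the
    distance (default is raw reflectance).
    """
    if species_means.spectra is None:
        raise ValueError("species means carry no spectra")
    lo, hi = (SPECTRAL_WINDOWS[band_window]
              if isinstance(band_window, str) else band_window)
    wl = np.asarray(species_means.spectra.columns, dtype=float)
    sel = (wl >= lo) & (wl < hi)
    if not sel.any():
        raise ValueError(f"no bands in window [{lo}, {hi}) nm")
    mat = species_means.spectra.to_numpy()[:, sel]
    if standardize:
        sd = mat.std(axis=0, ddof=1)
        mat = (mat - mat.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    d = squareform(pdist(mat))
    dm = DistanceMatrix(list(species_means.spectra.index), d)
    return rescale_distance(dm) if rescale else dm


def _tri(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], 1)
    return values[iu]


def mantel_test(d1: DistanceMatrix, d2: DistanceMatrix,
                n_permutations: int = 9999,
                seed: int | None = None) -> MantelResult:
    """One-sided (greater) permutation Mantel test between two matrices."""
    if list(d1.labels) != list(d2.labels):
        raise ValueError("distance matrices must share labels and order")
    k = len(d1.labels)
    if k < 3:
        raise ValueError("Mantel test needs at least 3 labels")
    a = _tri(d1.values)
    b = _tri(d2.values)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in a distance matrix")
    r_obs = float(np.corrcoef(a, b)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    v2 = d2.values
    for _ in range(n_permutations):
        perm = rng.permutation(k)
        r_perm = float(np.corrcoef(a, _tri(v2[np.ix_(perm, perm)]))[0, 1])
        if r_perm >= r_obs:
            count += 1
    p = (1.0 + count) / (1.0 + n_permutations)
    return MantelResult(r_obs, p, n_permutations, seed)


def mantel_suite(species_means: SpeciesMeans, phylo: DistanceMatrix,
                 n_permutations: int = 9999, seed: int = 0) -> pd.DataFrame:
    """The standard comparisons: trait subsets and spectral windows vs phylogeny.

    Returns a table with one row per matrix pair (r, p, n_permutations).
    """
    phylo_r = phylo if phylo.rescaled else rescale_distance(phylo)
    order = list(species_means.traits.index)
    if sorted(order) != sorted(phylo_r.labels):
        raise ValueError("species sets of trait and phylogenetic matrices "
                         "differ")
    idx = [phylo_r.labels.index(s) for s in order]
    phylo_r = DistanceMatrix(order,
                             phylo_r.values[np.ix_(idx, idx)], rescaled=True)
    rows = []
    pairs = [("traits:" + name, trait_distance(species_means, name))
             for name in TRAIT_SUBSETS]
    if species_means.spectra is not None:
        pairs += [("spectra:" + w, spectral_distance(species_means, w))
                  for w in SPECTRAL_WINDOWS]
    for i, (name, dm) in enumerate(pairs):
        res = mantel_test(dm, phylo_r, n_permutations, seed + i)
        rows.append({"comparison": name, "vs": "phylogeny", "r": res.r,
                     "p": res.p, "n_permutations": n_permutations,
                     "seed": seed + i})
    return pd.DataFrame(rows)
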