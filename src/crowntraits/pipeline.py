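"""End-to-end orchestration: simulate -> retrieve -> partition -> distances
and Mantel -> classify -> trait maps, with a JSON manifest of every artifact.

The pipeline is deliberately a thin composition of the library stages; each
stage reads and writes the package's own formats so any stage can be rerun
in isolation from saved intermediates.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .anova import (TraitVarianceModel, build_analysis_frame, default_design,
                    multivariate_partition)
from .classify import TraitDiscriminant
from .datatypes import TRAITS
from .mantel import filter_species, mantel_suite
from .phylo import distance_matrix, rescale_distance, write_phylip
from .retrieval import pixels_in_crown, retrieve_traits
from .simulate import (SimConfig, default_config, simulate_forest,
                       synthesize_alignment)

#: Trait triplets rendered as (R, G, B) channels.
RGB_CONVENTIONS = {
    "biochemical": ("CAR", "CHL", "LWC"),   # red=CAR, green=CHL, blue=LWC
    "architectural": ("CH", "FHD", "PAI"),  # red=CH, green=FHD, blue=PAI
}


@dataclass
class PipelineConfig:
    """Stage toggles, generator block and analysis parameters."""

    simulate: SimConfig = field(default_factory=default_config)
    stages: tuple = ("simulate", "retrieve", "partition", "distances",
                     "classify", "map")
    elimination: bool = True
    min_species_n: int = 10
    mantel_permutations: int = 9999
    alignment_sites: int = 2000
    bootstrap_reps: int = 1000
    classify_priors: str = "proportional"
    seed: int = 0


def render_trait_rgb(trait_table: pd.DataFrame, crowns, triplet,
                     origin=(0.0, 0.0), pixel_size: float = 2.0,
                     extent=None):
    """Rasterised RGB map of three traits over the crown polygons.

    Each trait is min-max rescaled to 0-255 across crowns; crowns missing
    any of the three traits render as no-data (0, 0, 0 with zero alpha).
    Returns ``(rgba array, per-crown channel table)``.
    """
    if extent is None:
        xs = [c.polygon.bounds[2] for c in crowns]
        ys = [c.polygon.bounds[3] for c in crowns]
        extent = (max(xs), max(ys))
    rows = int(np.ceil((extent[1] - origin[1]) / pixel_size))
    cols = int(np.ceil((extent[0] - origin[0]) / pixel_size))
    channels = pd.DataFrame(index=trait_table.index, dtype=float)
    for t in triplet:
        vals = trait_table[t]
        lo, hi = vals.min(), vals.max()
        if hi == lo:
            warnings.warn(f"trait {t} constant across crowns; channel set "
                          "to 0")
            channels[t] = 0.0
        else:
            channels[t] = (vals - lo) / (hi - lo) * 255.0
    rgba = np.zeros((rows, cols, 4), dtype=np.uint8)

    class _Grid:
        def pixel_centroids(self):
            x = origin[0] + (np.arange(cols) + 0.5) * pixel_size
            y = origin[1] + (np.arange(rows) + 0.5) * pixel_size
            return np.meshgrid(x, y)

    grid = _Grid()
    for crown in crowns:
        vals = channels.loc[crown.crown_id, list(triplet)]
        if vals.isna().any():
            continue
        rr, cc = pixels_in_crown(grid, crown)
        rgba[rr, cc, 0] = int(round(vals.iloc[0]))
        rgba[rr, cc, 1] = int(round(vals.iloc[1]))
        rgba[rr, cc, 2] = int(round(vals.iloc[2]))
        rgba[rr, cc, 3] = 255
    return rgba, channels


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the enabled stages; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stages = set(config.stages)
    scene = None
    log: dict = {}

    if "simulate" in stages:
        scene = simulate_forest(config.simulate)
        cio.save_config(config.simulate, outdir / "sim_config.yaml")
        cio.save_crowns_geojson(scene.crowns, outdir / "crowns.geojson")
        cio.save_trait_table(scene.truth, outdir / "truth.csv")
        scene.truth_partition.to_csv(outdir / "truth_partition.csv")
        cio.save_cube_envi(scene.cube, outdir / "cube.img")
        cio.save_pointcloud_csv(scene.cloud, outdir / "cloud.csv")
        cio.save_env_rasters(scene.env_rasters, outdir / "env.npz")
        for name in ("sim_config.yaml", "crowns.geojson", "truth.csv",
                     "truth_partition.csv", "cube.img", "cloud.csv",
                     "env.npz"):
            artifacts[name] = outdir / name

    downstream = stages & {"retrieve", "partition", "distances",
                           "classify", "map"}
    if not downstream:
        manifest = {
            "seed": config.seed, "stages": sorted(stages),
            "artifacts": {k: _sha256(p)
                          for k, p in sorted(artifacts.items())},
            "log": log,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest

    crowns = scene.crowns if scene else cio.load_crowns_geojson(
        outdir / "crowns.geojson")
    spectra = None
    if "retrieve" in stages:
        cube = scene.cube if scene else cio.load_cube_envi(outdir / "cube.img")
        cloud = scene.cloud if scene else cio.load_pointcloud_csv(
            outdir / "cloud.csv")
        traits, spectra, rlog = retrieve_traits(cube, cloud, crowns)
        log["retrieval"] = {str(k): v for k, v in rlog.items() if v}
        cio.save_trait_table(traits, outdir / "traits.csv")
        artifacts["traits.csv"] = outdir / "traits.csv"
    else:
        traits = cio.load_trait_table(outdir / "traits.csv")

    if "partition" in stages:
        frame = build_analysis_frame(crowns, traits)
        shares = {}
        for t in TRAITS:
            model = TraitVarianceModel(frame, default_design(t))
            res = model.fit(eliminate=config.elimination)
            res.table.to_csv(outdir / f"anova_{t}.csv")
            artifacts[f"anova_{t}.csv"] = outdir / f"anova_{t}.csv"
            shares[t] = res.aggregate()
        agg = pd.DataFrame(shares).T
        mv = multivariate_partition(frame)
        agg.loc["multivariate"] = mv.groupby("category")["pct_ss"].sum()
        agg.to_csv(outdir / "aggregated_shares.csv")
        mv.to_csv(outdir / "anova_multivariate.csv")
        artifacts["aggregated_shares.csv"] = outdir / "aggregated_shares.csv"
        artifacts["anova_multivariate.csv"] = outdir / "anova_multivariate.csv"

    if "distances" in stages:
        means = filter_species(traits, crowns, spectra,
                               min_n=config.min_species_n)
        aln = synthesize_alignment(config.alignment_sites, seed=config.seed)
        aln.to_fasta(outdir / "alignment.fasta")
        phylo_full = distance_matrix(aln)
        keep = [i for i, n in enumerate(phylo_full.labels)
                if n in set(means.traits.index)]
        sub = phylo_full.values[np.ix_(keep, keep)]
        from .phylo import DistanceMatrix
        phylo = DistanceMatrix([phylo_full.labels[i] for i in keep], sub)
        write_phylip(rescale_distance(phylo), outdir / "phylo_rescaled.phy")
        if config.bootstrap_reps > 0:
            from .phylo import bootstrap_distances
            lo_ci, hi_ci, _ = bootstrap_distances(
                aln, n_reps=config.bootstrap_reps, seed=config.seed)
            iu = np.triu_indices(len(aln.names), 1)
            ci = pd.DataFrame({
                "taxon_a": [aln.names[i] for i in iu[0]],
                "taxon_b": [aln.names[j] for j in iu[1]],
                "distance": phylo_full.values[iu],
                "ci_lower": lo_ci[iu], "ci_upper": hi_ci[iu]})
            ci.to_csv(outdir / "phylo_bootstrap_ci.csv", index=False)
            artifacts["phylo_bootstrap_ci.csv"] = (
                outdir / "phylo_bootstrap_ci.csv")
        results = mantel_suite(means, phylo,
                               n_permutations=config.mantel_permutations,
                               seed=config.seed)
        results.to_csv(outdir / "mantel.csv", index=False)
        for name in ("alignment.fasta", "phylo_rescaled.phy", "mantel.csv"):
            artifacts[name] = outdir / name

    if "classify" in stages:
        counts = pd.Series([c.species for c in crowns]).value_counts()
        keep_sp = set(counts[counts >= config.min_species_n].index)
        labels = pd.Series({c.crown_id: c.species for c in crowns
                            if c.species in keep_sp})
        model = TraitDiscriminant(traits.loc[labels.index], labels,
                                  priors=config.classify_priors)
        res = model.fit()
        res.confusion_matrix().to_csv(outdir / "confusion.csv")
        assign = pd.DataFrame({
            "true": pd.Series(res.y, index=res.index),
            "predicted": res.predict(traits.loc[res.index])})
        assign.to_csv(outdir / "assignments.csv")
        acc = {"resubstitution": res.accuracy(),
               "loo": res.accuracy("loo"),
               "priors": res.priors_mode,
               "n_classes": len(res.classes), "n_crowns": int(len(res.y))}
        (outdir / "accuracy.json").write_text(json.dumps(acc, indent=2))
        for name in ("confusion.csv", "assignments.csv", "accuracy.json"):
            artifacts[name] = outdir / name
        log["classify"] = acc

    if "map" in stages:
        for label, triplet in RGB_CONVENTIONS.items():
            rgba, channels = render_trait_rgb(
                traits, crowns, triplet,
                pixel_size=config.simulate.pixel_size)
            np.save(outdir / f"map_{label}.npy", rgba)
            channels.to_csv(outdir / f"map_{label}_channels.csv")
            try:
                import matplotlib
                matplotlib.use("Agg")
                import matplotlib.pyplot as plt
                fig, ax = plt.subplots(figsize=(6, 6))
                ax.imshow(rgba, origin="lower")
                ax.set_title(f"{label} traits "
                             f"(R={triplet[0]}, G={triplet[1]}, "
                             f"B={triplet[2]})")
                fig.savefig(outdir / f"map_{label}.png", dpi=150)
                plt.close(fig)
                artifacts[f"map_{label}.png"] = outdir / f"map_{label}.png"
            except Exception:   # plotting is best-effort
                pass
            artifacts[f"map_{label}.npy"] = outdir / f"map_{label}.npy"
            artifacts[f"map_{label}_channels.csv"] = (
                outdir / f"map_{label}_channels.csv")

    manifest = {
        "seed": config.seed,
        "stages": sorted(stages),
        "artifacts": {k: _sha256(p) for k, p in sorted(artifacts.items())},
        "log": log,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
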