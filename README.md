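# crowntraits

Individual-tree-crown functional traits from airborne imaging spectroscopy
and laser scanning: retrieval, variance partitioning, phylogenetic-distance
correlation and species assignment — with a synthetic forest-scene generator
so the entire analysis runs and is testable without any remote-sensing
download.

## The scientific problem

Trait-based forest ecology needs traits per *individual tree*, but remote
sensing delivers them per *pixel*. Once every crown in a stand has been
delineated as a polygon, pixel- and point-level data can be aggregated to
crown level, and the classical toolbox of field ecology applies: how much
trait variation lies between taxa, how much is environmental plasticity,
and how much remains unexplained within species?

The package works on a mixed conifer–angiosperm temperate stand of 13
species (~1,300 canopy trees) and six crown traits:

* **Biochemical** (from the shadow-masked crown-mean reflectance spectrum):
  - CHL — red-edge normalised difference, (R₇₅₀ − R₇₀₅)/(R₇₅₀ + R₇₀₅)
  - CAR — reciprocal reflectance difference, 1/R₅₁₀ − 1/R₅₅₀
  - LWC — NIR water index, (R₈₆₀ − R₁₂₄₀)/(R₈₆₀ + R₁₂₄₀)
* **Architectural** (from terrain-normalised lidar returns per crown):
  - CH — maximum return height (m)
  - PAI — Beer–Lambert gap-fraction inversion, −ln(gap)/k
  - FHD — Shannon entropy (nats) of returns in 5-m height layers

Downstream analyses:

* **Variance partitioning** — sequential (Type I) sums of squares in a fixed
  order (class, species | environment | class×env, species×env | 90-m and
  40-m spatial grids), with backward elimination of non-significant terms.
  %SS values are additive, so aggregated shares (taxonomy / environment /
  interaction / spatial / residual) sum to 100.
* **Mantel tests** — species-mean trait and spectral distances (Euclidean on
  min–max rescaled data; VIS/NIR/SWIR windows) against F84 phylogenetic
  distances, permutation p-values (9,999 permutations, one-sided).
* **Discriminant analysis** — Gaussian LDA on the six traits, with
  resubstitution and leave-one-out accuracy.
* **Synthetic scenes** — crowns, reflectance cube, point cloud and
  environmental rasters with *known* ground truth, built so the retrieval
  stage inverts the forward models exactly in the noise-free limit.

## Worked example

```python
from crowntraits import (default_config, simulate_forest, retrieve_traits,
                         TraitVarianceModel, default_design,
                         build_analysis_frame)

cfg = default_config(n_crowns=1307, seed=1)     # the 13-species demo stand
scene = simulate_forest(cfg)
traits, spectra, log = retrieve_traits(scene.cube, scene.cloud, scene.crowns)

frame = build_analysis_frame(scene.crowns, traits)
res = TraitVarianceModel(frame, default_design("LWC")).fit(eliminate=True)
print(res.summary())
```

The LWC table from this exact run (seed 1) ends with:

```
term            category     df     ss   pct_ss       F      p
tree_class      taxonomy      1  1.112   28.877  651.16  0.000
species         taxonomy     11  0.087    2.258    4.63  0.000
PAR             environment   1  0.049    1.275   28.75  0.000
elevation       environment   1  0.080    2.066   46.59  0.000
...
G40             spatial      48  0.295    7.664    3.60  0.000
Residual        residual   1224  2.091   54.281
```

Read: the conifer/angiosperm split alone explains ~29% of leaf-water
variation (conifers retain more water), species within class add ~2%,
light and topography a few percent each, unexplained spatial structure
~9%, and the rest is residual within-species variation. Aggregated across
all six traits the same run gives taxonomy ≈ 16%, environment ≈ 11%,
spatial ≈ 13%, residual ≈ 58% — biochemical traits are far more taxonomic
(LWC 31%) than architectural ones (FHD 2.7%), while environment dominates
CH (28%) and PAI (18%).

The Mantel stage of the same run reports that biochemical trait distances
track phylogeny closely (r = 0.95, p = 0.006) while architectural distances
do not (r = 0.29, p = 0.06), and the six-trait discriminant assigns 50%
(resubstitution) / 49% (leave-one-out) of individuals to the correct
species — species overlap heavily in trait space even when the traits are
retrieved without noise.

A command-line interface mirrors the stages:

```bash
crowntraits run-all --seed 1 --out out/demo
crowntraits partition --seed 1 --out out/demo     # rerun one stage in place
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full demonstration analysis from scratch — simulate the
default stand, retrieve all six traits, fit and eliminate the sequential
ANOVAs per trait and jointly, build the distance matrices and run the
Mantel suite against the synthetic phylogeny, fit the discriminant model —
and writes the results JSON to `--out`, with all stage artifacts (ANOVA
tables, aggregated shares, Mantel table, confusion matrix, RGB trait maps,
manifest) in `results/acceptance_artifacts/`.
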