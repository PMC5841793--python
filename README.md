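# carapace

Landmark-based shape analysis of turtle carapaces, built to delineate what
modern variation can and cannot explain in the fossil record of the Eastern
Box Turtle (*Terrapene carolina*). The package implements the full chain as
a reusable, tested library with numbered analysis drivers:

- **maturity proxies** — growth-ring counts, carapace length, and
  fontanelle closure evaluated against each other; a maturity filter for
  building adult-only datasets;
- **superposition** — generalized Procrustes analysis of 2-D landmark
  configurations with sliding semilandmarks (Procrustes-distance
  criterion), missing-landmark estimation by midline reflection, symmetric
  components for object-symmetric views, tangent-space PCA;
- **shape statistics** — Procrustes ANOVA with sequential (Type I) sums of
  squares and residual-randomization permutation p-values, FDR-adjusted
  pairwise tests, measurement error / ICC repeatability, jackknifed CVA
  assignment, BIC-ranked Gaussian mixture clustering;
- **sexual dimorphism** — the compressed sexual dimorphism index
  SDI = F̄/M̄ − 1 (females larger) or −(M̄/F̄ − 1) (males larger), with
  stratified bootstrap CIs;
- **geographic variation** — Moran's I and spatial eigenvector mapping
  (principal coordinates of the great-circle distance matrix) with forward
  selection of the spatial eigenvectors that explain shape;
- **fossil comparison** — largest-gap bimodality splitting,
  bimodality-as-dimorphism SDI tests, allometric slope comparison and
  residual correction against the modern growth model, pairwise site
  tests, and disparity rarefaction (is more morphospace occupied once
  fossils are added?).

A seeded synthetic-data generator (`carapace.synthgen`) reproduces the
statistical structure of the study — three views per specimen with the
exact landmark topology, allometry, a sexed sample with male-biased size
dimorphism, smooth geographic clines, photographic replicates, and fossil
sites with shifted shapes and a bimodal size distribution — so the entire
pipeline runs and is tested without any data download. Real data in TPS
(tpsDig dialect) plus a metadata CSV go through the identical code path.

## Worked example

The numbered drivers under `analysis/` run the study on the default
synthetic conditions (200 modern specimens, a 52-specimen sexed sample,
four fossil sites), writing tables under `results/`:

```sh
python analysis/01_simulate_study.py     # data -> results/data/
python analysis/02_maturity_proxies.py
python analysis/03_align_shapes.py
python analysis/04_sexual_dimorphism.py
python analysis/05_geographic_variation.py
python analysis/06_fossil_record.py
```

Output of the maturity, dimorphism, and fossil stages (seed 42):

```
log length ~ MGR, specimens with <= 8 rings: adj R^2 = 0.912, p = 1.63e-41
log length ~ MGR, specimens with  > 8 rings: adj R^2 = 0.009, p = 0.134
...
size dimorphism: t-test p = 0.0115; compressed SDI = -0.105 [-0.189, -0.027] (male-larger)
dorsal: sex R^2 = 7.5%, p = 0.001; jackknife CVA accuracy 92.3%
...
vero_melbourne: bimodal (gap 104 mm); modelled-as-sexes SDI = -0.97 vs
  modern CI [-0.189, -0.027] -> REJECTED as dimorphism
dorsal: slope-homogeneity interaction p = 0.476
  sites different from Modern after correction: friesenhahn, haile, vero_melbourne_large
  disparity added beyond the 95% bound by: friesenhahn, haile, all_fossils
```

Reading this: carapace length tracks growth-ring count only up to eight
rings (adjusted R² 0.91 below, ≈ 0 above), so ring count and fontanelle
closure jointly define maturity. The sexed sample shows weak male-biased
size dimorphism (SDI −0.105; the generator's true value is −0.086, and at
n = 26 per sex the estimate moves by ±0.04–0.05 between seeds). Sex
explains 4–8% of shape variation — statistically significant, weakly
diagnosable. In the fossil record, one site pair has a bimodal size
distribution far too extreme to be two sexes of one morph (SDI ≈ −1 against
a modern CI near −0.1). The generator gives fossils the modern growth
trajectory, so the slope-interaction test is null here (the correction
against the modern allometric model is applied regardless, as it would be
after a significant interaction); the shifted sites remain significantly
different from moderns after that correction and add disparity beyond the
95% rarefaction bound.

The same pipeline is scriptable via `carapace run`/`carapace all`
(`--seed`, `--output`, YAML config) or `carapace.pipeline.run_pipeline`.

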