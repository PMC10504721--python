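# lipisf

Lipid annotation for MALDI mass spectrometry imaging (MSI) peak matrices
that takes **in-source fragmentation** seriously. At MS1, fragments produced
inside the ion source are indistinguishable from intact isobaric lipids —
e.g. the inositol-loss fragment of PI c:d is exactly isobaric with
deprotonated PA (c+2):(d+2). `lipisf` matches every peak against the
adducts *and* in-source fragments of each lipid class, then ranks candidate
lipids by how many of their ion forms appear and how strongly those ion
images co-localize:

    S = LO · (1 + C)

where **LO** is the number of distinct ion forms of the lipid found by
exact-mass search (ppm tolerance, user-set, default 5 ppm), and **C** is the
mean Pearson correlation over all distinct pairs of the matched ion images.
A lipid genuinely present tends to appear as several co-localized forms
(S ≈ 2·LO); an accidental isobar appears once (S = 1).

Because no ground truth exists for MS1 annotation, performance is estimated
by **target-decoy search**: the same matrix is searched with a decoy library
(implausible ion transforms built from elements foreign to lipid chemistry,
or out-of-sample compounds mass-matched to the target library), giving ROC
AUC of the S scores and an FDR estimate (decoy/target hits) per top-N
cutoff. A seeded synthetic-data generator produces ground-truthed peak
matrices — planted lipids with correlated ion images, isotope satellites,
noise peaks — so the entire pipeline is testable without any download.

Intended for practitioners analyzing centroided MSI peak matrices
(CSV dialect below, or centroid imzML) in lipidomics.

## Worked example

```bash
# 64x64-pixel synthetic matrix: 8 planted lipids x 4 ion forms, 30 noise
# peaks, plus 12 background peaks placed where the seed-1 decoy library
# can hit them
lipisf synth --seed 1 --decoy-background 12 \
    --out-peaks peaks.csv --out-truth truth.json
# -> 4096 pixels x 74 peaks -> peaks.csv

lipisf annotate --peaks peaks.csv --ppm 5 --top-n 3 --out annotations.csv
# -> 32 annotation rows for 32 peaks (8 candidate lipids) -> annotations.csv

lipisf validate --peaks peaks.csv --decoy-seed 1 --out-prefix val
# -> AUC = 1.0000 (8 target / 11 decoy groups)

lipisf network --peaks peaks.csv --out net.graphml
# -> 40 nodes, 32 edges -> net.graphml
```

The rows of `annotations.csv` for the planted lipid PI 38:3:

```
 observed_mz   lipid  transform   kind  ppm_error  LO      C      S  rank_within_peak
    871.5700 PI 38:3    [M-OH]- adduct    -0.0458   4 0.9078 7.6314                 1
    873.5514 PI 38:3   [M-CH3]- adduct     2.4412   4 0.9078 7.6314                 1
    887.5658 PI 38:3     [M-H]- adduct     0.3615   4 0.9078 7.6314                 1
    909.5476 PI 38:3 [M+Na-2H]- adduct     0.8061   4 0.9078 7.6314                 1
```

All four ion forms of the lipid were found (LO = 4) with mean pairwise
image correlation C = 0.91, so every one of its peaks carries S = 4 × 1.91
≈ 7.63 and ranks first among the candidates for that peak; deprotonated
PI 38:3 is recovered at m/z 887.57. The `validate` run writes the scored
groups, the ROC points, the FDR-vs-top-N curve and a JSON summary: here the
8 planted lipids (S ≈ 7.6) separate perfectly from the 11 decoy hits
(S ≈ 1), hence AUC 1.0 — an intentionally exaggerated effect size; see
`docs/methods.md` for what this does and does not say about real data.

The same pipeline runs on real data: `--peaks your_matrix.csv` (or
`--format imzml your_data.imzML`), `--library <dir>` with your own
`species.tsv`, `transforms.tsv`, `pathways.tsv` (schemas below), and the
instrument-appropriate `--ppm`.

## Input formats

* **Peak matrix CSV** — header `x,y,<mz1>,<mz2>,...` (m/z at ≥4 decimals),
  one row per pixel; or centroid ("processed") imzML with a shared m/z axis.
* **species.tsv** — `name  class  carbons  double_bonds  formula` (Hill
  notation; optional `mass` column is cross-checked). An LMSD-style export
  (NAME/FORMULA/ABBREVIATION) can be converted with
  `lipisf.library.load_lipidmaps_species`.
* **transforms.tsv** — `name  polarity  kind  delta_gain  delta_loss
  charge_carrier  plausible`.
* **pathways.tsv** — `class  polarity  transform_name`, listing which
  transforms each lipid class can form.

A bundled mini-library (63 species across PC, PE, PS, PA, PG, PI, SM; 11
transforms) is used when `--library` is omitted.

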