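# msimet

Differential metabolomics for MALDI-FTICR mass spectrometry imaging (MSI),
built for case/control tissue studies: exact-mass metabolite annotation,
spectrum preprocessing, covariate-adjusted statistics, and a ground-truthed
synthetic data generator so the entire pipeline is testable without any
external data.

The package targets the analysis design of ultra-high-resolution imaging
studies of dystrophic (DMD) vs control muscle: two ionization modes, nine
biopsies per group, child-aged patients vs adult controls, and a metabolite
signature dominated by phospholipids (PC, lysoPC, SM, PA, PS) and energy
metabolites (ATP, ADP, glycerophosphocholine, inositol phosphates).

## What it computes

**Exact-mass engine** (`msimet.chem`). Monoisotopic masses from Hill-style
formulas and a packaged atomic mass table, and adduct ion m/z

```
m/z = (M + m_added − m_removed − z·mₑ) / |z|
```

with explicit electron-mass handling — at FTICR accuracy a protonated ion
is 0.55 mDa lighter than neutral-plus-H-atom. Mass errors are signed
relative deviations, `(obs − theo)/theo`, in ppm and ppb.

**Annotation** (`msimet.annotation`). MS1: all (compound, adduct)
candidates within ±2 ppm of an observed m/z, from a user-extensible TSV
database (positive adducts [M+H]⁺/[M+Na]⁺/[M+K]⁺, negative [M−H]⁻).
MS/MS: neutral-loss and diagnostic-fragment rules at ppb tolerance — e.g.
trimethylamine (C₃H₉N, 59.073499 Da) and phosphocholine (C₅H₁₄NO₄P,
183.066045 Da) losses identify choline lipids; the C₅H₈O₉P₂ [M−H]⁻ fragment
(adenine loss) identifies ATP. `consolidate` combines both levels and flags
ambiguous calls.

**Preprocessing** (`msimet.preprocess`). Single-point or linear
recalibration against a calibrant list; total-ion-current normalization per
pixel; greedy ±1 ppm binning of all peaks into features with
intensity-weighted consensus recentering; aggregation to a features ×
samples matrix of per-sample mean intensities.

**Statistics** (`msimet.stats`). Per feature, OLS of log intensity on a
group indicator plus age (the t-test with age as covariate); FDR control by
Benjamini–Yekutieli (BH selectable); Spearman co-expression; agglomerative
sample clustering on Euclidean distances with Newick export.

**Synthetic studies** (`msimet.synthetic`, `msimet.evaluate`). A generator
that plants 27 up- and 7 down-regulated species (21 positive-mode, 13
negative-mode) among matrix and null peaks, with FTICR-grade m/z jitter,
log-normal intensities, per-pixel TIC variation and per-sample calibration
drift — plus scoring utilities that measure realized FDR, per-feature power
and direction recovery against the truth table.

## Worked example

`examples/` contains one narrative script per capability. Running
`python examples/02_annotate_peaks.py` prints:

```
m/z 566.32166 (positive mode)
  -> LysoPC(20:4) [M+Na]+, theoretical 566.321711, error -0.09 ppm, evidence MS2
     loss C3H9N observed 59.07351 (+181 ppb)
     loss C5H14NO4P observed 183.06608 (+192 ppb)

m/z 505.98833 (negative mode)
  -> Adenosine triphosphate [M-H]-, theoretical 505.988470, error -0.28 ppm, evidence MS2
     fragment C5H8O9P2 observed 272.95698 (-364 ppb)
```

i.e. the observed peak at m/z 566.32166 matches the sodium adduct of
lysoPC(20:4) within 0.09 ppm, and its two fragment losses match the choline
head-group rules within ~200 ppb, promoting the call to MS2-confirmed.
`python examples/04_differential_analysis.py` runs the full pipeline on a
synthetic study and prints the significant-feature table
(34 significant: 27 up / 7 down in patients, realized FDP 0.000, cluster
adjusted Rand index 1.00 against the true groups).

The same stages are scriptable from a shell:

```bash
msimet run -o results/bundle --seed 11        # all stages, synthetic source
msimet annotate --mz 505.98833 --mode negative
msimet simulate -o data/sim --seed 1 --grid 16 16
```

Every run writes a `manifest.json` with the resolved configuration and
SHA-256 checksums; identical config + seed reproduce bit-identical CSVs.

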