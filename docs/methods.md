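# Methods

## Scope and model

`msimet` implements the analysis chain of a two-group MALDI-FTICR imaging
metabolomics study: per-pixel centroided peak lists are recalibrated,
TIC-normalized and binned into a features × samples matrix; features are
annotated by exact mass and MS/MS evidence; group differences are tested
per feature with an age covariate and FDR-corrected; the significant
signature is summarized by co-expression and sample clustering. Because
studies of this design rarely deposit raw imaging data, the package ships a
generative model of the study itself, and all statistical claims are
validated by parameter recovery against that model's ground truth.

## Exact-mass arithmetic

Monoisotopic masses use a packaged table of atomic masses (≥7 decimals;
AME/CODATA values) with the electron mass as an explicit entry. Adduct m/z
is `(M + m_added − m_removed − z·mₑ)/|z|`; the electron term is mandatory —
published FTICR calibration lists are proton-accurate, and omitting mₑ
shifts every singly charged ion by 0.55 mDa (≈3 ppm at m/z 184, far outside
sub-ppm tolerances). Formula grammar is flat Hill notation (no brackets,
isotopes or charges), which covers every species in the packaged database.
Display rounding is 6 decimals, round-half-even; comparisons always use
full precision.

## Annotation

MS1 matching scans every (compound, allowed adduct) pair within a ppm
window (default ±2 ppm, the standard FTICR database-search tolerance);
candidates are ranked by |error| with lexicographic id tie-break. MS/MS
rules are of two kinds: neutral losses (match when the observed
precursor−fragment difference is within tolerance of the loss mass) and
diagnostic fragments (match on absolute fragment m/z). The default MS/MS
tolerance is 500 ppb — published worked examples show loss errors of
~180–360 ppb, and 500 ppb covers them with margin while staying far tighter
than the MS1 window. All rule and database masses are recomputed from
formulas at load time. Consolidation policy: a unique MS1 candidate is
reported as-is (MS2-confirmed if any class-consistent rule matched); when
several candidates compete, class-discriminating MS/MS evidence may single
one out; otherwise the call is flagged ambiguous and never auto-resolved,
mirroring the practice of reporting only unambiguous identifications.

The packaged compound database covers the species a study of this kind
names explicitly — nucleotides (ATP, ADP, adenosine tetraphosphate, CMP),
glycerophosphocholine, inositol tetra/pentakis-phosphate, phosphoribosyl pyrophosphate, carnitines, phosphocholine,
representative PC/LPC/SM/PA/PS/TG lipids — plus MALDI matrix ions (DHB and
its clusters, 9-aminoacridine) carrying an `is_matrix` flag. It is a plain
TSV and user-extensible.

## Synthetic study generator

Each pixel of each sample receives one peak per panel compound:

* m/z: theoretical adduct m/z × (1 + (offset + jitter)·10⁻⁶), with a
  per-sample calibration offset (SD 1 ppm) and per-peak jitter (SD 0.3 ppm,
  FTICR-grade precision);
* intensity: `exp(base + effect·[patient & differential] + age drift +
  sample noise + pixel noise) × TIC scale`, i.e. log-normal intensities
  with multiplicative noise at three scales — biological between-sample
  (SD 0.2), within-section pixel texture (SD 0.5) and a per-pixel
  acquisition scale shared by all species in the pixel (log-SD 0.3).

The default study plants the published signature structure: 9 patients
(ages ~5.5 ± 1.9 y) vs 9 adult controls (uniform 28–58 y), 27 up- and 7
down-regulated species split 21/13 across positive/negative modes, among
null metabolites and matrix peaks (43 panel species in total, echoing the
~52 discriminant ions such studies report before curation). Default planted
effects are ±2.5 natural-log units (~12-fold): the signature metabolites in
the emulated study are strongly altered (glycerophosphocholine near-absent
in patients; the cohorts separate into two clean clusters), and with the
strong age-group confound of the design (below) smaller effects would not
be the study's own operating point.

Deliberate generative choices with analysis consequences:

* **Matrix dominance.** Matrix/calibrant ions are ~3 orders of magnitude
  more intense than analytes, as in real MALDI spectra, so the TIC is
  matrix-dominated and TIC normalization removes acquisition scale rather
  than the biological composition shift of 27 up-regulated lipids.
* **Matrix ions carry no biological sample noise.** Their
  section-to-section deposition variability *is* the shared acquisition
  scale; giving them independent per-sample noise would let TIC
  normalization re-inject that noise into every analyte.
* **Matrix ions are excluded from differential testing** (they remain in
  the feature matrix and annotation report). Under TIC normalization a
  global analyte increase slightly dilutes the (near-noiseless) matrix
  peaks, which would otherwise surface as highly significant spurious
  "down" calls — the synthetic analogue of why real pipelines never report
  matrix peaks as metabolites.
* **Spatial structure** is off by default (uniform tissue); an optional
  half-section mask per compound supports ion-image tests.
* **Seeds.** A master seed spawns one child stream per (mode, sample) via
  `SeedSequence(seed, spawn_key=(mode, sample))`, so any sample regenerates
  stably and two modes share a cohort but not noise.

What the generator does **not** emulate: isotope envelopes and fine
structure, profile-mode peak shape, detector saturation, spatially
correlated histology (fibrosis, fiber mosaic), missing peaks/dropouts, and
realistic annotation ambiguity from isomeric lipids. Passing tests
therefore validate the pipeline's arithmetic and statistical calibration
under the declared noise model, not robustness to those real-data features.

## Preprocessing

**Recalibration.** Calibrant lists are packaged per mode (matrix ions,
carnitines, phosphocholine, nucleotides, abundant lipids); theoretical m/z
are recomputed from formulas at load and must agree with any stored value
to 1e-5 Da. Single-point calibration zeroes the error of the most intense
matched calibrant; the linear model fits ppm drift against m/z by least
squares. The pipeline estimates the correction per *sample* (median
calibrant error over all pixels): the synthetic drift is a per-acquisition
offset, and per-pixel correction would subtract the calibrant peak's own
jitter from every m/z in the pixel, inflating effective jitter by √2. The
per-spectrum API remains available.

**TIC normalization** scales each pixel to the dataset-mean TIC (unit
target selectable), preserving within-pixel ratios exactly; zero-TIC pixels
are excluded and logged.

**Binning.** All peaks from all pixels and samples are sorted by m/z and
clustered greedily: a peak joins the current feature while it lies within
±1 ppm of the running intensity-weighted consensus; a final full-member
check recursively splits any cluster at its largest gap until every member
is within tolerance of its consensus. Features occurring in <5% of all
pixels are dropped: with 0.3 ppm jitter against a ±1 ppm window, ~0.1% of
a compound's peaks fall outside the main cluster and would otherwise form
one-pixel satellite features; 5% still retains a species present in a
single sample or half a section. Per sample, the feature intensity is the
mean over all the sample's pixels (absent pixels contribute zero); zero
cells are imputed at half the matrix-wide minimum positive intensity before
log transformation — the standard metabolomics detection floor.

## Statistics

Per feature, ordinary least squares of natural-log intensity on intercept,
patient indicator and age; the reported estimate is the patient−control
log-intensity difference adjusted for age, tested two-sided on n−3 residual
degrees of freedom. All features share one design matrix, so the fits are
solved vectorized; the test suite verifies exact agreement with per-feature
statsmodels OLS, and with the pooled two-sample t-test when the covariate
is dropped. Exact fits (zero residual) are reported as estimate 0, p = 1
when the group difference is numerically zero. A rank-deficient design
yields missing p values with a warning.

FDR control defaults to Benjamini–Yekutieli — the hyphenated
"Benjamini–Hochberg–Yekutieli" naming and the strong metabolite
correlations point to the arbitrary-dependence variant, which inflates BH
by c(m) = Σ 1/k — with BH selectable; the implementation wraps statsmodels
and is pinned by a hand-computed three-element oracle and an explicit
step-up reimplementation in the tests. Significance is adjusted p < 0.05.
Missing p values propagate and are excluded from m.

Spearman correlation uses average ranks (scipy), with zero-variance
features reported missing. Sample clustering is agglomerative on Euclidean
distances (complete linkage by default; ward/average/single selectable),
with samples pre-sorted lexicographically so ties break deterministically,
a k = 2 cut for the two-group readout, and Newick export.

## Validation design and problem sizes

The single end-to-end demonstration run uses the full default geometry
(40×40 pixels × 18 samples × 2 modes). Replicate Monte-Carlos (power, null
calibration, type-I error) use 4×4 to 8×8 grids: per-sample feature values
are pixel means, so grid size only shrinks the already-small pixel-noise
term, and small grids let a replicate run in ~0.3 s. "2-SD effects" means
twice the *realized* within-group SD of log feature intensity, estimated
from zero-effect calibration runs of the same pipeline (root mean pooled
variance over effect-carrying features, averaged over several runs):
normalization and pixel averaging contribute noise beyond the generative
sample SD, and an analytic formula would understate it.

Power at 2-SD effects is measured with age-balanced groups. The emulated
cohort design confounds age with group almost completely (correlation
−0.94 to −0.99 across draws, variance inflation up to ~30 for the group
coefficient); with the covariate in the model this is the correct price of
adjustment, but it means per-feature power at small effects is a property
of the confound, not of the test. At the default ±2.5 effects the
confounded design still recovers the full 27/7 direction split on most
seeds (occasionally missing 2–3 lipids on extreme collinearity draws,
always with correct directions and realized FDP ≤ 0.08).

## Known limitations

* Annotation is exact-mass + loss-rule only: no spectral-library scoring,
  no isotope-pattern or fine-structure checks, no retention/mobility
  dimension; isomeric lipids within 2 ppm are genuinely ambiguous and are
  flagged, not resolved.
* Binning assumes centroided input; there is no peak picking, baseline
  correction or spatial segmentation.
* The age covariate enters linearly; with complete age-group separation the
  adjusted group effect extrapolates across a 20-year age gap and its CI
  should be read accordingly.
* imzML support covers processed (centroided) mode with one file per
  sample; vendor raw formats are out of scope.
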