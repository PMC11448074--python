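# Methods

This note documents the generative model behind the synthetic cohorts, the
preprocessing and analysis conventions, the defaults and why they were
chosen, and what conclusions the synthetic experiments do and do not
support.

## Generative model of a cohort

A cohort is defined by classes with strain counts, a set of extraction
methods, a replicate count, and a mass range (default: *sakei* 93,
*carnosus* 106, non-*L. sakei* 28; methods on-plate and off-plate; two
technical replicates; 2,000–20,000 Da on a uniform 1 Da grid). The spectrum
count is always `Σ strains × methods × replicates`; the default design
yields 908 spectra (372/424/112 per class).

Peak structure is two-level:

* **Strain level.** Each of the 49 default peak templates carries a
  per-class prevalence; a strain realizes each template independently as a
  Bernoulli draw. The realized peak set is a property of the strain: all of
  its spectra (both methods, both replicates) share it. This encodes the
  presence/absence semantics of the strain-level marker analysis.
* **Spectrum level.** Each spectrum draws every realized peak's amplitude
  from a log-normal with the template's mean intensity and a coefficient of
  variation (default 0.30), multiplied by a per-method factor (1.0
  on-plate, 1.2 off-plate — method-correlated variation without any change
  of presence). The apex position is jittered by a Gaussian with SD 1 Da.
  Peak shape is Gaussian with σ = 8·10⁻⁴ × m/z (linear-TOF resolution
  scaling; FWHM/m ≈ 0.0019).

The clean signal is `A·exp(−k(m − m_lo))` (baseline, A = 20 a.u.,
k = 4/range, so the baseline dominates near 2,000 Da and has decayed ~98%
by 20,000 Da) plus the Gaussian peaks. Detector noise is then added and the
result truncated at zero.

### Noise model

Default detector noise is **shot-scaled and bounded**: the SD at mass m is
`0.5 · sqrt(clean(m)/A)` a.u. (i.e. variance proportional to the local
expected intensity, as for ion-counting detectors) and the amplitude
distribution is uniform rather than Gaussian. Two reasons:

* Signal-proportional variance is precisely the noise structure the
  square-root transform is designed to stabilize; after the transform the
  noise is homoscedastic across the mass range. With constant-variance
  noise the sqrt-scale noise grows ~7-fold toward high mass and SNR-based
  detection degenerates there.
* Averaging ≥ 40 laser shots per spectrum makes real profile noise
  short-tailed; a bounded distribution reproduces the empirically clean,
  reproducible peak sets of real linear-mode fingerprints (the study
  recovered 49 distinct peaks from 908 spectra). With the default SNR
  threshold the off-peak residual never reaches the detection cutoff, so
  the detected peak set equals the planted one.

Constant-variance and Gaussian options remain available
(`NoiseParams(shot_scaled=False, additive_distribution="gaussian")`).

### Default peak templates

The 49 loci comprise 10 subspecies-differential markers, 15 *L. sakei*
species-backbone peaks, 12 genus-common peaks, and 12 non-*sakei*-specific
peaks. The two strongest differential markers carry the study's printed
prevalences (9,653 m/z: 90.6% *carnosus* vs 21.5% *sakei*; 4,826 m/z:
90.6% vs 26.9%); the remaining differential loci are deliberately weaker
(gaps of ~0.4–0.5), mirroring the reported dominance of those two loci in
the importance ranking. Centres are spaced ≥ 90 Da apart so peaks never
overlap within the detection window.

## Preprocessing

The chain is fixed — sqrt → SNIP → subtraction → TIC → detection → binning
→ matrix — and each spectrum records its state; applying a step out of
order raises.

* **SNIP baseline.** Clipping step `y_k ← min(y_k, (y_{k−i}+y_{k+i})/2)`
  over a window schedule decreasing from 100 to 1 (the decreasing schedule
  distorts peak flanks less; the increasing variant is available). The
  schedule is repeated until the estimate stops changing (tolerance 1e−12,
  at most 50 passes; typically < 20), so the returned baseline is a true
  fixed point: it never exceeds the input and a second application leaves
  it unchanged. Window counts exceeding half the spectrum length are
  clamped with a warning.
* **TIC normalization.** Intensities are scaled so the summed intensity is
  exactly 1; an all-zero spectrum is an error, not a silent pass.
* **Noise estimate.** Median absolute deviation × 1.4826
  (Gaussian-consistent), robust to sparse peaks.
* **Peak detection.** Local maxima over ±20 grid points with apex
  intensity ≥ 3 × noise. The threshold of 3 (a common choice for
  linear-mode profiles) is deliberate: the SNIP-subtracted residual of a
  noise field has a max/MAD ratio of ~2.7 almost independently of noise
  amplitude, so a threshold of 2 admits hundreds of noise maxima per
  spectrum while 3 admits essentially none. Plateaus collapse to their
  centre point; with a zero noise estimate (noise-free input) any strict
  local maximum qualifies and its SNR is reported as infinite.
* **Binning.** Divisive strict binning: all peak m/z pooled and sorted,
  recursively split at the largest gap until every member is within 0.002
  (relative) of the bin mean. Deterministic and independent of spectrum
  order, unlike greedy accumulation. A spectrum contributing two peaks to
  one bin keeps the stronger.
* **Feature matrix.** Rows are spectra, columns bin reference m/z. Cells
  without a detected peak are filled by linear interpolation of the
  spectrum's preprocessed intensity at the bin position (default) or with
  zero; bins outside a spectrum's range are zero-filled with a warning.
  The pre-fill detection mask is kept alongside the intensities because
  the presence/absence analysis must not see filled values.

## Peak association

Spectra are aggregated to strains by an inclusive majority rule: a peak is
present for a strain when detected in ≥ 50% of its spectra (2 of 4 under
the default design). Association between two classes uses the two-sided
Fisher exact test on the 2×2 presence-by-class table (chi-square with
continuity correction available for large cohorts); no multiple-testing
correction is applied by default, matching the raw-threshold convention of
the marker analysis (Benjamini–Hochberg is available via a flag).
Prevalences are rounded half-up to one decimal so printed percentages like
90.6% (96/106) are reproduced exactly. Discriminative peaks are those with
p below α (default 0.01), ranked ascending with ties broken by m/z.

## Classification

* 80/20 split, train size `floor(0.8 n)`, stratified by class (the
  112-spectrum minority class otherwise risks vanishing from the test
  set); a group-by-strain mode keeps all four spectra of a strain on one
  side, avoiding technical-replicate leakage.
* Features are standardized with training-set statistics for PLS-DA,
  PCA-KNN and SVM; the random forest sees raw intensities.
* PLS-DA regresses a one-hot class matrix (PLS2) and assigns the argmax
  score; the component count (default 10) is capped at
  min(n−1, p) with a warning.
* PCA-KNN keeps the fewest leading components reaching 95% cumulative
  explained variance, then votes among k = 9 Euclidean neighbours; ties go
  to the smallest class index.
* SVM-RBF uses C = 1, gamma = 1/(p·Var(X_train)). Its ROC scores are a
  softmax over one-vs-rest decision values — a ranking convention, not a
  calibrated probability.
* RF uses 100 trees, min_samples_split = 2 and √p features per split.
  Importance is mean impurity decrease; the top ceil(0.10·p) features are
  reported, ties broken by ascending m/z.

## Evaluation

Multiclass results are reduced one-vs-rest per class; the five metrics
(precision, accuracy, sensitivity, specificity, recall — the last two
pairs sharing formulas by construction) are computed per class and
macro-averaged unweighted by default (micro and support-weighted modes
selectable). Overall accuracy is additionally reported as trace/total.
Zero-denominator metrics are reported as NaN with a warning — never as 0 —
and excluded from averages. ROC curves are one-vs-rest threshold sweeps
with trapezoidal AUROC (equivalent to the Mann–Whitney midrank
convention under ties); classes absent from the truth are excluded from
the macro average with a warning.

## Reproducibility

One master seed is split (via `numpy.random.SeedSequence`) into per-stage
seeds for profile sampling, spectrum noise, the data split, and model
fitting; a config plus seed reproduces a run bit for bit, and every output
file records the SHA-256 hash (12 hex digits) of its configuration.

## What the synthetic experiments show — and what they do not

The generator reproduces the *structure* the analysis relies on: cohort
composition, strain-level presence with class-specific prevalence,
method- and replicate-correlated intensity variation, a baseline that
makes SNIP consequential, and marker loci at the published prevalences.
It does not reproduce the hardness of the real classification problem:
real fingerprints carry correlated biological variation, calibration
drift, overlapping isotope envelopes and library-scale peak diversity
that the synthetic cohort lacks, and the synthetic classes are more
separable than the real ones (the classifiers here reach high-0.9
accuracies). Passing tests therefore validate the pipeline's correctness
and its ability to recover planted structure, not any claim about
real-data accuracy. Test problem sizes were chosen for fast iteration:
module tests use scaled cohorts of 6–20 strains per class; the
whole-pipeline checks use the full 908-spectrum design, 10 seeds for the
classifier check and 100 seeds for the marker-recovery check.

## Known limitations

* Uniform m/z grid (1 Da default); real TOF grids are non-uniform.
* No isotope envelopes, charge states, detector saturation, or
  mass-calibration drift; peak jitter is i.i.d. Gaussian per spectrum.
* Peak quantification uses apex intensity, not integrated area.
* The association analysis tests each locus marginally; correlated
  presence between loci is neither simulated nor modelled.
* Vendor raw formats are out of scope; the file dialect is two-column CSV
  plus a TSV manifest.
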