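# Methods

## Physical model

Re-186 decays with a fixed half-life of 89.2 h (`lambda = ln 2 / 89.2` per
hour, exposed in config for sensitivity analyses). After convection-enhanced
delivery the nanoliposome carrier is retained at the site of administration,
so by default activity in brain follows pure physical decay with no
biological clearance term; urinary excretion is modeled separately as
counted voided samples, decay-corrected to administration time and expressed
as percent injected dose (%ID).

Absorbed dose uses the local-deposition approximation for the Re-186 beta
spectrum: all beta energy (mean path ~1.8 mm) is absorbed in the source
region and the gamma component is neglected,

    D [Gy] = 7.126 * A~ / m,

with 7.126 in Gy·g/(mCi·h), A~ the cumulated activity in mCi·h and m the
region mass in g at density 1 g/mL. The same constant, times 100, is applied
to organ compartments (cGy, normalized per administered mCi); organ outputs
are labeled a local-deposition approximation because cross-organ photon dose
and phantom geometry are deliberately out of scope. Blood dose, when
computed from a blood time–activity curve, carries the same label.

## Quantification chain

* **Calibration**: a sealed vial of known activity imaged with the patient
  gives the counts-to-mCi factor per frame. The EOI frame is optionally
  rescaled so the image total equals the administered activity (whole-image
  scale correction standing in for CT-based attenuation correction, which
  requires the CT and is out of scope); later frames share the EOI factor so
  the correction cannot bend the decay curve.
* **Treated region**: fixed thresholding relative to the maximum voxel.
  The fraction defaults to 0.40 — the common nuclear-medicine convention
  when the protocol fraction is unreported — is configurable, and is
  recorded in every run manifest. Ties exactly at the cut are included.
  An all-zero field has no maximum and is a hard error.
* **Coverage**: Vd = mask voxels x voxel volume; %TVT = overlap with the
  GTV / GTV x 100, reported from the 120 h frame by default. Grids must be
  pre-registered; shape mismatch is a hard error (no resampling here).
* **Time–activity curves**: tumor activity per frame = (tumor-ROI counts /
  whole-image counts) x whole-image activity. Cumulated activity is the
  trapezoidal integral over [0, 192] h with *no* decay tail by default
  (matching a finite imaging window); `tail="physical_decay"` adds
  A(end)/lambda. The trapezoid was chosen because it is standard and
  testable against closed forms; at 1 h sampling of an 89.2 h exponential
  its relative error is under 0.5% (verified against quadrature).
* **Tumor mass** uses the baseline GTV volume, not the treated-region
  volume: the dose equation's m is the mass of tumor.

## Synthetic cohort generator

The generator reproduces the *structure* of the modeled phase 1 study so
every downstream stage runs without patient data:

* **Escalation plan and demographics** follow the published per-cohort
  tables (`trial_tables.py`): infused volumes 0.66–8.8 mL, administered
  activity 1–22.3 mCi, cohort sizes 3/3/3/3/3/6, per-cohort age and
  baseline-tumor-volume means/SDs/ranges (tumors 0.9–22.8 mL), ECOG
  proportions. Ages and volumes are truncated-normal draws within the
  published ranges.
* **Phantoms**: near-spherical GTV (mild random anisotropy) at grid center
  on a 64^3 grid of 2 mm voxels; activity is a sum of isotropic Gaussian
  kernels at 1–4 catheter tips (single catheter in cohorts 1–3), scaled so
  the voxel sum equals the administered activity exactly, plus a 2% uniform
  background. The Gaussian was chosen because no spatial distribution model
  is published and it yields analytic 40%-isosurface volumes for tests.
  Kernel sigma is drawn per patient on 12–20 mm, putting single-catheter
  treated volumes in the tens of mL; with probability 0.15 a tip is grossly
  displaced (1.5–2.5 tumor radii), emulating occasional poorly converged
  infusions and producing the wide coverage range (single-digit %TVT to
  100%) seen clinically.
* **Imaging**: expected counts = activity x 2^(-t/89.2) x counts_per_mCi at
  {0, 24, 120, 192} h post-EOI; observed counts Poisson; detector
  sensitivity defaults to 5e5 counts/mCi. A synthetic vial record decays
  with the frames. No separate detector PSF is modeled — spatial blur is
  represented only through the deposition kernel width; resolution effects
  on thresholding are therefore understated relative to real SPECT.
* **Outcomes**: log T = intercept + X beta + sigma eps (standard normal
  eps), administrative censoring at 36 months. Coverage and dose effects
  default to the adjusted overall-survival fold changes reported for the
  modeled trial (ln 1.274 per 10 %TVT points; ln 1.312 per 100 Gy). The
  remaining defaults (age -0.010/y, ECOG -0.30/level, baseline volume
  -0.020/mL, sigma 0.80, intercept 1.12) were set once so a cohort-average
  patient has a median OS near 11 months; PFS shares the linear predictor
  with a log shift of ln(4/11) and is clipped at OS. Best response is a
  multinomial whose stable-disease/partial-response odds rise with coverage.
* **Adverse events**: per-patient Poisson event counts (mean 159/21), grade
  and attribution multinomials defaulting to the published event-level
  proportions, CNS/non-CNS terms, exponential resolution times. With
  `dlt_free=True` (default, matching the modeled trial's 0 DLTs) any
  attributable grade-3 draw is downgraded to unlikely attribution.

What passing tests on this generator do *not* show: robustness to real
SPECT physics (scatter, collimator response, attenuation heterogeneity,
registration error), to non-Gaussian convection geometry (backflow, CSF
spillage, anisotropic white-matter tracts), or to informative censoring —
none of which the generator emulates.

## Statistics

* **Kaplan–Meier**: product-limit estimator (lifelines); median = smallest t
  with S(t) <= 0.5, undefined medians reported as None, not coerced.
  Median 95% CI by inverting the pointwise log–log (exp(-exp)) band — the
  Brookmeyer–Crowley construction; the method name is recorded in output.
  Landmark survival (default 9 months) with Greenwood SE.
* **Log-rank**: standard 1-df statistic; verified against a brute-force
  observed-minus-expected oracle and exhaustive label permutation on toy
  sets.
* **AFT**: right-censored lognormal regression by maximum likelihood
  (lifelines). Fold change = exp(beta x increment) with Wald 95% CIs
  exponentiated from the log scale (the exact software conventions of the
  original analysis are unpublished; Wald-on-log is used and stated).
  Zero durations are nudged to half the smallest positive duration rather
  than dropping subjects. The covariate "baseline volume administered" is
  interpreted as the infused volume in mL.
* **Correlations**: Pearson by default (Spearman via flag), pairwise
  deletion, t-based two-sided p; zero-variance pairs are flagged, not
  computed.
* No multiplicity correction; two-sided alpha = 0.05 throughout.
* **Safety**: per-patient tables deduplicate by maximum grade within
  (patient, term); grade/attribution tables are event-level. DLT = grade
  >= 3 attributable toxicity within 28 days, with CNS events additionally
  requiring >= 96 h persistence; an unresolved CNS grade >= 3 event is
  conservatively treated as persisting. Attributable = relation in
  {possible, probable, definite} (configurable). Escalation uses the
  canonical 3+3 decision table (the trial's specific "modification" is
  unpublished) with DSMB sign-off as an approval flag; the 90-day extended
  CNS window is a timing gate, not a DLT criterion, and is not part of the
  per-event classifier.

## Numerical and reproducibility choices

* One global seed; per-stage integer streams (< 2^31) derived via
  `numpy.random.SeedSequence.spawn`. Reruns with identical config and seed
  are byte-identical; CSVs use a fixed float format and JSON is
  key-sorted, with no timestamps in outputs.
* Voxel coordinates are 0-based; volumes in mL = mm^3/1000; voxel-center
  inclusion defines masks (discretization error of a 6.2 mm sphere at 1 mm
  voxels is ~2.3% and vanishes as voxels shrink).
* Problem sizes: the demo cohort is 21 patients on 64^3 grids (2 mm
  voxels); pipeline tests use 32^3 grids at 3 mm; parameter-recovery checks
  use n = 500 over 3 seeds and the null-coverage simulation 200 replicates
  of n = 60 — sizes at which the Monte-Carlo error bands in the tests are
  meaningful for each check.

## Known limitations

* Organ dosimetry is a local-deposition approximation, not phantom-based
  S-value dosimetry; values are labeled accordingly and are not comparable
  to OLINDA outputs.
* The treated region is activity-thresholded, not an isodose volume; 3D
  dosimetry by isodose lines is out of scope.
* The survival generator is a correctly specified lognormal AFT — parameter
  recovery demonstrates estimator correctness, not robustness to model
  misspecification.
* Reproducing the modeled trial's survival medians requires its
  patient-level source data, which is not publicly deposited; the
  corresponding check reports that absence explicitly.
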