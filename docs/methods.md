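# Methods

This note documents the models, numerical choices and limitations behind
`amylofilter`. It is written for users who need to judge what the package's
results do — and do not — establish.

## Data model

A dataset is a rectangular pixel grid (default 200 µm pitch) whose acquired
pixels each hold a centroided peak list in the m/z × drift plane. Drift time
is an integer bin index on a 200-bin mobility axis; fractional drift values
appear only as *reference* drifts, because references are averages over
cases. All peaks are treated as singly protonated species; profile-mode
spectra, deisotoping and z-stacks are out of scope. Internally peaks live in
parallel NumPy arrays sorted by (m/z, drift). On disk the package reads and
writes imzML 1.1 (processed mode) through pyimzml, with the per-spectrum
drift-bin array encoded as a vendor-style userParam (pyimzml writes
userParams but does not parse them back, so reading uses a small lxml pass
over the XML in document order); an HDF5 cache with flat concatenated
arrays is the fast format for repeated access. imzML coordinates are 1-based
at the file boundary and 0-based everywhere else.

## Preprocessing

**Order.** Lock-mass recalibration runs on raw centroids, *before* peak
picking, then base-peak normalization after picking. Rationale: the
matrix-cluster lock peak is present in every raw pixel, whereas the
dataset-wide top-N retention of the picker can drop lock peaks in
deposit-rich pixels and starve the calibration estimator; and an intensity
threshold expressed in counts is meaningless after normalization.

**Lock-mass correction** is a single multiplicative factor
`lock_mz / median(observed lock m/z across pixels)` — one external
calibration per dataset, robust to pixels lacking the matrix cluster. If
fewer than 50 % of pixels contain a lock peak within the search window
(default 100 ppm) the dataset is left uncorrected with a warning.
Multiplicativity guarantees that m/z ratios within a pixel are preserved to
machine precision.

**Peak picking** is a deterministic stand-in for proprietary vendor
software, defined by the four published parameters (m/z window 0.1 Da,
intensity threshold 10 counts, drift window 5 bins, IMS peak width 2–10
bins, 3000 most intense signals): per pixel, the most intense unassigned
event seeds a cluster absorbing every unassigned event within ±mz_window/2
and ±drift_window; cluster m/z and drift are intensity-weighted means (drift
rounded to a bin), intensity is the member sum. Clusters whose apex is below
the threshold, or whose drift extent (occupied-bin span) falls outside the
accepted IMS peak width, are discarded — single-event clusters have no
measurable extent and bypass the width check, otherwise centroided synthetic
data would be unpickable. Seeding ties break by (lower m/z, lower drift), so
the output is unique; a brute-force reference implementation written
independently from the same rules is part of the test suite.

**Top-N semantics.** "3000 most intense signals" is interpreted at the
dataset level: per-pixel clusters are grouped into m/z × drift *signals*
(same greedy windows, dataset-wide), signals are ranked by their summed
intensity, and every per-pixel cluster of a top-3000 signal is retained.
The alternative — keeping the 3000 most intense per-pixel clusters pooled
over pixels — was implemented first and measurably destroys the method: each
peptide then survives only in a sparse, mutually disjoint subset of its
pixels, image correlations against the reference collapse to R ≈ 0.1–0.3,
and the colocalization criterion can never be met. Retaining whole signals
keeps every survivor's ion image intact, which is what an imaging pipeline
needs.

## The MDIC filter

A target is detected when it passes mass accuracy (|signed ppm error| ≤ 30),
drift time (|observed − reference drift| ≤ 2.5 bins) and image correlation
(Pearson R ≥ 0.75 against the m/z 968.55 reference image) simultaneously.
Observed m/z and drift are intensity-weighted means over all peaks matched
inside a search window widened by a factor 2 relative to the tolerances, so
that signed errors can be measured before the pass/fail decision.

**Minimum pixel support.** A candidate only enters scoring when its matched
peaks occupy at least 1 % of acquired pixels. A genuine tissue peptide emits
in a large share of pixels; a chance near-isobaric decoy occupies a handful.
Without this guard a stray decoy inside the 30-ppm window can (a) bias the
drift-reference average for the reference peptide — whose image correlation
with itself is tautologically 1 and therefore filters nothing — and (b) flip
a control case to amyloid-positive. Both failure modes were observed on
synthetic data before the guard was added.

**The amyloid call** is exactly "the reference peptide at m/z 968.55 passes
M and D". The detected-peptide signature of the other targets is reported
but does not alter the call; it varies from case to case, which is why the
method speaks of a *universal signature with variable composition*.

**Reference drift calibration** mirrors the derivation procedure: over a
derivation cohort, collect the observed drift of every target that passes M
and whose mass-only ion image correlates with the mass-only reference image
at R ≥ 0.75, then average per target (plain mean). Targets never observed
keep their reference drift unset and are reported undetected thereafter —
they cannot satisfy all three criteria. Pearson R is computed over all
acquired pixels including zeros (absence colocalizes too); correlations of
zero-variance images are undefined and returned as NaN, never as a pass.

**Detection frequencies** are reported as n_D/n per target and group with
percentages rounded half-away-from-zero — the convention that reproduces
every published percentage cell (62/66 → 94, 31/32 → 97, 30/32 → 93.8).

## Cohort statistics and typing

Regions of interest are pixels strictly above the 0.8 quantile of the
nonzero reference-image intensities (fallback: the argmax pixel). ROI pixels
are exported as 19-dimensional TIC-normalized intensity vectors computed
from *raw-count* picked spectra, the pixel's total ion current being the sum
of all its picked peaks.

The Mann–Whitney U test runs per target on pooled ROI pixels of the two
groups (two-tailed, tie-corrected, Bonferroni threshold 0.05/19). Pixels
maximize power and mirror the per-spectrum export, but they are
pseudoreplicates of their case: with thousands of pooled pixels even small
presence-frequency differences become significant, so on synthetic cohorts
nearly all 19 targets flag. The test is therefore best read as a feature
screen, and the classifier — not the U test — is the diagnostic claim.

The SVM types *cases*: each case enters as the median TIC-normalized
intensity of the feature masses over its ROI pixels (default features: the
six masses with higher ATTR intensity — 764.45, 1156.60, 1406.67, 1811.89,
1422.65, 1366.76). Kernel k(x, y) = exp(−‖x−y‖²/2σ²) with σ = 2 and C = 10,
stratified fourfold cross-validation; the confusion matrix aggregates
held-out predictions. Two numerical choices matter:

* **Standardization (default on).** TIC-normalized medians have magnitude
  ~0.01–0.1, so without scaling the RBF kernel is numerically constant
  (exp(−~10⁻⁴) ≈ 1 for all pairs) and the classifier degenerates to a
  majority vote. Features are z-scored before the kernel; a `z_score=False`
  escape hatch restores raw features.
* **Order independence.** Cases are sorted by case id before fold
  assignment, so the stratified folds — and hence the confusion matrix —
  depend only on the seed, never on input order.

Diagnostic metrics (sensitivity, specificity, predictive values) are
percentages rounded to one decimal, half away from zero: 31/34 → 91.2,
30/32 → 93.8, 31/33 → 93.9, 30/33 → 90.9.

## Synthetic data

The generator emulates the statistical situation the filter assumes, on a
64 × 64 grid with a deposit drawn as a union of random discs (radii 3–8 px,
discs added until ~15 % coverage). Per case and panel target, presence is an
independent Bernoulli draw with the published per-class detection
frequencies as probabilities (controls carry no targets). Present targets
emit one centroid per pixel: m/z perturbed by a global +25 ppm calibration
offset plus N(0, 8 ppm) noise; drift N(target mean, 0.8 bins) rounded to a
bin, with target means spread deterministically over bins 40–160; intensity
log-normal with median 100 counts inside the deposit and a 10× contrast over
the background. ATTR cases scale the six discriminating masses by 2× — the
class difference is an intensity effect, not presence alone. Every pixel
also carries the lock-mass peak (median 500 counts) and 30 uniform decoys
(median 8 counts, σ = 0.5).

Two intensity parameters were fixed by design-time analysis rather than
taken from published values (none exist for them):

* **log-normal σ = 0.35.** With contrast c = 10 and deposit fraction
  p = 0.15, the expected Pearson R between two independent present targets
  is p(1−p)Δ² / (p(1−p)Δ² + p·σ²_dep + (1−p)·σ²_bg) ≈ 0.83 at σ = 0.35 but
  ≈ 0.70 at σ = 0.5 — below the filter's own working regime (R ≥ 0.75 for
  the vast majority of true detections). A generator in which genuinely
  colocalized peptides systematically fail the IC criterion would not
  emulate the data-generating situation the method was built for.
* **lock median 500 counts.** On real tissue the matrix cluster dominates
  most pixels' base peak. If panel peptides were the base peak inside
  deposits, per-pixel base-peak normalization would divide the deposit
  signal by itself and erase the contrast the filter depends on.

What the generator does **not** model: realistic tissue morphology and
partial tissue coverage, matrix crystallization artefacts, detector
saturation, isotope patterns, chimeric peaks, case-to-case biological
variability of intensity beyond the class effect, and correlated noise
between targets. Passing tests therefore demonstrate that the
implementation recovers the structure it assumes — calibration offsets,
colocalization, class effects — not that the method attains the published
performance on real tissue.

## Problem sizes used by the test and acceptance suites

Unit tests run on 16 × 16-pixel cases; the acceptance suite runs the full
97-case validation preset (32 ALλ + 34 ATTR + 31 controls, 64 × 64 pixels,
~180 000 centroids per case) with drift calibration on a 16-case derivation
cohort, 500 random picking instances against the brute-force oracle, a
1000-replicate null simulation of the Bonferroni-corrected U test, and 100
random cases for filter monotonicity. The complete suite and the acceptance
script each finish in a few minutes on one CPU; the clustering kernel is
JIT-compiled with numba.

## Known limitations

* Reference drift bins are not portable constants: they must be calibrated
  per instrument setup (the packaged synthetic drift table is labelled as
  such and is valid only for generated data).
* The greedy picker is a documented approximation of the vendor algorithm,
  which is unpublished; only its four public parameters are honoured.
* The pooled-pixel U test overstates significance relative to case-level
  tests (see above).
* The amyloid call rests entirely on one ApoE peptide; tissues where ApoE
  co-deposition is weak (e.g. prefibrillar aggregates) are outside the
  method's guarantees.
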