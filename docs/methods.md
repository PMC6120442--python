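# Methods

## Scope and data model

`iainmap` operates on per-pixel, per-date, per-band observations: optical
top-of-atmosphere (TOA) reflectance in [0, 1] (BLUE, GREEN, RED, NIR) and
C-band SAR backscatter in dB (VV, VH). All tabular I/O is plain CSV/JSON;
the in-memory container is the `FeatureCube` — a pixels × features matrix
(feature = band × half-month period) with an explicit boolean missing
mask. Missingness is never encoded as a sentinel value; masked cells hold
NaN only as hygiene and are never read.

## Compositing

Calendar half-months (days 1–15, day 16–month end) define the composite
periods. Optical bands composite by the **median** of valid observations
in the period; SAR by the **maximum**, per polarization independently.
NDVI is computed per period from the composited NIR and RED reflectances;
a zero denominator or a missing input yields a missing NDVI. Composite
columns whose missing fraction **strictly exceeds** 0.5 are dropped (a
column at exactly 50 % is kept), matching the convention of discarding
composites with more than half cloud cover. The median of an even-length
sequence is the mean of the two middle values (the standard sample
median).

## Non-vegetation mask

The mask thresholds the per-pixel seasonal maximum of NIR reflectance.
The default threshold is 0.3; `derive_threshold` recovers it from
reference vegetation pixels as mean − standard deviation (population sd)
of their seasonal NIR maxima. A pixel exactly at the threshold counts as
vegetation (≥); a pixel with no NIR observation at all is masked. Masked
pixels are excluded before classification and labeled `masked` (code 0 in
raster-style outputs); pixels with no available feature are
`unclassifiable` (code 255).

## Feature ranking

Two scores are computed per candidate feature:

* **Jeffries–Matusita distance** per unordered class pair, under Gaussian
  class models: JM = 2(1 − e^(−B)) with
  B = ⅛ Δμᵀ[(Σa+Σb)/2]⁻¹Δμ + ½ ln(det((Σa+Σb)/2)/√(det Σa det Σb)).
  Covariances are regularized by adding 1e−6 to the diagonal; log-dets use
  `slogdet` for stability. JM is bounded in [0, 2]; 1.5 is the
  conventional separability floor. Rows missing the feature are excluded;
  a class pair left with fewer than 2 samples on a side is reported NaN.
* **Gini importance** from a random forest (scikit-learn), default 1000
  trees and √p candidate features per split, reported as the raw
  (unnormalized) sum over all trees of the node-weighted Gini impurity
  decreases, so scores add up to the forest's total impurity decrease.
  Missing entries are mean-imputed per feature *for ranking only* —
  classification never imputes.

`rank_and_select` orders features by Gini (descending, name ascending on
ties) and retains a feature when its Gini reaches 30 % of the maximum
observed score (raw Gini sums are data-scale dependent, so the floor is
relative), when its rank is within an optional top-k, or when its minimum
JM over the target class pairs reaches the 1.5 floor. The pipeline caps
the selection at the top 10 Gini-ranked features by default, mirroring
the practice of carrying the ten most important features forward.

## The IAIN classifier

**State.** Antigens are labeled, complete feature vectors min–max
normalized to [0, 1] with bounds fitted on the training set (degenerate
features map to 0.5; application-time values outside the bounds clip).
Antibodies carry a label, a center in [0, 1]ⁿ and a recognition radius.

**Radius rule.** A candidate center's radius is the Euclidean distance to
the nearest antigen of a *different* label minus a purity margin
ε = 1e−6, floored at 0; with no foreign antigen the radius is the cube
diagonal √n. Radii therefore never enclose foreign-class training points.

**Training loop.** Until every antigen is recognized (or a cap of 1000
antibodies per class, never reached in practice):

1. *Pre-selection*: the unrecognized antigen covering the most
   unrecognized same-label antigens within its own candidate radius (ties
   → lowest index).
2. *Cloning and mutation*: `n_clones` = 10 copies perturbed with
   per-feature Gaussian noise, sd 0.05 in normalized units, clipped to
   [0, 1]; the unmutated original always competes.
3. *Commit*: the candidate recognizing the most unrecognized same-label
   antigens becomes an antibody (ties → original, then candidate order);
   the antigens it recognizes leave the pool. The original covers itself
   at distance 0, so every iteration strictly shrinks the pool — this is
   the termination argument, and it bounds the antibody count by the
   antigen count.
4. *Reorganization* (after the loop): scanning antibodies in reverse
   creation order, any antibody whose covered same-label antigen set is
   contained in the union covered by the remaining antibodies is removed;
   the union is invariant, so every antigen stays within radius of a
   surviving same-label antibody.

A single seeded generator drives mutation; creation order is the
canonical tie-break everywhere, so training is bit-reproducible given the
seed. Training requires complete vectors — incomplete training pixels are
rejected with a count (missing values are a classification-time concern).
Identical vectors with conflicting labels are kept (each under a
zero-radius antibody) with a warning.

**Classification.** A query is normalized with the training bounds;
every antibody is restricted to the query's available coordinates (its
*sub-antibody*) and the nearest restricted center's label wins (ties →
earliest antibody). Restricted distances are deliberately **not**
rescaled by the number of available features: all antibodies are
restricted to the same index set for a given query, so the comparison is
internally consistent, and rescaling would cancel in the argmin anyway.
The radius is reported only as a diagnostic "recognized" flag and never
changes the label; a query with no available feature raises an
unclassifiable error. Networks serialize to JSON exactly (floats
round-trip via shortest-repr).

**Limitation — overlap.** Training terminates when every antigen is
*covered*, but labeling is nearest-distance, so on strongly overlapping
classes a training antigen can lie closer to a foreign antibody than to
any of its own (we measured ~30 % training error on two 6-feature
Gaussians at means 0.45/0.55 with sd 0.1). The training-consistency
property (100 % training-set accuracy) is an empirical contract of the
separable regime crop signatures live in, not a theorem; the test suite
asserts it on separable fixtures only, and the Euclidean metric's noise
sensitivity is a known general limitation of this classifier family.

## Accuracy assessment

Confusion matrices are oriented rows = predicted, columns = reference, so
UA (user's accuracy) is diagonal / row sum and PA (producer's accuracy)
diagonal / column sum — the orientation that reproduces the published
validation tables this package's metric checks are frozen against.
OA = 100 · trace/N; kappa = (N·Σdiag − Σ rowᵢcolᵢ)/(N² − Σ rowᵢcolᵢ).
Percentages print to two decimals but are stored at full precision.

The early-season sweep takes a cumulative feature plan (the features
gained at each half-month length), retrains the classifier per length on
the training pixels complete in those features, classifies the validation
pixels (missing allowed), and reports per-length OA/kappa/PA/UA.
`saturation_point` returns the earliest length at which a class's PA and
UA both reach 95 % — first crossing, even if accuracy later dips.

## Synthetic scenes

`phenosynth` emulates exactly the statistical structure the pipeline
assumes, and no more:

* **NDVI trajectories** are double-logistic:
  v(t) = vmin + (vmax − vmin)[σ(k1(t − t_green)) − σ(k2(t − t_senesce))].
  Defaults follow a North China Plain calendar — winter wheat t_green 75,
  t_senesce 160 (harvested early June); cotton 145/266 with a slow
  green-up (k1 = 0.06); spring maize 141/243 (fast, k1 = 0.12); summer
  maize 190/274 (sown in the first half of July, flat at vmin through
  spring); a "bare" profile (NDVI ≈ 0.05) for non-vegetation. Inflection
  days sit roughly 20 days after the sowing window and at the midpoint of
  maturation. Per-observation NDVI noise sd is 0.02.
* **Optical bands** derive from NDVI by RED = 0.12 − 0.08·v and
  NIR = RED(1 + v)/(1 − v), an exact algebraic inverse of the NDVI
  formula, so the index computed downstream recovers the generating curve
  to machine precision; BLUE and GREEN are scaled copies of RED with
  small noise. SAR is a per-crop mean (VV/VH in dB) plus Gaussian noise
  (sd 1.5 dB).
* **Cloud loss** is period-correlated: one Bernoulli draw per (pixel,
  half-month) removes all optical observations of that period, while SAR
  is never lost — mirroring radar's cloud insensitivity. Default loss
  probability 0.2. `inject_missing` additionally knocks out an exact
  fraction of present optical cells uniformly at random.

What the generator does **not** emulate: atmospheric and angular
(BRDF) effects, SAR speckle, mixed pixels and field-boundary spectra,
spatial autocorrelation of classes and clouds, and inter-annual
phenological shift. Passing tests therefore demonstrate the mechanics of
compositing, selection, missing-value classification and evaluation —
not performance on real imagery, where separability is set by the
sensors and the landscape.

## Pipeline defaults and problem sizes

The orchestrated run (`run_pipeline`) uses: composite discard threshold
0.5; NIR mask threshold 0.3; ranking forest of 300 trees (the library
default is 1000; the pipeline default favors fast interactive runs, and
rankings on the synthetic scenes are already stable at 300) with top-10
cap; IAIN with 10 clones, mutation sd 0.05, ε = 1e−6. One run seed fans
out to per-stage child seeds via `numpy.random.SeedSequence`, so stages
are individually reproducible and reruns are identical. IAIN training
consumes the training pixels that are complete in the *selected*
features: with 20 % period-correlated cloud loss, completeness over all
~14 periods is rare (~0.8¹⁴ ≈ 4 %), but over the handful of selected
periods it is ample (tens of pixels per class at the default scene
sizes), which is precisely why selection precedes training.

Reference experiments (test suite and acceptance script) use a 4-crop
scene with 100 pixels per class and a held-out half for validation, a
two-class Gaussian benchmark (means 0.2/0.8, sd 0.05, 10 features, 40
training / 200 test vectors, 30 % of test entries masked), and a
two-crop late-divergence scene (identical profiles except senescence day
220 vs 270, 60 pixels per class) for the sweep — sizes chosen to keep a
full suite run around ten seconds while leaving the measured quantities
far from their acceptance margins.
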