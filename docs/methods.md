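# Methods

This note documents the models, conventions and numerical choices behind
`ctcmorph`, and what the synthetic-data experiments do and do not show.

## Measurement model

Each marked event is a set of three spatially aligned grayscale
thumbnails (DAPI, CK, CD45) with a physical pixel size (default
0.64 μm/px, the value implied by a 6.4 μm scale bar spanning ten pixels
in CellSearch-style galleries; always configurable, and read from TIFF
resolution tags when present).

**Segmentation** is deterministic and parameter-light:

1. 3×3 median filter (noise suppression);
2. Otsu's global threshold;
3. a background guard: if the threshold does not clear the background
   level (median of the 2-px border ring) by 4 robust standard
   deviations (1.4826·MAD), the thumbnail is declared signal-free. This
   prevents Otsu from hallucinating foreground on noise-only channels —
   e.g. the CK channel of a leukocyte;
4. connected components smaller than 4 μm² (the platform's minimum CK
   signal, converted to pixels via the pixel size) are dropped;
5. the component nearest the thumbnail center seeds the event; any other
   component within the merge distance (default 3.2 μm) of the kept set
   is agglomerated into it, so the blobs of a doublet/cluster are
   measured as one region while distant debris is excluded. The merged
   region is measured as a single area and perimeter, because the shape
   classifier judges the whole event, not each blob.

Degenerate inputs (constant or noise-only images) produce an empty mask
and an "undefined" measurement, never an exception.

**Features.** Area = foreground pixel count × (pixel size)²; mean
intensity over the foreground; perimeter from the marching-squares
contour at the 0.5 level of the (padded) mask, with each closed contour
regularized by a circular moving average of window 3 before summing
segment lengths. The raw staircase contour overestimates smooth
boundaries by ≈ 5–11%; the window-3 smoothing brings digitized disks of
radius ≥ 4 px to within ~2% of the true perimeter while shaving only a
few percent off true corners (a side-50 square scores P2A within 3% of
4/π). We use this contour-based estimator rather than the classical
weighted pixel-boundary estimator because the latter biases small-disk
P2A down by 8–23% and square P2A by −6%, which would distort the 1.5
class edge for small nuclei. P2A = P²/(4πA) is dimensionless, equals 1
for an ideal circle, and is undefined (not 0) for empty masks; the
residual discretization tolerance motivates the documented invariant
P2A ≥ 0.9 rather than ≥ 1.

**Positivity** is defined uniformly as a nonempty segmented signal
(area > 0 μm²) for all three channels.

## Classification and selection

CK P2A bins (half-open, lower-closed): single [0, 1.5), doublet
[1.5, 2.5), small cluster [2.5, 4), large cluster [4, ∞). The edges are
configuration, not constants, but the defaults follow the published
convention, including 1.5 counting as a doublet and 4.0 as a large
cluster. Events without a CK signal are "undefined" and excluded from
all classes rather than defaulted.

The cascade flags, in order: `size_eligible` (CK+ and single);
`dapi_evaluable` (size-eligible, DAPI area > 0 and DAPI < CK — the
intact-nucleus rule); `ncr_eligible` (additionally a single DAPI
signal, where the same bins are reused on the DAPI P2A with doublet →
"double" and both cluster bins → "clustered"); `leukocyte`
(CD45+/DAPI+/CK− with a single CD45 signal — the CK singularity rule
applied to the CD45 channel). Tabulation preserves the identities
single + doublet + small + large = CK-positive and
dapi_single + dapi_double + dapi_clustered = dapi_evaluable per cohort;
totals are always computed column sums (one published row total differs
from its printed cells by 1; we report the computed sum).

## Morphometry conventions

* Computed diameter CD = 2·√(A/π). This reproduces every published
  (median area, CD) pair at the printed precision.
* NCR is an **area** ratio A_DAPI/A_CK, not a diameter ratio, although
  the source text mentions diameters: the published per-cohort NCR
  values match area ratios (e.g. 52.0/83.6 = 0.62, 43.4/57.8 = 0.75)
  and none match diameter ratios (which would be their square roots).
  The diameter-ratio variant is available via
  `AnalysisConfig(ncr_convention="diameter")`.
* A cohort NCR can be the median of per-event ratios or the ratio of
  cohort medians; the published values are consistent with either at
  the ±0.02 level except the breast cell-line cohort (printed 0.37,
  area ratio of medians 0.355). The summaries report both (`ncr` and
  `ncr_of_medians`).
* Reports round diameters to 1 decimal and NCR to 2 decimals; full
  precision is kept internally.

## Statistics

Quantiles use linear interpolation (type 7); the IQR is reported as the
single width Q3 − Q1. Group comparisons use scipy implementations behind
the module interface: Kruskal–Wallis with tie correction (χ², k−1 df;
all-identical inputs return H = 0, p = 1), two-sided Mann–Whitney U
(exact null distribution when the smaller sample has ≤ 8 observations
and the pooled sample is tie-free, otherwise normal approximation with
tie and continuity correction), and the independent-samples median test
(values classified as above vs at-or-below the pooled median; a
degenerate classification yields an explicitly undefined result). Tests
are cross-checked in the suite against independent enumeration oracles
(exhaustive assignment enumeration for U, the rank-mean formula for H).
No multiplicity correction is applied by default, matching the published
analysis; Bonferroni is available as a config flag.

The default comparison plan: KW + median test across the four tumor-type
blood cohorts; all 6 pairwise MWU; blood vs liquor within breast; CTCs
vs cultured cell lines within breast and prostate; leukocytes vs each
tumor type. Missing optional cohorts (liquor, cell lines, leukocytes)
are skipped with a warning; missing tumor cohorts are an error. The same
battery is repeated for nucleus areas and NCRs over the evaluable
subsets.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes;
real per-event distributions are unpublished, so the parametric families
are assumptions and labeled as such:

* **Cell areas**: lognormal, the minimal right-skewed two-parameter
  family that can match a positive median and a large IQR
  simultaneously. Calibration is closed-form:
  μ = ln(median), σ = asinh(IQR/(2·median))/z₀.₇₅. Draws are capped at
  2000 μm² (far beyond every cohort's Q3) so every event fits a
  thumbnail; the cap is beyond the quartiles and does not affect
  median/IQR calibration.
* **NCR**: Beta with target median (median ≈ (a−1/3)/(a+b−2/3)) at
  concentration 20 — single-cell NCR spreads of roughly ±0.1–0.2 around
  the cohort median, a realistic within-cohort spread.
* **Class mix**: the published per-cohort singularity frequencies.
* **Rendering**: events are anti-aliased disks on a constant background
  (level 60) with foreground level 500 and Gaussian read noise σ = 15
  (arbitrary units, ~30:1 peak signal to noise — fluorescence thumbnails
  of enriched, stained cells are high-contrast). Doublets and clusters
  are 2, 3 and 5 equal disks (chain; compact cross for large clusters)
  with a 2 μm edge-to-edge gap: the measurement stage merges them into
  one region whose P2A is ≈ k for k circles, i.e. near the middle of
  each class bin (2 for doublets, 3 for small, 5 for large clusters).
  The gap is below the merge distance but wide enough that the median
  filter does not fuse the cells into one round blob. Nuclei are single
  disks inside the first cytoplasm disk at the event's true NCR;
  configurable rates produce DAPI-negative events, oversized
  (non-intact, DAPI ≥ CK) nuclei and two-lobe nuclei. Leukocytes carry
  their disk in CD45 + DAPI with an empty CK channel.
* **Preset** (`reference_cohorts`): eight cohorts — four tumor types
  (blood), breast liquor, breast and prostate cell lines, leukocytes —
  with the published medians, IQRs, NCR targets, class mixes,
  DAPI-evaluability rates and detected-event counts; a `scale` argument
  shrinks all cohorts proportionally. The leukocyte NCR target (0.80)
  is a realism choice (lymphocytes have scant cytoplasm), not a
  published value.

What passing recovery tests show: the pipeline (segmentation →
classification → cascade → morphometry → statistics) is unbiased at the
few-percent level under the generator's assumptions — disk-like cells,
high contrast, Gaussian noise, exact marker centering. What they do not
show: robustness to real-cartridge phenomena such as irregular cell
shapes, debris and staining artifacts, out-of-focus planes, overlapping
(rather than adjacent) cells, or vendor-specific segmentation behavior;
numeric agreement with the original analysis software on real cartridges
cannot be asserted from synthetic data.

## Problem sizes

The acceptance computations use the sizes at which the statistical
guarantees are meaningful while staying desk-scale: parameter recovery
on one rendered cohort of 5000 events (median CD within 3%, NCR within
±0.03 of generator truth; ~1 minute on one CPU) and 500 null replicates
for the type-I calibration of the rank tests (target 0.05 within
[0.03, 0.07]). The published arithmetic (diameter conversions, NCR
triples, tabulation percentages over the 71612 published events) is
exact and immediate.

## Known limitations

* The marker-file dialect is a minimal open stand-in; the vendor's
  actual schema is proprietary and is not parsed.
* Only the features the analysis consumes are measured (area, perimeter,
  P2A, mean intensity); eccentricity and other texture features are out
  of scope.
* The P2A thresholds are taken as given, not re-derived from data.
* Cluster geometry (equal disks, fixed gap) is a modeling convenience;
  real clusters have unequal, overlapping cells. Cluster-class recovery
  is therefore asserted at rendered-geometry level only; the ≥95%
  recovery guarantee is stated for singles and doublets.
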