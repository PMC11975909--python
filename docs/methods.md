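# Methods

This note documents the models, algorithms and design choices behind
`phenoscreen`, and what its synthetic benchmarks do and do not demonstrate
about real high-content data.

## The experiment being modeled

PBMCs from multiple donors are plated in 384-well plates, stimulated with
TLR pathway agonists (TLR4, TLR7, TLR8, TLR7/8, TLR9) or DMSO vehicle, and
imaged at 6, 24 and 48 hours in five fluorescence channels: nuclei
(Hoechst-class stain), filamentous actin (phalloidin), membrane/ER
(concanavalin A), mitochondria (MitoTracker) and annexin V (early
apoptosis). The analysis asks, per well: how many cells, of which
morphological classes (small round lymphocyte-like, 6–15 µm; large round
myeloid-like, ~20 µm), and what fraction of each class carries each
phenotype of interest — annexin V positivity, nuclear fragmentation,
contracted vs dispersed actin, podosomes, phagocytic morphology — relative
to the DMSO wells of the same plate, donor and timepoint. Matched
supernatants are profiled on a 51-analyte secreted-protein panel and
normalized the same way.

## Synthetic data generator

There is no public generative model for this kind of image, so the
generator is deliberately minimal: the simplest structure that supports
every downstream readout with known truth.

* **Cell population.** A two-component size mixture: small round cells
  (diameter uniform on 6–15 µm) and large round cells (uniform 17–23 µm),
  mixture weight `large_frac` (default 0.30).
* **Phenotypes.** Independent Bernoulli flags per cell: annexin V+ (default
  baseline 0.08, any cell), fragmented nucleus (0.06, any cell; 2–4 lobes),
  actin staining (0.80 of small cells; a stained cell is *contracted* with
  conditional probability 0.25, else *dispersed* — the two are mutually
  exclusive by construction), podosomes (0.35 of large cells), phagocytosis
  (0.20 of large cells). Baseline prevalences are configuration values
  chosen to be plausible for PBMC cultures, not literature claims.
* **Condition effects** are multiplicative on these rates per (condition,
  timepoint). The actin effect multiplies P(contracted | stained) directly:
  since the reported normalized feature is contracted/(contracted +
  dispersed), an injected fold *f* appears as a fold *f* on that feature in
  expectation, which is what the recovery experiments measure. Probabilities
  pushed outside [0, 1] are clamped and counted.
* **Donor heterogeneity** is a log-normal multiplicative random effect (SD
  0.15 on the log scale) on each baseline rate, drawn once per (donor,
  phenotype) and shared across that donor's wells. Because the effect
  multiplies control and stimulated wells alike, it cancels in within-donor
  fold changes — the reason the analysis normalizes per donor in the first
  place.
* **Rendering.** Fields default to 512×512 px at 0.5 µm/px (a 2048 px
  full-acquisition size is a config value; 512 px keeps simulation
  desk-scale). Cells are placed by rejection sampling, largest first, with a
  minimum separation of the two radii plus a 10 px margin; the margin
  guarantees that lobes of one fragmented nucleus (placed within 0.35 cell
  radii of center) are always closer to each other than to any neighbor, so
  the 8 µm fragment-grouping radius cannot bridge cells. Structures are
  painted as soft-edged disks, rings, Gaussian blobs and puncta: nuclei
  (intact disk, or 2–4 adjacent lobes that render as one multi-lobed,
  low-solidity component); membrane footprint (with a vacuole hole on
  phagocytic cells); cytoplasmic mitochondrial annulus; actin as a cortical
  polarized cap (contracted), a uniform peripheral ring (dispersed), faint
  signal (unstained), cytoplasmic signal with bright peripheral puncta
  (podosomes) or an internal phagocytic cup; annexin V as a membrane ring on
  positive cells only. Constant background (default 40) and Gaussian read
  noise (default SD 6) are added per channel. No optical PSF, no
  photorealism — the renders are meant to carry the *geometry* of each
  phenotype, not its microscopy.
* **Cytokines.** Per-analyte log-normal baselines, per-(donor, analyte)
  log-normal multipliers (SD 0.3), per-well log-normal measurement noise
  (SD 0.2), and injected fold effects on stimulated wells.
* **Linear coupling.** For slope-recovery experiments the generator emits
  well-level (Δx, Δy) pairs with Δy = slope·Δx + N(0, noise_sd). The design
  requirement on this generator is that OLS recover the slope within 10% at
  200 wells and noise SD 0.01, including at the smallest magnitude probed
  (0.03142), so Δx is spread uniformly over the full admissible range of a
  fraction delta, [−1, 1]: the widest (most D-optimal-like) probe design
  the variable allows, giving the slope estimator a relative sampling SD of
  about 4% at those settings. (A narrower, more typical ±0.6 spread leaves
  the estimator's SD near 8%, which violates the 10% recovery requirement
  for an appreciable fraction of seeds.)

Everything is driven by explicit integer seeds through
`numpy.random.default_rng`; identical configuration and seed give
byte-identical tables and images.

## Segmentation

The nuclear channel is smoothed (Gaussian, σ = 2 px), thresholded (Otsu,
with a minimum foreground–background contrast of 20 intensity units so pure
noise fields yield no objects), hole-filled, and split by a
distance-transform watershed seeded at h-maxima (h = 2 px) of the distance
map; components outside [50, 5000] px² are discarded and labels are
re-assigned in raster order (4-connectivity throughout), so the output is
deterministic and order-stable. Nuclear components whose centroids fall
within 8 µm of each other (half a large-cell diameter) are merged by single
linkage into one cell seed flagged as fragmented. Crops default to 64 px
(32 µm) squares centered on the seed centroid, zero-padded at field
borders. The crop side and border policy are package choices; nothing in
the modeled experiment dictates them.

## Embeddings

Each crop maps to a fixed 128-long vector of named descriptor blocks
(indices beyond the last block are zero): nuclear morphology (area,
equivalent diameter, eccentricity, solidity, lobe count, total intensity);
mean/SD/quantiles/max per channel; actin radial and angular organization
(center-vs-periphery ratios, a squared-intensity-weighted circular
resultant as the polarization readout, the share of angular mass in the
densest octant, mean normalized radius, cell-local totals and maximum);
peripheral top-hat puncta count and amplitude (podosome proxy); membrane
footprint area/diameter and central dip (size and vacuole proxies); an
annexin membrane-ring readout; a phagocytic-cup score; and per-channel
gradient energy. All radial/angular descriptors are computed around the
intensity centroid of the *central* nuclear component — neighbor cells
inside the crop are explicitly excluded from the reference frame, which is
what makes the descriptors robust to small placement shifts. Non-finite
values are imputed to 0 with a per-cell flag. A standardizer (per-dimension
mean/SD from a reference population such as all DMSO cells) flags
zero-variance dimensions and passes them through unscaled, so the transform
is exactly invertible.

This embedding is a deliberate design choice: interpretable classical
descriptors rather than a pretrained CNN, keeping the package dependency-
light, deterministic, and free of shipped weights, at the cost of
generality on real imagery.

## Basis scoring and SSMD

With control centroids c⁻, c⁺ (arithmetic means of the negative/positive
control embeddings), the axis is u = (c⁺−c⁻)/‖c⁺−c⁻‖. A point x scores
on-basis (x−c⁻)·u (also reported normalized by the axis length, so c⁻ → 0
and c⁺ → 1) and off-basis ‖(x−c⁻) − ((x−c⁻)·u)u‖; the decomposition
satisfies ‖x−c⁻‖² = on² + off² to numerical precision. Assay quality is the
SSMD β = (μ₊−μ₋)/√(σ₊²+σ₋²) of on-basis scores, with sample variances
(n−1) by default and a population-variance option. β is invariant under any
common positive-scale affine transform, so whether raw or normalized scores
feed it is immaterial; reports default to normalized scores aggregated to
well means, with the aggregation level a config choice. The default QC
threshold flags β < 2. The caller must name which conditions serve as
negative and positive controls.

## Phenotype sorting

Separate models per phenotype family — size class (all cells), annexin and
nuclear fragmentation (all cells), actin state (small round cells only:
contracted / dispersed / unstained), podosomes and phagocytosis (large
round cells only) — mirroring how sorting models are built per category,
with eligibility gated on the *predicted* size class at inference time.
Labeled examples are split 80/20 (stratified, seeded); the baseline is a
k-nearest-neighbor vote (k = 15) weighted by inverse class frequency, and
the final model is a gradient-boosted tree ensemble (200 trees, depth 4,
learning rate 0.1 — package defaults, nothing deeper) trained with the same
balanced example weights, seeded and single-threaded for reproducibility.
Held-out metrics (balanced accuracy, per-class precision/recall) are
computed only on cells whose ids are disjoint from training. In tests and
synthetic experiments, generator truth labels stand in for hand labels; a
(cell_id, label) CSV is accepted for real data. Models serialize to a
directory with a JSON metadata file (format version 1) plus the boosted
booster or the kNN training arrays.

## Quantification and normalization

Per well: size-class fractions are over classified round cells; annexin and
fragmented-nucleus fractions are over all detected cells (the denominator
for these is genuinely ambiguous in this kind of reporting; both are
computable, and this default is documented rather than claimed); actin
states over small round cells; podosome and phagocytosis over large round
cells. The paired features are renormalized as

    phagocytosis_norm     = P / (P + large-round-non-phagocytic)
    actin_contracted_norm = AC / (AC + AD)      (dispersed analogously)
    podosome_norm         = Pod / (Pod + NoPod) (no-podosome analogously)

so each pair sums to exactly 1 where its denominator is positive; zero
denominators yield NaN flags, never exceptions. Effects are computed per
(plate, donor, timepoint) stratum against the mean (optionally median) of
that stratum's DMSO wells: per-well delta and fold, then per-donor means,
then the median across donors per (condition, timepoint, feature). Strata
without controls are skipped with a warning. Associations between two
features' per-well deltas report an ordinary-least-squares slope side by
side with Spearman's rank correlation and its p-value — the slope carries
the magnitude, the rank test the evidence, and reporting both loses
nothing.

## Cytokine fold changes

Within each (plate, donor, analyte) stratum, fold = median(stimulated
wells) / median(control wells) per (condition, timepoint); control
conditions map to fold 1 identically. A zero control median is replaced by
a pseudocount of 1% of the analyte's global median (or an explicit ε), and
the row is flagged. Folds are invariant under a common positive rescaling
of a stratum's concentrations. Per-donor measurements are arithmetic means
over replicates; cohort comparisons use the two-sided Mann-Whitney test at
p < 0.05 per comparison, uncorrected by default to match conventional
per-asterisk reporting, with an optional Benjamini–Hochberg adjustment.
Heatmap exports support mean or median per-donor folds.

## Statistics

Mann-Whitney U: exact two-sided p by full enumeration of all C(n₁+n₂, n₁)
assignments of the pooled average ranks when n₁+n₂ ≤ 12 (group sizes of
5–30 donors straddle the exact/approximate regimes, so both are needed);
otherwise a normal approximation with tie correction and a 0.5 continuity
correction. Two-sided exact p is 2·min(P(U≤u), P(U≥u)) capped at 1.
Spearman: rho from average ranks; exact permutation p (full enumeration,
chunked and vectorized) for n ≤ 10, t-approximation with n−2 degrees of
freedom above. Constant vectors yield undefined-flagged results. The
in-test oracles (independent enumeration loops, scipy) confirm exact values
and the approximation error at the crossover (< 0.02).

## Pipeline

`RunConfig` validates strictly (unknown keys rejected, DMSO required)
before any stage runs. Stages — simulate, segment, featurize, basis QC,
train, classify, quantify, cytokines — exchange CSV/TIFF/JSON artifacts in
the output directory; a manifest records the config hash, seeds, per-stage
timings and SHA-256 checksums of every output, so reruns with identical
config and seed are verifiable (all stages are pure functions of config and
seed; boosted-tree training is seeded and reproducible on a fixed
platform). A failed stage leaves partial outputs plus a `FAILED` marker.

## Benchmark problem sizes

The packaged recovery experiments use: 30 simulated donors × (2 conditions
× 2 timepoints × 3 wells) at 80 cells per 512 px field for the
actin-contraction fold recovery (~360 wells, a few minutes on one CPU, the
bulk in rendering and watershed segmentation), trained on 24
phenotype-enriched wells (about 1,900 labeled cells — enough that
training-draw variation in classifier sensitivity no longer biases the
recovered folds appreciably); and 200 wells at noise SD 0.01 for slope
recovery. These sizes were chosen as the smallest at which the estimators'
sampling error is comfortably inside the 10% recovery tolerance.

## What the synthetic benchmarks do and do not show

Passing recovery tests shows the *analysis* is correct and unbiased under
the generative model: segmentation finds the cells it should, the
descriptors separate the phenotypes the renderer draws, classification
error is small enough not to attenuate fold estimates materially, and the
normalization/effect/association arithmetic recovers injected truth. It
does not validate performance on real microscopy: real PBMC images have
debris, clumping, focus drift, uneven illumination, staining variability
and phenotype ambiguity that the renderer deliberately omits, and the
classical descriptors were designed around the renderer's geometry. On real
data the segmentation and featurization stages are the ones to re-validate
first; the scoring, QC, quantification and statistics layers are
data-agnostic.

## Known limitations

* Classical descriptors, not learned embeddings; no GPU path.
* No multivariate or robust (median/MAD) SSMD variants.
* No mixed-effects modeling; donor structure is handled by within-donor
  normalization and donor-level medians only.
* Phenotype flags are independent Bernoullis; real phenotypes co-occur
  (e.g. annexin V and fragmentation late in apoptosis).
* The spearman exact path enumerates up to 10! permutations; n = 9–10
  takes seconds.
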