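# phenoscreen

High-content imaging analysis of TLR-agonist-stimulated PBMC cultures, built
so that every stage — from raw multi-channel field images to per-donor
statistics — can be exercised end to end on synthetic plates with known
ground truth.

## Who this is for and what it does

Immunology groups running image-based stimulation screens face a common
pipeline: 384-well plates of PBMCs treated with TLR4/7/8/9 agonists (DMSO as
vehicle control), imaged in five fluorescence channels (Hoechst nuclei,
phalloidin actin, concanavalin A membrane/ER, MitoTracker mitochondria,
annexin V apoptosis), with matched culture supernatants profiled on a
51-analyte cytokine panel. `phenoscreen` implements the analysis side of
that experiment as a tested, reusable library:

1. **Synthetic data generator** — plate layouts, per-cell phenotype ground
   truth, rendered five-channel fields and cytokine tables with injected,
   configurable condition effects, so the whole pipeline is benchmarkable
   without any raw data.
2. **Segmentation** — classical nuclei detection (Gaussian smooth, Otsu,
   distance-transform watershed with h-maxima seeds, area filter),
   single-linkage grouping of fragmented-nucleus lobes into cells, and
   cell-centered multi-channel crops.
3. **Featurization** — a 128-long morphological embedding per cell, built
   from interpretable descriptor blocks (nuclear shape, intensity
   statistics, actin radial/angular organization, peripheral puncta,
   membrane footprint, texture).
4. **Basis scoring + assay QC** — each cell or well decomposes against the
   control axis c⁻ → c⁺ into an *on-basis* projection and an *off-basis*
   orthogonal residual (‖x − c⁻‖² = on² + off²), and assay quality is the
   strictly standardized mean difference
   β = (μ₊ − μ₋)/√(σ₊² + σ₋²) of on-basis scores between control groups.
5. **Phenotype sorting** — per-family supervised classifiers (size class,
   annexin V, nuclear fragmentation, actin state, podosomes, phagocytosis):
   80/20 split, balanced-class-weight kNN baseline, boosted-tree final
   model applied to the whole dataset.
6. **Quantification** — per-well phenotype fractions with the paired-feature
   normalization scheme (e.g. contracted/(contracted + dispersed),
   podosome/(podosome + no-podosome)), DMSO-relative deltas and folds per
   (plate, donor, timepoint) stratum, and slope + Spearman association
   analyses between feature shifts.
7. **Cytokine analysis** — fold change over DMSO per (plate, donor,
   analyte), per-donor averaging, and Mann-Whitney cohort comparisons
   (e.g. healthy volunteers vs people living with HIV).
8. **Self-contained statistics** — Mann-Whitney U (exact by enumeration for
   small samples, tie- and continuity-corrected normal approximation
   otherwise) and Spearman rank correlation (exact permutation p for small
   n, t-approximation above).

## Worked example

```python
import numpy as np
from phenoscreen import basis, make_layout, count_images, mann_whitney

# acquisition arithmetic for a full campaign
layout = make_layout(24, 384, 9, ["DMSO", "TLR8"], [6, 24, 48],
                     [f"D{i:02d}" for i in range(24)])
print(count_images(layout))            # 414720 single-channel images

# assay quality from control populations
rng = np.random.default_rng(0)
neg = rng.normal(0.0, 1.0, 2000)       # on-basis scores, negative controls
pos = rng.normal(3.79, 1.0, 2000)      # positive controls
print(round(basis.ssmd(neg, pos).beta, 2))   # 2.7 (exact parameters: 2.68)

# two cohorts of per-donor fold changes
print(round(mann_whitney([1.2, 1.8, 2.4], [4.1, 5.0, 6.2]).pvalue, 3))  # 0.1
```

The layout call enumerates the full acquisition (24 plates x 384 wells x 9
fields x 5 channels = 414,720 images). The SSMD of 2.7 from 2,000 sampled
control scores sits next to the 2.68 implied by the exact population
parameters — a separation conventionally read as a good-to-excellent
phenotypic assay. The Mann-Whitney p of 0.1 is the exact two-sided
enumeration value for two fully separated groups of three.

A complete staged run (images, detections, embeddings, QC, labels, well
summaries, cytokine folds, manifest) from one config:

```bash
phenoscreen run --config examples/small.yaml --seed 0 --out run_artifacts
```

(any omitted config block falls back to defaults; see
`phenoscreen show-config`).

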