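"""Fixed-length morphological embeddings from cell crops.

Each crop is reduced to a 128-long descriptor vector built from named,
interpretable blocks: nuclear morphology, per-channel intensity statistics,
actin radial/angular organization, peripheral puncta (podosome proxy),
membrane footprint (size-class proxy), an annexin membrane-ring readout, a
phagocytic-cup readout, and per-channel gradient-energy texture. Indices not
used by any block are zero. All radial/angular descriptors are computed
around the nuclear intensity centroid, which makes them robust to small
placement shifts of the cell within the crop.

The embedding is deterministic: identical crop, identical vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, morphology
from skimage.feature import peak_local_max
from skimage.measure import label as sk_label, regionprops

from .segmentation import CellCrop

EMBEDDING_LENGTH = 128


class FeaturizationError(ValueError):
    """Raised when a crop lacks a channel required for featurization."""


#: descriptor blocks: name -> list of descriptor names (order defines indices)
_BLOCKS: dict[str, list[str]] = {
    "nuclear": ["area_um2", "equiv_diam_um", "eccentricity", "solidity",
                "lobe_count", "log_total_intensity"],
    "intensity": [f"{ch}_{stat}"
                  for ch in ("nucleus", "actin", "membrane", "mito", "annexin")
                  for stat in ("mean", "sd", "q10", "q50", "q90", "max")],
    "actin_radial": ["center_periphery_ratio", "mid_ring_ratio",
                     "polarization", "top_octant_share", "mean_radius_norm",
                     "log_disk_total", "log_ring_total", "log_disk_max"],
    "puncta": ["peripheral_puncta_count", "puncta_amplitude"],
    "footprint": ["area_um2", "equiv_diam_um", "center_dip"],
    "annexin_ring": ["ring_mean", "ring_center_ratio"],
    "phago": ["cup_score", "hole_score"],
    "texture": [f"{ch}_gradient_energy"
                for ch in ("nucleus", "actin", "membrane", "mito", "annexin")],
}


def block_map() -> dict[str, tuple[int, int]]:
    """Index ranges (start, stop) of each descriptor block in the embedding."""
    out, start = {}, 0
    for name, names in _BLOCKS.items():
        out[name] = (start, start + len(names))
        start += len(names)
    return out


def feature_names() -> list[str]:
    """Full descriptor name per embedding index (zero-pad entries included)."""
    names = [f"{blk}:{n}" for blk, lst in _BLOCKS.items() for n in lst]
    names += [f"pad:{i}" for i in range(EMBEDDING_LENGTH - len(names))]
    return names


@dataclass
class Embedding:
    """One cell's descriptor vector plus provenance."""

    vector: np.ndarray                      # shape (EMBEDDING_LENGTH,)
    cell_id: int = -1
    imputed: bool = False                   # any non-finite value replaced by 0

    @property
    def blocks(self) -> dict[str, tuple[int, int]]:
        return block_map()


def _required_channels(crop: CellCrop) -> dict[str, np.ndarray]:
    planes = {}
    for role in ("nucleus", "actin", "membrane", "mito", "annexin"):
        if role not in crop.channel_roles:
            raise FeaturizationError(f"crop is missing required channel {role!r}")
        planes[role] = np.asarray(crop.data[crop.channel_roles.index(role)],
                                  dtype=np.float64)
    return planes


def _foreground(plane: np.ndarray) -> np.ndarray:
    """Otsu foreground mask; empty mask for a flat plane."""
    if plane.max() - plane.min() < 1e-9:
        return np.zeros(plane.shape, dtype=bool)
    return plane > filters.threshold_otsu(plane)


def _central_region(mask: np.ndarray, center: tuple[float, float] | None = None):
    """The single foreground component closest to ``center`` (crop center by
    default), so neighboring cells in the crop are excluded."""
    lab = sk_label(mask, connectivity=1)
    if lab.max() == 0:
        return None
    h, w = mask.shape
    cy, cx = center if center is not None else ((h - 1) / 2.0, (w - 1) / 2.0)
    fg = np.argwhere(mask)
    d = np.hypot(fg[:, 0] - cy, fg[:, 1] - cx)
    keep = lab[tuple(fg[np.argmin(d)])]
    return lab == keep


def _components_near(mask: np.ndarray, center: tuple[float, float],
                     radius: float):
    """All foreground components whose centroid lies within ``radius`` of
    ``center`` (keeps every lobe of a fragmented nucleus, drops neighbors)."""
    lab = sk_label(mask, connectivity=1)
    if lab.max() == 0:
        return None
    keep = []
    for p in regionprops(lab):
        if np.hypot(p.centroid[0] - center[0], p.centroid[1] - center[1]) <= radius:
            keep.append(p.label)
    if not keep:
        return _central_region(mask, center)
    return np.isin(lab, keep)


def embed(crop: CellCrop, length: int = EMBEDDING_LENGTH) -> Embedding:
    """Compute the descriptor embedding of one cell crop."""
    planes = _required_channels(crop)
    px = crop.pixel_size_um
    h, w = planes["nucleus"].shape
    values: list[float] = []

    nuc = planes["nucleus"]
    act = planes["actin"]
    mem = planes["membrane"]
    anx = planes["annexin"]

    # per-channel background estimate: 20th percentile (fields are mostly empty)
    bg = {k: np.percentile(v, 20) for k, v in planes.items()}
    nuc_fg = np.clip(nuc - bg["nucleus"], 0, None)
    act_fg = np.clip(act - bg["actin"], 0, None)
    mem_fg = np.clip(mem - bg["membrane"], 0, None)
    anx_fg = np.clip(anx - bg["annexin"], 0, None)

    # --- reference center: intensity centroid of the central nucleus ----
    # (restricted to lobes near the crop center so neighboring cells in the
    # crop cannot drag the reference frame)
    geo_center = ((h - 1) / 2.0, (w - 1) / 2.0)
    central_nuc = _components_near(_foreground(nuc), geo_center, 8.0 / px)
    if central_nuc is not None and (nuc_fg * central_nuc).sum() > 0:
        cy, cx = ndi.center_of_mass(nuc_fg * central_nuc)
    else:
        cy, cx = geo_center
    total_nuc = (nuc_fg * central_nuc).sum() if central_nuc is not None \
        else nuc_fg.sum()
    yy, xx = np.mgrid[0:h, 0:w]
    rr = np.hypot(yy - cy, xx - cx)
    theta = np.arctan2(yy - cy, xx - cx)

    # cell radius estimate from the membrane footprint around the center,
    # cross-checked against nuclear size and clipped to the crop
    mem_mask = _central_region(_foreground(mem), (cy, cx))
    if mem_mask is not None and mem_mask.sum() >= 9:
        cell_r = float(np.sqrt(mem_mask.sum() / np.pi))
    else:
        cell_r = max(4.0, 0.25 * min(h, w))
    if total_nuc > 0 and central_nuc is not None:
        nuc_loc = nuc_fg * central_nuc
        nuc_r_est = float(np.sqrt((nuc_loc > 0.5 * nuc_loc.max()).sum() / np.pi))
        cell_r = max(cell_r, 1.05 * nuc_r_est)
    cell_r = min(cell_r, 0.45 * min(h, w))

    # --- nuclear morphology ---------------------------------------------
    # keep every lobe within ~8 um of the nuclear centroid (fragmented
    # nuclei), excluding neighbors further out
    nuc_mask = _components_near(_foreground(nuc), (cy, cx), 8.0 / px)
    if nuc_mask is not None and nuc_mask.sum() >= 9:
        props = regionprops(nuc_mask.astype(np.int32))[0]
        area_um2 = props.area * px * px
        equiv_um = props.equivalent_diameter_area * px
        ecc = props.eccentricity
        sol = props.solidity
        lobes = sk_label(nuc_mask, connectivity=1).max()
    else:
        area_um2 = equiv_um = ecc = sol = lobes = 0.0
    values += [area_um2, equiv_um, ecc, sol, float(lobes),
               float(np.log1p(total_nuc))]

    # --- per-channel intensity statistics --------------------------------
    for role in ("nucleus", "actin", "membrane", "mito", "annexin"):
        v = planes[role].ravel()
        values += [float(v.mean()), float(v.std()),
                   float(np.percentile(v, 10)), float(np.percentile(v, 50)),
                   float(np.percentile(v, 90)), float(v.max())]

    # --- actin radial / angular organization -----------------------------
    inner = rr <= 0.45 * cell_r
    mid = (rr > 0.30 * cell_r) & (rr <= 0.55 * cell_r)
    outer = (rr > 0.55 * cell_r) & (rr <= 1.10 * cell_r)
    disk = rr <= 1.10 * cell_r

    def _mean(m, img):
        return float(img[m].mean()) if m.any() else 0.0

    center_mean = _mean(inner, act_fg)
    outer_mean = _mean(outer, act_fg)
    mid_mean = _mean(mid, act_fg)
    cp_ratio = center_mean / (center_mean + outer_mean + 1e-9)
    mid_ratio = mid_mean / (mid_mean + center_mean + outer_mean + 1e-9)

    # angular organization over the cell-local ring, weighted by squared
    # (smoothed) intensity so bright structure dominates read noise
    act_sm = ndi.gaussian_filter(act_fg, 0.8)
    ring_mask_a = (rr > 0.40 * cell_r) & (rr <= 1.10 * cell_r)
    ring_w = (act_sm * ring_mask_a) ** 2
    tot = ring_w.sum()
    if tot > 1e-9:
        pol = float(np.hypot((ring_w * np.cos(theta)).sum(),
                             (ring_w * np.sin(theta)).sum()) / tot)
        bins = ((theta[ring_mask_a] + np.pi) / (2 * np.pi) * 8).astype(int) % 8
        hist = np.bincount(bins, weights=ring_w[ring_mask_a], minlength=8)
        octant = float(hist.max() / tot)
    else:
        pol, octant = 0.0, 0.0
    disk_int = act_fg * disk
    mean_r = float((disk_int * rr).sum() / (disk_int.sum() + 1e-9) / cell_r)
    values += [cp_ratio, mid_ratio, pol, octant, mean_r,
               float(np.log1p(disk_int.sum())),
               float(np.log1p((act_fg * ring_mask_a).sum())),
               float(np.log1p((act_sm * disk).max() if disk.any() else 0.0))]

    # --- peripheral puncta (podosome proxy) ------------------------------
    tophat = morphology.white_tophat(act_fg, morphology.disk(2))
    peri = (rr > 0.5 * cell_r) & (rr <= 1.1 * cell_r)
    th_max = tophat.max()
    if th_max > 1e-6:
        peaks = peak_local_max(tophat, min_distance=3,
                               threshold_abs=0.35 * th_max)
        if len(peaks):
            on_peri = peri[peaks[:, 0], peaks[:, 1]]
            n_puncta = int(on_peri.sum())
            amp = float(tophat[peaks[on_peri, 0], peaks[on_peri, 1]].mean()) \
                if n_puncta else 0.0
        else:
            n_puncta, amp = 0, 0.0
    else:
        n_puncta, amp = 0, 0.0
    values += [float(n_puncta), amp]

    # --- membrane footprint (size-class proxy) ----------------------------
    if mem_mask is not None and mem_mask.sum() >= 9:
        fp_area = mem_mask.sum() * px * px
        fp_equiv = 2.0 * np.sqrt(mem_mask.sum() / np.pi) * px
    else:
        fp_area = fp_equiv = 0.0
    center_mem = _mean(inner, mem_fg)
    mid_mem = _mean(mid | outer, mem_fg)
    center_dip = 1.0 - center_mem / (mid_mem + 1e-9) if mid_mem > 1e-9 else 0.0
    values += [float(fp_area), float(fp_equiv), float(center_dip)]

    # --- annexin membrane ring --------------------------------------------
    ring = (rr > 0.8 * cell_r) & (rr <= 1.15 * cell_r)
    ring_mean = _mean(ring, anx_fg)
    ring_center = _mean(inner, anx_fg)
    values += [ring_mean, ring_mean / (ring_mean + ring_center + 1e-9)]

    # --- phagocytic cup ----------------------------------------------------
    # bright actin ring fragments inside the cell + membrane hole
    cup = _mean(mid, act_fg) / (_mean(disk, act_fg) + 1e-9)
    hole = center_dip * (fp_equiv > 0)
    values += [float(cup), float(hole)]

    # --- texture: gradient energy per channel ------------------------------
    for role in ("nucleus", "actin", "membrane", "mito", "annexin"):
        gy, gx = np.gradient(planes[role])
        values.append(float(np.log1p(np.mean(gy * gy + gx * gx))))

    vec = np.zeros(length, dtype=np.float64)
    arr = np.asarray(values, dtype=np.float64)
    bad = ~np.isfinite(arr)
    if bad.any():
        arr[bad] = 0.0
    vec[:arr.size] = arr
    return Embedding(vector=vec, cell_id=crop.cell_id, imputed=bool(bad.any()))


def embed_all(crops, length: int = EMBEDDING_LENGTH) -> np.ndarray:
    """Stack embeddings for many crops into an (n, length) matrix."""
    if not crops:
        return np.zeros((0, length))
    return np.vstack([embed(c, length).vector for c in crops])


# ---------------------------------------------------------------------------
# Standardization against a reference population
# ---------------------------------------------------------------------------


@dataclass
class EmbeddingStandardizer:
    """Per-dimension center/scale learned from a reference population.

    Dimensions with zero variance in the reference are flagged and passed
    through unscaled (scale 1), so constant descriptors and zero padding
    survive the round trip unchanged.
    """

    center: np.ndarray
    scale: np.ndarray
    constant_mask: np.ndarray           # True where reference variance was 0

    def apply(self, embeddings: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(embeddings, dtype=np.float64))
        return (x - self.center) / self.scale

    def invert(self, standardized: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(standardized, dtype=np.float64))
        return x * self.scale + self.center


def fit_standardizer(embeddings: np.ndarray,
                     reference_mask: np.ndarray | None = None,
                     min_reference: int = 10) -> EmbeddingStandardizer:
    """Learn per-dimension mean/SD from a reference subpopulation.

    ``reference_mask`` selects the reference rows (e.g. all DMSO cells);
    by default every row is reference. Requires >= ``min_reference`` rows.
    """
    x = np.asarray(embeddings, dtype=np.float64)
    if reference_mask is not None:
        x = x[np.asarray(reference_mask, dtype=bool)]
    if x.shape[0] < min_reference:
        raise ValueError(
            f"reference population has {x.shape[0]} cells; need >= {min_reference}")
    center = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    constant = sd <= 1e-12
    scale = np.where(constant, 1.0, sd)
    center = np.where(constant, 0.0, center)
    return EmbeddingStandardizer(center=center, scale=scale, constant_mask=constant)
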