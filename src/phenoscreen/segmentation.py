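"""Nuclei detection, fragment grouping, and cell-centered cropping.

Classical, fully deterministic segmentation of the nuclear channel:
Gaussian smoothing, Otsu thresholding, hole filling, distance-transform
watershed with h-maxima seeds, and an area filter. Nuclear components whose
centroids fall within a grouping radius are merged (single linkage) into one
cell seed so that fragmented-nucleus lobes count as a single cell. Crops are
centered on seed centroids across all channels, zero-padded at field borders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from skimage import filters, morphology, segmentation as sk_seg
from skimage.measure import regionprops

from .synthetic import FieldImage


class ShapeError(ValueError):
    """Raised when an image does not have the expected dimensionality."""


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables for nuclear segmentation (defaults sized for 0.5 um/px)."""

    smoothing_sigma: float = 2.0        # px, Gaussian pre-smoothing
    h_maxima: float = 2.0               # px, depth criterion for watershed seeds
    min_area: int = 50                  # px^2, discard smaller components
    max_area: int = 5000                # px^2, discard larger components
    threshold: str = "otsu"             # only method currently implemented
    min_contrast: float = 20.0          # required foreground-background gap


@dataclass
class CellSeed:
    """One detected cell: merged nuclear components sharing a neighborhood."""

    cell_id: int
    centroid: tuple[float, float]       # (row, col), area-weighted over members
    member_labels: tuple[int, ...]
    fragmented_hint: bool = False       # >= 2 nuclear components merged


@dataclass
class CellCrop:
    """Cell-centered multi-channel crop with border-padding bookkeeping."""

    cell_id: int
    data: np.ndarray                    # (n_channels, side, side)
    channel_roles: tuple[str, ...]
    pixel_size_um: float
    center: tuple[float, float]
    padded: bool = False
    pad_widths: tuple[int, int, int, int] = (0, 0, 0, 0)  # top, bottom, left, right


def segment_nuclei(nuclear_channel: np.ndarray,
                   params: SegmentationParams | None = None) -> np.ndarray:
    """Label nuclei in a single-channel image.

    Returns an int32 label map (0 = background, labels 1..N contiguous,
    4-connected components, relabeled in raster-scan order so output is
    order-stable). Touching nuclei are split by a distance-transform
    watershed seeded at h-maxima of the distance map. An all-background
    image yields an all-zero map, not an error.
    """
    params = params or SegmentationParams()
    img = np.asarray(nuclear_channel, dtype=np.float64)
    if img.ndim != 2:
        raise ShapeError(f"expected a 2-D image, got ndim={img.ndim}")

    smoothed = filters.gaussian(img, sigma=params.smoothing_sigma,
                                preserve_range=True)
    lo, hi = float(smoothed.min()), float(smoothed.max())
    if hi - lo < 1e-9:
        return np.zeros(img.shape, dtype=np.int32)
    thresh = filters.threshold_otsu(smoothed)
    mask = smoothed > thresh
    if not mask.any():
        return np.zeros(img.shape, dtype=np.int32)
    # reject threshold splits of pure noise/background
    if smoothed[mask].mean() - smoothed[~mask].mean() < params.min_contrast:
        return np.zeros(img.shape, dtype=np.int32)
    mask = ndi.binary_fill_holes(mask)

    distance = ndi.distance_transform_edt(mask)
    peaks = morphology.h_maxima(distance, params.h_maxima)
    markers, n_markers = ndi.label(peaks, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if n_markers == 0:
        labels, _ = ndi.label(mask, structure=np.array(
            [[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    else:
        labels = sk_seg.watershed(-distance, markers, mask=mask,
                                  connectivity=1)

    # area filter + raster-scan-stable relabeling
    out = np.zeros(img.shape, dtype=np.int32)
    flat = labels.ravel()
    order = {}
    counts = np.bincount(flat)
    next_id = 1
    for pos in np.flatnonzero(flat):
        lab = flat[pos]
        if lab in order or lab == 0:
            continue
        if params.min_area <= counts[lab] <= params.max_area:
            order[lab] = next_id
            next_id += 1
        else:
            order[lab] = 0
    if order:
        lut = np.zeros(counts.size, dtype=np.int32)
        for lab, new in order.items():
            lut[lab] = new
        out = lut[labels]
    return out


def group_fragments(labels: np.ndarray, grouping_radius_um: float = 8.0,
                    pixel_size_um: float = 0.5) -> list[CellSeed]:
    """Merge nuclear components within a radius into single cell seeds.

    Single-linkage: components are merged whenever any chain of pairwise
    centroid distances <= grouping_radius_um connects them. A seed built
    from >= 2 components carries ``fragmented_hint=True``. Seed centroids
    are area-weighted means of member centroids; seeds are ordered (and
    ids assigned) by centroid raster order for stability.
    """
    if grouping_radius_um <= 0:
        raise ValueError("grouping_radius_um must be > 0")
    props = regionprops(labels)
    if not props:
        return []
    cents = np.array([p.centroid for p in props])
    areas = np.array([p.area for p in props], dtype=float)
    labs = np.array([p.label for p in props])

    radius_px = grouping_radius_um / pixel_size_um
    tree = cKDTree(cents)
    pairs = tree.query_pairs(radius_px, output_type="ndarray")
    n = len(props)
    if len(pairs):
        adj = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                         shape=(n, n))
        n_comp, assignment = connected_components(adj, directed=False)
    else:
        n_comp, assignment = n, np.arange(n)

    seeds = []
    for comp in range(n_comp):
        members = np.flatnonzero(assignment == comp)
        w = areas[members]
        centroid = tuple((cents[members] * w[:, None]).sum(axis=0) / w.sum())
        seeds.append(CellSeed(
            cell_id=-1,
            centroid=(float(centroid[0]), float(centroid[1])),
            member_labels=tuple(int(v) for v in sorted(labs[members])),
            fragmented_hint=len(members) >= 2,
        ))
    seeds.sort(key=lambda s: s.centroid)
    for i, s in enumerate(seeds):
        s.cell_id = i
    return seeds


def crop_cells(field: FieldImage, seeds: list[CellSeed],
               side_px: int = 64) -> list[CellCrop]:
    """Cut one ``side_px`` x ``side_px`` crop per seed across all channels.

    Crops centered on the seed centroid (rounded to the nearest pixel);
    out-of-field area is zero-padded and flagged.
    """
    if side_px < 16 or side_px % 2:
        raise ValueError("side_px must be even and >= 16")
    n_ch, h, w = field.data.shape
    half = side_px // 2
    crops = []
    for seed in seeds:
        cy = int(round(seed.centroid[0]))
        cx = int(round(seed.centroid[1]))
        r0, r1 = cy - half, cy + half
        c0, c1 = cx - half, cx + half
        pad_t, pad_b = max(0, -r0), max(0, r1 - h)
        pad_l, pad_r = max(0, -c0), max(0, c1 - w)
        sub = field.data[:, max(r0, 0):min(r1, h), max(c0, 0):min(c1, w)]
        if any((pad_t, pad_b, pad_l, pad_r)):
            sub = np.pad(sub, ((0, 0), (pad_t, pad_b), (pad_l, pad_r)))
        crops.append(CellCrop(
            cell_id=seed.cell_id, data=np.ascontiguousarray(sub),
            channel_roles=field.channel_roles,
            pixel_size_um=field.pixel_size_um,
            center=seed.centroid,
            padded=any((pad_t, pad_b, pad_l, pad_r)),
            pad_widths=(pad_t, pad_b, pad_l, pad_r)))
    return crops


def write_label_map(labels: np.ndarray, path) -> None:
    """Write a label map as a 16-bit single-page TIFF."""
    import tifffile

    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels; cannot write 16-bit TIFF")
    tifffile.imwrite(str(path), labels.astype(np.uint16))


def detect_cells(field: FieldImage, params: SegmentationParams | None = None,
                 grouping_radius_um: float = 8.0,
                 side_px: int = 64) -> tuple[list[CellSeed], list[CellCrop]]:
    """Full detection for one field: segment, group fragments, crop."""
    labels = segment_nuclei(field.channel("nucleus"), params)
    seeds = group_fragments(labels, grouping_radius_um, field.pixel_size_um)
    return seeds, crop_cells(field, seeds, side_px)


def match_seeds(seeds: list[CellSeed], truth_cells: pd.DataFrame,
                max_dist_px: float | None = None) -> pd.DataFrame:
    """Greedy nearest match of detected seeds to ground-truth centroids.

    A truth cell matches the closest unmatched seed within its own radius
    (or ``max_dist_px`` if given). Returns a DataFrame with columns
    seed_cell_id, truth_index, distance_px; unmatched items are absent.
    """
    placed = truth_cells.dropna(subset=["centroid_row", "centroid_col"])
    if not seeds or placed.empty:
        return pd.DataFrame(columns=["seed_cell_id", "truth_index", "distance_px"])
    seed_xy = np.array([s.centroid for s in seeds])
    truth_xy = placed[["centroid_row", "centroid_col"]].to_numpy()
    d = np.hypot(truth_xy[:, None, 0] - seed_xy[None, :, 0],
                 truth_xy[:, None, 1] - seed_xy[None, :, 1])
    limits = (np.full(len(placed), max_dist_px) if max_dist_px is not None
              else placed["radius_px"].to_numpy())
    rows = []
    used_seeds: set[int] = set()
    # match in order of increasing distance (greedy, deterministic)
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    used_truth: set[int] = set()
    for ti, si in order:
        if ti in used_truth or si in used_seeds:
            continue
        if d[ti, si] <= limits[ti]:
            rows.append((seeds[si].cell_id, placed.index[ti], float(d[ti, si])))
            used_truth.add(ti)
            used_seeds.add(si)
    return pd.DataFrame(rows, columns=["seed_cell_id", "truth_index", "distance_px"])
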