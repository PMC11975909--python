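"""Synthetic high-content screening data with known ground truth.

Emulates the imaging arm of a TLR-agonist PBMC stimulation experiment:
384-well plate layouts with DMSO vehicle controls, five-channel fluorescence
fields (nucleus / actin / membrane-ER / mitochondria / annexin V), a
two-component cell size mixture (small round lymphocyte-like cells, 6-15 um;
large round myeloid-like cells, ~20 um) with per-cell Bernoulli phenotype
flags (annexin V positivity, nuclear fragmentation, actin contracted vs
dispersed, podosomes, phagocytosis), multiplicative condition x timepoint
effects, log-normal donor random effects, and a 51-analyte secreted-protein
panel with injected fold effects.

Every draw is controlled by explicit seeds; identical (config, seed) gives
byte-identical layouts, truths and images.
"""

from __future__ import annotations

import dataclasses
import json
import string
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Channel vocabulary
# ---------------------------------------------------------------------------

#: Fixed channel order used throughout: Hoechst-like nuclear stain,
#: phalloidin-like actin stain, concanavalin-A-like membrane/ER stain,
#: MitoTracker-like mitochondrial stain, annexin-V apoptosis marker.
CHANNELS: tuple[str, ...] = ("nucleus", "actin", "membrane", "mito", "annexin")

N_CHANNELS = len(CHANNELS)

#: Phenotype flag columns carried on every ground-truth cell table.
PHENOTYPE_FLAGS: tuple[str, ...] = (
    "annexin_pos",
    "fragmented_nucleus",
    "actin_contracted",
    "actin_dispersed",
    "podosome_pos",
    "phagocytosis",
)

#: Default 51-analyte secreted-protein panel (cytokines, chemokines,
#: growth factors and soluble receptors typical of a PBMC multiplex assay).
DEFAULT_PANEL: tuple[str, ...] = (
    "CCL1", "CCL2", "CCL3", "CCL4", "CCL5", "CCL7", "CCL11", "CCL17",
    "CCL19", "CCL20", "CCL22", "CXCL1", "CXCL5", "CXCL8", "CXCL9",
    "CXCL10", "CXCL11", "CXCL12", "CXCL13", "IL-1a", "IL-1b", "IL-1Ra",
    "IL-2", "IL-4", "IL-5", "IL-6", "IL-6Ra", "IL-7", "IL-10", "IL-12p70",
    "IL-13", "IL-15", "IL-17A", "IL-18", "IL-21", "IL-23", "IL-27",
    "IL-33", "TNF-a", "IFN-a2a", "IFN-g", "GM-CSF", "G-CSF", "M-CSF",
    "VEGF-A", "EGF", "FGF-2", "PDGF-BB", "TRAIL", "MMP-1", "OPN",
)

DMSO = "DMSO"


class ConfigurationError(ValueError):
    """Raised when a layout or effect configuration is internally inconsistent."""


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed in a field without overlap."""


def _stable_seed(*parts) -> int:
    """Deterministic 31-bit child seed from a base seed plus string/int parts."""
    text = "|".join(str(p) for p in parts)
    return zlib.crc32(text.encode()) & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# Plate layouts
# ---------------------------------------------------------------------------

LAYOUT_COLUMNS = [
    "plate_id", "well_id", "field_index", "condition", "concentration",
    "concentration_unit", "timepoint_h", "donor_id", "cohort",
]


def well_name(index: int, plate_cols: int = 24) -> str:
    """384-well style well id (A01..P24) for a 0-based well index."""
    row, col = divmod(index, plate_cols)
    return f"{string.ascii_uppercase[row]}{col + 1:02d}"


def make_layout(
    n_plates: int,
    wells_per_plate: int,
    fields_per_well: int,
    conditions: list[str],
    timepoints: list[float],
    donors: list[str],
    cohorts: dict[str, str] | None = None,
    concentration: float = 1.0,
    concentration_unit: str = "uM",
) -> pd.DataFrame:
    """Enumerate a full plate/well/field layout as a tidy DataFrame.

    One donor is assigned per plate (cycling through ``donors``); wells cycle
    through the cartesian product of conditions and timepoints so that every
    (plate, donor) stratum contains DMSO control wells.

    Raises :class:`ConfigurationError` if DMSO is missing from ``conditions``
    or any count is < 1.
    """
    if min(n_plates, wells_per_plate, fields_per_well) < 1:
        raise ConfigurationError("all layout counts must be >= 1")
    if DMSO not in conditions:
        raise ConfigurationError("conditions must include the DMSO vehicle control")
    if not timepoints or not donors:
        raise ConfigurationError("timepoints and donors must be non-empty")
    if wells_per_plate > 384:
        raise ConfigurationError("wells_per_plate cannot exceed 384")

    combos = [(c, t) for c in conditions for t in timepoints]
    rows = []
    for p in range(n_plates):
        plate_id = f"P{p + 1:02d}"
        donor = str(donors[p % len(donors)])
        cohort = (cohorts or {}).get(donor, "HV")
        for w in range(wells_per_plate):
            cond, tp = combos[w % len(combos)]
            conc = 0.0 if cond == DMSO else concentration
            for f in range(fields_per_well):
                rows.append((plate_id, well_name(w), f, cond, conc,
                             concentration_unit, float(tp), donor, cohort))
    return pd.DataFrame(rows, columns=LAYOUT_COLUMNS)


def count_images(layout: pd.DataFrame, n_channels: int = N_CHANNELS) -> int:
    """Number of single-channel images the layout implies (fields x channels)."""
    n_fields = len(layout[["plate_id", "well_id", "field_index"]].drop_duplicates())
    return n_fields * n_channels


# ---------------------------------------------------------------------------
# Effects
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhenotypeBaseline:
    """Baseline (DMSO, population-average) phenotype prevalences.

    The study reports no baseline prevalences, so these are configuration
    values chosen to be plausible for PBMC cultures, not literature claims.
    """

    large_frac: float = 0.30            # mixture weight of large round cells
    annexin: float = 0.08               # P(annexin V+), any cell
    fragmented: float = 0.06            # P(fragmented nucleus), any cell
    actin_stained: float = 0.80         # P(actin stain visible | small round)
    contracted_given_stained: float = 0.25  # P(contracted | small, stained)
    podosome: float = 0.35              # P(podosome+ | large round)
    phagocytosis: float = 0.20          # P(phagocytic | large round)


@dataclass(frozen=True)
class ConditionEffect:
    """Multiplicative effects of one (condition, timepoint) on phenotype rates.

    ``contracted_fold`` multiplies P(contracted | actin-stained) directly, so
    an injected fold f appears as a fold f on the normalized actin-contracted
    fraction (contracted / (contracted + dispersed)) in expectation.
    """

    large_frac_fold: float = 1.0
    annexin_fold: float = 1.0
    fragmented_fold: float = 1.0
    contracted_fold: float = 1.0
    podosome_fold: float = 1.0
    phagocytosis_fold: float = 1.0


_NEUTRAL_EFFECT = ConditionEffect()

#: phenotypes that receive an independent donor-level random multiplier
_DONOR_AFFECTED = (
    "large_frac", "annexin", "fragmented", "contracted", "podosome", "phagocytosis",
)


@dataclass
class EffectSpec:
    """Full effect model: baselines, per-(condition, timepoint) folds, donor
    heterogeneity, and optional linear couplings between well-level deltas.

    Donor heterogeneity is a log-normal multiplicative random effect applied
    to baseline rates (shared across conditions within a donor, so it cancels
    in within-donor fold changes). ``coupling`` maps (x_feature, y_feature)
    pairs to a generating slope for slope-recovery experiments.
    """

    baseline: PhenotypeBaseline = field(default_factory=PhenotypeBaseline)
    effects: dict[tuple[str, float], ConditionEffect] = field(default_factory=dict)
    donor_sd: float = 0.15
    donor_seed: int = 0
    coupling: dict[tuple[str, str], float] = field(default_factory=dict)

    def effect_for(self, condition: str, timepoint_h: float) -> ConditionEffect:
        return self.effects.get((condition, float(timepoint_h)), _NEUTRAL_EFFECT)

    def donor_multipliers(self, donor_id: str) -> dict[str, float]:
        """Per-donor log-normal multipliers, deterministic in (donor, donor_seed)."""
        if self.donor_sd < 0:
            raise ConfigurationError("donor_sd must be >= 0")
        if self.donor_sd == 0:
            return {k: 1.0 for k in _DONOR_AFFECTED}
        rng = np.random.default_rng(_stable_seed(self.donor_seed, "donor", donor_id))
        draws = rng.normal(0.0, self.donor_sd, size=len(_DONOR_AFFECTED))
        return {k: float(np.exp(d)) for k, d in zip(_DONOR_AFFECTED, draws)}

    def to_dict(self) -> dict:
        return {
            "baseline": dataclasses.asdict(self.baseline),
            "effects": [
                {"condition": c, "timepoint_h": t, **dataclasses.asdict(e)}
                for (c, t), e in self.effects.items()
            ],
            "donor_sd": self.donor_sd,
            "donor_seed": self.donor_seed,
            "coupling": [
                {"x": x, "y": y, "slope": s} for (x, y), s in self.coupling.items()
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EffectSpec":
        baseline = PhenotypeBaseline(**d.get("baseline", {}))
        effects = {}
        for row in d.get("effects", []):
            row = dict(row)
            key = (row.pop("condition"), float(row.pop("timepoint_h")))
            effects[key] = ConditionEffect(**row)
        coupling = {(r["x"], r["y"]): float(r["slope"]) for r in d.get("coupling", [])}
        return cls(baseline=baseline, effects=effects,
                   donor_sd=float(d.get("donor_sd", 0.15)),
                   donor_seed=int(d.get("donor_seed", 0)), coupling=coupling)


def _clamp01(p: float, counter: list[int]) -> float:
    if p < 0.0 or p > 1.0:
        counter[0] += 1
        return min(1.0, max(0.0, p))
    return p


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = [
    "cell_id", "plate_id", "well_id", "field_index", "condition",
    "timepoint_h", "donor_id", "cohort", "size_class",
    *PHENOTYPE_FLAGS,
    "centroid_row", "centroid_col", "radius_px", "nucleus_r_px", "n_lobes",
]


@dataclass
class GroundTruth:
    """Per-cell ground truth for one well plus the effect spec and seed used.

    ``cells`` carries one row per cell with the well key, size class and
    phenotype flags; centroid/radius columns are filled in by
    :func:`render_field` when the well is rendered.
    """

    cells: pd.DataFrame
    effects: EffectSpec
    seed: int
    n_clamped: int = 0

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def realized_fractions(self) -> dict[str, float]:
        """Exact realized fractions (flag counts over their denominators).

        Size fractions are over all cells; annexin/fragmented over all cells;
        actin states over small round cells; podosome/phagocytosis over large
        round cells. Undefined denominators yield NaN.
        """
        c = self.cells
        n = len(c)
        if n == 0:
            keys = ["small_round", "large_round", *PHENOTYPE_FLAGS]
            return {k: float("nan") for k in keys}
        small = c["size_class"] == "small_round"
        large = ~small
        n_small, n_large = int(small.sum()), int(large.sum())

        def frac(num, den):
            return float(num) / den if den > 0 else float("nan")

        return {
            "small_round": frac(n_small, n),
            "large_round": frac(n_large, n),
            "annexin_pos": frac(c["annexin_pos"].sum(), n),
            "fragmented_nucleus": frac(c["fragmented_nucleus"].sum(), n),
            "actin_contracted": frac(c.loc[small, "actin_contracted"].sum(), n_small),
            "actin_dispersed": frac(c.loc[small, "actin_dispersed"].sum(), n_small),
            "podosome_pos": frac(c.loc[large, "podosome_pos"].sum(), n_large),
            "phagocytosis": frac(c.loc[large, "phagocytosis"].sum(), n_large),
        }


def simulate_well(
    layout_row,
    effects: EffectSpec,
    n_cells: int,
    seed: int,
    n_fields: int = 1,
) -> GroundTruth:
    """Draw per-cell phenotypes for one well from effect-adjusted probabilities.

    ``layout_row`` is one row of a layout table (anything with plate_id,
    well_id, condition, timepoint_h, donor_id, cohort attributes/keys). Cells
    are assigned round-robin to ``n_fields`` fields. Probabilities pushed
    outside [0, 1] by effects are clamped and counted on the returned truth.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    row = layout_row if hasattr(layout_row, "condition") else pd.Series(layout_row)
    eff = effects.effect_for(row.condition, row.timepoint_h)
    dm = effects.donor_multipliers(str(row.donor_id))
    base = effects.baseline
    clamped = [0]

    p_large = _clamp01(base.large_frac * dm["large_frac"] * eff.large_frac_fold, clamped)
    p_annexin = _clamp01(base.annexin * dm["annexin"] * eff.annexin_fold, clamped)
    p_frag = _clamp01(base.fragmented * dm["fragmented"] * eff.fragmented_fold, clamped)
    p_contr = _clamp01(
        base.contracted_given_stained * dm["contracted"] * eff.contracted_fold, clamped)
    p_pod = _clamp01(base.podosome * dm["podosome"] * eff.podosome_fold, clamped)
    p_phag = _clamp01(base.phagocytosis * dm["phagocytosis"] * eff.phagocytosis_fold,
                      clamped)

    rng = np.random.default_rng(seed)
    large = rng.random(n_cells) < p_large
    annexin = rng.random(n_cells) < p_annexin
    frag = rng.random(n_cells) < p_frag
    stained = (rng.random(n_cells) < base.actin_stained) & ~large
    contracted = stained & (rng.random(n_cells) < p_contr)
    dispersed = stained & ~contracted
    podosome = large & (rng.random(n_cells) < p_pod)
    phago = large & (rng.random(n_cells) < p_phag)
    n_lobes = np.where(frag, rng.integers(2, 5, size=n_cells), 1)

    cells = pd.DataFrame({
        "cell_id": [f"{row.plate_id}:{row.well_id}:{i}" for i in range(n_cells)],
        "plate_id": row.plate_id,
        "well_id": row.well_id,
        "field_index": np.arange(n_cells) % max(n_fields, 1),
        "condition": row.condition,
        "timepoint_h": float(row.timepoint_h),
        "donor_id": str(row.donor_id),
        "cohort": getattr(row, "cohort", "HV"),
        "size_class": np.where(large, "large_round", "small_round"),
        "annexin_pos": annexin,
        "fragmented_nucleus": frag,
        "actin_contracted": contracted,
        "actin_dispersed": dispersed,
        "podosome_pos": podosome,
        "phagocytosis": phago,
        "centroid_row": np.nan,
        "centroid_col": np.nan,
        "radius_px": np.nan,
        "nucleus_r_px": np.nan,
        "n_lobes": n_lobes,
    })
    if clamped[0]:
        warnings.warn(f"{clamped[0]} effect-adjusted probabilities clamped to [0,1]",
                      stacklevel=2)
    return GroundTruth(cells=cells, effects=effects, seed=seed, n_clamped=clamped[0])


# ---------------------------------------------------------------------------
# Field rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RenderParams:
    """Geometry, intensity and noise parameters for field rendering.

    Pixel coordinates are (row, col) integer indices with origin at the
    top-left; physical sizes derive from ``pixel_size_um``. The default
    512 px field keeps simulations desk-scale; 2048 px mirrors a full
    high-content acquisition and is just a configuration value.
    """

    pixel_size_um: float = 0.5
    field_px: int = 512
    small_cell_diam_um: tuple[float, float] = (6.0, 15.0)
    large_cell_diam_um: tuple[float, float] = (17.0, 23.0)
    channel_gains: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0)
    background_level: tuple[float, ...] = (40.0, 40.0, 40.0, 40.0, 40.0)
    noise_sd: tuple[float, ...] = (6.0, 6.0, 6.0, 6.0, 6.0)
    overlap_allowed: bool = False
    placement_margin_px: float = 10.0
    max_placement_tries: int = 2000

    def __post_init__(self):
        if self.field_px < 64:
            raise ConfigurationError("field_px must be >= 64")
        if min(self.small_cell_diam_um) <= 0 or min(self.large_cell_diam_um) <= 0:
            raise ConfigurationError("cell diameters must be > 0")
        if min(self.noise_sd) < 0:
            raise ConfigurationError("noise_sd must be >= 0")


@dataclass
class FieldImage:
    """One multi-channel fluorescence field (channels x rows x cols, float32)."""

    data: np.ndarray
    channel_roles: tuple[str, ...] = CHANNELS
    pixel_size_um: float = 0.5

    def channel(self, role: str) -> np.ndarray:
        return self.data[self.channel_roles.index(role)]

    def save(self, path) -> None:
        """Write a multi-page TIFF (one page per channel) + JSON sidecar."""
        import tifffile

        path = str(path)
        tifffile.imwrite(path, self.data.astype(np.float32))
        sidecar = {"channel_roles": list(self.channel_roles),
                   "pixel_size_um": self.pixel_size_um}
        with open(path + ".json", "w") as fh:
            json.dump(sidecar, fh)

    @classmethod
    def load(cls, path) -> "FieldImage":
        import tifffile

        path = str(path)
        data = np.asarray(tifffile.imread(path), dtype=np.float32)
        with open(path + ".json") as fh:
            sidecar = json.load(fh)
        return cls(data=data, channel_roles=tuple(sidecar["channel_roles"]),
                   pixel_size_um=float(sidecar["pixel_size_um"]))


def _soft_disk(shape, cy, cx, radius, edge=1.5):
    """Anti-aliased disk mask: 1 inside, linear ramp of width ``edge`` at rim."""
    h, w = shape
    r0 = max(int(cy - radius - edge - 1), 0)
    r1 = min(int(cy + radius + edge + 2), h)
    c0 = max(int(cx - radius - edge - 1), 0)
    c1 = min(int(cx + radius + edge + 2), w)
    if r0 >= r1 or c0 >= c1:
        return None, (0, 0, 0, 0)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    d = np.hypot(yy - cy, xx - cx)
    m = np.clip((radius + edge - d) / edge, 0.0, 1.0)
    return m, (r0, r1, c0, c1)


def _add(img, patch, box, amp):
    if patch is None:
        return
    r0, r1, c0, c1 = box
    img[r0:r1, c0:c1] += amp * patch


def _ring(shape, cy, cx, radius, width):
    """Soft annulus of mean radius ``radius`` and full width ``width``."""
    h, w = shape
    ext = radius + width + 2
    r0 = max(int(cy - ext), 0)
    r1 = min(int(cy + ext + 1), h)
    c0 = max(int(cx - ext), 0)
    c1 = min(int(cx + ext + 1), w)
    if r0 >= r1 or c0 >= c1:
        return None, (0, 0, 0, 0)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    d = np.hypot(yy - cy, xx - cx)
    m = np.clip(1.0 - np.abs(d - radius) / max(width, 1e-6), 0.0, 1.0)
    return m, (r0, r1, c0, c1)


def _gauss_blob(shape, cy, cx, sigma):
    h, w = shape
    ext = 3.5 * sigma + 1
    r0 = max(int(cy - ext), 0)
    r1 = min(int(cy + ext + 1), h)
    c0 = max(int(cx - ext), 0)
    c1 = min(int(cx + ext + 1), w)
    if r0 >= r1 or c0 >= c1:
        return None, (0, 0, 0, 0)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    return np.exp(-d2 / (2.0 * sigma ** 2)), (r0, r1, c0, c1)


# intensity amplitudes above background, per structure (arbitrary units)
_AMP = {
    "nucleus": 900.0,
    "actin_cap": 800.0,
    "actin_ring": 500.0,
    "actin_large": 300.0,
    "actin_faint": 30.0,
    "podosome": 700.0,
    "phago_cup": 600.0,
    "membrane": 350.0,
    "mito": 250.0,
    "annexin_ring": 700.0,
}


def render_field(
    truth: GroundTruth,
    field_index: int,
    params: RenderParams,
    seed: int,
) -> FieldImage:
    """Render one field of a simulated well and record placements in the truth.

    Cells of the requested field are placed by rejection sampling (no two
    cells closer than the sum of their radii plus ``placement_margin_px``
    unless ``overlap_allowed``), then painted channel by channel:

    * nucleus: soft disk (or 2-4 lobes within 0.35 cell radius if fragmented);
    * actin: polarized peripheral cap if contracted, uniform peripheral ring
      if dispersed, faint signal if unstained; large cells get cytoplasmic
      actin, peripheral podosome puncta, and a bright internal phagocytic cup;
    * membrane: cell footprint (with a vacuole hole for phagocytic cells);
    * mito: cytoplasmic annulus between nucleus and membrane;
    * annexin: bright membrane ring on annexin V+ cells only.

    Gaussian read noise and a constant background are added per channel.
    Centroids, radii and nuclear radii are written back into ``truth.cells``.
    """
    rng = np.random.default_rng(seed)
    h = w = params.field_px
    shape = (h, w)
    img = np.zeros((N_CHANNELS, h, w), dtype=np.float64)

    sel = truth.cells["field_index"] == field_index
    idx = truth.cells.index[sel]

    # --- geometry draws -------------------------------------------------
    radii = np.empty(len(idx))
    for j, i in enumerate(idx):
        if truth.cells.at[i, "size_class"] == "large_round":
            lo, hi = params.large_cell_diam_um
            d_um = rng.uniform(lo, hi)
        else:
            lo, hi = params.small_cell_diam_um
            d_um = rng.uniform(lo, hi)
        radii[j] = 0.5 * d_um / params.pixel_size_um

    # --- placement (largest first packs much denser) --------------------
    order = np.argsort(-radii, kind="stable")
    centers_arr = np.empty((len(idx), 2))
    placed_r: list[float] = []
    placed_c: list[tuple[float, float]] = []
    for j in order:
        r = radii[j]
        placed = False
        for _ in range(params.max_placement_tries):
            cy = rng.uniform(r + 2, h - r - 2)
            cx = rng.uniform(r + 2, w - r - 2)
            if params.overlap_allowed or all(
                np.hypot(cy - oy, cx - ox) >= r + ro + params.placement_margin_px
                for ro, (oy, ox) in zip(placed_r, placed_c)
            ):
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place {len(idx)} cells in a {h}x{w} field "
                "without overlap")
        placed_r.append(r)
        placed_c.append((cy, cx))
        centers_arr[j] = (cy, cx)
    centers = [tuple(c) for c in centers_arr]

    # --- painting -------------------------------------------------------
    nch = img[CHANNELS.index("nucleus")]
    ach = img[CHANNELS.index("actin")]
    mch = img[CHANNELS.index("membrane")]
    tch = img[CHANNELS.index("mito")]
    xch = img[CHANNELS.index("annexin")]

    for j, i in enumerate(idx):
        cell = truth.cells.loc[i]
        cy, cx = centers[j]
        r = radii[j]
        large = cell["size_class"] == "large_round"
        nr = (0.45 if large else 0.70) * r

        # nucleus (possibly fragmented into lobes within 0.35 r)
        if cell["fragmented_nucleus"]:
            k = int(cell["n_lobes"])
            lobe_r = nr * 0.55
            base_ang = rng.uniform(0, 2 * np.pi)
            for li in range(k):
                ang = base_ang + 2 * np.pi * li / k + rng.uniform(-0.2, 0.2)
                off = 0.35 * r * rng.uniform(0.6, 1.0)
                m, box = _soft_disk(shape, cy + off * np.sin(ang),
                                    cx + off * np.cos(ang), lobe_r)
                _add(nch, m, box, _AMP["nucleus"])
        else:
            m, box = _soft_disk(shape, cy, cx, nr)
            _add(nch, m, box, _AMP["nucleus"])

        # membrane footprint (+ vacuole hole for phagocytic cells)
        m, box = _soft_disk(shape, cy, cx, r)
        _add(mch, m, box, _AMP["membrane"])
        vac_ang = rng.uniform(0, 2 * np.pi)
        if large and cell["phagocytosis"]:
            vy = cy + 0.30 * r * np.sin(vac_ang)
            vx = cx + 0.30 * r * np.cos(vac_ang)
            m, box = _soft_disk(shape, vy, vx, 0.30 * r)
            _add(mch, m, box, -0.9 * _AMP["membrane"])

        # mitochondria: cytoplasmic annulus between nucleus and membrane
        m, box = _ring(shape, cy, cx, 0.5 * (nr + r), 0.5 * (r - nr) + 1.0)
        _add(tch, m, box, _AMP["mito"] * (1.2 if large else 0.6))

        # actin
        if large:
            m, box = _soft_disk(shape, cy, cx, 0.95 * r)
            _add(ach, m, box, _AMP["actin_large"])
            if cell["podosome_pos"]:
                n_p = rng.integers(6, 11)
                ang0 = rng.uniform(0, 2 * np.pi)
                for pi in range(n_p):
                    ang = ang0 + 2 * np.pi * pi / n_p + rng.uniform(-0.15, 0.15)
                    py = cy + 0.80 * r * np.sin(ang)
                    px = cx + 0.80 * r * np.cos(ang)
                    m, box = _gauss_blob(shape, py, px, 1.3)
                    _add(ach, m, box, _AMP["podosome"])
            if cell["phagocytosis"]:
                vy = cy + 0.30 * r * np.sin(vac_ang)
                vx = cx + 0.30 * r * np.cos(vac_ang)
                m, box = _ring(shape, vy, vx, 0.32 * r, 2.0)
                _add(ach, m, box, _AMP["phago_cup"])
        elif cell["actin_contracted"]:
            # cortical actin cap: polarized blob at the cell edge
            ang = rng.uniform(0, 2 * np.pi)
            by = cy + 0.62 * r * np.sin(ang)
            bx = cx + 0.62 * r * np.cos(ang)
            m, box = _gauss_blob(shape, by, bx, max(0.25 * r, 1.2))
            _add(ach, m, box, _AMP["actin_cap"])
        elif cell["actin_dispersed"]:
            m, box = _ring(shape, cy, cx, 0.80 * r, 0.18 * r + 1.0)
            _add(ach, m, box, _AMP["actin_ring"])
        else:
            m, box = _soft_disk(shape, cy, cx, 0.8 * r)
            _add(ach, m, box, _AMP["actin_faint"])

        # annexin V membrane ring
        if cell["annexin_pos"]:
            m, box = _ring(shape, cy, cx, r, 0.14 * r + 1.0)
            _add(xch, m, box, _AMP["annexin_ring"])

        truth.cells.at[i, "centroid_row"] = cy
        truth.cells.at[i, "centroid_col"] = cx
        truth.cells.at[i, "radius_px"] = r
        truth.cells.at[i, "nucleus_r_px"] = nr

    # --- gains, background, noise --------------------------------------
    for c in range(N_CHANNELS):
        img[c] *= params.channel_gains[c]
        img[c] += params.background_level[c]
        if params.noise_sd[c] > 0:
            img[c] += rng.normal(0.0, params.noise_sd[c], size=shape)
    np.maximum(img, 0.0, out=img)
    return FieldImage(data=img.astype(np.float32), channel_roles=CHANNELS,
                      pixel_size_um=params.pixel_size_um)


def render_well(truth: GroundTruth, params: RenderParams, seed: int,
                n_fields: int | None = None) -> list[FieldImage]:
    """Render every field of a well (seeds derived per field)."""
    if n_fields is None:
        n_fields = int(truth.cells["field_index"].max()) + 1 if len(truth.cells) else 1
    return [render_field(truth, f, params, _stable_seed(seed, "field", f))
            for f in range(n_fields)]


# ---------------------------------------------------------------------------
# Cytokine panel simulation
# ---------------------------------------------------------------------------


def simulate_cytokines(
    layout: pd.DataFrame,
    fold_effects: dict[tuple[str, float, str], float],
    panel: tuple[str, ...] = DEFAULT_PANEL,
    donor_sd: float = 0.3,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate an analyte x well concentration table with injected folds.

    Each analyte has a log-normal baseline concentration; each (donor,
    analyte) a log-normal donor multiplier (SD ``donor_sd`` on the log
    scale, shared across that donor's wells so it cancels in within-donor
    fold changes); each well a log-normal measurement error (``noise_sd``).
    Stimulated wells are multiplied by ``fold_effects[(condition,
    timepoint_h, analyte)]`` (default 1). Returns the long-format table and
    a truth dict with the baselines and injected folds.
    """
    for (cond, tp, analyte), fold in fold_effects.items():
        if analyte not in panel:
            raise ConfigurationError(f"analyte {analyte!r} not in panel")
        if fold <= 0:
            raise ConfigurationError("all fold effects must be > 0")
    if not (layout["condition"] == DMSO).any():
        raise ConfigurationError("layout has no DMSO control wells")

    wells = layout[["plate_id", "well_id", "condition", "timepoint_h",
                    "donor_id", "cohort"]].drop_duplicates()
    rng = np.random.default_rng(seed)
    baselines = {a: float(np.exp(rng.normal(np.log(50.0), 1.0))) for a in panel}

    rows = []
    for _, wrow in wells.iterrows():
        wrng = np.random.default_rng(
            _stable_seed(seed, "cyt", wrow.plate_id, wrow.well_id))
        for a in panel:
            donor_mult = 1.0
            if donor_sd > 0:
                drng = np.random.default_rng(
                    _stable_seed(seed, "cytdonor", wrow.donor_id, a))
                donor_mult = float(np.exp(drng.normal(0.0, donor_sd)))
            fold = fold_effects.get((wrow.condition, float(wrow.timepoint_h), a), 1.0)
            noise = float(np.exp(wrng.normal(0.0, noise_sd))) if noise_sd > 0 else 1.0
            conc = baselines[a] * donor_mult * fold * noise
            rows.append((wrow.plate_id, wrow.well_id, wrow.donor_id, wrow.cohort,
                         wrow.condition, float(wrow.timepoint_h), a, conc))
    table = pd.DataFrame(rows, columns=[
        "plate_id", "well_id", "donor_id", "cohort", "condition",
        "timepoint_h", "analyte", "concentration"])
    truth = {"baselines": baselines, "fold_effects": dict(fold_effects),
             "donor_sd": donor_sd, "noise_sd": noise_sd, "seed": seed}
    return table, truth


# ---------------------------------------------------------------------------
# Linear coupling (well-level delta pairs for slope recovery)
# ---------------------------------------------------------------------------


def simulate_coupled_deltas(
    slope: float,
    n_wells: int,
    noise_sd: float = 0.01,
    x_half_range: float = 1.0,
    seed: int = 0,
    x_feature: str = "delta_x",
    y_feature: str = "delta_y",
) -> pd.DataFrame:
    """Well-level (delta_x, delta_y) pairs with a known generating slope.

    delta_x is uniform over the admissible range of fraction deltas
    ([-x_half_range, +x_half_range], default the full [-1, 1]); spreading
    the probe design over the whole range maximizes the precision of the
    slope estimate, which must be recoverable by OLS within 10% at the
    default noise level and well count. delta_y = slope * delta_x plus
    Gaussian noise of SD ``noise_sd``.
    """
    rng = np.random.default_rng(seed)
    dx = rng.uniform(-x_half_range, x_half_range, size=n_wells)
    dy = slope * dx + rng.normal(0.0, noise_sd, size=n_wells)
    return pd.DataFrame({
        "well_index": np.arange(n_wells),
        x_feature: dx,
        y_feature: dy,
    })


def simulate_coupled_wells(effects: EffectSpec, n_wells: int,
                           noise_sd: float = 0.01, x_half_range: float = 1.0,
                           seed: int = 0) -> dict[tuple[str, str], pd.DataFrame]:
    """Apply every coupling in an EffectSpec; one delta table per pair."""
    out = {}
    for k, ((x, y), s) in enumerate(sorted(effects.coupling.items())):
        out[(x, y)] = simulate_coupled_deltas(
            s, n_wells, noise_sd=noise_sd, x_half_range=x_half_range,
            seed=_stable_seed(seed, "coupling", x, y), x_feature=x, y_feature=y)
    return out
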