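"""Well-level phenotype quantification, normalization, and DMSO-relative
effect and association analyses.

Per-cell phenotype labels are reduced to per-well counts and fractions.
Size-class fractions use classified round cells as the denominator; annexin
and fragmented-nucleus fractions use all detected cells; actin states use
small round cells; podosome and phagocytosis use large round cells. The
normalization scheme for the paired features is

    phagocytosis_norm    = P  / (P + LargeRoundNonPhagocytic)
    actin_contracted_norm = AC / (AC + AD)
    actin_dispersed_norm  = AD / (AC + AD)
    podosome_norm         = Pod / (Pod + NoPod)
    no_podosome_norm      = NoPod / (Pod + NoPod)

with zero denominators producing NaN (undefined), never an exception; the
complementary pairs sum to exactly 1 wherever defined. Effects are per-well
deltas and folds against the mean of the DMSO wells in the same (plate,
donor, timepoint) stratum, with donor-level medians reported; associations
between per-well deltas pair an ordinary-least-squares slope with Spearman's
rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as _stats

WELL_KEY = ["plate_id", "well_id", "donor_id", "cohort", "condition",
            "timepoint_h"]

#: fraction columns carried on a well summary
FRACTION_FEATURES = [
    "frac_small", "frac_large", "frac_annexin", "frac_fragmented",
    "frac_actin_contracted", "frac_actin_dispersed",
    "frac_podosome", "frac_phagocytosis",
]

NORMALIZED_FEATURES = [
    "phagocytosis_norm", "actin_contracted_norm", "actin_dispersed_norm",
    "podosome_norm", "no_podosome_norm",
]

_BIN_VOCAB = {
    "size_class": {"small_round", "large_round"},
    "annexin": {"annexin_pos", "annexin_neg"},
    "fragment": {"fragmented", "intact"},
    "actin": {"contracted", "dispersed", "unstained"},
    "podosome": {"podosome_pos", "podosome_neg"},
    "phago": {"phagocytosis", "large_round"},
}


class LabelVocabularyError(ValueError):
    """Raised when a per-cell label falls outside the known bin vocabulary."""


def labels_from_truth(cells: pd.DataFrame) -> pd.DataFrame:
    """Convert ground-truth flag columns into the per-cell label layout
    consumed by :func:`summarize_wells` (identity pipeline for tests)."""
    small = cells["size_class"] == "small_round"
    out = cells[WELL_KEY].copy() if set(WELL_KEY) <= set(cells.columns) \
        else pd.DataFrame(index=cells.index)
    out["size_class"] = cells["size_class"].astype(str)
    out["annexin"] = np.where(cells["annexin_pos"], "annexin_pos", "annexin_neg")
    out["fragment"] = np.where(cells["fragmented_nucleus"], "fragmented", "intact")
    actin = pd.Series(pd.NA, index=cells.index, dtype=object)
    actin[small] = "unstained"
    actin[small & cells["actin_contracted"]] = "contracted"
    actin[small & cells["actin_dispersed"]] = "dispersed"
    out["actin"] = actin
    pod = pd.Series(pd.NA, index=cells.index, dtype=object)
    pod[~small] = np.where(cells.loc[~small, "podosome_pos"],
                           "podosome_pos", "podosome_neg")
    out["podosome"] = pod
    ph = pd.Series(pd.NA, index=cells.index, dtype=object)
    ph[~small] = np.where(cells.loc[~small, "phagocytosis"],
                          "phagocytosis", "large_round")
    out["phago"] = ph
    return out


def _check_vocab(labels: pd.DataFrame) -> None:
    for col, vocab in _BIN_VOCAB.items():
        if col not in labels.columns:
            continue
        seen = set(labels[col].dropna().unique())
        bad = seen - vocab
        if bad:
            raise LabelVocabularyError(f"unknown {col} label(s): {sorted(bad)}")


def summarize_well(labels: pd.DataFrame) -> pd.Series:
    """Counts and raw fractions for one well's per-cell labels.

    An empty well yields n_cells = 0 with every fraction NaN (undefined).
    """
    _check_vocab(labels)
    n = len(labels)
    size = labels.get("size_class", pd.Series(dtype=object))
    n_small = int((size == "small_round").sum())
    n_large = int((size == "large_round").sum())
    n_round = n_small + n_large

    def _count(col, value):
        return int((labels[col] == value).sum()) if col in labels.columns else 0

    n_annexin = _count("annexin", "annexin_pos")
    n_frag = _count("fragment", "fragmented")
    n_ac = _count("actin", "contracted")
    n_ad = _count("actin", "dispersed")
    n_pod = _count("podosome", "podosome_pos")
    n_nopod = _count("podosome", "podosome_neg")
    n_ph = _count("phago", "phagocytosis")
    n_large_nonph = _count("phago", "large_round")

    def frac(num, den):
        return num / den if den > 0 else np.nan

    return pd.Series({
        "n_cells": n, "n_small": n_small, "n_large": n_large,
        "n_annexin": n_annexin, "n_fragmented": n_frag,
        "n_actin_contracted": n_ac, "n_actin_dispersed": n_ad,
        "n_podosome": n_pod, "n_no_podosome": n_nopod,
        "n_phagocytosis": n_ph, "n_large_nonphago": n_large_nonph,
        "frac_small": frac(n_small, n_round),
        "frac_large": frac(n_large, n_round),
        "frac_annexin": frac(n_annexin, n),
        "frac_fragmented": frac(n_frag, n),
        "frac_actin_contracted": frac(n_ac, n_small),
        "frac_actin_dispersed": frac(n_ad, n_small),
        "frac_podosome": frac(n_pod, n_pod + n_nopod),
        "frac_phagocytosis": frac(n_ph, n_ph + n_large_nonph),
    })


def summarize_wells(labels: pd.DataFrame,
                    by: list[str] | None = None) -> pd.DataFrame:
    """Per-well summaries for a table of per-cell labels with well keys."""
    by = by or [k for k in WELL_KEY if k in labels.columns]
    rows = []
    for key, grp in labels.groupby(by, sort=True):
        s = summarize_well(grp)
        for k, v in zip(by, key if isinstance(key, tuple) else (key,)):
            s[k] = v
        rows.append(s)
    if not rows:
        return pd.DataFrame()
    return pd.DataFrame(rows).reset_index(drop=True)


def normalize(summary: pd.DataFrame | pd.Series) -> pd.DataFrame | pd.Series:
    """Add the paired-feature normalized columns to a well summary.

    Zero denominators give NaN; the complement pairs sum to 1 where defined.
    """
    single = isinstance(summary, pd.Series)
    df = summary.to_frame().T.infer_objects() if single else summary.copy()

    def safe_div(num, den):
        num = df[num].astype(float)
        den_v = sum(df[d].astype(float) for d in den)
        return np.where(den_v > 0, num / den_v.replace(0, np.nan), np.nan)

    df["phagocytosis_norm"] = safe_div(
        "n_phagocytosis", ["n_phagocytosis", "n_large_nonphago"])
    df["actin_contracted_norm"] = safe_div(
        "n_actin_contracted", ["n_actin_contracted", "n_actin_dispersed"])
    df["actin_dispersed_norm"] = safe_div(
        "n_actin_dispersed", ["n_actin_contracted", "n_actin_dispersed"])
    df["podosome_norm"] = safe_div("n_podosome", ["n_podosome", "n_no_podosome"])
    df["no_podosome_norm"] = safe_div(
        "n_no_podosome", ["n_podosome", "n_no_podosome"])
    return df.iloc[0] if single else df


# ---------------------------------------------------------------------------
# DMSO-relative effects
# ---------------------------------------------------------------------------


def effect_vs_control(
    summaries: pd.DataFrame,
    features: list[str] | None = None,
    control_condition: str = "DMSO",
    by: tuple[str, ...] = ("plate_id", "donor_id", "timepoint_h"),
    control_agg: str = "mean",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-well deltas/folds vs the stratum control, plus donor-level medians.

    For every stratum (default plate x donor x timepoint) the control level
    of each feature is the mean (or median) over that stratum's control
    wells; each non-control well contributes delta = value - control and
    fold = value / control. Strata without control wells are skipped with a
    warning. The second return value aggregates per (condition, timepoint,
    feature): the median across donors of each donor's mean fold and delta.
    """
    import warnings

    features = features or [c for c in FRACTION_FEATURES + NORMALIZED_FEATURES
                            if c in summaries.columns]
    by = [b for b in by if b in summaries.columns]
    agg_fn = np.median if control_agg == "median" else np.mean

    per_well_rows = []
    for key, grp in summaries.groupby(by, sort=True):
        ctrl = grp[grp["condition"] == control_condition]
        if ctrl.empty:
            warnings.warn(f"stratum {key} has no {control_condition} wells; "
                          "skipped", stacklevel=2)
            continue
        ctrl_levels = {f: agg_fn(ctrl[f].dropna().to_numpy())
                       if ctrl[f].notna().any() else np.nan
                       for f in features}
        for _, well in grp.iterrows():
            for f in features:
                ref = ctrl_levels[f]
                val = well[f]
                delta = val - ref if np.isfinite(val) and np.isfinite(ref) else np.nan
                fold = (val / ref if np.isfinite(val) and np.isfinite(ref)
                        and ref != 0 else np.nan)
                per_well_rows.append({
                    **{b: well[b] for b in by},
                    "well_id": well.get("well_id", ""),
                    "condition": well["condition"],
                    "feature": f, "value": val, "control_level": ref,
                    "delta": delta, "fold": fold,
                })
    per_well = pd.DataFrame(per_well_rows)
    if per_well.empty:
        return per_well, pd.DataFrame()

    stim = per_well[per_well["condition"] != control_condition]
    est_rows = []
    gb_keys = ["condition", "feature"]
    if "timepoint_h" in per_well.columns:
        gb_keys.insert(1, "timepoint_h")
    for key, grp in stim.groupby(gb_keys, sort=True):
        donor_key = "donor_id" if "donor_id" in grp.columns else None
        if donor_key:
            donor_folds = grp.groupby(donor_key)["fold"].mean()
            donor_deltas = grp.groupby(donor_key)["delta"].mean()
        else:
            donor_folds, donor_deltas = grp["fold"], grp["delta"]
        def _nanmedian(values):
            arr = values.to_numpy(dtype=float)
            return float(np.median(arr[np.isfinite(arr)])) \
                if np.isfinite(arr).any() else np.nan

        rec = dict(zip(gb_keys, key if isinstance(key, tuple) else (key,)))
        rec.update({
            "median_fold": _nanmedian(donor_folds),
            "median_delta": _nanmedian(donor_deltas),
            "n_donors": int(donor_folds.notna().sum()) if donor_key else len(grp),
            "n_wells": len(grp),
        })
        est_rows.append(rec)
    return per_well, pd.DataFrame(est_rows)


# ---------------------------------------------------------------------------
# Association analysis (OLS slope + Spearman)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssociationResult:
    """Paired readout of a well-level association: OLS slope + Spearman."""

    slope: float
    intercept: float
    rho: float
    pvalue: float
    n: int
    undefined: bool = False


def associate(x, y) -> AssociationResult:
    """OLS slope of y on x alongside Spearman rho and its p-value.

    Requires >= 3 paired finite observations. Zero variance in x leaves the
    slope NaN-flagged; a constant vector leaves rho/p NaN-flagged.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError("need >= 3 paired wells")
    if np.ptp(x) == 0:
        return AssociationResult(np.nan, np.nan, np.nan, np.nan, n,
                                 undefined=True)
    slope, intercept = np.polyfit(x, y, 1)
    sp = _stats.spearman(x, y) if np.ptp(y) > 0 else None
    if sp is None or sp.undefined:
        return AssociationResult(float(slope), float(intercept), np.nan,
                                 np.nan, n, undefined=True)
    return AssociationResult(float(slope), float(intercept),
                             float(sp.statistic), float(sp.pvalue), n)


def associate_deltas(per_well: pd.DataFrame, x_feature: str, y_feature: str,
                     value: str = "delta") -> AssociationResult:
    """Associate two features' per-well deltas from an effect table."""
    keys = [c for c in ("plate_id", "donor_id", "timepoint_h", "well_id",
                        "condition") if c in per_well.columns]
    wide = per_well.pivot_table(index=keys, columns="feature", values=value,
                                aggfunc="first")
    return associate(wide[x_feature].to_numpy(), wide[y_feature].to_numpy())
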