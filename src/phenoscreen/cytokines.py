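"""Secreted-protein (cytokine/chemokine) fold-change analysis.

Concentrations are normalized as fold changes over the DMSO vehicle control
within each (plate, donor, analyte) stratum: fold = median(stimulated wells)
/ median(control wells), computed per (condition, timepoint). Fold changes
are then averaged over replicate wells per donor to give per-donor
measurements, and donor cohorts (e.g. healthy volunteers vs people living
with HIV) are compared per analyte with a two-sided Mann-Whitney U test at
p < 0.05, without multiple-testing correction by default (a
Benjamini-Hochberg option is available).

A control median of zero is replaced by a pseudocount (1% of the analyte's
global median concentration unless given explicitly) so folds stay finite;
such rows are flagged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import stats as _stats

TABLE_COLUMNS = ["plate_id", "well_id", "donor_id", "cohort", "condition",
                 "timepoint_h", "analyte", "concentration"]


class CytokineTableError(ValueError):
    pass


def _validate(table: pd.DataFrame) -> None:
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise CytokineTableError(f"cytokine table missing columns: {missing}")
    if (table["concentration"] < 0).any():
        raise CytokineTableError("concentrations must be non-negative")
    dup = table.duplicated(subset=["plate_id", "well_id", "analyte"])
    if dup.any():
        raise CytokineTableError("(plate, well, analyte) rows must be unique")


def fold_changes(table: pd.DataFrame, control_condition: str = "DMSO",
                 pseudocount: float | None = None) -> pd.DataFrame:
    """Fold changes over the control per (plate, donor, analyte) stratum.

    Returns rows (plate_id, donor_id, cohort, condition, timepoint_h,
    analyte, fold, n_wells, pseudocount_used). Control conditions map to
    fold 1 identically. Analytes with no control wells in a stratum are
    flagged and excluded.
    """
    _validate(table)
    if not (table["condition"] == control_condition).any():
        raise CytokineTableError(f"no {control_condition} wells in table")
    global_medians = table.groupby("analyte")["concentration"].median()

    rows = []
    for (plate, donor, analyte), grp in table.groupby(
            ["plate_id", "donor_id", "analyte"], sort=True):
        cohort = grp["cohort"].iloc[0]
        ctrl = grp[grp["condition"] == control_condition]
        if ctrl.empty:
            continue    # stratum-analyte without control: excluded
        # control fold is identically 1 per (timepoint) group
        for tp, cgrp in ctrl.groupby("timepoint_h"):
            rows.append((plate, donor, cohort, control_condition, tp, analyte,
                         1.0, len(cgrp), False))
        ctrl_median = float(ctrl["concentration"].median())
        used_pseudo = False
        if ctrl_median == 0.0:
            eps = (pseudocount if pseudocount is not None
                   else 0.01 * float(global_medians[analyte]))
            if eps <= 0:
                eps = np.finfo(float).tiny
            ctrl_median = eps
            used_pseudo = True
        stim = grp[grp["condition"] != control_condition]
        for (cond, tp), sgrp in stim.groupby(["condition", "timepoint_h"],
                                             sort=True):
            fold = float(sgrp["concentration"].median()) / ctrl_median
            rows.append((plate, donor, cohort, cond, tp, analyte, fold,
                         len(sgrp), used_pseudo))
    return pd.DataFrame(rows, columns=[
        "plate_id", "donor_id", "cohort", "condition", "timepoint_h",
        "analyte", "fold", "n_wells", "pseudocount_used"])


def per_donor_matrix(folds: pd.DataFrame) -> pd.DataFrame:
    """Donor x (condition, timepoint, analyte) matrix of mean fold changes.

    Fold changes are averaged (arithmetic mean) over plates/replicates per
    donor; missing combinations are NaN.
    """
    if folds.empty:
        raise ValueError("fold-change table is empty")
    return folds.pivot_table(
        index="donor_id", columns=["condition", "timepoint_h", "analyte"],
        values="fold", aggfunc="mean")


def compare_groups(matrix: pd.DataFrame, cohorts: pd.Series | dict,
                   alpha: float = 0.05,
                   bh_correction: bool = False) -> pd.DataFrame:
    """Mann-Whitney comparison of per-donor folds between two cohorts.

    ``cohorts`` maps donor_id -> cohort label (exactly two labels used).
    Returns one row per matrix column with U, two-sided p, which group is
    higher (by median), a significance flag at ``alpha``, and an
    ``untestable`` flag when either group has < 2 donors with data.
    ``bh_correction`` applies Benjamini-Hochberg across testable rows
    (off by default).
    """
    cohorts = pd.Series(cohorts)
    labels = sorted(cohorts.loc[matrix.index].unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 cohorts, got {labels}")
    g1 = matrix.index[cohorts.loc[matrix.index] == labels[0]]
    g2 = matrix.index[cohorts.loc[matrix.index] == labels[1]]

    rows = []
    for col in matrix.columns:
        a = matrix.loc[g1, col].dropna().to_numpy()
        b = matrix.loc[g2, col].dropna().to_numpy()
        cond, tp, analyte = col if isinstance(col, tuple) else (col, None, None)
        if len(a) < 2 or len(b) < 2:
            rows.append((cond, tp, analyte, np.nan, np.nan, None, False, True))
            continue
        res = _stats.mann_whitney(a, b)
        higher = labels[0] if np.median(a) > np.median(b) else labels[1]
        if np.median(a) == np.median(b):
            higher = None
        rows.append((cond, tp, analyte, res.statistic, res.pvalue, higher,
                     res.pvalue < alpha, False))
    out = pd.DataFrame(rows, columns=[
        "condition", "timepoint_h", "analyte", "U", "pvalue", "higher_group",
        "significant", "untestable"])
    if bh_correction:
        testable = out.index[~out["untestable"]]
        p = out.loc[testable, "pvalue"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 1.0
        for rank_pos in range(m - 1, -1, -1):
            i = order[rank_pos]
            running = min(running, p[i] * m / (rank_pos + 1))
            adj[i] = running
        out.loc[testable, "pvalue_adj"] = adj
        out.loc[testable, "significant"] = out.loc[testable, "pvalue_adj"] < alpha
    return out


def heatmap_matrix(folds: pd.DataFrame, agg: str = "mean",
                   comparisons: pd.DataFrame | None = None):
    """Analyte x (condition, timepoint, cohort) heatmap-ready matrix.

    ``agg`` selects mean or median of per-donor folds per cell. If a
    comparison table is supplied, a same-shaped boolean significance mask is
    returned alongside.
    """
    donor_level = folds.groupby(
        ["analyte", "condition", "timepoint_h", "cohort", "donor_id"],
        sort=True)["fold"].mean().reset_index()
    mat = donor_level.pivot_table(
        index="analyte", columns=["condition", "timepoint_h", "cohort"],
        values="fold", aggfunc=agg)
    if comparisons is None:
        return mat
    sig = pd.DataFrame(False, index=mat.index, columns=mat.columns)
    for _, row in comparisons.iterrows():
        if not row["significant"]:
            continue
        for col in sig.columns:
            cond, tp, _cohort = col
            if cond == row["condition"] and tp == row["timepoint_h"] \
                    and row["analyte"] in sig.index:
                sig.loc[row["analyte"], col] = True
    return mat, sig
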