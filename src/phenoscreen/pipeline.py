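"""End-to-end orchestration: configuration, staged runs, run manifests, and
the packaged recovery experiments.

``run_all`` drives the stages (simulate, segment, featurize, basis QC,
train, classify, quantify, cytokines) from a single validated
:class:`RunConfig`, writing CSV/TIFF/JSON artifacts plus a manifest with the
config hash and per-file checksums so reruns are verifiable.

The module also packages two self-contained recovery experiments used to
check the pipeline against known injected truths:

* :func:`actin_fold_experiment` injects multiplicative actin-contraction
  effects for a TLR8-like condition, runs the full image pipeline
  (simulate, render, segment, embed, classify, quantify) over simulated
  donors and reports the recovered median fold of the normalized
  actin-contracted fraction vs DMSO per timepoint;
* :func:`slope_recovery_experiment` imposes a linear coupling between two
  features' well-level deltas and reports the OLS slope the association
  analysis recovers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import basis as _basis
from . import cytokines as _cyt
from . import featurization as _feat
from . import phenosorter as _ps
from . import quantification as _quant
from . import segmentation as _seg
from . import synthetic as _syn
from .synthetic import DMSO, EffectSpec, RenderParams, _stable_seed

STAGES = ("simulate", "segment", "featurize", "basis", "train", "classify",
          "quantify", "cytokines")


class ConfigError(ValueError):
    pass


def _from_mapping(cls, data: dict, path: str):
    """Build a dataclass from a mapping, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} under {path!r}")
    return cls(**data)


@dataclass
class LayoutConfig:
    n_plates: int = 2
    wells_per_plate: int = 12
    fields_per_well: int = 1
    conditions: list[str] = field(default_factory=lambda: [DMSO, "TLR8"])
    timepoints: list[float] = field(default_factory=lambda: [24.0])
    donors: list[str] = field(default_factory=lambda: ["D01", "D02"])
    cohorts: dict[str, str] = field(default_factory=dict)


@dataclass
class ClassifierConfig:
    families: list[str] = field(default_factory=lambda: list(_ps.MODEL_FAMILIES))
    n_estimators: int = 200
    max_depth: int = 4
    learning_rate: float = 0.1


@dataclass
class CytokineConfig:
    enabled: bool = True
    donor_sd: float = 0.3
    noise_sd: float = 0.2
    fold_effects: dict = field(default_factory=dict)   # "cond|tp|analyte" -> fold


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    seed: int = 0
    out_dir: str = "phenoscreen_run"
    cells_per_well: int = 60
    crop_side_px: int = 64
    grouping_radius_um: float = 8.0
    positive_control: str | None = None     # default: first non-DMSO condition
    ssmd_threshold: float = 2.0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    layout: LayoutConfig = field(default_factory=LayoutConfig)
    render: RenderParams = field(default_factory=RenderParams)
    effects: EffectSpec = field(default_factory=EffectSpec)
    segmentation: _seg.SegmentationParams = field(
        default_factory=_seg.SegmentationParams)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    cytokines: CytokineConfig = field(default_factory=CytokineConfig)

    def __post_init__(self):
        if DMSO not in self.layout.conditions:
            raise ConfigError("layout.conditions must include DMSO")
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ConfigError(f"unknown stage(s): {sorted(bad)}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sub = {
            "layout": (LayoutConfig, "layout"),
            "render": (RenderParams, "render"),
            "segmentation": (_seg.SegmentationParams, "segmentation"),
            "classifier": (ClassifierConfig, "classifier"),
            "cytokines": (CytokineConfig, "cytokines"),
        }
        kwargs = {}
        for key, (klass, path) in sub.items():
            if key in d:
                val = d.pop(key)
                if key == "render" and "small_cell_diam_um" in val:
                    val["small_cell_diam_um"] = tuple(val["small_cell_diam_um"])
                if key == "render" and "large_cell_diam_um" in val:
                    val["large_cell_diam_um"] = tuple(val["large_cell_diam_um"])
                kwargs[key] = _from_mapping(klass, val, path)
        if "effects" in d:
            eff = d.pop("effects")
            kwargs["effects"] = (eff if isinstance(eff, EffectSpec)
                                 else EffectSpec.from_dict(eff))
        top = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - top
        if unknown:
            raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
        kwargs.update(d)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "effects" in data and isinstance(data["effects"], dict):
            data["effects"] = EffectSpec.from_dict(data["effects"])
        return cls.from_dict(data)

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, EffectSpec):
                return o.to_dict()
            raise TypeError(type(o))

        d = dataclasses.asdict(self)
        d["effects"] = self.effects.to_dict()
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


# ---------------------------------------------------------------------------
# Core per-well processing
# ---------------------------------------------------------------------------


def process_well(truth: _syn.GroundTruth, render: RenderParams,
                 seg_params: _seg.SegmentationParams, seed: int,
                 grouping_radius_um: float = 8.0, crop_side_px: int = 64,
                 n_fields: int = 1):
    """Render, segment and embed one simulated well.

    Returns (fields, detections DataFrame, embedding matrix) where each
    detection row carries the well key, centroid and, when the detection
    matches a ground-truth cell, that truth row's index (else -1).
    """
    det_rows = []
    embeddings = []
    fields = []
    for f in range(n_fields):
        fld = _syn.render_field(truth, f, render, _stable_seed(seed, "field", f))
        fields.append(fld)
        seeds, crops = _seg.detect_cells(fld, seg_params, grouping_radius_um,
                                         crop_side_px)
        match = _seg.match_seeds(
            seeds, truth.cells[truth.cells["field_index"] == f])
        match_map = dict(zip(match["seed_cell_id"], match["truth_index"]))
        for s, c in zip(seeds, crops):
            det_rows.append({
                "field_index": f, "det_id": s.cell_id,
                "centroid_row": s.centroid[0], "centroid_col": s.centroid[1],
                "fragmented_hint": s.fragmented_hint,
                "truth_index": match_map.get(s.cell_id, -1),
            })
            embeddings.append(_feat.embed(c).vector)
    det = pd.DataFrame(det_rows)
    emb = np.vstack(embeddings) if embeddings else np.zeros(
        (0, _feat.EMBEDDING_LENGTH))
    return fields, det, emb


def _training_effects(donor_seed: int = 1) -> EffectSpec:
    """Phenotype-enriched spec for training wells: every class well
    represented, no donor heterogeneity."""
    return EffectSpec(
        baseline=_syn.PhenotypeBaseline(
            large_frac=0.40, annexin=0.30, fragmented=0.25,
            actin_stained=0.80, contracted_given_stained=0.50,
            podosome=0.50, phagocytosis=0.40),
        donor_sd=0.0, donor_seed=donor_seed)


def build_training_set(render: RenderParams, seg_params: _seg.SegmentationParams,
                       seed: int, n_wells: int = 24, cells_per_well: int = 80,
                       grouping_radius_um: float = 8.0, crop_side_px: int = 64):
    """Simulate phenotype-enriched wells and return truth-labeled detections.

    Stand-in for hand-labeled training examples: detections are matched to
    generator truth cells and inherit their labels. Returns (cells, matrix)
    aligned row-for-row.
    """
    spec = _training_effects()
    rows, mats = [], []
    for wi in range(n_wells):
        layout_row = pd.Series({
            "plate_id": "TRAIN", "well_id": _syn.well_name(wi),
            "condition": DMSO, "timepoint_h": 24.0,
            "donor_id": "train", "cohort": "HV", "concentration": 0.0,
        })
        truth = _syn.simulate_well(layout_row, spec, cells_per_well,
                                   _stable_seed(seed, "trainwell", wi))
        _, det, emb = process_well(truth, render, seg_params,
                                   _stable_seed(seed, "trainproc", wi),
                                   grouping_radius_um, crop_side_px)
        matched = det[det["truth_index"] >= 0]
        if matched.empty:
            continue
        cells = truth.cells.loc[matched["truth_index"]].reset_index(drop=True)
        cells["cell_id"] = [f"T{wi}:{d}" for d in matched["det_id"]]
        rows.append(cells)
        mats.append(emb[matched.index.to_numpy()])
    cells = pd.concat(rows, ignore_index=True)
    return cells, np.vstack(mats)


# ---------------------------------------------------------------------------
# Recovery experiments
# ---------------------------------------------------------------------------


def actin_fold_experiment(
    seed: int = 0,
    fold_by_timepoint: dict[float, float] = {24.0: 1.55, 48.0: 1.91},
    condition: str = "TLR8",
    n_donors: int = 30,
    wells_per_condition: int = 3,
    cells_per_well: int = 80,
    field_px: int = 512,
    progress: bool = False,
) -> dict[float, float]:
    """Inject actin-contraction folds and recover them through the pipeline.

    One plate per simulated donor; each plate carries
    ``wells_per_condition`` wells per (condition x timepoint) combination,
    one field each. Per timepoint, the recovered value is the median across
    donors of (condition actin_contracted_norm / DMSO actin_contracted_norm)
    computed from classifier output after segmentation and featurization.
    """
    render = RenderParams(field_px=field_px)
    seg_params = _seg.SegmentationParams()
    timepoints = sorted(fold_by_timepoint)
    effects = EffectSpec(
        effects={(condition, tp): _syn.ConditionEffect(
            contracted_fold=fold_by_timepoint[tp]) for tp in timepoints},
        donor_sd=0.15, donor_seed=_stable_seed(seed, "donors"))

    train_cells, train_emb = build_training_set(
        render, seg_params, _stable_seed(seed, "training"))
    model_set = _ps.train_model_set(train_cells, train_emb,
                                    families=("size", "actin"),
                                    seed=_stable_seed(seed, "xgb") % (2 ** 31))

    donors = [f"D{i + 1:02d}" for i in range(n_donors)]
    layout = _syn.make_layout(
        n_plates=n_donors,
        wells_per_plate=2 * len(timepoints) * wells_per_condition,
        fields_per_well=1, conditions=[DMSO, condition],
        timepoints=timepoints, donors=donors)

    label_tables = []
    wells = layout.drop_duplicates(subset=["plate_id", "well_id"])
    for wi, (_, row) in enumerate(wells.iterrows()):
        wseed = _stable_seed(seed, "well", row.plate_id, row.well_id)
        truth = _syn.simulate_well(row, effects, cells_per_well, wseed)
        _, det, emb = process_well(truth, render, seg_params,
                                   _stable_seed(wseed, "proc"))
        labels = model_set.classify(emb)
        for k in _quant.WELL_KEY:
            labels[k] = row[k]
        label_tables.append(labels)
        if progress and (wi + 1) % 50 == 0:
            print(f"  processed {wi + 1}/{len(wells)} wells")

    all_labels = pd.concat(label_tables, ignore_index=True)
    summaries = _quant.normalize(_quant.summarize_wells(all_labels))
    _, estimates = _quant.effect_vs_control(
        summaries, features=["actin_contracted_norm"])
    out = {}
    for tp in timepoints:
        sel = estimates[(estimates["condition"] == condition)
                        & (estimates["timepoint_h"] == tp)]
        out[tp] = float(sel["median_fold"].iloc[0])
    return out


def slope_recovery_experiment(slope: float, seed: int = 0, n_wells: int = 200,
                              noise_sd: float = 0.01) -> float:
    """Recover a generator-imposed linear coupling slope by OLS."""
    deltas = _syn.simulate_coupled_deltas(slope, n_wells, noise_sd=noise_sd,
                                          seed=seed)
    res = _quant.associate(deltas["delta_x"], deltas["delta_y"])
    return res.slope


# ---------------------------------------------------------------------------
# Staged artifact run
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> Path:
    """Run the configured stages end to end, writing artifacts + manifest.

    Returns the output directory. Any stage failure leaves partial outputs
    in place with a ``FAILED`` marker file naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    state: dict = {}
    stage_log = []
    try:
        for stage in STAGES:
            if stage not in config.stages:
                continue
            t_stage = time.time()
            _run_stage(stage, config, out, state)
            stage_log.append({"stage": stage,
                              "seconds": round(time.time() - t_stage, 3)})
    except Exception as exc:
        (out / "FAILED").write_text(f"{stage}: {exc}\n")
        raise

    files = sorted(p for p in out.rglob("*") if p.is_file()
                   and p.name != "manifest.json")
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": stage_log,
        "started_unix": round(t0, 3),
        "finished_unix": round(time.time(), 3),
        "checksums": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out


def _run_stage(stage: str, cfg: RunConfig, out: Path, state: dict) -> None:
    seed = cfg.seed
    if stage == "simulate":
        lc = cfg.layout
        layout = _syn.make_layout(lc.n_plates, lc.wells_per_plate,
                                  lc.fields_per_well, lc.conditions,
                                  lc.timepoints, lc.donors, lc.cohorts)
        layout.to_csv(out / "layout.csv", index=False)
        truths = {}
        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)
        wells = layout.drop_duplicates(subset=["plate_id", "well_id"])
        for _, row in wells.iterrows():
            wseed = _stable_seed(seed, "well", row.plate_id, row.well_id)
            truth = _syn.simulate_well(row, cfg.effects, cfg.cells_per_well,
                                       wseed, n_fields=lc.fields_per_well)
            for f, fld in enumerate(_syn.render_well(truth, cfg.render, wseed)):
                fld.save(img_dir / f"{row.plate_id}_{row.well_id}_f{f}.tiff")
            truths[(row.plate_id, row.well_id)] = truth
        pd.concat([t.cells for t in truths.values()],
                  ignore_index=True).to_csv(out / "truth.csv", index=False)
        state["layout"], state["truths"] = layout, truths
        if cfg.cytokines.enabled:
            fold_effects = {}
            for key, fold in cfg.cytokines.fold_effects.items():
                cond, tp, analyte = key.split("|")
                fold_effects[(cond, float(tp), analyte)] = float(fold)
            table, _ = _syn.simulate_cytokines(
                layout, fold_effects, donor_sd=cfg.cytokines.donor_sd,
                noise_sd=cfg.cytokines.noise_sd,
                seed=_stable_seed(seed, "cyt"))
            table.to_csv(out / "cytokines.csv", index=False)
            state["cytokine_table"] = table
    elif stage == "segment" or stage == "featurize":
        if stage == "featurize" and "detections" in state:
            return      # featurize runs jointly with segment below
        dets, embs = [], []
        for (plate, well), truth in state["truths"].items():
            wseed = _stable_seed(seed, "well", plate, well)
            n_fields = cfg.layout.fields_per_well
            _, det, emb = process_well(
                truth, cfg.render, cfg.segmentation,
                _stable_seed(wseed, "proc"), cfg.grouping_radius_um,
                cfg.crop_side_px, n_fields=n_fields)
            det.insert(0, "plate_id", plate)
            det.insert(1, "well_id", well)
            dets.append(det)
            embs.append(emb)
        det = pd.concat(dets, ignore_index=True)
        emb = np.vstack([e for e in embs if len(e)])
        det.to_csv(out / "detections.csv", index=False)
        emb_df = pd.DataFrame(emb, columns=_feat.feature_names())
        emb_df.insert(0, "cell_index", range(len(emb_df)))
        emb_df.to_csv(out / "embeddings.csv", index=False)
        with open(out / "embedding_blocks.json", "w") as fh:
            json.dump({k: list(v) for k, v in _feat.block_map().items()}, fh)
        state["detections"], state["embeddings"] = det, emb
    elif stage == "basis":
        layout = state["layout"]
        det, emb = state["detections"], state["embeddings"]
        pos_cond = cfg.positive_control or next(
            c for c in cfg.layout.conditions if c != DMSO)
        well_cond = layout.drop_duplicates(["plate_id", "well_id"]).set_index(
            ["plate_id", "well_id"])["condition"]
        cond = well_cond.loc[list(zip(det["plate_id"], det["well_id"]))]
        cond.index = det.index
        neg_cells = emb[(cond == DMSO).to_numpy()]
        pos_cells = emb[(cond == pos_cond).to_numpy()]
        b = _basis.fit_basis(neg_cells, pos_cells)
        scores = _basis.score_many(b, emb)
        det2 = det.copy()
        det2["on_basis_norm"] = scores[:, 1]
        det2["off_basis"] = scores[:, 2]
        well_means = det2.groupby(["plate_id", "well_id"])[
            "on_basis_norm"].mean()
        neg_wells = well_means[well_cond.loc[well_means.index] == DMSO]
        pos_wells = well_means[well_cond.loc[well_means.index] == pos_cond]
        report = _basis.ssmd(neg_wells, pos_wells, threshold=cfg.ssmd_threshold)
        pd.DataFrame([dataclasses.asdict(report)]).to_csv(
            out / "ssmd_qc.csv", index=False)
        with open(out / "ssmd_qc.json", "w") as fh:
            json.dump(dataclasses.asdict(report), fh, indent=2)
        state["qc"] = report
    elif stage == "train":
        det, emb = state["detections"], state["embeddings"]
        matched = det[det["truth_index"] >= 0]
        truth_all = pd.concat([t.cells for t in state["truths"].values()])
        # truth_index refers to each well's truth frame; rebuild by lookup
        cells_rows, mat_rows = [], []
        for (plate, well), truth in state["truths"].items():
            sel = matched[(matched["plate_id"] == plate)
                          & (matched["well_id"] == well)]
            cells_rows.append(truth.cells.loc[sel["truth_index"]])
            mat_rows.append(state["embeddings"][sel.index.to_numpy()])
        cells = pd.concat(cells_rows, ignore_index=True)
        mat = np.vstack(mat_rows)
        model_set = _ps.train_model_set(
            cells, mat, families=tuple(cfg.classifier.families),
            seed=seed % (2 ** 31),
            n_estimators=cfg.classifier.n_estimators,
            max_depth=cfg.classifier.max_depth,
            learning_rate=cfg.classifier.learning_rate)
        with open(out / "classifier_metrics.json", "w") as fh:
            json.dump(model_set.metrics, fh, indent=2)
        state["model_set"] = model_set
        del truth_all
    elif stage == "classify":
        det, emb = state["detections"], state["embeddings"]
        labels = state["model_set"].classify(emb)
        labels = pd.concat([det[["plate_id", "well_id", "field_index",
                                 "det_id"]].reset_index(drop=True),
                            labels.reset_index(drop=True)], axis=1)
        layout = state["layout"].drop_duplicates(["plate_id", "well_id"])
        labels = labels.merge(
            layout[["plate_id", "well_id", "donor_id", "cohort", "condition",
                    "timepoint_h"]], on=["plate_id", "well_id"])
        labels.to_csv(out / "cell_labels.csv", index=False)
        state["labels"] = labels
    elif stage == "quantify":
        summaries = _quant.normalize(_quant.summarize_wells(state["labels"]))
        summaries.to_csv(out / "well_summaries.csv", index=False)
        per_well, estimates = _quant.effect_vs_control(summaries)
        per_well.to_csv(out / "effects_per_well.csv", index=False)
        estimates.to_csv(out / "effect_estimates.csv", index=False)
        state["summaries"] = summaries
    elif stage == "cytokines":
        if "cytokine_table" not in state:
            return
        folds = _cyt.fold_changes(state["cytokine_table"])
        folds.to_csv(out / "cytokine_folds.csv", index=False)
        matrix = _cyt.per_donor_matrix(folds)
        matrix.to_csv(out / "cytokine_donor_matrix.csv")
        cohorts = state["layout"].drop_duplicates("donor_id").set_index(
            "donor_id")["cohort"]
        if cohorts.nunique() == 2:
            comp = _cyt.compare_groups(matrix, cohorts)
            comp.to_csv(out / "cytokine_comparisons.csv", index=False)
    else:       # pragma: no cover
        raise ConfigError(f"unknown stage {stage!r}")
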