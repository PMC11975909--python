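"""Supervised single-cell phenotype sorting from embeddings.

Workflow mirroring interactive phenotype-sorting tools used in high-content
screening: a labeled example set is split 80/20 (optionally stratified), a
k-nearest-neighbor baseline with balanced class weighting is trained and
evaluated on the held-out cells, then a gradient-boosted tree model with the
same balanced weighting is trained as the final classifier and applied to
the whole dataset, binning every cell into a phenotype class.

Balanced class weighting means each training example carries weight
inversely proportional to its class frequency, so the expected total weight
per class is equal and the model is penalized more for misclassifying rare
classes. In this package hand labels are usually replaced by generator
ground truth; a plain CSV (cell_id, label) hand-label format is also
accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import balanced_accuracy_score, precision_recall_fscore_support
from sklearn.neighbors import NearestNeighbors


class NotFittedError(RuntimeError):
    pass


@dataclass
class LabeledSet:
    """Cell ids, embedding matrix and phenotype labels for one model family."""

    cell_ids: np.ndarray            # (n,) any hashable ids
    embeddings: np.ndarray          # (n, d)
    labels: np.ndarray              # (n,) str
    provenance: str = "generator-truth"

    def __post_init__(self):
        self.cell_ids = np.asarray(self.cell_ids)
        self.embeddings = np.asarray(self.embeddings, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if len({*map(str, self.cell_ids)}) != len(self.cell_ids):
            raise ValueError("duplicate cell_ids in labeled set")
        if not (len(self.cell_ids) == len(self.embeddings) == len(self.labels)):
            raise ValueError("cell_ids, embeddings and labels must align")

    def __len__(self):
        return len(self.labels)

    @property
    def classes(self) -> list[str]:
        return sorted(np.unique(self.labels).tolist())

    def subset(self, idx) -> "LabeledSet":
        return LabeledSet(self.cell_ids[idx], self.embeddings[idx],
                          self.labels[idx], self.provenance)

    @classmethod
    def from_csv(cls, labels_path, embeddings: np.ndarray,
                 cell_ids) -> "LabeledSet":
        """Join a hand-label CSV (cell_id, label) onto an embedding matrix."""
        lab = pd.read_csv(labels_path).set_index("cell_id")["label"]
        cell_ids = np.asarray(cell_ids)
        keep = np.array([cid in lab.index for cid in cell_ids])
        return cls(cell_ids[keep], np.asarray(embeddings)[keep],
                   lab.loc[cell_ids[keep]].to_numpy(), provenance="hand-label")


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


def split(data: LabeledSet, spec: SplitSpec = SplitSpec()):
    """Random train/test split; stratified splits preserve class proportions.

    Returns (train, test) LabeledSets that are disjoint and exhaustive.
    Stratification requires >= 2 members per class.
    """
    rng = np.random.default_rng(spec.seed)
    n = len(data)
    if spec.stratified:
        train_idx: list[int] = []
        test_idx: list[int] = []
        for cls_name in data.classes:
            members = np.flatnonzero(data.labels == cls_name)
            if len(members) < 2:
                raise ValueError(
                    f"class {cls_name!r} has {len(members)} member(s); "
                    "stratified split needs >= 2")
            perm = rng.permutation(members)
            n_train = int(round(spec.train_fraction * len(members)))
            n_train = min(max(n_train, 1), len(members) - 1)
            train_idx.extend(perm[:n_train])
            test_idx.extend(perm[n_train:])
        train_idx = np.sort(np.asarray(train_idx))
        test_idx = np.sort(np.asarray(test_idx))
    else:
        perm = rng.permutation(n)
        n_train = int(round(spec.train_fraction * n))
        train_idx = np.sort(perm[:n_train])
        test_idx = np.sort(perm[n_train:])
    return data.subset(train_idx), data.subset(test_idx)


def _class_weights(labels: np.ndarray) -> dict[str, float]:
    """Inverse-frequency weights normalized to mean 1 over examples."""
    classes, counts = np.unique(labels, return_counts=True)
    w = len(labels) / (len(classes) * counts.astype(float))
    return dict(zip(classes.tolist(), w.tolist()))


@dataclass
class ClassifierModel:
    """A fitted phenotype classifier (kNN baseline or boosted trees)."""

    kind: str                               # "knn" | "xgboost"
    classes: list[str]
    class_weights: dict[str, float]
    hyperparams: dict = field(default_factory=dict)
    _knn: NearestNeighbors | None = None
    _train_labels: np.ndarray | None = None
    _booster: object | None = None
    metrics: dict = field(default_factory=dict)
    version: str = "1"

    @property
    def fitted(self) -> bool:
        return self._knn is not None or self._booster is not None

    def predict(self, embeddings: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise NotFittedError("model has not been fitted")
        x = np.atleast_2d(np.asarray(embeddings, dtype=np.float64))
        if x.shape[0] == 0:
            return np.array([], dtype=object)
        if self.kind == "knn":
            k = min(self.hyperparams.get("k", 15), len(self._train_labels))
            _, idx = self._knn.kneighbors(x, n_neighbors=k)
            neigh_labels = self._train_labels[idx]           # (n, k)
            out = np.empty(len(x), dtype=object)
            cls_arr = np.asarray(self.classes)
            votes = np.zeros((len(x), len(cls_arr)))
            for ci, cname in enumerate(cls_arr):
                votes[:, ci] = (
                    (neigh_labels == cname) * self.class_weights[cname]
                ).sum(axis=1)
            out[:] = cls_arr[np.argmax(votes, axis=1)]
            return out.astype(str)
        # xgboost
        pred = self._booster.predict(x)
        return np.asarray(self.classes)[pred.astype(int)].astype(str)


def train_baseline(train: LabeledSet, k: int = 15,
                   balanced: bool = True) -> ClassifierModel:
    """k-nearest-neighbor baseline with inverse-class-frequency vote weights.

    ``balanced=False`` drops the class weighting (plain majority vote),
    mainly for measuring what the weighting buys on imbalanced data.
    """
    if len(train) == 0:
        raise ValueError("training set is empty")
    if not 1 <= k <= len(train):
        raise ValueError("k must satisfy 1 <= k <= len(train)")
    weights = (_class_weights(train.labels) if balanced
               else {c: 1.0 for c in np.unique(train.labels)})
    nn = NearestNeighbors(n_neighbors=min(k, len(train)))
    nn.fit(train.embeddings)
    return ClassifierModel(kind="knn", classes=train.classes,
                           class_weights=weights, hyperparams={"k": k},
                           _knn=nn, _train_labels=train.labels.copy())


def train_final(train: LabeledSet,
                n_estimators: int = 200, max_depth: int = 4,
                learning_rate: float = 0.1, seed: int = 0,
                **extra) -> ClassifierModel:
    """Gradient-boosted tree model with balanced class weighting (seeded).

    A degenerate single-class training set yields a constant classifier with
    a warning rather than an error.
    """
    if len(train) == 0:
        raise ValueError("training set is empty")
    classes = train.classes
    weights = _class_weights(train.labels)
    if len(classes) == 1:
        import warnings

        warnings.warn("single-class training set; constant classifier",
                      stacklevel=2)
        model = ClassifierModel(kind="xgboost", classes=classes,
                                class_weights=weights)
        model._booster = _ConstantBooster(0)
        return model

    from xgboost import XGBClassifier

    y = np.searchsorted(np.asarray(classes), train.labels)
    sample_weight = np.array([weights[l] for l in train.labels])
    clf = XGBClassifier(
        n_estimators=n_estimators, max_depth=max_depth,
        learning_rate=learning_rate, random_state=seed, n_jobs=1,
        tree_method="hist", verbosity=0, **extra)
    clf.fit(train.embeddings, y, sample_weight=sample_weight)
    return ClassifierModel(
        kind="xgboost", classes=classes, class_weights=weights,
        hyperparams={"n_estimators": n_estimators, "max_depth": max_depth,
                     "learning_rate": learning_rate, "seed": seed},
        _booster=clf)


class _ConstantBooster:
    def __init__(self, value: int):
        self.value = value

    def predict(self, x):
        return np.full(len(np.atleast_2d(x)), self.value)


class _BoosterAdapter:
    """Raw xgboost Booster with sklearn-style class-index predictions."""

    def __init__(self, booster):
        self.booster = booster

    def predict(self, x):
        import xgboost

        p = self.booster.predict(xgboost.DMatrix(np.atleast_2d(x)))
        if p.ndim == 1:
            return (p > 0.5).astype(int)
        return p.argmax(axis=1)


def save_model(model: ClassifierModel, directory) -> None:
    """Serialize a fitted model: ``model.json`` metadata (kind, classes,
    weights, hyperparameters, metrics, format version) plus the payload —
    ``booster.json`` for boosted trees, ``train.npz`` for the kNN baseline."""
    import json
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = {"format_version": model.version, "kind": model.kind,
            "classes": model.classes, "class_weights": model.class_weights,
            "hyperparams": model.hyperparams, "metrics": model.metrics}
    (d / "model.json").write_text(json.dumps(meta, indent=2))
    if model.kind == "xgboost":
        if isinstance(model._booster, _ConstantBooster):
            (d / "constant.json").write_text(
                json.dumps({"value": model._booster.value}))
        else:
            booster = (model._booster.booster
                       if isinstance(model._booster, _BoosterAdapter)
                       else model._booster.get_booster())
            booster.save_model(d / "booster.json")
    else:
        np.savez(d / "train.npz", embeddings=model._knn._fit_X,
                 labels=model._train_labels)


def load_model(directory) -> ClassifierModel:
    """Load a model written by :func:`save_model`."""
    import json
    from pathlib import Path

    d = Path(directory)
    meta = json.loads((d / "model.json").read_text())
    model = ClassifierModel(kind=meta["kind"], classes=meta["classes"],
                            class_weights=meta["class_weights"],
                            hyperparams=meta["hyperparams"],
                            metrics=meta["metrics"],
                            version=meta["format_version"])
    if meta["kind"] == "xgboost":
        if (d / "constant.json").exists():
            value = json.loads((d / "constant.json").read_text())["value"]
            model._booster = _ConstantBooster(value)
        else:
            import xgboost

            booster = xgboost.Booster()
            booster.load_model(str(d / "booster.json"))
            model._booster = _BoosterAdapter(booster)
    else:
        data = np.load(d / "train.npz", allow_pickle=True)
        labels = data["labels"]
        nn = NearestNeighbors(
            n_neighbors=min(meta["hyperparams"].get("k", 15), len(labels)))
        nn.fit(data["embeddings"])
        model._knn = nn
        model._train_labels = labels
    return model


def evaluate(model: ClassifierModel, test: LabeledSet) -> dict:
    """Held-out metrics: balanced accuracy plus per-class precision/recall."""
    pred = model.predict(test.embeddings)
    prec, rec, f1, support = precision_recall_fscore_support(
        test.labels, pred, labels=model.classes, zero_division=0)
    metrics = {
        "balanced_accuracy": float(balanced_accuracy_score(test.labels, pred)),
        "per_class": {
            c: {"precision": float(p), "recall": float(r), "f1": float(f),
                "support": int(s)}
            for c, p, r, f, s in zip(model.classes, prec, rec, f1, support)
        },
        "n_test": len(test),
    }
    model.metrics = metrics
    return metrics


def classify_all(model: ClassifierModel, embeddings: np.ndarray) -> np.ndarray:
    """Bin every cell into a phenotype class (empty input -> empty output)."""
    x = np.asarray(embeddings, dtype=np.float64)
    if x.size == 0:
        return np.array([], dtype=str)
    return model.predict(x)


# ---------------------------------------------------------------------------
# Per-phenotype-family model sets
# ---------------------------------------------------------------------------

#: model families, the truth columns they read, and their eligibility rule
MODEL_FAMILIES = ("size", "annexin", "fragment", "actin", "podosome", "phago")


def family_labels(cells: pd.DataFrame, family: str) -> pd.Series:
    """Map ground-truth flag columns to this family's class labels.

    Returns a label per eligible cell (index-aligned subset of ``cells``):
    size (all cells), annexin and fragment (all cells), actin (small round
    only: contracted / dispersed / unstained), podosome and phago (large
    round only).
    """
    small = cells["size_class"] == "small_round"
    if family == "size":
        return cells["size_class"].astype(str)
    if family == "annexin":
        return cells["annexin_pos"].map({True: "annexin_pos", False: "annexin_neg"})
    if family == "fragment":
        return cells["fragmented_nucleus"].map(
            {True: "fragmented", False: "intact"})
    if family == "actin":
        sub = cells[small]
        lab = pd.Series("unstained", index=sub.index)
        lab[sub["actin_contracted"]] = "contracted"
        lab[sub["actin_dispersed"]] = "dispersed"
        return lab
    if family == "podosome":
        sub = cells[~small]
        return sub["podosome_pos"].map({True: "podosome_pos",
                                        False: "podosome_neg"})
    if family == "phago":
        sub = cells[~small]
        return sub["phagocytosis"].map({True: "phagocytosis", False: "large_round"})
    raise ValueError(f"unknown model family {family!r}")


@dataclass
class PhenotypeModelSet:
    """One classifier per phenotype family, with eligibility gating.

    The size model runs on every cell; actin models only on predicted small
    round cells; podosome/phagocytosis models only on predicted large round
    cells, mirroring how separate sorting models are built per phenotype
    category.
    """

    models: dict[str, ClassifierModel]
    metrics: dict[str, dict] = field(default_factory=dict)

    def classify(self, embeddings: np.ndarray) -> pd.DataFrame:
        """Per-cell labels for every family (NaN where ineligible)."""
        x = np.atleast_2d(np.asarray(embeddings, dtype=np.float64))
        n = len(x)
        out = pd.DataFrame(index=range(n))
        size = classify_all(self.models["size"], x) if n else np.array([])
        out["size_class"] = size
        small = out["size_class"] == "small_round"
        for fam in ("annexin", "fragment"):
            if fam in self.models:
                out[fam] = classify_all(self.models[fam], x)
        for fam, mask in (("actin", small), ("podosome", ~small),
                          ("phago", ~small)):
            if fam in self.models:
                col = pd.Series(pd.NA, index=out.index, dtype=object)
                if mask.any():
                    col[mask] = classify_all(self.models[fam], x[mask.to_numpy()])
                out[fam] = col
        return out


def train_model_set(cells: pd.DataFrame, embeddings: np.ndarray,
                    families=MODEL_FAMILIES, seed: int = 0,
                    spec: SplitSpec | None = None,
                    **xgb_params) -> PhenotypeModelSet:
    """Train a boosted-tree model per family from truth-labeled cells.

    ``cells`` rows align with ``embeddings`` rows. Each family model is
    trained only on its eligible cells, with an 80/20 held-out evaluation.
    """
    spec = spec or SplitSpec(seed=seed)
    embeddings = np.asarray(embeddings, dtype=np.float64)
    pos = pd.Series(range(len(cells)), index=cells.index)
    models, metrics = {}, {}
    for fam in families:
        labels = family_labels(cells, fam)
        rows = pos.loc[labels.index].to_numpy()
        if len(rows) == 0 or labels.nunique() < 1:
            continue
        data = LabeledSet(cells.loc[labels.index, "cell_id"].to_numpy(),
                          embeddings[rows], labels.to_numpy())
        if len(data.classes) == 1 or min(
                np.unique(data.labels, return_counts=True)[1]) < 2:
            models[fam] = train_final(data, seed=seed, **xgb_params)
            continue
        train, test = split(data, spec)
        model = train_final(train, seed=seed, **xgb_params)
        metrics[fam] = evaluate(model, test)
        models[fam] = model
    return PhenotypeModelSet(models=models, metrics=metrics)
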