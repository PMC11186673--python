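"""The classification cascade: a gradient-boosted tree stage whose
positive-importance features ("probes contributing to classification") become
the input layer of a feed-forward neural network.

Training protocol:

* 25% stratified test split;
* boosted-tree stage — binary default 450 estimators / depth 10 / learning
  rate 0.189, multiclass default 800 estimators / depth 3 / same rate, both
  with 50% feature and 50% row subsampling;
* every feature with gain importance strictly > 0 is kept;
* the network trains with Adam and cross-entropy for the full epoch budget
  (default 500) on 70% of the training data, and the weights from the epoch
  with the highest accuracy on the remaining 30% validation split are kept
  (ties go to the earliest epoch).

The network is a plain numpy implementation (He init, inverted dropout,
minibatch Adam) so that training, checkpointing and prediction are exactly
reproducible from a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import train_test_split


class CascadeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Labeled data
# ---------------------------------------------------------------------------

NORMAL_CLASS = "normal"


@dataclass
class LabeledDataset:
    """M-value matrix (probes x samples) with per-sample class labels and
    train/test split flags."""

    m_values: pd.DataFrame
    labels: pd.Series
    split: pd.Series | None = None

    def __post_init__(self) -> None:
        samples = list(self.m_values.columns)
        if set(self.labels.index) != set(samples):
            raise CascadeError("labels must cover exactly the matrix samples")
        self.labels = self.labels.loc[samples]
        if self.split is None:
            self.split = pd.Series("train", index=samples)
        else:
            self.split = self.split.loc[samples]

    def matrix(self, split: str | None = None) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """(samples x features array, labels array, sample ids) for a split."""
        if split is None:
            ids = list(self.m_values.columns)
        else:
            ids = [s for s in self.m_values.columns if self.split[s] == split]
        X = self.m_values[ids].to_numpy(dtype=float).T
        y = self.labels.loc[ids].to_numpy()
        return X, y, ids

    @property
    def feature_ids(self) -> list[str]:
        return list(self.m_values.index)

    def restrict_features(self, probe_ids: list[str]) -> "LabeledDataset":
        missing = [p for p in probe_ids if p not in self.m_values.index]
        if missing:
            raise CascadeError(f"features not in matrix: {missing[:5]}...")
        return LabeledDataset(self.m_values.loc[list(probe_ids)],
                              self.labels, self.split)


def labels_for_task(metadata: pd.DataFrame, task: str) -> pd.Series:
    """Binary: cancer vs normal (adenomas labelled normal, as in independent
    cohorts).  Multiclass: cancer samples get their tissue class, every
    tissue's normals are pooled into one ``normal`` class."""
    cond = metadata["condition"]
    if task == "binary":
        labels = np.where(cond == "cancer", "cancer", NORMAL_CLASS)
    elif task == "multiclass":
        labels = np.where(cond == "cancer", metadata["tissue"], NORMAL_CLASS)
    else:
        raise CascadeError(f"unknown task {task!r}")
    return pd.Series(labels, index=metadata.index, name="label")


def split_train_test(dataset: LabeledDataset, test_fraction: float = 0.25,
                     seed: int = 0) -> LabeledDataset:
    """Stratified train/test assignment, deterministic given the seed."""
    counts = dataset.labels.value_counts()
    singletons = counts[counts < 2]
    if len(singletons):
        raise CascadeError(
            f"classes with a single sample cannot be split: {list(singletons.index)}")
    samples = np.array(dataset.m_values.columns)
    train_ids, test_ids = train_test_split(
        samples, test_size=test_fraction, random_state=int(seed) % 2**31,
        stratify=dataset.labels.loc[samples].to_numpy())
    split = pd.Series("train", index=samples)
    split.loc[test_ids] = "test"
    return LabeledDataset(dataset.m_values, dataset.labels, split)


# ---------------------------------------------------------------------------
# Boosted-tree stage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoostConfig:
    n_estimators: int
    max_depth: int
    learning_rate: float = 0.189
    feature_subsample: float = 0.5
    row_subsample: float = 0.5
    objective: str = "binary"
    seed: int = 0

    @classmethod
    def binary_default(cls, seed: int = 0) -> "BoostConfig":
        return cls(n_estimators=450, max_depth=10, objective="binary", seed=seed)

    @classmethod
    def multiclass_default(cls, seed: int = 0) -> "BoostConfig":
        return cls(n_estimators=800, max_depth=3, objective="multiclass", seed=seed)


@dataclass
class BoostStage:
    model: GradientBoostingClassifier
    feature_ids: list[str]
    classes: list[str]
    config: BoostConfig

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(X)

    @property
    def importances(self) -> np.ndarray:
        """Gain-style importances: total loss-impurity reduction per feature,
        normalized to sum to 1 over used features."""
        return self.model.feature_importances_


def train_boost(dataset: LabeledDataset, config: BoostConfig) -> BoostStage:
    X, y, _ = dataset.matrix("train")
    if X.shape[0] == 0:
        raise CascadeError("empty training split")
    if not np.isfinite(X).all():
        raise CascadeError("non-finite feature values in training data")
    classes = sorted(set(y))
    if len(classes) < 2:
        raise CascadeError(f"training labels are single-class: {classes}")
    model = GradientBoostingClassifier(
        n_estimators=config.n_estimators,
        max_depth=config.max_depth,
        learning_rate=config.learning_rate,
        subsample=config.row_subsample,
        max_features=config.feature_subsample,
        random_state=int(config.seed) % 2**31,
    )
    model.fit(X, y)
    return BoostStage(model=model, feature_ids=dataset.feature_ids,
                      classes=[str(c) for c in model.classes_], config=config)


@dataclass
class SelectedFeatures:
    """Probes with strictly positive gain importance, sorted by descending
    importance with ties broken by probe ID."""

    table: pd.DataFrame  # columns: probe_id, importance

    def __post_init__(self) -> None:
        if (self.table["importance"] <= 0).any():
            raise CascadeError("selected features must have importance > 0")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table["probe_id"])

    def __len__(self) -> int:
        return len(self.table)


def select_features(boost_stage: BoostStage) -> SelectedFeatures:
    imp = boost_stage.importances
    table = pd.DataFrame({"probe_id": boost_stage.feature_ids, "importance": imp})
    table = table[table["importance"] > 0.0]
    table = table.sort_values(["importance", "probe_id"],
                              ascending=[False, True], kind="mergesort")
    return SelectedFeatures(table=table.reset_index(drop=True))


# ---------------------------------------------------------------------------
# Feed-forward network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DNNConfig:
    hidden_layers: tuple[int, ...] = (256, 64)
    activation: str = "relu"
    dropout: float = 0.3
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 500
    validation_fraction: float = 0.30
    class_weighting: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "hidden_layers", tuple(self.hidden_layers))
        if self.max_epochs < 1:
            raise CascadeError("max_epochs must be >= 1")
        if not 0.0 < self.validation_fraction < 1.0:
            raise CascadeError("validation_fraction must lie in (0, 1)")
        if not 0.0 <= self.dropout < 1.0:
            raise CascadeError("dropout must lie in [0, 1)")


_ACTIVATIONS = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z, a: (z > 0).astype(float)),
    "tanh": (np.tanh, lambda z, a: 1.0 - a ** 2),
}


class MLP:
    """Minimal feed-forward network: He-initialized dense layers, softmax
    cross-entropy, inverted dropout, minibatch Adam.  Deterministic given the
    init/shuffle RNG."""

    def __init__(self, n_in: int, hidden: tuple[int, ...], n_out: int,
                 activation: str, rng: np.random.Generator):
        if activation not in _ACTIVATIONS:
            raise CascadeError(f"unknown activation {activation!r}")
        self.activation = activation
        sizes = [n_in, *hidden, n_out]
        self.W = [rng.normal(0.0, np.sqrt(2.0 / sizes[i]),
                             size=(sizes[i], sizes[i + 1]))
                  for i in range(len(sizes) - 1)]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        self._adam_m = [np.zeros_like(w) for w in self.W + self.b]
        self._adam_v = [np.zeros_like(w) for w in self.W + self.b]
        self._adam_t = 0

    # -- forward / backward -------------------------------------------------
    def _forward(self, X, dropout=0.0, rng=None):
        """Returns logits and a cache of
        (input a_prev, pre-activation z, pre-dropout activation, mask) per layer."""
        act, _ = _ACTIVATIONS[self.activation]
        a = X
        cache = []
        for layer, (W, b) in enumerate(zip(self.W, self.b)):
            z = a @ W + b
            if layer < len(self.W) - 1:
                a_pre = act(z)
                mask = None
                a_next = a_pre
                if dropout > 0.0 and rng is not None:
                    mask = (rng.random(a_pre.shape) >= dropout) / (1.0 - dropout)
                    a_next = a_pre * mask
            else:
                a_pre, mask, a_next = z, None, z  # logits
            cache.append((a, z, a_pre, mask))
            a = a_next
        return a, cache

    @staticmethod
    def _softmax(logits):
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits, _ = self._forward(X)
        return self._softmax(logits)

    def train_step(self, X, y_onehot, sample_weight, lr, dropout, rng):
        _, deriv = _ACTIVATIONS[self.activation]
        logits, cache = self._forward(X, dropout=dropout, rng=rng)
        probs = self._softmax(logits)
        w = sample_weight[:, None] / sample_weight.sum()
        delta = (probs - y_onehot) * w
        grads_W, grads_b = [None] * len(self.W), [None] * len(self.b)
        for layer in range(len(self.W) - 1, -1, -1):
            a_in = cache[layer][0]
            grads_W[layer] = a_in.T @ delta
            grads_b[layer] = delta.sum(axis=0)
            if layer > 0:
                _, z_prev, a_pre_prev, mask_prev = cache[layer - 1]
                delta = delta @ self.W[layer].T
                if mask_prev is not None:
                    delta = delta * mask_prev
                delta = delta * deriv(z_prev, a_pre_prev)
        self._adam_update(grads_W + grads_b, lr)
        # weighted cross-entropy for the batch
        eps = 1e-12
        return float(-(w * np.log(probs + eps) * y_onehot).sum())

    def _adam_update(self, grads, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        params = self.W + self.b
        self._adam_t += 1
        t = self._adam_t
        for p, g, m, v in zip(params, grads, self._adam_m, self._adam_v):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g ** 2
            mhat = m / (1 - beta1 ** t)
            vhat = v / (1 - beta2 ** t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- checkpointing ------------------------------------------------------
    def get_weights(self):
        return ([w.copy() for w in self.W], [b.copy() for b in self.b])

    def set_weights(self, weights):
        W, b = weights
        self.W = [w.copy() for w in W]
        self.b = [x.copy() for x in b]


@dataclass
class DNNStage:
    net: MLP
    feature_ids: list[str]
    classes: list[str]
    config: DNNConfig
    manifest: dict = field(default_factory=dict)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        # M-values are already on a common log2 scale; fed to the net raw
        return self.net.predict_proba(X)


def _accuracy_evaluator(stage_predict, X_val, y_val) -> float:
    probs = stage_predict(X_val)
    return float((probs.argmax(axis=1) == y_val).mean())


def train_dnn(dataset: LabeledDataset, config: DNNConfig,
              evaluator=None) -> DNNStage:
    """Train the network on the training split, checkpointing the epoch with
    the best validation accuracy.

    ``evaluator(predict_fn, X_val, y_val_codes) -> float`` may be injected
    (e.g. for testing the argmax contract); the default computes plain
    accuracy.  Training always runs for the full ``max_epochs``; the returned
    stage carries the weights of the best epoch (1-based ``best_epoch`` in the
    manifest; ties resolved to the earliest epoch).
    """
    if dataset.m_values.shape[0] < 1:
        raise CascadeError(
            "empty feature selection: inspect the boost stage importances")
    X, y, _ = dataset.matrix("train")
    classes = sorted(set(y))
    if len(classes) < 2:
        raise CascadeError("need at least 2 classes to train")
    codes = np.array([classes.index(v) for v in y])
    seed = int(config.seed) % 2**31
    idx_train, idx_val = train_test_split(
        np.arange(len(y)), test_size=config.validation_fraction,
        random_state=seed, stratify=codes)
    X_tr, y_tr = X[idx_train], codes[idx_train]
    X_val, y_val = X[idx_val], codes[idx_val]

    onehot = np.eye(len(classes))[y_tr]
    if config.class_weighting:
        freq = np.bincount(y_tr, minlength=len(classes)).astype(float)
        class_w = freq.sum() / (len(classes) * np.maximum(freq, 1.0))
        sample_w = class_w[y_tr]
    else:
        sample_w = np.ones(len(y_tr))

    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    net = MLP(X.shape[1], tuple(config.hidden_layers), len(classes),
              config.activation, rng)
    evaluator = evaluator or _accuracy_evaluator

    best_acc, best_epoch, best_weights = -np.inf, 0, net.get_weights()
    val_history = []
    n = len(y_tr)
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = order[start:start + config.batch_size]
            net.train_step(X_tr[batch], onehot[batch], sample_w[batch],
                           config.learning_rate, config.dropout, rng)
        acc = float(evaluator(net.predict_proba, X_val, y_val))
        val_history.append(acc)
        if acc > best_acc:  # strict: ties keep the earliest epoch
            best_acc, best_epoch = acc, epoch
            best_weights = net.get_weights()
    net.set_weights(best_weights)
    manifest = {"validation_accuracy": val_history, "best_epoch": best_epoch,
                "best_validation_accuracy": best_acc,
                "n_train": int(len(idx_train)), "n_validation": int(len(idx_val))}
    return DNNStage(net=net, feature_ids=dataset.feature_ids, classes=classes,
                    config=config, manifest=manifest)


def hyperparameter_search(dataset: LabeledDataset, search_space,
                          budget: int, seed: int = 0) -> tuple[DNNConfig, pd.DataFrame]:
    """Evaluate up to ``budget`` configurations with the 30%-validation
    protocol and return the one with the highest validation accuracy, plus the
    full trial log."""
    space = list(search_space)
    if not space:
        raise CascadeError("empty hyperparameter search space")
    if len(space) > budget:
        rng = np.random.default_rng(int(seed) % 2**31)
        space = [space[i] for i in rng.choice(len(space), size=budget, replace=False)]
    rows, best = [], None
    for i, config in enumerate(space):
        stage = train_dnn(dataset, config)
        acc = stage.manifest["best_validation_accuracy"]
        rows.append({"trial": i, "config": config, "validation_accuracy": acc,
                     "best_epoch": stage.manifest["best_epoch"]})
        if best is None or acc > best[0]:
            best = (acc, config)
    return best[1], pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cascade assembly and prediction
# ---------------------------------------------------------------------------

@dataclass
class CascadeModel:
    boost_stage: BoostStage
    selected: SelectedFeatures
    dnn_stage: DNNStage
    class_names: list[str]
    training_manifest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dnn_stage.feature_ids != self.selected.probe_ids:
            raise CascadeError(
                "network input features differ from the selected feature set")


def train_cascade(dataset: LabeledDataset, boost_config: BoostConfig,
                  dnn_config: DNNConfig) -> CascadeModel:
    """Boost -> gate on importance > 0 -> network, on the training split."""
    boost_stage = train_boost(dataset, boost_config)
    selected = select_features(boost_stage)
    if len(selected) == 0:
        raise CascadeError(
            "boost stage selected no features (all importances zero)")
    gated = dataset.restrict_features(selected.probe_ids)
    dnn_stage = train_dnn(gated, dnn_config)
    manifest = {
        "boost_config": asdict(boost_config),
        "dnn_config": {**asdict(dnn_config),
                       "hidden_layers": list(dnn_config.hidden_layers)},
        "n_selected": len(selected),
        "best_epoch": dnn_stage.manifest["best_epoch"],
    }
    return CascadeModel(boost_stage=boost_stage, selected=selected,
                        dnn_stage=dnn_stage, class_names=list(dnn_stage.classes),
                        training_manifest=manifest)


def _align(m_values: pd.DataFrame, feature_ids: list[str],
           fill_missing: bool) -> np.ndarray:
    missing = [p for p in feature_ids if p not in m_values.index]
    if missing and not fill_missing:
        raise CascadeError(f"input lacks {len(missing)} model features, e.g. "
                           f"{missing[:5]}")
    aligned = m_values.reindex(index=feature_ids).fillna(0.0)  # M=0 <=> beta 0.5
    return aligned.to_numpy(dtype=float).T


def predict(model, m_values: pd.DataFrame,
            fill_missing: bool = True) -> tuple[pd.DataFrame, pd.Series]:
    """Class probabilities (samples x classes, rows sum to 1) and argmax
    labels for a cascade or a bare boost stage.  Probes absent from the input
    are filled at M=0 (the beta=0.5 missing-data policy); pass
    ``fill_missing=False`` to error on missing probes instead."""
    if isinstance(model, CascadeModel):
        X = _align(m_values, model.selected.probe_ids, fill_missing)
        probs = model.dnn_stage.predict_proba(X)
        classes = model.class_names
    elif isinstance(model, BoostStage):
        X = _align(m_values, model.feature_ids, fill_missing)
        probs = model.predict_proba(X)
        classes = model.classes
    elif isinstance(model, DNNStage):
        X = _align(m_values, model.feature_ids, fill_missing)
        probs = model.predict_proba(X)
        classes = model.classes
    else:
        raise CascadeError(f"cannot predict with {type(model).__name__}")
    samples = list(m_values.columns)
    probs_df = pd.DataFrame(probs, index=samples, columns=classes)
    labels = pd.Series([classes[i] for i in probs.argmax(axis=1)],
                       index=samples, name="label")
    return probs_df, labels


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_model(model: CascadeModel, outdir) -> None:
    """Write manifest JSON + native serializations of the two stages."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "schema_version": 1,
        "class_names": model.class_names,
        "boost": {"config": asdict(model.boost_stage.config),
                  "feature_ids": model.boost_stage.feature_ids,
                  "classes": model.boost_stage.classes},
        "dnn": {"config": {**asdict(model.dnn_stage.config),
                           "hidden_layers": list(model.dnn_stage.config.hidden_layers)},
                "classes": model.dnn_stage.classes,
                "manifest": model.dnn_stage.manifest},
        "selected": model.selected.table.to_dict(orient="list"),
        "training_manifest": model.training_manifest,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    joblib.dump(model.boost_stage.model, outdir / "boost_stage.joblib")
    arrays = {}
    for i, (w, b) in enumerate(zip(model.dnn_stage.net.W, model.dnn_stage.net.b)):
        arrays[f"W{i}"] = w
        arrays[f"b{i}"] = b
    np.savez(outdir / "dnn_stage.npz", **arrays)


def load_model(indir) -> CascadeModel:
    indir = Path(indir)
    with open(indir / "manifest.json") as fh:
        manifest = json.load(fh)
    boost_cfg = BoostConfig(**manifest["boost"]["config"])
    boost_stage = BoostStage(model=joblib.load(indir / "boost_stage.joblib"),
                             feature_ids=manifest["boost"]["feature_ids"],
                             classes=manifest["boost"]["classes"],
                             config=boost_cfg)
    selected = SelectedFeatures(pd.DataFrame(manifest["selected"]))
    dnn_raw = dict(manifest["dnn"]["config"])
    dnn_raw["hidden_layers"] = tuple(dnn_raw["hidden_layers"])
    dnn_cfg = DNNConfig(**dnn_raw)
    data = np.load(indir / "dnn_stage.npz")
    n_layers = sum(1 for k in data.files if k.startswith("W"))
    classes = manifest["dnn"]["classes"]
    net = MLP(data["W0"].shape[0], tuple(dnn_cfg.hidden_layers), len(classes),
              dnn_cfg.activation, np.random.default_rng(0))
    net.set_weights(([data[f"W{i}"] for i in range(n_layers)],
                     [data[f"b{i}"] for i in range(n_layers)]))
    dnn_stage = DNNStage(net=net, feature_ids=selected.probe_ids,
                         classes=classes, config=dnn_cfg,
                         manifest=manifest["dnn"]["manifest"])
    return CascadeModel(boost_stage=boost_stage, selected=selected,
                        dnn_stage=dnn_stage, class_names=manifest["class_names"],
                        training_manifest=manifest["training_manifest"])
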