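"""Training protocol and imbalanced-multi-class evaluation.

Per-class metrics are computed one-vs-rest from the confusion matrix:

    ACC_i = (TP_i + TN_i) / (TP_i + TN_i + FP_i + FN_i)
    PPV_i = TP_i / (TP_i + FP_i)
    SE_i  = TP_i / (TP_i + FN_i)
    F1_i  = 2 * PPV_i * SE_i / (PPV_i + SE_i)

reported in percent with macro averages (unweighted class means).  A
ratio with zero denominator is reported as 0 and flagged.  Splitting and
k-fold cross-validation are stratified so the rare fusion-beat class is
represented in every partition; class imbalance is otherwise left
untouched — no reweighting or resampling — because the architecture
itself is the imbalance treatment under study.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .network import ModelConfig, ParallelCrossNetwork, build_model

__all__ = [
    "AAMI_CLASSES",
    "LEARNING_RATE_GRID",
    "TrainConfig",
    "Dataset",
    "ConfusionMatrix",
    "ClassMetrics",
    "split_dataset",
    "train",
    "evaluate",
    "compute_metrics",
    "kfold_cv",
    "sweep_learning_rates",
    "sweep_wavelets",
]

AAMI_CLASSES = ("NB", "SVEB", "VEB", "FB")
#: learning-rate grid of the training protocol
LEARNING_RATE_GRID = (5e-4, 1e-4, 5e-5)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol: Adam + categorical cross-entropy."""

    batch_size: int = 512
    learning_rate: float = 1e-4
    epochs: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class Dataset:
    """Model-ready beats: waveforms, scalogram images and integer labels."""

    beats: np.ndarray        # (n, seq_len)
    scalograms: np.ndarray   # (n, h, w)
    labels: np.ndarray       # (n,) integer class indices
    class_names: tuple[str, ...] = AAMI_CLASSES

    def __post_init__(self) -> None:
        self.beats = np.asarray(self.beats, dtype=float)
        self.scalograms = np.asarray(self.scalograms, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n = self.labels.size
        if self.beats.shape[0] != n or self.scalograms.shape[0] != n:
            raise ValueError("beats, scalograms and labels must align")

    def __len__(self) -> int:
        return self.labels.size

    def one_hot(self) -> np.ndarray:
        k = len(self.class_names)
        out = np.zeros((len(self), k))
        out[np.arange(len(self)), self.labels] = 1.0
        return out

    def subset(self, idx) -> "Dataset":
        idx = np.asarray(idx)
        return Dataset(self.beats[idx], self.scalograms[idx], self.labels[idx],
                       self.class_names)

    def class_counts(self) -> dict[str, int]:
        return {
            name: int((self.labels == i).sum())
            for i, name in enumerate(self.class_names)
        }


@dataclass
class ConfusionMatrix:
    """K x K prediction counts; rows = true class, columns = predicted."""

    counts: np.ndarray
    class_names: tuple[str, ...] = AAMI_CLASSES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_names)
        if self.counts.shape != (k, k):
            raise ValueError(f"expected a {k}x{k} matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, i: int) -> tuple[int, int, int, int]:
        """(TP, FP, TN, FN) for class index ``i``."""
        tp = int(self.counts[i, i])
        fp = int(self.counts[:, i].sum() - tp)
        fn = int(self.counts[i, :].sum() - tp)
        tn = self.total - tp - fp - fn
        return tp, fp, tn, fn

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.class_names),
                            columns=list(self.class_names))


@dataclass
class ClassMetrics:
    """Per-class and macro ACC/PPV/SE/F1, in percent."""

    per_class: pd.DataFrame   # index class, columns ACC/PPV/SE/F1
    macro: pd.Series
    undefined: list[tuple[str, str]] = field(default_factory=list)

    def round2(self) -> "ClassMetrics":
        return ClassMetrics(self.per_class.round(2), self.macro.round(2),
                            self.undefined)


def split_dataset(dataset: Dataset, train_frac: float = 0.8, seed: int = 0):
    """Stratified train/test split; per-class fractions within 1 sample."""
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be strictly between 0 and 1")
    counts = dataset.class_counts()
    for name, c in counts.items():
        if c < 2:
            raise ValueError(f"class {name!r} has {c} sample(s); need at least 2")
    idx = np.arange(len(dataset))
    tr_idx, te_idx = train_test_split(
        idx, train_size=train_frac, stratify=dataset.labels, random_state=seed
    )
    return dataset.subset(np.sort(tr_idx)), dataset.subset(np.sort(te_idx))


def _cross_entropy(probs: np.ndarray, onehot: np.ndarray) -> float:
    p = np.clip(probs, 1e-12, None)
    return float(-(onehot * np.log(p)).sum(axis=1).mean())


def train(
    model: ParallelCrossNetwork,
    train_set: Dataset,
    cfg: TrainConfig | None = None,
    val_set: Dataset | None = None,
    verbose: bool = False,
) -> pd.DataFrame:
    """Mini-batch Adam training; returns a per-epoch history table.

    History columns: ``loss``/``accuracy`` on the training set (running
    mean over the epoch's batches) and ``val_loss``/``val_accuracy`` on
    ``val_set`` when given, for convergence-curve plots.
    """
    cfg = cfg or TrainConfig()
    if train_set.beats.shape[1] != model.cfg.seq_len or (
        train_set.scalograms.shape[1:3] != tuple(model.cfg.image_shape)
    ):
        raise ValueError(
            "dataset shapes do not match the model inputs: "
            f"beats {train_set.beats.shape[1:]} vs seq_len {model.cfg.seq_len}, "
            f"scalograms {train_set.scalograms.shape[1:]} vs "
            f"image {model.cfg.image_shape}"
        )
    rng = np.random.default_rng(cfg.seed)
    opt = model.make_optimizer(cfg.learning_rate)
    y = train_set.one_hot()
    n = len(train_set)
    rows = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses, hits, seen = [], 0, 0
        for lo in range(0, n, cfg.batch_size):
            sel = order[lo : lo + cfg.batch_size]
            yb = y[sel]
            probs = model.forward(train_set.beats[sel], train_set.scalograms[sel],
                                  training=True)
            losses.append(_cross_entropy(probs, yb) * len(sel))
            hits += int((probs.argmax(axis=1) == yb.argmax(axis=1)).sum())
            seen += len(sel)
            opt.zero_grad()
            model.backward((probs - yb) / len(sel))
            opt.step()
        row = {"epoch": epoch + 1, "loss": sum(losses) / seen,
               "accuracy": hits / seen}
        if val_set is not None:
            vprobs = model.predict_proba(val_set.beats, val_set.scalograms)
            row["val_loss"] = _cross_entropy(vprobs, val_set.one_hot())
            row["val_accuracy"] = float(
                (vprobs.argmax(axis=1) == val_set.labels).mean()
            )
        rows.append(row)
        if verbose:
            print("  " + "  ".join(f"{k}={v:.4f}" if k != "epoch" else f"epoch {v}"
                                   for k, v in row.items()))
    return pd.DataFrame(rows)


def evaluate(model: ParallelCrossNetwork, test_set: Dataset) -> ConfusionMatrix:
    """Argmax predictions on a test set; ties break toward the lower index."""
    if len(test_set) == 0:
        raise ValueError("test set is empty")
    probs = model.predict_proba(test_set.beats, test_set.scalograms)
    pred = probs.argmax(axis=1)  # np.argmax returns the first (lowest) maximum
    k = len(test_set.class_names)
    counts = np.zeros((k, k), dtype=int)
    np.add.at(counts, (test_set.labels, pred), 1)
    return ConfusionMatrix(counts, test_set.class_names)


def compute_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """One-vs-rest ACC/PPV/SE/F1 per class plus macro averages (percent)."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    rows, undefined = {}, []

    def ratio(num, den, cls, name):
        if den == 0:
            undefined.append((cls, name))
            return 0.0
        return 100.0 * num / den

    for i, name in enumerate(cm.class_names):
        tp, fp, tn, fn = cm.one_vs_rest(i)
        acc = ratio(tp + tn, tp + tn + fp + fn, name, "ACC")
        ppv = ratio(tp, tp + fp, name, "PPV")
        se = ratio(tp, tp + fn, name, "SE")
        if ppv + se == 0:
            f1 = 0.0
            undefined.append((name, "F1"))
        else:
            f1 = 2 * ppv * se / (ppv + se)
        rows[name] = {"ACC": acc, "PPV": ppv, "SE": se, "F1": f1}
    per_class = pd.DataFrame(rows).T[["ACC", "PPV", "SE", "F1"]]
    return ClassMetrics(per_class=per_class, macro=per_class.mean(axis=0),
                        undefined=undefined)


def kfold_cv(
    dataset: Dataset,
    k: int = 10,
    model_factory=None,
    cfg: TrainConfig | None = None,
) -> pd.DataFrame:
    """Stratified k-fold cross-validation with a fresh model per fold.

    Returns a table with one row per fold and an ``Average`` row; columns
    are a (class, metric) MultiIndex over PPV/SE/F1.
    """
    cfg = cfg or TrainConfig()
    counts = dataset.class_counts()
    for name, c in counts.items():
        if c < k:
            raise ValueError(f"class {name!r} has {c} sample(s) but k={k}")
    if model_factory is None:
        model_factory = lambda: build_model(ModelConfig(), seed=cfg.seed)[0]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=cfg.seed)
    rows = []
    for fold, (tr_idx, te_idx) in enumerate(
        skf.split(dataset.beats, dataset.labels), start=1
    ):
        model = model_factory()
        train(model, dataset.subset(tr_idx), cfg)
        metrics = compute_metrics(evaluate(model, dataset.subset(te_idx)))
        row = {}
        for cls in dataset.class_names:
            for m in ("PPV", "SE", "F1"):
                row[(cls, m)] = metrics.per_class.loc[cls, m]
        rows.append(pd.Series(row, name=f"Fold = {fold}"))
    table = pd.DataFrame(rows)
    table.columns = pd.MultiIndex.from_tuples(table.columns)
    table.loc["Average"] = table.mean(axis=0)
    return table


def sweep_learning_rates(
    make_model,
    train_set: Dataset,
    test_set: Dataset,
    cfg: TrainConfig | None = None,
    learning_rates=LEARNING_RATE_GRID,
) -> dict[float, dict]:
    """Train/evaluate once per learning rate; one result set per rate."""
    cfg = cfg or TrainConfig()
    results = {}
    for lr in learning_rates:
        model = make_model()
        history = train(model, train_set, replace(cfg, learning_rate=lr),
                        val_set=test_set)
        cm = evaluate(model, test_set)
        results[lr] = {"history": history, "confusion": cm,
                       "metrics": compute_metrics(cm)}
    return results


def sweep_wavelets(
    make_dataset,
    make_model,
    cfg: TrainConfig | None = None,
    wavelets=("gaus8", "gaus4", "mexh", "morl"),
    train_frac: float = 0.8,
) -> dict[str, dict]:
    """Re-derive scalograms per mother wavelet and evaluate each.

    ``make_dataset(wavelet)`` must return a :class:`Dataset` whose
    scalograms were computed with that wavelet (the beats and labels are
    expected to be shared).
    """
    cfg = cfg or TrainConfig()
    results = {}
    for wavelet in wavelets:
        ds = make_dataset(wavelet)
        tr, te = split_dataset(ds, train_frac=train_frac, seed=cfg.seed)
        model = make_model()
        history = train(model, tr, cfg)
        cm = evaluate(model, te)
        results[wavelet] = {"history": history, "confusion": cm,
                            "metrics": compute_metrics(cm)}
    return results
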