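"""The residual convolutional insertion-site classifier.

Architecture (defaults): a one-hot 100×4 input enters a stem convolution
(128 filters, kernel 4, stride 1, valid → length 97) with batch
normalization and ReLU, followed by four residual blocks — each two
Conv+BN+ReLU sub-blocks (length-preserving padding) whose input is added
to their output through a skip connection — each block followed by
dropout (rates 0.1, 0.1, 0.25, 0.5).  No pooling anywhere.  The feature
map is flattened into a 128-unit dense ReLU layer and a single sigmoid
output unit.  The default configuration has exactly 2,119,297 trainable
parameters (batch-norm scale/offset count as trainable, running
statistics do not).

Training is plain SGD on binary cross-entropy (defaults: batch 120,
learning rate 0.001), with optional on-the-fly window-shift/substitution
augmentation of training batches only.  Evaluation provides ROC/AUC,
precision-recall/AP, accuracy, the Youden operating threshold, the paired
DeLong AUC test, and per-group AUC tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn import metrics as skm

from . import nn
from .dataset import SampleSet, TrainingAugmenter
from .seq_core import CHANNELS, DnaSequence

logger = logging.getLogger(__name__)

DEFAULT_DROPOUT = (0.1, 0.1, 0.25, 0.5)


class ModelConfigError(ValueError):
    pass


class TrainingDivergedError(RuntimeError):
    pass


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters of the classifier."""

    n_res_blocks: int = 4
    use_skip_connections: bool = True
    filters: int = 128
    kernel_width: int = 4
    stride: int = 1
    dropout_rates: tuple[float, ...] = DEFAULT_DROPOUT
    dense_units: int = 128
    input_length: int = 100

    def __post_init__(self) -> None:
        if not 1 <= self.n_res_blocks <= 4:
            raise ModelConfigError("n_res_blocks must lie in [1, 4]")
        if len(self.dropout_rates) != self.n_res_blocks:
            raise ModelConfigError("need one dropout rate per residual block")
        if self.kernel_width > self.input_length:
            raise ModelConfigError("kernel_width cannot exceed input_length")
        if self.stride != 1:
            raise ModelConfigError("only stride 1 is supported")

    @property
    def stem_length(self) -> int:
        """Feature-map length after the valid stem convolution."""
        return self.input_length - self.kernel_width + 1


def k_block_spec(k: int, use_skip_connections: bool = True) -> ModelSpec:
    """The k-residual-block ablation variant.

    Dropout rates are the last k of (0.1, 0.1, 0.25, 0.5), keeping the
    strong 0.5 rate in front of the classifier head.
    """
    return ModelSpec(
        n_res_blocks=k,
        use_skip_connections=use_skip_connections,
        dropout_rates=DEFAULT_DROPOUT[-k:],
    )


def cnn_spec() -> ModelSpec:
    """The skip-free control: same stack with skip connections removed."""
    return ModelSpec(use_skip_connections=False)


class _ResidualBlock:
    def __init__(self, filters: int, kernel: int, dropout: float, skip: bool,
                 rng: np.random.Generator):
        pad = ((kernel - 1) // 2, kernel // 2)  # length-preserving for stride 1
        self.conv1 = nn.Conv1D(filters, filters, kernel, pad, rng)
        self.bn1 = nn.BatchNorm(filters)
        self.relu1 = nn.ReLU()
        self.conv2 = nn.Conv1D(filters, filters, kernel, pad, rng)
        self.bn2 = nn.BatchNorm(filters)
        self.relu2 = nn.ReLU()
        self.dropout = nn.Dropout(dropout)
        self.skip = skip

    def layers(self):
        return [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2, self.relu2, self.dropout]

    def forward(self, x, training, rng):
        h = self.conv1.forward(x, training)
        h = self.bn1.forward(h, training)
        h = self.relu1.forward(h, training)
        h = self.conv2.forward(h, training)
        h = self.bn2.forward(h, training)
        h = self.relu2.forward(h, training)
        out = h + x if self.skip else h
        return self.dropout.forward(out, training, rng)

    def backward(self, grad):
        g = self.dropout.backward(grad)
        h = self.relu2.backward(g)
        h = self.bn2.backward(h)
        h = self.conv2.backward(h)
        h = self.relu1.backward(h)
        h = self.bn1.backward(h)
        h = self.conv1.backward(h)
        return h + g if self.skip else h


class HgtClassifier:
    """The residual network with its weights and training history."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.stem_conv = nn.Conv1D(4, spec.filters, spec.kernel_width, (0, 0), rng)
        self.stem_bn = nn.BatchNorm(spec.filters)
        self.stem_relu = nn.ReLU()
        self.blocks = [
            _ResidualBlock(spec.filters, spec.kernel_width, rate, spec.use_skip_connections, rng)
            for rate in spec.dropout_rates
        ]
        self.dense1 = nn.Dense(spec.stem_length * spec.filters, spec.dense_units, rng, init="he")
        self.relu_d = nn.ReLU()
        self.head = nn.Dense(spec.dense_units, 1, rng, init="glorot")
        self.history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}

    # -- plumbing -----------------------------------------------------------

    def _all_layers(self):
        layers = [self.stem_conv, self.stem_bn, self.stem_relu]
        for b in self.blocks:
            layers.extend(b.layers())
        layers.extend([self.dense1, self.relu_d, self.head])
        return layers

    def count_parameters(self) -> int:
        """Number of trainable parameters (conv/dense weights and biases,
        batch-norm scale and offset; running statistics excluded)."""
        return int(sum(v.size for layer in self._all_layers() for _, v, _ in layer.params()))

    # -- forward / backward -------------------------------------------------

    def forward_logits(self, x: np.ndarray, training: bool = False,
                       rng: "np.random.Generator | None" = None,
                       stem_mask: "np.ndarray | None" = None) -> np.ndarray:
        """Logits for a (B, L, 4) one-hot batch.

        ``stem_mask`` is a boolean vector over the 97 stem feature-map
        positions; masked positions are zeroed after the stem's BN+ReLU, the
        interception point of the occlusion attribution statistic.
        """
        h = self.stem_conv.forward(x, training)
        h = self.stem_bn.forward(h, training)
        h = self.stem_relu.forward(h, training)
        if stem_mask is not None:
            h = h.copy()
            h[:, np.asarray(stem_mask, dtype=bool), :] = 0.0
        for block in self.blocks:
            h = block.forward(h, training, rng)
        flat = h.reshape(h.shape[0], -1)
        d = self.dense1.forward(flat, training)
        d = self.relu_d.forward(d, training)
        return self.head.forward(d, training)

    def _backward(self, dlogits: np.ndarray) -> None:
        g = self.head.backward(dlogits)
        g = self.relu_d.backward(g)
        g = self.dense1.backward(g)
        g = g.reshape(g.shape[0], self.spec.stem_length, self.spec.filters)
        for block in reversed(self.blocks):
            g = block.backward(g)
        g = self.stem_relu.backward(g)
        g = self.stem_bn.backward(g)
        self.stem_conv.backward(g)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256,
                      stem_mask: "np.ndarray | None" = None) -> np.ndarray:
        """Probabilities in (0, 1) for a (N, L, 4) one-hot array.

        Inference mode: dropout off, batch-norm running statistics — the
        result is independent of batch size and of other rows.
        """
        out = np.empty(x.shape[0], dtype=np.float64)
        for i in range(0, x.shape[0], batch_size):
            z = self.forward_logits(x[i : i + batch_size], training=False, stem_mask=stem_mask)
            out[i : i + batch_size] = nn.sigmoid(z).ravel()
        return out

    # -- persistence --------------------------------------------------------

    def save(self, path: "str | Path") -> None:
        arrays: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self._all_layers()):
            for name, value, _ in layer.params():
                arrays[f"layer{i}_{name}"] = value
            if isinstance(layer, nn.BatchNorm):
                arrays[f"layer{i}_running_mean"] = layer.running_mean
                arrays[f"layer{i}_running_var"] = layer.running_var
        meta = json.dumps({"spec": dataclasses.asdict(self.spec), "history": self.history})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: "str | Path") -> "HgtClassifier":
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        spec_d = meta["spec"]
        spec_d["dropout_rates"] = tuple(spec_d["dropout_rates"])
        model = cls(ModelSpec(**spec_d))
        model.history = {k: list(v) for k, v in meta["history"].items()}
        for i, layer in enumerate(model._all_layers()):
            for name, value, _ in layer.params():
                value[...] = data[f"layer{i}_{name}"]
            if isinstance(layer, nn.BatchNorm):
                layer.running_mean = data[f"layer{i}_running_mean"]
                layer.running_var = data[f"layer{i}_running_var"]
        return model


def build_model(spec: "ModelSpec | None" = None, seed: int = 0) -> HgtClassifier:
    """Build an untrained classifier from an architecture spec."""
    return HgtClassifier(spec or ModelSpec(), seed=seed)


def count_trainable_parameters(model: HgtClassifier) -> int:
    return model.count_parameters()


# ---------------------------------------------------------------------------
# encoding and training


@dataclasses.dataclass
class TrainConfig:
    """Optimization hyperparameters (defaults: SGD, batch 120, lr 0.001)."""

    batch_size: int = 120
    learning_rate: float = 0.001
    epochs: int = 10
    seed: int = 0
    augment: bool = False
    max_shift: int = 5
    max_changes: int = 10

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ModelConfigError("batch_size must be ≥ 1")
        if self.learning_rate <= 0:
            raise ModelConfigError("learning_rate must be > 0")
        if self.epochs < 0:
            raise ModelConfigError("epochs must be ≥ 0")


_ENCODE_LUT = np.zeros((256, 4), dtype=np.float32)
for _i, _b in enumerate(CHANNELS):
    _ENCODE_LUT[ord(_b), _i] = 1.0


def encode_sequences(seqs: Sequence[str], expected_length: Optional[int] = None) -> np.ndarray:
    """Vectorized one-hot encoding of equal-length sequence strings."""
    if len(seqs) == 0:
        raise ValueError("no sequences to encode")
    length = len(seqs[0])
    if expected_length is not None and length != expected_length:
        raise ValueError(f"sequence 0 has length {length}, expected {expected_length}")
    buf = "".join(seqs)
    if len(buf) != length * len(seqs):
        for i, s in enumerate(seqs):
            if len(s) != length:
                raise ValueError(f"sequence {i} has length {len(s)}, expected {length}")
    codes = np.frombuffer(buf.encode("ascii"), dtype=np.uint8).reshape(len(seqs), length)
    return _ENCODE_LUT[codes]


def _as_onehot(sequences, input_length: int) -> np.ndarray:
    if isinstance(sequences, np.ndarray):
        if sequences.ndim != 3 or sequences.shape[1] != input_length or sequences.shape[2] != 4:
            raise ValueError(
                f"expected a (N, {input_length}, 4) one-hot array, got {sequences.shape}"
            )
        return sequences.astype(np.float32, copy=False)
    if isinstance(sequences, SampleSet):
        strs = sequences.sequences()
        ids = [s.sequence.id for s in sequences]
    else:
        strs, ids = [], []
        for i, s in enumerate(sequences):
            if isinstance(s, DnaSequence):
                strs.append(s.bases)
                ids.append(s.id)
            else:
                strs.append(str(s).upper())
                ids.append(f"record {i}")
    for i, s in enumerate(strs):
        if len(s) != input_length:
            raise ValueError(
                f"{ids[i]}: length {len(s)} does not match the model input length {input_length}"
            )
    return encode_sequences(strs, input_length)


def predict(model: HgtClassifier, sequences, batch_size: int = 256) -> np.ndarray:
    """Predicted insertion-site probabilities for 100-nt sequences.

    Accepts a :class:`SampleSet`, an iterable of strings or
    :class:`DnaSequence`, or a pre-encoded (N, L, 4) array.
    """
    x = _as_onehot(sequences, model.spec.input_length)
    return model.predict_proba(x, batch_size=batch_size)


def train(
    model: HgtClassifier,
    train_set: SampleSet,
    val_set: Optional[SampleSet],
    config: TrainConfig,
    refs=None,
) -> HgtClassifier:
    """Fit with plain SGD on binary cross-entropy.

    Augmentation (when enabled) perturbs training batches only, freshly
    each epoch; validation windows are never augmented.  Per-epoch mean
    training loss and validation loss are appended to ``model.history``,
    so successive calls continue training.  Deterministic under
    ``config.seed``.
    """
    if len(train_set) == 0:
        raise ValueError("empty training set")
    if config.epochs == 0:
        return model
    rng = np.random.default_rng(config.seed)
    augmenter = (
        TrainingAugmenter(refs, config.max_shift, config.max_changes) if config.augment else None
    )
    y_train = train_set.labels().astype(np.float32)
    base_sequences = train_set.sequences()
    x_static = None
    if augmenter is None:
        x_static = encode_sequences(base_sequences, model.spec.input_length)
    x_val = y_val = None
    if val_set is not None and len(val_set):
        x_val = encode_sequences(val_set.sequences(), model.spec.input_length)
        y_val = val_set.labels().astype(np.float32)

    optimizer = nn.SGD(model._all_layers(), config.learning_rate)
    n = len(train_set)
    for epoch in range(config.epochs):
        if augmenter is not None:
            x_epoch = encode_sequences(
                augmenter.augment_epoch(train_set.samples, rng), model.spec.input_length
            )
        else:
            x_epoch = x_static
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            z = model.forward_logits(x_epoch[idx], training=True, rng=rng)
            loss, dz = nn.bce_with_logits(z, y_train[idx])
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite training loss at epoch {epoch + 1}; "
                    "reduce the learning rate"
                )
            losses.append(loss)
            model._backward(dz)
            optimizer.step()
        model.history["train_loss"].append(float(np.mean(losses)))
        if x_val is not None:
            z = np.concatenate(
                [
                    model.forward_logits(x_val[i : i + 512], training=False)
                    for i in range(0, x_val.shape[0], 512)
                ]
            )
            val_loss, _ = nn.bce_with_logits(z, y_val)
            model.history["val_loss"].append(val_loss)
            logger.info(
                "epoch %d: train loss %.4f, val loss %.4f",
                len(model.history["train_loss"]),
                model.history["train_loss"][-1],
                val_loss,
            )
        else:
            logger.info(
                "epoch %d: train loss %.4f",
                len(model.history["train_loss"]),
                model.history["train_loss"][-1],
            )
    return model


# ---------------------------------------------------------------------------
# evaluation


@dataclasses.dataclass
class EvalReport:
    """Classification metrics on a labeled set."""

    auc: float
    ap: float
    accuracy: float
    roc: pd.DataFrame  # columns fpr, tpr, threshold
    pr: pd.DataFrame  # columns precision, recall, threshold
    youden_threshold: float

    def to_json(self, path: "str | Path") -> None:
        payload = {
            "auc": self.auc,
            "ap": self.ap,
            "accuracy": self.accuracy,
            "youden_threshold": self.youden_threshold,
            "roc": self.roc.to_dict(orient="list"),
            "pr": self.pr.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _check_two_classes(labels: np.ndarray) -> None:
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present (AUC is undefined otherwise)")


def evaluate(preds, labels, threshold: float = 0.5) -> EvalReport:
    """ROC-AUC, average precision, accuracy and operating points.

    AUC equals the Mann–Whitney pair-counting statistic (ties count ½);
    AP is the step-wise precision-recall summation Σ (Rₙ − Rₙ₋₁)·Pₙ.
    """
    preds = np.asarray(preds, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if preds.shape != labels.shape:
        raise ValueError("preds and labels must have equal length")
    _check_two_classes(labels)
    fpr, tpr, roc_thr = skm.roc_curve(labels, preds)
    precision, recall, pr_thr = skm.precision_recall_curve(labels, preds)
    return EvalReport(
        auc=float(skm.roc_auc_score(labels, preds)),
        ap=float(skm.average_precision_score(labels, preds)),
        accuracy=float(np.mean((preds > threshold).astype(int) == labels)),
        roc=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": roc_thr}),
        pr=pd.DataFrame(
            {
                "precision": precision[:-1],
                "recall": recall[:-1],
                "threshold": pr_thr,
            }
        ),
        youden_threshold=youden_threshold(preds, labels),
    )


def youden_threshold(preds, labels) -> float:
    """The observed prediction value maximizing Youden's J = sens + spec − 1.

    A sample is called positive when its prediction is ≥ the threshold.
    Ties in J are broken toward the smaller threshold.
    """
    preds = np.asarray(preds, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    candidates = np.unique(preds)
    n_pos = int((labels == 1).sum())
    n_neg = labels.size - n_pos
    best_t, best_j = None, -np.inf
    for t in candidates:
        called = preds >= t
        sens = float((called & (labels == 1)).sum()) / n_pos
        spec = float((~called & (labels == 0)).sum()) / n_neg
        j = sens + spec - 1
        if j > best_j + 1e-12:
            best_j, best_t = j, float(t)
    if best_j <= 0:
        warnings.warn("best Youden J is ≤ 0; predictions rank inversely to labels")
    return best_t


# -- DeLong test ------------------------------------------------------------


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _delong_auc_variance(labels: np.ndarray, preds: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC with its positive/negative placement components (midranks)."""
    pos = preds[labels == 1]
    neg = preds[labels == 0]
    m, n = pos.size, neg.size
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n  # per-positive placements
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m  # per-negative placements
    return float(auc), v10, v01


def delong_test(preds_a, preds_b, labels) -> tuple[float, float, float]:
    """Paired DeLong comparison of two correlated ROC AUCs.

    Returns ``(auc_a, auc_b, p_value)`` for the two-sided null hypothesis
    that the two ROC curves have the same AUC, using the midrank
    covariance estimator and a normal reference.  Identical prediction
    vectors (zero variance of the difference) give p = 1 with a warning.
    """
    preds_a = np.asarray(preds_a, dtype=float)
    preds_b = np.asarray(preds_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not (preds_a.shape == preds_b.shape == labels.shape):
        raise ValueError("preds_a, preds_b and labels must have equal length")
    _check_two_classes(labels)
    auc_a, v10_a, v01_a = _delong_auc_variance(labels, preds_a)
    auc_b, v10_b, v01_b = _delong_auc_variance(labels, preds_b)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1)
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 0:
        warnings.warn("zero variance of the AUC difference; returning p = 1")
        return auc_a, auc_b, 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    return auc_a, auc_b, float(2 * sps.norm.sf(abs(z)))


def groupwise_auc(preds, labels, group_labels) -> pd.DataFrame:
    """Per-group AUC table (e.g. per species/genus of the positive samples).

    Each group must contain both classes (matched negatives carry the same
    group label); single-class groups are omitted with a warning.
    """
    preds = np.asarray(preds, dtype=float)
    labels = np.asarray(labels, dtype=int)
    groups = np.asarray(group_labels)
    rows = []
    for g in pd.unique(groups):
        mask = groups == g
        sub_labels = labels[mask]
        if np.unique(sub_labels).size < 2:
            warnings.warn(f"group {g!r} has a single class and was omitted")
            continue
        rep = evaluate(preds[mask], sub_labels)
        rows.append(
            {
                "group": g,
                "auc": rep.auc,
                "n_pos": int((sub_labels == 1).sum()),
                "n_neg": int((sub_labels == 0).sum()),
            }
        )
    return pd.DataFrame(rows, columns=["group", "auc", "n_pos", "n_neg"])
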