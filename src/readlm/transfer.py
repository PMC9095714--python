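"""Classification heads and fine-tuning on top of the pretrained encoder.

The classifier keeps the LSTM encoder and replaces the language-model decoder
with a pooling head: the encoder output at the final position is concatenated
with a max-pool and a mean-pool over all (non-padding) positions — three
embedding-size vectors, 3 x 104 = 312 features by default — then passed
through batch-norm + dropout, a linear layer to 50 hidden units, batch-norm +
dropout again, and a final linear layer with log-softmax output.

Fine-tuning is gradual: the head is trained first in isolation, then encoder
layers are progressively unfrozen from last to first, with discriminative
learning rates interpolated geometrically from a small rate at the earliest
unfrozen group up to the full rate at the head.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .lm import EncoderModel, LanguageModel, TrainingError
from .seqio import NucleotideVocabulary, tokenize


@dataclass
class PoolingHeadConfig:
    """Shape and regularization of the pooling classification head."""

    n_classes: int = 2
    hidden_dim: int = 50
    dropout1: float = 0.2
    dropout2: float = 0.1
    include_min_pool: bool = False

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be at least 2")
        if self.hidden_dim <= 0:
            raise ValueError("hidden_dim must be positive")


@dataclass
class FineTuneStage:
    """One stage of gradual unfreezing.

    ``n_groups`` counts unfrozen layer groups from the head backwards: 1 means
    head only, 2 adds the last encoder layer, and so on.
    """

    n_groups: int
    lr_max: float
    lr_min: float
    epochs: int

    def __post_init__(self) -> None:
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if not (self.lr_max >= self.lr_min > 0):
            raise ValueError("need lr_max >= lr_min > 0")


@dataclass
class FineTuneSchedule:
    """Ordered unfreezing stages; the first trains the head alone and groups
    accumulate monotonically."""

    stages: list[FineTuneStage]

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("schedule needs at least one stage")
        if self.stages[0].n_groups != 1:
            raise ValueError("first stage must train the head only")
        for prev, cur in zip(self.stages, self.stages[1:]):
            if cur.n_groups < prev.n_groups:
                raise ValueError("unfrozen groups must accumulate monotonically")


def default_schedule(
    lr_max: float = 1e-2, lr_min: float = 5e-4, epochs_per_stage: int = 1, n_encoder_groups: int = 3
) -> FineTuneSchedule:
    """Successive unfreezing: head, then encoder layers last to first.

    The endpoint pairs used for the published tasks were 1e-2 to 5e-4 for the
    binary enzyme-class task, 1e-3 to 5e-5 for reading frames, and 5e-2 to
    5e-4 for optimal temperature.
    """
    stages = [
        FineTuneStage(k, lr_max, lr_min, epochs_per_stage)
        for k in range(1, n_encoder_groups + 2)
    ]
    return FineTuneSchedule(stages)


@dataclass
class FineTuneReport:
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    valid_loss: list[float] = field(default_factory=list)
    valid_accuracy: list[float] = field(default_factory=list)


class ClassifierModel(ad.Module):
    """Encoder + pooling head producing per-read log-probabilities."""

    def __init__(self, encoder: EncoderModel, head_config: PoolingHeadConfig,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if rng is None:
            rng = np.random.default_rng(0)
        self.encoder = encoder
        self.head_config = head_config
        E = encoder.config.embedding_size
        n_pools = 4 if head_config.include_min_pool else 3
        self.feature_dim = n_pools * E
        self.bn1 = ad.BatchNorm1d(self.feature_dim, name="head.bn1")
        self.drop1 = ad.Dropout(head_config.dropout1, np.random.default_rng(rng.integers(0, 2**31)))
        self.lin1 = ad.Linear(self.feature_dim, head_config.hidden_dim, rng, name="head.lin1")
        self.bn2 = ad.BatchNorm1d(head_config.hidden_dim, name="head.bn2")
        self.drop2 = ad.Dropout(head_config.dropout2, np.random.default_rng(rng.integers(0, 2**31)))
        self.lin2 = ad.Linear(head_config.hidden_dim, head_config.n_classes, rng, name="head.lin2")

    def head_parameters(self) -> list[ad.Parameter]:
        return (
            self.bn1.parameters() + self.lin1.parameters()
            + self.bn2.parameters() + self.lin2.parameters()
        )

    def layer_groups(self) -> list[list[ad.Parameter]]:
        """Earliest group first: [embedding+layer1, layer2, ..., head]."""
        return self.encoder.layer_groups() + [self.head_parameters()]

    def forward(self, ids: np.ndarray, lengths: np.ndarray) -> ad.Tensor:
        """Log-probabilities (B, n_classes) for a padded (B, T) id batch.

        ``lengths`` counts real (non-pad) tokens per row, including the
        beginning-of-read token; pooling and the final-position pick ignore
        padding entirely, so padding a read leaves the output unchanged.
        """
        ids = np.asarray(ids, dtype=int)
        lengths = np.asarray(lengths, dtype=int)
        B, T = ids.shape
        outputs, _ = self.encoder.forward(ids)
        hidden = ad.stack(outputs, axis=1)  # (B, T, E)
        mask = (np.arange(T)[None, :] < lengths[:, None]).astype(float)[:, :, None]
        final = hidden[(np.arange(B), lengths - 1)]
        maxpool = (hidden + (mask - 1.0) * 1e9).max(axis=1)
        meanpool = (hidden * mask).sum(axis=1) / lengths[:, None]
        feats = [final, maxpool, meanpool]
        if self.head_config.include_min_pool:
            feats.append(-((-hidden + (mask - 1.0) * 1e9).max(axis=1)))
        x = ad.concatenate(feats, axis=-1)
        x = self.drop1(self.bn1(x))
        x = self.lin1(x).relu()
        x = self.drop2(self.bn2(x))
        return self.lin2(x).log_softmax(axis=-1)


def build_classifier(
    encoder, head_config: PoolingHeadConfig, rng: np.random.Generator | None = None
) -> ClassifierModel:
    """Attach a freshly initialized pooling head to a (pretrained) encoder.

    Accepts an encoder or a full language model; encoder weights are carried
    over unchanged (shared, not copied).
    """
    if isinstance(encoder, LanguageModel):
        encoder = encoder.encoder
    return ClassifierModel(encoder, head_config, rng)


def _batches(dataset, vocab: NucleotideVocabulary, batch_size: int, rng: np.random.Generator | None):
    """Yield (indices, ids, lengths, labels) padded batches, grouped by similar length."""
    idx = np.arange(len(dataset))
    if rng is not None:
        idx = rng.permutation(idx)
    # bucket by length to limit padding: stable-sort shuffled indices in blocks
    block = batch_size * 8
    buckets = []
    for lo in range(0, len(idx), block):
        sub = idx[lo : lo + block]
        buckets.extend(sorted(sub, key=lambda i: len(dataset[i][0])))
    for lo in range(0, len(buckets), batch_size):
        sel = buckets[lo : lo + batch_size]
        toks = [tokenize(dataset[i][0], vocab, add_bos=True) for i in sel]
        lengths = np.array([len(t.ids) for t in toks])
        T = int(lengths.max())
        ids = np.full((len(sel), T), vocab.pad_id, dtype=int)
        for r, t in enumerate(toks):
            ids[r, : len(t.ids)] = t.ids
        labels = np.array([dataset[i][1] for i in sel], dtype=int)
        yield np.asarray(sel), ids, lengths, labels


def _evaluate(classifier: ClassifierModel, dataset, batch_size: int = 64) -> tuple[float, float]:
    vocab = classifier.encoder.vocab
    was_training = classifier.training
    classifier.eval()
    try:
        loss_sum, correct, n = 0.0, 0, 0
        for _, ids, lengths, labels in _batches(dataset, vocab, batch_size, rng=None):
            log_probs = classifier.forward(ids, lengths)
            loss_sum += float(ad.nll_loss(log_probs, labels).data) * len(labels)
            correct += int((np.argmax(log_probs.data, axis=-1) == labels).sum())
            n += len(labels)
        return loss_sum / n, correct / n
    finally:
        classifier.train(was_training)


def _stage_learning_rates(stage: FineTuneStage, n_unfrozen: int) -> list[float]:
    """Geometric interpolation from lr_min (earliest group) to lr_max (head)."""
    if n_unfrozen == 1:
        return [stage.lr_max]
    ratio = stage.lr_max / stage.lr_min
    return [stage.lr_min * ratio ** (i / (n_unfrozen - 1)) for i in range(n_unfrozen)]


def fine_tune(
    classifier: ClassifierModel,
    train_set: Sequence[tuple[str, int]],
    valid_set: Sequence[tuple[str, int]],
    schedule: FineTuneSchedule,
    rng: np.random.Generator,
    batch_size: int = 32,
    grad_clip: float = 5.0,
) -> FineTuneReport:
    """Gradual-unfreezing fine-tuning of the classifier.

    Datasets are sequences of (nucleotide string, integer label). Per stage,
    only the stage's layer groups receive gradient updates (frozen parameters
    are left bit-identical, and batch-norm running statistics are only updated
    while their group is unfrozen — the head's, in practice, always is).
    """
    n_classes = classifier.head_config.n_classes
    for name, ds in (("train", train_set), ("valid", valid_set)):
        for _, label in ds:
            if not 0 <= label < n_classes:
                raise ValueError(f"{name} label {label} outside [0, {n_classes})")
    vocab = classifier.encoder.vocab
    groups = classifier.layer_groups()
    report = FineTuneReport()
    for stage in schedule.stages:
        k = min(stage.n_groups, len(groups))
        unfrozen = groups[len(groups) - k :]
        frozen = [p for g in groups[: len(groups) - k] for p in g]
        for p in frozen:
            p.requires_grad = False
        for g in unfrozen:
            for p in g:
                p.requires_grad = True
        lrs = _stage_learning_rates(stage, k)
        optimizer = ad.Adam(list(zip(unfrozen, lrs)))
        for _ in range(stage.epochs):
            classifier.train()
            loss_sum, correct, n = 0.0, 0, 0
            for _, ids, lengths, labels in _batches(train_set, vocab, batch_size, rng):
                log_probs = classifier.forward(ids, lengths)
                loss = ad.nll_loss(log_probs, labels)
                if not math.isfinite(float(loss.data)):
                    raise TrainingError("non-finite fine-tuning loss")
                classifier.zero_grad()
                loss.backward()
                ad.clip_grad_norm([p for g in unfrozen for p in g], grad_clip)
                optimizer.step()
                loss_sum += float(loss.data) * len(labels)
                correct += int((np.argmax(log_probs.data, axis=-1) == labels).sum())
                n += len(labels)
            va_loss, va_acc = _evaluate(classifier, valid_set)
            report.train_loss.append(loss_sum / n)
            report.train_accuracy.append(correct / n)
            report.valid_loss.append(va_loss)
            report.valid_accuracy.append(va_acc)
    for p in classifier.parameters():
        p.requires_grad = True
    return report


def predict_labels(
    classifier: ClassifierModel,
    reads: Sequence[str],
    threshold: float = 0.5,
    batch_size: int = 64,
) -> tuple[np.ndarray, np.ndarray]:
    """Predict labels and return per-class probabilities.

    Multiclass: argmax of log-probabilities (ties break toward the lowest
    class index). Binary: positive (class 1) iff the exponentiated
    positive-class log-probability is at least ``threshold``.
    """
    n_classes = classifier.head_config.n_classes
    binary = n_classes == 2
    if binary and not 0 < threshold < 1:
        raise ValueError("binary threshold must lie in (0, 1)")
    vocab = classifier.encoder.vocab
    dataset = [(seq, 0) for seq in reads]
    was_training = classifier.training
    classifier.eval()
    try:
        probs = np.empty((len(reads), n_classes))
        for sel, ids, lengths, _ in _batches(dataset, vocab, batch_size, rng=None):
            log_probs = classifier.forward(ids, lengths)
            probs[sel] = np.exp(log_probs.data)
    finally:
        classifier.train(was_training)
    if binary:
        labels = (probs[:, 1] >= threshold).astype(int)
    else:
        labels = np.argmax(probs, axis=-1)
    return labels, probs


def truncate_labels(labels: Sequence[str], depth: int) -> list[str]:
    """Truncate dot-separated EC codes to their first ``depth`` fields.

    Applied identically to truth and predictions before computing accuracy at
    a coarser functional resolution.
    """
    if not 1 <= depth <= 4:
        raise ValueError("depth must lie in 1..4")
    out = []
    for label in labels:
        fields = label.split(".")
        if len(fields) < depth or any(not f for f in fields[:depth]):
            raise ValueError(f"malformed EC label {label!r}")
        out.append(".".join(fields[:depth]))
    return out
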