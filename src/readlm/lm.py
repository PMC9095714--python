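"""Character-level recurrent language model over read-length DNA fragments.

The encoder is a three-layer LSTM: the first layers carry ``hidden_size``
units (1152 by default) and the final layer emits ``embedding_size`` units
(104 by default), so per-position encoder outputs double as read embeddings. A
linear decoder maps each position's output to logits over the full token
vocabulary, and the model is trained by causal next-nucleotide prediction —
each position's target is the following token — with cross-entropy loss and
Adam, on continuous token streams cut into back-propagation-through-time
windows of 100 positions. Recurrent state is carried across windows within a
batch lane, detached between windows, and reset at epoch boundaries.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import autodiff as ad
from .corpus import ChunkRecord
from .seqio import NucleotideVocabulary, tokenize

DEFAULT_DROPOUT = {
    "input": 0.25,
    "embedding": 0.02,
    "weight": 0.2,
    "hidden": 0.15,
    "output": 0.1,
}

#: decreasing three-phase schedule; (epochs, learning rate)
DEFAULT_SCHEDULE = [(15, 1e-2), (15, 2e-3), (45, 1e-3)]


class TrainingError(RuntimeError):
    """Raised when training diverges (non-finite loss)."""


@dataclass
class LMConfig:
    """Architecture and training hyperparameters of the language model."""

    embedding_size: int = 104
    hidden_size: int = 1152
    n_layers: int = 3
    bptt: int = 100
    batch_size: int = 512
    dropout: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DROPOUT))
    learning_rate_schedule: list[tuple[int, float]] = field(
        default_factory=lambda: list(DEFAULT_SCHEDULE)
    )
    optimizer: str = "adam"
    grad_clip: float = 5.0

    def __post_init__(self) -> None:
        for name in ("embedding_size", "hidden_size", "n_layers", "bptt", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for site, rate in self.dropout.items():
            if not 0 <= rate < 1:
                raise ValueError(f"dropout[{site!r}] must lie in [0, 1)")
        if not self.learning_rate_schedule:
            raise ValueError("learning_rate_schedule must be non-empty")

    def to_dict(self) -> dict:
        return {
            "embedding_size": self.embedding_size,
            "hidden_size": self.hidden_size,
            "n_layers": self.n_layers,
            "bptt": self.bptt,
            "batch_size": self.batch_size,
            "dropout": dict(self.dropout),
            "learning_rate_schedule": [list(x) for x in self.learning_rate_schedule],
            "optimizer": self.optimizer,
            "grad_clip": self.grad_clip,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LMConfig":
        d = dict(d)
        if "learning_rate_schedule" in d:
            d["learning_rate_schedule"] = [tuple(x) for x in d["learning_rate_schedule"]]
        return cls(**d)


@dataclass
class TrainReport:
    """Per-epoch loss (nats) and next-nucleotide accuracy on both streams."""

    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    valid_loss: list[float] = field(default_factory=list)
    valid_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = -1


class EncoderModel(ad.Module):
    """Stacked LSTM encoder producing one embedding-size vector per position."""

    def __init__(self, config: LMConfig, vocab: NucleotideVocabulary, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.vocab = vocab
        E, H, L = config.embedding_size, config.hidden_size, config.n_layers
        self.embedding = ad.Embedding(len(vocab), E, rng)
        widths = [E] + [H] * (L - 1) + [E]
        self.lstm_layers = [
            ad.LSTMLayer(widths[i], widths[i + 1], rng, name=f"lstm{i}") for i in range(L)
        ]
        self._drop_rng = np.random.default_rng(rng.integers(0, 2**31))

    # layer groups for gradual unfreezing: earliest group first
    def layer_groups(self) -> list[list[ad.Parameter]]:
        groups = [self.embedding.parameters() + self.lstm_layers[0].parameters()]
        for layer in self.lstm_layers[1:]:
            groups.append(layer.parameters())
        return groups

    def init_state(self, batch: int) -> list[tuple[ad.Tensor, ad.Tensor]]:
        return [layer.init_state(batch) for layer in self.lstm_layers]

    def forward(
        self,
        ids: np.ndarray,
        state: list[tuple[ad.Tensor, ad.Tensor]] | None = None,
    ) -> tuple[list[ad.Tensor], list[tuple[ad.Tensor, ad.Tensor]]]:
        """Run the encoder over an (B, T) id batch.

        Returns the final layer's output at every position (a list of T
        tensors of shape (B, embedding_size)) and the new recurrent state.
        Dropout (input/embedding/weight/hidden/output sites) is active only in
        training mode; evaluation is deterministic.
        """
        ids = np.asarray(ids, dtype=int)
        B, T = ids.shape
        if state is None:
            state = self.init_state(B)
        rates = self.config.dropout

        def drop(x: ad.Tensor, rate: float) -> ad.Tensor:
            if not self.training or rate <= 0:
                return x
            mask = (self._drop_rng.random(x.shape) >= rate) / (1 - rate)
            return x * mask

        # embedding dropout zeroes whole vocabulary rows for the forward pass
        weight = self.embedding.weight
        if self.training and rates.get("embedding", 0) > 0:
            row_mask = (
                self._drop_rng.random((weight.shape[0], 1)) >= rates["embedding"]
            ) / (1 - rates["embedding"])
            weight = weight * row_mask
        embedded = weight[ids]  # (B, T, E)

        # weight dropout: one DropConnect mask on each hidden-to-hidden matrix
        w_hh = []
        for layer in self.lstm_layers:
            w = layer.w_hh
            if self.training and rates.get("weight", 0) > 0:
                mask = (self._drop_rng.random(w.shape) >= rates["weight"]) / (1 - rates["weight"])
                w = w * mask
            w_hh.append(w)

        # layer-major traversal: each layer's input projection for all T
        # positions is a single matmul, only the recurrence runs stepwise
        new_state = list(state)
        layer_input = drop(embedded, rates.get("input", 0))  # (B, T, E)
        for li, layer in enumerate(self.lstm_layers):
            nh = layer.n_hidden
            n_in = layer_input.shape[-1]
            proj = layer_input.reshape(B * T, n_in) @ layer.w_ih + layer.bias
            h, c = new_state[li]
            outputs: list[ad.Tensor] = []
            for t in range(T):
                gates = proj[t::T] + h @ w_hh[li]
                i = gates[:, 0 * nh : 1 * nh].sigmoid()
                f = gates[:, 1 * nh : 2 * nh].sigmoid()
                g = gates[:, 2 * nh : 3 * nh].tanh()
                o = gates[:, 3 * nh : 4 * nh].sigmoid()
                c = f * c + i * g
                h = o * c.tanh()
                outputs.append(h)
            new_state[li] = (h, c)
            if li < len(self.lstm_layers) - 1:
                layer_input = drop(ad.stack(outputs, axis=1), rates.get("hidden", 0))
        final = [drop(o, rates.get("output", 0)) for o in outputs]
        return final, new_state

    @staticmethod
    def detach_state(state: list[tuple[ad.Tensor, ad.Tensor]]) -> list[tuple[ad.Tensor, ad.Tensor]]:
        return [(h.detach(), c.detach()) for h, c in state]


class LanguageModel(ad.Module):
    """Encoder plus the linear next-nucleotide decoder."""

    def __init__(self, config: LMConfig, vocab: NucleotideVocabulary, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.vocab = vocab
        self.encoder = EncoderModel(config, vocab, rng)
        self.decoder = ad.Linear(config.embedding_size, len(vocab), rng, name="decoder")

    def forward(self, ids: np.ndarray, state=None):
        outputs, state = self.encoder.forward(ids, state)
        hidden = ad.stack(outputs, axis=1)  # (B, T, E)
        B, T = np.asarray(ids).shape
        flat = hidden.reshape(B * T, self.config.embedding_size)
        logits = self.decoder(flat)  # (B*T, V)
        return logits, state


def build_lm(
    config: LMConfig | None = None,
    vocab: NucleotideVocabulary | None = None,
    rng: np.random.Generator | None = None,
) -> LanguageModel:
    """Construct the language model (encoder + linear decoder) from a config."""
    if config is None:
        config = LMConfig()
    if vocab is None:
        vocab = NucleotideVocabulary()
    if rng is None:
        rng = np.random.default_rng(0)
    return LanguageModel(config, vocab, rng)


class LMBatchStream:
    """Continuous token stream cut into bptt windows over parallel lanes.

    Reads are shuffled, prefixed with the beginning-of-read token, and
    concatenated into one long stream which is reshaped into ``batch_size``
    lanes. Windows of ``bptt`` positions are yielded with targets shifted by
    one; the final ragged window is kept (shorter) and never padded. One
    target is lost at the end of each lane.
    """

    def __init__(self, lanes: np.ndarray, bptt: int):
        self.lanes = lanes  # (B, L)
        self.bptt = bptt

    @property
    def batch_size(self) -> int:
        return self.lanes.shape[0]

    @property
    def n_targets(self) -> int:
        return self.lanes.shape[0] * (self.lanes.shape[1] - 1)

    def windows(self):
        L = self.lanes.shape[1]
        for i in range(0, L - 1, self.bptt):
            inputs = self.lanes[:, i : i + self.bptt]
            targets = self.lanes[:, i + 1 : i + 1 + self.bptt]
            inputs = inputs[:, : targets.shape[1]]
            yield inputs, targets

    def __len__(self) -> int:
        return math.ceil((self.lanes.shape[1] - 1) / self.bptt)


def make_lm_batches(
    chunks: Sequence[ChunkRecord | str],
    config: LMConfig,
    rng: np.random.Generator,
    vocab: NucleotideVocabulary | None = None,
) -> LMBatchStream:
    """Assemble a shuffled, BOS-prefixed continuous stream from reads."""
    if len(chunks) == 0:
        raise ValueError("cannot build a batch stream from zero reads")
    if vocab is None:
        vocab = NucleotideVocabulary()
    order = rng.permutation(len(chunks))
    ids: list[int] = []
    for idx in order:
        chunk = chunks[idx]
        seq = chunk if isinstance(chunk, str) else chunk.sequence
        ids.extend(tokenize(seq, vocab, add_bos=True).ids)
    total = len(ids)
    B = config.batch_size
    if total < 2 * B:
        raise ValueError(
            f"stream of {total} tokens is too short for batch_size={B} (need >= {2 * B})"
        )
    L = total // B
    lanes = np.asarray(ids[: B * L], dtype=int).reshape(B, L)
    return LMBatchStream(lanes, config.bptt)


def _run_stream(
    model: LanguageModel,
    stream: LMBatchStream,
    optimizer: ad.Adam | None,
    grad_clip: float,
) -> tuple[float, float]:
    """One pass over a stream; trains when an optimizer is given."""
    state = None
    total_loss = 0.0
    total_correct = 0
    total_count = 0
    for inputs, targets in stream.windows():
        if state is not None:
            state = EncoderModel.detach_state(state)
        logits, state = model.forward(inputs, state)
        flat_targets = targets.reshape(-1)
        log_probs = logits.log_softmax(axis=-1)
        loss = ad.nll_loss(log_probs, flat_targets)
        n = flat_targets.size
        total_loss += float(loss.data) * n
        # argmax breaks ties toward the lowest token id
        preds = np.argmax(log_probs.data, axis=-1)
        total_correct += int((preds == flat_targets).sum())
        total_count += n
        if optimizer is not None:
            model.zero_grad()
            loss.backward()
            ad.clip_grad_norm(model.parameters(), grad_clip)
            optimizer.step()
    if total_count == 0:
        raise ValueError("empty stream")
    return total_loss / total_count, total_correct / total_count


def eval_lm(model: LanguageModel, stream: LMBatchStream) -> tuple[float, float]:
    """Mean next-token cross-entropy (nats) and argmax accuracy on a stream."""
    was_training = model.training
    model.eval()
    try:
        return _run_stream(model, stream, optimizer=None, grad_clip=0.0)
    finally:
        model.train(was_training)


def train_lm(
    model: LanguageModel,
    train_stream: LMBatchStream,
    valid_stream: LMBatchStream,
    config: LMConfig | None = None,
) -> TrainReport:
    """Train by next-nucleotide prediction with the configured phase schedule.

    Returns the per-epoch report; the model ends loaded with the parameters of
    its best validation epoch (lowest validation loss).
    """
    if config is None:
        config = model.config
    report = TrainReport()
    best_loss = math.inf
    best_state: dict | None = None
    epoch = 0
    for n_epochs, lr in config.learning_rate_schedule:
        optimizer = ad.Adam([(model.parameters(), lr)])
        for _ in range(n_epochs):
            model.train()
            tr_loss, tr_acc = _run_stream(model, train_stream, optimizer, config.grad_clip)
            if not math.isfinite(tr_loss):
                raise TrainingError(f"non-finite training loss at epoch {epoch}")
            va_loss, va_acc = eval_lm(model, valid_stream)
            report.train_loss.append(tr_loss)
            report.train_accuracy.append(tr_acc)
            report.valid_loss.append(va_loss)
            report.valid_accuracy.append(va_acc)
            if va_loss < best_loss:
                best_loss = va_loss
                best_state = model.state_dict()
                report.best_epoch = epoch
            epoch += 1
    if best_state is not None:
        model.load_state_dict(best_state)
    return report


def save_checkpoint(model: LanguageModel, path: str | Path) -> None:
    """Write parameters, config, and vocabulary into one .npz archive."""
    path = Path(path)
    state = model.state_dict()
    meta = json.dumps(
        {"config": model.config.to_dict(), "vocab": list(model.vocab.tokens)}
    )
    np.savez(path, __meta__=np.array(meta), **state)


def load_checkpoint(path: str | Path) -> LanguageModel:
    with np.load(Path(path), allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    config = LMConfig.from_dict(meta["config"])
    vocab = NucleotideVocabulary(tuple(meta["vocab"]))
    model = build_lm(config, vocab, np.random.default_rng(0))
    model.load_state_dict(state)
    return model
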