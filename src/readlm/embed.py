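"""Fixed-length read embeddings and similarity.

A read's embedding is the encoder's output vector at the final nucleotide of
the read (the last non-padding position when reads are batched), computed in
evaluation mode so it is deterministic. Cosine similarity between such
vectors serves as the embedding similarity throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .lm import EncoderModel, LanguageModel
from .seqio import NucleotideVocabulary, tokenize


@dataclass
class EmbeddingVector:
    """One read's fixed-length embedding."""

    read_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError(f"embedding for {self.read_id!r} contains non-finite entries")


def _resolve_encoder(model) -> EncoderModel:
    return model.encoder if isinstance(model, LanguageModel) else model


def embed_reads(
    model,
    reads: Sequence,
    batch_size: int = 64,
    vocab: NucleotideVocabulary | None = None,
) -> list[EmbeddingVector]:
    """Embed reads as the encoder output at each read's final nucleotide.

    Accepts an encoder or a full language model (the decoder is ignored).
    Reads may be strings, ChunkRecords, or (id, sequence) pairs. Reads are
    batched by padding on the right; the embedding is always taken at the last
    non-pad position, so batched and one-at-a-time results agree.
    """
    encoder = _resolve_encoder(model)
    if vocab is None:
        vocab = encoder.vocab
    items: list[tuple[str, str]] = []
    for i, read in enumerate(reads):
        if isinstance(read, str):
            items.append((f"read_{i}", read))
        elif isinstance(read, tuple):
            items.append(read)
        else:
            rid = getattr(read, "chunk_id", None) or getattr(read, "id", f"read_{i}")
            items.append((rid, read.sequence))
    for rid, seq in items:
        if len(seq) < 1:
            raise ValueError(f"read {rid!r} is shorter than 1 nt")

    was_training = encoder.training
    encoder.eval()
    try:
        out: list[EmbeddingVector] = []
        # sort by length so padding in each batch is minimal; restore order after
        order = sorted(range(len(items)), key=lambda i: len(items[i][1]))
        results: dict[int, EmbeddingVector] = {}
        for lo in range(0, len(order), batch_size):
            batch_idx = order[lo : lo + batch_size]
            toks = [tokenize(items[i][1], vocab, add_bos=True) for i in batch_idx]
            lengths = np.array([len(t.ids) for t in toks])
            T = int(lengths.max())
            ids = np.full((len(toks), T), vocab.pad_id, dtype=int)
            for r, t in enumerate(toks):
                ids[r, : len(t.ids)] = t.ids
            outputs, _ = encoder.forward(ids)
            hidden = np.stack([o.data for o in outputs], axis=1)  # (B, T, E)
            final = hidden[np.arange(len(toks)), lengths - 1]
            for r, i in enumerate(batch_idx):
                results[i] = EmbeddingVector(read_id=items[i][0], values=final[r])
        out = [results[i] for i in range(len(items))]
        return out
    finally:
        encoder.train(was_training)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two vectors; in [-1, 1]."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def write_embeddings_tsv(embeddings: Sequence[EmbeddingVector], path: str | Path) -> None:
    """Dense embedding matrix as TSV with a read_id first column."""
    rows = [{"read_id": e.read_id, **{f"e{i}": x for i, x in enumerate(e.values)}} for e in embeddings]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_embeddings_tsv(path: str | Path) -> list[EmbeddingVector]:
    df = pd.read_csv(path, sep="\t")
    cols = [c for c in df.columns if c != "read_id"]
    return [
        EmbeddingVector(read_id=row["read_id"], values=row[cols].to_numpy(float))
        for _, row in df.iterrows()
    ]
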