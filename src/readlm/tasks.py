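"""Task-specific dataset constructors: reading frames and optimal temperature.

A read cut from a coding sequence carries a known translation frame, one of
six labels (1, 2, 3, -1, -2, -3): the sign encodes the strand and the
magnitude is the 1-based position, within the read as emitted, of the first
complete codon. Enzyme optimal temperatures are banded into psychrophilic
(<15 degC), mesophilic (20-40 degC), and thermophilic (>50 degC); the gap
temperatures in [15, 20) and (40, 50] receive no label and are dropped.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .corpus import ChunkRecord, LengthDistribution, chunk_genome
from .seqio import SequenceRecord

FRAME_LABELS = (1, 2, 3, -1, -2, -3)


@dataclass(frozen=True)
class TemperatureBands:
    """Disjoint optimal-temperature bands; temperatures in the gaps get no label."""

    psychrophilic_max: float = 15.0   # exclusive
    mesophilic_min: float = 20.0      # inclusive
    mesophilic_max: float = 40.0      # inclusive
    thermophilic_min: float = 50.0    # exclusive


def frame_label(cds_offset: int, strand: str = "+") -> int:
    """Translation-frame label for a chunk starting at ``cds_offset``.

    ``cds_offset`` is the 0-based offset of the chunk start within the coding
    sequence — measured on the reverse-complement coordinate system for minus
    strand chunks. The magnitude ((3 - offset mod 3) mod 3) + 1 is the 1-based
    read position of the first complete codon; minus strand negates it.
    """
    if cds_offset < 0:
        raise ValueError("cds_offset must be non-negative")
    if strand not in "+-":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    magnitude = ((3 - (cds_offset % 3)) % 3) + 1
    return magnitude if strand == "+" else -magnitude


def make_frame_dataset(
    cds_records: Sequence[SequenceRecord],
    dist: LengthDistribution | None = None,
    rng: np.random.Generator | None = None,
    revcomp_prob: float = 0.5,
) -> tuple[list[ChunkRecord], dict[int, int]]:
    """Zero-overlap chunking of coding sequences with frame labels.

    Coding sequences whose length is not a multiple of 3 are truncated to the
    last full codon (with a warning). For plus strand chunks the frame offset
    is the chunk start; for minus strand chunks it is measured from the CDS
    end (the chunk's start on the reverse-complement coordinate). Returns the
    labeled chunks and the per-class histogram.
    """
    if dist is None:
        dist = LengthDistribution.default()
    if rng is None:
        rng = np.random.default_rng()
    chunks: list[ChunkRecord] = []
    usable = 0
    for rec in cds_records:
        seq = rec.sequence
        if len(seq) % 3 != 0:
            warnings.warn(
                f"CDS {rec.id!r} length {len(seq)} is not a multiple of 3; "
                "truncating to the last full codon",
                stacklevel=2,
            )
            seq = seq[: len(seq) - len(seq) % 3]
        if len(seq) < dist.min_length:
            continue
        usable += 1
        trimmed = SequenceRecord(id=rec.id, sequence=seq, taxonomy=rec.taxonomy, label=rec.label)
        for chunk in chunk_genome(trimmed, dist, rng, revcomp_prob):
            if chunk.strand == "+":
                label = frame_label(chunk.start, "+")
            else:
                label = frame_label(len(seq) - chunk.end, "-")
            chunk.label = str(label)
            chunks.append(chunk)
    if usable == 0:
        raise ValueError("no CDS is long enough for the minimum read length")
    histogram = dict(Counter(int(c.label) for c in chunks))
    return chunks, histogram


def temperature_category(
    optimal_temp_c: float, bands: TemperatureBands | None = None
) -> str | None:
    """Band label for an optimal temperature, or None in the gaps."""
    if bands is None:
        bands = TemperatureBands()
    t = float(optimal_temp_c)
    if not np.isfinite(t):
        raise ValueError("temperature must be finite")
    if t < bands.psychrophilic_max:
        return "psychrophilic"
    if bands.mesophilic_min <= t <= bands.mesophilic_max:
        return "mesophilic"
    if t > bands.thermophilic_min:
        return "thermophilic"
    return None


def make_temperature_dataset(
    records: Sequence[tuple[SequenceRecord, float]],
    dist: LengthDistribution | None = None,
    rng: np.random.Generator | None = None,
    bands: TemperatureBands | None = None,
    revcomp_prob: float = 0.5,
) -> list[ChunkRecord]:
    """Chunk gene sequences and label chunks by optimal-temperature band.

    Records whose temperature falls in a band gap are excluded entirely.
    """
    if dist is None:
        dist = LengthDistribution.default()
    if rng is None:
        rng = np.random.default_rng()
    chunks: list[ChunkRecord] = []
    for rec, temp in records:
        category = temperature_category(temp, bands)
        if category is None:
            continue
        labeled = SequenceRecord(id=rec.id, sequence=rec.sequence, label=category)
        chunks.extend(chunk_genome(labeled, dist, rng, revcomp_prob))
    return chunks
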