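"""Sequence I/O, nucleotide vocabulary, tokenization, and reverse complementation.

The tokenizer is character level (k-mer size 1, stride 1): each nucleotide is one
token. The vocabulary holds the four standard bases plus special tokens for
beginning-of-read, unknown nucleotide, end-of-read, and padding. Only
beginning-of-read is emitted during language-model tokenization; padding exists
for classification batches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

IUPAC_CODES = set("ACGTRYSWKMBDHVN")

#: special-token names
BOS = "BOS"
PAD = "PAD"
UNK = "UNK"
EOS = "EOS"

#: canonical token order, pinned and serialized with every model checkpoint.
#: Specials first simplifies masking; the four bases follow in alphabetic order.
DEFAULT_TOKEN_ORDER = (BOS, PAD, UNK, EOS, "A", "C", "G", "T")


class FastaFormatError(ValueError):
    """Raised when a FASTA file is malformed (e.g., sequence before any header)."""


@dataclass(frozen=True)
class NucleotideVocabulary:
    """Ordered token list with contiguous integer ids starting at 0."""

    tokens: tuple[str, ...] = DEFAULT_TOKEN_ORDER

    def __post_init__(self) -> None:
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("vocabulary tokens must be unique")
        for base in "ACGT":
            if self.tokens.count(base) != 1:
                raise ValueError(f"base {base!r} must appear exactly once")
        for special in (BOS, PAD, UNK, EOS):
            if special not in self.tokens:
                raise ValueError(f"missing special token {special!r}")

    def __len__(self) -> int:
        return len(self.tokens)

    def token_id(self, token: str) -> int:
        try:
            return self.tokens.index(token)
        except ValueError:
            raise KeyError(f"unknown token {token!r}") from None

    @property
    def bos_id(self) -> int:
        return self.tokens.index(BOS)

    @property
    def pad_id(self) -> int:
        return self.tokens.index(PAD)

    @property
    def unk_id(self) -> int:
        return self.tokens.index(UNK)

    @property
    def eos_id(self) -> int:
        return self.tokens.index(EOS)

    def base_id(self, base: str) -> int:
        return self.tokens.index(base)

    def to_json(self) -> str:
        return json.dumps(list(self.tokens))

    @classmethod
    def from_json(cls, text: str) -> "NucleotideVocabulary":
        return cls(tuple(json.loads(text)))


@dataclass
class SequenceRecord:
    """One named nucleotide sequence with optional taxonomy and label."""

    id: str
    sequence: str
    taxonomy: dict[str, str] | None = None
    label: str | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        bad = set(self.sequence.upper()) - IUPAC_CODES
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TokenizedRead:
    """Integer token ids for one read; ``length`` counts nucleotide tokens only."""

    ids: list[int]
    length: int


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly line-wrapped) multi-record FASTA file.

    Header ids are taken up to the first whitespace; the remainder is kept as
    the record description. Sequence case is preserved verbatim — normalization
    is deferred to :func:`tokenize`.
    """
    path = Path(path)
    text = path.read_text()
    if text.strip() and not text.lstrip().startswith(">"):
        raise FastaFormatError(f"{path}: sequence data before first FASTA header")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            SequenceRecord(id=rec.id, sequence=str(rec.seq), description=rec.description)
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 80) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id else rec.description
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string (N maps to N).

    Length preserving and an involution. Case is preserved by Biopython's
    complement table.
    """
    bad = set(seq.upper()) - IUPAC_CODES
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)!r}")
    return str(Seq(seq).reverse_complement())


def tokenize(
    seq: str, vocab: NucleotideVocabulary | None = None, add_bos: bool = True
) -> TokenizedRead:
    """Tokenize a nucleotide string at single-character resolution.

    The sequence is uppercased; A/C/G/T map to their own ids and every other
    IUPAC symbol collapses to the unknown-nucleotide token. A beginning-of-read
    token is prepended iff ``add_bos``; no end-of-read token is appended in
    language-model mode.
    """
    if vocab is None:
        vocab = NucleotideVocabulary()
    if not seq:
        raise ValueError("cannot tokenize an empty sequence")
    base_ids = {b: vocab.base_id(b) for b in "ACGT"}
    unk = vocab.unk_id
    ids = [vocab.bos_id] if add_bos else []
    up = seq.upper()
    bad = set(up) - IUPAC_CODES
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)!r}")
    ids.extend(base_ids.get(ch, unk) for ch in up)
    return TokenizedRead(ids=ids, length=len(seq))


def detokenize(ids: Sequence[int], vocab: NucleotideVocabulary | None = None) -> str:
    """Map token ids back to a nucleotide string.

    BOS/EOS/PAD are stripped; the unknown token renders as ``N``.
    """
    if vocab is None:
        vocab = NucleotideVocabulary()
    specials = {vocab.bos_id, vocab.eos_id, vocab.pad_id}
    out = []
    for i in ids:
        if not 0 <= i < len(vocab):
            raise ValueError(f"token id {i} outside vocabulary of size {len(vocab)}")
        if i in specials:
            continue
        out.append("N" if i == vocab.unk_id else vocab.tokens[i])
    return "".join(out)
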