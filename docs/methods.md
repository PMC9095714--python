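# Methods

`readlm` implements a complete desk-scale workflow for representation
learning on read-length microbial DNA: corpus construction from genomes and
coding sequences, a character-level recurrent language model, read
embeddings, transfer learning with gradual unfreezing, and the evaluation
statistics used to assess functional and evolutionary signal in the
embeddings. This note records the model assumptions, the parameter choices
and their rationale, what the synthetic data does and does not emulate, and
the numerical decisions a user re-deriving results will want to know.

## Corpus construction

**Read-length chunks.** Genomes (or contigs — multi-contig inputs are
chunked per contig) are tiled left to right with zero overlap. Each chunk's
length is drawn with replacement from a read-length distribution supported
on [60, 300] bp; each chunk is independently reverse-complemented with
probability 0.5. The default distribution is a discretized truncated normal
with mean 136 bp and standard deviation 40 bp on [60, 300] — a smooth proxy
for the empirical distribution of average read lengths in short-read
sequencing runs (mean 136 bp); an empirical table can be loaded from TSV.
The per-chunk generator consumption order (length draw, then strand draw) is
fixed and documented so corpora are bit-reproducible from a seed. When the
remaining suffix is shorter than the largest support value, the length draw
is restricted to lengths that still fit; a trailing remainder below 60 bp is
discarded, which keeps every emitted length inside [60, 300].

**Leakage-aware splits.** Two split modes are provided. The taxonomic split
assigns whole taxa at a chosen rank to train/validation/test, so
near-identical genomes never straddle partitions; records whose taxon is not
in the assignment are returned separately rather than dropped. The
cluster-disjoint split keeps whole sequence clusters (e.g., groups above 50%
identity) inside one partition, assigning shuffled clusters greedily to the
partition currently most underfilled relative to its target fraction; this
lands within one cluster of the target sizes.

**Balancing and redundancy filtering.** Label balancing resamples every
class to a common target, by default the floor of the mean per-class count
(the natural reading of "downsample/oversample to the mean"); downsampling
is without replacement, oversampling resamples existing records. The
redundancy filter removes candidate reads whose best gapless identity
against any reference read exceeds 0.8. It is a light-weight stand-in for
greedy identity clustering tools: an exact shared 11-mer screen proposes
alignment diagonals and the best diagonal's matches divided by candidate
length is the identity proxy. Decisions very close to the threshold can
differ from a full clustering tool's; the tests assert agreement with a
brute-force all-offset oracle only at a margin of 0.05 or more from the
cutoff.

## Language model

The encoder is a stacked LSTM over single-nucleotide tokens (k-mer size 1,
stride 1). The vocabulary is [BOS, PAD, UNK, EOS, A, C, G, T] — specials
first, order pinned and serialized with every checkpoint. Only
beginning-of-read is emitted during language-model tokenization; padding
exists for classification batches; every non-ACGT IUPAC symbol collapses to
the unknown token. Default architecture: three layers, 1152 units in each
hidden layer, and a final layer emitting 104 units so the per-position
output doubles as the read-embedding dimension and the classifier-head
arithmetic (3 x 104 = 312) comes out exactly. The decoder is a linear map
from 104 to the full vocabulary.

Training is standard causal next-nucleotide prediction: reads are shuffled,
BOS-prefixed, concatenated into a continuous stream, reshaped into
`batch_size` parallel lanes, and consumed in back-propagation-through-time
windows of 100 positions (the final ragged window is kept, never padded).
Recurrent state is carried across windows within a lane, detached between
windows, and reset at epoch boundaries. The loss is cross-entropy in nats
under Adam, with a three-phase decreasing learning-rate schedule (defaults
1e-2, 2e-3, 1e-3) and global gradient-norm clipping at 5. Dropout is applied
at five sites (input 0.25, embedding rows 0.02, recurrent-weight DropConnect
0.2, between-layer 0.15, output 0.1 by default); all rates are configuration,
and evaluation mode is exactly deterministic. Prediction accuracy breaks
ties toward the lowest token id.

The tensor backend is a small reverse-mode autodiff core written on numpy
(float32), with an LSTM whose per-layer input projections are computed in
one matrix product per layer so only the recurrence itself runs stepwise.
Recurrent matrices are initialized with one orthogonal block per gate:
orthogonal recurrent initialization keeps the dynamics well-conditioned and
able to sustain the oscillatory modes that periodic sequence structure
(codons) rewards. Forget-gate biases start at 1. Everything is
single-threaded and deterministic given a seed.

## Embeddings

A read's embedding is the encoder output at its final nucleotide, computed
in evaluation mode. In batched computation reads are right-padded and the
vector is read at the last non-pad position, so batched and one-at-a-time
results agree to float precision; BOS participates in the context but is
never the selected position. Embedding similarity is the cosine of the raw
(uncentered) vectors, as the embedding contract specifies.

## Transfer learning

The classifier keeps the pretrained encoder and replaces the decoder with a
pooling head: concat(final-position output, max-pool, mean-pool) over
non-padding positions — three embedding-size vectors, 312 features at the
default width — then batch-norm + dropout (0.2), a linear layer to 50 units
with ReLU, batch-norm + dropout (0.1), and a final linear layer with
log-softmax output. The stated head arithmetic (104 * 3) only accommodates
three concatenated vectors, so min-pooling is exposed as an option rather
than a default; batch-norm is applied before dropout within each stage, and
the inter-stage ReLU follows the standard pooled-classifier design for
recurrent text models.

Fine-tuning unfreezes the network gradually: the head alone first, then
encoder layers from last to first. Layer groups are (embedding + layer 1),
(layer 2), ..., (head). Within a stage the learning rates interpolate
geometrically from the minimum (earliest unfrozen group) to the maximum
(head); frozen parameters are left bit-identical, and batch-norm running
statistics update only in unfrozen groups. The published endpoint pairs per
task (1e-2 to 5e-4 for the binary enzyme-class task, 1e-3 to 5e-5 for
reading frames, 5e-2 to 5e-4 for temperature) are the schedule defaults at
full scale. Binary prediction thresholds the exponentiated positive-class
log-probability at 0.5 by default; multiclass prediction is the argmax with
ties toward the lowest class index.

## Evaluation statistics

Binary metrics follow the confusion-count definitions (accuracy, precision,
recall, F1 as the harmonic mean); a zero denominator reports the metric as 0
and flags it. Homology evaluation forms, per orthologous group, all
within-group pairs (10 for a 5-member group) and an equal number of
nonhomologous pairs drawn by rotating group members against random members
of other groups, so the pair set is balanced per group. Sequence similarity
is the Smith-Waterman local alignment score with affine gaps, gap open -10
and extension -1, computed by Biopython's pairwise aligner (the open penalty
is charged on a gap's first position); match/mismatch scores are not stated
alongside the gap penalties in the method this follows, so the defaults are
+1/0, exposed in `AlignmentParams`. The threshold sweep classifies a pair as
homologous when cosine similarity >= t over a grid (default -1.00 to 1.00,
step 0.01) and reports the maximum-accuracy threshold, ties toward the
smallest t. One-way MANOVA uses Pillai's trace V = tr(H(H+E)^-1) with the
standard F approximation, plus an optional label-permutation p-value; the
permutation route is also the fallback when the total scatter matrix is
singular.

## Task label conventions

Reading-frame labels are one of {1, 2, 3, -1, -2, -3}: the magnitude is the
1-based position, within the read as emitted, of the first complete codon
(offset o from a codon boundary gives ((3 − o mod 3) mod 3) + 1), and the
sign is the strand; minus-strand offsets are measured on the
reverse-complement coordinate (CDS length minus chunk end). The magnitude
convention for the offset→label map is not externally fixed; any
self-consistent convention defines the same six-class task, and generator
and evaluator here share this one (a translation oracle in the tests
confirms that decoding at the labeled position reproduces a substring of
the source protein). Coding sequences whose length is not a multiple of 3
are truncated to the last full codon with a warning.

Optimal-temperature bands are psychrophilic (<15 °C), mesophilic ([20, 40]
°C), and thermophilic (>50 °C). The band definitions leave gaps at [15, 20)
and (40, 50]; temperatures there receive no label and their records are
dropped rather than inventing boundaries.

## Synthetic data

The generators produce inputs with exactly the statistical structure the
pipeline assumes, with closed-form expectations where possible:

- **Taxonomy genomes.** A uniform-random root genome evolves along a rooted
  tree (configurable branching; per-edge substitution rate r expressed as
  expected mismatch fraction, implemented as uniform resampling of a site
  with probability 4r/3). Two leaves joined by edges r_1..r_k have expected
  divergence 0.75(1 − Π(1 − 4r_i/3)) — exact, substitution-only, no indels
  (an assumption that keeps identity oracles exact; alignment scoring is
  still exercised by the evaluation module). Rates are capped below 0.75,
  the random-saturation limit.
- **Gene families.** Each family is an ancestor coding sequence (codon-
  usage-biased — real orthologs are coding, and composition-free random
  ancestors leave a language model nothing to learn) with five members
  mutated at the family divergence rate (default 0.10), so within-family
  expected identity exceeds the ~0.25 between-family baseline by
  construction.
- **Coding sequences.** Codons are drawn i.i.d. from a 61-entry sense-codon
  usage table and terminated by a stop codon; the default table combines
  bacterial bulk amino-acid composition with a 75% preferred-codon bias per
  amino acid — a stylized but realistically strong codon preference, as in
  highly expressed prokaryotic genes. Translation uses NCBI table 11.
- **Labeled read sets.** The three-class read set separates classes by GC
  content (0.35 / 0.50 / 0.65), a sequence-composition stand-in for
  habitat- or temperature-linked classes that is separable by construction.

What the synthetic world does **not** emulate: indels, rate heterogeneity,
selection, repeat structure, real codon-usage variation across taxa, or
sequencing error. Passing the desk-scale suites therefore demonstrates that
the machinery is correct and that the models can extract planted structure
of realistic strength — not that full-scale accuracies on real data are
reproduced.

## Desk-scale study sizes and training recipes

All evaluation runs on one CPU. The problem sizes are chosen as the package's
desk-scale study conditions:

- Strand-rule estimate: one 10 Mbp genome, ~72,000 chunks.
- Language-model analogs: periodic corpus of 100 reads (deterministic
  source, expect >= 95% next-nucleotide accuracy within 3 epochs);
  uniform-random corpus of 80 reads (loss must stay above ln 4 ≈ 1.386).
  Toy models use 16–24 embedding dims and 32–128 hidden units; with corpora
  this small, many small optimizer steps (batch 4–8, bptt 20–50) matter more
  than capacity — large-batch schedules at toy scale leave too few Adam
  updates per epoch to move off the unigram solution.
- Reading-frame analog: 1500 synthetic CDS of 200 codons, chunked with the
  default length distribution (~6,700 labeled reads, six classes, chance
  16.7%). Recipe: 2 epochs of language-model pretraining on the chunked
  corpus (a 1-layer, 128-unit toy encoder — at this scale a single layer
  learns phase structure in a fraction of the epochs a deep stack needs),
  then fine-tuning with a short-read curriculum: 15 epochs on reads
  truncated to their first 60 nt, then 12 epochs on full-length reads. The
  first 60 nt of a read already determine its frame label almost completely
  (a position-specific linear model on those bases alone reaches ~0.96), so
  the truncated stage teaches start-anchored phase features quickly and the
  full-length stage teaches the encoder to carry that decision across up to
  300 positions. Validation accuracy reaches ~0.97 (chance 0.167) in about
  six CPU-minutes.
- Homology-embedding analog: 20 planted families x 5 members (300 nt,
  divergence 0.10); encoder pretrained 8 epochs on random chunks of the
  family genes; mean within-family cosine exceeds between-family with a
  999-permutation p-value below 0.01.

## Known limitations

- The full published architecture (1152 hidden units, 75 epochs on millions
  of reads) is expressible in the configuration but not trainable at desk
  scale; headline accuracies on real data are out of scope by design.
- The numpy LSTM is single-threaded; throughput is adequate for the study
  sizes above (~0.15 s per 64-read batch at 140 nt) but not for large
  corpora.
- The redundancy filter is gapless; indel-containing near-duplicates can
  evade it where a full clustering tool would not.
- Embeddings from weakly trained toy encoders concentrate near a dominant
  state direction (raw cosines cluster near 1); the within/between contrast
  is still resolvable, but magnitudes are not comparable to a fully trained
  model's.
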