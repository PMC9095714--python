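# readlm

Language modeling, embeddings, and transfer learning for **read-length
microbial DNA sequences** (60–300 nt), on CPU, with seeded synthetic data
for every step.

Most sequencing reads from environmental microbial communities cannot be
functionally annotated by alignment to reference databases, because the
majority of microbial diversity is uncultured and unannotated. One way
around the reference bottleneck is a *DNA language model*: a recurrent
network trained on read-length fragments of microbial genomes to predict
each nucleotide from its preceding context. The encoder of such a model
turns any read into a fixed-length vector that captures functional and
evolutionary signal, and it can be fine-tuned with small labeled datasets
into classifiers for tasks such as recognizing enzyme classes, predicting
an enzyme's optimal temperature band, or recovering the reading frame of a
coding fragment.

`readlm` implements that whole workflow at desk scale:

- **corpus** — cut genomes/CDS into read-length chunks (lengths drawn from a
  [60, 300] bp distribution, mean 136 bp; zero overlap; 50% reverse
  complement), taxonomy-disjoint and cluster-disjoint train/test splits,
  label balancing to the mean class count, >80%-identity redundancy
  filtering;
- **lm** — a character-level LSTM language model (default: 3 layers, 1152
  hidden units, 104-dim embedding, bptt 100, batch 512, Adam,
  cross-entropy), trained by next-nucleotide prediction on continuous
  token streams; the neural core is a small numpy reverse-mode autodiff
  engine inside the package;
- **embed** — read embeddings taken from the encoder output at the final
  nucleotide, compared by cosine similarity;
- **transfer** — a pooled classification head (final + max-pool + mean-pool
  = 3 × 104 = 312 features → 50 → classes, log-softmax), fine-tuned with
  gradual unfreezing and discriminative learning rates;
- **evalstats** — confusion metrics, balanced homolog/nonhomolog pair
  construction (10 pairs per 5-member group), Smith-Waterman alignment
  scores (gap open −10 / extend −1), similarity-threshold sweeps, Pearson
  correlation, and one-way MANOVA (Pillai's trace, F approximation and
  permutation);
- **tasks** — reading-frame labels (1, 2, 3, −1, −2, −3) and optimal-
  temperature bands (psychrophilic <15 °C, mesophilic 20–40 °C,
  thermophilic >50 °C);
- **synthetic** — seeded generators for taxonomy-structured genomes,
  planted gene families, codon-usage-biased CDS, and separable labeled read
  sets, so everything is testable without downloads.

## Worked example

```python
import numpy as np
import readlm as rl

# 1. synthetic world: genomes diverging along a small taxonomy
spec = rl.SyntheticSpec(branching=(4, 3), substitution_rate=0.05,
                        genome_length=12_000, seed=42)
genomes = rl.simulate_taxonomy_genomes(spec)

# 2. read-length chunks (zero overlap, 50% reverse complement)
rng = np.random.default_rng(42)
chunks = [c for g in genomes for c in rl.chunk_genome(g, rng=rng)]

# 3. a toy language model trained on codon-structured reads
cds = [rl.simulate_cds(n_codons=120, rng=rng, record_id=f"cds{i}")[0]
       for i in range(200)]
frame_chunks, hist = rl.make_frame_dataset(cds, rng=np.random.default_rng(1))
cfg = rl.LMConfig(embedding_size=24, hidden_size=96, n_layers=1, bptt=50,
                  batch_size=8,
                  dropout={k: 0.0 for k in ("input", "embedding", "weight",
                                            "hidden", "output")},
                  learning_rate_schedule=[(3, 5e-3)])
model = rl.build_lm(cfg, rng=np.random.default_rng(2))
stream = rl.make_lm_batches(frame_chunks, cfg, np.random.default_rng(3))
report = rl.train_lm(model, stream, stream)

# 4. embeddings and similarity
vecs = rl.embed_reads(model, frame_chunks[:2])
sim = rl.cosine_similarity(vecs[0].values, vecs[1].values)
```

Output:

```
12 genomes, e.g. genome_p1_p1.c1 ({'phylum': 'p1', 'class': 'p1.c1'})
1038 chunks, mean length 138.5 nt, minus-strand fraction 0.502
next-nucleotide accuracy per epoch: [0.291, 0.369, 0.374]
embedding dim 24, cosine(read0, read1) = 0.988
```

The chunker's minus-strand fraction sits at the expected 0.5. The toy
language model beats the 0.25 chance level on codon-structured reads within
three epochs — it is learning the 3-periodic codon statistics — and reads
embed as 24-dim vectors (104-dim at the default configuration) whose cosine
similarity is the package's embedding-similarity measure. The test suite
carries this further: a fine-tuned six-class reading-frame classifier on
synthetic coding fragments reaches ~97% validation accuracy against a 16.7%
chance level, and planted gene families show significantly higher
within-family than between-family embedding similarity.

## Command-line interface

Every step is also a subcommand of the `readlm` console script, each writing
a JSON run manifest (parameters, seed, input hashes, version) next to its
output:

```bash
readlm simulate --seed 3 --out sim/
readlm chunk --fasta sim/genomes.fasta --seed 11 --out chunks.tsv
readlm split --chunks chunks.tsv --taxonomy sim/taxonomy.tsv \
             --rank phylum --assign assign.tsv --out-prefix part
readlm train-lm --config lm.yaml --train part.train.tsv \
                --valid part.validation.tsv --seed 5 --out lm.npz
readlm embed --model lm.npz --reads sim/families.fasta --out emb.tsv
readlm eval-homology --model lm.npz --families-fasta sim/families.fasta \
                     --families-tsv sim/families.tsv --seed 7 --out pairs.tsv
readlm sweep --pairs pairs.tsv --out sweep.tsv
```

Other subcommands: `balance`, `filter-redundant`, `finetune`, `predict`,
`metrics`, `make-frame-set`, `make-temp-set`.

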