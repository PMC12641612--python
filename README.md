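# exolm

Desk-scale toolkit for pretraining nucleotide language models **directly on
aligned short reads**, rather than on an assembled genome or downstream VCF
calls.

Exome sequencing produces short (151 bp) reads aligned to a reference, with
coverage depths anywhere from 1 to 180 reads per position. Training a
transformer on this material raises three problems that this package
implements an explicit recipe for:

1. **Information organization** — reads are fragments, not a continuous
   sequence. `exolm.packing` assembles them into fixed-length token contexts
   under five preparations (consecutive, random, spaced, overlapping,
   reference-only) so their effect on next-token prediction can be compared.
2. **Data redundancy** — deep coverage means most reads repeat what other
   reads already say. `exolm.filtration` ranks reads by
   (carries-a-variant, mean base quality) and keeps exactly ⌈n/k⌉ of them
   (default k = 8), with a repair pass that swaps variant-supporting reads
   back into the retained set.
3. **Signal-to-noise** — variant bases are a tiny fraction of all bases, so
   an unweighted loss teaches the model to echo the reference.
   `exolm.weighting` assigns each token the inverse of its allele's relative
   pileup frequency,

   &nbsp;&nbsp;&nbsp;&nbsp;*u*(p, a) = (c(p, a)/d(p) + ε)^(−α),

   clipped and rescaled to corpus mean 1, so rare (variant) alleles carry
   more of the training signal.

The model itself (`exolm.model`) is a decoder-only transformer written in
pure NumPy with hand-derived backward passes — small enough to train on one
CPU core, complete enough to ablate every axis of the recipe: causal vs
masked (15 %) objectives, rotary / learnable / fixed-sinusoidal / relative
positional encodings, and dense vs sliding-window attention.
`exolm.pretrain` adds weighted-loss AdamW training, two-phase scheduling
(reference genome first, then a read/multispecies mixture), next-token
accuracy evaluation, and an ablation-grid runner. `exolm.tasks` evaluates
trained backbones on variant-centered sequence classification (70/12/18
splits, MCC) and per-layer probing (two-layer MLP, stratified 10-fold CV).

Everything runs from synthetic data: `exolm.simdata` simulates reference
genomes, variant-bearing donors, bounded-coverage 151-bp read sets,
multi-subject cohorts, and a diverged second genome, all seeded, with
FASTA/SAM/VCF export through `exolm.alignio`.

## Worked example

A model can only predict the next base to the extent the sequence is
predictable. The shortest meaningful demonstration is a tandem-repeat
contig, which a 4-layer × 128-dim causal model (≈ 0.8 M parameters) should
learn essentially perfectly:

```python
from exolm import packing
from exolm.core import ReferenceGenome
from exolm.model import ModelConfig, TransformerLM
from exolm.packing import PackingConfig
from exolm.pretrain import TrainConfig, train_two_phase, next_token_accuracy
from exolm.tokenizer import build_vocab

vocab = build_vocab()
ref = ReferenceGenome([("repeat", "ACGT" * 2500)])
corpus = packing.pack_reference(ref, vocab, PackingConfig("reference", 256))

model = TransformerLM(ModelConfig(n_layers=4, d_model=128, n_heads=4,
                                  vocab_size=9, context_length=256, seed=0))
trace = train_two_phase(
    model, corpus, None,
    TrainConfig(steps_phase1=2000, batch_size=8, learning_rate=3e-3,
                seed=0, eval_every=50, stop_accuracy=0.995),
    vocab=vocab, eval_contexts=corpus[:8],
)
res = next_token_accuracy(model, corpus, vocab=vocab)
print(f"steps run: {len(trace.losses)}")
print(f"final loss: {trace.losses[-1]:.4f}")
print(f"next-token accuracy: {res.next_token_accuracy:.3f} over {res.n_scored_slots} slots")
```

Output:

```
steps run: 50
final loss: 0.0349
next-token accuracy: 0.998 over 10000 slots
```

The trainer early-stopped after 50 of the allowed 2000 steps, the weighted
cross-entropy fell to 0.03 nats, and the model predicts 99.8 % of next
bases — against a 25 % chance baseline for uniform random guessing over
A/C/G/T.

## Command line

Every stage is also a subcommand of the `exolm` console script, chained on
files (FASTA/SAM/VCF in, packed `.npz` shards and TSV reports out):

```bash
exolm simulate --seed 3 --outdir run --contig-length 3000 \
      --coverage-min 2 --coverage-max 5 --variant-rate 5e-3
exolm filter   --reads run/reads.sam --reference run/reference.fa \
      --out run/filtered.sam -k 2
exolm pack     --reads run/filtered.sam --reference run/reference.fa \
      --out run/shard --packing consecutive --context-length 256
exolm weight   --shard run/shard --reads run/filtered.sam \
      --reference run/reference.fa --out run/shard_w --weighting dynamic
exolm pretrain --corpus-a run/shard_w --out run/model --phases 200,0
exolm eval     --model run/model --shard run/shard_w
```

`exolm pipeline --outdir run` executes simulate → filter → pack → weight →
pretrain → eval → benchmark/probe end to end from a YAML config and writes
a manifest with a content hash per artifact; identical config + seed
reproduces identical hashes. `exolm grid` trains one model per cell of an
ablation axis (packing strategy, weighting mode, positional encoding,
attention window, …) and renders an all-to-all accuracy matrix.

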