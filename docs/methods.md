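# Methods

This note documents the models and procedures implemented in `exolm`, the
assumptions behind them, and the numerical choices that are not forced by
the problem.

## Read simulator (`exolm.simdata`)

The simulator emulates aligned short-read exome data well enough to
exercise every downstream stage, without claiming to be a sequencing-error
model.

**Genomes.** Reference contigs are uniform random over {A, C, G, T}. Donor
genomes substitute each base independently with probability
`variant_rate` (default 10⁻³); a substitution is uniform over the three
alternative bases. The "multispecies" stand-in applies the same process at
`divergence` = 0.15. Only substitutions are modelled — no indels,
soft-clips, or structural events — so every read aligns with a single
match-run CIGAR and coordinates transfer unchanged between donor and
reference.

**Coverage.** Per 1-kb tile, a target depth is drawn uniformly from
[`coverage_min`, `coverage_max`] (defaults 1 and 180). Reads are then
placed by a left-to-right top-up sweep: at each candidate start position,
reads are added until the running depth meets the local target. Because
coverage from already-placed reads decays over at most one read length
after a tile transition, the depth at every position at least one read
length from a contig end is *guaranteed* to lie inside the configured
band — a hard contract the rest of the toolkit (and its tests) relies on,
which uniform random placement cannot provide. The cost is mildly clustered
read starts, which no downstream stage is sensitive to.

**Reads and qualities.** Reads are 151 bp (configurable), drawn from the
donor with independent per-base errors at `base_error_rate` (default
10⁻³); with both rates at their defaults a typical read carries ~0.3
non-reference bases, and variant-dense configurations reach the 1–2
mismatches characteristic of real exome reads. Phred qualities are integer
draws from a normal (mean 30, sd 5) clipped to [2, 40] — enough structure
to give quality-based filtration a meaningful ranking signal, nothing more.
Subject sub-seeds derive from `SeedSequence(master, spawn_key=(index,))`,
so cohorts are reproducible and per-subject independent.

**What passing tests do not show.** The simulator has no sequencing-by-
synthesis error profile, no quality–error correlation, no paired-end
structure, no GC bias, and random (information-free) reference sequence.
Tests passing on this material demonstrate that the mechanics of the
recipe are correct — contracts, conservation laws, training dynamics — not
that any accuracy level transfers to real exomes.

## Formats (`exolm.alignio`)

In memory everything is 0-based half-open; 1-based coordinates exist only
inside SAM/VCF files (pysam converts at the boundary). Records outside
scope — unmapped, secondary/supplementary, CIGARs with I/D/S operations,
multi-allelic or indel VCF rows — are skipped and counted, never fatal,
because the training recipe consumes matched bases only. BAM is accepted
wherever SAM is; SAM is canonical because fixtures stay human-readable.

## Tokenization (`exolm.tokenizer`)

The vocabulary is fixed at 9 symbols — PAD(0), BOS, SEP, MASK, A, C, G, T,
N — comfortably inside the 16-symbol budget of a 4-bit token dictionary.
Contig identity deliberately lives in context metadata, not in tokens:
giving contigs dedicated tokens would couple the vocabulary to the genome
build, and nothing in the recipe needs it.

## Filtration (`exolm.filtration`)

Reads are ranked globally by (carries-a-variant desc, mean base quality
desc, read id asc) and the top ⌈n/k⌉ are retained (k = 8 by default). The
ceiling (not floor) guarantees non-empty output for any non-empty input.
A repair pass then restores (position, alt-base) evidence lost to the cut:
dropped variant carriers whose evidence is otherwise absent are swapped in
for the lowest-ranked retained non-variant reads.

The retained count is a hard contract and is never grown. This has a
consequence worth stating plainly: when distinct mismatch sites outnumber
the quota — which happens at deep coverage with realistic error rates,
since nearly every sequencing error is a unique (position, base) site —
complete evidence preservation is impossible, and the swap pass preserves
what fits (highest-ranked first). The per-run report counts surviving
variant sites so the loss is observable. An alternative design,
per-position coverage capping, was considered and rejected in favour of
global ranking because it cannot guarantee the exact k-fold reduction.

## Packing (`exolm.packing`)

Every context is `BOS, unit₁, SEP, unit₂, SEP, …, PAD…` with exactly `L`
slots (default 1024, so the nucleotide payload is ≈ 1000 bp). Delimiters
give a causal model an unambiguous read-boundary signal; the loss mask is
False exactly on PAD and BOS (SEP is predicted — read length is itself
learnable signal). Reads are never split across contexts, and contexts
never mix contigs.

* *consecutive* — ascending (contig, start) order.
* *random* — seeded uniform shuffle within each contig.
* *spaced* — greedy non-overlap selection in passes; contexts flush between
  passes, so intervals within one context are pairwise disjoint.
* *overlapping* — maximal chains of overlapping/abutting reads merge into a
  consensus (per-position majority; ties resolve to the reference base);
  merged segments split at the payload capacity `L − 2`.
* *reference* — the genome itself in `L − 2`-bp chunks, for reference-only
  pretraining and evaluation.

## Loss weighting (`exolm.weighting`)

Uniform mode gives every loss-masked slot weight 1. Dynamic mode weights a
nucleotide slot carrying allele *a* at position *p* by

    u(p, a) = (c(p, a) / d(p) + ε)^(−α)

with allele count *c*, depth *d*, ε = 10⁻⁶, exponent α (default 1), raw
weights clipped to [1/100, 100], and nucleotide weights rescaled to mean 1
over the corpus (SEP slots stay at exactly 1, so the overall loss-masked
mean is also exactly 1). Properties that follow and are tested: a strictly
rarer allele gets a strictly larger weight wherever clipping does not bind;
α = 0 reproduces uniform weighting exactly; at α = 1 each allele's *total*
weighted mass at a position equalizes (count × 1/frequency = depth), which
is precisely the "normalization" the method aims for — the reference
allele can no longer dominate by count alone. The production values of α,
the clip, and ε are declared defaults, not inferred quantities.

## Model (`exolm.model`)

A pre-norm decoder transformer: token embedding, `n_layers` blocks of
multi-head self-attention plus a GELU feed-forward (4× expansion, tanh
approximation), final LayerNorm, untied output head. Desk defaults are 4
layers × 128 dims (≈ 0.8 M parameters); the production-scale 20 × 1856
configuration (≈ 0.8 B parameters at 29 heads) is expressible in config
but never instantiated by tests. Feed-forward ratio, activation, and norm
placement are conventional choices documented here as assumptions — they
are not dictated by the recipe.

Forward *and backward* passes are hand-written NumPy; every gradient is
verified against central finite differences in the test suite, and all
computation is bit-reproducible on CPU for a fixed seed. Initialization is
N(0, 0.02²) throughout.

Positional encodings (all interchangeable behind one config field):

* *rotary* — per-head-pair rotation of q/k with base 10000; attention
  scores depend only on relative offset (shift invariance is tested
  directly on single-layer score matrices).
* *learnable* — trained additive table of shape (L, d).
* *fixed* — sinusoidal additive table.
* *relative* — a learned shared bias per (head, offset), added to scores.

Attention masks: causal (j ≤ i) or bidirectional for the MLM objective; a
sliding window keeps the `w` most recent visible keys (causal) or the
symmetric band |i − j| < `w` (MLM). `w = L` reproduces dense attention
bit-exactly.

MLM corruption selects exactly round(0.15 × maskable) nucleotide slots per
context without replacement and applies the standard 80 % MASK / 10 %
random-base / 10 % unchanged recipe; contexts where the round hits zero
are skipped.

## Training and evaluation (`exolm.pretrain`)

The loss is Σ wᵢ·CEᵢ / Σ wᵢ over loss-masked slots; with uniform weights
this is exactly mean cross-entropy. The optimizer is AdamW (β = 0.9/0.999,
weight decay 0.01 on matrices only) at a fixed learning rate — schedules
add state without benefit at these scales. Two-phase training draws phase-1
batches from corpus A only and each phase-2 batch from corpus B with
probability `mix_ratio` (the 50:50 / 14:86 mixing axis), over the
`subset_fraction` of B made available (the "15 % of the multispecies
corpus" axis). An optional periodic evaluation early-stops once a target
accuracy is reached.

Next-token accuracy scores, for every slot whose token is one of the four
bases and whose loss mask is set, the argmax over the A/C/G/T logits at
the preceding slot. N is an ambiguity symbol, not a base call, so it is
excluded from targets and candidates alike — which also puts the uniform
chance baseline at exactly 1/4. An optional per-slot restriction mask
narrows scoring, e.g. to variant-supporting slots (token ≠ reference base
at that position). MLM models are scored by masked-token recovery instead,
since next-token prediction is undefined for bidirectional attention.

The ablation-grid runner trains one seeded model per cell of a named axis
set and evaluates it on every requested preparation, recording failures
per cell without aborting the grid; results are long-format tables plus
rendered accuracy matrices.

## Downstream tasks (`exolm.tasks`)

Benchmarks follow the variant-centered pattern: positives are reference
windows centered on a variant with the alternate allele substituted in;
controls are intact windows at seeded random non-variant positions. Near
contig edges the window shifts inward rather than padding — padding with N
would hand the classifier an alphabet signal. Splits are 70/12/18
(train/validation/test), sizes round(f·n) with the remainder to test,
stratified per class by default.

MCC is computed from the closed form with the 0-by-convention rule for
degenerate denominators; the implementation is checked against an
independent library oracle on 1000 random confusion tables.

Fine-tuning attaches a linear head to mean-pooled (over non-PAD slots)
final-layer states and trains end to end (backbone unfrozen unless
requested) at learning rate 3·10⁻⁴; the checkpoint with the best
validation MCC is kept and test MCC is reported once. Mean pooling for
both fine-tuning and probing is an assumption, documented here.

Probing freezes the backbone, extracts mean-pooled embeddings at layers
0 … n (layer 0 = post-embedding), and runs stratified 10-fold CV of a
two-layer MLP (hidden width 64) per layer. Embeddings are standardized
inside each fold's pipeline: raw residual-stream scales differ by orders
of magnitude across layers, and an unscaled MLP simply predicts the
majority class. The backbone is verified bit-unchanged after probing.

## Pipeline (`exolm.pipeline`, `exolm.cli`)

The pipeline runner executes simulate → filter → pack → weight → pretrain
→ eval → benchmark/probe from one YAML config (unknown keys are an error
naming the key), writing a manifest with config snapshot, seeds, stage
timings, and a content hash per artifact. Hashes cover array contents for
`.npz` files and raw bytes otherwise, so identical config + seed yields
identical hashes even though zip containers embed timestamps.

## Problem sizes

Defaults are chosen so the full recipe runs on a single CPU core: the toy
pipeline uses a 3-kb contig, 2 subjects, coverage 2–6, 256-token contexts,
and a 2 × 64 model (~25 s end to end); behavioral checks use 100–110 kb
genomes for statistical bounds, a 4 × 128 model for memorization, and a
3-kb, 5-subject cohort at variant rate 5·10⁻³ trained 500 steps per arm
for the weighting comparison. These sizes are the package's study
conditions, stated here so results are interpreted at the scale they were
produced.

## Known limitations

* The simulator's reference sequence is random, so "accuracy" on it
  measures memorization capacity, not genomic structure.
* Dynamic weighting assumes the pileup used for weights is the same read
  set being packed; weights are not recomputed if contexts are filtered
  afterwards.
* The overlapping consensus is unweighted majority voting; base qualities
  do not enter the merge.
* Classification heads and probes support binary tasks only.
* No learning-rate schedules, mixed precision, or multi-device training.
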