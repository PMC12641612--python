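"""End-to-end seeded pipeline: simulate -> filter -> pack -> weight ->
pretrain -> eval -> benchmark/probe, with a run manifest.

The manifest records the config snapshot, seeds, artifact paths, stage
timings, and a content hash per produced artifact (array contents for .npz
shards/checkpoints, raw bytes otherwise), so identical config + seed
reproduces identical hashes.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import yaml

from . import alignio, filtration, packing, pretrain, simdata, tasks, weighting
from .model import ModelConfig, TransformerLM
from .tokenizer import build_vocab

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "sim": {
        "n_contigs": 1,
        "contig_length": 3000,
        "read_length": 151,
        "coverage_min": 2,
        "coverage_max": 6,
        "variant_rate": 5e-3,
        "base_error_rate": 1e-3,
        "n_subjects": 2,
        "divergence": 0.15,
    },
    "filter": {"reduction_factor": 2, "preserve_variants": True},
    "pack": {"strategy": "consecutive", "context_length": 256},
    "weight": {"mode": "dynamic", "alpha": 1.0},
    "model": {
        "n_layers": 2,
        "d_model": 64,
        "n_heads": 2,
        "positional_encoding": "rotary",
        "objective": "causal",
    },
    "train": {
        "steps_phase1": 60,
        "steps_phase2": 40,
        "batch_size": 8,
        "learning_rate": 3e-3,
        "mix_ratio": 0.5,
        "subset_fraction": 1.0,
    },
    "tasks": {"window": 31, "controls": 60, "probe_folds": 10, "run_probe": True},
}


def load_config(path=None) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _merge(cfg, user, [])
    return cfg


def _merge(base: dict, user: dict, trail: list[str]) -> None:
    for key, val in user.items():
        if key not in base:
            raise ValueError(f"unknown config key: {'.'.join(trail + [str(key)])}")
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                raise ValueError(f"config key {'.'.join(trail + [str(key)])} must be a mapping")
            _merge(base[key], val, trail + [str(key)])
        else:
            base[key] = val


def artifact_hash(path) -> str:
    """Content hash: array contents for .npz, raw bytes otherwise."""
    path = Path(path)
    h = hashlib.sha256()
    if path.suffix == ".npz":
        with np.load(path) as data:
            for key in sorted(data.files):
                arr = np.ascontiguousarray(data[key])
                h.update(key.encode())
                h.update(str(arr.dtype).encode())
                h.update(str(arr.shape).encode())
                h.update(arr.tobytes())
    else:
        h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict, outdir) -> dict:
    """Execute every stage in order; returns the manifest (also written to
    ``outdir/manifest.json``). A stage failure raises with the stage named;
    artifacts produced so far stay on disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest: dict = {
        "config": config,
        "seed": seed,
        "artifacts": {},
        "timings": {},
    }
    vocab = build_vocab()

    def stage(name):
        log.info("pipeline stage: %s", name)
        return _Timer(manifest, name)

    def record(name, path):
        manifest["artifacts"][name] = {
            "path": str(path),
            "sha256": artifact_hash(path),
        }

    try:
        with stage("simulate"):
            sim_cfg = simdata.SimConfig(seed=seed, **config["sim"])
            ref = simdata.simulate_reference(sim_cfg)
            cohort = simdata.simulate_cohort(ref, sim_cfg)
            diverged = simdata.simulate_diverged_genome(ref, sim_cfg.divergence, seed + 1)
            alignio.write_fasta(ref, outdir / "reference.fa")
            alignio.write_fasta(diverged, outdir / "diverged.fa")
            all_reads = [r for _, reads, _ in cohort for r in reads]
            all_vars = sorted(
                (v for _, _, vt in cohort for v in vt),
                key=lambda v: (v.contig, v.position),
            )
            # de-duplicate positions hit in several subjects (keep first)
            seen, uniq = set(), []
            for v in all_vars:
                if (v.contig, v.position) not in seen:
                    seen.add((v.contig, v.position))
                    uniq.append(v)
            variants = simdata.VariantTable(uniq)
            alignio.write_alignments(all_reads, ref.lengths(), outdir / "reads.sam")
            alignio.write_variants(variants, ref.lengths(), outdir / "variants.vcf")
        record("reference", outdir / "reference.fa")
        record("diverged", outdir / "diverged.fa")
        record("reads", outdir / "reads.sam")
        record("variants", outdir / "variants.vcf")

        with stage("filter"):
            fcfg = filtration.FiltrationConfig(**config["filter"])
            kept = filtration.filter_reads(all_reads, ref, fcfg)
            report = filtration.filtration_report(all_reads, kept, ref)
            alignio.write_alignments(kept, ref.lengths(), outdir / "filtered.sam")
            with open(outdir / "filtration.tsv", "w") as fh:
                fh.write("\t".join(report) + "\n")
                fh.write("\t".join(str(report[k]) for k in report) + "\n")
        record("filtered_reads", outdir / "filtered.sam")
        record("filtration_report", outdir / "filtration.tsv")

        with stage("pack"):
            pcfg = packing.PackingConfig(seed=seed, **config["pack"])
            corpus_ref = packing.pack_reference(
                ref, vocab, replace(pcfg, strategy="reference")
            )
            corpus_reads = packing.pack(kept, ref, vocab, pcfg)
            packing.save_shard(corpus_ref, outdir / "shard_ref", pcfg)
            packing.save_shard(corpus_reads, outdir / "shard_reads", pcfg)
        record("shard_ref", outdir / "shard_ref.npz")
        record("shard_reads", outdir / "shard_reads.npz")

        with stage("weight"):
            wcfg = weighting.WeightingConfig(**config["weight"])
            pileup = weighting.build_pileup(kept, ref)
            corpus_reads = weighting.compute_weights(corpus_reads, pileup, wcfg, vocab)
            packing.save_shard(corpus_reads, outdir / "shard_reads_weighted", pcfg)
        record("shard_reads_weighted", outdir / "shard_reads_weighted.npz")

        with stage("pretrain"):
            mcfg = ModelConfig(
                vocab_size=len(vocab),
                context_length=config["pack"]["context_length"],
                seed=seed,
                **config["model"],
            )
            model = TransformerLM(mcfg)
            tcfg = pretrain.TrainConfig(seed=seed, **config["train"])
            trace = pretrain.train_two_phase(
                model, corpus_ref, corpus_reads, tcfg, vocab=vocab
            )
            model.save(outdir / "model")
            np.savetxt(outdir / "loss_trace.tsv", np.asarray(trace.losses), fmt="%.6f")
        record("model", outdir / "model.npz")
        record("loss_trace", outdir / "loss_trace.tsv")

        with stage("eval"):
            rows = []
            for name, corpus in (("reference", corpus_ref), ("reads", corpus_reads)):
                res = pretrain.next_token_accuracy(model, corpus, vocab=vocab, dataset=name)
                rows.append((name, res.next_token_accuracy, res.n_scored_slots))
            with open(outdir / "eval.tsv", "w") as fh:
                fh.write("dataset\tnext_token_accuracy\tn_scored_slots\n")
                for name, acc, n in rows:
                    fh.write(f"{name}\t{acc:.6f}\t{n}\n")
        record("eval", outdir / "eval.tsv")

        tcfg_tasks = config["tasks"]
        with stage("tasks"):
            ds = tasks.build_variant_benchmark(
                variants,
                ref,
                window=tcfg_tasks["window"],
                controls=tcfg_tasks["controls"],
                seed=seed,
            )
            with open(outdir / "benchmark.tsv", "w") as fh:
                fh.write("sequence\tlabel\torigin\n")
                for r in ds.records:
                    fh.write(f"{r.sequence}\t{r.label}\t{r.origin}\n")
            if tcfg_tasks["run_probe"]:
                report = tasks.probe_layers(
                    model, ds, folds=tcfg_tasks["probe_folds"], seed=seed, vocab=vocab
                )
                with open(outdir / "probe.tsv", "w") as fh:
                    fh.write("layer\t" + "\t".join(f"fold{i}" for i in range(report.folds)) + "\n")
                    for layer, vals in sorted(report.per_layer_mcc.items()):
                        fh.write(f"{layer}\t" + "\t".join(f"{v:.6f}" for v in vals) + "\n")
        record("benchmark", outdir / "benchmark.tsv")
        if tcfg_tasks["run_probe"]:
            record("probe", outdir / "probe.tsv")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {_Timer.current!r}: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


class _Timer:
    current: str | None = None

    def __init__(self, manifest, name):
        self.manifest, self.name = manifest, name

    def __enter__(self):
        _Timer.current = self.name
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, *exc):
        self.manifest["timings"][self.name] = round(time.perf_counter() - self.t0, 3)
        if exc[0] is None:
            _Timer.current = None
        return False
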