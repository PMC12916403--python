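"""End-to-end pipeline: simulate → preprocess → pretext → pretrain → train →
generate → evaluate → distribution check, with a reproducibility manifest.

One global seed fans out to per-stage seeds through ``numpy.random
.SeedSequence.spawn`` in a fixed stage order, so any stage can be re-run
deterministically.  The manifest records the config echo, per-stage seeds and
content digests of every artifact; deterministic stages reproduce identical
digests under identical config + seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from . import distcheck, models, preprocess, synthdata, training, transforms
from .config import PipelineConfig
from .evaluation import evaluate_windows

STAGES = ("simulate", "preprocess", "pretext", "pretrain", "train",
          "generate", "evaluate", "distcheck")


def stage_seeds(global_seed: int) -> dict:
    """Deterministic per-stage seeds (< 2^31) from one global seed."""
    seqs = np.random.SeedSequence(global_seed).spawn(len(STAGES))
    return {name: int(s.generate_state(1)[0] % (2**31))
            for name, s in zip(STAGES, seqs)}


def digest_path(path: Path) -> str:
    """Content digest; .npz archives are hashed member-wise so the digest
    depends only on array contents, not zip metadata."""
    h = hashlib.sha256()
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            for name in sorted(z.files):
                h.update(name.encode())
                h.update(np.ascontiguousarray(z[name]).tobytes())
    else:
        h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig, out_dir, force: bool = False) -> dict:
    """Execute all stages under ``out_dir``; returns the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(cfg.seed)
    manifest = {"config": cfg.model_dump(), "seeds": seeds, "stages": {},
                "started": time.time()}

    def record(stage, *paths, **info):
        manifest["stages"][stage] = {
            "artifacts": {p.name: digest_path(p) for p in paths}, **info}

    # -- simulate -----------------------------------------------------------
    cohort_dir = out / "cohort"
    if force or not cohort_dir.exists():
        records = synthdata.make_cohort(
            cfg.simulate.n_subjects, cfg.simulate.duration_s,
            seed=seeds["simulate"], ecg_fs=cfg.simulate.ecg_fs,
            ppg_fs=cfg.simulate.ppg_fs,
            artifact_level=cfg.simulate.artifact_level)
        synthdata.write_cohort(records, cohort_dir)
    records = synthdata.read_cohort(cohort_dir)
    record("simulate", *sorted(cohort_dir.glob("*/*.csv")),
           n_subjects=len(records))

    # -- preprocess ---------------------------------------------------------
    pcfg = preprocess.PreprocessConfig(
        target_fs=cfg.preprocess.target_fs, window_s=cfg.preprocess.window_s,
        overlap_frac=cfg.preprocess.overlap_frac,
        median_kernel=cfg.preprocess.median_kernel)
    seg_path = out / "segments.npz"
    if force or not seg_path.exists():
        pairs = preprocess.preprocess_cohort(records, pcfg)
        preprocess.save_segments(seg_path, pairs, pcfg)
    pairs, _ = preprocess.load_segments(seg_path)
    record("preprocess", seg_path, n_segments=len(pairs))

    # -- pretext dataset ----------------------------------------------------
    pretext_path = out / "pretext.npz"
    if force or not pretext_path.exists():
        examples = transforms.build_pretext_dataset(
            [sp.e for sp in pairs], seed=seeds["pretext"])
        np.savez(pretext_path,
                 signal=np.stack([ex.signal for ex in examples]),
                 labels=np.stack([ex.labels for ex in examples]))
    with np.load(pretext_path) as z:
        ex_sig, ex_lab = z["signal"], z["labels"]
    record("pretext", pretext_path, n_examples=len(ex_sig))

    # -- critic pre-training ------------------------------------------------
    dcfg = (models.reduced_discriminator_config() if cfg.train.reduced
            else models.DiscriminatorConfig())
    critic = models.Discriminator(
        dcfg, np.random.default_rng(seeds["pretrain"]))
    examples = [transforms.PretextExample(s, l) for s, l in zip(ex_sig, ex_lab)]
    critic_path = out / "critic_pretrained.npz"
    critic, pre_report = training.pretrain_multitask(
        examples, critic, epochs=cfg.pretext.epochs, batch=cfg.pretext.batch,
        lr=cfg.pretext.lr, n_folds=cfg.pretext.n_folds,
        seed=seeds["pretrain"])
    from .nn import save_checkpoint
    save_checkpoint(critic_path, critic, {"stage": "pretrain",
                                          "seed": seeds["pretrain"]})
    record("pretrain", critic_path,
           task_accuracy=pre_report["task_accuracy"])

    # -- adversarial fine-tuning with the frozen-transformer transfer -------
    gcfg = (models.reduced_generator_config(
        max_tokens=max(cfg.preprocess.window_s * 33, 520))
        if cfg.train.reduced else models.GeneratorConfig())
    generator = models.Generator(gcfg, np.random.default_rng(seeds["train"]))
    tcfg = training.TrainConfig(
        epochs=cfg.train.epochs, batch=cfg.train.batch, lr=cfg.train.lr,
        betas=cfg.train.betas,
        critic_steps_per_gen=cfg.train.critic_steps_per_gen,
        recon_weight=cfg.train.recon_weight, seed=seeds["train"])
    generator, critic, history = training.train_gan(
        pairs, generator, critic, tcfg,
        training.GPParams(cfg.train.gp_lambda), freeze_transformer=True,
        steps_per_epoch=cfg.train.steps_per_epoch)
    gen_path = out / "generator.npz"
    save_checkpoint(gen_path, generator, {"stage": "train",
                                          "seed": seeds["train"]})
    hist_path = out / "history.csv"
    import pandas as pd
    pd.DataFrame(history).to_csv(hist_path, index=False)
    record("train", gen_path, hist_path,
           final_loss_d=history["loss_d"][-1],
           final_grad_norm=history["grad_norm_mean"][-1])

    # -- generation + evaluation -------------------------------------------
    def generate_fn(p):
        with ad.no_grad():
            return generator(Tensor(p[None, :])).data[0]

    report = evaluate_windows({cfg.preprocess.window_s: pairs}, generate_fn,
                              fs=cfg.preprocess.target_fs)
    eval_path = out / "metrics.csv"
    report.table.to_csv(eval_path, index=False)
    record("evaluate", eval_path,
           rmse_mean=float(report.table["rmse_mean"].iloc[0]))

    # -- distributional check ----------------------------------------------
    n_embed = min(cfg.evaluation.n_embed, len(pairs))
    real_w = np.stack([sp.e for sp in pairs[:n_embed]])
    gen_w = np.stack([generate_fn(sp.p) for sp in pairs[:n_embed]])
    emb_r = distcheck.extract_embeddings(critic, real_w, "real")
    emb_g = distcheck.extract_embeddings(critic, gen_w, "generated")
    dist_report = distcheck.distribution_report(
        emb_r, emb_g, n_perm=cfg.evaluation.n_perm, seed=seeds["distcheck"])
    dist_path = out / "distcheck.json"
    dist_path.write_text(json.dumps(dist_report, indent=2))
    record("distcheck", dist_path, **dist_report)

    manifest["finished"] = time.time()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
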