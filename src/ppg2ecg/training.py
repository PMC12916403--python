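"""WGAN-GP training: losses, gradient penalty, pretext pre-training,
frozen-transfer adversarial fine-tuning, LOSO splits and the grid expander.

Loss conventions (critic = Wasserstein discriminator D, generator G):

    L_G  = −E[D(G(p))]
    L_D  = −E[D(e)] + E[D(G(p))] + λ·E[(‖∇_x̂ D(x̂)‖₂ − 1)²]
    x̂    = ε·e + (1−ε)·G(p),  ε ~ U(0, 1) per sample

The gradient penalty differentiates the critic with respect to its input and
then the penalty with respect to the critic's parameters (double backprop,
handled by the in-package autodiff engine).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

from . import autodiff as ad
from .autodiff import Tensor, grad
from .models import Discriminator, Generator


@dataclass(frozen=True)
class GPParams:
    lam: float = 30.0

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("gradient-penalty coefficient must be >= 0")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 90
    batch: int = 128
    lr: float = 0.001
    betas: tuple = (0.5, 0.9)
    critic_steps_per_gen: int = 5
    early_stop_patience: int = 10
    recon_weight: float = 0.0       # optional supervised term; 0 = pure WGAN
    divergence_bound: float = 1e4
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch < 1:
            raise ValueError("epochs and batch must be >= 1")
        if not (0 < self.betas[0] < 1 and 0 < self.betas[1] < 1):
            raise ValueError("Adam betas must lie strictly in (0, 1)")


@dataclass(frozen=True)
class LOSOSplit:
    fold_id: int
    train_subjects: tuple
    test_subject: str
    val_fraction: float = 0.10


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def generator_loss(critic_scores_on_fake: Tensor) -> Tensor:
    """L_G = −mean of critic scores on generated samples."""
    if critic_scores_on_fake.size == 0:
        raise ValueError("empty batch")
    return -critic_scores_on_fake.mean()


def critic_loss(scores_real: Tensor, scores_fake: Tensor, gp) -> Tensor:
    """L_D = −mean(real) + mean(fake) + gradient penalty."""
    if scores_real.size == 0 or scores_fake.size == 0:
        raise ValueError("empty batch")
    return -scores_real.mean() + scores_fake.mean() + gp


def gradient_penalty(critic_fn, real: Tensor, fake: Tensor, lam: float,
                     rng: np.random.Generator, return_norms: bool = False):
    """λ·E[(‖∇_x̂ D(x̂)‖₂ − 1)²] at per-sample uniform interpolates.

    ``critic_fn`` maps a (B, T) tensor to (B,) scores.  The returned tensor
    participates in the critic's parameter gradients (create_graph=True).
    """
    if real.shape != fake.shape:
        raise ValueError("real and fake batches must share a shape")
    eps = rng.uniform(0, 1, size=(real.shape[0],) + (1,) * (real.ndim - 1))
    x_hat = Tensor(eps) * real.detach() + Tensor(1.0 - eps) * fake.detach()
    x_hat.requires_grad = True
    scores = critic_fn(x_hat)
    g = grad(scores.sum(), x_hat, create_graph=True)
    axes = tuple(range(1, real.ndim))
    norms = ad.sqrt((g * g).sum(axis=axes) + 1e-12)
    penalty = Tensor(np.array(float(lam))) * ((norms - 1.0) ** 2).mean()
    if return_norms:
        return penalty, norms.data.copy()
    return penalty


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2 = self.betas
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            gd = g.data if isinstance(g, Tensor) else g
            m[...] = b1 * m + (1 - b1) * gd
            v[...] = b2 * v + (1 - b2) * gd * gd
            mh = m / (1 - b1**self.t)
            vh = v / (1 - b2**self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)


# ---------------------------------------------------------------------------
# pretext pre-training (multi-task, six binary heads)
# ---------------------------------------------------------------------------

def _bce_with_logits(logits: Tensor, targets: np.ndarray,
                     pos_weight: np.ndarray | None = None) -> Tensor:
    """Mean binary cross-entropy over all heads and samples.

    ``pos_weight`` (per head) counteracts the 1:6 class imbalance of the
    one-vs-rest pretext labels.
    """
    t = Tensor(targets)
    w = Tensor(pos_weight) if pos_weight is not None else Tensor(np.array(1.0))
    # -[w·t·log σ(x) + (1−t)·log σ(−x)]
    return -(w * t * ad.logsigmoid(logits)
             + (1.0 - t) * ad.logsigmoid(-logits)).mean()


def pretrain_multitask(examples, critic: Discriminator, epochs: int = 5,
                       batch: int = 32, lr: float = 1e-3, n_folds: int = 10,
                       seed: int = 0, verbose: bool = False):
    """Train the critic trunk + pretext heads on the six pseudo-label tasks.

    Returns ``(critic, report)`` where the report holds per-task validation
    accuracy from k-fold cross-validation (run on a fresh head each fold)
    followed by a final fit on all examples.
    """
    X = np.stack([ex.signal for ex in examples])
    Y = np.stack([ex.labels for ex in examples])
    if np.any(Y.sum(axis=0) == 0) or np.any(Y.sum(axis=0) == len(Y)):
        raise ValueError("every pretext task needs both classes present")
    rng = np.random.default_rng(seed)
    init_state = critic.state_dict()
    n_pos = Y.sum(axis=0)
    pos_weight = np.clip((len(Y) - n_pos) / n_pos, 1.0, 10.0)

    def _fit(x_tr, y_tr, x_va=None, y_va=None):
        critic.load_state_dict(init_state)
        params = critic.parameters()
        opt = Adam(params, lr=lr, betas=(0.9, 0.999))
        order_rng = np.random.default_rng(rng.integers(2**31))
        losses = []
        for _ in range(epochs):
            order = order_rng.permutation(len(x_tr))
            for lo in range(0, len(x_tr), batch):
                idx = order[lo:lo + batch]
                logits, _, _ = critic(Tensor(x_tr[idx]), mode="pretext")
                loss = _bce_with_logits(logits, y_tr[idx], pos_weight)
                opt.step(grad(loss, params))
                losses.append(loss.item())
        acc = None
        if x_va is not None:
            with ad.no_grad():
                logits, _, _ = critic(Tensor(x_va), mode="pretext")
            pred = (logits.data > 0).astype(float)
            acc = (pred == y_va).mean(axis=0)     # per-task accuracy
        return losses, acc

    per_task = []
    if n_folds >= 2:
        for tr_idx, va_idx in KFold(n_splits=n_folds, shuffle=True,
                                    random_state=seed).split(X):
            _, acc = _fit(X[tr_idx], Y[tr_idx], X[va_idx], Y[va_idx])
            per_task.append(acc)
    losses, _ = _fit(X, Y)
    report = {
        "task_accuracy": (np.mean(per_task, axis=0).tolist()
                          if per_task else None),
        "final_loss": losses[-1] if losses else None,
        "loss_history": losses,
    }
    return critic, report


# ---------------------------------------------------------------------------
# adversarial training
# ---------------------------------------------------------------------------

def pretrain_generator(generator: Generator, pairs, steps: int = 1000,
                       lr: float = 1e-3, seed: int = 0,
                       batch: int | None = None):
    """Supervised reconstruction warm-start / capacity check (MSE objective)."""
    P = np.stack([sp.p for sp in pairs])
    E = np.stack([sp.e for sp in pairs])
    params = generator.parameters()
    opt = Adam(params, lr=lr, betas=(0.9, 0.999))
    rng = np.random.default_rng(seed)
    b = batch or len(P)
    history = []
    for _ in range(steps):
        idx = rng.permutation(len(P))[:b]
        out = generator(Tensor(P[idx]))
        loss = ((out - Tensor(E[idx])) ** 2).mean()
        opt.step(grad(loss, params))
        history.append(loss.item())
    with ad.no_grad():
        rmse = float(np.sqrt(np.mean((generator(Tensor(P)).data - E) ** 2)))
    return generator, {"loss_history": history, "train_rmse": rmse}


def train_gan(pairs, generator: Generator, critic: Discriminator,
              cfg: TrainConfig, gp: GPParams,
              freeze_transformer: bool = False, val_pairs=None,
              steps_per_epoch: int | None = None, verbose: bool = False):
    """Alternating WGAN-GP optimisation; returns (generator, critic, history).

    When ``freeze_transformer`` is set (pre-trained critic transfer), the
    critic's Transformer-block parameters are excluded from the optimizer and
    asserted unchanged.  History rows per epoch: generator loss, critic loss,
    gradient penalty, mean critic gradient norm at interpolates, validation
    RMSE (if validation pairs were given).
    """
    P = np.stack([sp.p for sp in pairs])
    E = np.stack([sp.e for sp in pairs])
    rng = np.random.default_rng(cfg.seed)
    g_params = generator.parameters()
    frozen = set()
    if freeze_transformer:
        frozen = {id(p) for p in critic.transformer_parameters()}
    d_params = [p for p in critic.parameters() if id(p) not in frozen]
    opt_g = Adam(g_params, lr=cfg.lr, betas=cfg.betas)
    opt_d = Adam(d_params, lr=cfg.lr, betas=cfg.betas)

    spe = steps_per_epoch or max(len(P) // cfg.batch, 1)
    history = {k: [] for k in ("loss_g", "loss_d", "gp", "grad_norm_mean",
                               "val_rmse")}
    best_val, best_state, patience = np.inf, None, 0
    diverged_epochs = 0

    def sample_batch():
        idx = rng.integers(len(P), size=min(cfg.batch, len(P)))
        return P[idx], E[idx]

    for epoch in range(cfg.epochs):
        ep = {k: [] for k in ("loss_g", "loss_d", "gp", "norms")}
        for _ in range(spe):
            # --- critic updates -------------------------------------------
            for _ in range(cfg.critic_steps_per_gen):
                p_np, e_np = sample_batch()
                with ad.no_grad():
                    fake = generator(Tensor(p_np)).detach()
                real = Tensor(e_np)
                scores_real, _, _ = critic(real)
                scores_fake, _, _ = critic(fake)
                pen, norms = gradient_penalty(
                    lambda x: critic(x)[0], real, fake, gp.lam, rng,
                    return_norms=True)
                loss_d = critic_loss(scores_real, scores_fake, pen)
                opt_d.step(grad(loss_d, d_params))
                ep["loss_d"].append(loss_d.item())
                ep["gp"].append(pen.item())
                ep["norms"].extend(norms.tolist())
            # --- generator update -----------------------------------------
            p_np, e_np = sample_batch()
            fake = generator(Tensor(p_np))
            scores_fake, _, _ = critic(fake)
            loss_g = generator_loss(scores_fake)
            if cfg.recon_weight > 0:
                loss_g = loss_g + cfg.recon_weight * (
                    (fake - Tensor(e_np)) ** 2).mean()
            opt_g.step(grad(loss_g, g_params))
            ep["loss_g"].append(loss_g.item())

        history["loss_g"].append(float(np.mean(ep["loss_g"])))
        history["loss_d"].append(float(np.mean(ep["loss_d"])))
        history["gp"].append(float(np.mean(ep["gp"])))
        history["grad_norm_mean"].append(float(np.mean(ep["norms"])))

        if val_pairs:
            vp = np.stack([sp.p for sp in val_pairs])
            ve = np.stack([sp.e for sp in val_pairs])
            with ad.no_grad():
                vr = float(np.sqrt(np.mean((generator(Tensor(vp)).data - ve) ** 2)))
            history["val_rmse"].append(vr)
            if vr < best_val - 1e-6:
                best_val, patience = vr, 0
                best_state = generator.state_dict()
            else:
                patience += 1
                if patience >= cfg.early_stop_patience:
                    break
        else:
            history["val_rmse"].append(np.nan)

        if abs(history["loss_d"][-1]) > cfg.divergence_bound:
            diverged_epochs += 1
            if diverged_epochs >= 3:
                raise RuntimeError("critic loss diverged for 3 consecutive epochs")
        else:
            diverged_epochs = 0
        if verbose:
            print(f"epoch {epoch}: " +
                  ", ".join(f"{k}={history[k][-1]:.4f}" for k in history))

    if best_state is not None:
        generator.load_state_dict(best_state)
    return generator, critic, history


# ---------------------------------------------------------------------------
# cross-validation and grid search plumbing
# ---------------------------------------------------------------------------

def loso_folds(subject_ids, val_fraction: float = 0.10,
               seed: int = 0) -> list[LOSOSplit]:
    """One fold per subject; validation drawn from training subjects only."""
    subject_ids = list(subject_ids)
    if len(subject_ids) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    if len(set(subject_ids)) != len(subject_ids):
        raise ValueError("duplicate subject ids")
    folds = []
    for i, test in enumerate(subject_ids):
        train = tuple(s for s in subject_ids if s != test)
        folds.append(LOSOSplit(i, train, test, val_fraction))
    return folds


def split_fold_segments(pairs, fold: LOSOSplit, seed: int = 0):
    """Partition SegmentPairs into (train, val, test) for one LOSO fold.

    Validation segments come only from training subjects; the audit that no
    test-subject segment leaks is the caller's (and the test-suite's) job.
    """
    test = [sp for sp in pairs if sp.subject_id == fold.test_subject]
    pool = [sp for sp in pairs if sp.subject_id in fold.train_subjects]
    rng = np.random.default_rng(seed + fold.fold_id)
    idx = rng.permutation(len(pool))
    n_val = round(fold.val_fraction * len(pool))
    val = [pool[i] for i in idx[:n_val]]
    train = [pool[i] for i in idx[n_val:]]
    return train, val, test


GRID = {
    "lambda": [4, 6, 30, 50],
    "lr": [0.001, 0.002, 0.005],
    "batch": [64, 128],
}


def expand_grid(grid: dict | None = None, budget: int | None = None,
                seed: int = 0) -> list[dict]:
    """Cartesian expansion of a hyper-parameter grid with an optional cap."""
    from itertools import product
    grid = grid or GRID
    keys = sorted(grid)
    configs = [dict(zip(keys, vals)) for vals in product(*(grid[k] for k in keys))]
    if budget is not None and budget < len(configs):
        rng = np.random.default_rng(seed)
        configs = [configs[i] for i in
                   sorted(rng.choice(len(configs), budget, replace=False))]
    return configs
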