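"""Stochastic-gradient training with warmup + cosine learning-rate decay.

The published schedule (batch 128, 200,000 Adam iterations, linear
warmup over 1,000 iterations, cosine decay from 6e-4 to 6e-5, float32)
is expressed in :class:`TrainConfig`; :meth:`TrainConfig.desk_scale`
gives a profile sized for synthetic cohorts on a single CPU.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterator, Sequence

import numpy as np
import pandas as pd

from ._autodiff import Adam
from .loss import TargetPairing, pair_targets_batch, total_loss
from .model import TrajectoryTransformer
from .trajectory import Trajectory
from .vocab import TokenVocabulary


@dataclass
class TrainConfig:
    batch_size: int = 128
    total_iters: int = 200_000
    warmup_iters: int = 1_000
    lr_max: float = 6e-4
    lr_min: float = 6e-5
    seed: int = 0
    block_tokens: int = 256
    grad_clip: float = 1.0  # global gradient-norm ceiling; 0 disables
    log_every: int = 50
    checkpoint_every: int = 0  # 0 disables

    def __post_init__(self):
        if not self.warmup_iters < self.total_iters:
            raise ValueError("warmup_iters must be < total_iters")
        if self.lr_min > self.lr_max:
            raise ValueError("lr_min must be <= lr_max")

    @classmethod
    def desk_scale(cls, **kw) -> "TrainConfig":
        """Profile sized for synthetic cohorts on one CPU.

        The learning rate is 10x the full-scale schedule: a fit of a
        few thousand iterations must first descend the global rate
        scale (several nats of logit shift) before conditioning can be
        learned, and the full-scale rate does not get there.
        """
        kw.setdefault("batch_size", 48)
        kw.setdefault("total_iters", 6_000)
        kw.setdefault("warmup_iters", 200)
        kw.setdefault("lr_max", 6e-3)
        kw.setdefault("lr_min", 6e-4)
        kw.setdefault("block_tokens", 64)
        return cls(**kw)


def lr_schedule(iteration: int, cfg: TrainConfig) -> float:
    """Linear warmup to ``lr_max`` then cosine decay to ``lr_min``.

    Continuous at the warmup boundary; defined on 0..total_iters.
    """
    if iteration < 0 or iteration > cfg.total_iters:
        raise ValueError(f"iteration {iteration} outside 0..{cfg.total_iters}")
    if iteration < cfg.warmup_iters:
        return cfg.lr_max * iteration / cfg.warmup_iters
    frac = (iteration - cfg.warmup_iters) / (cfg.total_iters - cfg.warmup_iters)
    return cfg.lr_min + 0.5 * (cfg.lr_max - cfg.lr_min) * (1 + np.cos(np.pi * frac))


def clip_gradient_norm(params, max_norm: float) -> float:
    """Scale all gradients so their joint L2 norm is at most max_norm."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad.astype(np.float64) ** 2).sum())
    norm = np.sqrt(total)
    if norm > max_norm:
        scale = max_norm / (norm + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm


# ---------------------------------------------------------------------
# batching
# ---------------------------------------------------------------------

@dataclass
class Batch:
    tokens: np.ndarray  # (B, T) int
    ages: np.ndarray  # (B, T) float days
    key_padding: np.ndarray  # (B, T) bool, True on block padding
    pairing: TargetPairing


def _crop_or_pad(
    traj: Trajectory, block: int, pad_index: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = len(traj)
    if n > block:
        # contiguous window ending at a random event; ages kept intact
        end = int(rng.integers(block, n + 1))
        tokens = traj.tokens[end - block : end]
        ages = traj.ages[end - block : end]
        valid = np.ones(block, dtype=bool)
    else:
        tokens = np.concatenate(
            [traj.tokens, np.full(block - n, pad_index, dtype=np.int64)]
        )
        last = traj.ages[-1] if n else 0.0
        ages = np.concatenate([traj.ages, np.full(block - n, last)])
        valid = np.arange(block) < n
    return tokens, ages, valid


def make_training_batches(
    cohort: Sequence[Trajectory],
    vocab: TokenVocabulary,
    block_tokens: int,
    batch_size: int,
    seed: int,
) -> Iterator[Batch]:
    """Endless stream of fixed-shape batches, deterministic under seed.

    Trajectories are sampled with replacement; those longer than the
    block are cropped to a contiguous window ending at a random event
    (a cropped-off same-age prefix simply contributes no targets, since
    a target never pairs with an equal-age source).
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    rng = np.random.default_rng(seed)
    pad = vocab.pad_index
    while True:
        picks = rng.integers(0, len(cohort), size=batch_size)
        # batch width: longest sampled trajectory (capped by the block),
        # padded up to a multiple of 8 — avoids attention work on padding
        width = max(len(cohort[int(i)]) for i in picks)
        width = min(block_tokens, ((width + 7) // 8) * 8)
        toks, ages, valids = [], [], []
        for i in picks:
            t, a, v = _crop_or_pad(cohort[int(i)], width, pad, rng)
            toks.append(t)
            ages.append(a)
            valids.append(v)
        tokens = np.stack(toks)
        age_arr = np.stack(ages)
        valid = np.stack(valids)
        pairing = pair_targets_batch(age_arr, tokens, vocab, valid)
        yield Batch(tokens, age_arr, ~valid, pairing)


# ---------------------------------------------------------------------
# fit loop
# ---------------------------------------------------------------------

def fit(
    model: TrajectoryTransformer,
    cohort: Sequence[Trajectory],
    cfg: TrainConfig,
    checkpoint_dir: str | Path | None = None,
    callback: Callable[[int, dict], None] | None = None,
) -> pd.DataFrame:
    """Train in place; return the loss trace.

    The trace has one row per logged iteration with columns
    (iter, lr, token_loss, time_loss, total).  A NaN loss aborts with a
    diagnostic rather than training onward from poisoned weights.
    """
    batches = make_training_batches(
        cohort, model.vocab, cfg.block_tokens, cfg.batch_size, cfg.seed
    )
    opt = Adam(model.parameters())
    drop_rng = np.random.default_rng(cfg.seed + 1)
    rows = []
    for it in range(cfg.total_iters):
        batch = next(batches)
        lr = lr_schedule(it, cfg)
        logits = model.forward(
            batch.tokens, batch.ages, batch.key_padding, train=True, rng=drop_rng
        )
        loss, breakdown = total_loss(
            logits, batch.pairing, model.predictable_bias, model.predictable_f
        )
        if not np.isfinite(breakdown.total):
            raise RuntimeError(
                f"divergence at iteration {it}: loss={breakdown.total} "
                f"(token={breakdown.token_loss}, time={breakdown.time_loss})"
            )
        opt.zero_grad()
        loss.backward()
        # clip the global gradient norm: the waiting-time head emits huge
        # gradients while rates are miscalibrated early on, and letting
        # them into Adam's second moments stalls later learning
        if cfg.grad_clip:
            clip_gradient_norm(model.parameters(), cfg.grad_clip)
        opt.step(lr)
        if it % cfg.log_every == 0 or it == cfg.total_iters - 1:
            row = {
                "iter": it,
                "lr": lr,
                "token_loss": breakdown.token_loss,
                "time_loss": breakdown.time_loss,
                "total": breakdown.total,
            }
            rows.append(row)
            if callback is not None:
                callback(it, row)
        if (
            checkpoint_dir is not None
            and cfg.checkpoint_every
            and it
            and it % cfg.checkpoint_every == 0
        ):
            model.save(Path(checkpoint_dir) / f"iter_{it:07d}")
    if checkpoint_dir is not None:
        model.save(Path(checkpoint_dir) / "final")
    return pd.DataFrame(rows)
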