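"""Target pairing and the competing-exponentials likelihood.

Under the competing-exponentials model each predictable token ``i``
carries an exponential waiting time with rate ``lambda_i =
exp(logit_i)`` per day.  The identity of the next event is then
multinomial with probabilities ``lambda_j / sum_i lambda_i`` (the
softmax of the logits restricted to predictable tokens), and the time
to the next event is exponential with rate ``lambda* = sum_i
lambda_i``.  Both likelihood terms are therefore read off a *single*
logits vector:

    token loss   = -log softmax(logits)[j]
    time  loss   = -(logsumexp(logits) - sum(exp(logits)) * T*)

Targets are paired with their prediction source by the same-time rule:
every predictable token is predicted from the last position of
*strictly smaller* age, so co-occurring events never predict each
other.  Sex, lifestyle and block-padding tokens are excluded from both
heads by the -inf logit convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .vocab import TokenVocabulary


@dataclass
class TargetPairing:
    """Flat (source position -> target token) pairs for one batch.

    ``batch_index``/``source_pos`` address the logits row used as the
    prediction source; ``target_token`` is the vocabulary index of the
    predicted event and ``waiting_days`` the strictly positive time gap.
    """

    batch_index: np.ndarray
    source_pos: np.ndarray
    target_token: np.ndarray
    waiting_days: np.ndarray

    def __len__(self) -> int:
        return len(self.target_token)

    def __post_init__(self):
        if np.any(self.waiting_days <= 0):
            raise ValueError("waiting times must be strictly positive")


@dataclass
class LossBreakdown:
    token_loss: float
    time_loss: float
    total: float
    n_pairs: int


def pair_targets(
    ages: np.ndarray,
    tokens: np.ndarray,
    vocab: TokenVocabulary,
    valid: np.ndarray | None = None,
    batch_index: int = 0,
) -> TargetPairing:
    """Pair each predictable token with the last strictly-earlier event.

    Tokens whose age does not exceed the earliest (valid) event have no
    admissible source and are omitted.  ``valid`` marks real positions
    (False for block padding).  Ages must be sorted non-decreasing.
    """
    ages = np.asarray(ages, dtype=float)
    tokens = np.asarray(tokens, dtype=np.int64)
    if valid is None:
        valid = np.ones(len(ages), dtype=bool)
    valid = np.asarray(valid, dtype=bool)
    v_ages = ages[valid]
    v_pos = np.flatnonzero(valid)
    if np.any(np.diff(v_ages) < 0):
        raise ValueError("ages must be sorted non-decreasing")

    predictable = vocab.predictable_mask[tokens] & valid
    tgt_pos = np.flatnonzero(predictable)
    if len(tgt_pos) == 0 or len(v_ages) == 0:
        e = np.empty(0)
        return TargetPairing(e.astype(int), e.astype(int), e.astype(int), e)
    # index (into valid positions) of the last age strictly below the target's
    src_idx = np.searchsorted(v_ages, ages[tgt_pos], side="left") - 1
    keep = src_idx >= 0
    tgt_pos, src_idx = tgt_pos[keep], src_idx[keep]
    src_pos = v_pos[src_idx]
    waiting = ages[tgt_pos] - ages[src_pos]
    return TargetPairing(
        batch_index=np.full(len(tgt_pos), batch_index, dtype=np.int64),
        source_pos=src_pos.astype(np.int64),
        target_token=tokens[tgt_pos],
        waiting_days=waiting,
    )


def pair_targets_batch(
    ages: np.ndarray,
    tokens: np.ndarray,
    vocab: TokenVocabulary,
    valid: np.ndarray | None = None,
) -> TargetPairing:
    """Row-wise :func:`pair_targets` over a (B, T) batch, concatenated."""
    B = ages.shape[0]
    parts = [
        pair_targets(
            ages[b], tokens[b], vocab,
            None if valid is None else valid[b], batch_index=b,
        )
        for b in range(B)
    ]
    return TargetPairing(
        batch_index=np.concatenate([p.batch_index for p in parts]),
        source_pos=np.concatenate([p.source_pos for p in parts]),
        target_token=np.concatenate([p.target_token for p in parts]),
        waiting_days=np.concatenate([p.waiting_days for p in parts]),
    )


def _source_logits(logits: Tensor, pairing: TargetPairing) -> Tensor:
    if logits.data.ndim == 2:
        logits = logits.reshape(1, *logits.shape)
    return ad.gather_rows(logits, pairing.batch_index, pairing.source_pos)


def token_loss(
    logits: Tensor, pairing: TargetPairing, predictable_bias: np.ndarray
) -> Tensor:
    """Mean categorical NLL (nats/event), softmax over predictable tokens.

    Raises on an empty pairing: an empty batch contributes *no* loss,
    not zero, so cross-batch averages stay correct.
    """
    if len(pairing) == 0:
        raise ValueError("empty pairing has no defined loss")
    src = _source_logits(logits, pairing)
    logp = ad.log_softmax(src, predictable_bias)
    nll = -ad.gather_cols(logp, pairing.target_token)
    return nll.mean()


def time_loss(
    logits: Tensor,
    pairing: TargetPairing,
    predictable_bias: np.ndarray,
    predictable_f: np.ndarray,
) -> Tensor:
    """Mean exponential waiting-time NLL (nats/event).

    ``-(logsumexp(logits) - sum(exp(logits)) * T*)`` with the sums taken
    over predictable tokens only and ``T*`` in days.
    """
    if len(pairing) == 0:
        raise ValueError("empty pairing has no defined loss")
    src = _source_logits(logits, pairing)
    lse = ad.logsumexp(src, predictable_bias)
    total_rate = (src.exp() * Tensor(predictable_f)).sum(axis=-1)
    t = Tensor(pairing.waiting_days.astype(src.dtype))
    return (total_rate * t - lse).mean()


def total_loss(
    logits: Tensor,
    pairing: TargetPairing,
    predictable_bias: np.ndarray,
    predictable_f: np.ndarray,
) -> tuple[Tensor, LossBreakdown]:
    """Sum of the two heads over the same pairing, plus a breakdown."""
    tok = token_loss(logits, pairing, predictable_bias)
    tim = time_loss(logits, pairing, predictable_bias, predictable_f)
    tot = tok + tim
    return tot, LossBreakdown(
        token_loss=tok.item(),
        time_loss=tim.item(),
        total=tot.item(),
        n_pairs=len(pairing),
    )


def scalar_loss_oracle(
    logits_np: np.ndarray,
    pairing: TargetPairing,
    predictable_mask: np.ndarray,
) -> LossBreakdown:
    """Event-by-event reference likelihood in plain python floats.

    Walks the pairs one at a time, normalizing rates explicitly; kept
    deliberately independent of the batched tensor path.
    """
    if logits_np.ndim == 2:
        logits_np = logits_np[None]
    idx = np.flatnonzero(predictable_mask)
    tok_terms, time_terms = [], []
    for b, s, j, t in zip(
        pairing.batch_index, pairing.source_pos, pairing.target_token,
        pairing.waiting_days,
    ):
        lam = {int(i): float(np.exp(float(logits_np[b, s, i]))) for i in idx}
        lam_star = sum(lam.values())
        tok_terms.append(-np.log(lam[int(j)] / lam_star))
        time_terms.append(-(np.log(lam_star) - lam_star * float(t)))
    tok = float(np.mean(tok_terms))
    tim = float(np.mean(time_terms))
    return LossBreakdown(tok, tim, tok + tim, len(pairing))
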