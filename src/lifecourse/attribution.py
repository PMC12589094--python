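"""Masking-based Shapley attribution and nonparametric cross-checks.

A coalition game is defined on the tokens of one trajectory: a token
"plays" when left intact and is "masked" by replacing it with the
no-event placeholder (sex tokens are swapped to the opposite sex
instead of removed; ages are never altered).  The value of a coalition
is the log-rate (logit) of a target token evaluated at the
trajectory's last position.  Shapley values of this game decompose the
difference between the full and the fully-masked prediction into
per-token contributions of the target's log-rate; ``exp`` of a
contribution is the implied rate fold-change.

Exact Shapley values are computed by subset enumeration up to
``max_exact`` maskable tokens.  Above that, a hierarchical
(partition-style) approximation is used: tokens are recursively halved
by chronological order into a binary tree and every on/off
configuration of the sibling groups along each leaf's path is
enumerated — the Owen values of the binary partition.  Owen values
satisfy the efficiency axiom exactly and coincide with Shapley values
whenever the game is additive across the partition (in particular for
log-linear hazard oracles).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .evaluation import nelson_aalen_cumhaz
from .trajectory import DAYS_PER_YEAR, Trajectory
from .vocab import NO_EVENT, PAD, SEX, TokenVocabulary


# ---------------------------------------------------------------------
# masked evaluation
# ---------------------------------------------------------------------

def masked_tokens(
    tokens: np.ndarray, on: np.ndarray, positions: np.ndarray, vocab: TokenVocabulary
) -> np.ndarray:
    """Token array with OFF positions replaced by their mask value."""
    out = tokens.copy()
    female, male = vocab.sex_indices
    for pos, keep in zip(positions, on):
        if keep:
            continue
        t = int(tokens[pos])
        if vocab.token_class(t) == SEX:
            out[pos] = male if t == female else female
        else:
            out[pos] = vocab.no_event_index
    return out


def default_maskable_positions(
    traj: Trajectory, vocab: TokenVocabulary
) -> np.ndarray:
    """All positions except no-event and block padding (masking those
    is the identity and would only inflate the coalition space)."""
    cls = np.array([vocab.token_class(int(t)) for t in traj.tokens])
    return np.flatnonzero((cls != NO_EVENT) & (cls != PAD))


def _evaluate_coalitions(
    model,
    traj: Trajectory,
    positions: np.ndarray,
    coalitions: list[frozenset],
    targets: np.ndarray,
    chunk: int = 512,
) -> np.ndarray:
    """Value v(S) = target log-rates at the last position, per coalition.

    Batched through the transformer forward pass when available;
    otherwise falls back to per-coalition ``rate_vector`` calls (hazard
    oracles).  Returns shape (n_coalitions, n_targets).
    """
    variants = [
        masked_tokens(
            traj.tokens,
            np.array([positions_i in S for positions_i in positions]),
            positions,
            vocab=model.vocab,
        )
        for S in coalitions
    ]
    if hasattr(model, "forward"):
        out = np.empty((len(variants), len(targets)))
        ages = traj.ages
        for i0 in range(0, len(variants), chunk):
            block = np.stack(variants[i0 : i0 + chunk])
            logits = model.forward(
                block, np.broadcast_to(ages, block.shape).copy()
            ).data
            out[i0 : i0 + chunk] = logits[:, -1, targets].astype(float)
        return out
    out = np.empty((len(variants), len(targets)))
    for i, toks in enumerate(variants):
        rates = model.rate_vector(replace(traj, tokens=toks))
        with np.errstate(divide="ignore"):
            out[i] = np.log(rates[targets])
    return out


# ---------------------------------------------------------------------
# exact Shapley and hierarchical Owen values
# ---------------------------------------------------------------------

def _exact_coalition_plan(n: int) -> tuple[list[frozenset], list[list]]:
    """All 2^n coalitions plus, per player, the (S, weight) pairs of the
    Shapley sum over coalitions not containing the player."""
    from math import factorial

    coalitions = []
    index = {}
    for mask in range(2**n):
        S = frozenset(i for i in range(n) if mask >> i & 1)
        index[S] = len(coalitions)
        coalitions.append(S)
    plans: list[list] = [[] for _ in range(n)]
    for S in coalitions:
        s = len(S)
        for i in range(n):
            if i in S:
                continue
            w = factorial(s) * factorial(n - s - 1) / factorial(n)
            plans[i].append((index[S], index[S | {i}], w))
    return coalitions, plans


def _owen_coalition_plan(n: int) -> tuple[list[frozenset], list[list]]:
    """Coalition plan for Owen values on the chronological binary tree.

    Each leaf's attribution averages its marginal contribution over all
    on/off configurations of the sibling groups along its root path.
    """
    coalitions: list[frozenset] = []
    index: dict[frozenset, int] = {}

    def intern(S: frozenset) -> int:
        if S not in index:
            index[S] = len(coalitions)
            coalitions.append(S)
        return index[S]

    plans: list[list] = [[] for _ in range(n)]

    def descend(group: list[int], contexts: list[tuple[frozenset, float]]):
        if len(group) == 1:
            i = group[0]
            for base, w in contexts:
                plans[i].append((intern(base), intern(base | {i}), w))
            return
        half = len(group) // 2
        left, right = group[:half], group[half:]
        left_ctx = [(b, w / 2) for b, w in contexts] + [
            (b | frozenset(right), w / 2) for b, w in contexts
        ]
        right_ctx = [(b, w / 2) for b, w in contexts] + [
            (b | frozenset(left), w / 2) for b, w in contexts
        ]
        descend(left, left_ctx)
        descend(right, right_ctx)

    descend(list(range(n)), [(frozenset(), 1.0)])
    return coalitions, plans


@dataclass
class AttributionResult:
    """Per-input-token attributions of target log-rates.

    ``phi`` has shape (n_maskable, n_targets); ``positions`` are the
    maskable positions in the trajectory and ``targets`` the vocabulary
    indices attributed.  Efficiency holds per target:
    ``phi.sum(0) == f_full - f_masked``.
    """

    positions: np.ndarray
    tokens: np.ndarray
    targets: np.ndarray
    phi: np.ndarray
    f_full: np.ndarray
    f_masked: np.ndarray
    method: str

    def for_target(self, token: int) -> pd.DataFrame:
        j = int(np.flatnonzero(self.targets == token)[0])
        return pd.DataFrame(
            {
                "position": self.positions,
                "token": self.tokens,
                "attribution": self.phi[:, j],
                "fold_change": np.exp(self.phi[:, j]),
            }
        )


def shapley_attribution(
    traj: Trajectory,
    model,
    targets: int | list[int] | None = None,
    max_exact: int = 8,
    mask_positions: np.ndarray | None = None,
    force_hierarchical: bool = False,
) -> AttributionResult:
    """Attribute target log-rates to the trajectory's input tokens.

    Exact Shapley by enumeration when the number of maskable tokens is
    at most ``max_exact``; hierarchical Owen values otherwise.  The
    coalition structure does not depend on the target, so all targets
    are attributed from the same masked evaluations.
    """
    vocab = model.vocab
    if targets is None:
        target_arr = np.flatnonzero(vocab.predictable_mask)
    else:
        target_arr = np.atleast_1d(np.asarray(targets, dtype=np.int64))
    if not np.all(vocab.predictable_mask[target_arr]):
        raise ValueError("targets must be predictable tokens")
    positions = (
        default_maskable_positions(traj, vocab)
        if mask_positions is None
        else np.asarray(mask_positions, dtype=np.int64)
    )
    n = len(positions)
    if n == 0:
        raise ValueError("no maskable tokens")
    if n <= max_exact and not force_hierarchical:
        coalitions, plans = _exact_coalition_plan(n)
        method = "exact"
    else:
        coalitions, plans = _owen_coalition_plan(n)
        method = "hierarchical"
    # coalition members are indices into `positions`
    values = _evaluate_coalitions(
        model, traj, positions,
        [frozenset(positions[list(S)]) for S in coalitions],
        target_arr,
    )
    phi = np.zeros((n, len(target_arr)))
    for i, plan in enumerate(plans):
        for j_without, j_with, w in plan:
            phi[i] += w * (values[j_with] - values[j_without])
    full = frozenset(range(n))
    i_full = next(k for k, S in enumerate(coalitions) if S == full)
    i_empty = next(k for k, S in enumerate(coalitions) if not S)
    return AttributionResult(
        positions=positions,
        tokens=traj.tokens[positions],
        targets=target_arr,
        phi=phi,
        f_full=values[i_full],
        f_masked=values[i_empty],
        method=method,
    )


# ---------------------------------------------------------------------
# cohort-level aggregation
# ---------------------------------------------------------------------

def aggregate_effect_matrix(
    cohort: list[Trajectory],
    model,
    min_occurrences: int = 5,
    horizon_years: tuple[float, float] | None = None,
    targets: list[int] | None = None,
    max_exact: int = 8,
) -> pd.DataFrame:
    """Mean attribution of token A on token B's log-rate across a cohort.

    Attributions are computed at each trajectory's final position; pairs
    observed fewer than ``min_occurrences`` times are dropped, as is the
    diagonal.  ``horizon_years=(lo, hi)`` keeps only source tokens whose
    time-before-evaluation lies in the interval.  Returns a long-format
    frame (source, target, mean_effect, n).
    """
    vocab = model.vocab
    sums: dict[tuple[int, int], float] = {}
    counts: dict[tuple[int, int], int] = {}
    for traj in cohort:
        if len(traj) < 2:
            continue
        try:
            res = shapley_attribution(
                traj, model, targets=targets, max_exact=max_exact
            )
        except ValueError:
            continue
        eval_age = traj.ages[-1]
        for k, pos in enumerate(res.positions):
            lag = (eval_age - traj.ages[pos]) / DAYS_PER_YEAR
            if horizon_years is not None and not (
                horizon_years[0] <= lag < horizon_years[1]
            ):
                continue
            src = int(res.tokens[k])
            for j, tgt in enumerate(res.targets):
                if int(tgt) == src:
                    continue  # self-effect excluded by construction
                key = (src, int(tgt))
                sums[key] = sums.get(key, 0.0) + float(res.phi[k, j])
                counts[key] = counts.get(key, 0) + 1
    rows = [
        {
            "source": vocab.code(s),
            "target": vocab.code(t),
            "mean_effect": sums[(s, t)] / counts[(s, t)],
            "n": counts[(s, t)],
        }
        for (s, t) in sums
        if counts[(s, t)] >= min_occurrences
    ]
    return pd.DataFrame(rows, columns=["source", "target", "mean_effect", "n"])


def time_resolved_effect(
    cohort: list[Trajectory],
    model,
    source_token: int,
    target_token: int,
    time_bins_years: np.ndarray,
    max_exact: int = 8,
) -> pd.DataFrame:
    """Mean attribution of ``source_token`` on ``target_token`` binned by
    time since the source's occurrence.

    Returns one row per bin (bin_low, bin_high, n, mean_effect); empty
    bins carry n = 0 and NaN effect so gaps stay visible.
    """
    edges = np.asarray(time_bins_years, dtype=float)
    effects: list[list[float]] = [[] for _ in range(len(edges) - 1)]
    for traj in cohort:
        hits = np.flatnonzero(traj.tokens == source_token)
        if hits.size == 0 or len(traj) < 2:
            continue
        pos = int(hits[0])
        lag = (traj.ages[-1] - traj.ages[pos]) / DAYS_PER_YEAR
        b = int(np.digitize(lag, edges)) - 1
        if b < 0 or b >= len(effects):
            continue
        res = shapley_attribution(
            traj, model, targets=target_token, max_exact=max_exact
        )
        k = int(np.flatnonzero(res.positions == pos)[0])
        effects[b].append(float(res.phi[k, 0]))
    rows = [
        {
            "bin_low": edges[b],
            "bin_high": edges[b + 1],
            "n": len(effects[b]),
            "mean_effect": float(np.mean(effects[b])) if effects[b] else np.nan,
        }
        for b in range(len(effects))
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# nonparametric hazard-ratio cross-check
# ---------------------------------------------------------------------

def _smoothed_hazard(
    knot_times: np.ndarray,
    cumhaz: np.ndarray,
    grid: np.ndarray,
    bandwidth: float,
) -> np.ndarray:
    """Gaussian-kernel derivative of a cumulative-hazard step function."""
    increments = np.diff(np.concatenate([[0.0], cumhaz]))
    h = np.zeros_like(grid)
    for t_k, d_k in zip(knot_times, increments):
        h += d_k * np.exp(-0.5 * ((grid - t_k) / bandwidth) ** 2)
    return h / (bandwidth * np.sqrt(2 * np.pi))


def hazard_ratio_nonparametric(
    cohort: list[Trajectory],
    vocab: TokenVocabulary,
    source_token: int,
    target_token: int,
    controls_per_case: int = 5,
    kernel_bandwidth_years: float = 2.0,
    grid_years: np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Kernel-smoothed Nelson-Aalen hazard ratio of target after source.

    For each person with the source token, time runs from its
    occurrence to the target event or censoring (death / window end);
    ``controls_per_case`` age- and sex-matched individuals without the
    source at that age anchor the comparison group at the same age.
    The ratio of the two kernel-smoothed hazard derivatives estimates
    HR(t); rows where the control hazard is numerically zero are
    dropped.  Cases without enough matches are dropped and counted in
    ``df.attrs['n_dropped']``.
    """
    rng = np.random.default_rng(seed)

    # per-person summary arrays for vectorized matching
    n = len(cohort)
    first = np.full((n, 2), np.inf)  # first source / target age
    death_or_end = np.empty(n)
    sex_arr = np.empty(n, dtype=object)
    start_arr = np.empty(n)
    for i, c in enumerate(cohort):
        for j, tok in enumerate((source_token, target_token)):
            hits = np.flatnonzero(c.tokens == tok)
            if hits.size:
                first[i, j] = c.ages[hits[0]]
        d = c.death_age(vocab)
        death_or_end[i] = c.window_end if d is None else min(d, c.window_end)
        sex_arr[i] = c.sex_token(vocab)
        start_arr[i] = c.window_start

    def follow_up(i: int, from_age: float) -> tuple[float, bool]:
        t_target = first[i, 1]
        if np.isfinite(t_target) and t_target > from_age:
            return (t_target - from_age) / DAYS_PER_YEAR, True
        return max(death_or_end[i] - from_age, 0.0) / DAYS_PER_YEAR, False

    case_ev, case_cen, ctrl_ev, ctrl_cen = [], [], [], []
    n_dropped = 0
    for i in range(n):
        a_src = first[i, 0]
        if not np.isfinite(a_src) or first[i, 1] <= a_src:
            continue
        eligible = (
            (sex_arr == sex_arr[i])
            & (start_arr <= a_src)
            & (death_or_end > a_src)
            & (first[:, 0] > a_src)
            & (first[:, 1] > a_src)
        )
        eligible[i] = False
        pool = np.flatnonzero(eligible)
        if pool.size < controls_per_case:
            n_dropped += 1
            continue
        dur, ev = follow_up(i, a_src)
        (case_ev if ev else case_cen).append(dur)
        for k in rng.choice(pool, size=controls_per_case, replace=False):
            dur, ev = follow_up(int(k), a_src)
            (ctrl_ev if ev else ctrl_cen).append(dur)

    if not case_ev or not ctrl_ev:
        df = pd.DataFrame(columns=["t_years", "hr", "hazard_case", "hazard_control"])
        df.attrs["n_cases"] = len(case_ev) + len(case_cen)
        df.attrs["n_dropped"] = n_dropped
        return df
    if grid_years is None:
        t_max = np.percentile(np.concatenate([case_ev, case_cen]), 90)
        grid_years = np.linspace(0.5, max(t_max, 1.0), 40)
    kt_c, ch_c = nelson_aalen_cumhaz(np.array(case_ev), np.array(case_cen))
    kt_x, ch_x = nelson_aalen_cumhaz(np.array(ctrl_ev), np.array(ctrl_cen))
    h_case = _smoothed_hazard(kt_c, ch_c, grid_years, kernel_bandwidth_years)
    h_ctrl = _smoothed_hazard(kt_x, ch_x, grid_years, kernel_bandwidth_years)
    ok = h_ctrl > 1e-12
    df = pd.DataFrame(
        {
            "t_years": grid_years[ok],
            "hr": h_case[ok] / h_ctrl[ok],
            "hazard_case": h_case[ok],
            "hazard_control": h_ctrl[ok],
        }
    )
    df.attrs["n_cases"] = len(case_ev) + len(case_cen)
    df.attrs["n_dropped"] = n_dropped
    return df


# ---------------------------------------------------------------------
# embedding export
# ---------------------------------------------------------------------

def export_embeddings(model, top_k: int = 5) -> tuple[np.ndarray, pd.DataFrame]:
    """Tied embedding matrix plus cosine-nearest-neighbour lists.

    Returns ``(matrix, neighbours)`` where the matrix is (vocab x
    embed_dim) and the frame lists each token's ``top_k`` nearest codes
    by cosine similarity.
    """
    vocab = model.vocab
    emb = model.params["wte"].data.astype(float)
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    unit = emb / np.maximum(norms, 1e-12)
    sim = unit @ unit.T
    np.fill_diagonal(sim, -np.inf)
    rows = []
    for i in range(len(vocab)):
        order = np.argsort(sim[i])[::-1][:top_k]
        rows.append(
            {
                "code": vocab.code(i),
                "neighbours": [vocab.code(int(j)) for j in order],
                "similarities": [float(sim[i, j]) for j in order],
            }
        )
    return emb, pd.DataFrame(rows)
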