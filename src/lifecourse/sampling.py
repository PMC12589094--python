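"""Autoregressive simulation of future health trajectories.

The model (or the ground-truth hazard oracle — anything exposing
``rate_vector(trajectory)`` and ``vocab``) emits a vector of per-token
event rates at the current history point.  One waiting time is drawn
per positive-rate token from its exponential distribution and the
minimum is retained: the argmin gives the next token (multinomial with
probabilities ``lambda_j / sum lambda_i``) and the minimum itself the
time step (exponential with rate ``sum lambda_i``).  Rates are held
constant between consecutive events and re-evaluated after every
emitted token, including no-event padding — the piecewise-constant
assumption that padding keeps accurate over short gaps.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Protocol, Sequence

import numpy as np

from .trajectory import DAYS_PER_YEAR, Trajectory
from .vocab import DISEASE, TokenVocabulary


class RateModel(Protocol):
    vocab: TokenVocabulary

    def rate_vector(self, traj: Trajectory) -> np.ndarray: ...


#: hard safety cap on events appended per rollout
MAX_EVENTS_DEFAULT = 256
#: attempts to re-draw when a sampled disease repeats an existing one
RESAMPLE_ATTEMPTS = 100


def sample_next_event(
    rates: np.ndarray, rng: np.random.Generator
) -> tuple[int, float]:
    """Draw (token, waiting_days) by the argmin-of-exponentials rule.

    One exponential waiting time is drawn per strictly positive rate;
    the smallest wins.  Entries with rate 0 (non-predictable tokens, or
    suppressed diseases) can never fire.  Raises if no rate is positive.
    """
    rates = np.asarray(rates, dtype=float)
    pos = np.flatnonzero(rates > 0)
    if pos.size == 0:
        raise ValueError("all rates are zero; nothing can be sampled")
    waits = rng.exponential(1.0 / rates[pos])
    k = int(np.argmin(waits))
    return int(pos[k]), float(waits[k])


def rollout(
    prompt: Trajectory,
    model: RateModel,
    stop_age_years: float,
    max_events: int = MAX_EVENTS_DEFAULT,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> Trajectory:
    """Extend ``prompt`` autoregressively until death, ``stop_age`` or cap.

    The prompt prefix is preserved verbatim.  First-occurrence semantics
    are enforced: a sampled disease token already present is re-drawn
    (up to 100 attempts, then replaced by no-event keeping the drawn
    waiting time); death and no-event are always admissible.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    vocab = model.vocab
    stop_age_days = stop_age_years * DAYS_PER_YEAR
    if len(prompt) == 0:
        raise ValueError("rollout needs a non-empty prompt")
    ages = list(prompt.ages)
    tokens = list(int(t) for t in prompt.tokens)
    if ages[-1] >= stop_age_days:
        return prompt
    death = vocab.death_index
    current = replace(
        prompt, ages=np.array(ages), tokens=np.array(tokens, dtype=np.int64)
    )
    for _ in range(max_events):
        rates = model.rate_vector(current)
        present = {t for t in tokens if vocab.token_class(t) == DISEASE}
        tok, dt = sample_next_event(rates, rng)
        attempts = 0
        while (
            vocab.token_class(tok) == DISEASE
            and tok in present
            and attempts < RESAMPLE_ATTEMPTS
        ):
            tok, dt = sample_next_event(rates, rng)
            attempts += 1
        if vocab.token_class(tok) == DISEASE and tok in present:
            tok = vocab.no_event_index
        age = ages[-1] + dt
        if age >= stop_age_days:
            break
        ages.append(age)
        tokens.append(tok)
        current = replace(
            current,
            ages=np.array(ages),
            tokens=np.array(tokens, dtype=np.int64),
            window_end=max(current.window_end, age + 1.0),
        )
        if tok == death:
            break
    end = max(prompt.window_end, (ages[-1] if ages else 0.0) + 1.0, stop_age_days)
    return replace(
        current, ages=np.array(ages), tokens=np.array(tokens, dtype=np.int64),
        window_end=end,
    )


def generate_cohort(
    n: int,
    model: RateModel,
    stop_age_years: float = 80.0,
    sex_assignment: str = "random",
    seed: int = 0,
    max_events: int = MAX_EVENTS_DEFAULT,
    id_prefix: str = "gen",
) -> list[Trajectory]:
    """Sample ``n`` trajectories from birth, prompted with a sex token.

    ``sex_assignment`` is ``"random"`` (fair coin per person),
    ``"female"`` or ``"male"``.  Each trajectory runs on its own seeded
    substream, so cohorts are reproducible and order-independent.
    """
    vocab = model.vocab
    female, male = vocab.sex_indices
    cohort = []
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        if sex_assignment == "random":
            sex = male if rng.random() < 0.5 else female
        elif sex_assignment == "female":
            sex = female
        elif sex_assignment == "male":
            sex = male
        else:
            raise ValueError(f"unknown sex_assignment {sex_assignment!r}")
        prompt = Trajectory(
            person_id=f"{id_prefix}_{i:06d}",
            ages=np.array([0.0]),
            tokens=np.array([sex], dtype=np.int64),
            window_start=0.0,
            window_end=stop_age_years * DAYS_PER_YEAR,
        )
        cohort.append(
            rollout(prompt, model, stop_age_years, max_events=max_events, rng=rng)
        )
    return cohort
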