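"""Trajectory data model, TSV I/O and the data-preparation transforms.

A trajectory is one person's time-ordered stream of (age, token) events
inside a half-open observation window ``[start, end)``.  Ages are real
numbers measured in days from birth; the file format stores them with
two decimal places.  Disease events follow first-occurrence semantics
(one record per person per disease code) and nothing may occur strictly
after death.

The transforms here mirror the preparation applied to registry data
before training:

* :func:`insert_no_event_padding` interleaves "still healthy" markers at
  a constant average rate of 1 per 5 years (20 uniform draws over the
  0-100-year range, intersected with the window);
* :func:`randomize_lifestyle_times` spreads lifestyle tokens recorded at
  a fixed recruitment age over recruitment − 20 to + 40 years, breaking
  the immortal-time artefact that would otherwise tie them to a sudden
  mortality jump;
* :func:`truncate_at_death` enforces the terminal-death invariant.

Cohort-level helpers derive a per-person RNG substream from
``(seed, person_id)`` so results do not depend on cohort order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .vocab import DISEASE, LIFESTYLE, SEX, TokenVocabulary

#: full modelled age range, days (100 years of 365.25 days)
FULL_RANGE_DAYS = 36525.0
#: number of uniform padding candidates drawn over the full range
N_PADDING_DRAWS = 20
DAYS_PER_YEAR = 365.25


@dataclass
class Trajectory:
    """One person's event stream within a half-open observation window."""

    person_id: str
    ages: np.ndarray  # float days, non-decreasing
    tokens: np.ndarray  # int vocabulary indices
    window_start: float = 0.0
    window_end: float = FULL_RANGE_DAYS

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        self.tokens = np.asarray(self.tokens, dtype=np.int64)
        if self.ages.shape != self.tokens.shape:
            raise ValueError("ages and tokens must have equal length")

    def __len__(self) -> int:
        return len(self.ages)

    @property
    def events(self) -> list[tuple[float, int]]:
        return list(zip(self.ages.tolist(), self.tokens.tolist()))

    def sex_token(self, vocab: TokenVocabulary) -> int | None:
        for t in self.tokens:
            if vocab.token_class(int(t)) == SEX:
                return int(t)
        return None

    def death_age(self, vocab: TokenVocabulary) -> float | None:
        if vocab.death_index is None:
            return None
        hits = np.flatnonzero(self.tokens == vocab.death_index)
        return float(self.ages[hits[0]]) if hits.size else None

    def sorted_copy(self) -> "Trajectory":
        order = np.argsort(self.ages, kind="stable")
        return replace(self, ages=self.ages[order], tokens=self.tokens[order])


def validate_trajectory(traj: Trajectory, vocab: TokenVocabulary) -> None:
    """Check every structural invariant; raise ValueError on violation."""
    ages, tokens = traj.ages, traj.tokens
    if len(ages) == 0:
        return
    if np.any(np.diff(ages) < 0):
        raise ValueError(f"{traj.person_id}: events not sorted by age")
    if np.any(ages < 0):
        raise ValueError(f"{traj.person_id}: negative age")
    if np.any(ages < traj.window_start) or np.any(ages >= traj.window_end):
        raise ValueError(f"{traj.person_id}: event outside window")
    if np.any(tokens < 0) or np.any(tokens >= len(vocab)):
        raise ValueError(f"{traj.person_id}: token index out of range")
    disease = tokens[[vocab.token_class(int(t)) == DISEASE for t in tokens]]
    if len(disease) != len(np.unique(disease)):
        raise ValueError(f"{traj.person_id}: repeated disease code (first-occurrence)")
    death_age = traj.death_age(vocab)
    if death_age is not None and np.any(ages > death_age):
        raise ValueError(f"{traj.person_id}: event after death")


# ---------------------------------------------------------------------
# per-person RNG substreams
# ---------------------------------------------------------------------

def person_rng(seed: int, person_id: str) -> np.random.Generator:
    """Deterministic substream for one person, independent of cohort order."""
    h = zlib.crc32(person_id.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed), h]))


# ---------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------

def truncate_at_death(traj: Trajectory, vocab: TokenVocabulary) -> Trajectory:
    """Drop events strictly after the first death token.  Idempotent.

    Events co-occurring with death (equal age) are retained, matching
    the half-open "after" convention used throughout.
    """
    death_age = traj.death_age(vocab)
    if death_age is None:
        return traj
    keep = traj.ages <= death_age
    return replace(traj, ages=traj.ages[keep], tokens=traj.tokens[keep])


def insert_no_event_padding(
    traj: Trajectory, vocab: TokenVocabulary, seed: int
) -> Trajectory:
    """Insert "no event" tokens at an average rate of 1 per 5 years.

    Twenty candidate ages are drawn uniformly over ``(0, 36525)`` days;
    those falling inside ``[window_start, window_end)`` and not after
    death are interleaved with the existing events.  A full-range window
    therefore receives exactly 20 insertions, i.e. one per 5-year
    interval in expectation for any sub-window.
    """
    rng = person_rng(seed, traj.person_id)
    draws = rng.uniform(0.0, FULL_RANGE_DAYS, size=N_PADDING_DRAWS)
    keep = (draws >= traj.window_start) & (draws < traj.window_end)
    death_age = traj.death_age(vocab)
    if death_age is not None:
        keep &= draws < death_age
    draws = np.sort(draws[keep])
    ages = np.concatenate([traj.ages, draws])
    tokens = np.concatenate(
        [traj.tokens, np.full(len(draws), vocab.no_event_index, dtype=np.int64)]
    )
    order = np.argsort(ages, kind="stable")
    return replace(traj, ages=ages[order], tokens=tokens[order])


def randomize_lifestyle_times(
    traj: Trajectory,
    vocab: TokenVocabulary,
    recruitment_age_days: float,
    seed: int,
) -> Trajectory:
    """Re-time lifestyle tokens to recruitment + U(−20, +40) years.

    Lifestyle indicators are recorded at a single recruitment age, which
    coincides with the end of immortal-time bias; spreading them over a
    wide interval decorrelates their appearance from the mortality jump.
    Randomized ages are clipped into the observation window (and to the
    death age, if any) so the trajectory stays valid.
    """
    rng = person_rng(seed, traj.person_id)
    is_lifestyle = np.array(
        [vocab.token_class(int(t)) == LIFESTYLE for t in traj.tokens]
    )
    if not is_lifestyle.any():
        return traj
    offsets = rng.uniform(-20.0, 40.0, size=int(is_lifestyle.sum())) * DAYS_PER_YEAR
    new_ages = traj.ages.copy()
    hi = np.nextafter(traj.window_end, -np.inf)
    death_age = traj.death_age(vocab)
    if death_age is not None:
        hi = min(hi, death_age)
    new_ages[is_lifestyle] = np.clip(
        recruitment_age_days + offsets, traj.window_start, hi
    )
    out = replace(traj, ages=new_ages)
    return out.sorted_copy()


def prepare_cohort(
    cohort: Sequence[Trajectory],
    vocab: TokenVocabulary,
    seed: int,
    recruitment_age_days: float | None = None,
) -> list[Trajectory]:
    """Full preparation pipeline: truncate, randomize lifestyle, pad."""
    out = []
    for traj in cohort:
        t = truncate_at_death(traj, vocab)
        if recruitment_age_days is not None:
            t = randomize_lifestyle_times(t, vocab, recruitment_age_days, seed)
        t = insert_no_event_padding(t, vocab, seed)
        validate_trajectory(t, vocab)
        out.append(t)
    return out


# ---------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------

def write_trajectories(cohort: Iterable[Trajectory], vocab: TokenVocabulary, path) -> None:
    """Write a cohort as a 3-column TSV (person_id, age_days, code)."""
    rows = []
    for traj in cohort:
        for age, tok in zip(traj.ages, traj.tokens):
            rows.append((traj.person_id, f"{age:.2f}", vocab.code(int(tok))))
    df = pd.DataFrame(rows, columns=["person_id", "age_days", "code"])
    df.to_csv(path, sep="\t", index=False)


def read_trajectories(
    path,
    vocab: TokenVocabulary,
    window_start: float = 0.0,
    window_end: float = FULL_RANGE_DAYS,
) -> list[Trajectory]:
    """Read a cohort TSV, resolving codes against ``vocab``.

    Rows are grouped by person_id (order of first appearance); events
    are sorted by age within person.  Unknown codes, negative ages and
    events after death are rejected with the offending 1-based data line
    number.
    """
    df = pd.read_csv(path, sep="\t", dtype={"person_id": str, "code": str})
    expected = ["person_id", "age_days", "code"]
    if list(df.columns[:3]) != expected:
        raise ValueError(f"expected header {expected}, got {list(df.columns)}")
    ages = df["age_days"].to_numpy(dtype=float)
    for line, (age, code) in enumerate(zip(ages, df["code"]), start=2):
        if code not in vocab:
            raise ValueError(f"line {line}: unknown code {code!r}")
        if age < 0:
            raise ValueError(f"line {line}: negative age {age}")
    df["_token"] = [vocab.index(c) for c in df["code"]]
    df["_line"] = np.arange(2, len(df) + 2)

    cohort = []
    for pid, grp in df.groupby("person_id", sort=False):
        grp = grp.sort_values("age_days", kind="stable")
        traj = Trajectory(
            person_id=str(pid),
            ages=grp["age_days"].to_numpy(dtype=float),
            tokens=grp["_token"].to_numpy(dtype=np.int64),
            window_start=window_start,
            window_end=window_end,
        )
        death_age = traj.death_age(vocab)
        if death_age is not None and np.any(traj.ages > death_age):
            bad = grp["_line"].to_numpy()[traj.ages > death_age][0]
            raise ValueError(f"line {bad}: event after death for person {pid}")
        validate_trajectory(traj, vocab)
        cohort.append(traj)
    return cohort
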