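"""Token vocabulary for disease-trajectory event streams.

Every event in a trajectory is one token drawn from a fixed, ordered
vocabulary.  Six token classes exist:

``disease``
    First-occurrence diagnosis codes (e.g. ICD-10 level-3).  Predictable.
``death``
    A single terminal event token.  Predictable.
``lifestyle``
    Smoking, alcohol and BMI indicators, three ordinal levels each
    (9 tokens).  Input-only: the model conditions on them but never
    predicts them.
``sex``
    Two tokens presented at birth.  Input-only.
``no_event``
    The "still healthy" padding token inserted at a constant stochastic
    rate so that inter-event gaps stay short.  Predictable.
``pad``
    Non-informative block padding; masked everywhere.

Token order is deterministic — diseases in input order, then death,
lifestyle, sex, no_event, pad — so indices are reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DISEASE = "disease"
DEATH = "death"
LIFESTYLE = "lifestyle"
SEX = "sex"
NO_EVENT = "no_event"
PAD = "pad"

TOKEN_CLASSES = (DISEASE, DEATH, LIFESTYLE, SEX, NO_EVENT, PAD)

#: classes the model is trained to predict (they carry a rate/logit)
PREDICTABLE_CLASSES = frozenset({DISEASE, DEATH, NO_EVENT})

LIFESTYLE_FACTORS = ("smoking", "alcohol", "bmi")
LIFESTYLE_LEVELS = ("low", "medium", "high")
SEX_CODES = ("sex_female", "sex_male")
DEATH_CODE = "death"
NO_EVENT_CODE = "no_event"
PAD_CODE = "pad"


@dataclass(frozen=True)
class VocabEntry:
    code: str
    token_class: str
    predictable: bool


class TokenVocabulary:
    """Ordered, indexed token set with class labels.

    Parameters
    ----------
    entries
        Ordered ``VocabEntry`` sequence.  Indices are the positions
        0..N-1 in this sequence.

    Raises
    ------
    ValueError
        If codes are duplicated, the predictable flags disagree with the
        token classes, or the class counts violate the schema (exactly
        one no_event, one pad, two sex tokens; lifestyle tokens in
        threes).
    """

    def __init__(self, entries: Sequence[VocabEntry]):
        self.entries = list(entries)
        seen: dict[str, int] = {}
        for i, e in enumerate(self.entries):
            if e.code in seen:
                raise ValueError(f"duplicate token code {e.code!r}")
            seen[e.code] = i
            if e.token_class not in TOKEN_CLASSES:
                raise ValueError(f"unknown token class {e.token_class!r}")
            if e.predictable != (e.token_class in PREDICTABLE_CLASSES):
                raise ValueError(
                    f"token {e.code!r}: predictable flag must mirror its class"
                )
        self._index = seen
        counts = {c: 0 for c in TOKEN_CLASSES}
        for e in self.entries:
            counts[e.token_class] += 1
        if counts[NO_EVENT] != 1 or counts[PAD] != 1:
            raise ValueError("vocabulary needs exactly one no_event and one pad token")
        if counts[SEX] != 2:
            raise ValueError("vocabulary needs exactly two sex tokens")
        if counts[LIFESTYLE] % 3 != 0:
            raise ValueError("lifestyle tokens must come in 3 levels per factor")
        if counts[DEATH] > 1:
            raise ValueError("at most one death token")

        classes = np.array([e.token_class for e in self.entries])
        self.predictable_mask = np.array([e.predictable for e in self.entries])
        self.disease_mask = classes == DISEASE
        self.lifestyle_mask = classes == LIFESTYLE
        self.sex_indices = tuple(int(i) for i in np.flatnonzero(classes == SEX))
        self.no_event_index = int(np.flatnonzero(classes == NO_EVENT)[0])
        self.pad_index = int(np.flatnonzero(classes == PAD)[0])
        death = np.flatnonzero(classes == DEATH)
        self.death_index = int(death[0]) if death.size else None

    # -- basic container protocol ------------------------------------
    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, code: str) -> bool:
        return code in self._index

    def index(self, code: str) -> int:
        """Integer index of ``code``; KeyError if absent."""
        return self._index[code]

    def code(self, index: int) -> str:
        return self.entries[index].code

    def token_class(self, index: int) -> str:
        return self.entries[index].token_class

    @property
    def n_predictable(self) -> int:
        return int(self.predictable_mask.sum())

    def checksum(self) -> str:
        """Stable hex digest of the ordered (code, class) listing."""
        import hashlib

        h = hashlib.sha256()
        for e in self.entries:
            h.update(f"{e.code}\t{e.token_class}\n".encode())
        return h.hexdigest()[:16]

    # -- I/O ----------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": np.arange(len(self.entries)),
                "code": [e.code for e in self.entries],
                "token_class": [e.token_class for e in self.entries],
                "predictable": [e.predictable for e in self.entries],
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "TokenVocabulary":
        df = pd.read_csv(path, sep="\t", dtype={"code": str})
        df = df.sort_values("index")
        if not np.array_equal(df["index"].to_numpy(), np.arange(len(df))):
            raise ValueError("vocabulary indices must be contiguous 0..N-1")
        entries = [
            VocabEntry(str(r.code), str(r.token_class), bool(r.predictable))
            for r in df.itertuples()
        ]
        return cls(entries)


def lifestyle_codes() -> list[str]:
    """The nine lifestyle codes: 3 factors x 3 ordinal levels."""
    return [f"{f}_{lvl}" for f in LIFESTYLE_FACTORS for lvl in LIFESTYLE_LEVELS]


def build_vocabulary(
    disease_codes: Iterable[str], include_death: bool = True
) -> TokenVocabulary:
    """Assemble the full vocabulary from a list of disease codes.

    Ordering is fixed: diseases (input order), death, the 9 lifestyle
    tokens, 2 sex tokens, no_event, pad.  Total size is
    ``len(disease_codes) + include_death + 13``.

    Raises
    ------
    ValueError
        On duplicate disease codes (the message names the duplicate) or
        a disease code colliding with a reserved structural code.
    """
    disease_codes = list(disease_codes)
    seen: set[str] = set()
    for c in disease_codes:
        if c in seen:
            raise ValueError(f"duplicate disease code {c!r}")
        seen.add(c)
    reserved = set(lifestyle_codes()) | set(SEX_CODES) | {
        DEATH_CODE,
        NO_EVENT_CODE,
        PAD_CODE,
    }
    clash = seen & reserved
    if clash:
        raise ValueError(f"disease codes collide with reserved codes: {sorted(clash)}")

    entries = [VocabEntry(c, DISEASE, True) for c in disease_codes]
    if include_death:
        entries.append(VocabEntry(DEATH_CODE, DEATH, True))
    entries += [VocabEntry(c, LIFESTYLE, False) for c in lifestyle_codes()]
    entries += [VocabEntry(c, SEX, False) for c in SEX_CODES]
    entries.append(VocabEntry(NO_EVENT_CODE, NO_EVENT, True))
    entries.append(VocabEntry(PAD_CODE, PAD, False))
    return TokenVocabulary(entries)
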