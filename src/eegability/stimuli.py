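"""Stimulus sets and one-back trial schedules.

The default stimulus set mirrors a 49-image design: 24 face images carrying
identity / sex / expression attributes plus 25 nonface images spread over
animal, plant, object and scene categories. Trial schedules emulate a
one-back task in which each non-initial trial repeats the previous stimulus
with a fixed probability (0.1 by default) and otherwise draws a stimulus
uniformly at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import rng_for

__all__ = [
    "StimulusSet",
    "make_stimulus_set",
    "make_trial_schedule",
    "NONFACE_CATEGORIES",
    "EXPRESSIONS",
    "SEXES",
]

NONFACE_CATEGORIES = ("animal", "plant", "object", "scene")
EXPRESSIONS = ("neutral", "happy", "fearful")
SEXES = ("male", "female")


@dataclass(frozen=True)
class StimulusSet:
    """A set of experimental stimuli with per-stimulus attributes.

    ``table`` has one row per stimulus with columns ``stimulus_id``
    (contiguous, 0-based), ``category`` (face/animal/plant/object/scene)
    and, for faces only, ``identity`` (int), ``sex`` and ``expression``.
    Nonface rows carry missing values in the face-attribute columns.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        ids = self.table["stimulus_id"].to_numpy()
        if len(ids) == 0:
            raise ValueError("stimulus set must contain at least one stimulus")
        if not np.array_equal(ids, np.arange(len(ids))):
            raise ValueError("stimulus ids must be unique, contiguous and 0-based")
        is_face = self.table["category"] == "face"
        face_attrs = self.table[["identity", "sex", "expression"]]
        if face_attrs[is_face].isna().any().any():
            raise ValueError("every face stimulus needs identity, sex and expression")
        if face_attrs[~is_face].notna().any().any():
            raise ValueError("nonface stimuli must not carry face attributes")

    @property
    def n_stimuli(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> np.ndarray:
        return self.table["stimulus_id"].to_numpy()

    @property
    def is_face(self) -> np.ndarray:
        return (self.table["category"] == "face").to_numpy()

    @property
    def n_faces(self) -> int:
        return int(self.is_face.sum())

    def categories(self) -> np.ndarray:
        return self.table["category"].to_numpy()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _balanced_assignment(n: int, levels: tuple[str, ...], rng: np.random.Generator) -> np.ndarray:
    """Assign ``levels`` to n items as evenly as divisibility allows."""
    reps = -(-n // len(levels))
    pool = np.tile(np.asarray(levels, dtype=object), reps)[:n]
    return rng.permutation(pool)


def make_stimulus_set(
    n_face: int = 24,
    n_nonface: int = 25,
    *,
    n_identities: int = 13,
    seed: int = 0,
) -> StimulusSet:
    """Build a stimulus set with ``n_face`` faces and ``n_nonface`` nonfaces.

    Faces receive sex and expression labels balanced up to divisibility and
    identities cycled over ``n_identities`` distinct values. Nonface stimuli
    cycle through the animal/plant/object/scene categories. Deterministic
    given ``seed``.
    """
    if n_face < 0 or n_nonface < 0:
        raise ValueError("stimulus counts must be nonnegative")
    if n_face + n_nonface == 0:
        raise ValueError("stimulus set must contain at least one stimulus")
    rng = rng_for(seed, "stimuli")

    rows: list[dict] = []
    if n_face:
        sexes = _balanced_assignment(n_face, SEXES, rng)
        expressions = _balanced_assignment(n_face, EXPRESSIONS, rng)
        n_id = max(1, min(int(n_identities), n_face))
        identities = np.arange(n_face) % n_id
        for i in range(n_face):
            rows.append(
                dict(
                    category="face",
                    identity=int(identities[i]),
                    sex=sexes[i],
                    expression=expressions[i],
                )
            )
    if n_nonface:
        cats = np.asarray(NONFACE_CATEGORIES, dtype=object)[
            np.arange(n_nonface) % len(NONFACE_CATEGORIES)
        ]
        for c in cats:
            rows.append(dict(category=c, identity=np.nan, sex=None, expression=None))

    table = pd.DataFrame(rows)
    table.insert(0, "stimulus_id", np.arange(len(table)))
    return StimulusSet(table)


def make_trial_schedule(
    stimuli: StimulusSet,
    n_trials: int = 3200,
    *,
    p_repeat: float = 0.1,
    n_sessions: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a one-back trial schedule.

    Returns a DataFrame with columns ``trial_index``, ``stimulus_id``,
    ``is_repeat`` and ``session``. The first trial of each session is never
    a repeat; every later trial repeats its predecessor with probability
    ``p_repeat``, independently, and otherwise draws a stimulus uniformly.
    Trials are split across sessions as evenly as possible.
    """
    if not (0 <= p_repeat < 1):
        raise ValueError("p_repeat must lie in [0, 1)")
    if n_sessions < 1:
        raise ValueError("need at least one session")
    if n_trials < n_sessions:
        raise ValueError("need at least one trial per session")
    rng = rng_for(seed, "schedule")

    ids = stimuli.ids
    # even split, earlier sessions take the remainder
    base, extra = divmod(n_trials, n_sessions)
    sizes = [base + (1 if s < extra else 0) for s in range(n_sessions)]

    frames = []
    offset = 0
    for session, size in enumerate(sizes, start=1):
        draws = rng.choice(ids, size=size)
        rep = np.zeros(size, dtype=bool)
        if size > 1:
            rep[1:] = rng.random(size - 1) < p_repeat
        stim = draws.copy()
        for t in range(1, size):
            if rep[t]:
                stim[t] = stim[t - 1]
        frames.append(
            pd.DataFrame(
                dict(
                    trial_index=np.arange(offset, offset + size),
                    stimulus_id=stim,
                    is_repeat=rep,
                    session=session,
                )
            )
        )
        offset += size
    return pd.concat(frames, ignore_index=True)
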