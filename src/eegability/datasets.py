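"""In-memory containers for epoched EEG cohorts."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["EpochSet", "CohortDataset"]

TRIAL_COLUMNS = ("stimulus_id", "session", "is_repeat", "response_made")


@dataclass
class EpochSet:
    """Trial-epoched multichannel EEG for one participant.

    Attributes
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Signal in µV-equivalent units.
    times_ms : ndarray, shape (n_samples,)
        Sample times relative to stimulus onset, strictly increasing and
        uniformly spaced at 1000 / sampling_rate.
    sfreq : float
        Sampling rate in Hz.
    channel_labels : list of str
    channel_positions : ndarray, shape (n_channels, 3)
        Sensor coordinates on a synthetic head layout (unit hemisphere).
    trials : DataFrame
        Per-trial metadata: stimulus_id, session, is_repeat, response_made.
    """

    data: np.ndarray = field(repr=False)
    times_ms: np.ndarray = field(repr=False)
    sfreq: float
    channel_labels: list[str]
    channel_positions: np.ndarray = field(repr=False)
    trials: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_samples)")
        n_trials, n_channels, n_samples = self.data.shape
        if self.times_ms.shape != (n_samples,):
            raise ValueError("times_ms length must match the sample axis")
        dt = np.diff(self.times_ms)
        if n_samples > 1:
            if np.any(dt <= 0):
                raise ValueError("times_ms must be strictly increasing")
            if not np.allclose(dt, 1000.0 / self.sfreq, rtol=1e-6, atol=1e-6):
                raise ValueError("times_ms must be uniform at 1000/sfreq ms")
        if len(self.channel_labels) != n_channels:
            raise ValueError("channel_labels length must match channel axis")
        if len(self.trials) != n_trials:
            raise ValueError("trial metadata length must equal trial count")
        missing = [c for c in TRIAL_COLUMNS if c not in self.trials.columns]
        if missing:
            raise ValueError(f"trial metadata missing columns: {missing}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def sessions(self) -> np.ndarray:
        return np.unique(self.trials["session"].to_numpy())

    def select_trials(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        if mask.dtype == bool and mask.shape[0] != self.n_trials:
            raise ValueError("boolean mask length must equal trial count")
        return replace(
            self,
            data=self.data[mask],
            trials=self.trials.iloc[mask].reset_index(drop=True),
        )

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not present") from None


@dataclass
class CohortDataset:
    """A cohort of participants with ability scores and epoched EEG.

    ``participants`` has one row per participant: participant_id, group
    ('super' or 'typical') and ability (CFMT+-scale score, 0–102).
    ``epochs`` maps participant_id → EpochSet; it may be empty for
    metadata-only cohorts (trial bookkeeping without signal synthesis), in
    which case ``schedules`` still carries each participant's trial table.
    """

    participants: pd.DataFrame = field(repr=False)
    epochs: dict[str, EpochSet] = field(repr=False)
    schedules: dict[str, pd.DataFrame] = field(default_factory=dict, repr=False)
    stimuli: object | None = field(default=None, repr=False)
    meta: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        required = {"participant_id", "group", "ability"}
        if not required.issubset(self.participants.columns):
            raise ValueError(f"participants table needs columns {sorted(required)}")
        if len(self.participants) == 0:
            raise ValueError("cohort must contain at least one participant")
        bad = set(self.participants["group"]) - {"super", "typical"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    @property
    def participant_ids(self) -> list[str]:
        return list(self.participants["participant_id"])

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    def group_of(self, pid: str) -> str:
        row = self.participants.loc[self.participants["participant_id"] == pid]
        return str(row["group"].iloc[0])

    def ability_of(self, pid: str) -> float:
        row = self.participants.loc[self.participants["participant_id"] == pid]
        return float(row["ability"].iloc[0])

    def trial_table(self) -> pd.DataFrame:
        """Concatenated per-trial metadata across participants."""
        frames = []
        for pid in self.participant_ids:
            if pid in self.epochs:
                t = self.epochs[pid].trials.copy()
            elif pid in self.schedules:
                t = self.schedules[pid].copy()
            else:
                continue
            t.insert(0, "participant_id", pid)
            frames.append(t)
        if not frames:
            return pd.DataFrame(columns=["participant_id", *TRIAL_COLUMNS])
        return pd.concat(frames, ignore_index=True)

    def subset(self, pids: list[str]) -> "CohortDataset":
        keep = self.participants[self.participants["participant_id"].isin(pids)]
        return CohortDataset(
            participants=keep.reset_index(drop=True),
            epochs={p: self.epochs[p] for p in pids if p in self.epochs},
            schedules={p: self.schedules[p] for p in pids if p in self.schedules},
            stimuli=self.stimuli,
            meta=dict(self.meta),
        )
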