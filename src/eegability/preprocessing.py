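"""Epoch conditioning: rereference, band-pass, crop, resample, trial matching.

The default pipeline reproduces the emulated study's preprocessing:
rereference to the vertex channel (Cz), zero-phase band-pass 0.01–80 Hz,
epochs cropped to −200..1,100 ms, resampled to 256 Hz. The band-pass is
realized as a cascade of a 2nd-order Butterworth high-pass and a 6th-order
Butterworth low-pass, each applied forward–backward (zero phase) so filter
latency cannot bias decoding time courses. Resampling is polyphase
rational-rate conversion (anti-aliasing implied). Baseline correction is
off by default.
"""

from __future__ import annotations

from dataclasses import replace
from fractions import Fraction

import numpy as np
from scipy import signal

from ._rng import rng_for
from .datasets import CohortDataset, EpochSet

__all__ = ["preprocess_epochs", "preprocess_cohort", "match_trial_counts"]


def _apply_bandpass(
    data: np.ndarray, band: tuple[float, float], sfreq: float
) -> np.ndarray:
    """Zero-phase band-pass: 2nd-order Butterworth high-pass cascaded with a
    6th-order Butterworth low-pass, each forward–backward.

    A high-pass cutoff whose period exceeds twice the epoch duration (e.g.
    0.01 Hz on a ~1.3 s epoch) cannot be realized as a stable IIR on this
    support — its pole decays over far more samples than the epoch holds
    and padding transients dominate the output. All such a filter can
    remove on this support is the DC component, so it is realized exactly
    as per-epoch mean subtraction instead.
    """
    low, high = band
    nyq = sfreq / 2.0
    if not (0 <= low < high):
        raise ValueError("band must satisfy 0 <= low < high")
    if high >= nyq:
        raise ValueError(f"band upper edge {high} Hz is at or above Nyquist ({nyq} Hz)")
    duration_s = data.shape[-1] / sfreq
    if low > 0:
        if low * duration_s < 0.5:
            data = data - data.mean(axis=-1, keepdims=True)
        else:
            sos = signal.butter(2, low, btype="highpass", fs=sfreq, output="sos")
            data = signal.sosfiltfilt(sos, data, axis=-1)
    sos = signal.butter(6, high, btype="lowpass", fs=sfreq, output="sos")
    return signal.sosfiltfilt(sos, data, axis=-1)


def preprocess_epochs(
    raw: EpochSet,
    *,
    reference_channel: str | None = "Cz",
    band: tuple[float, float] | None = (0.01, 80.0),
    epoch_window_ms: tuple[float, float] = (-200.0, 1100.0),
    target_rate: float = 256.0,
    baseline_window_ms: tuple[float, float] | None = None,
) -> EpochSet:
    """Rereference, band-pass (zero phase), crop and resample an EpochSet.

    ``reference_channel=None`` or ``band=None`` disables that step.
    ``baseline_window_ms`` subtracts the per-trial, per-channel mean over
    the given window (off by default). Returns a new EpochSet; the input
    is not mutated.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    data = np.asarray(raw.data, dtype=np.float64)

    if reference_channel is not None:
        ref = raw.channel_index(reference_channel)
        data = data - data[:, ref : ref + 1, :]

    if band is not None:
        if band[1] >= target_rate / 2.0:
            raise ValueError(
                f"band upper edge {band[1]} Hz is at or above the target "
                f"Nyquist ({target_rate / 2.0} Hz)"
            )
        data = _apply_bandpass(data, band, raw.sfreq)

    t0, t1 = epoch_window_ms
    dt = 1000.0 / raw.sfreq
    # start inclusive, end exclusive; tolerate a window edge falling within
    # one sample beyond the recorded range
    if t0 < raw.times_ms[0] - dt or t1 > raw.times_ms[-1] + 2 * dt:
        raise ValueError("epoch_window_ms exceeds the raw time range")
    keep = (raw.times_ms >= t0 - 1e-9) & (raw.times_ms < t1 - 1e-9)
    if not keep.any():
        raise ValueError("epoch_window_ms selects no samples")
    data = data[:, :, keep]
    times = raw.times_ms[keep]

    frac = Fraction(target_rate / raw.sfreq).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    if up != down:
        data = signal.resample_poly(data, up, down, axis=2)
        n_out = data.shape[2]
        times = times[0] + np.arange(n_out) * 1000.0 / target_rate
        sfreq = float(target_rate)
    else:
        sfreq = raw.sfreq

    if baseline_window_ms is not None:
        b0, b1 = baseline_window_ms
        bmask = (times >= b0) & (times <= b1)
        if not bmask.any():
            raise ValueError("baseline window selects no samples")
        data = data - data[:, :, bmask].mean(axis=2, keepdims=True)

    return replace(
        raw,
        data=data.astype(raw.data.dtype, copy=False),
        times_ms=times,
        sfreq=sfreq,
    )


def preprocess_cohort(cohort: CohortDataset, **kwargs) -> CohortDataset:
    """Apply :func:`preprocess_epochs` to every participant, recording the
    applied steps in the cohort metadata."""
    epochs = {pid: preprocess_epochs(es, **kwargs) for pid, es in cohort.epochs.items()}
    meta = dict(cohort.meta)
    log = list(meta.get("preprocessing", []))
    log.append({k: (list(v) if isinstance(v, tuple) else v) for k, v in kwargs.items()})
    meta["preprocessing"] = log
    return CohortDataset(
        participants=cohort.participants,
        epochs=epochs,
        schedules=cohort.schedules,
        stimuli=cohort.stimuli,
        meta=meta,
    )


def match_trial_counts(cohort: CohortDataset, seed: int = 0) -> CohortDataset:
    """Equalize trial counts across participants.

    Every participant retains exactly the minimum per-participant trial
    count, with retained trials chosen uniformly at random without
    replacement (deterministic given ``seed``). Trial order is preserved.
    """
    if not cohort.epochs:
        raise ValueError("cohort has no epoch data")
    counts = {pid: es.n_trials for pid, es in cohort.epochs.items()}
    if min(counts.values()) < 1:
        raise ValueError("every participant needs at least one trial")
    n_keep = min(counts.values())
    rng = rng_for(seed, "trial-matching")
    epochs = {}
    for pid, es in cohort.epochs.items():
        if es.n_trials == n_keep:
            epochs[pid] = es
        else:
            keep = np.sort(rng.choice(es.n_trials, size=n_keep, replace=False))
            epochs[pid] = es.select_trials(keep)
    meta = dict(cohort.meta)
    meta["matched_trial_count"] = int(n_keep)
    return CohortDataset(
        participants=cohort.participants,
        epochs=epochs,
        schedules=cohort.schedules,
        stimuli=cohort.stimuli,
        meta=meta,
    )
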