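"""Forward simulation of EEG cohorts with planted representational geometry.

The generative model for a trial showing stimulus ``s`` at time ``t`` and
channel ``c`` is

    x[c, t] = sum_k  w_k(t) * ( A_k @ ( g_k * (f_k[s] + e_k) + jitter ) )[c]
              + sensor noise,

where, per geometry ``k``:

* ``f_k[s]`` are per-stimulus score vectors obtained by classical MDS of
  the geometry's target RDM (≤ 10 dimensions; residual stress recorded in
  the cohort metadata), so pairwise Euclidean distances of the scores
  match the target RDM;
* ``e_k`` is a stimulus-independent evoked offset occupying a dedicated
  latent dimension, giving the geometry a nonzero mean response whose
  amplitude scales with ability (this is what makes across-participant
  group decoding possible — pure geometry with centered scores would
  leave class means identical);
* ``g_k = 1 + ability_coupling_k * z`` with ``z`` the participant's
  standardized ability score;
* ``jitter`` is per-trial representational noise in latent space, *not*
  scaled by ``g_k``, so higher-ability participants carry a crisper
  stimulus geometry relative to trial-to-trial variability;
* ``A_k`` is a fixed random spatial pattern (channels × latent dims);
* ``w_k(t)`` is the geometry's Gaussian time profile (peak 1);
* sensor noise is i.i.d. Gaussian per channel × sample, optionally
  smoothed along time with a moving average to emulate autocorrelated
  EEG noise.

Channels live on a synthetic head layout: a Fibonacci lattice on the unit
hemisphere with a vertex reference channel ("Cz") at the pole.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from ._rng import child_seed, rng_for
from .datasets import CohortDataset, EpochSet
from .geometry import LatentGeometry, classical_mds
from .stimuli import StimulusSet, make_trial_schedule

__all__ = [
    "hemisphere_montage",
    "sample_ability_scores",
    "simulate_cohort",
]

SUPER_SCORE_RANGE = (92, 100)
TYPICAL_SCORE_RANGE = (50, 85)


def hemisphere_montage(n_channels: int) -> tuple[list[str], np.ndarray]:
    """Fibonacci-lattice sensor layout on the unit hemisphere.

    Channel 0 is the vertex reference 'Cz'; the remaining channels are
    labelled 'E001'… and spread quasi-uniformly over the upper hemisphere.
    """
    if n_channels < 1:
        raise ValueError("need at least one channel")
    labels = ["Cz"] + [f"E{i:03d}" for i in range(1, n_channels)]
    pos = np.zeros((n_channels, 3))
    pos[0] = (0.0, 0.0, 1.0)
    m = n_channels - 1
    if m:
        golden = np.pi * (3.0 - np.sqrt(5.0))
        i = np.arange(m)
        z = 1.0 - (i + 0.5) / m  # top → equator
        r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
        theta = golden * i
        pos[1:, 0] = r * np.cos(theta)
        pos[1:, 1] = r * np.sin(theta)
        pos[1:, 2] = z
    return labels, pos


def sample_ability_scores(
    n_super: int,
    n_typical: int,
    rng: np.random.Generator,
    *,
    super_range: tuple[int, int] = SUPER_SCORE_RANGE,
    typical_range: tuple[int, int] = TYPICAL_SCORE_RANGE,
) -> pd.DataFrame:
    """Draw integer ability scores: super uniform in ``super_range``,
    typical uniform in ``typical_range`` (bounds inclusive)."""
    rows = []
    for i in range(n_super):
        score = int(rng.integers(super_range[0], super_range[1] + 1))
        rows.append(dict(participant_id=f"sub-SR{i + 1:02d}", group="super", ability=score))
    for i in range(n_typical):
        score = int(rng.integers(typical_range[0], typical_range[1] + 1))
        rows.append(dict(participant_id=f"sub-TR{i + 1:02d}", group="typical", ability=score))
    return pd.DataFrame(rows)


def _geometry_assets(
    geometries: list[LatentGeometry],
    n_channels: int,
    evoked_strength: float,
    rng: np.random.Generator,
) -> tuple[list[dict], dict[str, float]]:
    """Per-geometry latent scores, evoked offsets and spatial patterns."""
    assets = []
    stresses = {}
    for geom in geometries:
        coords, stress = classical_mds(geom.target_rdm, n_components=10)
        stresses[geom.name] = stress
        if coords.size == 0:
            coords = np.zeros((geom.n_stimuli, 1))
        rms = np.sqrt(np.mean(np.sum(coords**2, axis=1)))
        if rms > 0:
            coords = coords / rms
        evoked = np.full((geom.n_stimuli, 1), float(evoked_strength))
        if geom.support is not None:
            coords = coords.copy()
            coords[~geom.support] = 0.0
            evoked[~geom.support] = 0.0
        latent = np.hstack([coords, evoked])  # (n_stim, d+1)
        # overall scale: per-channel signal SD ≈ amplitude at profile peak
        scale = geom.amplitude / np.sqrt(1.0 + evoked_strength**2)
        pattern = rng.normal(size=(n_channels, latent.shape[1]))
        assets.append(dict(geom=geom, latent=latent * scale, pattern=pattern, scale=scale))
    return assets, stresses


def simulate_cohort(
    stimuli: StimulusSet,
    geometries: list[LatentGeometry],
    *,
    n_super: int = 16,
    n_typical: int = 17,
    n_trials_per_participant: int = 3200,
    n_channels: int = 128,
    sampling_rate: float = 256.0,
    epoch_window_ms: tuple[float, float] = (-200.0, 1100.0),
    noise_sd: float = 2.0,
    jitter_sd: float = 1.0,
    evoked_strength: float = 1.0,
    noise_smoothing_ms: float = 0.0,
    p_repeat: float = 0.1,
    n_sessions: int = 2,
    hit_rate: float = 0.85,
    super_range: tuple[int, int] = SUPER_SCORE_RANGE,
    typical_range: tuple[int, int] = TYPICAL_SCORE_RANGE,
    metadata_only: bool = False,
    dtype=np.float32,
    seed: int = 0,
) -> CohortDataset:
    """Simulate a cohort of super- and typical recognizers.

    Defaults mirror the emulated study: 16 + 17 participants, ~3,200
    one-back trials per participant over 2 sessions with 0.1 repetition
    probability, 128 channels at 256 Hz, epochs −200..1,100 ms, ability
    scores 92–100 (super) and 50–85 (typical). With ``metadata_only=True``
    only participant/trial tables are generated (no signal synthesis),
    which is the appropriate mode at full paper scale.

    Deterministic given ``seed``. Raises on zero channels, zero trials or
    nonpositive sampling rate.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if n_trials_per_participant < n_sessions:
        raise ValueError("need at least one trial per session")
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    if n_super + n_typical < 1:
        raise ValueError("cohort must contain at least one participant")
    for geom in geometries:
        if geom.n_stimuli != stimuli.n_stimuli:
            raise ValueError(
                f"geometry {geom.name!r} is defined on {geom.n_stimuli} "
                f"stimuli but the stimulus set has {stimuli.n_stimuli}"
            )

    participants = sample_ability_scores(
        n_super,
        n_typical,
        rng_for(seed, "cohort/ability"),
        super_range=super_range,
        typical_range=typical_range,
    )
    ability = participants["ability"].to_numpy(dtype=float)
    sd = ability.std()
    z = (ability - ability.mean()) / sd if sd > 0 else np.zeros_like(ability)

    n_samples = int(round((epoch_window_ms[1] - epoch_window_ms[0]) * sampling_rate / 1000.0))
    times_ms = epoch_window_ms[0] + np.arange(n_samples) * 1000.0 / sampling_rate
    labels, positions = hemisphere_montage(n_channels)

    assets, stresses = _geometry_assets(
        geometries, n_channels, evoked_strength, rng_for(seed, "cohort/patterns")
    )
    profiles = [a["geom"].profile(times_ms) for a in assets]

    schedules: dict[str, pd.DataFrame] = {}
    epochs: dict[str, EpochSet] = {}
    for idx, row in participants.iterrows():
        pid = row["participant_id"]
        pseed = child_seed(seed, f"cohort/participant/{idx}")
        sched = make_trial_schedule(
            stimuli,
            n_trials_per_participant,
            p_repeat=p_repeat,
            n_sessions=n_sessions,
            seed=pseed,
        )
        rng_p = rng_for(pseed, "responses")
        sched["response_made"] = sched["is_repeat"].to_numpy() & (
            rng_p.random(len(sched)) < hit_rate
        )
        schedules[pid] = sched
        if metadata_only:
            continue

        rng_e = rng_for(pseed, "epochs")
        stim_idx = sched["stimulus_id"].to_numpy()
        n_trials = len(sched)
        data = rng_e.normal(scale=noise_sd, size=(n_trials, n_channels, n_samples))
        if noise_smoothing_ms > 0:
            width = max(1, int(round(noise_smoothing_ms * sampling_rate / 1000.0)))
            if width > 1:
                data = uniform_filter1d(data, size=width, axis=2, mode="nearest")
        for a, w in zip(assets, profiles):
            geom: LatentGeometry = a["geom"]
            g = 1.0 + geom.ability_coupling * z[idx]
            latent = g * a["latent"][stim_idx]  # (n_trials, d+1)
            latent = latent + rng_e.normal(
                scale=jitter_sd * a["scale"], size=latent.shape
            )
            chan = latent @ a["pattern"].T  # (n_trials, n_channels)
            data += chan[:, :, None] * w[None, None, :]
        epochs[pid] = EpochSet(
            data=data.astype(dtype, copy=False),
            times_ms=times_ms,
            sfreq=float(sampling_rate),
            channel_labels=list(labels),
            channel_positions=positions,
            trials=sched,
        )

    meta = dict(
        seed=int(seed),
        n_super=n_super,
        n_typical=n_typical,
        n_trials_per_participant=n_trials_per_participant,
        n_channels=n_channels,
        sampling_rate=float(sampling_rate),
        epoch_window_ms=list(epoch_window_ms),
        noise_sd=noise_sd,
        jitter_sd=jitter_sd,
        evoked_strength=evoked_strength,
        noise_smoothing_ms=noise_smoothing_ms,
        p_repeat=p_repeat,
        n_sessions=n_sessions,
        hit_rate=hit_rate,
        metadata_only=metadata_only,
        geometries=[
            dict(
                name=a["geom"].name,
                center_ms=a["geom"].center_ms,
                width_ms=a["geom"].width_ms,
                ability_coupling=a["geom"].ability_coupling,
                amplitude=a["geom"].amplitude,
                mds_stress=stresses[a["geom"].name],
            )
            for a in assets
        ],
    )
    return CohortDataset(
        participants=participants,
        epochs=epochs,
        schedules=schedules,
        stimuli=stimuli,
        meta=meta,
    )
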