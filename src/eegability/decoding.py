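"""Time-resolved group-membership and ability decoding with permutation inference.

Group decoding pools single trials across participants (all channels as
features, label = participant group) and reports repeated stratified
k-fold cross-validated AUC per time sample, per session, averaged over
sessions. Ability decoding regresses continuous ability scores on
single-trial topographies with fractional ridge (hyperparameter selected
on a validation split), aggregates predictions within participant and
reports the across-participant Spearman correlation per time sample.

Permutation nulls rerun the identical pipeline under participant-level
relabelings: group labels are reassigned to participants (group sizes
preserved) for group decoding, ability scores are shuffled across
participants for ability decoding. p-values use the "+1" convention
p = (1 + #{null ≥ observed}) / (n_permutations + 1), so p is never 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from ._fastlda import cv_lda_auc_timecourse
from ._rng import rng_for
from .datasets import CohortDataset, EpochSet
from .estimators import _frac_ridge_coords
from .preprocessing import match_trial_counts  # noqa: F401  (re-export convenience)

__all__ = [
    "DecodingTimecourse",
    "SearchlightMap",
    "timecourse_group_decoding",
    "cross_decode",
    "exclude_response_trials",
    "searchlight_group_decoding",
    "ability_decoding_timecourse",
    "permutation_pvalues",
    "permutation_null",
    "DEFAULT_FRACTIONS",
]

DEFAULT_FRACTIONS = np.linspace(0.001, 0.99, 20)


@dataclass
class DecodingTimecourse:
    """Per-time-sample decoding performance with optional permutation null."""

    metric: str  # 'auc' or 'spearman_rho'
    times_ms: np.ndarray = field(repr=False)
    values: np.ndarray = field(repr=False)
    null_distribution: np.ndarray | None = field(default=None, repr=False)
    p_values: np.ndarray | None = field(default=None, repr=False)
    meta: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.metric not in ("auc", "spearman_rho"):
            raise ValueError("metric must be 'auc' or 'spearman_rho'")
        if self.metric == "auc" and np.nanmin(self.values) < -1e-9:
            raise ValueError("AUC values must lie in [0, 1]")
        if self.p_values is not None:
            p = self.p_values[np.isfinite(self.p_values)]
            if len(p) and (p.min() <= 0 or p.max() > 1):
                raise ValueError("p-values must lie in (0, 1]")


@dataclass
class SearchlightMap:
    """One AUC per channel (center of its searchlight neighborhood)."""

    auc: np.ndarray = field(repr=False)
    channel_labels: list[str]
    window_ms: tuple[float, float] | None  # None = whole epoch
    searchlight_size: int


def permutation_pvalues(observed: np.ndarray, null: np.ndarray) -> np.ndarray:
    """p = (1 + #{null >= observed}) / (n_perm + 1), per time sample."""
    n_perm = null.shape[0]
    return (1.0 + np.sum(null >= observed[None, :], axis=0)) / (n_perm + 1.0)


def _stack_cohort(
    cohort: CohortDataset,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, EpochSet]:
    """Pool trials across participants → (X, pid_codes, group01, sessions, ability, ref)."""
    if not cohort.epochs:
        raise ValueError("cohort has no epoch data")
    pids = [p for p in cohort.participant_ids if p in cohort.epochs]
    ref = cohort.epochs[pids[0]]
    xs, codes, sess = [], [], []
    for k, pid in enumerate(pids):
        es = cohort.epochs[pid]
        if es.n_channels != ref.n_channels or es.n_samples != ref.n_samples:
            raise ValueError("participants have inconsistent epoch shapes")
        xs.append(es.data)
        codes.append(np.full(es.n_trials, k))
        sess.append(es.trials["session"].to_numpy())
    part = cohort.participants.set_index("participant_id")
    groups = np.array([1 if part.loc[p, "group"] == "super" else 0 for p in pids])
    ability = np.array([float(part.loc[p, "ability"]) for p in pids])
    return (
        np.concatenate(xs, axis=0),
        np.concatenate(codes),
        groups,
        np.concatenate(sess),
        ability,
        ref,
    )


def _condition_mask(cohort: CohortDataset, condition: str) -> np.ndarray:
    """Trial mask for 'face', 'nonface' or 'all' over the pooled cohort."""
    if condition not in ("face", "nonface", "all"):
        raise ValueError("condition must be 'face', 'nonface' or 'all'")
    if cohort.stimuli is None and condition != "all":
        raise ValueError("condition subsets need a stimulus set on the cohort")
    masks = []
    for pid in cohort.participant_ids:
        if pid not in cohort.epochs:
            continue
        stim = cohort.epochs[pid].trials["stimulus_id"].to_numpy()
        if condition == "all":
            masks.append(np.ones(len(stim), dtype=bool))
        else:
            is_face = cohort.stimuli.is_face[stim]
            masks.append(is_face if condition == "face" else ~is_face)
    return np.concatenate(masks)


def _group_permutations(
    groups: np.ndarray, n_permutations: int, rng: np.random.Generator
) -> np.ndarray:
    """Random participant-level relabelings preserving group sizes."""
    perms = np.empty((n_permutations, len(groups)), dtype=np.int64)
    for i in range(n_permutations):
        perms[i] = rng.permutation(groups)
    return perms


def _decode_conditions(
    cohort: CohortDataset,
    train_condition: str,
    test_condition: str,
    n_folds: int,
    n_repetitions: int,
    n_permutations: int,
    seed: int,
    grouped_cv: bool,
) -> DecodingTimecourse:
    x, pid, groups, sess, _, ref = _stack_cohort(cohort)
    if len(np.unique(groups)) < 2:
        raise ValueError("group decoding requires both groups in the cohort")
    rng = rng_for(seed, "group-decoding")
    train_mask_all = _condition_mask(cohort, train_condition)
    test_mask_all = _condition_mask(cohort, test_condition)
    perms = (
        _group_permutations(groups, n_permutations, rng) if n_permutations else None
    )
    sessions = np.unique(sess)
    acc = np.zeros(ref.n_samples)
    acc_null = np.zeros((n_permutations, ref.n_samples)) if n_permutations else None
    for s in sessions:
        in_s = sess == s
        obs, null = cv_lda_auc_timecourse(
            x[in_s],
            pid[in_s],
            groups,
            n_folds=n_folds,
            n_reps=n_repetitions,
            rng=rng,
            perm_unit_labels=perms,
            train_mask=train_mask_all[in_s],
            test_mask=test_mask_all[in_s],
            grouped_units=grouped_cv,
        )
        acc += obs
        if null is not None:
            acc_null += null
    acc /= len(sessions)
    p = None
    if acc_null is not None:
        acc_null /= len(sessions)
        p = permutation_pvalues(acc, acc_null)
    return DecodingTimecourse(
        metric="auc",
        times_ms=ref.times_ms,
        values=acc,
        null_distribution=acc_null,
        p_values=p,
        meta=dict(
            train_condition=train_condition,
            test_condition=test_condition,
            n_folds=n_folds,
            n_repetitions=n_repetitions,
            n_permutations=n_permutations,
            grouped_cv=grouped_cv,
            sessions=[int(v) for v in sessions],
            seed=int(seed),
        ),
    )


def timecourse_group_decoding(
    cohort: CohortDataset,
    condition: str = "all",
    *,
    n_folds: int = 5,
    n_repetitions: int = 5,
    n_permutations: int = 0,
    seed: int = 0,
    grouped_cv: bool = False,
) -> DecodingTimecourse:
    """Across-participant group decoding (super vs typical) per time sample.

    Trials of the requested condition are pooled across participants with
    all channels as features and the participant's group as label;
    repeated stratified k-fold CV AUC is computed per session and averaged
    across sessions. ``grouped_cv=True`` switches to participant-grouped
    folds (test participants unseen in training).
    """
    return _decode_conditions(
        cohort, condition, condition, n_folds, n_repetitions, n_permutations, seed, grouped_cv
    )


def cross_decode(
    cohort: CohortDataset,
    train_condition: str = "face",
    test_condition: str = "nonface",
    *,
    n_folds: int = 5,
    n_repetitions: int = 5,
    n_permutations: int = 0,
    seed: int = 0,
    grouped_cv: bool = False,
) -> DecodingTimecourse:
    """Train the group classifier on one stimulus condition, test on another.

    The fold structure is built over all trials, so no trial is ever used
    for both training and evaluation even when the conditions coincide
    (in which case this reduces to :func:`timecourse_group_decoding`).
    """
    return _decode_conditions(
        cohort,
        train_condition,
        test_condition,
        n_folds,
        n_repetitions,
        n_permutations,
        seed,
        grouped_cv,
    )


def exclude_response_trials(cohort: CohortDataset) -> CohortDataset:
    """Drop every trial on which a response was made (motor-control analysis)."""
    epochs = {}
    for pid, es in cohort.epochs.items():
        if "response_made" not in es.trials.columns:
            raise ValueError("response_made metadata is required")
        keep = ~es.trials["response_made"].to_numpy().astype(bool)
        if not keep.any():
            raise ValueError(f"participant {pid} would be left with no trials")
        epochs[pid] = es.select_trials(keep)
    return CohortDataset(
        participants=cohort.participants,
        epochs=epochs,
        schedules=cohort.schedules,
        stimuli=cohort.stimuli,
        meta=dict(cohort.meta, response_trials_excluded=True),
    )


def searchlight_group_decoding(
    cohort: CohortDataset,
    windows: list[tuple[float, float] | None] | None = None,
    *,
    searchlight_size: int = 5,
    n_folds: int = 5,
    n_repetitions: int = 5,
    seed: int = 0,
    grouped_cv: bool = False,
) -> list[SearchlightMap]:
    """Channel-searchlight group decoding.

    For each channel, features are the channel plus its
    ``searchlight_size − 1`` Euclidean nearest neighbours, over all
    samples in the window (``None`` = whole epoch), concatenated into one
    feature vector per trial. Defaults follow the emulated design: the
    whole epoch plus four 60-ms windows centered on 135, 350, 560 and
    775 ms.
    """
    x, pid, groups, sess, _, ref = _stack_cohort(cohort)
    if len(np.unique(groups)) < 2:
        raise ValueError("group decoding requires both groups in the cohort")
    n_ch = ref.n_channels
    if searchlight_size > n_ch:
        raise ValueError("searchlight_size exceeds the channel count")
    if windows is None:
        windows = [None] + [(c - 30.0, c + 30.0) for c in (135.0, 350.0, 560.0, 775.0)]
    pos = np.asarray(ref.channel_positions, dtype=float)
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
    neighbours = np.argsort(d, axis=1)[:, :searchlight_size]

    sessions = np.unique(sess)
    maps: list[SearchlightMap] = []
    for wi, win in enumerate(windows):
        if win is None:
            smask = np.ones(ref.n_samples, dtype=bool)
        else:
            smask = (ref.times_ms >= win[0]) & (ref.times_ms <= win[1])
            if not smask.any():
                raise ValueError(f"window {win} selects no samples")
        auc = np.zeros(n_ch)
        for c in range(n_ch):
            # identical fold structure for every channel: maps are comparable
            # across the scalp and a whole-scalp searchlight reproduces the
            # whole-scalp value exactly
            rng = rng_for(seed, f"searchlight/window{wi}")
            feats = x[:, neighbours[c], :][:, :, smask]
            feats = feats.reshape(len(feats), -1, 1)  # features × one pseudo-sample
            val = 0.0
            for s in sessions:
                in_s = sess == s
                obs, _ = cv_lda_auc_timecourse(
                    feats[in_s],
                    pid[in_s],
                    groups,
                    n_folds=n_folds,
                    n_reps=n_repetitions,
                    rng=rng,
                    grouped_units=grouped_cv,
                )
                val += obs[0]
            auc[c] = val / len(sessions)
        maps.append(
            SearchlightMap(
                auc=auc,
                channel_labels=list(ref.channel_labels),
                window_ms=win,
                searchlight_size=searchlight_size,
            )
        )
    return maps


def _spearman_over_participants(pred: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Spearman rho per time sample; pred (P, T), scores (P,)."""
    rp = rankdata(pred, axis=0)
    rs = rankdata(scores)
    rp = rp - rp.mean(axis=0)
    rs = rs - rs.mean()
    denom = np.sqrt((rp**2).sum(axis=0) * (rs**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, rs @ rp / denom, 0.0)


def ability_decoding_timecourse(
    cohort: CohortDataset,
    *,
    fractions: np.ndarray | None = None,
    split: tuple[float, float, float] = (0.6, 0.3, 0.1),
    n_repetitions: int = 10,
    n_permutations: int = 0,
    trial_level: bool = False,
    seed: int = 0,
) -> DecodingTimecourse:
    """Continuous ability decoding with fractional ridge regression.

    Intended for a typical-recognizer cohort. Per time sample and
    repetition: fit on a random 60% of trials (features = channels,
    target = the participant's ability score), choose the norm fraction
    with the best coefficient of determination on a 30% validation split
    among 20 fractions linear in [0.001, 0.99], predict the held-out 10%.
    Test predictions are averaged within participant and the Spearman
    correlation against the true scores across participants is reported
    (``trial_level=True`` correlates over trials instead). Repetitions use
    fresh random splits; sessions are analysed separately and averaged.

    The permutation null shuffles ability scores across participants and
    reruns the identical pipeline.
    """
    fracs = DEFAULT_FRACTIONS if fractions is None else np.asarray(fractions, float)
    if abs(sum(split) - 1.0) > 1e-9 or any(v <= 0 for v in split):
        raise ValueError("split proportions must be positive and sum to 1")
    x, pid, _, sess, ability, ref = _stack_cohort(cohort)
    n_p = len(ability)
    if n_p < 3 or len(np.unique(ability)) < 2:
        raise ValueError("need >= 3 participants with non-constant ability scores")
    rng = rng_for(seed, "ability-decoding")

    score_sets = [ability]
    for _ in range(n_permutations):
        score_sets.append(rng.permutation(ability))
    score_sets = np.asarray(score_sets)  # (L, P)
    L = len(score_sets)
    T = ref.n_samples
    sessions = np.unique(sess)

    rho_sum = np.zeros((L, T))
    for s in sessions:
        in_s = np.flatnonzero(sess == s)
        pid_s = pid[in_s]
        for _ in range(n_repetitions):
            # stratified-by-participant 60/30/10 split
            part = np.empty(len(in_s), dtype=np.int64)  # 0 train, 1 val, 2 test
            for u in np.unique(pid_s):
                idx = rng.permutation(np.flatnonzero(pid_s == u))
                n_tr = int(round(split[0] * len(idx)))
                n_va = int(round(split[1] * len(idx)))
                part[idx[:n_tr]] = 0
                part[idx[n_tr : n_tr + n_va]] = 1
                part[idx[n_tr + n_va :]] = 2
            tr, va, te = (np.flatnonzero(part == k) for k in range(3))
            if not (len(tr) and len(va) and len(te)):
                raise ValueError("split produced an empty subset")
            xtr = np.ascontiguousarray(
                x[in_s][tr].transpose(2, 0, 1), dtype=np.float64
            )  # (T, n, c)
            x_mean = xtr.mean(axis=1, keepdims=True)
            u_svd, s_svd, vt = np.linalg.svd(xtr - x_mean, full_matrices=False)
            xva = x[in_s][va].transpose(2, 0, 1) - x_mean
            xte = x[in_s][te].transpose(2, 0, 1) - x_mean

            for li in range(L):
                y_all = score_sets[li][pid_s]
                ytr = y_all[tr]
                y_mean = ytr.mean()
                c = np.einsum("tnk,n->tk", u_svd, ytr - y_mean)
                coords, _ = _frac_ridge_coords(s_svd, c, fracs)
                coef = np.einsum("tkp,tkf->tpf", vt, coords)  # (T, c, F)
                pv = np.einsum("tnp,tpf->tnf", xva, coef) + y_mean
                resid = pv - y_all[va][None, :, None]
                sse = np.sum(resid**2, axis=1)  # (T, F)
                best = np.argmin(sse, axis=1)  # max R^2 == min SSE
                pt_all = np.einsum("tnp,tpf->tnf", xte, coef)
                pt = (
                    np.take_along_axis(pt_all, best[:, None, None], axis=2)[:, :, 0]
                    + y_mean
                )  # (T, n_te)
                if trial_level:
                    rho_t = _spearman_over_participants(pt.T, y_all[te])
                else:
                    pid_te = pid_s[te]
                    uniq = np.unique(pid_te)
                    pred_p = np.stack(
                        [pt[:, pid_te == u].mean(axis=1) for u in uniq], axis=0
                    )  # (P_te, T)
                    rho_t = _spearman_over_participants(pred_p, score_sets[li][uniq])
                rho_sum[li] += rho_t
    rho_all = rho_sum / (len(sessions) * n_repetitions)
    observed = rho_all[0]
    null = rho_all[1:] if L > 1 else None
    p = permutation_pvalues(observed, null) if null is not None else None
    return DecodingTimecourse(
        metric="spearman_rho",
        times_ms=ref.times_ms,
        values=observed,
        null_distribution=null,
        p_values=p,
        meta=dict(
            n_repetitions=n_repetitions,
            n_permutations=n_permutations,
            split=list(split),
            n_fractions=len(fracs),
            trial_level=trial_level,
            sessions=[int(v) for v in sessions],
            seed=int(seed),
        ),
    )


def permutation_null(
    kind: str,
    cohort: CohortDataset,
    *,
    n_permutations: int = 1000,
    seed: int = 0,
    **kwargs,
) -> DecodingTimecourse:
    """Run a decoder together with its permutation null.

    ``kind`` is 'group' (participant group labels permuted) or 'ability'
    (ability scores permuted across participants). Returns the decoder's
    timecourse with ``null_distribution`` and ``p_values`` filled in.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if kind == "group":
        return timecourse_group_decoding(
            cohort, n_permutations=n_permutations, seed=seed, **kwargs
        )
    if kind == "ability":
        return ability_decoding_timecourse(
            cohort, n_permutations=n_permutations, seed=seed, **kwargs
        )
    raise ValueError("kind must be 'group' or 'ability'")
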