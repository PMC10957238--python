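"""Representational dissimilarity matrices from brains, models and raters.

Brain RDMs use cross-validated pairwise LDA decoding AUC as the
dissimilarity metric: one Fisher discriminant per stimulus pair per time
sample, channels as features, trials as observations. Model RDMs use
Pearson correlation distance over unit activations; semantic RDMs use
cosine distances between embeddings; behavioral RDMs are averaged across
raters after outlier exclusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.stats import rankdata

from ._fastlda import cv_lda_auc_timecourse
from ._rng import rng_for
from .datasets import EpochSet
from .stimuli import StimulusSet

__all__ = [
    "RDM",
    "RDMTimecourse",
    "brain_rdm_timecourse",
    "activation_rdm",
    "aggregate_layer_rdms",
    "embedding_rdm",
    "average_behavioral_rdms",
    "vectorize_rdm",
    "devectorize_rdm",
    "pair_class_mask",
    "subset_rdm_pairs",
    "rdm_cross_participant_similarity",
    "CrossParticipantSimilarity",
]

METRIC_RANGES = {
    "cv_auc": (0.0, 1.0),
    "pearson_distance": (0.0, 2.0),
    "cosine_distance": (0.0, 2.0),
    "behavioral": (0.0, np.inf),
}

PAIR_CLASSES = ("face-face", "face-nonface", "nonface-nonface")


@dataclass
class RDM:
    """Square symmetric dissimilarity matrix tagged with its metric.

    The diagonal is 0 for distance metrics and NaN ("undefined") for
    ``cv_auc``, where self-dissimilarity is not a distance and must never
    be used as one.
    """

    matrix: np.ndarray = field(repr=False)
    metric: str
    stimulus_ids: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if self.metric not in METRIC_RANGES:
            raise ValueError(f"unknown metric {self.metric!r}")
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("RDM matrix must be square")
        if not np.allclose(m, m.T, equal_nan=True):
            raise ValueError("RDM matrix must be symmetric")
        lo, hi = METRIC_RANGES[self.metric]
        off = m[~np.eye(len(m), dtype=bool)]
        off = off[np.isfinite(off)]
        if len(off) and (off.min() < lo - 1e-9 or off.max() > hi + 1e-9):
            raise ValueError(f"values outside the {self.metric} range [{lo}, {hi}]")
        if self.metric == "cv_auc":
            np.fill_diagonal(m, np.nan)
        self.matrix = m
        self.stimulus_ids = np.asarray(self.stimulus_ids)
        if len(self.stimulus_ids) != len(m):
            raise ValueError("stimulus_ids length must match the matrix")

    @property
    def n_stimuli(self) -> int:
        return len(self.matrix)

    def vector(self) -> np.ndarray:
        return vectorize_rdm(self)


@dataclass
class RDMTimecourse:
    """One RDM per time sample over a shared stimulus set and metric."""

    data: np.ndarray = field(repr=False)  # (T, n, n)
    times_ms: np.ndarray = field(repr=False)
    metric: str
    stimulus_ids: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[1] != self.data.shape[2]:
            raise ValueError("data must be (n_samples, n_stimuli, n_stimuli)")
        if len(self.times_ms) != len(self.data):
            raise ValueError("times_ms must match the time axis")

    @property
    def n_samples(self) -> int:
        return len(self.data)

    def at(self, index: int) -> RDM:
        return RDM(self.data[index], self.metric, self.stimulus_ids)

    def vectors(self) -> np.ndarray:
        """(T, n(n−1)/2) row-major upper-triangle cells per time sample."""
        n = self.data.shape[1]
        iu = np.triu_indices(n, k=1)
        return self.data[:, iu[0], iu[1]]


def vectorize_rdm(rdm: RDM | np.ndarray) -> np.ndarray:
    """Row-major upper triangle (diagonal excluded): length n(n−1)/2.

    Missing cells (NaN) propagate into the vector.
    """
    m = rdm.matrix if isinstance(rdm, RDM) else np.asarray(rdm, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("input must be square")
    if not np.allclose(m, m.T, equal_nan=True):
        raise ValueError("input must be symmetric")
    iu = np.triu_indices(len(m), k=1)
    return m[iu]


def devectorize_rdm(vector: np.ndarray, *, diagonal: float = 0.0) -> np.ndarray:
    """Inverse of :func:`vectorize_rdm` (upper triangle → full symmetric)."""
    vector = np.asarray(vector, dtype=float)
    c = len(vector)
    n = int(round((1 + np.sqrt(1 + 8 * c)) / 2))
    if n * (n - 1) // 2 != c:
        raise ValueError("vector length is not a valid n(n−1)/2")
    m = np.full((n, n), float(diagonal))
    iu = np.triu_indices(n, k=1)
    m[iu] = vector
    m.T[iu] = vector
    return m


def brain_rdm_timecourse(
    epochs: EpochSet,
    *,
    n_folds: int = 5,
    n_repetitions: int = 5,
    seed: int = 0,
) -> RDMTimecourse:
    """Cross-validated pairwise-decoding RDM at every time sample.

    For each pair of stimuli and each time sample, a shrinkage Fisher LDA
    is trained to discriminate the pair's trials (channels as features)
    and the cross-validated AUC fills the RDM cell. Sessions are analysed
    separately and averaged at the matrix level. A stimulus with fewer
    than 2·n_folds trials in a session leaves its cells missing (NaN) for
    that session, with a warning.
    """
    stim_ids = np.unique(epochs.trials["stimulus_id"].to_numpy())
    n_stim = len(stim_ids)
    if n_stim < 2:
        raise ValueError("need at least two distinct stimuli")
    code = {sid: i for i, sid in enumerate(stim_ids)}
    trial_stim = epochs.trials["stimulus_id"].map(code).to_numpy()
    sessions = epochs.trials["session"].to_numpy()
    rng = rng_for(seed, "brain-rdm")

    T = epochs.n_samples
    out = np.zeros((T, n_stim, n_stim))
    counts = np.zeros((n_stim, n_stim))
    min_needed = 2 * n_folds
    for s in np.unique(sessions):
        in_s = sessions == s
        per_stim = np.bincount(trial_stim[in_s], minlength=n_stim)
        low = np.flatnonzero(per_stim < min_needed)
        if len(low):
            warnings.warn(
                f"session {s}: stimuli {stim_ids[low].tolist()} have fewer than "
                f"{min_needed} trials; their cells are set to missing",
                stacklevel=2,
            )
        for i, j in combinations(range(n_stim), 2):
            if per_stim[i] < min_needed or per_stim[j] < min_needed:
                continue
            sel = in_s & ((trial_stim == i) | (trial_stim == j))
            y_pair = (trial_stim[sel] == j).astype(np.int64)
            auc, _ = cv_lda_auc_timecourse(
                epochs.data[sel],
                y_pair,  # unit == stimulus: labels constant within unit
                np.array([0, 1]),
                n_folds=n_folds,
                n_reps=n_repetitions,
                rng=rng,
            )
            out[:, i, j] += auc
            out[:, j, i] += auc
            counts[i, j] += 1
            counts[j, i] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(counts[None] > 0, out / np.where(counts[None] > 0, counts[None], 1), np.nan)
    out[:, np.arange(n_stim), np.arange(n_stim)] = np.nan
    return RDMTimecourse(out, epochs.times_ms, "cv_auc", stim_ids)


def activation_rdm(activations: np.ndarray, stimulus_ids=None) -> RDM:
    """Pearson-correlation-distance RDM of an activation matrix (units × stimuli).

    cell(i, j) = 1 − Pearson(column i, column j). Zero-variance columns
    leave their cells undefined (NaN), with a warning.
    """
    a = np.asarray(activations, dtype=float)
    if a.ndim != 2 or a.shape[0] < 2:
        raise ValueError("activations must be (units >= 2) × stimuli")
    n = a.shape[1]
    sd = a.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if len(bad):
        warnings.warn(
            f"stimuli {bad.tolist()} have zero-variance activations; cells undefined",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        ac = (a - a.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
        corr = ac.T @ ac / a.shape[0]
    m = 1.0 - np.clip(corr, -1.0, 1.0)
    m[bad, :] = np.nan
    m[:, bad] = np.nan
    np.fill_diagonal(m, 0.0)
    m = (m + m.T) / 2
    ids = np.arange(n) if stimulus_ids is None else np.asarray(stimulus_ids)
    return RDM(m, "pearson_distance", ids)


def aggregate_layer_rdms(layer_rdms: list[RDM], blocks: list[list[int]]) -> list[RDM]:
    """Cellwise mean of layer RDMs within each block (e.g. between pooling
    stages of a CNN). ``blocks`` must cover every layer index exactly once."""
    covered = [i for b in blocks for i in b]
    if sorted(covered) != list(range(len(layer_rdms))):
        raise ValueError("blocks must partition the layer indices exactly once")
    ref = layer_rdms[0]
    for r in layer_rdms[1:]:
        if not np.array_equal(r.stimulus_ids, ref.stimulus_ids):
            raise ValueError("layer RDMs must share one stimulus set")
    out = []
    for b in blocks:
        mean = np.mean([layer_rdms[i].matrix for i in b], axis=0)
        out.append(RDM(mean, ref.metric, ref.stimulus_ids))
    return out


def embedding_rdm(
    embeddings: np.ndarray | list[np.ndarray], stimulus_ids=None
) -> RDM:
    """Cosine-distance RDM of an embedding matrix (dimensions × stimuli).

    cell(i, j) = 1 − cos(embedding i, embedding j). A list of matrices is
    treated as multiple raters: per-rater RDMs are computed and averaged.
    All-zero embedding vectors are rejected.
    """
    if isinstance(embeddings, (list, tuple)):
        rdms = [embedding_rdm(e, stimulus_ids) for e in embeddings]
        mean = np.mean([r.matrix for r in rdms], axis=0)
        return RDM(mean, "cosine_distance", rdms[0].stimulus_ids)
    e = np.asarray(embeddings, dtype=float)
    if e.ndim != 2:
        raise ValueError("embeddings must be dimensions × stimuli")
    norms = np.linalg.norm(e, axis=0)
    if np.any(norms == 0):
        raise ValueError("all-zero embedding vector")
    en = e / norms
    m = 1.0 - np.clip(en.T @ en, -1.0, 1.0)
    np.fill_diagonal(m, 0.0)
    m = (m + m.T) / 2
    ids = np.arange(e.shape[1]) if stimulus_ids is None else np.asarray(stimulus_ids)
    return RDM(m, "cosine_distance", ids)


def average_behavioral_rdms(
    rater_rdms: list[np.ndarray | RDM], *, exclusion_sd: float = 2.0
) -> tuple[RDM, list[int]]:
    """Average rater RDMs after excluding outlier raters.

    A rater's distance-to-mean is the Euclidean distance between their
    vectorized RDM and the all-rater mean vector; raters more than
    ``exclusion_sd`` standard deviations above the mean distance are
    dropped and the mean recomputed from the survivors. Returns the
    average RDM (metric 'behavioral') and the excluded rater indices.
    """
    if len(rater_rdms) < 3:
        raise ValueError("need at least 3 raters")
    mats = [r.matrix if isinstance(r, RDM) else np.asarray(r, dtype=float) for r in rater_rdms]
    vecs = np.stack([vectorize_rdm(m) for m in mats])
    mean_vec = vecs.mean(axis=0)
    dist = np.linalg.norm(vecs - mean_vec, axis=1)
    if np.isfinite(exclusion_sd):
        sd = dist.std(ddof=1)
        cut = dist.mean() + exclusion_sd * sd
        excluded = np.flatnonzero(dist > cut) if sd > 0 else np.array([], dtype=int)
    else:
        excluded = np.array([], dtype=int)
    keep = np.setdiff1d(np.arange(len(mats)), excluded)
    if len(keep) == 0:
        raise ValueError("all raters excluded")
    mean = np.mean([mats[i] for i in keep], axis=0)
    ids = (
        rater_rdms[0].stimulus_ids
        if isinstance(rater_rdms[0], RDM)
        else np.arange(mats[0].shape[0])
    )
    return RDM(mean, "behavioral", ids), [int(i) for i in excluded]


def pair_class_mask(stimuli: StimulusSet, pair_class: str) -> np.ndarray:
    """Boolean mask over the vectorized upper triangle selecting pairs of a
    class ('face-face', 'face-nonface' or 'nonface-nonface'). Reusable
    across RDMs sharing the stimulus set."""
    if pair_class not in PAIR_CLASSES:
        raise ValueError(f"pair_class must be one of {PAIR_CLASSES}")
    is_face = stimuli.is_face
    iu = np.triu_indices(stimuli.n_stimuli, k=1)
    fi, fj = is_face[iu[0]], is_face[iu[1]]
    if pair_class == "face-face":
        return fi & fj
    if pair_class == "nonface-nonface":
        return ~fi & ~fj
    return fi ^ fj


def subset_rdm_pairs(rdm: RDM, stimuli: StimulusSet, pair_class: str) -> np.ndarray:
    """Vectorized RDM cells restricted to one stimulus-pair class."""
    if rdm.n_stimuli != stimuli.n_stimuli:
        raise ValueError("RDM and stimulus set sizes differ")
    return vectorize_rdm(rdm)[pair_class_mask(stimuli, pair_class)]


@dataclass
class CrossParticipantSimilarity:
    """Per-group cross-participant RDM similarity over time."""

    times_ms: np.ndarray = field(repr=False)
    group_means: dict = field(repr=False)  # group -> (T,)
    per_participant: dict = field(repr=False)  # pid -> (T,) leave-one-in mean
    groups: dict = field(repr=False)  # pid -> group
    cluster_result: object = None


def rdm_cross_participant_similarity(
    rdm_timecourses: dict[str, RDMTimecourse],
    groups: dict[str, str],
    *,
    t_threshold: float = 1.96,
    alpha: float = 0.05,
    n_permutations: int = 1000,
    seed: int = 0,
) -> CrossParticipantSimilarity:
    """Cross-participant similarity of brain RDMs, per group, over time.

    Per time sample and group: the mean pairwise Spearman correlation
    between participants' vectorized RDMs. Each participant's
    contribution (mean correlation with the other members of their group)
    forms a time course, and the super-vs-typical contrast of these time
    courses is tested with the cluster permutation machinery — the
    signal-to-noise control for group decoding results.
    """
    pids = list(rdm_timecourses)
    if len(pids) < 2:
        raise ValueError("need at least two participants")
    by_group: dict[str, list[str]] = {}
    for pid in pids:
        by_group.setdefault(groups[pid], []).append(pid)
    for g, members in by_group.items():
        if len(members) < 2:
            raise ValueError(f"group {g!r} has fewer than two participants")

    ref = rdm_timecourses[pids[0]]
    vecs = np.stack([rdm_timecourses[p].vectors() for p in pids])  # (P, T, C)
    good = np.isfinite(vecs).all(axis=(0, 1))
    vecs = vecs[:, :, good]
    r = rankdata(vecs, axis=2).astype(float)
    r -= r.mean(axis=2, keepdims=True)
    norm = np.sqrt((r**2).sum(axis=2))
    norm[norm == 0] = 1.0
    r /= norm[:, :, None]
    corr = np.einsum("ptc,qtc->pqt", r, r)  # (P, P, T)

    per_participant: dict[str, np.ndarray] = {}
    group_means: dict[str, np.ndarray] = {}
    idx = {p: i for i, p in enumerate(pids)}
    for g, members in by_group.items():
        ii = np.array([idx[p] for p in members])
        sub = corr[np.ix_(ii, ii)]
        off = ~np.eye(len(ii), dtype=bool)
        group_means[g] = sub[off].reshape(len(ii), len(ii) - 1, -1).mean(axis=(0, 1))
        for k, p in enumerate(members):
            per_participant[p] = sub[k][off[k]].mean(axis=0)

    cluster = None
    if set(by_group) == {"super", "typical"}:
        from .rsa_stats import cluster_permutation_test

        a = np.stack([per_participant[p] for p in by_group["super"]])
        b = np.stack([per_participant[p] for p in by_group["typical"]])
        cluster = cluster_permutation_test(
            a,
            b,
            times_ms=ref.times_ms,
            t_threshold=t_threshold,
            alpha=alpha,
            n_permutations=n_permutations,
            seed=seed,
        )
    return CrossParticipantSimilarity(
        times_ms=ref.times_ms,
        group_means=group_means,
        per_participant=per_participant,
        groups=dict(groups),
        cluster_result=cluster,
    )
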