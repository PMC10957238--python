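"""Gaussian-copula mutual information RSA and cluster permutation inference.

The association between a brain RDM time course and a model RDM is
measured with Gaussian-copula mutual information: each vectorized RDM is
rank-transformed, mapped through the standard normal quantile function,
and the closed-form Gaussian MI −½·log₂(1−r²) is computed from the
copula correlation r. The conditional variant I(x; y|z) removes the
information shared with a third RDM (e.g. the semantic model when
testing a visual model) using the Gaussian identity
I(x; y|z) = I(x; y,z) − I(x; z) on the copula-normal covariances.

Group contrasts of per-participant MI time courses use a nonparametric
cluster-based permutation test: pointwise independent-samples t
statistics, clusters = maximal contiguous runs of |t| above a threshold
with constant sign, cluster statistic = run length, and a null built by
randomly reassigning participants to groups and recording the maximum
cluster size over both signs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, ndtri
from scipy.stats import rankdata

from ._rng import rng_for
from .rdm import RDM, RDMTimecourse, pair_class_mask, vectorize_rdm

__all__ = [
    "gaussian_copula_mi",
    "gaussian_copula_cmi",
    "rsa_timecourse",
    "cluster_permutation_test",
    "compare_groups_rsa",
    "MITimecourse",
    "Cluster",
    "ClusterResult",
]

_R_CAP = 1.0 - 1e-12


@dataclass
class MITimecourse:
    """MI (bits) between one brain RDM time course and a model RDM."""

    values: np.ndarray = field(repr=False)
    times_ms: np.ndarray = field(repr=False)
    model: str
    conditioning: str | None = None
    participant_id: str | None = None


@dataclass(frozen=True)
class Cluster:
    start_ms: float
    end_ms: float
    sign: int
    size: int  # run length in samples
    p_value: float


@dataclass
class ClusterResult:
    """Outcome of a cluster-based permutation contrast."""

    clusters: list[Cluster]
    t_values: np.ndarray = field(repr=False)
    times_ms: np.ndarray = field(repr=False)
    t_threshold: float
    alpha: float
    n_permutations: int

    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value < self.alpha]


def _copula_normalize(x: np.ndarray) -> np.ndarray:
    """Rank-transform (average ranks for ties) and map to normal quantiles."""
    x = np.asarray(x, dtype=float)
    r = rankdata(x)
    return ndtri(r / (len(x) + 1.0))


def _check_pair(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if len(x) < 10:
        raise ValueError("need at least 10 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    return x, y


def _mi_bias_bits(n: int, dx: int = 1, dy: int = 1) -> float:
    """Analytic small-sample bias of the Gaussian MI estimate, in bits."""

    def ent_bias(d):
        return 0.5 * sum(
            digamma((n - i) / 2.0) - np.log((n - 1) / 2.0) for i in range(1, d + 1)
        )

    return (ent_bias(dx) + ent_bias(dy) - ent_bias(dx + dy)) / np.log(2)


def gaussian_copula_mi(x, y, *, bias_correction: bool = False) -> float:
    """Gaussian-copula mutual information I(x; y) in bits.

    Perfectly dependent inputs (copula correlation at ±1) have divergent
    Gaussian MI; the correlation is capped just inside ±1 and a warning
    is emitted. The estimator's small positive bias is left in place by
    default (group contrasts subtract it out); ``bias_correction=True``
    subtracts the analytic Gaussian bias.
    """
    x, y = _check_pair(x, y)
    zx, zy = _copula_normalize(x), _copula_normalize(y)
    r = float(np.corrcoef(zx, zy)[0, 1])
    if abs(r) >= _R_CAP:
        warnings.warn("perfect dependence between inputs; MI capped", stacklevel=2)
        r = np.sign(r) * _R_CAP
    mi = -0.5 * np.log2(1.0 - r**2)
    if bias_correction:
        mi -= _mi_bias_bits(len(x))
    return float(mi)


def gaussian_copula_cmi(x, y, z, *, bias_correction: bool = False) -> float:
    """Gaussian-copula conditional mutual information I(x; y | z) in bits.

    Computed in the Gaussian family on copula-normalized variables as
    I(x; y, z) − I(x; z), which reduces to −½·log₂(1 − ρ²_xy·z) with
    ρ_xy·z the partial correlation.
    """
    x, y = _check_pair(x, y)
    z = np.asarray(z, dtype=float)
    if z.shape != x.shape:
        raise ValueError("inputs must be 1-D vectors of equal length")
    if np.ptp(z) == 0:
        raise ValueError("constant input")
    zs = np.stack([_copula_normalize(v) for v in (x, y, z)])
    c = np.corrcoef(zs)
    rxy, rxz, ryz = c[0, 1], c[0, 2], c[1, 2]
    denom = (1.0 - rxz**2) * (1.0 - ryz**2)
    if denom <= 1e-12:
        warnings.warn("perfect dependence on the conditioning variable", stacklevel=2)
        return 0.0
    p = (rxy - rxz * ryz) / np.sqrt(denom)
    if abs(p) >= _R_CAP:
        warnings.warn("perfect conditional dependence; CMI capped", stacklevel=2)
        p = np.sign(p) * _R_CAP
    cmi = -0.5 * np.log2(1.0 - p**2)
    if bias_correction:
        cmi -= _mi_bias_bits(len(x), 1, 1)
    return float(cmi)


def rsa_timecourse(
    brain: RDMTimecourse,
    model: RDM,
    conditioning: RDM | None = None,
    *,
    pair_class=None,
    stimuli=None,
    participant_id: str | None = None,
    model_name: str | None = None,
    bias_correction: bool = False,
) -> MITimecourse:
    """MI (or CMI, when ``conditioning`` is given) between the brain RDM and
    a model RDM at every time sample.

    Missing brain cells are pairwise-deleted jointly from all vectors so
    x, y and z stay aligned. ``pair_class`` optionally restricts the
    analysis to face-face / face-nonface / nonface-nonface pairs (needs
    ``stimuli``). Raises if fewer than 10 pairs survive deletion.
    """
    if not np.array_equal(brain.stimulus_ids, model.stimulus_ids):
        raise ValueError("brain and model RDMs must share the stimulus set")
    vy = vectorize_rdm(model)
    vz = None
    if conditioning is not None:
        if not np.array_equal(conditioning.stimulus_ids, model.stimulus_ids):
            raise ValueError("conditioning RDM must share the stimulus set")
        vz = vectorize_rdm(conditioning)
    vx_t = brain.vectors()  # (T, C)

    mask = np.ones(vx_t.shape[1], dtype=bool)
    if pair_class is not None:
        if stimuli is None:
            raise ValueError("pair_class selection requires the stimulus set")
        mask &= pair_class_mask(stimuli, pair_class)
    mask &= np.isfinite(vy)
    if vz is not None:
        mask &= np.isfinite(vz)

    values = np.empty(brain.n_samples)
    for t in range(brain.n_samples):
        m = mask & np.isfinite(vx_t[t])
        if m.sum() < 10:
            raise ValueError(f"fewer than 10 usable pairs at sample {t}")
        if vz is None:
            values[t] = gaussian_copula_mi(
                vx_t[t][m], vy[m], bias_correction=bias_correction
            )
        else:
            values[t] = gaussian_copula_cmi(
                vx_t[t][m], vy[m], vz[m], bias_correction=bias_correction
            )
    return MITimecourse(
        values=values,
        times_ms=brain.times_ms,
        model=model_name or model.metric,
        conditioning=None if conditioning is None else (conditioning.metric),
        participant_id=participant_id,
    )


def _t_stat(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pooled-variance independent-samples t per column."""
    na, nb = len(a), len(b)
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, (ma - mb) / denom, 0.0)


def _clusters(t: np.ndarray, threshold: float) -> list[tuple[int, int, int]]:
    """Maximal runs (start, stop_exclusive, sign) with |t| > threshold and
    constant sign."""
    sign = np.where(t > threshold, 1, np.where(t < -threshold, -1, 0))
    out = []
    start = None
    for i in range(len(sign) + 1):
        cur = sign[i] if i < len(sign) else 0
        if start is not None and (cur != sign[start]):
            out.append((start, i, int(sign[start])))
            start = None
        if start is None and cur != 0:
            start = i
    return out


def cluster_permutation_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    *,
    times_ms: np.ndarray | None = None,
    t_threshold: float = 1.96,
    alpha: float = 0.05,
    n_permutations: int = 1000,
    seed: int = 0,
) -> ClusterResult:
    """Cluster-based permutation contrast of two groups of time courses.

    ``group_a``/``group_b``: (n_participants, n_samples). Pointwise
    pooled-variance t statistics are thresholded at ±``t_threshold``;
    maximal same-sign supra-threshold runs form clusters scored by run
    length. The null records, for each random reassignment of
    participants to groups (sizes preserved), the maximum cluster size
    over both signs; cluster p-values use the "+1" convention and a
    cluster is significant when p < ``alpha``.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share the time axis")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 participants per group")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    T = a.shape[1]
    if times_ms is None:
        times_ms = np.arange(T, dtype=float)
    times_ms = np.asarray(times_ms, dtype=float)

    t_obs = _t_stat(a, b)
    runs = _clusters(t_obs, t_threshold)

    pooled = np.vstack([a, b])
    na = len(a)
    rng = rng_for(seed, "cluster-test")
    null_max = np.zeros(n_permutations)
    for i in range(n_permutations):
        idx = rng.permutation(len(pooled))
        t_p = _t_stat(pooled[idx[:na]], pooled[idx[na:]])
        sizes = [stop - start for start, stop, _ in _clusters(t_p, t_threshold)]
        null_max[i] = max(sizes) if sizes else 0

    clusters = []
    for start, stop, sign in runs:
        size = stop - start
        p = (1.0 + np.sum(null_max >= size)) / (n_permutations + 1.0)
        clusters.append(
            Cluster(
                start_ms=float(times_ms[start]),
                end_ms=float(times_ms[stop - 1]),
                sign=sign,
                size=size,
                p_value=float(p),
            )
        )
    return ClusterResult(
        clusters=clusters,
        t_values=t_obs,
        times_ms=times_ms,
        t_threshold=t_threshold,
        alpha=alpha,
        n_permutations=n_permutations,
    )


def compare_groups_rsa(
    rdm_timecourses: dict[str, RDMTimecourse],
    groups: dict[str, str],
    model: RDM,
    conditioning: RDM | None = None,
    *,
    pair_class=None,
    stimuli=None,
    t_threshold: float = 1.96,
    alpha: float = 0.05,
    n_permutations: int = 1000,
    seed: int = 0,
) -> tuple[dict[str, MITimecourse], ClusterResult]:
    """Per-participant MI/CMI time courses and their super-vs-typical
    cluster contrast (super minus typical)."""
    mi = {
        pid: rsa_timecourse(
            tc,
            model,
            conditioning,
            pair_class=pair_class,
            stimuli=stimuli,
            participant_id=pid,
        )
        for pid, tc in rdm_timecourses.items()
    }
    supers = [mi[p].values for p in mi if groups[p] == "super"]
    typicals = [mi[p].values for p in mi if groups[p] == "typical"]
    if not supers or not typicals:
        raise ValueError("both groups must be present")
    ref = next(iter(rdm_timecourses.values()))
    result = cluster_permutation_test(
        np.stack(supers),
        np.stack(typicals),
        times_ms=ref.times_ms,
        t_threshold=t_threshold,
        alpha=alpha,
        n_permutations=n_permutations,
        seed=seed,
    )
    return mi, result
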