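"""Synthetic stand-ins for model representations consumed by RSA.

Real analyses compare brain RDMs against CNN layer activations, sentence
embeddings and behavioral multiple-arrangement RDMs. These generators
produce matrices with a *prescribed* representational geometry so the RSA
machinery can be validated end to end: activation matrices whose
Pearson-distance RDM rank-matches a target, embedding matrices whose
cosine-distance RDM matches a target (exactly, when the embedding
dimension allows), and per-rater behavioral RDMs with optional planted
outlier raters.

All of these are synthetic constructions; no network inference happens
anywhere in this package.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform

from ._rng import rng_for

__all__ = [
    "simulate_model_activations",
    "simulate_embeddings",
    "simulate_behavioral_rdms",
]


def _check_target(target_rdm: np.ndarray) -> np.ndarray:
    d = np.asarray(target_rdm, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("target_rdm must be square")
    if not np.allclose(d, d.T):
        raise ValueError("target_rdm must be symmetric")
    if np.any(d < 0):
        raise ValueError("target_rdm must be nonnegative")
    return d


def _similarity_gram(target_rdm: np.ndarray, strength: float) -> np.ndarray:
    """Unit-diagonal PSD similarity matrix C with 1 − C ∝ target ranks.

    Starts from C0 = 1 − strength * D/max(D), repairs indefiniteness by
    eigenvalue clipping and rescales back to a correlation matrix. For
    well-behaved targets the repair is a small perturbation, so 1 − C
    remains rank-aligned with the target distances.
    """
    d = _check_target(target_rdm)
    dmax = d.max()
    if dmax == 0:
        return np.ones_like(d)
    c0 = 1.0 - strength * d / dmax
    evals, evecs = np.linalg.eigh(c0)
    evals = np.clip(evals, 1e-10, None)
    c = (evecs * evals) @ evecs.T
    scale = np.sqrt(np.diag(c))
    c = c / np.outer(scale, scale)
    return (c + c.T) / 2


def _gram_root(c: np.ndarray) -> np.ndarray:
    """L with L @ L.T == c (eigenvalue square root; works for PSD input)."""
    evals, evecs = np.linalg.eigh(c)
    evals = np.clip(evals, 0.0, None)
    return evecs * np.sqrt(evals)


def simulate_model_activations(
    target_rdm: np.ndarray,
    n_units: int = 256,
    *,
    noise_sd: float = 0.0,
    strength: float = 0.8,
    seed: int = 0,
) -> np.ndarray:
    """Activation matrix (units × stimuli) whose Pearson-distance RDM
    rank-matches ``target_rdm``.

    Columns are drawn with population cross-column correlation
    C = 1 − strength·D/max(D) (PSD-repaired), so the population
    correlation-distance RDM is linear in the target. ``noise_sd`` adds
    i.i.d. unit noise, shrinking all correlations toward zero and thus
    degrading the match monotonically in expectation.
    """
    d = _check_target(target_rdm)
    n_stim = d.shape[0]
    if n_units < n_stim:
        raise ValueError("n_units must be at least the number of stimuli")
    rng = rng_for(seed, "activations")
    c = _similarity_gram(d, strength)
    root = _gram_root(c)  # (n_stim, n_stim)
    g = rng.normal(size=(n_units, n_stim))
    acts = g @ root.T  # column i has profile G @ root[i]
    if noise_sd > 0:
        acts = acts + rng.normal(scale=noise_sd, size=acts.shape)
    return acts


def simulate_embeddings(
    target_rdm: np.ndarray,
    n_dims: int = 512,
    *,
    strength: float = 0.9,
    seed: int = 0,
) -> np.ndarray:
    """Embedding matrix (dimensions × stimuli) whose cosine-distance RDM
    matches ``target_rdm`` in rank.

    When ``n_dims`` ≥ n_stimuli the unit-vector Gram matrix is realized
    exactly (up to the PSD repair), so cosine distances equal
    strength·D/max(D) cellwise; smaller ``n_dims`` uses the best
    rank-``n_dims`` approximation with renormalized columns.
    """
    d = _check_target(target_rdm)
    if n_dims < 2:
        raise ValueError("n_dims must be >= 2")
    if d.max() == 0:
        raise ValueError("degenerate target: all dissimilarities are zero")
    rng = rng_for(seed, "embeddings")
    c = _similarity_gram(d, strength)
    root = _gram_root(c)  # rows are stimulus vectors in n_stim-dim space
    n_stim = d.shape[0]
    if n_dims >= n_stim:
        # lift into n_dims with a random orthonormal map (inner products kept)
        q, _ = np.linalg.qr(rng.normal(size=(n_dims, n_stim)))
        emb = q @ root.T
    else:
        evals, evecs = np.linalg.eigh(c)
        order = np.argsort(evals)[::-1][:n_dims]
        emb = (evecs[:, order] * np.sqrt(np.clip(evals[order], 0, None))).T
        norms = np.linalg.norm(emb, axis=0)
        norms[norms == 0] = 1.0
        emb = emb / norms
    return emb


def simulate_behavioral_rdms(
    target_rdm: np.ndarray,
    n_raters: int = 32,
    *,
    noise_sd: float = 0.1,
    n_outliers: int = 0,
    seed: int = 0,
) -> list[np.ndarray]:
    """Per-rater behavioral RDMs around a shared target.

    The first ``n_raters − n_outliers`` raters return the target plus
    symmetric zero-diagonal noise (clipped at 0); the *last* ``n_outliers``
    raters return an unrelated random Euclidean RDM rescaled to the
    target's magnitude — these planted outliers are what a downstream
    2-SD exclusion rule should remove.
    """
    d = _check_target(target_rdm)
    if n_outliers >= n_raters:
        raise ValueError("n_outliers must be smaller than n_raters")
    rng = rng_for(seed, "behavioral")
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    scale = d[iu].mean() if n > 1 else 1.0

    rdms: list[np.ndarray] = []
    for _ in range(n_raters - n_outliers):
        noisy = np.zeros_like(d)
        noisy[iu] = np.clip(d[iu] + rng.normal(scale=noise_sd, size=len(iu[0])), 0, None)
        rdms.append(noisy + noisy.T)
    for _ in range(n_outliers):
        pts = rng.normal(size=(n, max(2, min(n, 5))))
        rand = squareform(pdist(pts))
        mean = rand[iu].mean() if n > 1 else 1.0
        if mean > 0 and scale > 0:
            rand = rand * (scale / mean)
        rdms.append(rand)
    return rdms
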