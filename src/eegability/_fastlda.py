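"""Vectorized cross-validated Fisher LDA AUC over time.

This is the shared engine for time-resolved group decoding, condition
cross-decoding and pairwise-stimulus (RDM) decoding. It exploits two
structural facts:

* labels are constant within a "unit" (a participant for group decoding,
  a stimulus for pairwise decoding), so class means under any relabeling
  are combinations of per-unit sufficient statistics;
* the pooled within-class scatter decomposes as
  S_pooled = S_total − n0·μ0 μ0ᵀ − n1·μ1 μ1ᵀ,
  so the expensive O(n·c²·T) accumulation is done once per fold and every
  permutation costs only rank-one updates plus a batched c×c solve.

Covariance regularization is Ledoit–Wolf shrinkage toward a scaled
identity, with the shrinkage intensity estimated from the *label-free*
(grand-centered) training data. Estimating it without reference to labels
keeps the whole statistic exchangeable under label permutations, which is
what makes the permutation p-values exact.
"""

from __future__ import annotations

import numpy as np

__all__ = ["cv_lda_auc_timecourse"]


def _fold_assignment(
    unit_ids: np.ndarray,
    n_units: int,
    n_folds: int,
    rng: np.random.Generator,
    grouped_units: bool,
    unit_labels: np.ndarray,
) -> np.ndarray:
    """Fold index per trial.

    Default: folds stratify over trials within each unit (every unit
    contributes to both train and test). ``grouped_units``: folds
    partition whole units instead, stratified by unit label, so test
    units are never seen during training.
    """
    n = len(unit_ids)
    folds = np.empty(n, dtype=np.int64)
    if grouped_units:
        unit_fold = np.empty(n_units, dtype=np.int64)
        for lab in np.unique(unit_labels):
            members = rng.permutation(np.flatnonzero(unit_labels == lab))
            unit_fold[members] = np.arange(len(members)) % n_folds
        folds = unit_fold[unit_ids]
    else:
        for u in range(n_units):
            idx = rng.permutation(np.flatnonzero(unit_ids == u))
            folds[idx] = np.arange(len(idx)) % n_folds
    return folds


def _lw_shrinkage(xc_t: np.ndarray) -> np.ndarray:
    """Ledoit–Wolf shrinkage intensity per time sample.

    ``xc_t``: (T, n, c) grand-centered training data. Returns (T,) in [0, 1].
    """
    T, n, c = xc_t.shape
    s = np.matmul(xc_t.transpose(0, 2, 1), xc_t) / n  # (T, c, c)
    m = np.trace(s, axis1=1, axis2=2) / c
    d2 = np.sum(s**2, axis=(1, 2)) - c * m**2
    x2 = np.sum(xc_t**2, axis=2)  # (T, n)
    b_bar2 = (np.sum(x2**2, axis=1) / n**2) - np.sum(s**2, axis=(1, 2)) / n
    b_bar2 = np.clip(b_bar2, 0.0, None)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(d2 > 0, np.minimum(b_bar2, d2) / np.where(d2 > 0, d2, 1.0), 1.0)
    return np.clip(rho, 0.0, 1.0)


def _auc_from_scores(
    scores: np.ndarray, y_mat: np.ndarray
) -> np.ndarray:
    """Rank-sum AUC. ``scores``: (T, n_test, L); ``y_mat``: (L, n_test) in {0,1}.

    Returns (L, T). The fast path uses ordinal ranks (discriminant scores
    of continuous data are tie-free almost surely); exact ties fall back
    to average ranks.
    """
    s = np.ascontiguousarray(scores.transpose(0, 2, 1))  # (T, L, n)
    order = np.argsort(s, axis=-1)
    n1 = y_mat.sum(axis=1).astype(float)  # (L,)
    n0 = y_mat.shape[1] - n1
    s_sorted = np.take_along_axis(s, order, axis=-1)
    if (s_sorted[..., 1:] == s_sorted[..., :-1]).any():
        # exact ties (e.g. duplicated trials): fall back to average ranks
        from scipy.stats import rankdata

        ranks = rankdata(s, axis=-1)
        r1 = np.einsum("tln,ln->lt", ranks, y_mat.astype(float))
    else:
        # rank-sum of class 1 == sum of (position+1) where sorted label is 1
        y_sorted = np.take_along_axis(
            np.broadcast_to(y_mat[None].astype(np.float64), s.shape), order, axis=-1
        )
        r1 = np.einsum("tln,n->lt", y_sorted, np.arange(1.0, s.shape[-1] + 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        auc = (r1 - n1[:, None] * (n1[:, None] + 1) / 2.0) / (n1 * n0)[:, None]
    return auc


def cv_lda_auc_timecourse(
    x: np.ndarray,
    unit_ids: np.ndarray,
    unit_labels: np.ndarray,
    *,
    n_folds: int = 5,
    n_reps: int = 5,
    rng: np.random.Generator,
    perm_unit_labels: np.ndarray | None = None,
    train_mask: np.ndarray | None = None,
    test_mask: np.ndarray | None = None,
    grouped_units: bool = False,
    label_chunk: int = 64,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Repeated k-fold cross-validated LDA AUC at every time sample.

    Parameters
    ----------
    x : (n_trials, n_channels, n_samples)
    unit_ids : (n_trials,) int
        Code of the label-carrying unit of each trial (0..n_units-1).
    unit_labels : (n_units,) int in {0, 1}
        Observed binary label per unit.
    perm_unit_labels : (n_perm, n_units) or None
        Permuted labelings evaluated alongside the observed one through
        the identical pipeline (same folds, same shrinkage).
    train_mask, test_mask : optional boolean trial masks
        Restrict fitting and evaluation to condition subsets; the fold
        structure is built on all trials so no trial is ever reused
        between a train and a test split.

    Returns
    -------
    auc : (n_samples,) observed AUC, averaged over folds and repetitions.
    null : (n_perm, n_samples) or None.
    """
    x = np.asarray(x)
    n, c, T = x.shape
    unit_ids = np.asarray(unit_ids)
    unit_labels = np.asarray(unit_labels)
    n_units = len(unit_labels)
    if set(np.unique(unit_labels)) - {0, 1}:
        raise ValueError("unit labels must be binary (0/1)")
    if len(np.unique(unit_labels)) < 2:
        raise ValueError("both classes must be present")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in features")

    if perm_unit_labels is None:
        labelings = unit_labels[None, :]
    else:
        labelings = np.vstack([unit_labels[None, :], np.asarray(perm_unit_labels)])
    L = labelings.shape[0]

    if train_mask is None:
        train_mask = np.ones(n, dtype=bool)
    if test_mask is None:
        test_mask = np.ones(n, dtype=bool)

    # keep the batched (B, T, c, c) scatter stack near ~200 MB
    label_chunk = max(1, min(label_chunk, int(2e8 / (T * c * c * 8)) or 1))

    auc_sum = np.zeros((L, T))
    n_eval = 0
    for _ in range(n_reps):
        folds = _fold_assignment(unit_ids, n_units, n_folds, rng, grouped_units, unit_labels)
        for f in range(n_folds):
            tr = (folds != f) & train_mask
            te = (folds == f) & test_mask
            if not te.any():
                continue
            xtr = x[tr]
            pid_tr = unit_ids[tr]
            y_tr_units = np.unique(pid_tr)
            if len(np.unique(unit_labels[y_tr_units])) < 2:
                raise ValueError("a training fold lacks one of the classes")

            # per-unit sufficient statistics (dense indicator matmul:
            # much faster than scattered adds for small unit counts)
            indicator = (pid_tr[None, :] == np.arange(n_units)[:, None]).astype(np.float64)
            usum = (indicator @ xtr.reshape(len(xtr), c * T)).reshape(n_units, c, T)
            ucount = indicator.sum(axis=1)

            xt = np.ascontiguousarray(xtr.transpose(2, 0, 1), dtype=np.float64)  # (T,n,c)
            s_tot = np.matmul(xt.transpose(0, 2, 1), xt)  # (T, c, c)
            n_tr = xtr.shape[0]
            grand = usum.sum(axis=0).T / n_tr  # (T, c)
            rho = _lw_shrinkage(xt - grand[:, None, :])  # (T,)

            xte = x[te]
            xte_t = np.ascontiguousarray(xte.transpose(2, 0, 1), dtype=np.float64)
            y_te_all = labelings[:, unit_ids[te]]  # (L, n_te)
            # skip labelings whose test split is single-class (AUC undefined)
            valid = (y_te_all.min(axis=1) == 0) & (y_te_all.max(axis=1) == 1)
            if not valid.all() and not valid[0]:
                raise ValueError("a test fold lacks one of the classes")

            usum_t = usum.reshape(n_units, c * T)
            eye = np.eye(c)
            for start in range(0, L, label_chunk):
                chunk = slice(start, min(start + label_chunk, L))
                lab = labelings[chunk].astype(float)  # (B, n_units)
                n1 = lab @ ucount
                n0 = n_tr - n1
                mu1 = (lab @ usum_t).reshape(-1, c, T) / n1[:, None, None]
                mu0 = ((1 - lab) @ usum_t).reshape(-1, c, T) / n0[:, None, None]
                mu1 = mu1.transpose(0, 2, 1)  # (B, T, c)
                mu0 = mu0.transpose(0, 2, 1)
                s_pool = (
                    s_tot[None]
                    - n1[:, None, None, None] * (mu1[..., :, None] * mu1[..., None, :])
                    - n0[:, None, None, None] * (mu0[..., :, None] * mu0[..., None, :])
                ) / max(n_tr - 2, 1)
                m_pool = np.trace(s_pool, axis1=2, axis2=3) / c  # (B, T)
                sigma = (1.0 - rho)[None, :, None, None] * s_pool + (
                    rho[None, :] * m_pool + 1e-12
                )[..., None, None] * eye
                delta = mu1 - mu0  # (B, T, c)
                w = np.linalg.solve(sigma, delta[..., None])[..., 0]  # (B, T, c)
                scores = np.matmul(xte_t, w.transpose(1, 2, 0))  # (T, n_te, B)
                auc = _auc_from_scores(scores, y_te_all[chunk])  # (B, T)
                auc_sum[chunk] += np.where(valid[chunk, None], auc, 0.5)
            n_eval += 1

    if n_eval == 0:
        raise ValueError("no usable folds")
    auc_all = auc_sum / n_eval
    observed = auc_all[0]
    null = auc_all[1:] if L > 1 else None
    return observed, null
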