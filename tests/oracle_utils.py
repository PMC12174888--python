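"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own computational paths: the filter is
checked against the unrolled joint-Gaussian density, ranking metrics against
exhaustive pair/threshold enumeration, and day labels against a literal
interval scan.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import multivariate_normal


def joint_gaussian_loglik(params, y, mask) -> float:
    """Log-density of the observed entries under the unrolled SSM joint law.

    Builds the exact (T*k)-dimensional latent Gaussian via covariance
    recursions, pushes it through the observation equation, and evaluates the
    resulting multivariate normal at the observed subvector.
    """
    T, n = y.shape
    k = params.k
    b = params.b
    # latent joint: mean 0; Cov(x_t, x_s) for t <= s is P_t * prod b over (t..s)
    P_marg = np.zeros((T, k, k))
    P_marg[0] = np.diag(params.stationary_var())
    for t in range(1, T):
        P_marg[t] = np.diag(b) @ P_marg[t - 1] @ np.diag(b) + np.eye(k)
    Sx = np.zeros((T * k, T * k))
    for t in range(T):
        for s in range(t, T):
            block = P_marg[t].copy()
            for step in range(t, s):
                block = block @ np.diag(b)
            Sx[t * k : (t + 1) * k, s * k : (s + 1) * k] = block
            Sx[s * k : (s + 1) * k, t * k : (t + 1) * k] = block.T
    Ablk = np.kron(np.eye(T), params.A)
    mu_y = np.tile(params.c, T)
    Sy = Ablk @ Sx @ Ablk.T + np.kron(np.eye(T), np.diag(params.r))
    obs = mask.ravel()
    if not obs.any():
        return 0.0
    return float(
        multivariate_normal(mean=mu_y[obs], cov=Sy[np.ix_(obs, obs)]).logpdf(
            y.ravel()[obs]
        )
    )


def pairwise_auroc(labels, scores) -> float:
    """AUROC by exhaustive positive-negative pair comparison, ties half."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


def threshold_auprc(labels, scores) -> float:
    """Average precision by explicit threshold enumeration (step PR curve)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    order = np.argsort(-scores, kind="stable")
    labels = labels[order]
    scores = scores[order]
    n_pos = labels.sum()
    ap = 0.0
    prev_recall = 0.0
    i = 0
    while i < len(scores):
        j = i
        while j < len(scores) and scores[j] == scores[i]:
            j += 1
        tp = labels[:j].sum()
        precision = tp / j
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return float(ap)


def interval_scan_labels(reports, study_start, T, boundary_hour=4.0):
    """Literal per-day interval membership scan (oracle for day labelling)."""
    from datetime import datetime, timedelta

    start = datetime(
        study_start.year, study_start.month, study_start.day
    ) + timedelta(hours=boundary_hour)
    labels = np.zeros(T, dtype=int)
    for rep in reports:
        for t in range(1, T + 1):
            lo = start + timedelta(days=t - 1)
            hi = start + timedelta(days=t)
            if lo <= rep.timestamp < hi:
                labels[t - 1] = 1
    return labels
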