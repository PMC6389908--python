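"""Independent brute-force / first-principles oracles used by the tests.

These deliberately avoid the package's own code paths (and statsmodels /
sklearn where the package relies on them) so that agreement is a real
cross-check, not a tautology.
"""

from __future__ import annotations

import numpy as np


def irls_logistic(
    X: np.ndarray, y: np.ndarray, max_iter: int = 200, tol: float = 1e-12
) -> tuple[np.ndarray, np.ndarray]:
    """Logistic MLE via hand-written iteratively-reweighted least squares.

    Returns (coefficients, observed-information standard errors).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        grad = X.T @ (y - p)
        hess = X.T @ (X * w[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    p = 1.0 / (1.0 + np.exp(-(X @ beta)))
    cov = np.linalg.inv(X.T @ (X * (p * (1.0 - p))[:, None]))
    return beta, np.sqrt(np.diag(cov))


def pairwise_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """O(n^2) concordant-pair AUC; tied pairs count one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    total = 0.0
    for c in cases:
        for k in controls:
            if c > k:
                total += 1.0
            elif c == k:
                total += 0.5
    return total / (len(cases) * len(controls))


def exhaustive_cutoff(scores: np.ndarray, labels: np.ndarray) -> float:
    """Best threshold by brute-force scan of every candidate.

    Candidates are -inf, every distinct score, and +inf; a sample is
    positive when score > threshold.  Maximizes mean(sens, spec), ties
    broken toward higher sensitivity, then the lower threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    best = None
    for t in np.concatenate([[-np.inf], np.unique(scores), [np.inf]]):
        sens = float(np.mean(cases > t))
        spec = float(np.mean(controls <= t))
        key = ((sens + spec) / 2.0, sens, -t)
        if best is None or key > best[0]:
            best = (key, t)
    return float(best[1])


def brute_force_mutual_rank(corr: np.ndarray) -> np.ndarray:
    """MR by explicit per-gene rank tables (average ranks on ties)."""
    corr = np.asarray(corr, dtype=float)
    n = corr.shape[0]
    ranks = np.full((n, n), np.nan)
    for a in range(n):
        others = [b for b in range(n) if b != a]
        values = sorted({corr[a, b] for b in others}, reverse=True)
        position = 1
        for v in values:
            tied = [b for b in others if corr[a, b] == v]
            avg_rank = position + (len(tied) - 1) / 2.0
            for b in tied:
                ranks[a, b] = avg_rank
            position += len(tied)
    mr = np.full((n, n), np.nan)
    for a in range(n):
        for b in range(n):
            if a != b:
                mr[a, b] = np.sqrt(ranks[a, b] * ranks[b, a])
    return mr


def eig2x2(cov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form eigendecomposition of a symmetric 2x2 matrix.

    Returns (eigenvalues descending, eigenvectors as columns).
    """
    a, b, c = cov[0, 0], cov[0, 1], cov[1, 1]
    disc = np.sqrt((a - c) ** 2 + 4.0 * b**2)
    lam1 = (a + c + disc) / 2.0
    lam2 = (a + c - disc) / 2.0
    vecs = []
    for lam in (lam1, lam2):
        if b != 0:
            v = np.array([b, lam - a])
        elif a >= c:
            v = np.array([1.0, 0.0]) if lam == lam1 else np.array([0.0, 1.0])
        else:
            v = np.array([0.0, 1.0]) if lam == lam1 else np.array([1.0, 0.0])
        vecs.append(v / np.linalg.norm(v))
    return np.array([lam1, lam2]), np.column_stack(vecs)
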