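"""State-dynamics statistics, the dynamic feature vector and its PCA, and
group comparison by permutation with multiplicity correction.

Given a per-window state sequence x(n) in 1..K, three families of
statistics summarize a session's dynamics:

* fraction time  f_k = #(x(n) = k) / N          — share of windows in state k
* dwell time     l_k = mean run length of k      — in window units (= TR at
  step 1); runs truncated by the sequence boundaries count as complete runs
* transition probability TP[i, j] = #(i -> j jumps) / #(all jumps), i != j

Concatenated as [f_1..f_K, l_1..l_K, TP off-diagonals row-major] they form
a 2K + K(K-1)-dimensional feature vector per subject (30 features at
K = 5), summarized across subjects by PCA ("Dyn-PCs").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_io import logger


@dataclass
class DynamicsSummary:
    """Fraction times, dwell times, run-length sets and transition matrix
    of one state sequence."""

    k: int
    fraction: np.ndarray  # (K,)
    dwell: np.ndarray  # (K,) mean run length, 0 for unvisited states
    runs: dict[int, list[int]]  # state -> run lengths
    visited: np.ndarray  # (K,) bool
    tp: np.ndarray  # (K, K), zero diagonal
    any_jump: bool


def _check_seq(x: np.ndarray, k: int) -> np.ndarray:
    x = np.asarray(x, dtype=int)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("state sequence must be a nonempty 1-D array")
    if x.min() < 1 or x.max() > k:
        raise ValueError(f"state labels must lie in 1..{k}")
    return x


def fraction_time(x: np.ndarray, k: int) -> np.ndarray:
    """f_k = #(x(n) = k) / N; sums to 1."""
    x = _check_seq(x, k)
    return np.bincount(x, minlength=k + 1)[1:] / x.size


def dwell_time(x: np.ndarray, k: int) -> tuple[np.ndarray, dict[int, list[int]]]:
    """Mean length of uninterrupted runs of each state, plus the run sets.

    Sequence boundaries terminate runs, and boundary-truncated runs count
    as complete.  A never-visited state has dwell time 0.
    """
    x = _check_seq(x, k)
    runs: dict[int, list[int]] = {s: [] for s in range(1, k + 1)}
    start = 0
    for t in range(1, x.size + 1):
        if t == x.size or x[t] != x[start]:
            runs[int(x[start])].append(t - start)
            start = t
    dwell = np.array(
        [np.mean(runs[s]) if runs[s] else 0.0 for s in range(1, k + 1)]
    )
    return dwell, runs


def transition_probabilities(x: np.ndarray, k: int) -> tuple[np.ndarray, bool]:
    """TP[i, j] = jumps i->j / total jumps; diagonal 0.

    With zero jumps TP is all-zero and the flag is False.
    """
    x = _check_seq(x, k)
    tp = np.zeros((k, k))
    jumps = np.flatnonzero(x[:-1] != x[1:])
    if jumps.size == 0:
        return tp, False
    for t in jumps:
        tp[x[t] - 1, x[t + 1] - 1] += 1
    return tp / jumps.size, True


def dynamics_summary(x: np.ndarray, k: int) -> DynamicsSummary:
    f = fraction_time(x, k)
    dwell, runs = dwell_time(x, k)
    tp, any_jump = transition_probabilities(x, k)
    return DynamicsSummary(
        k=k,
        fraction=f,
        dwell=dwell,
        runs=runs,
        visited=f > 0,
        tp=tp,
        any_jump=any_jump,
    )


# ---------------------------------------------------------------------------
# Feature vector and PCA
# ---------------------------------------------------------------------------


def feature_names(k: int) -> list[str]:
    names = [f"fraction_{s}" for s in range(1, k + 1)]
    names += [f"dwell_{s}" for s in range(1, k + 1)]
    names += [
        f"tp_{i}_{j}" for i in range(1, k + 1) for j in range(1, k + 1) if i != j
    ]
    return names


def feature_vector(summary: DynamicsSummary) -> np.ndarray:
    """[f_1..f_K, l_1..l_K, TP off-diagonals row-major]; length 2K + K(K-1)."""
    k = summary.k
    off = summary.tp[~np.eye(k, dtype=bool)]  # row-major off-diagonals
    return np.concatenate([summary.fraction, summary.dwell, off])


def unpack_feature_vector(vec: np.ndarray, k: int) -> DynamicsSummary:
    """Inverse of :func:`feature_vector` (runs are not recoverable)."""
    vec = np.asarray(vec, dtype=float)
    if vec.size != 2 * k + k * (k - 1):
        raise ValueError(f"expected length {2 * k + k * (k - 1)}, got {vec.size}")
    f = vec[:k]
    dwell = vec[k : 2 * k]
    tp = np.zeros((k, k))
    tp[~np.eye(k, dtype=bool)] = vec[2 * k :]
    return DynamicsSummary(
        k=k, fraction=f, dwell=dwell, runs={}, visited=f > 0, tp=tp,
        any_jump=bool(tp.sum() > 0),
    )


@dataclass
class DynPCA:
    """Principal components of the dynamic features across subjects."""

    loadings: np.ndarray  # (n_kept_features, n_components)
    scores: np.ndarray  # (n_subjects, n_components)
    variance_fraction: np.ndarray
    kept_features: np.ndarray  # indices of non-degenerate features
    mean: np.ndarray
    std: np.ndarray


def dyn_pca(features: np.ndarray, n_components: int = 3) -> DynPCA:
    """PCA of z-scored dynamic features across subjects.

    Features are z-scored across subjects (zero-variance features dropped
    with a warning); component signs are fixed by making the
    largest-magnitude loading positive.
    """
    from sklearn.decomposition import PCA

    X = np.asarray(features, dtype=float)
    if X.shape[0] < n_components + 1:
        raise ValueError("need more subjects than components")
    std = X.std(axis=0, ddof=1)
    kept = np.flatnonzero(std > 1e-12)
    if kept.size < X.shape[1]:
        logger.warning("dropping %d zero-variance feature(s)", X.shape[1] - kept.size)
    mean = X[:, kept].mean(axis=0)
    Z = (X[:, kept] - mean) / std[kept]
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(Z)
    loadings = pca.components_.T.copy()  # (features, components)
    for c in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[j, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    return DynPCA(
        loadings=loadings,
        scores=scores,
        variance_fraction=pca.explained_variance_ratio_.copy(),
        kept_features=kept,
        mean=mean,
        std=std[kept],
    )


def project_dyn_pca(pca: DynPCA, features: np.ndarray) -> np.ndarray:
    """Score new subjects' feature vectors on a fitted dynamic PCA."""
    X = np.asarray(features, dtype=float)[:, pca.kept_features]
    return (X - pca.mean) / pca.std @ pca.loadings


# ---------------------------------------------------------------------------
# Group tests
# ---------------------------------------------------------------------------


def group_permutation_test(
    a: np.ndarray,
    b: np.ndarray,
    n_perm: int = 10_000,
    sided: str = "two",
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Non-parametric two-sample permutation test on the t statistic.

    ``sided``: "two" (|t|), "greater" (mean(a) > mean(b)) or "less".
    The p-value uses the add-one estimator (1 + exceedances)/(1 + n_perm).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 observations")
    if n_perm < 100:
        logger.warning("n_perm=%d < 100: coarse p-value resolution", n_perm)
    if sided not in ("two", "greater", "less"):
        raise ValueError(f"unknown sidedness {sided!r}")
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    n_a = a.size

    def welch_t(x, y):
        vx = x.var(axis=-1, ddof=1) / x.shape[-1]
        vy = y.var(axis=-1, ddof=1) / y.shape[-1]
        return (x.mean(axis=-1) - y.mean(axis=-1)) / np.sqrt(vx + vy)

    obs = float(welch_t(a, b))
    # vectorized permutations: each row is an independent shuffle of the pool
    order = np.argsort(rng.random((n_perm, pooled.size)), axis=1)
    perm = pooled[order]
    t = welch_t(perm[:, :n_a], perm[:, n_a:])
    if sided == "two":
        exceed = int((np.abs(t) >= abs(obs)).sum())
    elif sided == "greater":
        exceed = int((t >= obs).sum())
    else:
        exceed = int((t <= obs).sum())
    return obs, (1 + exceed) / (1 + n_perm)


def adjust_pvalues(p: np.ndarray, method: str = "fdr", m: int | None = None) -> np.ndarray:
    """Multiple-comparison adjustment.

    ``method``: "bonferroni" -> min(1, m*p) with m defaulting to len(p);
    "fdr" -> Benjamini-Hochberg step-up adjusted values.
    """
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    method = method.lower()
    if method == "bonferroni":
        return np.minimum(1.0, (m if m is not None else p.size) * p)
    if method == "fdr":
        from statsmodels.stats.multitest import multipletests

        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown method {method!r}")
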