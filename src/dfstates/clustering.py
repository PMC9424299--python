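"""Dynamic functional states: K-means over rank-1 window features, K
selection, and per-state static-FC biomarkers.

Window features from all sessions are concatenated row-wise and clustered
with K-means under the correlation distance d(x, c) = 1 - corr(x, c)
(20 replicates, best total within-cluster distance kept), the convention of
the MATLAB k-means used in the reference analysis.  Each window is thereby
assigned to one dynamic functional state (DFS); states are labelled 1..K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from .core_io import AnalysisConfig, Parcellation, Session, logger
from .dfc import session_features

_MAX_ITER = 300


# ---------------------------------------------------------------------------
# Feature matrix
# ---------------------------------------------------------------------------


def build_feature_matrix(
    sessions: list[Session], cfg: AnalysisConfig
) -> tuple[np.ndarray, pd.DataFrame]:
    """Concatenate per-window rank-1 features across sessions.

    Returns (F, row_meta): F has one row per window; row_meta carries the
    session index, subject, timepoint and within-session window index of
    every row.
    """
    blocks, meta = [], []
    for s_idx, session in enumerate(sessions):
        feats = session_features(session, cfg)
        blocks.append(feats)
        meta.append(
            pd.DataFrame(
                {
                    "session": s_idx,
                    "subject_id": session.subject_id,
                    "timepoint": session.timepoint,
                    "window": np.arange(feats.shape[0]),
                }
            )
        )
    return np.vstack(blocks), pd.concat(meta, ignore_index=True)


# ---------------------------------------------------------------------------
# Correlation-distance K-means
# ---------------------------------------------------------------------------


def _standardize_rows(X: np.ndarray, what: str = "row") -> np.ndarray:
    """Center each row and scale to unit norm; correlation distance between
    standardized rows is then 1 minus their dot product."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    bad = np.flatnonzero(norms < 1e-12)
    if bad.size:
        raise ValueError(
            f"{what} {bad[0]} has zero variance; correlation distance undefined"
        )
    return Xc / norms[:, None]


@dataclass
class DFSModel:
    """Fitted state model: centroids, assignments and quality indices."""

    k: int
    centroids: np.ndarray  # (K, n_features), row-standardized
    assignments: np.ndarray  # state labels 1..K, one per row of F
    inertia: float  # total within-cluster correlation distance
    replicate_inertias: np.ndarray = field(default_factory=lambda: np.empty(0))
    silhouette: float = np.nan
    davies_bouldin: float = np.nan


def _lloyd_correlation(
    Xs: np.ndarray, init_rows: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """One Lloyd run on standardized rows; returns (labels0, centroids, inertia)."""
    k = init_rows.size
    C = Xs[init_rows].copy()
    labels = np.full(Xs.shape[0], -1)
    for _ in range(_MAX_ITER):
        Cn = _normalize_centroids(C, Xs, labels)
        D = 1.0 - Xs @ Cn.T  # (n, k) correlation distances
        new_labels = np.argmin(D, axis=1)
        # re-seed empty clusters from the row farthest from its centroid
        for j in range(k):
            if not (new_labels == j).any():
                far = int(np.argmax(D[np.arange(Xs.shape[0]), new_labels]))
                new_labels[far] = j
        if (new_labels == labels).all():
            break
        labels = new_labels
        C = np.vstack(
            [
                Xs[labels == j].mean(axis=0) if (labels == j).any() else C[j]
                for j in range(k)
            ]
        )
    Cn = _normalize_centroids(C, Xs, labels)
    D = 1.0 - Xs @ Cn.T
    inertia = float(D[np.arange(Xs.shape[0]), labels].sum())
    return labels, Cn, inertia


def _normalize_centroids(C: np.ndarray, Xs: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Re-standardize centroids (degenerate all-equal centroids fall back to
    the first row's pattern so the distance stays defined)."""
    Cc = C - C.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Cc, axis=1)
    out = np.empty_like(Cc)
    for j in range(C.shape[0]):
        if norms[j] < 1e-12:
            out[j] = Xs[0]
        else:
            out[j] = Cc[j] / norms[j]
    return out


def kmeans_correlation(
    F: np.ndarray,
    k: int,
    replicates: int = 20,
    seed: int | np.random.Generator = 0,
) -> DFSModel:
    """K-means with correlation distance; best of ``replicates`` seeded runs.

    Each replicate starts from K distinct random rows; iteration runs to an
    assignment fixed point; empty clusters are re-seeded from the farthest
    row.  The replicate with the lowest total within-cluster distance wins.
    Returned assignments are 1-based state labels.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    F = np.asarray(F, dtype=float)
    if F.shape[0] < k:
        raise ValueError("fewer rows than clusters")
    rng = np.random.default_rng(seed)
    Xs = _standardize_rows(F)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    inertias = np.empty(replicates)
    for rep in range(replicates):
        init = rng.choice(F.shape[0], size=k, replace=False)
        labels, C, inertia = _lloyd_correlation(Xs, init)
        inertias[rep] = inertia
        if best is None or inertia < best[0]:
            best = (inertia, labels, C)
    inertia, labels, C = best
    return DFSModel(
        k=k,
        centroids=C,
        assignments=labels + 1,
        inertia=inertia,
        replicate_inertias=inertias,
    )


def state_sequence(model: DFSModel, F_session: np.ndarray) -> np.ndarray:
    """Assign each window (row) of a session to its nearest centroid.

    Returns 1-based state labels; exact distance ties break toward the
    lowest state index (np.argmin convention).
    """
    Xs = _standardize_rows(np.asarray(F_session, dtype=float))
    D = 1.0 - Xs @ model.centroids.T
    return np.argmin(D, axis=1) + 1


def davies_bouldin_correlation(Xs: np.ndarray, model: DFSModel) -> float:
    """Davies-Bouldin index under correlation distance with the fitted
    centroids (lower is better)."""
    k = model.k
    C = model.centroids
    labels = model.assignments - 1
    S = np.empty(k)
    for j in range(k):
        member = Xs[labels == j]
        S[j] = float(np.mean(1.0 - member @ C[j])) if member.size else 0.0
    M = 1.0 - C @ C.T
    db = 0.0
    for i in range(k):
        ratios = [
            (S[i] + S[j]) / M[i, j] for j in range(k) if j != i and M[i, j] > 1e-12
        ]
        db += max(ratios) if ratios else 0.0
    return db / k


def select_k(
    F: np.ndarray,
    k_range: tuple[int, int] = (2, 10),
    replicates: int = 20,
    seed: int = 0,
    silhouette_row_budget: int = 20_000,
) -> tuple[pd.DataFrame, int, dict[int, DFSModel]]:
    """Fit every K in ``k_range`` (inclusive) and score each solution.

    Silhouette uses the correlation distance on the full row set (a seeded
    subsample above ``silhouette_row_budget`` rows); Davies-Bouldin uses the
    fitted centroids.  Recommendation = K maximizing silhouette; a
    disagreement with the Davies-Bouldin optimum is logged.
    """
    F = np.asarray(F, dtype=float)
    Xs = _standardize_rows(F)
    rng = np.random.default_rng(seed)
    rows = np.arange(F.shape[0])
    if F.shape[0] > silhouette_row_budget:
        rows = rng.choice(F.shape[0], size=silhouette_row_budget, replace=False)
    records, models = [], {}
    for k in range(k_range[0], k_range[1] + 1):
        model = kmeans_correlation(F, k, replicates=replicates, seed=rng)
        labels_sub = model.assignments[rows]
        if np.unique(labels_sub).size < 2:
            sil = -1.0
        else:
            sil = float(
                silhouette_score(F[rows], labels_sub, metric="correlation")
            )
        db = davies_bouldin_correlation(Xs, model)
        model.silhouette, model.davies_bouldin = sil, db
        models[k] = model
        records.append({"k": k, "silhouette": sil, "davies_bouldin": db})
    table = pd.DataFrame(records)
    k_sil = int(table.loc[table["silhouette"].idxmax(), "k"])
    k_db = int(table.loc[table["davies_bouldin"].idxmin(), "k"])
    if k_sil != k_db:
        logger.info("silhouette recommends K=%d, Davies-Bouldin K=%d", k_sil, k_db)
    if table["silhouette"].max() < 0.1:
        logger.warning("all silhouette values < 0.1: low-confidence K selection")
    return table, k_sil, models


# ---------------------------------------------------------------------------
# Per-state static-FC biomarkers
# ---------------------------------------------------------------------------


def homotopic_fc(z_matrix: np.ndarray, parcellation: Parcellation) -> dict[str, float]:
    """Per-network mean Fisher-z over homotopic (mirror-hemisphere) pairs.

    Networks without homotopic pairs are excluded with a warning.
    """
    out = {}
    for net in parcellation.cortical_networks():
        pairs = parcellation.homotopic_pairs(net)
        if not pairs:
            logger.warning("network %s has no homotopic pairs; excluded", net)
            continue
        out[net] = float(np.mean([z_matrix[i, j] for i, j in pairs]))
    return out


def dan_dmn_fc(
    z_matrix: np.ndarray,
    parcellation: Parcellation,
    net_a: str = "DAN",
    net_b: str = "DMN",
) -> float:
    """Mean Fisher-z between DAN and DMN regions within the same hemisphere
    (an index of task-positive/task-negative integration)."""
    a = parcellation.network_members(net_a)
    b = parcellation.network_members(net_b)
    if a.size == 0 or b.size == 0:
        raise ValueError(f"network {net_a if a.size == 0 else net_b} missing")
    hemi = np.asarray(parcellation.hemisphere)
    vals = [
        z_matrix[i, j]
        for i in a
        for j in b
        if hemi[i] == hemi[j] and hemi[i] in ("L", "R")
    ]
    if not vals:
        raise ValueError("no same-hemisphere DAN-DMN pairs")
    return float(np.mean(vals))


def modularity_signed(
    z_matrix: np.ndarray,
    partition: np.ndarray,
    densities: tuple[float, ...] = tuple(round(d / 100, 2) for d in range(4, 21)),
) -> float:
    """Newman modularity of a signed weighted FC matrix at a FIXED partition,
    averaged over edge densities.

    At each density d, the top d fraction of possible edges by |weight| is
    retained with its sign and weight (no binarization).  Positive and
    negative parts are each scored against their own configuration-model
    null and combined symmetrically, Q = Q+ - Q-.  Densities retaining no
    edge are skipped with a warning.
    """
    z_matrix = np.asarray(z_matrix, dtype=float)
    partition = np.asarray(partition)
    n = z_matrix.shape[0]
    if partition.shape != (n,):
        raise ValueError("partition must label every node")
    iu = np.triu_indices(n, k=1)
    w = z_matrix[iu]
    order = np.argsort(-np.abs(w))
    n_possible = w.size
    qs = []
    for d in densities:
        m = int(round(d * n_possible))
        if m < 1:
            logger.warning("density %.3f retains no edge; skipped", d)
            continue
        keep = order[:m]
        W = np.zeros_like(z_matrix)
        W[iu[0][keep], iu[1][keep]] = w[keep]
        W = W + W.T
        qs.append(_q_signed(W, partition))
    if not qs:
        raise ValueError("no density retained any edge")
    return float(np.mean(qs))


def _q_signed(W: np.ndarray, partition: np.ndarray) -> float:
    same = partition[:, None] == partition[None, :]
    q = 0.0
    for sign in (1.0, -1.0):
        Wp = np.clip(sign * W, 0.0, None)
        v = Wp.sum()
        if v <= 0:
            continue
        s = Wp.sum(axis=1)
        qp = ((Wp - np.outer(s, s) / v) * same).sum() / v
        q += sign * qp
    return q


@dataclass
class StateBiomarkers:
    """Mean +/- SEM of the three static-FC metrics per state."""

    table: pd.DataFrame  # columns: state, metric, mean, sem, n_windows
    empty_states: list[int]


def state_biomarkers(
    model: DFSModel,
    window_fcs: np.ndarray,
    parcellation: Parcellation,
    densities: tuple[float, ...] = tuple(round(d / 100, 2) for d in range(4, 21)),
) -> StateBiomarkers:
    """Homotopic FC (per network), DAN-DMN FC, and signed modularity per
    state, averaged over the windows assigned to the state.

    ``window_fcs`` must be aligned with ``model.assignments`` (one z-matrix
    per clustered window).  Single-window states report SEM = 0.
    """
    if len(window_fcs) != model.assignments.size:
        raise ValueError("window_fcs must align with model assignments")
    cortical = parcellation.cortical_idx
    partition = np.asarray(parcellation.network)[cortical]
    rows, empty = [], []
    for state in range(1, model.k + 1):
        member = np.flatnonzero(model.assignments == state)
        if member.size == 0:
            empty.append(state)
            continue
        metrics: dict[str, list[float]] = {}
        for w_idx in member:
            z = window_fcs[w_idx]
            for net, val in homotopic_fc(z, parcellation).items():
                metrics.setdefault(f"homotopic_{net}", []).append(val)
            metrics.setdefault("dan_dmn", []).append(dan_dmn_fc(z, parcellation))
            zc = z[np.ix_(cortical, cortical)]
            metrics.setdefault("modularity", []).append(
                modularity_signed(zc, partition, densities)
            )
        for name, vals in metrics.items():
            arr = np.asarray(vals)
            sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
            rows.append(
                {
                    "state": state,
                    "metric": name,
                    "mean": float(arr.mean()),
                    "sem": sem,
                    "n_windows": int(arr.size),
                }
            )
    if empty:
        logger.warning("states with no member windows: %s", empty)
    return StateBiomarkers(table=pd.DataFrame(rows), empty_states=empty)
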