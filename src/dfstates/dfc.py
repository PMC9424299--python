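"""Sliding-window Fisher-z functional connectivity and its rank-1
leading-eigenvector representation.

Each window's region x region Pearson correlation matrix is Fisher
z-transformed (r clipped to |r| <= 1 - 1e-6 so atanh stays finite, diagonal
set to 0) and summarized by the unit leading eigenvector ``v`` of the
z-matrix.  Because eigenvectors are defined up to sign, the sign-unambiguous
outer product ``v v^T`` (its vectorized upper triangle) is the clustering
feature; for signed time-course analyses a fixed sign convention is applied:
``v`` is flipped so that its mean over cortical entries is >= 0, ties broken
by making the largest-magnitude entry positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import AnalysisConfig, Parcellation, Session, logger, window_bounds

R_CLIP = 1.0 - 1e-6


@dataclass
class EigenWindow:
    """Leading-eigenvector summary of one window's Fisher-z FC."""

    v: np.ndarray  # unit leading eigenvector, sign-fixed
    eigenvalue: float
    window_index: int = -1


def fisher_z(r: np.ndarray) -> np.ndarray:
    """atanh with |r| clipped at 1 - 1e-6 to keep z finite."""
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def window_fc(session: Session, cfg: AnalysisConfig) -> np.ndarray:
    """Fisher-z FC matrix of every sliding window.

    Returns an array of shape (n_windows, R, R); each matrix is symmetric
    with an exactly zero diagonal.  A region that is constant within a
    window contributes zero correlations there (warned once per session).
    """
    if not session.censor_mask.all():
        raise ValueError("session must be trimmed before windowing")
    bounds = window_bounds(session.n_frames, cfg.window_width, cfg.window_step)
    out = np.empty((len(bounds), session.n_regions, session.n_regions))
    warned = False
    for i, (a, b) in enumerate(bounds):
        seg = session.data[:, a:b]
        sd = seg.std(axis=1)
        degenerate = sd == 0
        if degenerate.any() and not warned:
            logger.warning(
                "session %s window %d: %d constant region(s); correlations set to 0",
                session.subject_id, i, int(degenerate.sum()),
            )
            warned = True
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(seg)
        r[degenerate, :] = 0.0
        r[:, degenerate] = 0.0
        z = fisher_z(r)
        z = (z + z.T) / 2.0
        np.fill_diagonal(z, 0.0)
        out[i] = z
    return out


def leading_eigenvector(
    z_matrix: np.ndarray, parcellation: Parcellation | None = None
) -> EigenWindow:
    """Unit eigenvector of the largest-ALGEBRAIC eigenvalue, sign-fixed.

    The rank-1 reconstruction ``lambda * v v^T`` is the best rank-1
    symmetric approximation in Frobenius norm whenever the top eigenvalue
    dominates in magnitude (true for correlation-like matrices).  With a
    degenerate (tied) top eigenvalue the LAPACK eigenvector for the largest
    eigenvalue is returned, made deterministic by the sign convention.
    """
    z_matrix = np.asarray(z_matrix, dtype=float)
    if z_matrix.ndim != 2 or z_matrix.shape[0] != z_matrix.shape[1]:
        raise ValueError("z_matrix must be square")
    if not np.allclose(z_matrix, z_matrix.T, atol=1e-10):
        raise ValueError("z_matrix must be symmetric")
    if not np.isfinite(z_matrix).all():
        raise ValueError("z_matrix must be finite")
    n = z_matrix.shape[0]
    w, vec = np.linalg.eigh(z_matrix, UPLO="U")  # ascending eigenvalues
    v = vec[:, -1]
    v = v / np.linalg.norm(v)
    v = fix_sign(v, parcellation)
    return EigenWindow(v=v, eigenvalue=float(w[-1]))


def fix_sign(v: np.ndarray, parcellation: Parcellation | None = None) -> np.ndarray:
    """Flip ``v`` so the mean over cortical entries is >= 0; on an exact
    zero mean, make the largest-|entry| positive (lowest index on ties)."""
    idx = parcellation.cortical_idx if parcellation is not None else slice(None)
    m = float(np.mean(v[idx]))
    if m < 0:
        return -v
    if m == 0.0:
        j = int(np.argmax(np.abs(v)))
        if v[j] < 0:
            return -v
    return v


def rank1_feature(v: np.ndarray) -> np.ndarray:
    """Vectorized upper triangle of ``v v^T`` in row-major (i<j) pair order.

    Invariant under v -> -v; length R(R-1)/2.
    """
    v = np.asarray(v, dtype=float)
    outer = np.outer(v, v)
    iu = np.triu_indices(v.size, k=1)
    return outer[iu]


def pair_index(n_regions: int) -> list[tuple[int, int]]:
    """The fixed (i, j), i<j row-major pair ordering used for all
    vectorized region-pair features."""
    iu = np.triu_indices(n_regions, k=1)
    return list(zip(iu[0].tolist(), iu[1].tolist()))


def network_means(v: np.ndarray, parcellation: Parcellation) -> dict[str, float]:
    """Mean of ``v`` over the member regions of each cortical network."""
    if v.shape[0] != parcellation.n_regions:
        raise ValueError("v length must match parcellation size")
    out = {}
    for net in parcellation.cortical_networks():
        members = parcellation.network_members(net)
        if members.size == 0:
            raise ValueError(f"network {net!r} has no member regions")
        out[net] = float(v[members].mean())
    return out


def subcortical_subvector(v: np.ndarray, parcellation: Parcellation) -> np.ndarray:
    """Entries of ``v`` on the subcortical regions, in parcellation order."""
    if v.shape[0] != parcellation.n_regions:
        raise ValueError("v length must match parcellation size")
    return v[parcellation.subcortical_idx]


def session_eigenvectors(
    session: Session, cfg: AnalysisConfig, parcellation: Parcellation | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(windows x regions) sign-fixed eigenvector matrix and eigenvalues."""
    zs = window_fc(session, cfg)
    V = np.empty((zs.shape[0], session.n_regions))
    lam = np.empty(zs.shape[0])
    for i, z in enumerate(zs):
        ew = leading_eigenvector(z, parcellation)
        V[i] = ew.v
        lam[i] = ew.eigenvalue
    return V, lam


def session_features(session: Session, cfg: AnalysisConfig) -> np.ndarray:
    """(windows x pairs) rank-1 feature matrix of one session."""
    V, _ = session_eigenvectors(session, cfg)
    iu = np.triu_indices(session.n_regions, k=1)
    return np.einsum("wi,wj->wij", V, V)[:, iu[0], iu[1]]
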