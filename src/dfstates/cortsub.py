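"""Cortico-subcortical pattern reorganization: subcortical spatial PCA,
coupling projections, connectivity-shift series, jump binarization, and the
coincidence (simultaneity) test.

The subcortical entries of the per-window leading eigenvectors are reduced
by a spatial PCA to two components (SC1, SC2, typically a basal-ganglia /
thalamus "nuclei" cluster vs a hippocampus/amygdala "limbic" cluster).
Connectivity shifts are |differences| of the per-network eigenvector means
(cortex) or of the SC component scores (subcortex) between consecutive
windows, never across session boundaries.  Shifts above the 95th percentile
of the pooled distribution are "jumps"; the coincidence of subcortical and
cortical jumps is tested per network against the independence null with a
paired Wilcoxon signed-rank across subjects, Bonferroni-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import Parcellation, logger
from .dfc import network_means, subcortical_subvector


@dataclass
class SubcorticalPCA:
    """Two-component spatial PCA of the subcortical eigenvector entries."""

    loadings: np.ndarray  # P, (n_subcortical, 2), orthonormal columns
    mean: np.ndarray  # (n_subcortical,)
    variance_fraction: np.ndarray  # (2,)
    display_threshold: float = 0.2
    low_structure: bool = False

    def scores(self, v_sub: np.ndarray) -> np.ndarray:
        """w_sub = P^T (v_sub - mean); accepts one vector or a (T, n) stack."""
        return (np.atleast_2d(v_sub) - self.mean) @ self.loadings


def subcortical_pca(v_sub_stack: np.ndarray, n_components: int = 2) -> SubcorticalPCA:
    """Fit the spatial PCA on pooled subcortical subvectors.

    ``v_sub_stack``: (n_windows_total, n_subcortical) across all sessions.
    Component signs are fixed by making the largest-|loading| positive.
    Near-equal variance across components is flagged as low structure.
    """
    from sklearn.decomposition import PCA

    X = np.asarray(v_sub_stack, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need >= 3 pooled windows")
    if X.shape[1] < 2:
        raise ValueError("need >= 2 subcortical regions")
    pca = PCA(n_components=n_components)
    pca.fit(X)
    P = pca.components_.T.copy()
    for c in range(P.shape[1]):
        j = int(np.argmax(np.abs(P[:, c])))
        if P[j, c] < 0:
            P[:, c] *= -1
    vf = pca.explained_variance_ratio_.copy()
    low = bool(vf[0] < 1.5 * vf[-1])
    if low:
        logger.warning("subcortical PCA: near-isotropic variance split %s", vf)
    return SubcorticalPCA(
        loadings=P, mean=pca.mean_.copy(), variance_fraction=vf, low_structure=low
    )


def project_cortsub(
    v_net: np.ndarray, v_sub: np.ndarray, loadings: np.ndarray
) -> np.ndarray:
    """Network x SC-component coupling: (v_net v_sub^T) P.

    ``v_net``: per-network eigenvector means (n_networks,); the result has
    one row per network, one column per subcortical component.
    """
    v_net = np.asarray(v_net, dtype=float)
    v_sub = np.asarray(v_sub, dtype=float)
    if v_sub.shape[0] != loadings.shape[0]:
        raise ValueError("v_sub length must match loading rows")
    return np.outer(v_net, v_sub) @ loadings


@dataclass
class ShiftSeries:
    """|Delta| series of network means and SC scores, one entry per
    consecutive-window pair (length N-1 per session)."""

    networks: list[str]
    net_shifts: list[np.ndarray]  # per session: (N-1, n_networks)
    sub_shifts: list[np.ndarray]  # per session: (N-1, n_components)


def shift_series(
    eigvec_stacks: list[np.ndarray],
    parcellation: Parcellation,
    pca: SubcorticalPCA,
) -> ShiftSeries:
    """Within-session |differences| of v_net and w_sub between consecutive
    windows; session boundaries contribute no difference terms."""
    networks = parcellation.cortical_networks()
    net_out, sub_out = [], []
    for V in eigvec_stacks:
        V = np.asarray(V, dtype=float)
        if V.shape[0] < 2:
            raise ValueError("need >= 2 windows per session")
        vnet = np.stack(
            [
                V[:, parcellation.network_members(net)].mean(axis=1)
                for net in networks
            ],
            axis=1,
        )  # (N, n_networks)
        wsub = pca.scores(V[:, parcellation.subcortical_idx])  # (N, 2)
        net_out.append(np.abs(np.diff(vnet, axis=0)))
        sub_out.append(np.abs(np.diff(wsub, axis=0)))
    return ShiftSeries(networks=networks, net_shifts=net_out, sub_shifts=sub_out)


@dataclass
class JumpSeries:
    """Binarized shifts (jump = shift strictly above the threshold)."""

    threshold: float | dict[str, float]
    networks: list[str]
    net_jumps: list[np.ndarray]  # bool (N-1, n_networks) per session
    sub_jumps: list[np.ndarray]  # bool (N-1, n_components) per session


def binarize_jumps(
    shifts: ShiftSeries, percentile: float = 95.0, scope: str = "global"
) -> JumpSeries:
    """Threshold shifts at the ``percentile`` of the pooled distribution.

    ``scope="global"`` pools all subjects, networks and components into a
    single threshold (the study's single printed value); ``"per_series"``
    computes one threshold per network/component, pooled over subjects.
    """
    pooled_net = np.concatenate([s.ravel() for s in shifts.net_shifts])
    pooled_sub = np.concatenate([s.ravel() for s in shifts.sub_shifts])
    if scope == "global":
        theta = float(np.percentile(np.concatenate([pooled_net, pooled_sub]), percentile))
        net_j = [s > theta for s in shifts.net_shifts]
        sub_j = [s > theta for s in shifts.sub_shifts]
        return JumpSeries(theta, shifts.networks, net_j, sub_j)
    if scope == "per_series":
        n_net = shifts.net_shifts[0].shape[1]
        n_sub = shifts.sub_shifts[0].shape[1]
        th_net = np.array(
            [
                np.percentile(np.concatenate([s[:, c] for s in shifts.net_shifts]), percentile)
                for c in range(n_net)
            ]
        )
        th_sub = np.array(
            [
                np.percentile(np.concatenate([s[:, c] for s in shifts.sub_shifts]), percentile)
                for c in range(n_sub)
            ]
        )
        thresholds = {
            **{net: float(t) for net, t in zip(shifts.networks, th_net)},
            **{f"SC{c + 1}": float(t) for c, t in enumerate(th_sub)},
        }
        net_j = [s > th_net for s in shifts.net_shifts]
        sub_j = [s > th_sub for s in shifts.sub_shifts]
        return JumpSeries(thresholds, shifts.networks, net_j, sub_j)
    raise ValueError(f"unknown pooling scope {scope!r}")


def coincidence_probability(sub_jumps: np.ndarray, net_jumps: np.ndarray) -> float | None:
    """Observed P(subcortical jump | network jump) = #(both)/#(network jump).

    Returns None (subject excluded for this network) when the subject has
    no network jump.
    """
    sub_jumps = np.asarray(sub_jumps, dtype=bool)
    net_jumps = np.asarray(net_jumps, dtype=bool)
    n_net = int(net_jumps.sum())
    if n_net == 0:
        return None
    return float((sub_jumps & net_jumps).sum() / n_net)


def coincidence_test(
    jumps: JumpSeries,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Per-network coincidence test across subjects.

    Per subject: subcortical jumps are pooled across components (a jump in
    any SC component counts); the independence null for that subject is
    p_sub, the subject's overall subcortical jump rate.  A paired Wilcoxon
    signed-rank compares observed coincidence with p_sub per network;
    p-values are Bonferroni-corrected over the networks tested.
    """
    n_subjects = len(jumps.net_jumps)
    records = []
    per_network_obs: dict[str, list[float]] = {net: [] for net in jumps.networks}
    per_network_null: dict[str, list[float]] = {net: [] for net in jumps.networks}
    for s in range(n_subjects):
        sub_any = jumps.sub_jumps[s].any(axis=1)
        p_sub = float(sub_any.mean())
        for c, net in enumerate(jumps.networks):
            obs = coincidence_probability(sub_any, jumps.net_jumps[s][:, c])
            if obs is None:
                logger.info("subject %d: no %s jumps; excluded", s, net)
                continue
            per_network_obs[net].append(obs)
            per_network_null[net].append(p_sub)
    m = len(jumps.networks)
    for net in jumps.networks:
        obs = np.asarray(per_network_obs[net])
        null = np.asarray(per_network_null[net])
        if obs.size < 6:
            raise ValueError(f"network {net}: only {obs.size} subjects contribute")
        diff = obs - null
        if np.allclose(diff, 0):
            stat, p = 0.0, 1.0
        else:
            res = stats.wilcoxon(diff, alternative=alternative)
            stat, p = float(res.statistic), float(res.pvalue)
        records.append(
            {
                "network": net,
                "n_subjects": obs.size,
                "mean_observed": float(obs.mean()),
                "mean_null": float(null.mean()),
                "statistic": stat,
                "p": p,
                "p_bonferroni": min(1.0, m * p),
            }
        )
    return pd.DataFrame(records)
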