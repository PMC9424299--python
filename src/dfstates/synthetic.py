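"""Synthetic cohorts with planted hidden-Markov covariance states,
group-specific occupancy, lesions/disconnections, and behavior.

The generator plants exactly the statistical structure the pipeline
assumes, providing ground truth for every downstream stage:

* regional BOLD-like signals are Gaussian draws whose region x region
  covariance switches among K state-specific matrices according to a
  hidden Markov chain, smoothed by an order-1 autoregressive filter
  (AR(1) is the only hemodynamic realism; no HRF convolution — the
  analysis consumes correlation structure only);
* state covariances are specified at the network level (network x network
  coupling, within-network correlation, homotopic boost) and repaired to
  positive semi-definiteness by eigenvalue clipping;
* patient groups alter state occupancy through multipliers on the
  transition-matrix rows (renormalized);
* lesions are connected random blobs on a small voxel grid whose overlap
  with a hidden voxel weight field produces each subject's dynamics score;
* behavior scores are linear in (ST, Dyn-PC1..3) plus noise.

Every generator is bit-reproducible given (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import DEFAULT_NETWORKS, Parcellation, Session

SUBCORTICAL_CLUSTERS = ("nuclei", "limbic")


# ---------------------------------------------------------------------------
# Parcellation
# ---------------------------------------------------------------------------


def synthetic_parcellation(
    networks: tuple[str, ...] = DEFAULT_NETWORKS,
    regions_per_network: int = 6,
    n_nuclei: int = 6,
    n_limbic: int = 6,
) -> Parcellation:
    """Small test-scale parcellation: ``regions_per_network`` cortical
    regions per network, split evenly across hemispheres with every region
    homotopically paired, plus two subcortical clusters (48 + 12 regions at
    the defaults)."""
    if regions_per_network % 2:
        raise ValueError("regions_per_network must be even for homotopic pairing")
    labels, hemi, net, sub, partner = [], [], [], [], []
    half = regions_per_network // 2
    for network in networks:
        base = len(labels)
        for k in range(half):
            labels.append(f"{network}_L{k}")
            hemi.append("L")
            net.append(network)
            sub.append(False)
            partner.append(base + half + k)
        for k in range(half):
            labels.append(f"{network}_R{k}")
            hemi.append("R")
            net.append(network)
            sub.append(False)
            partner.append(base + k)
    for cluster, count in zip(SUBCORTICAL_CLUSTERS, (n_nuclei, n_limbic)):
        for k in range(count):
            labels.append(f"{cluster}_{k}")
            hemi.append("none")
            net.append(cluster)
            sub.append(True)
            partner.append(-1)
    return Parcellation(
        labels=tuple(labels),
        hemisphere=tuple(hemi),
        network=tuple(net),
        is_subcortical=tuple(sub),
        homotopic_partner=tuple(partner),
    )


# ---------------------------------------------------------------------------
# State covariances
# ---------------------------------------------------------------------------


@dataclass
class StateSpec:
    """Network-level description of one state's covariance.

    ``network_coupling`` is a symmetric (cluster x cluster) DataFrame over
    all network labels (cortical networks AND subcortical clusters), with
    entries in [-1, 1]; off-diagonal blocks of the region covariance take
    these values.  Within-network off-diagonal entries take
    ``within_network_r`` (the coupling diagonal is ignored), homotopic
    pairs get ``homotopic_boost`` added, and the whole matrix is scaled by
    ``noise_sd**2``.
    """

    network_coupling: pd.DataFrame
    within_network_r: float = 0.5
    homotopic_boost: float = 0.2
    noise_sd: float = 1.0

    def __post_init__(self):
        c = self.network_coupling.to_numpy(dtype=float)
        if (np.abs(c) > 1).any():
            raise ValueError("network couplings must lie in [-1, 1]")
        if not np.allclose(c, c.T, atol=1e-12):
            raise ValueError("network_coupling must be symmetric")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def psd_repair(sigma: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Clip negative eigenvalues to ``floor`` and re-symmetrize."""
    sigma = (sigma + sigma.T) / 2.0
    w, v = np.linalg.eigh(sigma)
    if w.min() >= floor:
        return sigma
    w = np.clip(w, floor, None)
    out = (v * w) @ v.T
    return (out + out.T) / 2.0


def build_state_covariance(spec: StateSpec, parcellation: Parcellation) -> np.ndarray:
    """Region x region covariance implied by a :class:`StateSpec`."""
    nets = np.asarray(parcellation.network)
    coupling = spec.network_coupling
    for label in np.unique(nets):
        if label not in coupling.index:
            raise ValueError(f"network {label!r} missing from network_coupling")
    n = parcellation.n_regions
    C = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                C[i, j] = 1.0
            elif nets[i] == nets[j]:
                C[i, j] = spec.within_network_r
            else:
                C[i, j] = coupling.loc[nets[i], nets[j]]
    for i, j in parcellation.homotopic_pairs():
        C[i, j] += spec.homotopic_boost
        C[j, i] += spec.homotopic_boost
    return psd_repair(spec.noise_sd**2 * C)


def default_state_specs(
    parcellation: Parcellation, k: int = 3, base_coupling: float = 0.6
) -> list[StateSpec]:
    """K well-separated states, each positively coupling its own disjoint
    block of networks/clusters against the rest."""
    clusters = parcellation.cortical_networks() + [
        c for c in SUBCORTICAL_CLUSTERS if c in set(parcellation.network)
    ]
    m = len(clusters)
    specs = []
    block = max(2, m // k)
    for s in range(k):
        cmat = pd.DataFrame(np.zeros((m, m)), index=clusters, columns=clusters)
        active = [clusters[(s * block + d) % m] for d in range(block)]
        for a in active:
            for b in active:
                if a != b:
                    cmat.loc[a, b] = base_coupling
        inactive = [c for c in clusters if c not in active]
        for a in active:
            for b in inactive:
                cmat.loc[a, b] = cmat.loc[b, a] = -base_coupling / 2
        np.fill_diagonal(cmat.values, 1.0)
        specs.append(StateSpec(network_coupling=cmat))
    return specs


# ---------------------------------------------------------------------------
# Markov switching
# ---------------------------------------------------------------------------


@dataclass
class MarkovPlant:
    """Hidden Markov chain over K states (row-stochastic transitions)."""

    transition_matrix: np.ndarray
    initial_dist: np.ndarray | None = None

    def __post_init__(self):
        P = np.asarray(self.transition_matrix, dtype=float)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("transition matrix must be square")
        if (P < 0).any() or not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transition-matrix rows must be non-negative and sum to 1")
        self.transition_matrix = P
        if self.initial_dist is None:
            self.initial_dist = stationary_distribution(P)
        else:
            self.initial_dist = np.asarray(self.initial_dist, dtype=float)
            if not np.isclose(self.initial_dist.sum(), 1.0):
                raise ValueError("initial_dist must sum to 1")

    @property
    def k(self) -> int:
        return self.transition_matrix.shape[0]

    @classmethod
    def from_mean_dwell(
        cls, mean_dwell: np.ndarray, stationary: np.ndarray | None = None
    ) -> "MarkovPlant":
        """Chain with P[i, i] = 1 - 1/dwell_i, off-diagonal mass spread
        uniformly (or toward ``stationary``)."""
        dwell = np.asarray(mean_dwell, dtype=float)
        k = dwell.size
        P = np.zeros((k, k))
        for i in range(k):
            stay = 1.0 - 1.0 / dwell[i]
            others = (
                np.delete(stationary, i) / np.delete(stationary, i).sum()
                if stationary is not None
                else np.full(k - 1, 1.0 / (k - 1))
            )
            P[i, i] = stay
            P[i, np.arange(k) != i] = (1.0 - stay) * others
        return cls(P)


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Left Perron eigenvector of a row-stochastic matrix, normalized."""
    w, v = np.linalg.eig(P.T)
    idx = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def apply_occupancy_multipliers(P: np.ndarray, multipliers: np.ndarray) -> np.ndarray:
    """Bias state occupancy: scale column j of every row by multiplier j,
    then renormalize rows.  Multipliers > 1 raise the target state's
    occupancy."""
    m = np.asarray(multipliers, dtype=float)
    if (m <= 0).any():
        raise ValueError("multipliers must be positive")
    Q = P * m[None, :]
    return Q / Q.sum(axis=1, keepdims=True)


def sample_state_sequence(
    plant: MarkovPlant, n_frames: int, rng: int | np.random.Generator = 0
) -> np.ndarray:
    """Frame-level state labels in 1..K sampled from the chain."""
    rng = np.random.default_rng(rng)
    P = plant.transition_matrix
    cum = np.cumsum(P, axis=1)
    x = np.empty(n_frames, dtype=int)
    state = int(rng.choice(plant.k, p=plant.initial_dist))
    u = rng.random(n_frames)
    for t in range(n_frames):
        x[t] = state + 1
        if t + 1 < n_frames:
            state = int(np.searchsorted(cum[state], u[t], side="right"))
            state = min(state, plant.k - 1)
    return x


# ---------------------------------------------------------------------------
# Sessions
# ---------------------------------------------------------------------------


def synth_session(
    parcellation: Parcellation,
    state_specs: list[StateSpec],
    frame_labels: np.ndarray,
    ar_coef: float = 0.3,
    rng: int | np.random.Generator = 0,
    tr: float = 2.0,
    subject_id: str = "synth",
    group: str = "control",
    timepoint: str = "visit1",
    severity: str = "n/a",
) -> Session:
    """One session whose frame t is drawn from its state's covariance and
    AR(1)-smoothed: s_t = a s_{t-1} + sqrt(1-a^2) e_t."""
    if not abs(ar_coef) < 1:
        raise ValueError("|ar_coef| must be < 1")
    frame_labels = np.asarray(frame_labels, dtype=int)
    k = len(state_specs)
    if frame_labels.min() < 1 or frame_labels.max() > k:
        raise ValueError("frame labels must index the provided state specs")
    rng = np.random.default_rng(rng)
    chols = [np.linalg.cholesky(build_state_covariance(s, parcellation)) for s in state_specs]
    n = parcellation.n_regions
    T = frame_labels.size
    eps = rng.standard_normal((T, n))
    data = np.empty((n, T))
    prev = np.zeros(n)
    scale = np.sqrt(1.0 - ar_coef**2)
    for t in range(T):
        innov = chols[frame_labels[t] - 1] @ eps[t]
        prev = ar_coef * prev + scale * innov
        data[:, t] = prev
    return Session(
        subject_id=subject_id,
        group=group,
        severity=severity,
        timepoint=timepoint,
        tr=tr,
        data=data,
        censor_mask=np.ones(T, dtype=bool),
    )


@dataclass
class CohortSpec:
    """Study-scale defaults: 300 retained frames at TR = 2 s per session;
    20 controls (two visits) and 47 patients (three timepoints); severe
    patients over-occupy state 2 at the expense of the others."""

    n_controls: int = 20
    n_patients: int = 47
    control_timepoints: tuple[str, ...] = ("visit1", "visit2")
    patient_timepoints: tuple[str, ...] = ("2wk", "3mo", "12mo")
    n_frames: int = 300
    tr: float = 2.0
    k: int = 5
    mean_dwell: float = 14.0  # frames; matches the ~14 TR scale of rest
    ar_coef: float = 0.3
    severe_fraction: float = 0.5
    severe_multipliers: np.ndarray | None = None  # per-state occupancy bias


def default_severe_multipliers(k: int) -> np.ndarray:
    """Severe patients over-occupy state 2, under-occupy the rest."""
    m = np.ones(k)
    m[1] = 2.5
    if k > 2:
        m[0] = 0.7
        m[2] = 0.7
    return m


@dataclass
class SyntheticCohort:
    sessions: list[Session]
    frame_labels: list[np.ndarray]  # planted per-frame states, aligned
    parcellation: Parcellation
    plant: MarkovPlant
    state_specs: list[StateSpec]
    subjects: pd.DataFrame  # subject_id, group, severity


def simulate_cohort(
    spec: CohortSpec | None = None,
    parcellation: Parcellation | None = None,
    state_specs: list[StateSpec] | None = None,
    seed: int | np.random.Generator = 0,
) -> SyntheticCohort:
    """Full cohort generator; returns sessions plus all planted truth."""
    spec = spec or CohortSpec()
    parcellation = parcellation or synthetic_parcellation()
    state_specs = state_specs or default_state_specs(parcellation, spec.k)
    if len(state_specs) != spec.k:
        raise ValueError("one StateSpec per state required")
    rng = np.random.default_rng(seed)
    base = MarkovPlant.from_mean_dwell(np.full(spec.k, spec.mean_dwell))
    severe_m = (
        spec.severe_multipliers
        if spec.severe_multipliers is not None
        else default_severe_multipliers(spec.k)
    )
    severe_plant = MarkovPlant(
        apply_occupancy_multipliers(base.transition_matrix, severe_m)
    )
    sessions, labels, subj_rows = [], [], []
    n_severe = int(round(spec.severe_fraction * spec.n_patients))
    for c in range(spec.n_controls):
        sid = f"ctl{c:03d}"
        subj_rows.append({"subject_id": sid, "group": "control", "severity": "n/a"})
        for tp in spec.control_timepoints:
            x = sample_state_sequence(base, spec.n_frames, rng)
            sessions.append(
                synth_session(
                    parcellation, state_specs, x, spec.ar_coef, rng,
                    tr=spec.tr, subject_id=sid, group="control", timepoint=tp,
                )
            )
            labels.append(x)
    for p in range(spec.n_patients):
        sid = f"pat{p:03d}"
        severity = "severe" if p < n_severe else "mild"
        plant = severe_plant if severity == "severe" else base
        subj_rows.append({"subject_id": sid, "group": "patient", "severity": severity})
        for tp in spec.patient_timepoints:
            x = sample_state_sequence(plant, spec.n_frames, rng)
            sessions.append(
                synth_session(
                    parcellation, state_specs, x, spec.ar_coef, rng,
                    tr=spec.tr, subject_id=sid, group="patient", timepoint=tp,
                    severity=severity,
                )
            )
            labels.append(x)
    return SyntheticCohort(
        sessions=sessions,
        frame_labels=labels,
        parcellation=parcellation,
        plant=base,
        state_specs=state_specs,
        subjects=pd.DataFrame(subj_rows),
    )


def window_majority_labels(frame_labels: np.ndarray, width: int, step: int = 1) -> np.ndarray:
    """Planted per-window state = majority frame label inside the window
    (ties toward the lower state), for comparison with clustering output."""
    from .core_io import window_bounds

    x = np.asarray(frame_labels, dtype=int)
    out = []
    for a, b in window_bounds(x.size, width, step):
        counts = np.bincount(x[a:b])
        out.append(int(np.argmax(counts)))
    return np.asarray(out)


# ---------------------------------------------------------------------------
# Lesions
# ---------------------------------------------------------------------------


@dataclass
class LesionPlant:
    """Hidden voxel weight field and lesion geometry on a small grid."""

    grid_shape: tuple[int, int, int] = (12, 12, 12)
    w_true: np.ndarray | None = None  # real weight per voxel
    blob_size_range: tuple[int, int] = (20, 120)
    score_noise_sd: float | None = None  # explicit noise level...
    snr: float | None = 3.0  # ...or signal-sd / noise-sd ratio

    def __post_init__(self):
        if self.w_true is None:
            self.w_true = default_weight_field(self.grid_shape)
        self.w_true = np.asarray(self.w_true, dtype=float)
        if self.w_true.shape != tuple(self.grid_shape):
            raise ValueError("w_true must match grid_shape")
        if not (self.w_true != 0).any():
            raise ValueError("w_true must have at least one nonzero voxel")
        if np.prod(self.grid_shape) == 0:
            raise ValueError("empty grid")


def default_weight_field(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Two smooth focal patches of opposite sign (Gaussian bumps)."""
    from scipy.ndimage import gaussian_filter

    w = np.zeros(grid_shape)
    gx, gy, gz = grid_shape
    w[gx // 4, gy // 4, gz // 4] = 1.0
    w[3 * gx // 4, 3 * gy // 4, 3 * gz // 4] = -1.0
    w = gaussian_filter(w, sigma=1.5, mode="constant")
    w[np.abs(w) < 0.02 * np.abs(w).max()] = 0.0
    return w / np.abs(w).max()


def _random_blob(
    grid_shape: tuple[int, int, int], size: int, rng: np.random.Generator
) -> np.ndarray:
    """Connected random blob grown from a seed voxel by boundary accretion."""
    mask = np.zeros(grid_shape, dtype=bool)
    seedv = tuple(rng.integers(0, s) for s in grid_shape)
    mask[seedv] = True
    frontier = {seedv}
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    while mask.sum() < size:
        candidates = set()
        for v in frontier:
            for d in offsets:
                nv = tuple(np.add(v, d))
                if all(0 <= nv[i] < grid_shape[i] for i in range(3)) and not mask[nv]:
                    candidates.add(nv)
        if not candidates:
            break
        pick_n = min(len(candidates), max(1, int(rng.integers(1, 4))))
        picks = rng.choice(len(candidates), size=pick_n, replace=False)
        cand_list = sorted(candidates)
        for pi in picks:
            mask[cand_list[pi]] = True
        frontier = {cand_list[pi] for pi in picks}
    return mask


def synth_lesion_cohort(
    n_subjects: int, plant: LesionPlant, rng: int | np.random.Generator = 0
) -> tuple[list[np.ndarray], np.ndarray]:
    """Random blob lesions plus scores = sum of w_true over lesioned voxels
    + Gaussian noise (sd from ``score_noise_sd`` or derived from ``snr``)."""
    if n_subjects < 10:
        raise ValueError("need >= 10 subjects")
    rng = np.random.default_rng(rng)
    masks = []
    for _ in range(n_subjects):
        size = int(rng.integers(plant.blob_size_range[0], plant.blob_size_range[1] + 1))
        masks.append(_random_blob(plant.grid_shape, size, rng))
    signal = np.array([plant.w_true[m].sum() for m in masks])
    if plant.score_noise_sd is not None:
        noise_sd = plant.score_noise_sd
    elif plant.snr is not None:
        noise_sd = signal.std() / plant.snr if signal.std() > 0 else 1.0
    else:
        noise_sd = 0.0
    scores = signal + noise_sd * rng.standard_normal(n_subjects)
    return masks, scores


def synth_disconnection_cohort(
    n_subjects: int,
    n_regions: int,
    rng: int | np.random.Generator = 0,
    n_true_pairs: int = 40,
    snr: float = 3.0,
) -> tuple[list[np.ndarray], np.ndarray, np.ndarray]:
    """Percent-disconnection matrices with a hidden pair-level weight
    vector; returns (matrices, scores, w_true_pairs)."""
    rng = np.random.default_rng(rng)
    iu = np.triu_indices(n_regions, k=1)
    n_pairs = iu[0].size
    w_true = np.zeros(n_pairs)
    idx = rng.choice(n_pairs, size=min(n_true_pairs, n_pairs), replace=False)
    w_true[idx] = rng.choice([-1.0, 1.0], size=idx.size)
    mats, signal = [], []
    for _ in range(n_subjects):
        vec = np.zeros(n_pairs)
        hit = rng.random(n_pairs) < 0.1
        vec[hit] = rng.uniform(0, 100, size=int(hit.sum()))
        m = np.zeros((n_regions, n_regions))
        m[iu] = vec
        mats.append(m + m.T)
        signal.append(float(vec @ w_true))
    signal = np.asarray(signal)
    noise_sd = signal.std() / snr if signal.std() > 0 else 1.0
    scores = signal + noise_sd * rng.standard_normal(n_subjects)
    return mats, scores, w_true


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------


@dataclass
class BehaviorPlant:
    """Linear map from (ST, Dyn-PC1..3) to each behavior domain."""

    coefficients: pd.DataFrame  # rows: ST, dyn1, dyn2, dyn3; cols: domains
    noise_sd: pd.Series  # per domain

    def __post_init__(self):
        if not np.isfinite(self.coefficients.to_numpy()).all():
            raise ValueError("coefficients must be finite")
        if list(self.coefficients.index) != ["ST", "dyn1", "dyn2", "dyn3"]:
            raise ValueError("coefficient rows must be [ST, dyn1, dyn2, dyn3]")


def synth_behavior(
    st: np.ndarray,
    dyn_pcs: np.ndarray,
    plant: BehaviorPlant,
    rng: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Behavior table: domain scores linear in (ST, Dyn-PCs) plus noise."""
    st = np.asarray(st, dtype=float)
    dyn_pcs = np.asarray(dyn_pcs, dtype=float)
    if dyn_pcs.shape != (st.size, 3):
        raise ValueError("dyn_pcs must be (n_subjects, 3) aligned with st")
    rng = np.random.default_rng(rng)
    X = np.column_stack([st, dyn_pcs])
    out = {}
    for domain in plant.coefficients.columns:
        beta = plant.coefficients[domain].to_numpy()
        out[domain] = X @ beta + plant.noise_sd[domain] * rng.standard_normal(st.size)
    return pd.DataFrame(out)
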