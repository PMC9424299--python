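"""Data model, file I/O, windowing convention, configuration and seeding.

The package operates on parcellated region x frame time-series matrices
("sessions") together with a parcellation table that assigns every region a
hemisphere, a cortical network label (or a subcortical cluster), and an
optional homotopic partner.

Windowing convention
--------------------
A session of ``T`` retained frames is divided into overlapping sliding
windows of width ``w`` frames stepped by ``step`` frames.  The number of
windows is

    N = floor((T - w) / step)

i.e. one FEWER than the conventional ``floor((T - w)/step) + 1``.  This
matches the reference analysis, which obtains 270 windows from 300 frames
at w = 30, step = 1.  Window ``i`` (0-based) covers the half-open frame
range ``[i*step, i*step + w)``; frame indices are 0-based throughout.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("dfstates")

HEMISPHERES = ("L", "R", "none")

#: canonical cortical network labels used in tests and the synthetic cohort
DEFAULT_NETWORKS = ("VIS", "SMN", "AUD", "CON", "DAN", "VAN", "FPN", "DMN")


class InsufficientFramesError(ValueError):
    """Raised when a session has fewer valid frames than requested."""


# ---------------------------------------------------------------------------
# Parcellation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Parcellation:
    """Region table: labels, hemispheres, networks, subcortical flags,
    homotopic partners.

    ``homotopic_partner[i]`` is the region_id of region i's mirror-position
    region in the opposite hemisphere, or -1 if it has none.  Pairing must
    be symmetric and cross hemispheres.
    """

    labels: tuple[str, ...]
    hemisphere: tuple[str, ...]
    network: tuple[str, ...]
    is_subcortical: tuple[bool, ...]
    homotopic_partner: tuple[int, ...]

    def __post_init__(self):
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("region labels must be unique")
        for name in ("hemisphere", "network", "is_subcortical", "homotopic_partner"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        for h in self.hemisphere:
            if h not in HEMISPHERES:
                raise ValueError(f"invalid hemisphere {h!r}")
        for i, (net, sub) in enumerate(zip(self.network, self.is_subcortical)):
            if not sub and not net:
                raise ValueError(f"cortical region {i} lacks a network label")
        for i, j in enumerate(self.homotopic_partner):
            if j < 0:
                continue
            if not (0 <= j < n) or j == i:
                raise ValueError(f"invalid homotopic partner {j} for region {i}")
            if self.homotopic_partner[j] != i:
                raise ValueError(f"homotopic pairing not symmetric at region {i}")
            if self.hemisphere[i] == self.hemisphere[j]:
                raise ValueError(f"homotopic pair ({i},{j}) does not cross hemispheres")

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    @property
    def subcortical_idx(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.is_subcortical))

    @property
    def cortical_idx(self) -> np.ndarray:
        return np.flatnonzero(~np.asarray(self.is_subcortical))

    def cortical_networks(self) -> list[str]:
        """Cortical network labels in first-appearance order."""
        seen: dict[str, None] = {}
        for net, sub in zip(self.network, self.is_subcortical):
            if not sub and net not in seen:
                seen[net] = None
        return list(seen)

    def network_members(self, network: str) -> np.ndarray:
        """Region indices of the cortical members of ``network``."""
        idx = [
            i
            for i, (net, sub) in enumerate(zip(self.network, self.is_subcortical))
            if net == network and not sub
        ]
        return np.asarray(idx, dtype=int)

    def homotopic_pairs(self, network: str | None = None) -> list[tuple[int, int]]:
        """Unordered homotopic pairs (i < j), optionally within one network."""
        pairs = []
        for i, j in enumerate(self.homotopic_partner):
            if j > i:
                if network is None or self.network[i] == network:
                    pairs.append((i, j))
        return pairs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": np.arange(self.n_regions),
                "label": self.labels,
                "hemisphere": self.hemisphere,
                "network": self.network,
                "is_subcortical": [int(s) for s in self.is_subcortical],
                "homotopic_partner": self.homotopic_partner,
            }
        )

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Parcellation":
        df = df.sort_values("region_id").reset_index(drop=True)
        if not (df["region_id"].to_numpy() == np.arange(len(df))).all():
            raise ValueError("region_ids must be contiguous from 0")
        return cls(
            labels=tuple(df["label"].astype(str)),
            hemisphere=tuple(df["hemisphere"].astype(str)),
            network=tuple(df["network"].astype(str)),
            is_subcortical=tuple(bool(x) for x in df["is_subcortical"]),
            homotopic_partner=tuple(int(x) for x in df["homotopic_partner"]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "Parcellation":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# Session
# ---------------------------------------------------------------------------


@dataclass
class Session:
    """One recording: a region x frame signal matrix plus metadata.

    ``censor_mask[t]`` is True where frame t is retained (valid signal);
    the mask is an input of the analysis — framewise displacement is never
    recomputed here.
    """

    subject_id: str
    group: str  # "control" | "patient"
    timepoint: str  # "visit1" | "visit2" | "2wk" | "3mo" | "12mo"
    tr: float
    data: np.ndarray  # (n_regions, n_frames)
    censor_mask: np.ndarray  # (n_frames,) bool
    severity: str = "n/a"  # "severe" | "mild" | "n/a"
    parcellation_file: str | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.censor_mask = np.asarray(self.censor_mask, dtype=bool)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (regions x frames)")
        if self.censor_mask.shape != (self.data.shape[1],):
            raise ValueError("censor_mask length must equal frame count")
        if not np.isfinite(self.data[:, self.censor_mask]).all():
            raise ValueError("data must be finite on retained frames")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def n_valid(self) -> int:
        return int(self.censor_mask.sum())


def trim_session(session: Session, n_keep: int = 300) -> Session:
    """Keep the first ``n_keep`` uncensored frames, in temporal order.

    Raises :class:`InsufficientFramesError` when fewer than ``n_keep`` valid
    frames exist, naming the deficit.
    """
    valid = np.flatnonzero(session.censor_mask)
    if valid.size < n_keep:
        raise InsufficientFramesError(
            f"session {session.subject_id}/{session.timepoint}: "
            f"{valid.size} valid frames < required {n_keep} "
            f"(short by {n_keep - valid.size})"
        )
    keep = valid[:n_keep]
    return dataclasses.replace(
        session,
        data=session.data[:, keep].copy(),
        censor_mask=np.ones(n_keep, dtype=bool),
    )


def count_windows(n_frames: int, width: int, step: int = 1) -> int:
    """Number of sliding windows: ``floor((T - w)/step)``.

    Deliberately one fewer than the conventional count (see module
    docstring); (300, 30, 1) -> 270.
    """
    if width < 2:
        raise ValueError("window width must be >= 2 frames")
    if step < 1:
        raise ValueError("window step must be >= 1")
    if n_frames <= width:
        raise ValueError(f"need more than {width} frames, got {n_frames}")
    return (n_frames - width) // step


def window_bounds(n_frames: int, width: int, step: int = 1) -> list[tuple[int, int]]:
    """Half-open frame ranges [start, stop) of each window."""
    n = count_windows(n_frames, width, step)
    return [(i * step, i * step + width) for i in range(n)]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    """Tunable parameters of the whole pipeline, with the study defaults."""

    n_keep: int = 300  # retained frames per session
    window_width: int = 30  # frames (60 s at TR = 2 s)
    window_step: int = 1
    k_range: tuple[int, int] = (2, 10)  # inclusive K-means search range
    kmeans_replicates: int = 20
    jump_percentile: float = 95.0
    jump_pooling: str = "global"  # "global" | "per_series"
    modularity_densities: tuple[float, ...] = tuple(
        round(d / 100, 2) for d in range(4, 21)
    )  # 4%..20%
    lambda_min: float = 1e-5
    lambda_max: float = 1e5
    lambda_steps: int = 200
    ridge_var_frac: float = 0.97
    n_permutations: int = 10_000
    silhouette_row_budget: int = 20_000
    master_seed: int = 0

    def __post_init__(self):
        if self.window_step < 1:
            raise ValueError("window_step must be >= 1")
        if self.window_width >= self.n_keep:
            raise ValueError("window_width must be smaller than retained frames")
        lo, hi = self.k_range
        if not (2 <= lo <= hi):
            raise ValueError("invalid k_range")
        for v in (self.kmeans_replicates, self.lambda_steps, self.n_permutations):
            if v < 1:
                raise ValueError("counts must be positive")

    @property
    def lambda_grid(self) -> np.ndarray:
        return np.logspace(
            np.log10(self.lambda_min), np.log10(self.lambda_max), self.lambda_steps
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_range"] = list(self.k_range)
        d["modularity_densities"] = list(self.modularity_densities)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        kw = {k: v for k, v in d.items() if k in known}
        if "k_range" in kw:
            kw["k_range"] = tuple(kw["k_range"])
        if "modularity_densities" in kw:
            kw["modularity_densities"] = tuple(kw["modularity_densities"])
        return cls(**kw)


def spawn_rngs(master_seed: int, n: int) -> list[np.random.Generator]:
    """Deterministic fan-out of a master seed to independent generators."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(master_seed).spawn(n)]


def child_seed(master_seed: int, label: str) -> int:
    """Stable per-purpose integer seed (< 2**31) derived from the master seed."""
    h = hashlib.sha256(f"{master_seed}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# Session file I/O
# ---------------------------------------------------------------------------


def write_session(session: Session, matrix_path: str | Path) -> None:
    """Write the region x frame matrix (TSV, first column = region label)
    and a JSON sidecar with the metadata."""
    matrix_path = Path(matrix_path)
    df = pd.DataFrame(
        session.data,
        index=[f"R{i:04d}" for i in range(session.n_regions)],
    )
    df.to_csv(matrix_path, sep="\t", header=False, float_format="%.8g")
    sidecar = {
        "subject_id": session.subject_id,
        "group": session.group,
        "severity": session.severity,
        "timepoint": session.timepoint,
        "TR": session.tr,
        "censor_mask": [int(v) for v in session.censor_mask],
        "parcellation_file": session.parcellation_file,
    }
    matrix_path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_session(matrix_path: str | Path) -> Session:
    matrix_path = Path(matrix_path)
    df = pd.read_csv(matrix_path, sep="\t", header=None, index_col=0)
    meta = json.loads(matrix_path.with_suffix(".json").read_text())
    return Session(
        subject_id=meta["subject_id"],
        group=meta["group"],
        severity=meta.get("severity", "n/a"),
        timepoint=meta["timepoint"],
        tr=meta["TR"],
        data=df.to_numpy(dtype=float),
        censor_mask=np.asarray(meta["censor_mask"], dtype=bool),
        parcellation_file=meta.get("parcellation_file"),
    )


def load_disconnection_matrix(path: str | Path) -> pd.DataFrame:
    """Square region x region percent-disconnection matrix, TSV with labels."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError("disconnection matrix must be square")
    return df


def run_manifest(config: AnalysisConfig, seed: int) -> dict:
    """Provenance record written next to every CLI output."""
    import dfstates

    cfg = config.to_dict()
    return {
        "package": "dfstates",
        "version": dfstates.__version__,
        "numpy": np.__version__,
        "seed": seed,
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
    }
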