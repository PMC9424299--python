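"""Static-FC summary component (ST), behavioral recovery scores, and nested
GLM likelihood-ratio tests of static vs dynamic regressors.

The ST score summarizes each patient's static-FC abnormality: every FC edge
is z-scored against the control distribution, and the first spatial PC of
these abnormality maps — fitted on a reference patient set — scores each
analysis patient.  The component sign is oriented so that a higher ST means
lower mean homotopic FC (the "severe" direction); patients with ST > 0 are
labelled severe, ST < 0 mild.

Behavioral models are Gaussian identity-link GLMs (ordinary linear models
fitted by maximum likelihood); nested models are compared with the
likelihood-ratio test, chi2 = 2 (ll_full - ll_reduced) on df = number of
added regressors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core_io import Parcellation, Session, logger
from .dfc import fisher_z
from .clustering import homotopic_fc
from .lesion import r_squared


def static_fc(session: Session) -> np.ndarray:
    """Fisher-z correlation over ALL retained frames (zero diagonal).

    Note: this is not identical to the mean of the windowed z-matrices.
    Constant regions get zero rows/columns with a warning.
    """
    data = session.data[:, session.censor_mask]
    sd = data.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning(
            "session %s: %d constant region(s) in static FC",
            session.subject_id, int(degenerate.sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data)
    r[degenerate, :] = 0.0
    r[:, degenerate] = 0.0
    z = fisher_z(r)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return z


@dataclass
class StaticSummary:
    """ST scores and severity labels of the analysis patients."""

    st: np.ndarray  # per analysis patient
    severity: list[str]  # "severe" (ST > 0) / "mild"
    loading: np.ndarray  # spatial PC on kept edges
    kept_edges: np.ndarray  # indices into the upper-triangle edge vector


def _edge_vectors(fcs: list[np.ndarray]) -> np.ndarray:
    n = fcs[0].shape[0]
    iu = np.triu_indices(n, k=1)
    return np.stack([fc[iu] for fc in fcs])


def static_summary(
    patient_fcs: list[np.ndarray],
    control_fcs: list[np.ndarray],
    parcellation: Parcellation,
    reference_fcs: list[np.ndarray] | None = None,
) -> StaticSummary:
    """ST score per analysis patient from control-referenced abnormality maps.

    Each edge is z-scored against the control mean/sd (zero-sd edges are
    dropped); the spatial PCA is fitted on ``reference_fcs`` when given
    (the independent-reference device), else on the analysis patients.
    """
    if len(control_fcs) < 2:
        raise ValueError("need >= 2 controls")
    ref_fcs = reference_fcs if reference_fcs is not None else patient_fcs
    if len(ref_fcs) < 3:
        raise ValueError("need >= 3 reference patients")
    ctl = _edge_vectors(control_fcs)
    mu, sd = ctl.mean(axis=0), ctl.std(axis=0, ddof=1)
    kept = np.flatnonzero(sd > 1e-12)
    if kept.size < sd.size:
        logger.warning("dropping %d zero-variance control edges", sd.size - kept.size)

    def abnormality(fcs):
        return (_edge_vectors(fcs)[:, kept] - mu[kept]) / sd[kept]

    from sklearn.decomposition import PCA

    pca = PCA(n_components=1)
    pca.fit(abnormality(ref_fcs))
    loading = pca.components_[0].copy()
    ab = abnormality(patient_fcs)
    st = (ab - pca.mean_) @ loading

    # orient: higher ST must track LOWER mean homotopic FC (severe direction)
    homo = np.array(
        [np.mean(list(homotopic_fc(fc, parcellation).values())) for fc in patient_fcs]
    )
    if np.corrcoef(st, homo)[0, 1] > 0:
        loading, st = -loading, -st
    severity = ["severe" if s > 0 else "mild" for s in st]
    return StaticSummary(st=st, severity=severity, loading=loading, kept_edges=kept)


def recovery(score_2wk: float, score_1y: float) -> float:
    """(score_1y - score_2wk) / |score_2wk|; NaN (excluded) when the
    2-week score is exactly 0."""
    if score_2wk == 0:
        logger.info("recovery undefined for a zero 2-week score; excluded")
        return np.nan
    return (score_1y - score_2wk) / abs(score_2wk)


@dataclass
class NestedGLMResult:
    r2_reduced: float
    r2_full: float
    chi2: float
    df: int
    p: float
    coef: pd.DataFrame  # full-model estimates with p-values


def nested_glm_lrt(
    y: np.ndarray, X_reduced: np.ndarray, X_full: np.ndarray
) -> NestedGLMResult:
    """Likelihood-ratio test of nested Gaussian linear models (intercept
    added to both).  ``X_reduced``'s columns must be a prefix/subset of
    ``X_full``'s columns by construction of the caller."""
    y = np.asarray(y, dtype=float)
    Xr = np.column_stack([np.ones(y.size), np.asarray(X_reduced, dtype=float)])
    Xf = np.column_stack([np.ones(y.size), np.asarray(X_full, dtype=float)])
    df = Xf.shape[1] - Xr.shape[1]
    if df <= 0 and Xf.shape[1] != Xr.shape[1]:
        raise ValueError("full model must add regressors")
    if y.size <= Xf.shape[1]:
        raise ValueError("too few observations for the full model")
    if np.linalg.matrix_rank(Xf) < Xf.shape[1]:
        raise ValueError("rank-deficient full design")
    fit_r = sm.OLS(y, Xr).fit()
    fit_f = sm.OLS(y, Xf).fit()
    chi2 = max(0.0, 2.0 * (fit_f.llf - fit_r.llf))
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    coef = pd.DataFrame(
        {
            "estimate": fit_f.params,
            "p": fit_f.pvalues,
        },
        index=[f"b{i}" for i in range(Xf.shape[1])],
    )
    return NestedGLMResult(
        r2_reduced=r_squared(y, fit_r.fittedvalues),
        r2_full=r_squared(y, fit_f.fittedvalues),
        chi2=float(chi2),
        df=df,
        p=p if df > 0 else 1.0,
        coef=coef,
    )


def model_comparison_suite(
    behavior: pd.DataFrame,
    st: np.ndarray,
    dyn_pcs: np.ndarray,
    min_cases: int = 10,
) -> pd.DataFrame:
    """Per behavioral domain: static-only, dynamic-only and full model R^2,
    with LRTs full-vs-static and full-vs-dynamic.

    ``behavior``: one column per domain, one row per subject, aligned with
    ``st`` and ``dyn_pcs``; missing scores are dropped per domain
    (complete-case); domains with fewer than ``min_cases`` complete cases
    are skipped with a log entry.
    """
    st = np.asarray(st, dtype=float)
    dyn_pcs = np.asarray(dyn_pcs, dtype=float)
    if behavior.shape[0] != st.size or dyn_pcs.shape[0] != st.size:
        raise ValueError("behavior, ST and Dyn-PCs must align subject-wise")
    rows = []
    for domain in behavior.columns:
        y_all = behavior[domain].to_numpy(dtype=float)
        ok = np.isfinite(y_all)
        if ok.sum() < min_cases:
            logger.info("domain %s: %d complete cases; skipped", domain, int(ok.sum()))
            continue
        y = y_all[ok]
        Xs = st[ok, None]
        Xd = dyn_pcs[ok]
        Xfull = np.column_stack([Xs, Xd])
        vs_static = nested_glm_lrt(y, Xs, Xfull)
        vs_dynamic = nested_glm_lrt(y, Xd, np.column_stack([Xd, Xs]))
        rows.append(
            {
                "domain": domain,
                "n": int(ok.sum()),
                "r2_static": vs_static.r2_reduced,
                "r2_dynamic": vs_dynamic.r2_reduced,
                "r2_full": vs_static.r2_full,
                "lrt_full_vs_static_chi2": vs_static.chi2,
                "lrt_full_vs_static_p": vs_static.p,
                "lrt_full_vs_dynamic_chi2": vs_dynamic.chi2,
                "lrt_full_vs_dynamic_p": vs_dynamic.p,
            }
        )
    return pd.DataFrame(rows)
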