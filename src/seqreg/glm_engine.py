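"""First-level GLM on ROI time series and group-level window statistics.

First level: ordinary least squares of each ROI's signal on the assembled
design (optionally AR(1)-prewhitened, Cochrane–Orcutt style), with
t contrasts on the fitted coefficients.  Second level: the per-subject
modulator betas across window lengths enter a one-way repeated-measures
ANOVA with subjects as the blocking factor, Benjamini–Hochberg FDR over
ROIs, and post-hoc paired t tests between the extreme window lengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .design_builder import DesignMatrix


@dataclass
class GLMFit:
    """Fitted first-level model for one or more ROIs sharing a design.

    ``betas`` is columns-by-ROIs; ``sigma2`` the residual variance per ROI
    with ``df = n_retained - rank(X)``; ``xtx_inv`` the (pseudo)inverse of
    the normal matrix used for contrast variances.  ``phi`` records the
    AR(1) coefficient per ROI when prewhitening was applied.
    """

    betas: pd.DataFrame
    sigma2: np.ndarray
    df: int
    xtx_inv: np.ndarray
    columns: list[str]
    whitening: str = "none"
    phi: np.ndarray | None = None

    def beta(self, column: str, roi: str | int = 0) -> float:
        return float(self.betas.loc[column].iloc[roi] if isinstance(roi, int) else self.betas.loc[column, roi])


def _as_matrix(roi_ts: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(roi_ts, pd.DataFrame):
        return roi_ts.to_numpy(float), [str(c) for c in roi_ts.columns]
    arr = np.asarray(roi_ts, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, [f"roi_{i}" for i in range(arr.shape[1])]


def _ols(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int, np.ndarray]:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"design is rank deficient after trimming (rank {rank} < "
            f"{X.shape[1]} columns)"
        )
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    df = X.shape[0] - rank
    sigma2 = (resid**2).sum(axis=0) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    return beta, sigma2, df, xtx_inv


def lag1_autocorr(x: np.ndarray) -> float:
    """Sample lag-1 autocorrelation of a 1-D series."""
    x = np.asarray(x, float)
    x = x - x.mean()
    denom = (x**2).sum()
    if denom == 0:
        return 0.0
    return float((x[1:] * x[:-1]).sum() / denom)


def fit_first_level(
    design: DesignMatrix,
    roi_ts: pd.DataFrame | np.ndarray,
    whitening: str = "none",
    ar1_phi: float | None = None,
) -> GLMFit:
    """Estimate the GLM on one or more ROI series (rows = retained volumes).

    ``whitening='ar1'`` estimates phi from the lag-1 autocorrelation of the
    OLS residuals per ROI (or uses the fixed ``ar1_phi`` if given) and
    refits on quasi-differenced data (Cochrane–Orcutt); ``phi = 0``
    reproduces OLS exactly.
    """
    if whitening not in ("none", "ar1"):
        raise ValueError(f"unknown whitening {whitening!r}")
    X = design.matrix
    Y, roi_names = _as_matrix(roi_ts)
    if Y.shape[0] != X.shape[0]:
        raise ValueError(
            f"time series has {Y.shape[0]} rows but design retains {X.shape[0]} volumes"
        )
    beta, sigma2, df, xtx_inv = _ols(X, Y)
    phi = None
    if whitening == "ar1":
        if ar1_phi is not None:
            phi = np.full(Y.shape[1], float(ar1_phi))
        else:
            resid = Y - X @ beta
            phi = np.array([lag1_autocorr(resid[:, j]) for j in range(Y.shape[1])])
        betas_w = np.empty_like(beta)
        sig_w = np.empty_like(sigma2)
        xtx_list = []
        for j, ph in enumerate(phi):
            if ph == 0.0:  # no differencing: identical to OLS
                Xw, yw = X, Y[:, j]
            else:
                Xw = X[1:] - ph * X[:-1]
                yw = Y[1:, j] - ph * Y[:-1, j]
            bj, s2j, df, xtx_j = _ols(Xw, yw[:, None])
            betas_w[:, j] = bj[:, 0]
            sig_w[j] = s2j[0]
            xtx_list.append(xtx_j)
        beta, sigma2 = betas_w, sig_w
        xtx_inv = np.stack(xtx_list)  # per-ROI normal matrices
    return GLMFit(
        betas=pd.DataFrame(beta, index=design.columns, columns=roi_names),
        sigma2=np.atleast_1d(sigma2),
        df=df,
        xtx_inv=xtx_inv,
        columns=design.columns,
        whitening=whitening,
        phi=phi,
    )


def contrast(
    fit: GLMFit, weights: Mapping[str, float] | np.ndarray
) -> pd.DataFrame:
    """t contrast ``c'beta`` per ROI, with SE from ``c'(X'X)^-1 c sigma^2``."""
    if isinstance(weights, Mapping):
        unknown = set(weights) - set(fit.columns)
        if unknown:
            raise ValueError(f"weights on unknown columns: {sorted(unknown)}")
        c = np.array([weights.get(name, 0.0) for name in fit.columns])
    else:
        c = np.asarray(weights, dtype=float)
        if c.shape != (len(fit.columns),):
            raise ValueError(
                f"weight vector length {c.shape} != {len(fit.columns)} columns"
            )
    est = c @ fit.betas.to_numpy()
    if fit.xtx_inv.ndim == 3:  # AR(1) path: one normal matrix per ROI
        quad = np.array([c @ M @ c for M in fit.xtx_inv])
    else:
        quad = float(c @ fit.xtx_inv @ c)
    var = quad * fit.sigma2
    se = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = est / se
    p = 2 * scipy.stats.t.sf(np.abs(t), fit.df)
    return pd.DataFrame(
        {"estimate": est, "se": se, "t": t, "df": fit.df, "p": p},
        index=fit.betas.columns,
    )


def rm_anova_window(table: np.ndarray | pd.DataFrame) -> tuple[float, tuple[int, int], float]:
    """One-way repeated-measures ANOVA over a subjects x windows table.

    Subjects are the blocking factor; no sphericity correction is applied,
    giving df = (k - 1, (n - 1)(k - 1)).  A table with no within-subject
    variation across windows returns F = 0, p = 1.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 window levels")
    if np.isnan(arr).any():
        raise ValueError("missing cells in the effects table")
    n, k = arr.shape
    grand = arr.mean()
    ss_cond = n * ((arr.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((arr.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((arr - grand) ** 2).sum()
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = k - 1, (n - 1) * (k - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    scale = max(ss_total, 1.0)
    if ms_err <= 1e-15 * scale:
        if ms_cond <= 1e-15 * scale:
            return 0.0, (df1, df2), 1.0
        return float("inf"), (df1, df2), 0.0
    F = ms_cond / ms_err
    p = float(scipy.stats.f.sf(F, df1, df2))
    return float(F), (df1, df2), p


def greenhouse_geisser_epsilon(table: np.ndarray) -> float:
    """Greenhouse–Geisser sphericity epsilon for a subjects x windows table."""
    arr = np.asarray(table, dtype=float)
    k = arr.shape[1]
    S = np.cov(arr, rowvar=False)
    mean_diag = np.trace(S) / k
    num = (k * (mean_diag - S.mean())) ** 2
    den = (k - 1) * ((S**2).sum() - 2 * k * (S.mean(axis=0) ** 2).sum() + k**2 * S.mean() ** 2)
    if den <= 0:
        return 1.0
    return float(min(1.0, max(num / den, 1.0 / (k - 1))))


def bh_fdr(p_values: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up FDR: rejections and adjusted p values."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def posthoc_paired_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, int, float]:
    """Two-sided paired t test between effects at two window lengths."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need paired, equal-length samples with n >= 2")
    d = a - b
    if np.std(d, ddof=1) == 0:
        raise ValueError("zero variance of paired differences; t undefined")
    res = scipy.stats.ttest_rel(a, b)
    return float(res.statistic), len(a) - 1, float(res.pvalue)


@dataclass
class GroupResult:
    """Second-level summary per ROI and measure.

    ``effects``: tidy (subject, window, roi, measure, beta) table.
    ``anova``: per (roi, measure) rm-ANOVA F, dfs, p, BH-FDR decision.
    ``posthoc``: paired t between the smallest and largest window.
    """

    effects: pd.DataFrame
    anova: pd.DataFrame
    posthoc: pd.DataFrame


def group_window_stats(effects: pd.DataFrame, q: float = 0.05) -> GroupResult:
    """Window-length statistics from a tidy per-subject effects table.

    ``effects`` needs columns subject, window, roi, measure, beta with a
    complete subject x window cell structure per (roi, measure).
    """
    required = {"subject", "window", "roi", "measure", "beta"}
    if not required.issubset(effects.columns):
        raise ValueError(f"effects table needs columns {sorted(required)}")
    anova_rows, posthoc_rows = [], []
    for (roi, measure), grp in effects.groupby(["roi", "measure"]):
        wide = grp.pivot(index="subject", columns="window", values="beta")
        if wide.isna().any().any():
            raise ValueError(f"missing cells for roi={roi}, measure={measure}")
        F, (df1, df2), p = rm_anova_window(wide.to_numpy())
        anova_rows.append(
            {"roi": roi, "measure": measure, "F": F, "df1": df1, "df2": df2, "p": p}
        )
        windows = sorted(wide.columns)
        lo, hi = windows[0], windows[-1]
        d = wide[hi] - wide[lo]
        if np.std(d, ddof=1) > 0:
            t, df, tp = posthoc_paired_t(wide[hi].to_numpy(), wide[lo].to_numpy())
            posthoc_rows.append(
                {
                    "roi": roi,
                    "measure": measure,
                    "window_pair": f"{hi}-{lo}",
                    "t": t,
                    "df": df,
                    "p": tp,
                }
            )
    anova = pd.DataFrame(anova_rows)
    reject, p_adj = bh_fdr(anova["p"].to_numpy(), q=q)
    anova["p_fdr"] = p_adj
    anova["significant_fdr"] = reject
    return GroupResult(effects=effects, anova=anova, posthoc=pd.DataFrame(posthoc_rows))
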