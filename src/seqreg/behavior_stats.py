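"""Group-level behavioral statistics over the randomness series.

Covers the cross-window correlation structure of each measure (how similar
a measure is when estimated at different timescales), Fisher z transforms,
the nonparametric repeated-measures tests used at the group level
(Friedman, one-sample Wilcoxon signed-rank), and the within-subject GLM of
single-trial response time on TE/SE/SUP.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .info_measures import MEASURES
from .sequence_sim import Session


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Fisher z transform atanh(r); requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("|r| must be < 1 for the Fisher z transform")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def pearson_on_valid(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r over indices where both series are finite."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 3:
        raise ValueError(f"only {int(mask.sum())} overlapping valid trials (< 3)")
    xv, yv = x[mask], y[mask]
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ValueError("zero-variance series; correlation undefined")
    return float(np.corrcoef(xv, yv)[0, 1])


@dataclass
class CorrelationPanel:
    """Per-subject cross-window Pearson matrices for one measure.

    ``matrices`` has shape (n_subjects, k, k) over the window grid; the
    diagonal is exactly 1.  ``fisher_z`` transforms the off-diagonal
    entries (diagonal left NaN, since atanh(1) diverges); ``group_mean``
    averages the raw matrices across subjects.
    """

    measure: str
    windows: tuple[int, ...]
    matrices: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.windows)
        if self.matrices.shape[1:] != (k, k):
            raise ValueError("matrix shape does not match window grid")

    @property
    def group_mean(self) -> np.ndarray:
        return self.matrices.mean(axis=0)

    @property
    def fisher_z(self) -> np.ndarray:
        out = np.full_like(self.matrices, np.nan)
        off = ~np.eye(len(self.windows), dtype=bool)
        out[:, off] = np.arctanh(self.matrices[:, off])
        return out


def cross_window_correlations(
    series_by_window: Mapping[int, pd.DataFrame], measure: str
) -> np.ndarray:
    """Pairwise Pearson r of one subject's measure across window lengths.

    Only trials valid under *both* window lengths enter each pairwise
    correlation (early trials lack values at the larger window).
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}")
    windows = sorted(series_by_window)
    k = len(windows)
    mat = np.eye(k)
    cols = {n: series_by_window[n][measure].to_numpy(float) for n in windows}
    lengths = {len(v) for v in cols.values()}
    if len(lengths) != 1:
        raise ValueError("series do not share a trial index set")
    for i in range(k):
        for j in range(i + 1, k):
            r = pearson_on_valid(cols[windows[i]], cols[windows[j]])
            mat[i, j] = mat[j, i] = r
    return mat


def correlation_panel(
    per_subject_series: Sequence[Mapping[int, pd.DataFrame]], measure: str
) -> CorrelationPanel:
    """Stack per-subject cross-window matrices into a group panel."""
    windows = tuple(sorted(per_subject_series[0]))
    mats = np.stack(
        [cross_window_correlations(s, measure) for s in per_subject_series]
    )
    return CorrelationPanel(measure=measure, windows=windows, matrices=mats)


def between_measure_correlations(
    series_by_window: Mapping[int, pd.DataFrame], pair: tuple[str, str]
) -> dict[int, float]:
    """Per-window Pearson r between two measures for one subject."""
    a, b = pair
    return {
        n: pearson_on_valid(tab[a].to_numpy(float), tab[b].to_numpy(float))
        for n, tab in sorted(series_by_window.items())
    }


def friedman_test(table: np.ndarray | pd.DataFrame) -> tuple[float, float]:
    """Friedman rank test over a subjects x conditions table.

    Average ranks are used for ties.  A fully tied table (every subject's
    row constant) has no rank variation at all; it is returned as
    statistic 0, p 1 rather than the 0/0 the tie-corrected formula gives.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need a 2-D table with >= 2 subjects and >= 2 conditions")
    if np.isnan(arr).any():
        raise ValueError("missing cells in the Friedman table")
    if all(np.ptp(row) == 0 for row in arr):
        return 0.0, 1.0
    stat, p = scipy.stats.friedmanchisquare(*arr.T)
    return float(stat), float(p)


def wilcoxon_signed_rank(
    values: np.ndarray | Sequence[float], mu: float = 0.0
) -> tuple[float, float]:
    """One-sample two-sided Wilcoxon signed-rank test against location ``mu``.

    Zero differences are dropped.  The exact null distribution is used for
    n <= 25 without ties in |differences|; otherwise the normal
    approximation with tie correction and continuity correction.
    """
    d = np.asarray(values, dtype=float) - mu
    if np.isnan(d).any():
        raise ValueError("missing values")
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("all values equal the null location; test undefined")
    ties = len(np.unique(np.abs(d))) < len(d)
    method = "exact" if (len(d) <= 25 and not ties) else "approx"
    res = scipy.stats.wilcoxon(
        d, alternative="two-sided", method=method, correction=(method == "approx")
    )
    return float(res.statistic), float(res.pvalue)


@dataclass
class RTModelResult:
    """Within-subject RT GLM coefficients and the group-level tests.

    ``coefficients`` is a tidy frame (subject, window, predictor, beta);
    ``group_tests`` holds the across-subject Wilcoxon signed-rank statistic
    and p per predictor and window length.
    """

    coefficients: pd.DataFrame
    group_tests: pd.DataFrame


def _rt_design(session: Session, table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Predictors [1, TE, SE, SUP] and RT for valid, correct task trials."""
    trials = {t.index: t for t in session.task_trials}
    rows, rts = [], []
    for rec in table.itertuples(index=False):
        t = trials[rec.trial_index]
        if not rec.valid or t.error or t.rt is None:
            continue
        rows.append([1.0, rec.TE, rec.SE, rec.SUP])
        rts.append(t.rt)
    return np.asarray(rows, float), np.asarray(rts, float)


def rt_glm_single(
    session: Session, table: pd.DataFrame
) -> dict[str, float]:
    """OLS of single-trial RT on TE, SE and SUP for one subject and window."""
    X, y = _rt_design(session, table)
    if len(y) <= X.shape[1]:
        raise ValueError("too few valid RT trials for the RT GLM")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        corr = np.corrcoef(X[:, 1:].T)
        pairs = [
            (MEASURES[i], MEASURES[j])
            for i in range(3)
            for j in range(i + 1, 3)
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise ValueError(f"rank-deficient RT predictors; collinear pairs: {pairs}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return dict(zip(("intercept", "TE", "SE", "SUP"), map(float, beta)))


def rt_glm(
    sessions: Sequence[Session],
    per_subject_series: Sequence[Mapping[int, pd.DataFrame]],
) -> RTModelResult:
    """Two-level RT analysis: per-subject OLS, then group signed-rank tests."""
    coef_rows = []
    for subj, (session, series) in enumerate(zip(sessions, per_subject_series)):
        for n, table in sorted(series.items()):
            betas = rt_glm_single(session, table)
            for name, b in betas.items():
                coef_rows.append(
                    {"subject": subj, "window": n, "predictor": name, "beta": b}
                )
    coefficients = pd.DataFrame(coef_rows)
    test_rows = []
    for (n, name), grp in coefficients.groupby(["window", "predictor"]):
        if name == "intercept":
            continue
        stat, p = wilcoxon_signed_rank(grp["beta"].to_numpy())
        test_rows.append({"window": n, "predictor": name, "statistic": stat, "p": p})
    return RTModelResult(
        coefficients=coefficients, group_tests=pd.DataFrame(test_rows)
    )


def apply_rt_modulation(
    session: Session,
    table: pd.DataFrame,
    coefs: Mapping[str, float],
) -> Session:
    """Add linear TE/SE/SUP terms to the RTs of valid, correct task trials.

    Utility for power analyses: the generator's RTs are independent of the
    measures by construction, and this injects a known effect afterwards.
    Modifies the session in place and returns it.
    """
    by_index = {rec.trial_index: rec for rec in table.itertuples(index=False)}
    for t in session.task_trials:
        rec = by_index.get(t.index)
        if rec is None or not rec.valid or t.rt is None:
            continue
        t.rt += sum(coefs.get(m, 0.0) * getattr(rec, m) for m in MEASURES)
    return session


def bootstrap_ci(
    values: np.ndarray,
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI over subjects for a group-mean quantity."""
    values = np.asarray(values, float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    means = values[idx].mean(axis=1)
    lo, hi = np.quantile(means, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)
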