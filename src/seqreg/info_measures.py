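"""Sliding-window randomness measures over trial and action sequences.

Three measures are computed from a window of the ``n`` most recent *task*
trials (null trials carry no stimulus and do not advance the window):

* **trial entropy (TE)** — Shannon entropy of the eight task stimuli within
  the window; high TE means the recent stimulus sequence is close to
  uniform, low TE that a few stimuli dominate.
* **selection entropy (SE)** — conditional entropy of the action given the
  stimulus, estimated over the *chosen* trials in the window; it quantifies
  the randomness of voluntary selection after accounting for which chosen
  stimuli occurred.
* **surprise (SUP)** — the self-information ``-log P(stimulus_i)`` of the
  current trial's stimulus under the window's empirical distribution.

Each measure is assigned to the last trial of its window, so a series is
defined for task trials ``i >= n`` (1-based); earlier trials carry an
explicit missing value, never zero.  The default log base is 2 (bits);
correlations and GLM effects downstream are invariant to the base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .sequence_sim import (
    ACTIONS,
    CHOSEN_STIMULI,
    TASK_STIMULI,
    Session,
    Trial,
)

MEASURES = ("TE", "SE", "SUP")
DEFAULT_WINDOWS = (25, 30, 35, 40, 45, 50)

_STIM_INDEX = {s: i for i, s in enumerate(TASK_STIMULI)}
_CHOSEN_INDEX = {s: i for i, s in enumerate(CHOSEN_STIMULI)}


def _log(x: np.ndarray | float, base: float) -> np.ndarray | float:
    if base == 2:
        return np.log2(x)
    if base in (np.e, "e"):
        return np.log(x)
    return np.log(x) / np.log(base)


def _xlogx(p: np.ndarray, base: float) -> np.ndarray:
    out = xlogy(p, p)
    if base == 2:
        out = out / np.log(2)
    elif base not in (np.e, "e"):
        out = out / np.log(base)
    return out


@dataclass
class WindowHistogram:
    """Counts of stimuli, and of (chosen stimulus, action) pairs, in a window.

    ``stimulus_counts`` covers all 8 task stimuli over the ``n`` task trials
    of the window; ``joint_counts`` covers the chosen trials only (error
    trials excluded by default, since an error trial has no valid action).
    """

    n: int
    stimulus_counts: dict[str, int]
    joint_counts: dict[tuple[str, int], int]
    n_chosen: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("empty window")
        if sum(self.stimulus_counts.values()) != self.n:
            raise ValueError("stimulus counts do not sum to window length")
        if sum(self.joint_counts.values()) != self.n_chosen:
            raise ValueError("joint counts do not sum to n_chosen")
        if self.n_chosen > self.n:
            raise ValueError("more chosen trials than window trials")

    @classmethod
    def from_trials(
        cls, trials: Sequence[Trial], include_error_actions: bool = False
    ) -> "WindowHistogram":
        """Histogram a window of task trials.

        Error trials always contribute their stimulus (it was displayed);
        their responses enter the joint counts only if
        ``include_error_actions`` is set and an action was recorded.
        """
        stim: dict[str, int] = {}
        joint: dict[tuple[str, int], int] = {}
        n_chosen = 0
        for t in trials:
            if not t.is_task:
                raise ValueError("window may contain task trials only")
            stim[t.stimulus] = stim.get(t.stimulus, 0) + 1
            if t.condition == "chosen" and t.action is not None:
                if include_error_actions or not t.error:
                    joint[(t.stimulus, t.action)] = joint.get((t.stimulus, t.action), 0) + 1
                    n_chosen += 1
        return cls(
            n=len(trials),
            stimulus_counts=stim,
            joint_counts=joint,
            n_chosen=n_chosen,
        )


def trial_entropy(hist: WindowHistogram, base: float = 2) -> float:
    """Shannon entropy of the window's stimulus distribution."""
    counts = np.array(list(hist.stimulus_counts.values()), dtype=float)
    p = counts / hist.n
    return float(-_xlogx(p, base).sum())


def selection_entropy(hist: WindowHistogram, base: float = 2) -> float:
    """Conditional entropy H(action | stimulus) over the window's chosen trials.

    Computed as ``-sum_{k,m} P(m, k) log P(m | k)`` with probabilities
    estimated from the chosen-trial joint counts.
    """
    if hist.n_chosen < 1:
        raise ValueError("window contains no chosen trials")
    joint = np.zeros((4, 4))
    for (stim, action), c in hist.joint_counts.items():
        joint[_CHOSEN_INDEX[stim], ACTIONS.index(action)] = c
    p_joint = joint / hist.n_chosen
    p_stim = p_joint.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_cond = np.where(p_stim > 0, p_joint / np.where(p_stim > 0, p_stim, 1), 0.0)
        terms = xlogy(p_joint, p_cond)
    val = -np.nansum(terms)
    if base == 2:
        val = val / np.log(2)
    elif base not in (np.e, "e"):
        val = val / np.log(base)
    return float(val)


def surprise(hist: WindowHistogram, current_stimulus: str, base: float = 2) -> float:
    """Self-information of the current stimulus under the window distribution."""
    count = hist.stimulus_counts.get(current_stimulus, 0)
    if count < 1:
        raise ValueError(
            f"stimulus {current_stimulus!r} absent from window; the current "
            "trial must be the window's last element"
        )
    return float(-_log(count / hist.n, base))


@dataclass
class RandomnessSeries:
    """Per-task-trial values of one measure at one window length.

    ``values[i]`` (0-based over task trials) is the measure for the window
    ending at task trial ``i``; entries before ``valid_from = n - 1`` are
    NaN.  ``valid`` marks finite, in-window values (SE may additionally be
    NaN in a window without chosen trials).
    """

    measure: str
    window_length: int
    values: np.ndarray
    log_base: float = 2

    @property
    def valid_from(self) -> int:
        return self.window_length - 1

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)

    def __len__(self) -> int:
        return len(self.values)


def window_grid(lengths: Iterable[int] | None = None) -> tuple[int, ...]:
    """Validated grid of window lengths; default 25–50 in steps of 5."""
    if lengths is None:
        return DEFAULT_WINDOWS
    grid = tuple(int(n) for n in lengths)
    if not grid:
        raise ValueError("empty window grid")
    if any(n <= 0 for n in grid):
        raise ValueError("window lengths must be positive")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("window lengths must be strictly increasing")
    return grid


def _task_arrays(
    session: Session, include_error_actions: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-task-trial (stimulus index, one-hot stimulus, one-hot chosen joint)."""
    task = session.task_trials
    m = len(task)
    stim_idx = np.empty(m, dtype=int)
    stim_onehot = np.zeros((m, 8), dtype=np.int64)
    joint_onehot = np.zeros((m, 16), dtype=np.int64)  # 4 chosen stimuli x 4 actions
    for i, t in enumerate(task):
        k = _STIM_INDEX[t.stimulus]
        stim_idx[i] = k
        stim_onehot[i, k] = 1
        if (
            t.condition == "chosen"
            and t.action is not None
            and (include_error_actions or not t.error)
        ):
            joint_onehot[i, _CHOSEN_INDEX[t.stimulus] * 4 + (t.action - 1)] = 1
    return stim_idx, stim_onehot, joint_onehot


def sliding_series(
    session: Session,
    n: int,
    measure: str,
    base: float = 2,
    include_error_actions: bool = False,
) -> RandomnessSeries:
    """One measure for every window of ``n`` consecutive task trials.

    The window slides over task trials only; the value for the window
    ``[i - n + 1, i]`` (1-based task-trial indices) is assigned to trial
    ``i``.  SE is computed for every task trial — chosen or specified —
    from the chosen trials inside its window; a window with no chosen
    trial yields NaN.
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}")
    task = session.task_trials
    m = len(task)
    if m < n:
        raise ValueError(f"session has {m} task trials, fewer than window {n}")

    stim_idx, stim_onehot, joint_onehot = _task_arrays(session, include_error_actions)

    # windowed counts via cumulative sums: counts[i] covers task trials
    # [i - n + 1, i] for i >= n - 1 (0-based)
    cum_stim = np.vstack([np.zeros((1, 8), dtype=np.int64), np.cumsum(stim_onehot, 0)])
    win_stim = cum_stim[n:] - cum_stim[:-n]  # (m - n + 1, 8)

    values = np.full(m, np.nan)
    if measure == "TE":
        p = win_stim / n
        values[n - 1 :] = -_xlogx(p, base).sum(axis=1)
    elif measure == "SUP":
        ends = np.arange(n - 1, m)
        counts = win_stim[np.arange(len(ends)), stim_idx[ends]]
        values[n - 1 :] = -_log(counts / n, base)
    else:  # SE
        cum_joint = np.vstack(
            [np.zeros((1, 16), dtype=np.int64), np.cumsum(joint_onehot, 0)]
        )
        win_joint = (cum_joint[n:] - cum_joint[:-n]).reshape(-1, 4, 4).astype(float)
        n_chosen = win_joint.sum(axis=(1, 2))
        with np.errstate(divide="ignore", invalid="ignore"):
            p_joint = win_joint / n_chosen[:, None, None]
            p_stim = p_joint.sum(axis=2, keepdims=True)
            p_cond = np.where(p_stim > 0, p_joint / np.where(p_stim > 0, p_stim, 1), 0)
            terms = xlogy(p_joint, p_cond)
        se = -np.nansum(terms, axis=(1, 2))
        if base == 2:
            se = se / np.log(2)
        elif base not in (np.e, "e"):
            se = se / np.log(base)
        se[n_chosen < 1] = np.nan
        values[n - 1 :] = se
    return RandomnessSeries(measure=measure, window_length=n, values=values, log_base=base)


def randomness_table(
    session: Session,
    n: int,
    base: float = 2,
    include_error_actions: bool = False,
) -> pd.DataFrame:
    """TE/SE/SUP series for one window length as a tidy per-task-trial table.

    Columns: ``trial_index`` (position in the full session, so the series
    can be joined back to events), ``task_index`` (0-based position among
    task trials), ``TE``, ``SE``, ``SUP``, ``valid``.
    """
    task = session.task_trials
    out = pd.DataFrame(
        {
            "trial_index": [t.index for t in task],
            "task_index": np.arange(len(task)),
        }
    )
    for measure in MEASURES:
        out[measure] = sliding_series(
            session, n, measure, base, include_error_actions
        ).values
    out["valid"] = out[list(MEASURES)].notna().all(axis=1)
    return out


def series_set(
    session: Session,
    windows: Iterable[int] | None = None,
    base: float = 2,
    include_error_actions: bool = False,
) -> dict[int, pd.DataFrame]:
    """Randomness tables for every window length in the grid."""
    return {
        n: randomness_table(session, n, base, include_error_actions)
        for n in window_grid(windows)
    }


def write_series(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False, float_format="%.12g", na_rep="n/a")
    return path


def read_series(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", na_values=["n/a"])
    frame["valid"] = frame["valid"].astype(bool)
    return frame
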