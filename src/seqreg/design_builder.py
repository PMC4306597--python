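"""First-level fMRI design matrices for the randomness-modulator GLM.

The model for one window length contains, in order: a stimulus-onset
regressor over all correct task trials; a +1/-1 chosen-vs-specified
contrast; the TE, SUP and SE parametric modulators (mean-centred across
the session and, by default, serially Gram–Schmidt orthogonalized in that
order, so shared variance is credited to the earlier regressor); a
response-time nuisance modulator; separate regressors for error trials of
each condition; optional motion covariates; a discrete-cosine high-pass
basis (400 s cutoff); and an intercept.

Event trains are built at a microtime resolution of ``microtime_bins_per_TR``
bins per TR, convolved with a canonical double-gamma HRF, and sampled at
the microtime reference bin of each volume.  Volumes acquired before the
first full sliding window are excluded by row removal (not zeroing), so
degrees of freedom remain correct downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .info_measures import MEASURES
from .sequence_sim import Session, Trial

MODULATOR_ORDER = ("onset", "condition", "TE", "SUP", "SE")


@dataclass(frozen=True)
class HRFSpec:
    """Canonical double-gamma HRF parameters (SPM-style defaults).

    The kernel is the difference of two gamma densities — a peak at
    ``peak_delay`` s and an undershoot at ``undershoot_delay`` s scaled by
    ``1 / peak_to_undershoot_ratio`` — truncated at ``kernel_length`` s and
    normalized to unit sum.
    """

    family: str = "canonical_double_gamma"
    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    peak_to_undershoot_ratio: float = 6.0
    kernel_length: float = 32.0
    microtime_bins_per_TR: int = 16
    microtime_reference: int | None = None  # default: middle bin

    def reference_bin(self) -> int:
        if self.microtime_reference is not None:
            return self.microtime_reference
        return self.microtime_bins_per_TR // 2

    def kernel(self, dt: float) -> np.ndarray:
        """HRF sampled on a grid of spacing ``dt`` seconds, unit sum."""
        t = np.arange(0.0, self.kernel_length, dt)
        peak = scipy.stats.gamma.pdf(
            t, self.peak_delay / self.dispersion, scale=self.dispersion
        )
        under = scipy.stats.gamma.pdf(
            t,
            self.undershoot_delay / self.undershoot_dispersion,
            scale=self.undershoot_dispersion,
        )
        h = peak - under / self.peak_to_undershoot_ratio
        s = h.sum()
        if s <= 0:
            raise ValueError("HRF kernel does not integrate to a positive value")
        return h / s


def build_event_regressor(
    onsets_s: Sequence[float],
    amplitudes: Sequence[float],
    tr: float,
    n_volumes: int,
    hrf: HRFSpec | None = None,
    durations_s: Sequence[float] | float | None = None,
) -> np.ndarray:
    """HRF-convolved regressor for a set of events.

    Events are impulses by default, or boxcars when ``durations_s`` is
    given.  The stick train lives at microtime resolution and the column is
    read out at each volume's reference bin.
    """
    hrf = hrf or HRFSpec()
    onsets = np.asarray(onsets_s, dtype=float)
    amps = np.asarray(amplitudes, dtype=float)
    if onsets.shape != amps.shape:
        raise ValueError("onsets and amplitudes differ in length")
    scan_end = n_volumes * tr
    if np.any(onsets < 0) or np.any(onsets >= scan_end):
        bad = onsets[(onsets < 0) | (onsets >= scan_end)]
        raise ValueError(f"events outside the scan: onsets {bad.tolist()}")
    dt = tr / hrf.microtime_bins_per_TR
    n_bins = n_volumes * hrf.microtime_bins_per_TR
    train = np.zeros(n_bins)
    if durations_s is None:
        bins = np.floor(onsets / dt).astype(int)
        np.add.at(train, bins, amps)
    else:
        durs = np.broadcast_to(np.asarray(durations_s, float), onsets.shape)
        for onset, amp, dur in zip(onsets, amps, durs):
            a = int(np.floor(onset / dt))
            b = min(max(a + 1, int(np.ceil((onset + dur) / dt))), n_bins)
            train[a:b] += amp
    conv = np.convolve(train, hrf.kernel(dt))[:n_bins]
    ref = hrf.reference_bin()
    return conv[ref :: hrf.microtime_bins_per_TR][:n_volumes]


def build_condition_contrast(session: Session) -> tuple[np.ndarray, np.ndarray]:
    """Onsets (s) and +1/-1 amplitudes for correct chosen/specified trials.

    Error trials are excluded here; they are modeled by the dedicated
    error regressors.
    """
    onsets, amps = [], []
    for t in session.task_trials:
        if t.error:
            continue
        if t.condition not in ("chosen", "specified"):
            raise ValueError(f"trial {t.index} has no task condition label")
        onsets.append(t.onset / 1000.0)
        amps.append(1.0 if t.condition == "chosen" else -1.0)
    return np.asarray(onsets), np.asarray(amps)


def serial_orthogonalize(
    columns: np.ndarray, n_protected: int = 0
) -> np.ndarray:
    """Classical Gram–Schmidt residualization of columns in declared order.

    Each column is replaced by its residual after least-squares projection
    onto all (already residualized) columns before it; the first
    ``n_protected`` columns pass through unchanged but still serve as
    projection targets.  A column that is (numerically) zero cannot anchor
    a projection and raises.
    """
    X = np.asarray(columns, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D array with >= 2 columns")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in design columns")
    out = X.copy()
    scale = np.linalg.norm(X, axis=0).max()
    for j in range(X.shape[1]):
        prior = out[:, :j]
        if j >= max(n_protected, 1):
            coef, *_ = np.linalg.lstsq(prior, out[:, j], rcond=None)
            out[:, j] = out[:, j] - prior @ coef
        if np.linalg.norm(out[:, j]) <= 1e-12 * max(scale, 1.0):
            raise ValueError(
                f"column {j} has zero norm after orthogonalization"
            )
    return out


def highpass_dct(n_volumes: int, tr: float, cutoff_s: float = 400.0) -> np.ndarray:
    """Discrete-cosine basis spanning drifts slower than ``1 / cutoff_s`` Hz.

    Returns ``floor(2 * n_volumes * tr / cutoff_s) + 1`` columns: the
    constant (k = 0) plus one cosine per DCT frequency ``k / (2 N TR)``
    below the cutoff.  With a cutoff of at least twice the scan length no
    cosine fits and only the intercept-like column remains.
    """
    if cutoff_s <= 2 * tr:
        raise ValueError("cutoff must exceed twice the TR")
    if n_volumes < 2:
        raise ValueError("need at least two volumes")
    n_basis = int(np.floor(2.0 * n_volumes * tr / cutoff_s)) + 1
    t = np.arange(n_volumes)
    basis = np.column_stack(
        [np.cos(np.pi * k * (2 * t + 1) / (2.0 * n_volumes)) for k in range(n_basis)]
    )
    return basis


@dataclass
class DesignMatrix:
    """Assembled first-level design, restricted to retained volumes.

    ``frame`` holds the retained (post-trim) volume-by-regressor matrix
    with named columns; ``trim_mask`` marks retained volumes on the full
    acquisition grid.  ``provenance`` records the HRF, orthogonalization
    order, filter cutoff and trim range for the JSON sidecar.
    """

    frame: pd.DataFrame
    tr: float
    n_volumes: int
    trim_mask: np.ndarray
    provenance: dict

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy(float)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))

    def write(self, path: str | Path) -> Path:
        """Write the design TSV plus a JSON provenance sidecar."""
        path = Path(path)
        out = self.frame.copy()
        out.insert(0, "volume", self.frame.index.to_numpy())
        out.to_csv(path, sep="\t", index=False, float_format="%.12g")
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps(self.provenance, indent=2, sort_keys=True))
        return path


def read_design(path: str | Path) -> DesignMatrix:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    frame = frame.set_index("volume")
    prov = json.loads(path.with_suffix(".json").read_text())
    n_volumes = int(prov["n_volumes"])
    trim_mask = np.zeros(n_volumes, dtype=bool)
    trim_mask[frame.index.to_numpy()] = True
    return DesignMatrix(
        frame=frame,
        tr=float(prov["tr"]),
        n_volumes=n_volumes,
        trim_mask=trim_mask,
        provenance=prov,
    )


def _modulator_amplitudes(
    session: Session, series_table: pd.DataFrame, measure: str
) -> tuple[np.ndarray, np.ndarray]:
    """Onsets and mean-centred amplitudes of one modulator over correct trials.

    Values are centred across the session's valid events; trials before the
    first full window get amplitude 0 (their volumes are trimmed anyway).
    """
    values = dict(
        zip(series_table["trial_index"], series_table[measure].to_numpy(float))
    )
    onsets, amps = [], []
    for t in session.task_trials:
        if t.error:
            continue
        onsets.append(t.onset / 1000.0)
        amps.append(values.get(t.index, np.nan))
    amps = np.asarray(amps)
    finite = np.isfinite(amps)
    amps = np.where(finite, amps - np.nanmean(amps), 0.0)
    return np.asarray(onsets), amps


def assemble_design(
    session: Session,
    series_table: pd.DataFrame,
    tr: float = 2.0,
    n_volumes: int = 1294,
    motion: np.ndarray | pd.DataFrame | None = None,
    hrf: HRFSpec | None = None,
    serial_orth: bool = True,
    hp_cutoff_s: float = 400.0,
    stim_duration_s: float | None = None,
) -> DesignMatrix:
    """Build the full first-level design for one window length.

    ``series_table`` is the per-task-trial randomness table for that window
    (as produced by :func:`seqreg.info_measures.randomness_table`).  With
    ``serial_orth`` the modulator chain onset → condition → TE → SUP → SE is
    Gram–Schmidt residualized in order; without it each column is
    residualized against the onset regressor only.  Volumes before the
    onset of the first task trial with a full window are dropped.
    """
    hrf = hrf or HRFSpec()
    window = int(series_table["task_index"][series_table["valid"]].min()) + 1
    task = session.task_trials
    if len(task) < window:
        raise ValueError("session shorter than the series' window length")

    def conv(onsets, amps):
        return build_event_regressor(
            onsets, amps, tr, n_volumes, hrf, durations_s=stim_duration_s
        )

    correct = [t for t in task if not t.error]
    onset_col = conv([t.onset / 1000 for t in correct], np.ones(len(correct)))
    cond_onsets, cond_amps = build_condition_contrast(session)
    cond_col = conv(cond_onsets, cond_amps)

    mod_cols = {}
    for measure in ("TE", "SUP", "SE"):
        onsets, amps = _modulator_amplitudes(session, series_table, measure)
        mod_cols[measure] = conv(onsets, amps)

    rts = np.array([t.rt if t.rt is not None else np.nan for t in correct])
    rt_amps = np.where(np.isfinite(rts), rts - np.nanmean(rts), 0.0) / 1000.0
    rt_col = conv([t.onset / 1000 for t in correct], rt_amps)

    err_cols = {}
    for cond in ("chosen", "specified"):
        errs = [t for t in task if t.error and t.condition == cond]
        if errs:
            err_cols[f"error_{cond}"] = conv(
                [t.onset / 1000 for t in errs], np.ones(len(errs))
            )

    # trim: drop volumes acquired before the first task trial with a full
    # window of randomness values
    first_valid_onset_s = task[window - 1].onset / 1000.0
    volume_times = np.arange(n_volumes) * tr
    trim_mask = volume_times >= first_valid_onset_s
    if trim_mask.sum() < 2:
        raise ValueError("trimming leaves fewer than two volumes")

    dct = highpass_dct(n_volumes, tr, hp_cutoff_s)

    cols: dict[str, np.ndarray] = {
        "onset": onset_col,
        "condition": cond_col,
        "TE": mod_cols["TE"],
        "SUP": mod_cols["SUP"],
        "SE": mod_cols["SE"],
        "rt": rt_col,
    }
    cols.update(err_cols)
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape != (n_volumes, 6):
            raise ValueError("motion covariates must be n_volumes x 6")
        for i in range(6):
            cols[f"motion_{i + 1}"] = motion[:, i]
    for k in range(1, dct.shape[1]):
        cols[f"dct_{k}"] = dct[:, k]
    cols["intercept"] = np.ones(n_volumes)

    frame = pd.DataFrame(cols).loc[trim_mask]
    frame.index = np.flatnonzero(trim_mask)

    # an error regressor whose only events precede the trim has no support
    # on the retained volumes; keep it out rather than leave a zero column
    for name in list(err_cols):
        if np.linalg.norm(frame[name]) <= 1e-10:
            frame = frame.drop(columns=name)

    # centre modulator and RT columns over retained volumes (innocuous given
    # the intercept; makes the modulator betas directly interpretable)
    for name in ("TE", "SUP", "SE", "rt"):
        frame[name] = frame[name] - frame[name].mean()

    # the intercept heads the chain as a protected projection target, so the
    # residualized modulators stay exactly mean-zero over retained volumes
    chain = ["intercept", *MODULATOR_ORDER]
    X_chain = frame[chain].to_numpy()
    if serial_orth:
        frame[chain] = serial_orthogonalize(X_chain, n_protected=2)
    else:
        # variant: modulators residualized against the onset regressor only
        base = X_chain[:, :2]  # intercept + onset
        for j, name in enumerate(chain[2:], start=2):
            coef, *_ = np.linalg.lstsq(base, X_chain[:, j], rcond=None)
            frame[name] = X_chain[:, j] - (base @ coef)

    prov = {
        "tr": tr,
        "n_volumes": n_volumes,
        "window_length": window,
        "hrf": asdict(hrf),
        "serial_orthogonalization": bool(serial_orth),
        "orthogonalization_order": chain,
        "highpass_cutoff_s": hp_cutoff_s,
        "trim_first_retained_volume": int(np.flatnonzero(trim_mask)[0]),
        "columns": list(frame.columns),
    }
    design = DesignMatrix(
        frame=frame,
        tr=tr,
        n_volumes=n_volumes,
        trim_mask=trim_mask,
        provenance=prov,
    )
    if design.condition_number() > 1e6:
        import warnings

        warnings.warn(
            f"design condition number {design.condition_number():.3g} exceeds 1e6",
            stacklevel=2,
        )
    return design


def repetition_labels(session: Session) -> pd.DataFrame:
    """Label each task trial as repeating or switching stimulus and action.

    Comparison is with the previous *task* trial (interleaved null trials
    are transparent).  The first task trial, and trials where either member
    of an action comparison lacks a response, are unlabeled (None).
    """
    task = session.task_trials
    if len(task) < 2:
        raise ValueError("need at least two task trials")
    rows = []
    prev: Trial | None = None
    for t in task:
        stim_label = None
        act_label = None
        if prev is not None:
            stim_label = "repeat" if t.stimulus == prev.stimulus else "switch"
            if t.action is not None and prev.action is not None:
                act_label = "repeat" if t.action == prev.action else "switch"
        rows.append(
            {
                "trial_index": t.index,
                "stim_label": stim_label,
                "act_label": act_label,
            }
        )
        prev = t
    return pd.DataFrame(rows)
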