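"""Synthetic ROI BOLD signals with known ground truth.

The simulator closes the loop for testing: given an assembled design and a
set of true coefficients per ROI, it produces ``y = X beta + drift + noise``
on the retained-volume grid, with white or AR(1) noise.  Ground-truth
presets encode the directions the analysis is built to detect — negative
coupling to the entropies (TE, SE) and positive coupling to surprise
(SUP) — so sign recovery is a meaningful end-to-end check.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.signal

from .design_builder import DesignMatrix, assemble_design, HRFSpec
from .info_measures import randomness_table, window_grid
from .sequence_sim import AgentPolicy, ExperimentConfig, Session, generate_session


@dataclass(frozen=True)
class NoiseModel:
    """Additive noise for simulated BOLD.

    ``sigma`` is the innovation standard deviation; with ``family='ar1'``
    the noise follows x_t = phi x_{t-1} + e_t (stationary start, 100-sample
    burn-in).  ``drift_amplitudes`` optionally adds slow cosines (one per
    amplitude, at the lowest DCT frequencies of the retained grid).
    """

    family: str = "ar1"
    sigma: float = 1.0
    phi: float = 0.3
    drift_amplitudes: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.family not in ("white", "ar1"):
            raise ValueError(f"unknown noise family {self.family!r}")
        if not -1 < self.phi < 1:
            raise ValueError("|phi| must be < 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.sigma == 0:
            noise = np.zeros(n)
        elif self.family == "white":
            noise = rng.normal(0.0, self.sigma, n)
        else:
            burn = 100
            e = rng.normal(0.0, self.sigma, n + burn)
            e[0] /= np.sqrt(1 - self.phi**2)  # stationary start
            noise = scipy.signal.lfilter([1.0], [1.0, -self.phi], e)[burn:]
        if self.drift_amplitudes:
            t = np.arange(n)
            for k, amp in enumerate(self.drift_amplitudes, start=1):
                noise = noise + amp * np.cos(np.pi * k * (2 * t + 1) / (2 * n))
        return noise


@dataclass(frozen=True)
class GroundTruth:
    """True coefficients per ROI: mapping roi -> {column -> beta}.

    Columns not named default to beta 0.  ``gen_window`` is the window
    length whose design generates the signal for each ROI (effects of a
    measure computed at one timescale are then probed by fitting designs at
    every timescale).
    """

    betas: Mapping[str, Mapping[str, float]]
    gen_window: int = 25

    def beta_vector(self, design: DesignMatrix, roi: str) -> np.ndarray:
        table = dict(self.betas[roi])
        unknown = set(table) - set(design.columns)
        if unknown:
            raise ValueError(f"truth names unknown design columns: {sorted(unknown)}")
        return np.array([table.get(c, 0.0) for c in design.columns])


def preset_signs(
    te: float = -0.5, se: float = -0.5, sup: float = 0.5, gen_window: int = 25
) -> GroundTruth:
    """One ROI per measure, with the canonical coupling directions."""
    return GroundTruth(
        betas={
            "roi_te": {"TE": te},
            "roi_se": {"SE": se},
            "roi_sup": {"SUP": sup},
        },
        gen_window=gen_window,
    )


def sigma_for_cnr(design: DesignMatrix, column: str, beta: float, cnr: float) -> float:
    """Innovation sigma giving contrast-to-noise |beta| sd(column) / sigma = cnr."""
    col = design.frame[column].to_numpy()
    return abs(beta) * float(np.std(col)) / cnr


def simulate_roi_bold(
    design: DesignMatrix,
    truth: GroundTruth,
    noise: NoiseModel | Mapping[str, NoiseModel],
    seed: int = 0,
) -> pd.DataFrame:
    """ROI signals on the retained-volume grid: X beta + drift + noise.

    ``noise`` may be one model for all ROIs or a mapping per ROI.
    """
    X = design.matrix
    rng = np.random.default_rng(seed)
    out = {}
    for roi in truth.betas:
        b = truth.beta_vector(design, roi)
        model = noise[roi] if isinstance(noise, Mapping) else noise
        out[roi] = X @ b + model.sample(X.shape[0], rng)
    frame = pd.DataFrame(out, index=design.frame.index)
    return frame


@dataclass
class SubjectBundle:
    """Everything simulated for one subject."""

    subject: int
    session: Session
    series: dict[int, pd.DataFrame]
    designs: dict[int, DesignMatrix]
    roi_ts: pd.DataFrame
    true_betas: dict[str, dict[str, float]]
    seed: int


def simulate_group(
    n_subjects: int = 16,
    config: ExperimentConfig | None = None,
    policy: AgentPolicy | None = None,
    windows: Sequence[int] | None = None,
    truth: GroundTruth | None = None,
    between_subject_sd: float = 0.0,
    noise: NoiseModel | None = None,
    tr: float = 2.0,
    n_volumes: int = 1294,
    hrf: HRFSpec | None = None,
    serial_orth: bool = True,
    target_cnr: float | None = None,
    seed: int = 0,
) -> list[SubjectBundle]:
    """Independent sessions, designs and ROI BOLD for a simulated group.

    Each subject's true betas are drawn from a normal centred on the
    group-level truth with SD ``between_subject_sd``; BOLD is generated
    from the subject's design at ``truth.gen_window``.  With
    ``target_cnr`` set, each ROI's innovation sigma is rescaled so that
    |beta| sd(column) / sigma equals the target for the ROI's largest
    injected modulator coupling (its column of maximal |beta|).
    """
    if n_subjects < 2:
        raise ValueError("need at least two subjects")
    config = config or ExperimentConfig()
    policy = policy or AgentPolicy()
    grid = window_grid(windows)
    truth = truth or preset_signs(gen_window=grid[0])
    noise = noise or NoiseModel()
    if truth.gen_window not in grid:
        raise ValueError(
            f"generating window {truth.gen_window} not in grid {grid}"
        )
    ss = np.random.SeedSequence(seed)
    bundles = []
    for subj, child in enumerate(ss.spawn(n_subjects)):
        s_session, s_beta, s_noise = (
            int(c.generate_state(1)[0] % 2**31) for c in child.spawn(3)
        )
        session = generate_session(config, policy, s_session)
        series = {
            n: randomness_table(session, n) for n in grid
        }
        designs = {
            n: assemble_design(
                session,
                series[n],
                tr=tr,
                n_volumes=n_volumes,
                hrf=hrf,
                serial_orth=serial_orth,
            )
            for n in grid
        }
        beta_rng = np.random.default_rng(s_beta)
        subj_betas = {
            roi: {
                col: float(beta_rng.normal(val, between_subject_sd))
                for col, val in cols.items()
            }
            for roi, cols in truth.betas.items()
        }
        subj_truth = GroundTruth(betas=subj_betas, gen_window=truth.gen_window)
        gen_design = designs[truth.gen_window]
        roi_noise: NoiseModel | dict[str, NoiseModel] = noise
        if target_cnr is not None:
            roi_noise = {}
            for roi, cols in truth.betas.items():
                if not cols:
                    roi_noise[roi] = noise
                    continue
                col, b = max(cols.items(), key=lambda kv: abs(kv[1]))
                sigma = sigma_for_cnr(gen_design, col, b, target_cnr)
                roi_noise[roi] = replace(noise, sigma=sigma)
        roi_ts = simulate_roi_bold(gen_design, subj_truth, roi_noise, seed=s_noise)
        bundles.append(
            SubjectBundle(
                subject=subj,
                session=session,
                series=series,
                designs=designs,
                roi_ts=roi_ts,
                true_betas=subj_betas,
                seed=s_session,
            )
        )
    return bundles


def write_roi_ts(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_roi_ts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
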