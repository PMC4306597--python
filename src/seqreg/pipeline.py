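"""One-command orchestration of the synthetic experiment and analysis.

``run_full_pipeline`` chains the stages — session generation, sliding-window
randomness series, design assembly per window length, ROI BOLD simulation,
first-level GLM fits, behavioral statistics and group window statistics —
writing every intermediate artifact as TSV with fixed float formatting plus
a manifest of configuration, seeds and checksums, so a rerun reproduces
every file byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import behavior_stats, bold_sim, design_builder, glm_engine, info_measures
from .bold_sim import GroundTruth, NoiseModel, SubjectBundle, simulate_group
from .glm_engine import GroupResult, contrast, fit_first_level, group_window_stats
from .info_measures import MEASURES, window_grid
from .sequence_sim import AgentPolicy, ExperimentConfig, write_events

logger = logging.getLogger("seqreg")

FLOAT_FORMAT = "%.12g"


DEFAULT_CONFIG: dict = {
    "n_subjects": 16,
    "seed": 0,
    "windows": list(info_measures.DEFAULT_WINDOWS),
    "tr": 2.0,
    "n_volumes": 1294,
    "serial_orth": True,
    "whitening": "none",
    "experiment": {},  # ExperimentConfig overrides
    "policy": {},  # AgentPolicy overrides
    "truth": {
        "gen_window": 25,
        "betas": {"roi_te": {"TE": -0.5}, "roi_se": {"SE": -0.5}, "roi_sup": {"SUP": 0.5}},
    },
    "noise": {"family": "ar1", "sigma": 1.0, "phi": 0.3},
    "between_subject_sd": 0.0,
}


def load_config(path: str | Path | None = None, overrides: Mapping | None = None) -> dict:
    """Merge a YAML config file (and/or overrides) over the defaults."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    loaded = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
    for source in (loaded, overrides or {}):
        for key, value in source.items():
            if isinstance(value, Mapping) and isinstance(cfg.get(key), dict):
                cfg[key].update(value)
            else:
                cfg[key] = value
    return cfg


def _experiment(cfg: dict) -> ExperimentConfig:
    return ExperimentConfig(**cfg.get("experiment", {}))


def _policy(cfg: dict) -> AgentPolicy:
    pol = dict(cfg.get("policy", {}))
    if "action_weights" in pol and pol["action_weights"] is not None:
        pol["action_weights"] = tuple(pol["action_weights"])
    return AgentPolicy(**pol)


def _truth(cfg: dict) -> GroundTruth:
    t = cfg["truth"]
    return GroundTruth(betas=t["betas"], gen_window=int(t["gen_window"]))


def _noise(cfg: dict) -> NoiseModel:
    n = dict(cfg["noise"])
    n["drift_amplitudes"] = tuple(n.get("drift_amplitudes", ()))
    return NoiseModel(**n)


def group_effects(
    bundles: Sequence[SubjectBundle],
    columns: Sequence[str] = MEASURES,
    whitening: str = "none",
) -> pd.DataFrame:
    """Fit every subject's designs to their ROI series; tidy effects table.

    ROI rows are aligned to each design's retained volumes by volume index
    (larger windows trim more, so their grids are subsets of the
    generating design's grid).
    """
    rows = []
    for b in bundles:
        for n, design in sorted(b.designs.items()):
            idx = design.frame.index
            missing = idx.difference(b.roi_ts.index)
            if len(missing):
                raise ValueError(
                    f"ROI series lacks volumes {missing[:3].tolist()}... for window {n}"
                )
            fit = fit_first_level(design, b.roi_ts.loc[idx], whitening=whitening)
            for roi in b.roi_ts.columns:
                for col in columns:
                    rows.append(
                        {
                            "subject": b.subject,
                            "window": n,
                            "roi": roi,
                            "measure": col,
                            "beta": float(fit.betas.loc[col, roi]),
                        }
                    )
    return pd.DataFrame(rows)


def null_window_anova_calibration(
    n_replicates: int = 1000,
    n_subjects: int = 4,
    config: ExperimentConfig | None = None,
    windows: Sequence[int] = (25, 50),
    noise: NoiseModel | None = None,
    tr: float = 2.0,
    n_volumes: int = 380,
    measure: str = "TE",
    alpha: float = 0.05,
    pool_size: int | None = None,
    seed: int = 0,
) -> float:
    """Rejection rate of the window rm-ANOVA when all true betas are zero.

    A pool of ``pool_size`` subject sessions and designs is built once
    (default ``3 * n_subjects``); each replicate draws ``n_subjects``
    members from the pool and fresh noise-only BOLD for each (under the
    null the signal is independent of the design, so calibration is over
    noise realizations and design draws), fits every window's design, and
    tests the subject-by-window table of ``measure`` betas.  Returns the
    fraction of replicates with p < ``alpha``; a calibrated test sits near
    ``alpha``.
    """
    config = config or ExperimentConfig(n_trials=300)
    noise = noise or NoiseModel()
    grid = info_measures.window_grid(windows)
    pool_size = pool_size or 3 * n_subjects
    ss = np.random.SeedSequence(seed)
    subj_seeds = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(pool_size)]
    noise_rng = np.random.default_rng(int(ss.generate_state(1)[0] % 2**31))

    # precompute, per subject and window, the row extracting the measure's
    # beta from the pseudoinverse, aligned to the full volume grid
    extractors: list[list[tuple[np.ndarray, np.ndarray]]] = []
    from .info_measures import randomness_table
    from .design_builder import assemble_design

    for s in subj_seeds:
        from .sequence_sim import generate_session

        session = generate_session(config, None, s)
        rows = []
        for n in grid:
            design = assemble_design(
                session, randomness_table(session, n), tr=tr, n_volumes=n_volumes
            )
            pinv = np.linalg.pinv(design.matrix)
            rows.append((design.frame.index.to_numpy(), pinv[design.columns.index(measure)]))
        extractors.append(rows)

    rejections = 0
    for _ in range(n_replicates):
        members = noise_rng.choice(pool_size, size=n_subjects, replace=False)
        table = np.empty((n_subjects, len(grid)))
        for i, member in enumerate(members):
            y = noise.sample(n_volumes, noise_rng)
            for j, (idx, extractor) in enumerate(extractors[member]):
                table[i, j] = extractor @ y[idx]
        _, _, p = glm_engine.rm_anova_window(table)
        rejections += p < alpha
    return rejections / n_replicates


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Provenance of one pipeline run: config, seeds, artifacts, checksums."""

    config: dict
    artifacts: dict[str, str]
    elapsed_s: float

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "config": self.config,
                    "artifacts": self.artifacts,
                    "elapsed_s": round(self.elapsed_s, 3),
                },
                indent=2,
                sort_keys=True,
            )
        )
        return path


def run_full_pipeline(
    config: dict | str | Path | None = None, out_dir: str | Path = "seqreg_out"
) -> RunManifest:
    """Run every stage on synthetic data and write all artifacts.

    Raises with the failing stage named if any stage errors.
    """
    t0 = time.time()
    cfg = config if isinstance(config, dict) else load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def record(name: str, path: Path) -> None:
        artifacts[str(path.relative_to(out))] = _sha256(path)

    stage = "simulate_group"
    try:
        logger.info("stage %s: %d subjects, windows %s", stage, cfg["n_subjects"], cfg["windows"])
        bundles = simulate_group(
            n_subjects=int(cfg["n_subjects"]),
            config=_experiment(cfg),
            policy=_policy(cfg),
            windows=cfg["windows"],
            truth=_truth(cfg),
            between_subject_sd=float(cfg["between_subject_sd"]),
            noise=_noise(cfg),
            tr=float(cfg["tr"]),
            n_volumes=int(cfg["n_volumes"]),
            serial_orth=bool(cfg["serial_orth"]),
            seed=int(cfg["seed"]),
        )

        stage = "write_subject_artifacts"
        for b in bundles:
            subj_dir = out / f"sub-{b.subject:02d}"
            subj_dir.mkdir(exist_ok=True)
            record("events", write_events(b.session, subj_dir / "events.tsv"))
            for n, table in b.series.items():
                p = subj_dir / f"series_n{n}.tsv"
                info_measures.write_series(table, p)
                record("series", p)
            for n, design in b.designs.items():
                p = subj_dir / f"design_n{n}.tsv"
                design.write(p)
                record("design", p)
                record("design_json", p.with_suffix(".json"))
            p = subj_dir / "roi_ts.tsv"
            ts = b.roi_ts.copy()
            ts.insert(0, "volume", ts.index.to_numpy())
            ts.to_csv(p, sep="\t", index=False, float_format=FLOAT_FORMAT)
            record("roi_ts", p)

        stage = "behavior_stats"
        per_subject_series = [b.series for b in bundles]
        sessions = [b.session for b in bundles]
        stats_rows = []
        for measure in MEASURES:
            panel = behavior_stats.correlation_panel(per_subject_series, measure)
            k = len(panel.windows)
            for i in range(k):
                for j in range(i + 1, k):
                    stats_rows.append(
                        {
                            "kind": "cross_window_r",
                            "measure": measure,
                            "window_a": panel.windows[i],
                            "window_b": panel.windows[j],
                            "statistic": panel.group_mean[i, j],
                            "p": np.nan,
                        }
                    )
            z2550 = panel.fisher_z[:, 0, -1]
            stat, p = behavior_stats.wilcoxon_signed_rank(z2550)
            stats_rows.append(
                {
                    "kind": "fisher_z_25_50_signed_rank",
                    "measure": measure,
                    "window_a": panel.windows[0],
                    "window_b": panel.windows[-1],
                    "statistic": stat,
                    "p": p,
                }
            )
        rt_result = behavior_stats.rt_glm(sessions, per_subject_series)
        for rec in rt_result.group_tests.itertuples(index=False):
            stats_rows.append(
                {
                    "kind": "rt_glm_signed_rank",
                    "measure": rec.predictor,
                    "window_a": rec.window,
                    "window_b": np.nan,
                    "statistic": rec.statistic,
                    "p": rec.p,
                }
            )
        behavior = pd.DataFrame(stats_rows)
        p = out / "behavior_stats.tsv"
        behavior.to_csv(p, sep="\t", index=False, float_format=FLOAT_FORMAT)
        record("behavior_stats", p)

        stage = "first_level_and_group"
        effects = group_effects(bundles, whitening=cfg["whitening"])
        p = out / "effects.tsv"
        effects.to_csv(p, sep="\t", index=False, float_format=FLOAT_FORMAT)
        record("effects", p)
        group = group_window_stats(effects)
        p = out / "group_anova.tsv"
        group.anova.to_csv(p, sep="\t", index=False, float_format=FLOAT_FORMAT)
        record("group_anova", p)
        p = out / "group_posthoc.tsv"
        group.posthoc.to_csv(p, sep="\t", index=False, float_format=FLOAT_FORMAT)
        record("group_posthoc", p)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = RunManifest(config=cfg, artifacts=artifacts, elapsed_s=time.time() - t0)
    manifest.write(out / "manifest.json")
    logger.info("pipeline finished in %.1f s, %d artifacts", manifest.elapsed_s, len(artifacts))
    return manifest
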