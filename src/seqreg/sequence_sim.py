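"""Synthetic task sessions for the constrained visuomotor choice paradigm.

The experiment interleaves three trial conditions:

* *chosen* — the stimulus marks three of four fingers as permitted and the
  agent freely selects one of them;
* *specified* — the stimulus instructs exactly one finger;
* *null* — a blank inter-trial period with no stimulus and no response,
  used only to jitter stimulus timing.

A session is a fixed-composition, pseudorandomly ordered sequence of these
trials in which no more than ``max_run_length`` consecutive trials share a
condition, and the stimulus identity of each task trial depends on the
previous response: in each condition, the option (chosen) or instruction
(specified) to repeat the last action is made available in exactly half of
the eligible trials.

Stimuli carry fixed labels: ``a``–``d`` are the four chosen stimuli, each
identified by its single *unfilled* circle (the one non-permitted finger);
``e``–``h`` are the four specified stimuli, each identified by its single
*filled* circle (the instructed finger).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("chosen", "specified", "null")
ACTIONS = (1, 2, 3, 4)
CHOSEN_STIMULI = ("a", "b", "c", "d")
SPECIFIED_STIMULI = ("e", "f", "g", "h")
TASK_STIMULI = CHOSEN_STIMULI + SPECIFIED_STIMULI

#: stimulus label -> the action marked by its distinguishing circle
#: (unfilled = non-permitted for chosen stimuli, filled = instructed for
#: specified stimuli)
STIMULUS_KEY_ACTION = {s: i + 1 for i, s in enumerate(CHOSEN_STIMULI)}
STIMULUS_KEY_ACTION.update({s: i + 1 for i, s in enumerate(SPECIFIED_STIMULI)})


class ConstraintError(RuntimeError):
    """Raised when a sequence constraint cannot be satisfied."""


class EventsParseError(ValueError):
    """Raised when an events table fails validation; names the offending row."""


def permitted_actions(stimulus: str) -> tuple[int, ...]:
    """Set of fingers permitted by a stimulus (3 for chosen, 1 for specified)."""
    if stimulus in CHOSEN_STIMULI:
        forbidden = STIMULUS_KEY_ACTION[stimulus]
        return tuple(a for a in ACTIONS if a != forbidden)
    if stimulus in SPECIFIED_STIMULI:
        return (STIMULUS_KEY_ACTION[stimulus],)
    raise ValueError(f"unknown stimulus {stimulus!r}")


@dataclass(frozen=True)
class ExperimentConfig:
    """Session-level design parameters.

    Defaults reproduce the original design: 1008 trials, half chosen, a
    quarter specified, a quarter null, at most four consecutive trials of
    one condition, 1000 ms stimulus + 1400 ms inter-stimulus interval for
    task trials and 2400 ms null trials.
    """

    n_trials: int = 1008
    prop_chosen: float = 0.50
    prop_specified: float = 0.25
    prop_null: float = 0.25
    max_run_length: int = 4
    stim_duration: float = 1000.0  # ms
    iti_duration: float = 1400.0  # ms
    null_duration: float = 2400.0  # ms
    repeat_available_fraction: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        total = self.prop_chosen + self.prop_specified + self.prop_null
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"condition proportions sum to {total}, not 1")
        if self.max_run_length < 1:
            raise ValueError("max_run_length must be >= 1")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        for name in ("chosen", "specified", "null"):
            count = self.n_trials * getattr(self, f"prop_{name}")
            if abs(count - round(count)) > 1e-9:
                raise ValueError(
                    f"n_trials * prop_{name} = {count} is not an integer"
                )

    @property
    def condition_counts(self) -> dict[str, int]:
        return {
            "chosen": round(self.n_trials * self.prop_chosen),
            "specified": round(self.n_trials * self.prop_specified),
            "null": round(self.n_trials * self.prop_null),
        }

    @property
    def task_trial_duration(self) -> float:
        return self.stim_duration + self.iti_duration


@dataclass(frozen=True)
class AgentPolicy:
    """Response policy of a simulated participant.

    ``uniform`` picks uniformly among permitted actions, ``sticky`` repeats
    the previous response with probability ``stickiness`` whenever it is
    permitted, ``biased`` samples with fixed per-finger weights renormalised
    over the permitted set.  Response times are log-normal with median
    ``rt_median`` ms and log-scale ``rt_sigma``; ``error_rate`` is the
    per-trial probability of an omitted/invalid response.
    """

    kind: str = "uniform"
    stickiness: float = 0.0
    action_weights: tuple[float, float, float, float] | None = None
    rt_median: float = 500.0  # ms
    rt_sigma: float = 0.25
    error_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "sticky", "biased"):
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if self.kind == "biased":
            if self.action_weights is None or len(self.action_weights) != 4:
                raise ValueError("biased policy requires 4 action weights")
            if any(w < 0 for w in self.action_weights):
                raise ValueError("action weights must be nonnegative")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.rt_median <= 0:
            raise ValueError("rt_median must be positive")


@dataclass
class Trial:
    """One trial: condition, stimulus, the agent's response and its timing."""

    index: int
    condition: str
    stimulus: str | None = None
    permitted: tuple[int, ...] = ()
    action: int | None = None
    onset: float = 0.0  # ms from session start
    rt: float | None = None  # ms
    error: bool = False

    @property
    def is_task(self) -> bool:
        return self.condition != "null"


@dataclass
class Session:
    """An ordered, fully realised trial sequence with its provenance."""

    trials: list[Trial]
    config: ExperimentConfig
    policy: AgentPolicy | None = None
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def task_trials(self) -> list[Trial]:
        return [t for t in self.trials if t.is_task]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            rows.append(
                {
                    "onset": t.onset / 1000.0,
                    "duration": (
                        self.config.stim_duration / 1000.0
                        if t.is_task
                        else self.config.null_duration / 1000.0
                    ),
                    "condition": t.condition,
                    "stimulus": t.stimulus if t.stimulus is not None else "n/a",
                    "action": t.action if t.action is not None else "n/a",
                    "rt": t.rt / 1000.0 if t.rt is not None else "n/a",
                    "error": int(t.error),
                }
            )
        return pd.DataFrame(rows)

    def validate(self) -> None:
        """Check the structural invariants of a generated session."""
        counts = {c: 0 for c in CONDITIONS}
        run, run_cond = 0, None
        prev_onset = -np.inf
        for t in self.trials:
            counts[t.condition] += 1
            if t.condition == run_cond:
                run += 1
            else:
                run, run_cond = 1, t.condition
            if run > self.config.max_run_length:
                raise ConstraintError(
                    f"run of {run} {t.condition!r} trials at index {t.index}"
                )
            if t.onset <= prev_onset and t.index > 0:
                raise ValueError(f"non-increasing onset at trial {t.index}")
            prev_onset = t.onset
            if t.is_task and not t.error and t.action is not None:
                if t.action not in t.permitted:
                    raise ValueError(
                        f"action {t.action} not permitted at trial {t.index}"
                    )
        if counts != self.config.condition_counts:
            raise ValueError(
                f"condition counts {counts} do not match config "
                f"{self.config.condition_counts}"
            )


def longest_run(conditions: Sequence[str]) -> int:
    """Length of the longest run of identical consecutive labels."""
    best, run, prev = 0, 0, object()
    for c in conditions:
        run = run + 1 if c == prev else 1
        prev = c
        best = max(best, run)
    return best


def _run_feasible(counts: dict[str, int], max_run: int) -> bool:
    # A multiset can avoid runs longer than L iff the most frequent label
    # fits into the slots created by the others: ceil(m / L) - 1 <= rest.
    total = sum(counts.values())
    m = max(counts.values())
    rest = total - m
    return -(-m // max_run) - 1 <= rest


def generate_condition_order(
    config: ExperimentConfig, seed: int, max_attempts: int = 10_000
) -> list[str]:
    """Pseudorandom condition sequence with the exact condition multiset.

    Conditions are drawn one at a time with probability proportional to
    their remaining counts, excluding any condition that would extend a run
    beyond ``max_run_length``.  A draw that reaches a dead end restarts the
    whole sequence; attempts are bounded, and an infeasible multiset is
    rejected up front.
    """
    counts = config.condition_counts
    if not _run_feasible(counts, config.max_run_length):
        raise ConstraintError(
            f"counts {counts} cannot satisfy max_run_length="
            f"{config.max_run_length}"
        )
    rng = np.random.default_rng(seed)
    labels = list(counts)
    for _ in range(max_attempts):
        remaining = np.array([counts[c] for c in labels], dtype=float)
        out: list[str] = []
        run, run_cond = 0, None
        ok = True
        for _pos in range(config.n_trials):
            weights = remaining.copy()
            if run >= config.max_run_length and run_cond is not None:
                weights[labels.index(run_cond)] = 0.0
            total = weights.sum()
            if total <= 0:
                ok = False
                break
            pick = rng.choice(len(labels), p=weights / total)
            cond = labels[pick]
            remaining[pick] -= 1
            out.append(cond)
            run = run + 1 if cond == run_cond else 1
            run_cond = cond
        if ok:
            return out
    raise ConstraintError(
        f"no valid condition order found in {max_attempts} attempts"
    )


def assign_stimulus(
    condition: str,
    prev_action: int | None,
    repeat_flag: bool | None,
    rng: np.random.Generator,
) -> tuple[str, tuple[int, ...]]:
    """Draw the trial's stimulus given the previous response.

    For a chosen trial, ``repeat_flag`` true means the previous action is
    among the three permitted fingers (equivalently, the unfilled circle is
    *not* the previous action); false forces the unique stimulus whose
    unfilled circle is the previous action.  For a specified trial, true
    forces the unique stimulus instructing the previous action; false draws
    among the other three.  Without a previous action the stimulus is
    uniform over the condition's four stimuli.
    """
    if condition == "null":
        raise ValueError("null trials carry no stimulus")
    pool = CHOSEN_STIMULI if condition == "chosen" else SPECIFIED_STIMULI
    if prev_action is None:
        stim = pool[rng.integers(4)]
    else:
        if repeat_flag is None:
            raise ValueError("repeat_flag required when prev_action exists")
        if condition == "chosen":
            # repeat available <=> unfilled circle != prev_action
            if repeat_flag:
                options = [s for s in pool if STIMULUS_KEY_ACTION[s] != prev_action]
                stim = options[rng.integers(len(options))]
            else:
                stim = pool[prev_action - 1]
        else:
            # repeat instructed <=> filled circle == prev_action
            if repeat_flag:
                stim = pool[prev_action - 1]
            else:
                options = [s for s in pool if STIMULUS_KEY_ACTION[s] != prev_action]
                stim = options[rng.integers(len(options))]
    return stim, permitted_actions(stim)


def make_skeleton(config: ExperimentConfig, seed: int) -> Session:
    """Session with conditions and onsets only (no stimuli or responses)."""
    order = generate_condition_order(config, seed)
    trials: list[Trial] = []
    t_ms = 0.0
    for i, cond in enumerate(order):
        trials.append(Trial(index=i, condition=cond, onset=t_ms))
        t_ms += (
            config.task_trial_duration if cond != "null" else config.null_duration
        )
    return Session(trials=trials, config=config, policy=None, seed=seed)


class _BalancedFlagUrn:
    """Emit repeat flags keeping the true/false counts within one of parity.

    When counts are tied the flag is random; otherwise the lagging side is
    emitted, so |#true - #false| <= 1 holds at every point in the stream.
    """

    def __init__(self, rng: np.random.Generator) -> None:
        self._rng = rng
        self._n_true = 0
        self._n_false = 0

    def draw(self) -> bool:
        if self._n_true > self._n_false:
            flag = False
        elif self._n_false > self._n_true:
            flag = True
        else:
            flag = bool(self._rng.integers(2))
        if flag:
            self._n_true += 1
        else:
            self._n_false += 1
        return flag


def _sample_action(
    policy: AgentPolicy,
    permitted: tuple[int, ...],
    prev_action: int | None,
    rng: np.random.Generator,
) -> int:
    if policy.kind == "sticky" and prev_action in permitted:
        if rng.random() < policy.stickiness:
            return prev_action
        others = [a for a in permitted if a != prev_action]
        return others[rng.integers(len(others))]
    if policy.kind == "biased":
        w = np.array([policy.action_weights[a - 1] for a in permitted], float)
        if w.sum() <= 0:
            w = np.ones(len(permitted))
        return int(rng.choice(permitted, p=w / w.sum()))
    return int(permitted[rng.integers(len(permitted))])


def simulate_agent(skeleton: Session, policy: AgentPolicy, seed: int) -> Session:
    """Fill stimuli, actions, RTs and error flags of a session skeleton.

    Stimulus assignment and behaviour must be interleaved because each
    stimulus depends on the previous response: trials following a null, an
    error, or the session start have no usable previous action and receive a
    uniformly drawn stimulus without consuming a repeat flag.
    """
    ss = np.random.SeedSequence(seed)
    stim_rng, act_rng, rt_rng, err_rng, urn_rng = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    urns = {
        "chosen": _BalancedFlagUrn(urn_rng),
        "specified": _BalancedFlagUrn(urn_rng),
    }
    trials: list[Trial] = []
    prev_action: int | None = None
    for t in skeleton.trials:
        new = dataclasses.replace(t)
        if not new.is_task:
            new.stimulus, new.permitted = None, ()
            new.action, new.rt, new.error = None, None, False
            trials.append(new)
            continue  # nulls do not reset the previous response
        if new.stimulus is None:
            flag = urns[new.condition].draw() if prev_action is not None else None
            new.stimulus, new.permitted = assign_stimulus(
                new.condition, prev_action, flag, stim_rng
            )
        else:
            new.permitted = permitted_actions(new.stimulus)
        new.error = bool(err_rng.random() < policy.error_rate)
        if new.error:
            new.action, new.rt = None, None
            prev_action = None
        else:
            if new.condition == "specified":
                new.action = new.permitted[0]
            else:
                new.action = _sample_action(policy, new.permitted, prev_action, act_rng)
            # response-box resolution: whole milliseconds (also makes the
            # seconds-valued events TSV round-trip exactly)
            new.rt = float(
                np.round(rt_rng.lognormal(np.log(policy.rt_median), policy.rt_sigma))
            )
            prev_action = new.action
        trials.append(new)
    return Session(trials=trials, config=skeleton.config, policy=policy, seed=seed)


def generate_session(
    config: ExperimentConfig | None = None,
    policy: AgentPolicy | None = None,
    seed: int = 0,
) -> Session:
    """End-to-end session generation: order, stimuli, behaviour."""
    config = config if config is not None else ExperimentConfig()
    policy = policy if policy is not None else AgentPolicy()
    ss = np.random.SeedSequence(seed)
    order_seed, agent_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
    skeleton = make_skeleton(config, order_seed)
    session = simulate_agent(skeleton, policy, agent_seed)
    session.seed = seed
    return session


def repeat_flags(session: Session) -> pd.DataFrame:
    """Recover the per-trial repeat availability from a realised session.

    Returns one row per task trial with a preceding response, with columns
    ``condition`` and ``repeat`` (whether the previous action was available
    / instructed again).  Useful for checking the half/half design balance.
    """
    rows = []
    prev_action: int | None = None
    for t in session.trials:
        if not t.is_task:
            continue
        if prev_action is not None:
            rows.append(
                {
                    "index": t.index,
                    "condition": t.condition,
                    "repeat": prev_action in t.permitted
                    if t.condition == "chosen"
                    else t.permitted[0] == prev_action,
                }
            )
        prev_action = t.action if (not t.error and t.action is not None) else None
    return pd.DataFrame(rows, columns=["index", "condition", "repeat"])


# ---------------------------------------------------------------------------
# events TSV round trip (BIDS-style: onset/duration in seconds, n/a missing)
# ---------------------------------------------------------------------------

EVENTS_COLUMNS = ("onset", "duration", "condition", "stimulus", "action", "rt", "error")


def write_events(session: Session, path: str | Path) -> Path:
    """Write the session as a BIDS-style events TSV (times in seconds)."""
    path = Path(path)
    frame = session.to_frame()
    with path.open("w") as fh:
        fh.write("\t".join(EVENTS_COLUMNS) + "\n")
        for _, row in frame.iterrows():
            rt = row["rt"]
            fh.write(
                "\t".join(
                    [
                        f"{row['onset']:.4f}",
                        f"{row['duration']:.4f}",
                        str(row["condition"]),
                        str(row["stimulus"]),
                        str(row["action"]),
                        rt if isinstance(rt, str) else f"{rt:.6f}",
                        str(int(row["error"])),
                    ]
                )
                + "\n"
            )
    return path


def read_events(path: str | Path, config: ExperimentConfig | None = None) -> Session:
    """Parse an events TSV back into a :class:`Session`.

    Validation failures report the 1-based data row number.  If no config is
    given, one is reconstructed from the observed composition (durations from
    the first rows of each kind; proportions from the counts).
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in EVENTS_COLUMNS if c not in frame.columns]
    if missing:
        raise EventsParseError(f"{path}: missing columns {missing}")

    trials: list[Trial] = []
    prev_onset = -np.inf
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        cond = row.condition
        if cond not in CONDITIONS:
            raise EventsParseError(f"{path} row {i}: unknown condition {cond!r}")
        try:
            onset = float(row.onset)
            duration = float(row.duration)
        except ValueError as exc:
            raise EventsParseError(f"{path} row {i}: bad number ({exc})") from exc
        if onset <= prev_onset:
            raise EventsParseError(
                f"{path} row {i}: onset {onset} not greater than previous"
            )
        prev_onset = onset
        stimulus = None if row.stimulus == "n/a" else row.stimulus
        if stimulus is not None and stimulus not in TASK_STIMULI:
            raise EventsParseError(f"{path} row {i}: unknown stimulus {stimulus!r}")
        if cond == "null" and stimulus is not None:
            raise EventsParseError(f"{path} row {i}: null trial with stimulus")
        action = None if row.action == "n/a" else int(row.action)
        # snap seconds back onto the millisecond grid the session was
        # generated on, so write -> read is field-exact
        rt = None if row.rt == "n/a" else round(float(row.rt) * 1000.0, 6)
        error = row.error not in ("0", "false", "False")
        trials.append(
            Trial(
                index=i - 1,
                condition=cond,
                stimulus=stimulus,
                permitted=permitted_actions(stimulus) if stimulus else (),
                action=action,
                onset=round(onset * 1000.0, 6),
                rt=rt,
                error=error,
            )
        )

    if config is None:
        n = len(trials)
        counts = {c: sum(t.condition == c for t in trials) for c in CONDITIONS}
        task = [t for t in trials if t.is_task]
        stim_ms = float(frame.loc[frame.condition != "null", "duration"].astype(float).iloc[0]) * 1000 if task else 1000.0
        nulls = frame.condition == "null"
        null_ms = float(frame.loc[nulls, "duration"].astype(float).iloc[0]) * 1000 if nulls.any() else 2400.0
        gaps = np.diff([t.onset for t in trials])
        task_gap = None
        for t, gap in zip(trials[:-1], gaps):
            if t.is_task:
                task_gap = gap
                break
        iti_ms = (task_gap - stim_ms) if task_gap is not None else 1400.0
        config = ExperimentConfig(
            n_trials=n,
            prop_chosen=counts["chosen"] / n,
            prop_specified=counts["specified"] / n,
            prop_null=counts["null"] / n,
            max_run_length=max(longest_run([t.condition for t in trials]), 1),
            stim_duration=stim_ms,
            iti_duration=iti_ms,
            null_duration=null_ms,
        )
    return Session(trials=trials, config=config)
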