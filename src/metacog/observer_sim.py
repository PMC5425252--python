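"""Generative model of the global-motion confidence task.

Simulates synthetic cohorts with the statistical structure of a
two-alternative global-motion discrimination experiment with trial-wise
confidence ratings:

* stimuli are noisy dot clouds whose mean direction (left/right of
  vertical) carries the signal and whose angular standard deviation sets
  the variance condition;
* task difficulty is controlled online by a two-consecutive-correct-down /
  one-error-up adaptive staircase on the mean orientation, whose fixed
  point is sqrt(0.5) ~ 70.7% accuracy;
* responses come from a two-stage signal-detection observer: a first-order
  Gaussian evidence variable drives the left/right choice, and a
  second-order copy of that evidence, corrupted by additional
  "metacognitive" noise, drives the confidence rating.

The metacognitive-noise parameter ``sigma_meta`` is the handle that
emulates a pharmacological manipulation of metacognition: lowering it
tightens the coupling between confidence and accuracy (higher AUROC2)
without touching first-order accuracy, which the staircase pins near 71%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StimulusSpec",
    "StaircaseState",
    "ObserverParams",
    "CohortSpec",
    "TRIAL_COLUMNS",
    "sample_dot_directions",
    "staircase_update",
    "simulate_trial",
    "simulate_session",
    "simulate_cohort",
    "write_cohort_csv",
    "default_group_params",
]

#: Canonical column order of a trial table, as written to CSV.
TRIAL_COLUMNS = [
    "subject_id",
    "group",
    "block",
    "trial",
    "variance_condition",
    "mean_orientation_deg",
    "stimulus_direction",
    "response",
    "correct",
    "rt_ms",
    "confidence",
    "confidence_start",
    "confidence_bin",
]

_DIRECTION_SIGN = {"left": -1.0, "right": 1.0}


@dataclass(frozen=True)
class StimulusSpec:
    """One dot-motion stimulus.

    The per-dot motion direction is ``sign(direction) * mean_orientation_deg
    + N(0, direction_sd_deg)`` degrees from vertical (negative = left).
    """

    direction: str
    mean_orientation_deg: float
    direction_sd_deg: float
    n_dots: int = 1100
    duration_ms: float = 250.0

    def __post_init__(self) -> None:
        if self.direction not in _DIRECTION_SIGN:
            raise ValueError(f"direction must be 'left' or 'right', got {self.direction!r}")
        if self.mean_orientation_deg < 0:
            raise ValueError("mean_orientation_deg must be >= 0")
        if self.direction_sd_deg <= 0:
            raise ValueError("direction_sd_deg must be > 0")
        if self.n_dots < 1:
            raise ValueError("n_dots must be >= 1")


@dataclass(frozen=True)
class StaircaseState:
    """State of one adaptive staircase track.

    ``n_correct_pending`` counts consecutive correct responses since the
    last level change (0 or 1): two in a row lower the level (harder), a
    single error raises it (easier).
    """

    level_deg: float
    n_correct_pending: int = 0
    step_deg: float = 0.5
    floor_deg: float = 0.1
    ceiling_deg: float = 45.0

    def __post_init__(self) -> None:
        if not (self.floor_deg <= self.level_deg <= self.ceiling_deg):
            raise ValueError("level_deg must lie within [floor_deg, ceiling_deg]")
        if self.n_correct_pending not in (0, 1):
            raise ValueError("n_correct_pending must be 0 or 1")
        if self.step_deg <= 0:
            raise ValueError("step_deg must be > 0")


@dataclass(frozen=True)
class ObserverParams:
    """Two-stage signal-detection observer.

    First-order evidence on a trial with signed mean orientation ``s*m``
    (s = +/-1) under variance condition ``v`` is

        x ~ Normal(s * k_signal * m * variance_penalty[v], sigma_perc)

    and the choice is right iff x > 0.  The confidence stage sees a noisy
    copy ``x2 = x + Normal(0, sigma_meta)`` and reports

        confidence = logistic(conf_gain * (|x2| - conf_center))

    so ``sigma_meta`` degrades metacognition without affecting accuracy,
    and ``conf_gain = 0`` yields a constant rating at the squashing
    midpoint.  Response times follow a shifted lognormal; with probability
    ``p_fast`` an anticipatory response (< 100 ms) is emitted, and with
    probability ``p_miss`` the response is missing/late.
    """

    sigma_perc: float = 1.0
    k_signal: float = 0.08
    variance_penalty: Mapping[float, float] = field(
        default_factory=lambda: {20.0: 1.0, 30.0: 0.75}
    )
    sigma_meta: float = 0.8
    conf_gain: float = 1.0
    conf_center: float = 0.0
    p_miss: float = 0.02
    p_fast: float = 0.01
    rt_location_ms: float = 300.0
    rt_scale_ms: float = 250.0
    rt_sigma: float = 0.5

    def __post_init__(self) -> None:
        if self.sigma_perc <= 0:
            raise ValueError("sigma_perc must be > 0")
        if self.sigma_meta < 0:
            raise ValueError("sigma_meta must be >= 0")
        for p, label in ((self.p_miss, "p_miss"), (self.p_fast, "p_fast")):
            if not 0 <= p:
                raise ValueError(f"{label} must be >= 0")
        if self.p_miss + self.p_fast >= 1:
            raise ValueError("p_miss + p_fast must be < 1")

    def penalty(self, variance_condition: float) -> float:
        return float(self.variance_penalty.get(float(variance_condition), 1.0))


def default_group_params() -> dict[str, ObserverParams]:
    """Observer parameters per drug group.

    The noradrenergic-blockade group is modelled purely as a reduction of
    metacognitive noise; the dopaminergic group is identical to placebo.
    """
    return {
        "placebo": ObserverParams(),
        "propranolol": ObserverParams(sigma_meta=0.25),
        "amisulpride": ObserverParams(),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Design of a simulated cohort (groups x subjects x trials)."""

    n_per_group: int = 20
    group_params: Mapping[str, ObserverParams] = field(default_factory=default_group_params)
    n_trials: int = 144
    n_blocks: int = 4
    variance_conditions: Sequence[float] = (20.0, 30.0)
    start_level_deg: float = 10.0
    step_deg: float = 0.5
    floor_deg: float = 0.1
    ceiling_deg: float = 45.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        n_cond = len(self.variance_conditions)
        if len(set(self.variance_conditions)) != n_cond:
            raise ValueError("variance_conditions must be distinct")
        if self.n_trials % self.n_blocks or self.n_trials % n_cond:
            raise ValueError(
                "n_trials must be divisible by n_blocks and by the number "
                "of variance conditions"
            )
        if (self.n_trials // self.n_blocks) % n_cond:
            raise ValueError("each block must hold an equal count of every variance condition")
        if not isinstance(self.group_params, Mapping):
            # sequence of (name, params) pairs; reject duplicate names
            pairs = list(self.group_params)
            names = [g for g, _ in pairs]
            if len(set(names)) != len(names):
                raise ValueError("duplicate group names")
            object.__setattr__(self, "group_params", dict(pairs))

    def initial_staircase(self) -> StaircaseState:
        return StaircaseState(
            level_deg=self.start_level_deg,
            step_deg=self.step_deg,
            floor_deg=self.floor_deg,
            ceiling_deg=self.ceiling_deg,
        )


def sample_dot_directions(spec: StimulusSpec, rng_seed) -> np.ndarray:
    """Per-dot signed directions (degrees from vertical) for one stimulus.

    Each dot moves at ``sign * mean + N(0, sd)`` where sign is -1 for a
    left stimulus and +1 for a right one; every dot is a signal dot and
    the angular SD alone sets the variance condition.
    """
    rng = np.random.default_rng(rng_seed)
    sign = _DIRECTION_SIGN[spec.direction]
    return sign * spec.mean_orientation_deg + rng.normal(
        0.0, spec.direction_sd_deg, size=spec.n_dots
    )


def staircase_update(state: StaircaseState, correct: bool) -> StaircaseState:
    """Advance the two-consecutive-correct-down / one-error-up staircase.

    An error immediately raises the level by one step (easier); a correct
    response only lowers it (harder) when it is the second in a row.  The
    level is clamped to [floor, ceiling].  The rule's asymptotic fixed
    point is the accuracy p with p^2 = 0.5, i.e. ~70.7%.
    """
    if correct:
        if state.n_correct_pending == 0:
            return replace(state, n_correct_pending=1)
        new_level = max(state.floor_deg, state.level_deg - state.step_deg)
    else:
        new_level = min(state.ceiling_deg, state.level_deg + state.step_deg)
    return replace(state, level_deg=new_level, n_correct_pending=0)


def _confidence(observer: ObserverParams, x2_abs: np.ndarray) -> np.ndarray:
    z = observer.conf_gain * (x2_abs - observer.conf_center)
    return 1.0 / (1.0 + np.exp(-z))


def simulate_trial(
    observer: ObserverParams,
    spec: StimulusSpec,
    state: StaircaseState,
    rng_seed,
) -> dict:
    """Simulate a single trial; returns a TrialRecord-shaped dict.

    The record carries no block/subject bookkeeping (the session
    simulator adds those).  The staircase state is read, not advanced;
    callers apply :func:`staircase_update` with the returned ``correct``.
    """
    rng = np.random.default_rng(rng_seed)
    sign = _DIRECTION_SIGN[spec.direction]
    mu = sign * observer.k_signal * spec.mean_orientation_deg * observer.penalty(
        spec.direction_sd_deg
    )
    x = rng.normal(mu, observer.sigma_perc)
    x2 = x + (rng.normal(0.0, observer.sigma_meta) if observer.sigma_meta > 0 else 0.0)
    u_event = rng.uniform()
    conf_start = 0.5 + rng.uniform(-0.12, 0.12)

    if u_event < observer.p_miss:
        return {
            "variance_condition": spec.direction_sd_deg,
            "mean_orientation_deg": spec.mean_orientation_deg,
            "stimulus_direction": spec.direction,
            "response": "missing",
            "correct": np.nan,
            "rt_ms": np.nan,
            "confidence": np.nan,
            "confidence_start": conf_start,
        }
    if u_event < observer.p_miss + observer.p_fast:
        rt = rng.uniform(0.0, 100.0)
    else:
        rt = observer.rt_location_ms + observer.rt_scale_ms * math.exp(
            observer.rt_sigma * rng.normal()
        )
        rt = min(max(rt, 100.0), 1499.0)
    response = "right" if x > 0 else "left"
    return {
        "variance_condition": spec.direction_sd_deg,
        "mean_orientation_deg": spec.mean_orientation_deg,
        "stimulus_direction": spec.direction,
        "response": response,
        "correct": float(response == spec.direction),
        "rt_ms": rt,
        "confidence": float(_confidence(observer, np.abs(x2))),
        "confidence_start": conf_start,
    }


def _condition_order(cohort: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Trial-wise variance-condition sequence: equal counts shuffled per block."""
    per_block = cohort.n_trials // cohort.n_blocks
    conds = np.asarray(cohort.variance_conditions, dtype=float)
    per_cond = per_block // len(conds)
    order = []
    for _ in range(cohort.n_blocks):
        block = np.repeat(conds, per_cond)
        rng.shuffle(block)
        order.append(block)
    return np.concatenate(order)


def simulate_session(
    observer: ObserverParams,
    cohort: CohortSpec,
    subject_id: str,
    group: str,
    rng_seed,
) -> pd.DataFrame:
    """Simulate one subject's full session as a trial table.

    Each variance condition runs its own independent staircase; staircase
    state persists across the four contiguous blocks.  All stochastic
    draws come from a single generator seeded with ``rng_seed``, so equal
    seeds give bit-identical tables.
    """
    rng = np.random.default_rng(rng_seed)
    n = cohort.n_trials
    conds = _condition_order(cohort, rng)
    signs = rng.choice([-1.0, 1.0], size=n)
    eps = rng.normal(0.0, observer.sigma_perc, size=n)
    meta_eps = (
        rng.normal(0.0, observer.sigma_meta, size=n)
        if observer.sigma_meta > 0
        else np.zeros(n)
    )
    u_event = rng.uniform(size=n)
    rt_fast = rng.uniform(0.0, 100.0, size=n)
    rt_norm = observer.rt_location_ms + observer.rt_scale_ms * np.exp(
        observer.rt_sigma * rng.normal(size=n)
    )
    rt_norm = np.clip(rt_norm, 100.0, 1499.0)
    conf_start = 0.5 + rng.uniform(-0.12, 0.12, size=n)

    states = {c: cohort.initial_staircase() for c in conds}
    levels = np.empty(n)
    x = np.empty(n)
    correct = np.empty(n)
    missing = u_event < observer.p_miss
    fast = (~missing) & (u_event < observer.p_miss + observer.p_fast)

    for t in range(n):
        c = conds[t]
        st = states[c]
        levels[t] = st.level_deg
        mu = signs[t] * observer.k_signal * st.level_deg * observer.penalty(c)
        x[t] = mu + eps[t]
        correct[t] = float((x[t] > 0) == (signs[t] > 0))
        if not missing[t]:
            # missed trials give no response, hence no staircase step
            states[c] = staircase_update(st, bool(correct[t]))

    conf = _confidence(observer, np.abs(x + meta_eps))
    response = np.where(x > 0, "right", "left").astype(object)
    rt = np.where(fast, rt_fast, rt_norm)

    response[missing] = "missing"
    correct = correct.astype(object)
    correct[missing] = np.nan
    rt[missing] = np.nan
    conf[missing] = np.nan

    per_block = n // cohort.n_blocks
    df = pd.DataFrame(
        {
            "subject_id": subject_id,
            "group": group,
            "block": np.repeat(np.arange(1, cohort.n_blocks + 1), per_block),
            "trial": np.arange(1, n + 1),
            "variance_condition": conds,
            "mean_orientation_deg": levels,
            "stimulus_direction": np.where(signs > 0, "right", "left"),
            "response": response,
            "correct": pd.array(correct, dtype="Float64"),
            "rt_ms": rt,
            "confidence": conf,
            "confidence_start": conf_start,
            "confidence_bin": pd.array([pd.NA] * n, dtype="Int64"),
        }
    )
    return df[TRIAL_COLUMNS]


def subject_seed(master_seed: int, subject_index: int) -> np.random.SeedSequence:
    """Counter-based per-subject seed: stable under cohort growth."""
    return np.random.SeedSequence(master_seed, spawn_key=(subject_index,))


def simulate_cohort(cohort: CohortSpec) -> pd.DataFrame:
    """Simulate every subject in every group into one trial table.

    Subject seeds derive deterministically from ``cohort.seed`` and the
    subject's position in the roster, so adding groups or subjects never
    perturbs previously generated data.
    """
    frames = []
    idx = 0
    for group, params in cohort.group_params.items():
        for j in range(cohort.n_per_group):
            sid = f"{group[:4]}{j + 1:02d}"
            frames.append(
                simulate_session(params, cohort, sid, group, subject_seed(cohort.seed, idx))
            )
            idx += 1
    return pd.concat(frames, ignore_index=True)


def staircase_longrun_accuracy(
    n_trials: int = 12000,
    burn_in: int = 2000,
    observer: ObserverParams | None = None,
    start_level_deg: float = 10.0,
    step_deg: float = 0.5,
    variance_condition: float = 20.0,
    rng_seed=0,
) -> float:
    """Long-run accuracy of an ideal observer driven by the staircase.

    The observer's monotone psychometric function is implicit in the
    evidence model: correct iff the signed first-order evidence matches
    the stimulus.  Returns mean accuracy over the post-burn-in trials;
    the staircase rule's fixed point puts this near sqrt(0.5) ~ 70.7%.
    """
    obs = observer or ObserverParams(p_miss=0.0, p_fast=0.0)
    rng = np.random.default_rng(rng_seed)
    st = StaircaseState(level_deg=start_level_deg, step_deg=step_deg)
    gain = obs.k_signal * obs.penalty(variance_condition)
    eps = rng.normal(0.0, obs.sigma_perc, size=n_trials)
    correct = np.empty(n_trials, dtype=bool)
    for t in range(n_trials):
        correct[t] = gain * st.level_deg + eps[t] > 0
        st = staircase_update(st, bool(correct[t]))
    return float(correct[burn_in:].mean())


def write_cohort_csv(trials: pd.DataFrame, path) -> None:
    """Write a trial table in the canonical CSV dialect (empty = missing)."""
    trials.to_csv(path, index=False, na_rep="")
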