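"""Trial-loop engine: soft-max action selection over the two-object scene.

A trial proceeds as: draw the communicative cue, draw the internal state
(per variant), compute soft-max choice probabilities from the current action
values, sample the action, resolve whether the infant's look landed on the
actor's target (certain for gaze following, a fair coin for random looking),
and apply the delta-rule update. In the default full-information mode both
action values are updated every trial with the shared trial context; in
``selected_only`` mode only the chosen action's value moves.

Randomness: one independent `numpy` PCG64 stream per trajectory, seeded
explicitly. Draw order within a trial is fixed — cue, then state, then
action, then target coin (the coin is consumed even on gaze-follow trials)
— so trajectories are bit-stable across runs and releases.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .model_core import (
    ModelSpec,
    TrialContext,
    UpdateMode,
    Variant,
    draw_cue,
    draw_state,
    modulate_state,
    q_update,
)

__all__ = [
    "Action",
    "QState",
    "TrialRecord",
    "Trajectory",
    "Ensemble",
    "softmax_policy",
    "select_action",
    "run_trial",
    "run_simulation",
    "run_replicates",
]


class Action(str, enum.Enum):
    RANDOM_LOOK = "random_look"
    GAZE_FOLLOW = "gaze_follow"


@dataclasses.dataclass(frozen=True)
class QState:
    """Current action values Q(A) (random looking) and Q(B) (gaze following).

    Both start at zero: each simulated experiment begins with all weights
    set to zero.
    """

    q_random: float = 0.0
    q_follow: float = 0.0
    trial_index: int = 0

    def __post_init__(self) -> None:
        if self.q_random < 0.0 or self.q_follow < 0.0:
            raise ValueError("action values must be >= 0")
        if self.trial_index < 0:
            raise ValueError("trial_index must be >= 0")


@dataclasses.dataclass(frozen=True)
class TrialRecord:
    """Everything one trial produced: context draws, policy, choice, values."""

    trial_index: int
    cue: float
    state: float
    p_random: float
    p_follow: float
    action: Action
    looked_at_target: bool
    q_random_after: float
    q_follow_after: float
    default_state: Optional[float] = None


def softmax_policy(q_random: float, q_follow: float, tau: float) -> tuple[float, float]:
    """Soft-max choice probabilities: p(a) proportional to exp(Q(a)/tau).

    The worthier action gets the higher probability, but the other is still
    chosen with probability weighted by its value estimate. Computed with
    max-subtraction so large Q/tau ratios cannot overflow.
    """
    if not np.isfinite(q_random) or not np.isfinite(q_follow):
        raise ValueError("action values must be finite")
    if not tau > 0.0:
        raise ValueError(f"tau must be > 0, got {tau}")
    m = max(q_random, q_follow)
    er = np.exp((q_random - m) / tau)
    ef = np.exp((q_follow - m) / tau)
    z = er + ef
    return float(er / z), float(ef / z)


def select_action(p_random: float, p_follow: float, rng: np.random.Generator) -> Action:
    """Sample the action from its soft-max probabilities."""
    if not np.isclose(p_random + p_follow, 1.0, atol=1e-9):
        raise ValueError("probabilities must sum to 1")
    u = rng.random()
    return Action.GAZE_FOLLOW if u < p_follow else Action.RANDOM_LOOK


def _draw_context(spec: ModelSpec, rng: np.random.Generator) -> TrialContext:
    cue = draw_cue(spec, rng)
    if spec.variant is Variant.ENHANCEMENT:
        ds = draw_state(spec, rng)
        state = modulate_state(ds, cue, spec.motivation, spec.variant)
        return TrialContext(cue=cue, state=state, default_state=ds)
    if spec.variant is Variant.INDEPENDENT_STATE:
        return TrialContext(cue=cue, state=draw_state(spec, rng))
    return TrialContext(cue=cue, state=1.0)


def run_trial(
    state: QState, spec: ModelSpec, rng: np.random.Generator
) -> tuple[QState, TrialRecord]:
    """Advance the learner by one trial.

    Returns the updated :class:`QState` and a :class:`TrialRecord` of the
    draws, the policy, the sampled action, and the post-update values. The
    gaze outcome ``looked_at_target`` is always true for gaze following and
    a fair coin for random looking (two equally salient objects).
    """
    ctx = _draw_context(spec, rng)
    p_random, p_follow = softmax_policy(state.q_random, state.q_follow, spec.tau)
    action = select_action(p_random, p_follow, rng)
    coin = rng.random()  # consumed every trial to keep the stream layout fixed
    looked_at_target = True if action is Action.GAZE_FOLLOW else bool(coin < 0.5)

    q_r, q_f = state.q_random, state.q_follow
    if spec.update_mode is UpdateMode.BOTH_ACTIONS:
        q_r = q_update(q_r, spec.pr_random, ctx, spec)
        q_f = q_update(q_f, spec.pr_follow, ctx, spec)
    elif action is Action.RANDOM_LOOK:
        q_r = q_update(q_r, spec.pr_random, ctx, spec)
    else:
        q_f = q_update(q_f, spec.pr_follow, ctx, spec)

    record = TrialRecord(
        trial_index=state.trial_index,
        cue=ctx.cue,
        state=ctx.state,
        default_state=ctx.default_state,
        p_random=p_random,
        p_follow=p_follow,
        action=action,
        looked_at_target=looked_at_target,
        q_random_after=q_r,
        q_follow_after=q_f,
    )
    new_state = QState(q_random=q_r, q_follow=q_f, trial_index=state.trial_index + 1)
    return new_state, record


@dataclasses.dataclass(frozen=True)
class Trajectory:
    """One seeded run: per-trial arrays, deterministic given (spec, seed)."""

    spec: ModelSpec
    seed: int
    cue: np.ndarray
    state: np.ndarray
    default_state: Optional[np.ndarray]
    p_random: np.ndarray
    p_follow: np.ndarray
    action: np.ndarray  # bool, True = gaze_follow
    looked_at_target: np.ndarray
    q_random: np.ndarray
    q_follow: np.ndarray

    def __len__(self) -> int:
        return len(self.cue)

    def record(self, i: int) -> TrialRecord:
        """Materialize trial ``i`` as a :class:`TrialRecord`."""
        return TrialRecord(
            trial_index=i,
            cue=float(self.cue[i]),
            state=float(self.state[i]),
            default_state=(
                None if self.default_state is None else float(self.default_state[i])
            ),
            p_random=float(self.p_random[i]),
            p_follow=float(self.p_follow[i]),
            action=Action.GAZE_FOLLOW if self.action[i] else Action.RANDOM_LOOK,
            looked_at_target=bool(self.looked_at_target[i]),
            q_random_after=float(self.q_random[i]),
            q_follow_after=float(self.q_follow[i]),
        )

    def records(self) -> Iterator[TrialRecord]:
        return (self.record(i) for i in range(len(self)))

    def to_dataframe(self) -> pd.DataFrame:
        """Per-trial table with one row per trial."""
        df = pd.DataFrame(
            {
                "trial": np.arange(len(self)),
                "cue": self.cue,
                "default_state": (
                    np.full(len(self), np.nan)
                    if self.default_state is None
                    else self.default_state
                ),
                "state": self.state,
                "q_random": self.q_random,
                "q_follow": self.q_follow,
                "p_random": self.p_random,
                "p_follow": self.p_follow,
                "action": np.where(
                    self.action, Action.GAZE_FOLLOW.value, Action.RANDOM_LOOK.value
                ),
                "looked_at_target": self.looked_at_target,
            }
        )
        return df

    @property
    def terminal(self) -> QState:
        n = len(self)
        if n == 0:
            return QState()
        return QState(
            q_random=float(self.q_random[-1]),
            q_follow=float(self.q_follow[-1]),
            trial_index=n,
        )


def run_simulation(spec: ModelSpec, seed: int) -> Trajectory:
    """Run ``spec.n_trials`` sequential trials from all-zero action values.

    The single code path is :func:`run_trial`; this function only collects
    its outputs into arrays.
    """
    n = spec.n_trials
    rng = np.random.default_rng(seed)
    needs_ds = spec.variant is Variant.ENHANCEMENT
    cue = np.empty(n)
    state_arr = np.empty(n)
    ds_arr = np.empty(n) if needs_ds else None
    p_r = np.empty(n)
    p_f = np.empty(n)
    act = np.empty(n, dtype=bool)
    hit = np.empty(n, dtype=bool)
    q_r = np.empty(n)
    q_f = np.empty(n)

    qstate = QState()
    for i in range(n):
        qstate, rec = run_trial(qstate, spec, rng)
        cue[i] = rec.cue
        state_arr[i] = rec.state
        if needs_ds:
            ds_arr[i] = rec.default_state
        p_r[i] = rec.p_random
        p_f[i] = rec.p_follow
        act[i] = rec.action is Action.GAZE_FOLLOW
        hit[i] = rec.looked_at_target
        q_r[i] = rec.q_random_after
        q_f[i] = rec.q_follow_after

    return Trajectory(
        spec=spec,
        seed=seed,
        cue=cue,
        state=state_arr,
        default_state=ds_arr,
        p_random=p_r,
        p_follow=p_f,
        action=act,
        looked_at_target=hit,
        q_random=q_r,
        q_follow=q_f,
    )


@dataclasses.dataclass(frozen=True)
class Ensemble:
    """Trajectories across seeds plus per-trial cross-seed summaries."""

    spec: ModelSpec
    seeds: tuple[int, ...]
    trajectories: tuple[Trajectory, ...]
    mean_q_follow: np.ndarray
    sd_q_follow: np.ndarray
    mean_q_random: np.ndarray
    sd_q_random: np.ndarray
    mean_p_follow: np.ndarray
    sd_p_follow: np.ndarray

    @property
    def n_seeds(self) -> int:
        return len(self.seeds)

    def terminal_mean_q_follow(self) -> float:
        return float(self.mean_q_follow[-1])

    def terminal_mean_q_random(self) -> float:
        return float(self.mean_q_random[-1])

    def summary_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(len(self.mean_q_follow)),
                "mean_q_follow": self.mean_q_follow,
                "sd_q_follow": self.sd_q_follow,
                "mean_q_random": self.mean_q_random,
                "sd_q_random": self.sd_q_random,
                "mean_p_follow": self.mean_p_follow,
                "sd_p_follow": self.sd_p_follow,
            }
        )


def run_replicates(spec: ModelSpec, seeds: Sequence[int]) -> Ensemble:
    """Independent trajectories, one per seed, with per-trial mean/sd summaries.

    Cross-seed sd uses ddof=1 (sample sd) when more than one seed is given.
    """
    seeds = tuple(int(s) for s in seeds)
    if len(seeds) == 0:
        raise ValueError("at least one seed is required")
    if len(set(seeds)) != len(seeds):
        raise ValueError("duplicate seeds are not allowed")
    trajs = tuple(run_simulation(spec, s) for s in seeds)
    qf = np.stack([t.q_follow for t in trajs])
    qr = np.stack([t.q_random for t in trajs])
    pf = np.stack([t.p_follow for t in trajs])
    ddof = 1 if len(seeds) > 1 else 0
    return Ensemble(
        spec=spec,
        seeds=seeds,
        trajectories=trajs,
        mean_q_follow=qf.mean(axis=0),
        sd_q_follow=qf.std(axis=0, ddof=ddof),
        mean_q_random=qr.mean(axis=0),
        sd_q_random=qr.std(axis=0, ddof=ddof),
        mean_p_follow=pf.mean(axis=0),
        sd_p_follow=pf.std(axis=0, ddof=ddof),
    )
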