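"""Model variants and per-trial update rules for the gaze-following learner.

The learner faces a two-object scene: an actor looks at one of two equally
salient objects, and the infant either follows the actor's gaze (rewarded
with probability ``pr_follow``, default 1 — joint attention always lands on
the target) or looks at one of the objects at random (``pr_random``, default
0.5). Each action carries a behavioral value Q updated by a delta rule whose
target is the *expected* reward ``R * Pr`` — reward is never sampled; the
equations place the probability inside the target.

Four variants differ in how communicative context and the infant's internal
state enter the update:

``baseline``
    plain delta rule, ``Q += alpha * (R*Pr - Q)``.
``cue``
    the other's communicative intent C (uniform on [0.5, 1.5] per trial)
    scales the subjective reward target: ``Q += alpha * (R*Pr*C - Q)``.
``independent_state``
    an attentional state S (normal(0.5, 0.16) clipped to [0, 1]), drawn
    independently of C, scales the learning rate:
    ``Q += alpha * S * (R*Pr*C - Q)``.
``enhancement``
    the cue enhances a default state Ds through a decision tree
    (see :func:`modulate_state`), and a fixed motivation offset M shifts the
    cue: ``Q += alpha * S * (R*Pr*(C+M) - Q)``.
"""

from __future__ import annotations

import enum
import math
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

__all__ = [
    "Variant",
    "UpdateMode",
    "ModelSpec",
    "TrialContext",
    "draw_cue",
    "draw_state",
    "modulate_state",
    "q_update",
]


class Variant(str, enum.Enum):
    """Which update rule governs learning."""

    BASELINE = "baseline"
    CUE = "cue"
    INDEPENDENT_STATE = "independent_state"
    ENHANCEMENT = "enhancement"


class UpdateMode(str, enum.Enum):
    """Whether both action values are updated each trial or only the chosen one."""

    BOTH_ACTIONS = "both_actions"
    SELECTED_ONLY = "selected_only"


class ModelSpec(BaseModel):
    """Full parameterization of one model variant.

    Parameters
    ----------
    variant
        One of :class:`Variant`; selects the update rule.
    alpha
        Learning rate in (0, 1]; caps how much one trial can teach.
    reward_value
        Reward magnitude R.
    pr_follow, pr_random
        Reward probabilities of gaze following and random looking.
    cue_low, cue_high
        Bounds of the uniform distribution of the communicative cue C.
    state_mean, state_sd
        Parameters of the normal distribution of the internal state
        (S or Ds), clipped to [0, 1].
    motivation
        M, a fixed offset added to the cue; nonzero only for the
        ``enhancement`` variant. Negative M models avoidance of
        communication. Must satisfy ``cue_low + motivation >= 0`` so reward
        targets stay nonnegative.
    tau
        Soft-max temperature for action selection.
    n_trials
        Trials per simulation.
    update_mode
        ``both_actions`` (full-information; default) or ``selected_only``.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    variant: Variant = Variant.BASELINE
    alpha: float = 0.005
    reward_value: float = 1.0
    pr_follow: float = 1.0
    pr_random: float = 0.5
    cue_low: float = 0.5
    cue_high: float = 1.5
    state_mean: float = 0.5
    state_sd: float = 0.16
    motivation: float = 0.0
    tau: float = 0.46
    n_trials: int = 2000
    update_mode: UpdateMode = UpdateMode.BOTH_ACTIONS

    @model_validator(mode="after")
    def _check_ranges(self) -> "ModelSpec":
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if not self.tau > 0.0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if not self.cue_low < self.cue_high:
            raise ValueError(
                f"cue_low must be < cue_high, got [{self.cue_low}, {self.cue_high}]"
            )
        for name in ("pr_follow", "pr_random"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.state_sd <= 0.0:
            raise ValueError(f"state_sd must be > 0, got {self.state_sd}")
        if self.n_trials < 0:
            raise ValueError(f"n_trials must be >= 0, got {self.n_trials}")
        if self.motivation != 0.0 and self.variant is not Variant.ENHANCEMENT:
            raise ValueError(
                "motivation != 0 is only defined for the enhancement variant; "
                f"got M={self.motivation} with variant={self.variant.value}"
            )
        if self.cue_low + self.motivation < 0.0:
            raise ValueError(
                "cue_low + motivation must be >= 0 so reward targets stay "
                f"nonnegative; got {self.cue_low} + {self.motivation}"
            )
        if self.reward_value < 0.0:
            raise ValueError(f"reward_value must be >= 0, got {self.reward_value}")
        return self

    @property
    def uses_state_draw(self) -> bool:
        """True when the variant draws an internal state each trial."""
        return self.variant in (Variant.INDEPENDENT_STATE, Variant.ENHANCEMENT)


class TrialContext(BaseModel):
    """One trial's random context: cue, default state, effective state.

    ``default_state`` is defined only for the enhancement variant (it is the
    state before cue enhancement); for baseline and cue variants ``state`` is
    exactly 1, and for independent_state it is the raw clipped-normal draw.
    """

    model_config = ConfigDict(frozen=True)

    cue: float
    state: float
    default_state: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "TrialContext":
        if not (0.0 <= self.state <= 1.0):
            raise ValueError(f"state must be in [0, 1], got {self.state}")
        if self.default_state is not None and not (0.0 <= self.default_state <= 1.0):
            raise ValueError(
                f"default_state must be in [0, 1], got {self.default_state}"
            )
        return self


def draw_cue(spec: ModelSpec, rng: np.random.Generator) -> float:
    """Draw the communicative-intent cue C ~ Uniform(cue_low, cue_high)."""
    return float(rng.uniform(spec.cue_low, spec.cue_high))


def draw_state(spec: ModelSpec, rng: np.random.Generator) -> float:
    """Draw an internal-state value from N(state_mean, state_sd) clipped to [0, 1].

    This is S for the independent_state variant and Ds (the default state
    before cue enhancement) for the enhancement variant. Clipping is
    symmetric about the default mean 0.5, so the mean is preserved and the
    sd shrinks only negligibly (about 0.1% under defaults).
    """
    return float(np.clip(rng.normal(spec.state_mean, spec.state_sd), 0.0, 1.0))


def modulate_state(
    default_state: float,
    cue: float,
    motivation: float = 0.0,
    variant: Variant = Variant.ENHANCEMENT,
) -> float:
    """Apply the cue-enhancement decision tree to a default state.

    With the motivation-shifted cue C' = C + M:

    * C' <= 1 (no or weak communicative signal): the state is not modulated,
      S = Ds.
    * C' > 1: the cue enhances arousal, S = Ds * C', capped at 1 because the
      learning rate alpha already bounds what one trial can teach.

    The boundary C' == 1 is measure-zero and takes the unmodulated branch.

    Raises
    ------
    ValueError
        If called for a variant that has no default-state concept.
    """
    if variant is not Variant.ENHANCEMENT:
        raise ValueError(
            f"modulate_state is defined only for the enhancement variant, got {variant}"
        )
    if not (0.0 <= default_state <= 1.0):
        raise ValueError(f"default_state must be in [0, 1], got {default_state}")
    c_eff = cue + motivation
    if c_eff <= 1.0:
        return default_state
    return min(default_state * c_eff, 1.0)


def update_target(action_pr: float, context: TrialContext, spec: ModelSpec) -> float:
    """Expected-reward target of the delta rule for an action with reward
    probability ``action_pr``.

    baseline: ``R * Pr``; all cue-bearing variants: ``R * Pr * (C + M)``
    (M = 0 except for the enhancement variant). The cue scales the target of
    *both* actions — it is a property of the trial, not of the action; the
    reward probability is the only action-specific factor.
    """
    if spec.variant is Variant.BASELINE:
        target = spec.reward_value * action_pr
    else:
        target = spec.reward_value * action_pr * (context.cue + spec.motivation)
    if target < 0.0:
        raise ValueError(
            f"negative update target {target}; motivation violates its valid range"
        )
    return target


def q_update(
    q: float, action_pr: float, context: TrialContext, spec: ModelSpec
) -> float:
    """One delta-rule step: ``q + alpha * S * (target - q)``.

    S is the effective state multiplier from the trial context (exactly 1
    for baseline and cue variants). The step is a contraction with factor
    ``1 - alpha*S``, so from q = 0 the value stays within
    [0, max attainable target].
    """
    if not math.isfinite(q) or q < 0.0:
        raise ValueError(f"q must be finite and >= 0, got {q}")
    target = update_target(action_pr, context, spec)
    return q + spec.alpha * context.state * (target - q)
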