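"""Synthetic dyad experiment: stimuli, session logs and paired gaze streams.

Reproduces the joint category-judgment design so the full model-data loop is
testable without recorded participants: 12 objects (3 per category x
difficulty cell) in two handle orientations give 24 stimuli per session; a
bot partner responds correctly on Easy objects and always incorrectly on
Hard ones; human-like agents respond by a noisy category rule with a
tunable Hard-object ambiguity; paired pupil-position streams share a smooth
latent trajectory whose mixing weight rho tunes gaze synchrony.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core import (
    CATEGORIES,
    ModelConfig,
    TrialRecord,
    free_energy,
    init_belief,
    update_double_bayes,
    update_single_bayes,
)
from .synchrony import GazeSeries

__all__ = [
    "Stimulus",
    "SessionSpec",
    "build_stimulus_set",
    "order_trials",
    "bot_policy",
    "human_agent",
    "simulate_session",
    "synthesize_gaze_pair",
]

SESSION_TYPES = ("practice", "individual", "bot_pair", "human_pair")


@dataclass(frozen=True)
class Stimulus:
    object_id: str
    category: str            # "Kitchen" or "Garage"
    difficulty: int          # 0 = Easy, 1 = Hard
    handle_side: str         # "left" or "right"


@dataclass(frozen=True)
class SessionSpec:
    """Session layout: type, trial count, the self agent's assigned category."""

    session_type: Literal["practice", "individual", "bot_pair", "human_pair"]
    self_category: str = "Kitchen"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.session_type not in SESSION_TYPES:
            raise ValueError(f"session_type must be one of {SESSION_TYPES}")
        if self.self_category not in CATEGORIES:
            raise ValueError(f"self_category must be one of {CATEGORIES}")

    @property
    def n_trials(self) -> int:
        return 8 if self.session_type == "practice" else 24

    @property
    def partner_category(self) -> str:
        return "Garage" if self.self_category == "Kitchen" else "Kitchen"


def build_stimulus_set(seed: int | None = None) -> list[Stimulus]:
    """The default stimulus set: 3 objects per category x difficulty cell,
    each presented with the handle on either side — 24 stimuli.

    The set is deterministic; ``seed`` is accepted for interface symmetry
    but does not alter it.
    """
    stimuli = []
    for category, prefix in (("Kitchen", "K"), ("Garage", "G")):
        for difficulty, tag in ((0, "E"), (1, "H")):
            for k in range(1, 4):
                object_id = f"{prefix}{tag}{k}"
                for handle_side in ("left", "right"):
                    stimuli.append(Stimulus(object_id, category, difficulty, handle_side))
    return stimuli


def order_trials(stimuli: list[Stimulus], spec: SessionSpec) -> list[Stimulus]:
    """Seeded presentation order with balanced category/difficulty counts.

    Full sessions permute all 24 stimuli (12 per category, 12 per
    difficulty by construction).  Practice sessions draw a balanced subset
    of 8 (2 per category x difficulty cell).
    """
    _check_balanced(stimuli)
    rng = np.random.default_rng(spec.seed)
    if spec.session_type == "practice":
        picked = []
        for category in CATEGORIES:
            for difficulty in (0, 1):
                cell = [s for s in stimuli
                        if s.category == category and s.difficulty == difficulty]
                idx = rng.choice(len(cell), size=2, replace=False)
                picked.extend(cell[i] for i in idx)
        order = rng.permutation(len(picked))
        return [picked[i] for i in order]
    order = rng.permutation(len(stimuli))
    return [stimuli[i] for i in order]


def _check_balanced(stimuli: list[Stimulus]) -> None:
    for category in CATEGORIES:
        for difficulty in (0, 1):
            n = sum(1 for s in stimuli
                    if s.category == category and s.difficulty == difficulty)
            if n != 6:
                raise ValueError(
                    f"unbalanced stimulus set: cell ({category}, {difficulty}) has "
                    f"{n} stimuli, expected 6 (3 objects x 2 handle sides)"
                )


def bot_policy(stimulus: Stimulus, assigned_category: str) -> int:
    """Deterministic bot: correct on Easy, always incorrect on Hard.

    Correct behavior is touching exactly the objects of the bot's assigned
    category; on Hard objects the bot inverts that rule.
    """
    own = stimulus.category == assigned_category
    if stimulus.difficulty == 0:
        return int(own)
    return int(not own)


def human_agent(
    stimulus: Stimulus,
    assigned_category: str,
    rng: np.random.Generator,
    noise: float = 0.05,
    hard_touch_prob: float = 0.5,
) -> int:
    """Table-driven human-like agent.

    Easy objects follow the category rule (touch iff own category) with a
    lapse probability ``noise`` of flipping the response.  Hard objects are
    ambiguous: the agent touches with probability ``hard_touch_prob``
    regardless of the nominal category.
    """
    if not 0.0 <= noise <= 0.5:
        raise ValueError("noise must lie in [0, 0.5]")
    if not 0.0 <= hard_touch_prob <= 1.0:
        raise ValueError("hard_touch_prob must lie in [0, 1]")
    if stimulus.difficulty == 1:
        return int(rng.random() < hard_touch_prob)
    action = int(stimulus.category == assigned_category)
    if rng.random() < noise:
        action = 1 - action
    return action


class _ModelAgent:
    """Active-inference agent wrapping the core model, for coupled dyads."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.belief = init_belief(config)

    def act(self, gamma_t: float) -> int:
        return free_energy(self.belief, gamma_t, self.config).chosen_action

    def observe(self, a_self: int, a_other: int) -> None:
        self.belief = update_single_bayes(self.belief, a_self, a_other)
        self.belief = update_double_bayes(self.belief, a_self, a_other,
                                          self.config.ema_alpha)


def simulate_session(
    spec: SessionSpec,
    noise: float = 0.05,
    hard_touch_prob: float = 0.5,
    rho: float | None = None,
    gaze: bool = True,
    self_agent: Literal["table", "model"] = "table",
    model_config: ModelConfig | None = None,
) -> tuple[list[TrialRecord], dict[int, tuple[GazeSeries, GazeSeries]]]:
    """Simulate one session: trial log plus per-trial paired gaze streams.

    The self agent is either table-driven (noisy category rule) or an
    active-inference agent from the core model; the partner is the
    deterministic bot in ``bot_pair`` sessions and a table-driven agent in
    ``human_pair`` sessions.  When both agents intend to touch, each draws a
    latent reaction time and the earlier touch is recorded (ties go to
    self); only the first touch enters the log, so (a_s, a_p) = (1, 1)
    never appears.

    ``rho`` tunes gaze synchrony; the default emulates the empirical
    ordering (human pairs more synchronous than bot pairs): 0.7 for
    ``human_pair``, 0.2 otherwise.
    """
    rng = np.random.default_rng(spec.seed)
    if rho is None:
        rho = 0.7 if spec.session_type == "human_pair" else 0.2
    stimuli = build_stimulus_set()
    trials = order_trials(stimuli, spec)

    model_agent = None
    if self_agent == "model":
        model_agent = _ModelAgent(model_config or ModelConfig())
    elif self_agent != "table":
        raise ValueError("self_agent must be 'table' or 'model'")

    records: list[TrialRecord] = []
    gaze_pairs: dict[int, tuple[GazeSeries, GazeSeries]] = {}
    for i, stim in enumerate(trials, start=1):
        if model_agent is not None:
            intent_self = model_agent.act(0.0)
        else:
            intent_self = human_agent(stim, spec.self_category, rng,
                                      noise=noise, hard_touch_prob=hard_touch_prob)
        if spec.session_type == "bot_pair":
            intent_partner = bot_policy(stim, spec.partner_category)
        elif spec.session_type == "human_pair":
            intent_partner = human_agent(stim, spec.partner_category, rng,
                                         noise=noise, hard_touch_prob=hard_touch_prob)
        else:
            intent_partner = 0  # practice/individual: partner does not act

        rt_self = rng.uniform(0.5, 2.5)
        rt_partner = rng.uniform(0.5, 2.5)
        if intent_self and intent_partner:
            touch_outcome = 1 if rt_self <= rt_partner else -1
        elif intent_self:
            touch_outcome = 1
        elif intent_partner:
            touch_outcome = -1
        else:
            touch_outcome = 0

        if touch_outcome == 1:
            correct = int(stim.category == spec.self_category)
            reaction_time = rt_self
        elif touch_outcome == -1:
            correct = int(stim.category == spec.partner_category)
            reaction_time = rt_partner
        else:
            correct = 0
            reaction_time = 3.0

        record = TrialRecord(
            trial_index=i,
            object_id=stim.object_id,
            category=stim.category,
            difficulty=stim.difficulty,
            handle_side=stim.handle_side,
            touch_outcome=touch_outcome,
            correct=correct,
            reaction_time=round(reaction_time, 4),
        )
        records.append(record)
        if model_agent is not None:
            model_agent.observe(record.a_s, record.a_p)

        if gaze:
            sub = int(rng.integers(0, 2**31 - 1))
            a, b = synthesize_gaze_pair(rho=rho, seed=sub)
            a.participant_id, a.trial_id = "host", i
            b.participant_id, b.trial_id = "client", i
            gaze_pairs[i] = (a, b)

    return records, gaze_pairs


def synthesize_gaze_pair(
    rho: float,
    duration: float = 3.0,
    rate: float = 80.0,
    lag: float = 0.0,
    jitter: float = 0.0,
    missing_rate: float = 0.0,
    smooth_sigma: float = 8.0,
    seed: int = 0,
) -> tuple[GazeSeries, GazeSeries]:
    """Paired 3-axis pupil-position streams with tunable synchrony.

    Both streams derive from a shared smooth latent trajectory (low-pass
    filtered Gaussian noise, smoothing width ``smooth_sigma`` samples).
    Stream A is the latent itself; stream B mixes the (optionally lagged)
    latent with an independent smooth trajectory:

        B = rho * latent(t - lag) + (1 - rho) * independent

    so rho = 1 with zero jitter reproduces A exactly and rho = 0 is fully
    uncoupled.  ``jitter`` adds white sensor noise to both streams;
    ``missing_rate`` blanks coordinates at random to emulate dropouts.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    lag_samples = int(round(lag * rate))
    t = np.arange(n) / rate

    def smooth_track(m: int) -> np.ndarray:
        raw = rng.standard_normal((m, 3))
        sm = gaussian_filter1d(raw, sigma=smooth_sigma, axis=0)
        # restore unit variance lost to smoothing so rho mixes like scales
        sd = sm.std(axis=0)
        sd[sd == 0] = 1.0
        return sm / sd

    latent = smooth_track(n + abs(lag_samples))
    indep = smooth_track(n + abs(lag_samples))
    if lag_samples >= 0:
        xyz_a = latent[lag_samples:lag_samples + n].copy()
        xyz_b = rho * latent[:n] + (1.0 - rho) * indep[:n]
    else:
        xyz_a = latent[:n].copy()
        xyz_b = rho * latent[-lag_samples:-lag_samples + n] + (1.0 - rho) * indep[:n]
    if jitter > 0:
        xyz_a = xyz_a + jitter * rng.standard_normal(xyz_a.shape)
        xyz_b = xyz_b + jitter * rng.standard_normal(xyz_b.shape)
    if missing_rate > 0:
        for xyz in (xyz_a, xyz_b):
            mask = rng.random(len(xyz)) < missing_rate
            xyz[mask, :] = np.nan

    a = GazeSeries("host", 0, t.copy(), xyz_a)
    b = GazeSeries("client", 0, t.copy(), xyz_b)
    return a, b
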