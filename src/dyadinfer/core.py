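"""Dual-layer Bayesian partner model and free-energy action selection.

The model maintains, for each self action ``a_s`` in {0, 1}, a belief about
the probability that the partner touches the object (``a_p = 1``):

* a *single-Bayes* layer — conjugate Beta-Bernoulli pseudo-counts updated by
  observed (a_s, a_p) pairs, whose posterior mean is ``p_t(a)``;
* a *double-Bayes* layer — an exponential moving average of observed partner
  actions, ``q_t(a)``, refreshed only on trials where the self action equals
  ``a``.

Per candidate action ``a`` the free energy is

    G(a) = kappa * d / (1 + d) + lambda0 * gamma_t * (2 q(a) - 1),

with ``d = KL(Bern(q(a)) || Bern(p(a)))``.  The compressed KL term measures
the tension between the two belief layers (bounded in [0, kappa)), while the
second term weights anticipated (dis)agreement with the partner by the
trial's gaze-synchrony weight ``gamma_t``.  Actions are chosen by
deterministic argmin of G; a softmax over -G/tau provides selection
probabilities for evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrialRecord",
    "DyadBelief",
    "ModelConfig",
    "FreeEnergyResult",
    "actions_from_touch_outcome",
    "init_belief",
    "update_single_bayes",
    "point_estimate",
    "update_double_bayes",
    "bernoulli_kl",
    "free_energy",
    "select_action",
    "run_session",
]

#: categories used in the joint classification task
CATEGORIES = ("Kitchen", "Garage")


def actions_from_touch_outcome(touch_outcome: int) -> tuple[int, int]:
    """Map the single recorded touch code to the (a_s, a_p) action pair.

    ``1`` = self touched first, ``-1`` = partner touched first, ``0`` = no
    touch.  Only the first touch is ever recorded, so (1, 1) cannot occur.
    """
    try:
        return {1: (1, 0), -1: (0, 1), 0: (0, 0)}[int(touch_outcome)]
    except (KeyError, ValueError, TypeError):
        raise ValueError(f"touch_outcome must be in {{1, -1, 0}}, got {touch_outcome!r}")


@dataclass(frozen=True)
class TrialRecord:
    """One trial of the joint handle task.

    ``touch_outcome`` encodes who touched first (1 self, -1 partner, 0
    nobody); ``a_s``/``a_p`` are the binary actions derived from it.
    """

    trial_index: int                  # 1-based position within the session
    object_id: str
    category: str                     # "Kitchen" or "Garage"
    difficulty: int                   # 0 = Easy/Low, 1 = Hard/High
    handle_side: str                  # "left" or "right"
    touch_outcome: int                # 1 / -1 / 0
    correct: int = 0
    reaction_time: float = 3.0        # seconds, capped at 3

    def __post_init__(self) -> None:
        if self.touch_outcome not in (1, -1, 0):
            raise ValueError(f"touch_outcome must be 1, -1 or 0, got {self.touch_outcome}")
        if self.difficulty not in (0, 1):
            raise ValueError(f"difficulty must be 0 or 1, got {self.difficulty}")
        if self.category not in CATEGORIES:
            raise ValueError(f"category must be one of {CATEGORIES}, got {self.category!r}")
        if self.handle_side not in ("left", "right"):
            raise ValueError(f"handle_side must be 'left' or 'right', got {self.handle_side!r}")
        if not 0.0 <= self.reaction_time <= 3.0:
            raise ValueError(f"reaction_time must lie in [0, 3] s, got {self.reaction_time}")

    @property
    def a_s(self) -> int:
        """Self action (1 = touch) derived from touch_outcome."""
        return actions_from_touch_outcome(self.touch_outcome)[0]

    @property
    def a_p(self) -> int:
        """Partner action (1 = touch) derived from touch_outcome."""
        return actions_from_touch_outcome(self.touch_outcome)[1]


@dataclass(frozen=True)
class ModelConfig:
    """Fixed parameters of the agreement model.

    kappa
        Scale of the compressed-KL term; the term lives in [0, kappa).
    lambda0
        Base weight of the agreement/risk term.
    tau
        Softmax temperature for selection probabilities.
    ema_alpha
        Decay of the double-Bayes exponential moving average.
    gamma0
        Base synchrony weight; the per-trial weight is gamma0 times the
        normalized gaze-synchrony index, hence bounded by gamma0.
    epsilon
        Clipping constant protecting the Bernoulli KL logs.
    prior_alpha, prior_beta
        Beta pseudo-count priors (uniform by default).
    q_init
        Initial EMA probability; 0.5 matches the uniform-prior mean so both
        layers start maximally uncertain.
    tie_break
        Action returned when both free energies are exactly equal.
    """

    kappa: float = 0.1
    lambda0: float = 1.0
    tau: float = 1.0
    ema_alpha: float = 0.8
    gamma0: float = 0.0
    epsilon: float = 1e-12
    prior_alpha: float = 1.0
    prior_beta: float = 1.0
    q_init: float = 0.5
    tie_break: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not 0.0 < self.ema_alpha <= 1.0:
            raise ValueError("ema_alpha must lie in (0, 1]")
        if not 0.0 <= self.gamma0 <= 1.0:
            raise ValueError("gamma0 must lie in [0, 1]")
        if not 0.0 < self.epsilon < 0.5:
            raise ValueError("epsilon must lie in (0, 0.5)")
        if self.prior_alpha <= 0 or self.prior_beta <= 0:
            raise ValueError("Beta priors must be positive")
        if not 0.0 <= self.q_init <= 1.0:
            raise ValueError("q_init must lie in [0, 1]")
        if self.tie_break not in (0, 1):
            raise ValueError("tie_break must be 0 or 1")


@dataclass(frozen=True)
class DyadBelief:
    """The four Beta pseudo-counts plus the two EMA probabilities.

    ``alpha_a1/beta_a1`` parameterize P(A_p=1 | A_s=a); ``q_a`` is the EMA
    refinement Q(A_p=1 | A_s=a).
    """

    alpha_11: float
    beta_11: float
    alpha_01: float
    beta_01: float
    q_1: float
    q_0: float


@dataclass(frozen=True)
class FreeEnergyResult:
    """Free energy of both candidate actions with its components."""

    g_0: float
    g_1: float
    kl_term_0: float
    kl_term_1: float
    reward_term_0: float
    reward_term_1: float
    pi_0: float
    pi_1: float
    chosen_action: int

    @property
    def fe_min(self) -> float:
        return min(self.g_0, self.g_1)


def init_belief(config: ModelConfig) -> DyadBelief:
    """Fresh belief: uniform Beta priors, EMAs at ``q_init``."""
    return DyadBelief(
        alpha_11=config.prior_alpha,
        beta_11=config.prior_beta,
        alpha_01=config.prior_alpha,
        beta_01=config.prior_beta,
        q_1=config.q_init,
        q_0=config.q_init,
    )


def _check_binary(name: str, value: int) -> int:
    if value not in (0, 1):
        raise ValueError(f"{name} must be 0 or 1, got {value!r}")
    return int(value)


def update_single_bayes(belief: DyadBelief, a_s: int, a_p: int) -> DyadBelief:
    """Conjugate count update: increment the pseudo-count selected by
    (a_s, a_p), leaving the other self-action conditional untouched."""
    a_s = _check_binary("a_s", a_s)
    a_p = _check_binary("a_p", a_p)
    if a_s == 1:
        if a_p == 1:
            return replace(belief, alpha_11=belief.alpha_11 + 1.0)
        return replace(belief, beta_11=belief.beta_11 + 1.0)
    if a_p == 1:
        return replace(belief, alpha_01=belief.alpha_01 + 1.0)
    return replace(belief, beta_01=belief.beta_01 + 1.0)


def point_estimate(belief: DyadBelief, a: int) -> float:
    """Posterior-mean estimate of P(A_p=1 | A_s=a): alpha / (alpha + beta)."""
    a = _check_binary("a", a)
    if a == 1:
        return belief.alpha_11 / (belief.alpha_11 + belief.beta_11)
    return belief.alpha_01 / (belief.alpha_01 + belief.beta_01)


def update_double_bayes(belief: DyadBelief, a_s: int, a_p: int, ema_alpha: float) -> DyadBelief:
    """EMA refinement: q_{a_s} <- alpha * a_p + (1 - alpha) * q_{a_s}.

    Only the conditional matching the observed self action moves; trials
    with no recorded partner touch contribute a_p = 0.
    """
    a_s = _check_binary("a_s", a_s)
    a_p = _check_binary("a_p", a_p)
    if not 0.0 < ema_alpha <= 1.0:
        raise ValueError("ema_alpha must lie in (0, 1]")
    if a_s == 1:
        return replace(belief, q_1=ema_alpha * a_p + (1.0 - ema_alpha) * belief.q_1)
    return replace(belief, q_0=ema_alpha * a_p + (1.0 - ema_alpha) * belief.q_0)


def bernoulli_kl(q: float, p: float, epsilon: float = 1e-12) -> float:
    """KL(Bern(q) || Bern(p)) in nats, with both arguments clipped to
    [epsilon, 1 - epsilon] so boundary beliefs stay finite."""
    q = min(max(float(q), epsilon), 1.0 - epsilon)
    p = min(max(float(p), epsilon), 1.0 - epsilon)
    return q * math.log(q / p) + (1.0 - q) * math.log((1.0 - q) / (1.0 - p))


def free_energy(belief: DyadBelief, gamma_t: float, config: ModelConfig) -> FreeEnergyResult:
    """Evaluate G(a) for both candidate self actions.

    ``gamma_t`` is the trial's synchrony weight in [0, gamma0]; with
    gamma_t = 0 the agreement term vanishes and G reduces to the compressed
    KL between the two belief layers.
    """
    if gamma_t < 0.0:
        raise ValueError("gamma_t must be non-negative")
    kl_terms = []
    reward_terms = []
    gs = []
    for a in (0, 1):
        p_a = point_estimate(belief, a)
        q_a = belief.q_1 if a == 1 else belief.q_0
        d = bernoulli_kl(q_a, p_a, config.epsilon)
        kl = config.kappa * d / (1.0 + d)
        reward = config.lambda0 * gamma_t * (2.0 * q_a - 1.0)
        kl_terms.append(kl)
        reward_terms.append(reward)
        gs.append(kl + reward)
    action, pi_0, pi_1 = _softmax_argmin(gs[0], gs[1], config.tau, config.tie_break)
    return FreeEnergyResult(
        g_0=gs[0], g_1=gs[1],
        kl_term_0=kl_terms[0], kl_term_1=kl_terms[1],
        reward_term_0=reward_terms[0], reward_term_1=reward_terms[1],
        pi_0=pi_0, pi_1=pi_1, chosen_action=action,
    )


def _softmax_argmin(g_0: float, g_1: float, tau: float, tie_break: int) -> tuple[int, float, float]:
    # shift by the minimum before exponentiating for numerical stability
    lo = min(g_0, g_1)
    w0 = math.exp(-(g_0 - lo) / tau)
    w1 = math.exp(-(g_1 - lo) / tau)
    z = w0 + w1
    if g_0 < g_1:
        action = 0
    elif g_1 < g_0:
        action = 1
    else:
        action = tie_break
    return action, w0 / z, w1 / z


def select_action(result: FreeEnergyResult, tau: float, tie_break: int = 0) -> tuple[int, float, float]:
    """Deterministic argmin of G with softmax probabilities at temperature tau."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    return _softmax_argmin(result.g_0, result.g_1, tau, tie_break)


def run_session(
    trials: Sequence[TrialRecord],
    sync: Sequence[float] | None,
    config: ModelConfig,
) -> pd.DataFrame:
    """Run the model over one session, predicting before updating.

    Per trial the trace records the belief state *before* observing that
    trial, the free energies and softmax probabilities, the predicted self
    action (argmin G) and the partner-touch probability conditioned on that
    predicted action — then applies the single- and double-Bayes updates
    with the trial's observed actions.

    ``sync`` holds the per-trial synchrony weights gamma_t; ``None`` means
    no gaze data, i.e. gamma_t = 0 on every trial.  Individual NaN entries
    likewise fall back to 0 for that trial only.
    """
    trials = list(trials)
    if sync is None:
        sync_arr = np.zeros(len(trials))
    else:
        sync_arr = np.asarray(list(sync), dtype=float)
        if len(sync_arr) != len(trials):
            raise ValueError(
                f"sync length {len(sync_arr)} does not match {len(trials)} trials"
            )
        sync_arr = np.where(np.isnan(sync_arr), 0.0, sync_arr)
    indices = [t.trial_index for t in trials]
    if indices != sorted(indices):
        raise ValueError("trials must be ordered by trial_index")

    belief = init_belief(config)
    rows = []
    for trial, gamma_t in zip(trials, sync_arr):
        fe = free_energy(belief, float(gamma_t), config)
        pred_self = fe.chosen_action
        pred_partner_prob = point_estimate(belief, pred_self)
        rows.append({
            "trial_index": trial.trial_index,
            "object_id": trial.object_id,
            "category": trial.category,
            "difficulty": trial.difficulty,
            "gamma_t": float(gamma_t),
            "p_0": point_estimate(belief, 0),
            "p_1": point_estimate(belief, 1),
            "q_0": belief.q_0,
            "q_1": belief.q_1,
            "g_0": fe.g_0,
            "g_1": fe.g_1,
            "pi_1": fe.pi_1,
            "predicted_partner_prob": pred_partner_prob,
            "predicted_self_action": pred_self,
            "fe_min": fe.fe_min,
            "a_s": trial.a_s,
            "a_p": trial.a_p,
        })
        belief = update_single_bayes(belief, trial.a_s, trial.a_p)
        belief = update_double_bayes(belief, trial.a_s, trial.a_p, config.ema_alpha)

    columns = [
        "trial_index", "object_id", "category", "difficulty", "gamma_t",
        "p_0", "p_1", "q_0", "q_1", "g_0", "g_1", "pi_1",
        "predicted_partner_prob", "predicted_self_action", "fe_min",
        "a_s", "a_p",
    ]
    return pd.DataFrame(rows, columns=columns)
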