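"""Q-learning choice model: value recursion, softmax policy, fitting.

Model
-----
Two action values, one per spout. After each non-timeout trial with
reward indicator ``R`` (1 when water was dispensed):

* chosen spout:    ``Q <- Q + alpha * (R - Q)``
* unchosen spout:  ``Q <- (1 - zeta) * Q``

The policy is logistic in the value difference; the *right* spout is the
reference, so ``P(R) = sigmoid(beta * (Q_R - Q_L) + bias)``. Flipping the
reference convention flips only the sign of the bias.

Timeout trials contribute nothing to the likelihood and trigger no value
update. Values are initialised to ``Q_L = Q_R = 0`` at the start of every
session (no cross-session carryover).

Fitting minimises the mean negative log-likelihood per training trial.
Each session is split into 4 contiguous trial-quarters; a seeded random 3
of 4 form the training set (75%) and the remaining quarter is held out.
Parameters are optimised on unconstrained scales (logistic for alpha and
zeta, softplus for beta, identity for bias) by full-batch gradient descent
with an optional quasi-Newton refinement. Gradients are analytic: the
sensitivities of the value recursion with respect to alpha and zeta are
propagated forward alongside the values themselves.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .bandit_task import SessionLog, TaskConfig, Trial, run_session

__all__ = [
    "QParams",
    "QState",
    "FitConfig",
    "FitResult",
    "q_update",
    "choice_prob",
    "session_nll",
    "nll_and_grad",
    "split_quarters",
    "fit_q",
    "simulate_agent",
    "fit_result_to_json",
]


@dataclass(frozen=True)
class QParams:
    """Model parameters: learning rate, forgetting rate, inverse temperature, bias."""

    alpha: float
    zeta: float
    beta: float
    bias: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must be in [0,1], got {self.alpha}")
        if not (0.0 <= self.zeta <= 1.0):
            raise ValueError(f"zeta must be in [0,1], got {self.zeta}")
        if not (self.beta >= 0.0):
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        for v in (self.alpha, self.zeta, self.beta, self.bias):
            if not math.isfinite(v):
                raise ValueError("parameters must be finite")


@dataclass(frozen=True)
class QState:
    q_left: float = 0.0
    q_right: float = 0.0


def q_update(state: QState, choice: str, rewarded: bool, params: QParams) -> QState:
    """One step of the value recursion. ``choice`` must be 'L' or 'R'."""
    if choice not in ("L", "R"):
        raise ValueError(
            f"q_update requires a spout choice, got {choice!r}; filter timeouts first"
        )
    r = 1.0 if rewarded else 0.0
    if choice == "L":
        return QState(
            q_left=state.q_left + params.alpha * (r - state.q_left),
            q_right=(1.0 - params.zeta) * state.q_right,
        )
    return QState(
        q_left=(1.0 - params.zeta) * state.q_left,
        q_right=state.q_right + params.alpha * (r - state.q_right),
    )


def choice_prob(state: QState, params: QParams) -> float:
    """Probability of choosing the reference (right) spout."""
    x = params.beta * (state.q_right - state.q_left) + params.bias
    return float(expit(x))


# ---------------------------------------------------------------------------
# Likelihood machinery


def _session_arrays(session: SessionLog) -> tuple[np.ndarray, np.ndarray]:
    """(choices, rewards) over non-timeout trials; choice coded 0=L, 1=R."""
    choices, rewards = [], []
    for t in session.trials:
        if t.choice == "timeout":
            continue
        choices.append(1 if t.choice == "R" else 0)
        rewards.append(1.0 if t.rewarded else 0.0)
    return np.asarray(choices, dtype=np.int64), np.asarray(rewards)


def _forward_probs(choices: np.ndarray, rewards: np.ndarray, params: QParams) -> np.ndarray:
    """P(choose R) at every non-timeout trial, values propagated in order."""
    a, z, b, bias = params.alpha, params.zeta, params.beta, params.bias
    qL = qR = 0.0
    p = np.empty(len(choices))
    for i in range(len(choices)):
        p[i] = expit(b * (qR - qL) + bias)
        if choices[i] == 1:
            qR += a * (rewards[i] - qR)
            qL *= 1.0 - z
        else:
            qL += a * (rewards[i] - qL)
            qR *= 1.0 - z
    return p


def session_nll(sessions: Sequence[SessionLog], params: QParams) -> float:
    """Mean negative log-likelihood per included (non-timeout) trial."""
    total, n = 0.0, 0
    for s in sessions:
        choices, rewards = _session_arrays(s)
        if len(choices) == 0:
            continue
        p_r = _forward_probs(choices, rewards, params)
        p_obs = np.where(choices == 1, p_r, 1.0 - p_r)
        total += -np.sum(np.log(np.clip(p_obs, 1e-300, None)))
        n += len(choices)
    if n == 0:
        raise ValueError("no non-timeout trials to evaluate")
    return total / n


def nll_and_grad(
    sessions: Sequence[SessionLog],
    params: QParams,
    masks: Sequence[np.ndarray] | None = None,
) -> tuple[float, np.ndarray]:
    """Mean NLL and its analytic gradient wrt (alpha, zeta, beta, bias).

    ``masks``, when given, selects which non-timeout trials of each session
    contribute to the loss; the value recursion is always propagated over
    every non-timeout trial in order.
    """
    a, z, b, bias = params.alpha, params.zeta, params.beta, params.bias
    nll = 0.0
    g = np.zeros(4)
    n = 0
    for si, s in enumerate(sessions):
        choices, rewards = _session_arrays(s)
        mask = None if masks is None else masks[si]
        qL = qR = 0.0
        dqL_a = dqL_z = dqR_a = dqR_z = 0.0
        for i in range(len(choices)):
            c = choices[i]
            included = True if mask is None else bool(mask[i])
            if included:
                x = b * (qR - qL) + bias
                p = expit(x)
                nll += -math.log(max(p if c == 1 else 1.0 - p, 1e-300))
                dx = p - c  # d(-log P(obs))/dx
                g[0] += dx * b * (dqR_a - dqL_a)
                g[1] += dx * b * (dqR_z - dqL_z)
                g[2] += dx * (qR - qL)
                g[3] += dx
                n += 1
            r = rewards[i]
            if c == 1:
                dqR_a = (1.0 - a) * dqR_a + (r - qR)
                dqR_z = (1.0 - a) * dqR_z
                dqL_a = (1.0 - z) * dqL_a
                dqL_z = (1.0 - z) * dqL_z - qL
                qR += a * (r - qR)
                qL *= 1.0 - z
            else:
                dqL_a = (1.0 - a) * dqL_a + (r - qL)
                dqL_z = (1.0 - a) * dqL_z
                dqR_a = (1.0 - z) * dqR_a
                dqR_z = (1.0 - z) * dqR_z - qR
                qL += a * (r - qL)
                qR *= 1.0 - z
    if n == 0:
        raise ValueError("no trials selected for the likelihood")
    return nll / n, g / n


# ---------------------------------------------------------------------------
# Fitting


@dataclass(frozen=True)
class FitConfig:
    learn_rate: float = 0.1
    n_iters: int = 10_000
    train_fraction: float = 0.75
    seed: int = 0
    refine: bool = True  # quasi-Newton polish after gradient descent
    tol: float = 1e-9  # convergence: loss change over ``patience`` iterations
    patience: int = 100

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0,1)")
        if self.n_iters < 1:
            raise ValueError("n_iters must be >= 1")


@dataclass
class FitResult:
    params: QParams
    train_nll: float
    heldout_accuracy: float
    converged: bool
    n_trials: int
    trace: list[float] = field(default_factory=list)
    weakly_identified: bool = False


N_QUARTERS = 4


def split_quarters(
    n_trials: int, rng: np.random.Generator, n_train: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Split trial indices 0..n-1 into 4 contiguous quarters and pick a
    random ``n_train`` of them for training. Returns (train_mask, quarter_ids)."""
    quarter_ids = np.zeros(n_trials, dtype=np.int64)
    for qi, idx in enumerate(np.array_split(np.arange(n_trials), N_QUARTERS)):
        quarter_ids[idx] = qi
    train_quarters = rng.choice(N_QUARTERS, size=n_train, replace=False)
    return np.isin(quarter_ids, train_quarters), quarter_ids


def _softplus(x: float) -> float:
    return float(np.logaddexp(0.0, x))


def _softplus_inv(y: float) -> float:
    y = max(y, 1e-8)
    return y + math.log(-math.expm1(-y))


def _theta_to_params(theta: np.ndarray) -> QParams:
    return QParams(
        alpha=float(expit(theta[0])),
        zeta=float(expit(theta[1])),
        beta=_softplus(theta[2]),
        bias=float(theta[3]),
    )


def _params_to_theta(params: QParams) -> np.ndarray:
    def logit(p: float) -> float:
        p = min(max(p, 1e-8), 1 - 1e-8)
        return math.log(p / (1 - p))

    return np.array(
        [logit(params.alpha), logit(params.zeta), _softplus_inv(params.beta), params.bias]
    )


def _chain(theta: np.ndarray, grad_params: np.ndarray) -> np.ndarray:
    """Gradient wrt unconstrained coordinates from the gradient wrt params."""
    sa, sz = expit(theta[0]), expit(theta[1])
    jac = np.array([sa * (1 - sa), sz * (1 - sz), expit(theta[2]), 1.0])
    return grad_params * jac


def fit_q(sessions: Sequence[SessionLog], config: FitConfig | None = None) -> FitResult:
    """Fit the model to a pool of sessions from one mouse/epoch.

    The training partition covers 3 of each session's 4 contiguous
    trial-quarters; the likelihood is the mean NLL over training trials with
    values propagated over all trials in order. Held-out accuracy is the
    fraction of held-out non-timeout trials where the argmax of the fitted
    choice probability matches the observed choice (an exact 0.5 counts as
    incorrect).
    """
    if config is None:
        config = FitConfig()
    if not sessions:
        raise ValueError("need at least one session")
    rng = np.random.default_rng(config.seed)
    n_train = round(config.train_fraction * N_QUARTERS)
    masks = []
    n_total = 0
    for s in sessions:
        choices, _ = _session_arrays(s)
        mask, _ = split_quarters(len(choices), rng, n_train=n_train)
        masks.append(mask)
        n_total += len(choices)
    if n_total == 0:
        raise ValueError("no non-timeout trials in the supplied sessions")

    theta = _params_to_theta(QParams(alpha=0.5, zeta=0.5, beta=1.0, bias=0.0))
    trace: list[float] = []
    converged = False
    for it in range(config.n_iters):
        loss, g_params = nll_and_grad(sessions, _theta_to_params(theta), masks)
        if not math.isfinite(loss):
            raise FloatingPointError(f"non-finite loss at iteration {it}: {loss}")
        trace.append(loss)
        theta = theta - config.learn_rate * _chain(theta, g_params)
        if (
            it >= config.patience
            and abs(trace[-1 - config.patience] - trace[-1]) < config.tol
        ):
            converged = True
            break

    if config.refine:

        def objective(th: np.ndarray) -> tuple[float, np.ndarray]:
            loss, g = nll_and_grad(sessions, _theta_to_params(th), masks)
            return loss, _chain(th, g)

        res = minimize(objective, theta, jac=True, method="L-BFGS-B")
        if math.isfinite(res.fun) and res.fun <= trace[-1]:
            theta = res.x
            trace.append(float(res.fun))
            converged = converged or bool(res.success)

    params = _theta_to_params(theta)
    train_nll, _ = nll_and_grad(sessions, params, masks)

    correct = heldout = 0
    all_one_choice = True
    for s, mask in zip(sessions, masks):
        choices, rewards = _session_arrays(s)
        if len(np.unique(choices)) > 1:
            all_one_choice = False
        p_r = _forward_probs(choices, rewards, params)
        held = ~mask
        pred = p_r[held] > 0.5  # exact 0.5 predicts L; counted per observed choice
        correct += int(np.sum(pred == (choices[held] == 1)))
        heldout += int(held.sum())
    accuracy = correct / heldout if heldout else float("nan")

    return FitResult(
        params=params,
        train_nll=float(train_nll),
        heldout_accuracy=float(accuracy),
        converged=converged,
        n_trials=n_total,
        trace=trace,
        weakly_identified=all_one_choice,
    )


def fit_result_to_json(result: FitResult, mouse_id: str, epoch: str, seed: int) -> str:
    return json.dumps(
        {
            "mouse_id": mouse_id,
            "epoch": epoch,
            "alpha": result.params.alpha,
            "zeta": result.params.zeta,
            "beta": result.params.beta,
            "bias": result.params.bias,
            "train_nll": result.train_nll,
            "heldout_accuracy": result.heldout_accuracy,
            "n_trials": result.n_trials,
            "seed": seed,
        }
    )


# ---------------------------------------------------------------------------
# Agent simulation


class _QAgentPolicy:
    """Stateful policy sampling choices from the softmax over evolving values."""

    def __init__(self, params: QParams, rng: np.random.Generator):
        self.params = params
        self.rng = rng
        self.state = QState()
        self._seen = 0

    def __call__(self, history: Sequence[tuple[str, bool]], high_spout: str) -> str:
        while self._seen < len(history):
            choice, rewarded = history[self._seen]
            if choice != "timeout":
                self.state = q_update(self.state, choice, rewarded, self.params)
            self._seen += 1
        p_right = choice_prob(self.state, self.params)
        return "R" if self.rng.random() < p_right else "L"


def simulate_agent(
    params: QParams,
    task: TaskConfig,
    n_sessions: int,
    seed: int,
    *,
    mouse_id: str = "sim",
    epoch: str = "habituation",
    day0: int = 0,
) -> list[SessionLog]:
    """Simulate a Q-learning agent on the bandit task.

    Values reset at the start of every session. Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    logs = []
    for k in range(n_sessions):
        policy = _QAgentPolicy(params, rng)
        logs.append(
            run_session(
                task,
                policy,
                rng,
                mouse_id=mouse_id,
                session_id=f"{mouse_id}_{epoch}_{k}",
                epoch=epoch,
                day=day0 + k,
            )
        )
    return logs
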