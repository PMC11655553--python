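"""Core computational model of the Information Bias Learning Task.

The winning model tracks two independent probability estimates per block —
``rwin``, the probability that the win outcome is associated with shape A, and
``rloss``, the same for the loss outcome.  Both are updated every trial with a
delta rule (Rescorla-Wagner), each with its own learning rate::

    rwin[i+1]  = rwin[i]  + alpha_win  * (winout[i]  - rwin[i])
    rloss[i+1] = rloss[i] + alpha_loss * (lossout[i] - rloss[i])

where ``winout``/``lossout`` are 1 iff the respective outcome was assigned to
shape A on trial *i*.  Updating is full-feedback: both outcome assignments are
shown on screen every trial, so the estimates are updated regardless of which
shape was chosen.  A two-temperature softmax maps the estimates to the choice
probability::

    P(choice = A) = 1 / (1 + exp(-(beta_win*(rwin - 0.5) - beta_loss*(rloss - 0.5))))

Learning rates are always fitted block-wise; the inverse temperatures are
either shared across all blocks of a session ("constant" scope, the winning
model) or fitted per block ("block-wise" scope).  This module is pure
computation — no file I/O.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter
from scipy.special import expit, logit as _logit

__all__ = [
    "LatentState",
    "AgentParams",
    "ModelSpec",
    "WINNING_MODEL",
    "COMPARATOR_FAMILY",
    "update_state",
    "choice_probability",
    "state_trajectory",
    "sequence_negative_log_likelihood",
    "transform_params",
    "untransform_params",
]

N_BLOCKS = 6


@dataclass(frozen=True)
class LatentState:
    """Running probability estimates (win/loss associated with shape A)."""

    rwin: float
    rloss: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.rwin <= 1.0 and 0.0 <= self.rloss <= 1.0):
            raise ValueError(f"state probabilities must lie in [0,1], got {self}")


@dataclass(frozen=True)
class AgentParams:
    """Natural-scale parameters of one agent for a single block.

    Learning rates live in (0,1); inverse temperatures are >= 0 and may be
    shared across blocks depending on the :class:`ModelSpec` in play.
    """

    alpha_win: float
    alpha_loss: float
    beta_win: float
    beta_loss: float

    def __post_init__(self) -> None:
        for name in ("alpha_win", "alpha_loss"):
            a = getattr(self, name)
            if not (0.0 <= a <= 1.0):
                raise ValueError(f"{name}={a} outside [0,1]")
        for name in ("beta_win", "beta_loss"):
            b = getattr(self, name)
            if b < 0.0:
                raise ValueError(f"{name}={b} must be >= 0")


@dataclass(frozen=True)
class ModelSpec:
    """One member of the comparator model family.

    The family is the crossing {single vs dual learning rate} x {single vs
    dual inverse temperature} with constant-across-blocks temperatures, plus
    the dual/dual block-wise-temperature variant.  Learning rates are
    block-wise in every member.  This is a documented surrogate family built
    around the constant vs block-wise temperature contrast; it is not a
    reconstruction of any particular published six-model set.
    """

    name: str
    dual_learning_rates: bool
    dual_temperatures: bool
    blockwise_temperatures: bool

    def n_params(self, n_blocks: int = N_BLOCKS) -> int:
        n_alpha = (2 if self.dual_learning_rates else 1) * n_blocks
        n_beta = (2 if self.dual_temperatures else 1) * (
            n_blocks if self.blockwise_temperatures else 1
        )
        return n_alpha + n_beta


WINNING_MODEL = ModelSpec("dual-lr_dual-temp_constant", True, True, False)

COMPARATOR_FAMILY: tuple[ModelSpec, ...] = (
    ModelSpec("single-lr_single-temp_constant", False, False, False),
    ModelSpec("dual-lr_single-temp_constant", True, False, False),
    ModelSpec("single-lr_dual-temp_constant", False, True, False),
    WINNING_MODEL,
    ModelSpec("dual-lr_dual-temp_blockwise", True, True, True),
)


def update_state(
    state: LatentState,
    winout: int,
    lossout: int,
    alpha_win: float,
    alpha_loss: float,
) -> LatentState:
    """One delta-rule update of both probability tracks (pure function)."""
    if not (0.0 <= alpha_win <= 1.0 and 0.0 <= alpha_loss <= 1.0):
        raise ValueError("learning rates must lie in [0,1]")
    if winout not in (0, 1) or lossout not in (0, 1):
        raise ValueError("outcome codes must be 0 or 1")
    return LatentState(
        rwin=state.rwin + alpha_win * (winout - state.rwin),
        rloss=state.rloss + alpha_loss * (lossout - state.rloss),
    )


def choice_probability(state: LatentState, beta_win: float, beta_loss: float) -> float:
    """P(choose shape A) under the two-temperature softmax."""
    if beta_win < 0 or beta_loss < 0:
        raise ValueError("inverse temperatures must be >= 0")
    z = beta_win * (state.rwin - 0.5) - beta_loss * (state.rloss - 0.5)
    return float(expit(z))


def state_trajectory(outcomes: np.ndarray, alpha: float, r0: float = 0.5) -> np.ndarray:
    """Pre-choice estimate on each trial for one outcome stream.

    Returns ``r[i]`` = estimate entering trial *i* (``r[0] = r0``); the update
    with ``outcomes[i]`` happens after the trial.  The recursion
    ``r[i+1] = (1-alpha) r[i] + alpha o[i]`` is a first-order linear filter,
    evaluated with :func:`scipy.signal.lfilter`.
    """
    outcomes = np.asarray(outcomes, dtype=float)
    post, _ = lfilter([alpha], [1.0, alpha - 1.0], outcomes, zi=[(1.0 - alpha) * r0])
    r = np.empty(len(outcomes))
    r[0] = r0
    r[1:] = post[:-1]
    return r


def _grad_trajectory(outcomes: np.ndarray, r_pre: np.ndarray, alpha: float) -> np.ndarray:
    # s[i] = d r_pre[i] / d alpha;  s[i+1] = (1-alpha) s[i] + (o[i] - r_pre[i])
    u = np.asarray(outcomes, dtype=float) - r_pre
    post, _ = lfilter([1.0], [1.0, alpha - 1.0], u, zi=[0.0])
    s = np.empty(len(u))
    s[0] = 0.0
    s[1:] = post[:-1]
    return s


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


@dataclass(frozen=True)
class BlockData:
    """Numeric view of one block's trials for likelihood evaluation."""

    choice_a: np.ndarray  # 1 if shape A chosen
    winout: np.ndarray
    lossout: np.ndarray

    @property
    def n_trials(self) -> int:
        return len(self.choice_a)


def blocks_from_frame(df) -> list[BlockData]:
    """Split a trial table (one subject-session) into per-block arrays."""
    out = []
    for _, g in df.sort_values(["block_index", "trial"]).groupby("block_index", sort=True):
        choice_a = (g["choice"].to_numpy() == "A").astype(float)
        out.append(
            BlockData(
                choice_a=choice_a,
                winout=g["winout"].to_numpy(dtype=float),
                lossout=g["lossout"].to_numpy(dtype=float),
            )
        )
    return out


def unpack_params(x: np.ndarray, spec: ModelSpec, n_blocks: int) -> dict[str, np.ndarray]:
    """Unconstrained vector -> per-block natural-scale parameter arrays.

    Layout: logit learning rates first (win block 1..B, then loss block 1..B
    for dual specs; shared block 1..B otherwise), then log temperatures
    (win[, loss], per block if block-wise scope).
    """
    x = np.asarray(x, dtype=float)
    if len(x) != spec.n_params(n_blocks):
        raise ValueError(
            f"parameter vector of length {len(x)} does not match "
            f"{spec.name} ({spec.n_params(n_blocks)} parameters, {n_blocks} blocks)"
        )
    b = n_blocks
    if spec.dual_learning_rates:
        aw, al = expit(x[:b]), expit(x[b : 2 * b])
        i = 2 * b
    else:
        aw = al = expit(x[:b])
        i = b
    n_temp_sets = b if spec.blockwise_temperatures else 1
    if spec.dual_temperatures:
        bw = np.exp(x[i : i + n_temp_sets])
        bl = np.exp(x[i + n_temp_sets : i + 2 * n_temp_sets])
    else:
        bw = bl = np.exp(x[i : i + n_temp_sets])
    if not spec.blockwise_temperatures:
        bw = np.repeat(bw, b)
        bl = np.repeat(bl, b)
    return {"alpha_win": aw, "alpha_loss": al, "beta_win": bw, "beta_loss": bl}


def nll_and_grad(
    x: np.ndarray, spec: ModelSpec, blocks: list[BlockData]
) -> tuple[float, np.ndarray]:
    """Negative log-likelihood (nats) and its gradient on the unconstrained scale.

    State resets to (0.5, 0.5) at each block start.  The choice probability on
    trial *i* uses the pre-choice state; the update with that trial's outcomes
    follows.  Gradients use the linear-filter form of d(state)/d(alpha).
    """
    if not blocks:
        raise ValueError("empty trial list")
    n_blocks = len(blocks)
    p = unpack_params(x, spec, n_blocks)
    grad = np.zeros_like(np.asarray(x, dtype=float))
    b = n_blocks
    n_temp_sets = b if spec.blockwise_temperatures else 1
    i_beta = (2 * b if spec.dual_learning_rates else b)

    nll = 0.0
    for k, blk in enumerate(blocks):
        aw, al = p["alpha_win"][k], p["alpha_loss"][k]
        bw, bl = p["beta_win"][k], p["beta_loss"][k]
        rw = state_trajectory(blk.winout, aw)
        rl = state_trajectory(blk.lossout, al)
        z = bw * (rw - 0.5) - bl * (rl - 0.5)
        # -log P(observed) = softplus(-z) for A-choices, softplus(z) for B
        c = blk.choice_a
        nll += float(np.sum(c * _softplus(-z) + (1.0 - c) * _softplus(z)))
        resid = expit(z) - c  # d nll / d z
        sw = _grad_trajectory(blk.winout, rw, aw)
        sl = _grad_trajectory(blk.lossout, rl, al)
        # chain rule through logit(alpha) and log(beta)
        g_aw = bw * float(resid @ sw) * aw * (1.0 - aw)
        g_al = -bl * float(resid @ sl) * al * (1.0 - al)
        g_bw = float(resid @ (rw - 0.5)) * bw
        g_bl = -float(resid @ (rl - 0.5)) * bl
        if spec.dual_learning_rates:
            grad[k] += g_aw
            grad[b + k] += g_al
        else:
            grad[k] += g_aw + g_al
        tk = k if spec.blockwise_temperatures else 0
        if spec.dual_temperatures:
            grad[i_beta + tk] += g_bw
            grad[i_beta + n_temp_sets + tk] += g_bl
        else:
            grad[i_beta + tk] += g_bw + g_bl
    return nll, grad


def sequence_negative_log_likelihood(
    trials, params: AgentParams | list[AgentParams], spec: ModelSpec = WINNING_MODEL
) -> float:
    """NLL of a trial table under natural-scale parameters.

    ``params`` is a single :class:`AgentParams` (applied to every block) or a
    list with one entry per block.  For constant-temperature specs the
    temperatures must agree across blocks.
    """
    blocks = blocks_from_frame(trials) if not isinstance(trials, list) else trials
    if not blocks:
        raise ValueError("empty trial list")
    n_blocks = len(blocks)
    if isinstance(params, AgentParams):
        params = [params] * n_blocks
    if len(params) != n_blocks:
        raise ValueError(f"{len(params)} parameter sets for {n_blocks} blocks")
    if not spec.blockwise_temperatures:
        bws = {p.beta_win for p in params}
        bls = {p.beta_loss for p in params}
        if len(bws) > 1 or len(bls) > 1:
            raise ValueError(f"{spec.name} requires temperatures shared across blocks")
    nll = 0.0
    for pk, blk in zip(params, blocks):
        rw = state_trajectory(blk.winout, pk.alpha_win)
        rl = state_trajectory(blk.lossout, pk.alpha_loss)
        z = pk.beta_win * (rw - 0.5) - pk.beta_loss * (rl - 0.5)
        c = blk.choice_a
        nll += float(np.sum(c * _softplus(-z) + (1.0 - c) * _softplus(z)))
    return nll


def transform_params(alpha: float | np.ndarray = None, beta: float | np.ndarray = None):
    """Natural -> unconstrained scale: rates to logit, temperatures to log.

    Returns the transformed alpha, beta, or an (alpha, beta) pair depending on
    which arguments are given.  Boundary values are rejected: fits operate on
    the unconstrained scale precisely so the boundaries are unreachable.
    """
    out = []
    if alpha is not None:
        a = np.asarray(alpha, dtype=float)
        if np.any(a <= 0.0) or np.any(a >= 1.0):
            raise ValueError("learning rates must lie strictly in (0,1) for the logit map")
        out.append(_logit(a))
    if beta is not None:
        bt = np.asarray(beta, dtype=float)
        if np.any(bt <= 0.0):
            raise ValueError("inverse temperatures must be > 0 for the log map")
        out.append(np.log(bt))
    if not out:
        raise ValueError("nothing to transform")
    return out[0] if len(out) == 1 else tuple(out)


def untransform_params(logit_alpha=None, log_beta=None):
    """Unconstrained -> natural scale (inverse of :func:`transform_params`)."""
    out = []
    if logit_alpha is not None:
        out.append(expit(np.asarray(logit_alpha, dtype=float)))
    if log_beta is not None:
        out.append(np.exp(np.asarray(log_beta, dtype=float)))
    if not out:
        raise ValueError("nothing to transform")
    return out[0] if len(out) == 1 else tuple(out)
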