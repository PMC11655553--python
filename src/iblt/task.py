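"""Information Bias Learning Task: schedules, sessions, agents, cohorts.

The task is six 80-trial blocks of choosing between two shapes (A/B).  On
every trial a win (+10p) and a loss (-10p) are each assigned to one of the two
shapes, independently of each other; the chosen shape collects whichever
outcomes landed on it (win only -> +10p, loss only -> -10p, both or neither ->
0p).  Volatility of the two outcome streams is manipulated per block:

* ``both-volatile``   — win and loss each follow a reversing 80/20 contingency;
* ``wins-volatile``   — wins follow 80/20 with reversals, losses are 50/50;
* ``losses-volatile`` — the mirror image.

A session starts and ends with a both-volatile block; blocks 2-5 alternate
wins-/losses-volatile according to the counterbalanced block order.  Outcome
sequences are realised by exact-count shuffling (each 80/20 segment contains
exactly its quota of favoured-shape assignments; 50/50 streams are balanced
over the block), so the printed contingencies hold in every single block
rather than only in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.special import expit

from .model import AgentParams, LatentState, choice_probability, update_state

__all__ = [
    "CONDITIONS",
    "BlockSchedule",
    "TrialRecord",
    "SessionDesign",
    "ParamDistribution",
    "CohortSpec",
    "Cohort",
    "payoff",
    "make_block_schedule",
    "realize_outcomes",
    "make_session_design",
    "simulate_agent",
    "simulate_cohort",
]

CONDITIONS = ("both-volatile", "wins-volatile", "losses-volatile")
GROUPS = ("during-task", "before-task", "healthy-baseline")
N_TRIALS_PER_BLOCK = 80
N_BLOCKS = 6


# ---------------------------------------------------------------------------
# schedules


@dataclass(frozen=True)
class BlockSchedule:
    """Per-trial contingency schedule for one block.

    ``win_p_shapeA[i]`` is the probability that the win is assigned to shape A
    on trial *i* (0.8/0.2 on volatile segments, 0.5 when uninformative);
    ``reversal_trials_win`` holds the 1-based trial indices at which the
    favoured shape of the win stream flips (likewise for losses).
    """

    condition: str
    n_trials: int
    win_p_shapeA: np.ndarray
    loss_p_shapeA: np.ndarray
    reversal_trials_win: tuple[int, ...]
    reversal_trials_loss: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        for stream in (self.win_p_shapeA, self.loss_p_shapeA):
            if len(stream) != self.n_trials:
                raise ValueError("per-trial probability length mismatch")


@dataclass(frozen=True)
class TrialRecord:
    """One realised trial (1-based trial index within its block)."""

    i: int
    block_index: int
    condition: str
    choice: str
    win_shape: str
    loss_shape: str

    @property
    def winout(self) -> int:
        return int(self.win_shape == "A")

    @property
    def lossout(self) -> int:
        return int(self.loss_shape == "A")

    @property
    def payoff(self) -> int:
        return payoff(self.choice, self.win_shape, self.loss_shape)


def payoff(choice: str, win_shape: str, loss_shape: str) -> int:
    """Pence collected: +10 win only, -10 loss only, 0 both or neither."""
    return 10 * int(win_shape == choice) - 10 * int(loss_shape == choice)


def _segment_lengths(
    n_trials: int, n_reversals: int, p_high: float, min_segment: int, rng: np.random.Generator
) -> list[int]:
    """Uniform draw of segment lengths with exact-count feasibility.

    Each segment must be at least ``min_segment`` trials long and must admit an
    integral favoured-shape count (``p_high * length`` integral), i.e. lengths
    are multiples of the denominator of ``p_high``.  Rejects infeasible
    arithmetic explicitly.
    """
    frac = Fraction(p_high).limit_denominator(1000)
    if abs(float(frac) - p_high) > 1e-12:
        raise ValueError(f"p_high={p_high} is not a small rational; exact counts undefined")
    g = frac.denominator
    k = n_reversals + 1
    if n_trials % g:
        raise ValueError(
            f"n_trials={n_trials} not divisible by {g}; exact {p_high:.0%} counts impossible"
        )
    m = -(-min_segment // g)  # ceil, in units of g
    total = n_trials // g
    spare = total - k * m
    if spare < 0:
        raise ValueError(
            f"cannot fit {k} segments of >= {m * g} trials into {n_trials} trials"
        )
    # stars and bars: uniform composition of `spare` into k non-negative parts
    if k == 1:
        parts = np.array([spare])
    else:
        bars = np.sort(rng.choice(spare + k - 1, size=k - 1, replace=False))
        parts = np.diff(np.concatenate(([-1], bars, [spare + k - 1]))) - 1
    return [(m + int(p)) * g for p in parts]


def _volatile_stream(
    n_trials: int, p_high: float, n_reversals: int, min_segment: int, rng: np.random.Generator
) -> tuple[np.ndarray, tuple[int, ...]]:
    lengths = _segment_lengths(n_trials, n_reversals, p_high, min_segment, rng)
    p_low = float(1 - Fraction(p_high).limit_denominator(1000))  # exact complement
    favoured_a = bool(rng.integers(2))  # initial favoured shape
    p = np.empty(n_trials)
    reversals = []
    start = 0
    for j, length in enumerate(lengths):
        if j > 0:
            reversals.append(start + 1)  # 1-based first trial of the new segment
        p[start : start + length] = p_high if favoured_a else p_low
        favoured_a = not favoured_a
        start += length
    return p, tuple(reversals)


def make_block_schedule(
    condition: str,
    n_trials: int = N_TRIALS_PER_BLOCK,
    p_high: float = 0.8,
    n_reversals: int = 3,
    min_segment: int = 14,
    seed: int | np.random.Generator = 0,
) -> BlockSchedule:
    """Draw a block schedule with reversing 80/20 (or flat 50/50) streams."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if not (0.5 < p_high <= 1.0):
        raise ValueError("p_high must lie in (0.5, 1]")
    if n_trials % 2:
        raise ValueError("n_trials must be even for an exactly balanced 50/50 stream")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flat = np.full(n_trials, 0.5)
    if condition == "wins-volatile":
        win_p, rev_w = _volatile_stream(n_trials, p_high, n_reversals, min_segment, rng)
        loss_p, rev_l = flat, ()
    elif condition == "losses-volatile":
        win_p, rev_w = flat, ()
        loss_p, rev_l = _volatile_stream(n_trials, p_high, n_reversals, min_segment, rng)
    else:  # both-volatile: independent reversal schedules per stream
        win_p, rev_w = _volatile_stream(n_trials, p_high, n_reversals, min_segment, rng)
        loss_p, rev_l = _volatile_stream(n_trials, p_high, n_reversals, min_segment, rng)
    return BlockSchedule(condition, n_trials, win_p, loss_p, rev_w, rev_l)


def realize_outcomes(
    schedule: BlockSchedule, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Assign outcomes to shapes with exact per-segment counts.

    Returns boolean arrays (win on shape A, loss on shape A).  Within each
    constant-probability segment of a volatile stream exactly ``p * length``
    trials put the outcome on shape A; a 50/50 stream is balanced over the
    whole block.  Positions are shuffled uniformly.
    """

    def realise(p: np.ndarray) -> np.ndarray:
        out = np.empty(len(p), dtype=bool)
        boundaries = np.flatnonzero(np.diff(p)) + 1
        for lo, hi in zip(np.r_[0, boundaries], np.r_[boundaries, len(p)]):
            length = hi - lo
            count = p[lo] * length
            n_a = int(round(count))
            if abs(count - n_a) > 1e-9:
                raise ValueError(f"non-integral outcome count {count} in segment {lo}:{hi}")
            seg = np.zeros(length, dtype=bool)
            seg[:n_a] = True
            out[lo:hi] = rng.permutation(seg)
        return out

    return realise(schedule.win_p_shapeA), realise(schedule.loss_p_shapeA)


# ---------------------------------------------------------------------------
# sessions


@dataclass(frozen=True)
class SessionDesign:
    """Six ordered block schedules plus stimulation metadata (pass-through)."""

    group: str
    stim: str
    block_order: str
    blocks: tuple[BlockSchedule, ...]
    stim_blocks: frozenset[int]
    pre_task_stim: bool = False

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(b.condition for b in self.blocks)


def session_conditions(block_order: str) -> tuple[str, ...]:
    """Block conditions in protocol order for a given counterbalancing arm."""
    if block_order == "wins-first":
        middle = ("wins-volatile", "losses-volatile", "wins-volatile", "losses-volatile")
    elif block_order == "losses-first":
        middle = ("losses-volatile", "wins-volatile", "losses-volatile", "wins-volatile")
    else:
        raise ValueError(f"unknown block order {block_order!r}")
    return ("both-volatile",) + middle + ("both-volatile",)


def make_session_design(
    group: str,
    stim: str,
    block_order: str,
    seed: int | np.random.Generator = 0,
    n_trials: int = N_TRIALS_PER_BLOCK,
    p_high: float = 0.8,
    n_reversals: int = 3,
    min_segment: int = 14,
) -> SessionDesign:
    """Assemble the six-block protocol with fresh schedules for each block."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    if stim not in ("real", "sham"):
        raise ValueError(f"unknown stim label {stim!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    blocks = tuple(
        make_block_schedule(cond, n_trials, p_high, n_reversals, min_segment, rng)
        for cond in session_conditions(block_order)
    )
    stim_blocks = frozenset({2, 3}) if group == "during-task" else frozenset()
    return SessionDesign(
        group=group,
        stim=stim,
        block_order=block_order,
        blocks=blocks,
        stim_blocks=stim_blocks,
        pre_task_stim=(group == "before-task"),
    )


# ---------------------------------------------------------------------------
# agents


def simulate_agent(
    params: AgentParams | list[AgentParams],
    design: SessionDesign,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate one session of choices under the winning model.

    ``params`` is one :class:`AgentParams` for all blocks or a list with one
    entry per block.  Both outcome streams are realised from the schedule and
    update the latent state every trial (full feedback); the state resets to
    (0.5, 0.5) at each block start.  Returns a trial table with the canonical
    columns.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if isinstance(params, AgentParams):
        params = [params] * len(design.blocks)
    if len(params) != len(design.blocks):
        raise ValueError(f"{len(params)} parameter sets for {len(design.blocks)} blocks")
    rows = []
    for b, (schedule, p) in enumerate(zip(design.blocks, params), start=1):
        win_a, loss_a = realize_outcomes(schedule, rng)
        state = LatentState(0.5, 0.5)
        u = rng.random(schedule.n_trials)
        for i in range(schedule.n_trials):
            p_a = choice_probability(state, p.beta_win, p.beta_loss)
            choice = "A" if u[i] < p_a else "B"
            ws = "A" if win_a[i] else "B"
            ls = "A" if loss_a[i] else "B"
            rows.append(
                (
                    b,
                    schedule.condition,
                    i + 1,
                    choice,
                    ws,
                    ls,
                    int(win_a[i]),
                    int(loss_a[i]),
                    payoff(choice, ws, ls),
                )
            )
            state = update_state(state, int(win_a[i]), int(loss_a[i]), p.alpha_win, p.alpha_loss)
    return pd.DataFrame(
        rows,
        columns=[
            "block_index",
            "condition",
            "trial",
            "choice",
            "win_shape",
            "loss_shape",
            "winout",
            "lossout",
            "payoff",
        ],
    )


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class ParamDistribution:
    """Group-level generative distributions on the transformed scale.

    Learning rates are drawn around condition means (volatile vs stable
    stream) on the logit scale with a subject-level random effect shared
    across conditions; inverse temperatures are log-normal and constant across
    blocks within a subject (the winning-model structure).  ``*_win_offset``
    shifts the win-valence mean up and the loss-valence mean down by the same
    amount, for generating well-separated win/loss parameter regimes.
    """

    mu_logit_alpha_volatile: float = -0.619  # alpha ~ 0.35 when volatile
    mu_logit_alpha_stable: float = -1.735  # alpha ~ 0.15 when stable
    sd_logit_alpha: float = 0.5  # subject effect shared across conditions
    sd_logit_adjustment: float = 0.4  # subject effect on the volatile-stable gap
    mu_log_beta: float = 2.079  # beta ~ 8
    sd_log_beta: float = 0.5
    logit_alpha_win_offset: float = 0.0
    log_beta_win_offset: float = 0.0

    def __post_init__(self) -> None:
        if min(self.sd_logit_alpha, self.sd_logit_adjustment, self.sd_log_beta) < 0:
            raise ValueError("standard deviations must be >= 0")


def well_separated_distribution() -> ParamDistribution:
    """Win/loss parameters pushed apart for model-recovery exercises.

    Both valences' learning rates sit in the identifiable range (even the
    stable-stream rate produces visible estimate fluctuations) and the win
    rates/temperatures are well above the loss ones, so the dual-parameter
    structure of the generating model is maximally expressed in the choices.
    """
    return ParamDistribution(
        mu_logit_alpha_volatile=0.2,
        mu_logit_alpha_stable=-0.62,
        sd_logit_alpha=0.3,
        mu_log_beta=2.2,
        sd_log_beta=0.25,
        logit_alpha_win_offset=0.8,
        log_beta_win_offset=0.5,
    )


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic cohort with injectable group-level effects.

    ``sample_shift_*`` are additive natural-scale shifts on the volatile-
    condition learning rate of the given valence, applied to every session of
    low-mood groups (``during-task``/``before-task``) — they move the win/loss
    learning-rate *adjustment* by exactly that amount.  ``stim_shift_*`` are
    applied on top, only in the stimulated blocks (2-3) of real-tDCS sessions
    of the ``during-task`` group; before-task stimulation is generated with no
    effect, which is the ground truth the analyses are meant to recover.
    """

    n_subjects: int
    group: str = "healthy-baseline"
    params: ParamDistribution = field(default_factory=ParamDistribution)
    sample_shift_win: float = 0.0
    sample_shift_loss: float = 0.0
    stim_shift_win: float = 0.0
    stim_shift_loss: float = 0.0
    n_sessions: int = 2
    seed: int = 0
    n_trials: int = N_TRIALS_PER_BLOCK
    n_reversals: int = 3

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if self.n_sessions not in (1, 2):
            raise ValueError("n_sessions must be 1 or 2")


class Cohort(NamedTuple):
    trials: pd.DataFrame
    truth: pd.DataFrame
    metadata: pd.DataFrame


def _shifted_alpha(base: float, shift: float, where: str) -> float:
    a = base + shift
    if not (0.0 < a < 1.0):
        raise ValueError(
            f"injected shift {shift:+.3f} pushes {where} learning rate to {a:.3f}, outside (0,1)"
        )
    return a


def _questionnaires(rng: np.random.Generator, low_mood: bool) -> tuple[float, float]:
    # Score distributions emulate typical low-mood vs general-population samples
    if low_mood:
        bdi = float(np.clip(rng.normal(26.8, 9.7), 10, 63))
        stai = float(np.clip(rng.normal(56.9, 8.9), 20, 80))
    else:
        bdi = float(np.clip(rng.normal(4.7, 6.5), 0, 63))
        stai = float(np.clip(rng.normal(35.7, 7.2), 20, 80))
    return round(bdi), round(stai)


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Simulate a cohort: trial table, ground-truth parameters, metadata.

    Block order and (for two-session cohorts) real/sham order are
    counterbalanced across subjects.  All randomness derives from the master
    seed via per-subject spawned streams, so a fixed spec reproduces the
    cohort bit-for-bit.
    """
    ss = np.random.SeedSequence(spec.seed)
    subject_seeds = ss.spawn(spec.n_subjects)
    low_mood = spec.group in ("during-task", "before-task")
    d = spec.params

    trial_frames: list[pd.DataFrame] = []
    truth_rows = []
    meta_rows = []
    for s, sseed in enumerate(subject_seeds):
        rng = np.random.default_rng(sseed)
        subject_id = f"{spec.group}-{s + 1:03d}"
        block_order = "wins-first" if s % 2 == 0 else "losses-first"
        stim_order = ("sham", "real") if (s // 2) % 2 == 0 else ("real", "sham")
        # subject heterogeneity bounded at +/- 2 SD: keeps agents inside the
        # plausible range and additive effect injections feasible
        z_win, z_loss = np.clip(
            rng.normal(0.0, d.sd_logit_alpha, 2), -2 * d.sd_logit_alpha, 2 * d.sd_logit_alpha
        )
        # individual differences in volatility adaptation itself: widens or
        # narrows the volatile-stable gap per valence
        g_win, g_loss = np.clip(
            rng.normal(0.0, d.sd_logit_adjustment, 2),
            -2 * d.sd_logit_adjustment,
            2 * d.sd_logit_adjustment,
        )
        beta_win = float(np.exp(rng.normal(d.mu_log_beta + d.log_beta_win_offset, d.sd_log_beta)))
        beta_loss = float(np.exp(rng.normal(d.mu_log_beta - d.log_beta_win_offset, d.sd_log_beta)))
        bdi, stai = _questionnaires(rng, low_mood)
        meta_rows.append(
            (subject_id, spec.group, block_order, stim_order[0], bdi, stai)
        )

        base = {
            "win": {
                "volatile": expit(
                    d.mu_logit_alpha_volatile + d.logit_alpha_win_offset + z_win + g_win / 2
                ),
                "stable": expit(
                    d.mu_logit_alpha_stable + d.logit_alpha_win_offset + z_win - g_win / 2
                ),
            },
            "loss": {
                "volatile": expit(
                    d.mu_logit_alpha_volatile - d.logit_alpha_win_offset + z_loss + g_loss / 2
                ),
                "stable": expit(
                    d.mu_logit_alpha_stable - d.logit_alpha_win_offset + z_loss - g_loss / 2
                ),
            },
        }
        sample_shift = {"win": spec.sample_shift_win, "loss": spec.sample_shift_loss}
        stim_shift = {"win": spec.stim_shift_win, "loss": spec.stim_shift_loss}

        for sess in range(1, spec.n_sessions + 1):
            stim = stim_order[sess - 1] if spec.n_sessions == 2 else "sham"
            design = make_session_design(
                spec.group,
                stim,
                block_order,
                seed=rng,
                n_trials=spec.n_trials,
                n_reversals=spec.n_reversals,
            )
            stim_active = spec.group == "during-task" and stim == "real"
            block_params = []
            for b, schedule in enumerate(design.blocks, start=1):
                volatile = {
                    "win": schedule.condition in ("both-volatile", "wins-volatile"),
                    "loss": schedule.condition in ("both-volatile", "losses-volatile"),
                }
                alphas = {}
                for v in ("win", "loss"):
                    cond = "volatile" if volatile[v] else "stable"
                    a = base[v][cond]
                    if volatile[v] and low_mood:
                        a = _shifted_alpha(a, sample_shift[v], f"{v} (sample shift)")
                    if volatile[v] and stim_active and b in design.stim_blocks:
                        a = _shifted_alpha(a, stim_shift[v], f"{v} (stim shift)")
                    alphas[v] = a
                block_params.append(
                    AgentParams(alphas["win"], alphas["loss"], beta_win, beta_loss)
                )
                truth_rows.append(
                    (
                        subject_id,
                        sess,
                        b,
                        schedule.condition,
                        alphas["win"],
                        alphas["loss"],
                        beta_win,
                        beta_loss,
                    )
                )
            trials = simulate_agent(block_params, design, seed=rng)
            trials.insert(0, "stim", stim)
            trials.insert(0, "session", sess)
            trials.insert(0, "group", spec.group)
            trials.insert(0, "subject_id", subject_id)
            trial_frames.append(trials)

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "subject_id",
            "session",
            "block_index",
            "condition",
            "alpha_win",
            "alpha_loss",
            "beta_win",
            "beta_loss",
        ],
    )
    metadata = pd.DataFrame(
        meta_rows,
        columns=["subject_id", "group", "block_order", "first_session_stim", "bdi", "stai"],
    )
    return Cohort(pd.concat(trial_frames, ignore_index=True), truth, metadata)
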