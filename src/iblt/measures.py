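"""Derived learning-rate-adjustment measures with per-analysis block selection.

The outcome measures are built from fitted block-wise learning rates:

* ``win learning rate adjustment``  = win LR (wins-volatile) - win LR (losses-volatile)
* ``loss learning rate adjustment`` = loss LR (losses-volatile) - loss LR (wins-volatile)
* ``learning rate adjustment bias`` = loss adjustment - win adjustment

Positive adjustments mean the rate was up-regulated when its outcome stream
was volatile (informative); a negative bias means losses were adjusted less
than wins.  Two analysis windows exist: the stimulation analyses use blocks
2-3 only (the stimulated/immediately-post-stimulation blocks), while the
group-contrast analysis uses both halves of the session (blocks 1-3 and 4-6,
each containing one block of every volatility condition) so Time can enter
the ANOVA as a factor.
"""

from __future__ import annotations

from typing import NamedTuple

import pandas as pd

__all__ = [
    "Adjustments",
    "adjustment_from_rates",
    "select_blocks",
    "measures_table",
    "rates_table",
]


class Adjustments(NamedTuple):
    win_adjustment: float
    loss_adjustment: float
    bias: float


def adjustment_from_rates(
    win_lr_winsvol: float,
    win_lr_lossesvol: float,
    loss_lr_lossesvol: float,
    loss_lr_winsvol: float,
) -> Adjustments:
    """Adjustment measures from four condition-labelled learning rates."""
    win_adj = win_lr_winsvol - win_lr_lossesvol
    loss_adj = loss_lr_lossesvol - loss_lr_winsvol
    return Adjustments(win_adj, loss_adj, loss_adj - win_adj)


HALVES = {1: (1, 2, 3), 2: (4, 5, 6)}


def _one_block(session: pd.DataFrame, condition: str, blocks: tuple[int, ...]) -> pd.Series:
    sel = session[
        session["condition"].eq(condition) & session["block_index"].isin(blocks)
    ]
    if len(sel) != 1:
        raise ValueError(
            f"expected exactly one {condition} block among blocks {blocks}, found {len(sel)}"
        )
    return sel.iloc[0]


def select_blocks(session_fits: pd.DataFrame, analysis: str) -> pd.DataFrame:
    """Condition-labelled learning rates for one subject-session.

    ``session_fits`` needs one row per block with columns ``block_index``,
    ``condition``, ``alpha_win``, ``alpha_loss``.  For ``analysis="tdcs"``
    returns a single row taken from blocks 2-3 (whichever of the pair is
    wins-volatile supplies the wins-volatile rates, etc.); for
    ``analysis="low-mood"`` returns one row per session half.  Missing blocks
    are rejected.
    """
    required = {"block_index", "condition", "alpha_win", "alpha_loss"}
    if not required.issubset(session_fits.columns):
        raise ValueError(f"session fits must carry columns {sorted(required)}")
    present = set(session_fits["block_index"])
    if analysis == "tdcs":
        missing = {2, 3} - present
        if missing:
            raise ValueError(f"missing blocks {sorted(missing)} for the tdcs window")
        wins = _one_block(session_fits, "wins-volatile", (2, 3))
        losses = _one_block(session_fits, "losses-volatile", (2, 3))
        return pd.DataFrame(
            [
                {
                    "window": "blocks-2-3",
                    "half": 0,
                    "win_lr_winsvol": wins["alpha_win"],
                    "win_lr_lossesvol": losses["alpha_win"],
                    "loss_lr_lossesvol": losses["alpha_loss"],
                    "loss_lr_winsvol": wins["alpha_loss"],
                }
            ]
        )
    if analysis == "low-mood":
        missing = set(range(1, 7)) - present
        if missing:
            raise ValueError(f"missing blocks {sorted(missing)} for the per-half window")
        rows = []
        for half, blocks in HALVES.items():
            wins = _one_block(session_fits, "wins-volatile", blocks)
            losses = _one_block(session_fits, "losses-volatile", blocks)
            rows.append(
                {
                    "window": "per-half",
                    "half": half,
                    "win_lr_winsvol": wins["alpha_win"],
                    "win_lr_lossesvol": losses["alpha_win"],
                    "loss_lr_lossesvol": losses["alpha_loss"],
                    "loss_lr_winsvol": wins["alpha_loss"],
                }
            )
        return pd.DataFrame(rows)
    raise ValueError(f"unknown analysis window {analysis!r}")


def measures_table(fits: pd.DataFrame, analysis: str) -> pd.DataFrame:
    """Adjustment measures for every subject-session in a fitted-rate table.

    ``fits`` is the block-wise fitted parameter table (one row per subject x
    session x block) carrying a ``condition`` column.  Returns one row per
    subject-session (and per half for the ``low-mood`` window) with
    ``win_adjustment``, ``loss_adjustment`` and ``bias``.
    """
    rows = []
    for (sid, sess), g in fits.groupby(["subject_id", "session"], sort=True):
        sel = select_blocks(g, analysis)
        for _, r in sel.iterrows():
            adj = adjustment_from_rates(
                r["win_lr_winsvol"],
                r["win_lr_lossesvol"],
                r["loss_lr_lossesvol"],
                r["loss_lr_winsvol"],
            )
            rows.append(
                {
                    "subject_id": sid,
                    "session": sess,
                    "window": r["window"],
                    "half": int(r["half"]),
                    "win_adjustment": adj.win_adjustment,
                    "loss_adjustment": adj.loss_adjustment,
                    "bias": adj.bias,
                }
            )
    return pd.DataFrame(rows)


def rates_table(fits: pd.DataFrame, analysis: str = "low-mood") -> pd.DataFrame:
    """Long table of learning rates by Valence x Volatility (x Time).

    Feeds the learning-rates ANOVA: one row per subject-session x valence x
    volatility condition (x half for the per-half window; blocks 2-3 only for
    the tdcs window, where the both-volatile condition does not occur).
    """
    rows = []
    for (sid, sess), g in fits.groupby(["subject_id", "session"], sort=True):
        if analysis == "tdcs":
            blocks = g[g["block_index"].isin((2, 3))]
            halves = {0: blocks}
        elif analysis == "low-mood":
            halves = {h: g[g["block_index"].isin(b)] for h, b in HALVES.items()}
        else:
            raise ValueError(f"unknown analysis window {analysis!r}")
        for half, sub in halves.items():
            for _, blk in sub.iterrows():
                for valence, col in (("win", "alpha_win"), ("loss", "alpha_loss")):
                    rows.append(
                        {
                            "subject_id": sid,
                            "session": sess,
                            "half": half,
                            "volatility": blk["condition"],
                            "valence": valence,
                            "learning_rate": blk[col],
                        }
                    )
    return pd.DataFrame(rows)
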