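"""Model-free validation: lagged logistic regression of choice on outcome history.

Each choice is predicted from the win and loss outcome assignments of the
previous three trials::

    Choice(n) ~ win(n-1) + loss(n-1) + win(n-2) + loss(n-2) + win(n-3) + loss(n-3)

The response is 1 if shape A was chosen; outcome regressors are coded +0.5 if
the outcome was assigned to shape A and -0.5 otherwise, which makes the fitted
weights invariant to relabelling the shapes.  Lags never cross block
boundaries, so the first three trials of every block are dropped.  The lag-1
weights are the model-free analogue of learning rates (a larger learning rate
concentrates weight on the most recent outcome), and their volatile-minus-
stable condition differences mirror the learning-rate adjustment measures.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .measures import Adjustments

__all__ = [
    "build_lagged_design",
    "fit_choice_regression",
    "condition_weights",
    "weight_adjustment",
    "weight_adjustment_table",
]

N_LAGS = 3
REGRESSORS = [f"{v}_lag{k}" for k in range(1, N_LAGS + 1) for v in ("win", "loss")]


def build_lagged_design(trials: pd.DataFrame, n_lags: int = N_LAGS) -> pd.DataFrame:
    """Lagged design rows for every block in a trial table.

    Requires columns ``block_index``, ``trial``, ``choice``, ``winout``,
    ``lossout`` (plus ``condition``, carried through).  Returns one row per
    trial with ``n_lags`` predecessors in the same block: the centred outcome
    codes of trials n-1 .. n-lags and the binary response.
    """
    frames = []
    for _, g in trials.groupby("block_index", sort=True):
        g = g.sort_values("trial")
        if len(g) <= n_lags:
            raise ValueError(f"block needs more than {n_lags} trials")
        win = g["winout"].to_numpy(dtype=float) - 0.5
        loss = g["lossout"].to_numpy(dtype=float) - 0.5
        out = {
            "block_index": g["block_index"].to_numpy()[n_lags:],
            "trial": g["trial"].to_numpy()[n_lags:],
            "response": (g["choice"].to_numpy() == "A").astype(int)[n_lags:],
        }
        if "condition" in g:
            out["condition"] = g["condition"].to_numpy()[n_lags:]
        for k in range(1, n_lags + 1):
            out[f"win_lag{k}"] = win[n_lags - k : -k]
            out[f"loss_lag{k}"] = loss[n_lags - k : -k]
        frames.append(pd.DataFrame(out))
    return pd.concat(frames, ignore_index=True)


def fit_choice_regression(design: pd.DataFrame, ridge_alpha: float = 1.0) -> pd.Series:
    """Maximum-likelihood logistic weights for one design table.

    On perfect separation (or non-convergence) the fit is repeated with an L2
    ridge penalty and a warning; the intercept is fitted but not returned.
    """
    X = sm.add_constant(design[REGRESSORS].to_numpy(), has_constant="add")
    y = design["response"].to_numpy()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # PerfectSeparationWarning -> except
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        params = res.params
        if not np.all(np.isfinite(params)) or np.abs(params).max() > 50:
            raise RuntimeError("implausible weights, likely separation")
    except Exception:
        warnings.warn("separation or non-convergence; refitting with ridge penalty")
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(C=1.0 / ridge_alpha, solver="lbfgs", max_iter=1000)
        lr.fit(X[:, 1:], y)
        params = np.concatenate([lr.intercept_, lr.coef_.ravel()])
    return pd.Series(params[1:], index=REGRESSORS)


def condition_weights(
    trials: pd.DataFrame, pool_blocks: bool = True, ridge_alpha: float = 1.0,
    blocks: tuple[int, ...] | None = None,
) -> pd.DataFrame:
    """Per-condition lagged-regression weights for one subject-session.

    ``pool_blocks=True`` stacks the design rows of all blocks sharing a
    condition into one regression; otherwise blocks are fitted separately and
    the weights averaged per condition.  ``blocks`` restricts the analysis
    window (e.g. ``(2, 3)`` for the stimulation blocks).
    """
    t = trials if blocks is None else trials[trials["block_index"].isin(blocks)]
    design = build_lagged_design(t)
    rows = []
    if pool_blocks:
        for cond, g in design.groupby("condition", sort=True):
            w = fit_choice_regression(g, ridge_alpha)
            rows.append({"condition": cond, **w.to_dict()})
    else:
        per_block = []
        for (cond, b), g in design.groupby(["condition", "block_index"], sort=True):
            w = fit_choice_regression(g, ridge_alpha)
            per_block.append({"condition": cond, **w.to_dict()})
        rows = (
            pd.DataFrame(per_block).groupby("condition", as_index=False).mean().to_dict("records")
        )
    return pd.DataFrame(rows)


def weight_adjustment(weights: pd.DataFrame) -> Adjustments:
    """Volatile-minus-stable adjustment of the lag-1 weights.

    Mirrors the learning-rate adjustment definitions: the win weight
    adjustment is the lag-1 win weight in the wins-volatile condition minus
    that in the losses-volatile condition; the loss analogue is mirrored; the
    bias is loss minus win adjustment.  Under the shape-A outcome coding a
    recent loss on a shape pushes choice *away* from it, so the raw lag-1
    loss coefficient is negative; its influence magnitude (the negated
    coefficient) is the quantity analogous to the loss learning rate.
    """
    idx = weights.set_index("condition")
    for cond in ("wins-volatile", "losses-volatile"):
        if cond not in idx.index:
            raise ValueError(f"weights for condition {cond!r} missing")
    win_adj = float(idx.loc["wins-volatile", "win_lag1"] - idx.loc["losses-volatile", "win_lag1"])
    loss_adj = float(
        -idx.loc["losses-volatile", "loss_lag1"] + idx.loc["wins-volatile", "loss_lag1"]
    )
    return Adjustments(win_adj, loss_adj, loss_adj - win_adj)


def weight_adjustment_table(
    trials: pd.DataFrame, blocks: tuple[int, ...] | None = None, pool_blocks: bool = True
) -> pd.DataFrame:
    """Weight-adjustment measures for every subject-session in a trial table."""
    rows = []
    for (sid, sess), g in trials.groupby(["subject_id", "session"], sort=True):
        adj = weight_adjustment(condition_weights(g, pool_blocks=pool_blocks, blocks=blocks))
        rows.append(
            {
                "subject_id": sid,
                "session": sess,
                "win_weight_adjustment": adj.win_adjustment,
                "loss_weight_adjustment": adj.loss_adjustment,
                "weight_bias": adj.bias,
            }
        )
    return pd.DataFrame(rows)
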