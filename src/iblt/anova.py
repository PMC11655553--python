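"""Mixed-design repeated-measures ANOVA for arbitrary factorial layouts.

Univariate mixed-model ANOVA computed the way dedicated repeated-measures
packages do it: the subject x within-cell matrix is projected onto orthonormal
within-subject contrasts (one set per within effect, Kronecker products across
factors), and each projected column set is analysed with an ordinary
least-squares model over the between-subject factors using Type III sums of
squares with sum-to-zero coding.  This supports any number of crossed within
and between factors with 2+ levels, handles unbalanced between-group sizes,
and yields Greenhouse-Geisser epsilon for within effects with more than one
degree of freedom (from the residual covariance of the contrast scores).

Subjects with incomplete within-cells are dropped listwise (and logged);
multiple observations per subject-cell are averaged first.
"""

from __future__ import annotations

import logging
from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["rm_anova"]

log = logging.getLogger(__name__)


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k x (k-1) orthonormal basis of the space orthogonal to the constant."""
    q, _ = np.linalg.qr(np.column_stack([np.ones(k), np.eye(k)[:, :-1]]))
    return q[:, 1:]


def _sum_coding(levels: list) -> dict:
    """Level -> deviation-coded row ((k-1) columns, last level = -1)."""
    k = len(levels)
    rows = np.vstack([np.eye(k - 1), -np.ones((1, k - 1))])
    return {lv: rows[i] for i, lv in enumerate(levels)}


def _rss(X: np.ndarray, Y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return float(np.sum(resid**2))


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    within: list[str] | tuple[str, ...] = (),
    between: list[str] | tuple[str, ...] = (),
) -> pd.DataFrame:
    """F, df, p (and GG-corrected p) for every main effect and interaction.

    Returns one row per effect with columns ``effect, df1, df2, F, p,
    partial_eta_sq, gg_eps, p_gg`` (the GG columns are NaN for effects whose
    within-part has a single degree of freedom, where no correction applies).
    """
    within, between = list(within), list(between)
    if not within and not between:
        raise ValueError("need at least one factor")
    cols = [subject, dv, *within, *between]
    d = data[cols].dropna()

    # one value per subject x within-cell; average replicates
    d = d.groupby([subject, *within, *between], as_index=False, observed=True)[dv].mean()

    w_levels = {f: sorted(d[f].unique()) for f in within}
    b_levels = {f: sorted(d[f].unique()) for f in between}
    for f, lv in {**w_levels, **b_levels}.items():
        if len(lv) < 2:
            raise ValueError(f"factor {f!r} has fewer than 2 levels")

    cells = list(product(*(w_levels[f] for f in within))) if within else [()]
    if within:
        wide = d.pivot_table(index=subject, columns=within, values=dv, observed=True)
        # enforce canonical cell order
        wide = wide.reindex(
            columns=[c if len(within) > 1 else c[0] for c in cells]
        )
        complete = wide.dropna()
        n_dropped = len(wide) - len(complete)
        if n_dropped:
            log.warning(
                "rm_anova: dropping %d subject(s) with incomplete within-cells", n_dropped
            )
        P = complete.to_numpy(dtype=float)
        subjects = complete.index
    else:
        wide = d.set_index(subject)[[dv]]
        P = wide.to_numpy(dtype=float)
        subjects = wide.index
    n = len(subjects)
    if n < 3:
        raise ValueError("need at least 3 complete subjects")

    # between design (Type III: sum-to-zero coding, full factorial)
    if between:
        bmeta = d.drop_duplicates(subject).set_index(subject).loc[subjects, between]
        for combo, g in bmeta.groupby(between, observed=True):
            if g.empty:
                raise ValueError(f"empty between-factor cell {combo}")
        codings = {f: _sum_coding(b_levels[f]) for f in between}
        # verify no empty cells in the full crossing
        counts = bmeta.value_counts(between)
        if len(counts) < int(np.prod([len(b_levels[f]) for f in between])):
            raise ValueError("empty cell in the between-factor crossing")
    X_terms: dict[tuple, np.ndarray] = {(): np.ones((n, 1))}
    for r in range(1, len(between) + 1):
        for T in combinations(between, r):
            mats = []
            for f in T:
                coded = np.vstack([codings[f][v] for v in bmeta[f]])
                mats.append(coded)
            cols_T = mats[0]
            for m in mats[1:]:
                cols_T = np.einsum("ni,nj->nij", cols_T, m).reshape(n, -1)
            X_terms[tuple(T)] = cols_T
    X_full = np.hstack(list(X_terms.values()))
    rank_X = np.linalg.matrix_rank(X_full)

    # within contrast sets
    w_contrasts = {f: _orthonormal_contrasts(len(w_levels[f])) for f in within}
    w_avg = {f: np.full((len(w_levels[f]), 1), 1.0 / len(w_levels[f])) for f in within}

    def within_projection(S: tuple[str, ...]) -> np.ndarray:
        M = np.ones((1, 1))
        for f in within:
            M = np.kron(M, w_contrasts[f] if f in S else w_avg[f])
        return M

    rows = []
    w_subsets = [()]
    for r in range(1, len(within) + 1):
        w_subsets += list(combinations(within, r))
    b_subsets = list(X_terms.keys())  # includes ()

    for S in w_subsets:
        M = within_projection(S) if within else np.ones((1, 1))
        Y = P @ M
        d_w = Y.shape[1]
        rss_full = _rss(X_full, Y)
        df_err = (n - rank_X) * d_w
        # GG epsilon from residual covariance of the contrast scores
        gg_eps = np.nan
        if d_w > 1:
            beta, *_ = np.linalg.lstsq(X_full, Y, rcond=None)
            E = Y - X_full @ beta
            Sigma = E.T @ E / (n - rank_X)
            gg_eps = float(np.trace(Sigma) ** 2 / (d_w * np.sum(Sigma * Sigma)))
        for T in b_subsets:
            if not S and not T:
                continue  # grand mean
            reduced = [m for key, m in X_terms.items() if key != T]
            rss_red = _rss(np.hstack(reduced), Y) if reduced else float(np.sum(Y**2))
            ss_h = rss_red - rss_full
            df_h = X_terms[T].shape[1] * d_w
            # degenerate stratum (dv constant in these cells): define F = 0
            tiny = 1e-12 * max(1.0, float(np.sum(P**2)))
            if ss_h < tiny and rss_full < tiny:
                ss_h, rss_full_eff = 0.0, np.inf
            else:
                rss_full_eff = rss_full
            F = (ss_h / df_h) / (rss_full_eff / df_err) if np.isfinite(rss_full_eff) else 0.0
            p = float(sps.f.sf(F, df_h, df_err))
            p_gg = (
                float(sps.f.sf(F, gg_eps * df_h, gg_eps * df_err))
                if d_w > 1
                else np.nan
            )
            rows.append(
                {
                    "effect": " x ".join([*T, *S]),
                    "df1": df_h,
                    "df2": df_err,
                    "F": float(F),
                    "p": p,
                    "partial_eta_sq": float(ss_h / (ss_h + rss_full)),
                    "gg_eps": gg_eps,
                    "p_gg": p_gg,
                    "n": n,
                }
            )
    return pd.DataFrame(rows)
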