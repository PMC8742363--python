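"""Session-level aggregation and small-sample correlation/paired statistics.

Per-segment jumping-jack metrics are averaged into one summary per
(participant, session); change scores are the session-6 minus session-1
differences of those means.  The analysis layer correlates change scores
with external outcome deltas (e.g. pre/post clinical totals treated as
plain numeric columns) using Spearman's rho, and compares paired pre/post
vectors with the Wilcoxon signed-rank test.

Both statistical kernels default to *exact* small-sample p-values — full
permutation enumeration for Spearman (n ≤ 10) and full sign-assignment
enumeration for Wilcoxon (n ≤ 12) — because the study design has on the
order of ten participants, where asymptotic approximations are unreliable.
Larger samples fall back to the standard t- and normal approximations
(with tie and continuity corrections for Wilcoxon).
"""

from __future__ import annotations

import itertools
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sst

from .errors import ParameterError, UndefinedStatisticError
from .jj_metrics import MEASURES

__all__ = [
    "summarize_sessions",
    "change_scores",
    "spearman_rho",
    "wilcoxon_signed_rank",
    "correlation_table",
    "MEASURES",
]

logger = logging.getLogger(__name__)

EXACT_SPEARMAN_N = 10
EXACT_WILCOXON_N = 12


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def summarize_sessions(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-(participant, session) means of the 11 measures.

    ``metrics`` is the per-segment table (columns ``participant``,
    ``session``, plus the measures); NaN (undefined) values are excluded
    from their mean, and ``n_<measure>`` columns count the defined values.
    """
    required = {"participant", "session"}
    if not required.issubset(metrics.columns):
        raise ParameterError(f"metrics table must carry columns {required}")
    grouped = metrics.groupby(["participant", "session"], sort=True)
    means = grouped[list(MEASURES)].mean()  # pandas mean skips NaN
    counts = grouped[list(MEASURES)].count().rename(
        columns={m: f"n_{m}" for m in MEASURES}
    )
    return pd.concat([means, counts], axis=1).reset_index()


def change_scores(
    summaries: pd.DataFrame, first: int = 1, last: int = 6
) -> pd.DataFrame:
    """Session ``last`` minus session ``first`` change per participant.

    Participants missing either session are excluded with a logged notice.
    """
    out_rows = []
    for pid, grp in summaries.groupby("participant"):
        by_sess = grp.set_index("session")
        if first not in by_sess.index or last not in by_sess.index:
            logger.info(
                "participant %s excluded from change scores: needs sessions "
                "%d and %d", pid, first, last,
            )
            continue
        row = {"participant": pid}
        for m in MEASURES:
            row[m] = by_sess.loc[last, m] - by_sess.loc[first, m]
        out_rows.append(row)
    return pd.DataFrame(out_rows, columns=["participant", *MEASURES])


# ---------------------------------------------------------------------------
# Spearman's rho with exact permutation p-value
# ---------------------------------------------------------------------------

_perm_cache: dict[tuple, np.ndarray] = {}


def _rank(x: np.ndarray) -> np.ndarray:
    return sst.rankdata(x, method="average")


def _perm_null_sums(rx: np.ndarray, ry: np.ndarray) -> np.ndarray:
    """Null distribution of Σ rx·σ(ry) over all permutations σ (cached by
    the rank multisets, which fully determine it)."""
    key = (tuple(np.sort(rx)), tuple(np.sort(ry)))
    hit = _perm_cache.get(key)
    if hit is not None:
        return hit
    chunks = []
    it = itertools.permutations(ry)
    while True:
        block = list(itertools.islice(it, 200_000))
        if not block:
            break
        chunks.append(np.asarray(block) @ rx)
    sums = np.concatenate(chunks)
    _perm_cache[key] = sums
    return sums


def spearman_rho(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    rho is the product-moment correlation of average ranks (ties averaged).
    ``method='exact'`` (default for n ≤ 10) enumerates all permutations of
    one rank vector; ``'approx'`` uses the t approximation
    ``t = rho·sqrt((n−2)/(1−rho²))`` on n−2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be equal-length vectors")
    n = len(x)
    if n < 4:
        raise ParameterError(f"need n >= 4, got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ParameterError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError(
            "correlation undefined for zero-variance input"
        )
    rx, ry = _rank(x), _rank(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if method == "auto":
        method = "exact" if n <= EXACT_SPEARMAN_N else "approx"
    if method == "exact":
        # rho is a monotone affine function of Σ rx·ry, so tail counts on
        # the sum translate directly to tail counts on rho
        sums = _perm_null_sums(rx, ry)
        obs = float(rx @ ry)
        center = n * (n + 1) ** 2 / 4.0  # E[Σ rx·σ(ry)] = n·mean(rx)·mean(ry)
        dev = abs(obs - center)
        p = float(np.mean(np.abs(sums - center) >= dev - 1e-9))
    elif method == "approx":
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * sst.t.sf(abs(t), df=n - 2))
    else:
        raise ParameterError(f"unknown method {method!r}")
    return rho, p


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank with exact enumeration p-value
# ---------------------------------------------------------------------------


def _signed_rank_stats(d: np.ndarray) -> tuple[np.ndarray, float, float]:
    """(ranks of |d|, T+, T−) after dropping zero differences."""
    ranks = _rank(np.abs(d))
    t_plus = float(np.sum(ranks[d > 0]))
    t_minus = float(np.sum(ranks[d < 0]))
    return ranks, t_plus, t_minus


def _exact_tplus_tail(ranks: np.ndarray, t_plus: float, tail: str) -> float:
    """Exact tail probability of T+ under the null by enumerating all 2^n
    sign assignments via dynamic programming on integerized ranks."""
    # average ranks are multiples of 0.5 → double to integers
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    # dist[s] = number of sign assignments with doubled T+ equal to s
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    obs = int(np.rint(2.0 * t_plus))
    if tail == "ge":
        return float(dist[obs:].sum())
    return float(dist[: obs + 1].sum())


def wilcoxon_signed_rank(
    pre: Sequence[float],
    post: Sequence[float],
    alternative: str = "two-sided",
    method: str = "auto",
) -> tuple[float, float, float]:
    """Wilcoxon signed-rank test for paired samples.

    Returns ``(W, z, p)`` where ``W = min(T+, T−)`` and ``z`` is the
    normal-approximation deviate of T+ with tie and continuity corrections
    (negative when T+ is below its null mean, the usual reporting
    convention).  Zero differences are dropped.  ``alternative`` is
    ``two-sided``, ``greater`` (post > pre) or ``less``.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ParameterError("pre and post must be equal-length vectors")
    if len(pre) < 5:
        raise ParameterError(f"need n >= 5 pairs, got {len(pre)}")
    d = post - pre
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise UndefinedStatisticError("all paired differences are zero")
    ranks, t_plus, t_minus = _signed_rank_stats(d)
    w = min(t_plus, t_minus)

    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
        tie_counts**3 - tie_counts
    ) / 48.0
    sd = np.sqrt(var) if var > 0 else np.nan
    cc = 0.5 * np.sign(t_plus - mean)
    z = float((t_plus - mean - cc) / sd) if sd and np.isfinite(sd) else float("nan")

    if method == "auto":
        method = "exact" if n <= EXACT_WILCOXON_N else "approx"
    if method == "exact":
        p_ge = _exact_tplus_tail(ranks, t_plus, "ge")
        p_le = _exact_tplus_tail(ranks, t_plus, "le")
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        elif alternative == "two-sided":
            p = min(1.0, 2.0 * min(p_ge, p_le))
        else:
            raise ParameterError(f"unknown alternative {alternative!r}")
    elif method == "approx":
        if alternative == "greater":
            p = float(sst.norm.sf((t_plus - mean - 0.5) / sd))
        elif alternative == "less":
            p = float(sst.norm.cdf((t_plus - mean + 0.5) / sd))
        elif alternative == "two-sided":
            p = float(2.0 * sst.norm.sf(abs(z)))
        else:
            raise ParameterError(f"unknown alternative {alternative!r}")
    else:
        raise ParameterError(f"unknown method {method!r}")
    return float(w), z, min(p, 1.0)


# ---------------------------------------------------------------------------
# Correlation table
# ---------------------------------------------------------------------------


def correlation_table(
    changes: pd.DataFrame,
    outcome_deltas: pd.DataFrame,
    min_cases: int = 4,
    method: str = "auto",
    fdr: bool = False,
) -> pd.DataFrame:
    """Spearman correlations between measure changes and outcome deltas.

    ``changes`` carries ``participant`` plus measure columns;
    ``outcome_deltas`` carries ``participant`` plus one column per outcome.
    Returns a tidy table with one row per (measure, outcome) cell: ``rho``,
    ``p``, ``n``; cells with fewer than ``min_cases`` complete cases are
    reported with NaN statistics.  ``fdr=True`` appends
    Benjamini–Hochberg-adjusted p-values (off by default; the analysis
    convention is per-cell significance).
    """
    merged = changes.merge(outcome_deltas, on="participant", how="inner")
    measures = [m for m in MEASURES if m in changes.columns]
    outcomes = [c for c in outcome_deltas.columns if c != "participant"]
    rows = []
    for outcome in outcomes:
        for m in measures:
            sub = merged[[m, outcome]].dropna()
            n = len(sub)
            if n < min_cases:
                rows.append(
                    {"measure": m, "outcome": outcome, "rho": np.nan,
                     "p": np.nan, "n": n}
                )
                continue
            try:
                rho, p = spearman_rho(
                    sub[m].to_numpy(), sub[outcome].to_numpy(), method=method
                )
            except UndefinedStatisticError:
                rho, p = np.nan, np.nan
            rows.append(
                {"measure": m, "outcome": outcome, "rho": rho, "p": p, "n": n}
            )
    table = pd.DataFrame(rows)
    if fdr:
        mask = table["p"].notna()
        adj = np.full(len(table), np.nan)
        if mask.any():
            adj[mask.to_numpy()] = sst.false_discovery_control(
                table.loc[mask, "p"].to_numpy()
            )
        table["p_fdr"] = adj
    return table
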