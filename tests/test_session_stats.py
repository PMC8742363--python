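"""Aggregation and small-sample statistics against brute-force oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitmetrics.errors import ParameterError, UndefinedStatisticError
from gaitmetrics.jj_metrics import MEASURES
from gaitmetrics.session_stats import (
    change_scores,
    correlation_table,
    spearman_rho,
    summarize_sessions,
    wilcoxon_signed_rank,
)

# ---------------------------------------------------------------------------
# Brute-force oracles (pure-python, no scipy/numpy shortcuts)
# ---------------------------------------------------------------------------


def oracle_ranks(values):
    """Average ranks computed by explicit counting."""
    out = []
    for v in values:
        less = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        out.append(less + (equal + 1) / 2.0)
    return out


def oracle_spearman(x, y):
    rx, ry = oracle_ranks(x), oracle_ranks(y)
    n = len(x)
    mx = sum(rx) / n
    my = sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    rho = num / den
    # exact two-sided permutation p-value
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        num_p = sum((a - mx) * (b - my) for a, b in zip(rx, perm))
        if abs(num_p / den) >= abs(rho) - 1e-12:
            count += 1
        total += 1
    return rho, count / total


def oracle_wilcoxon(pre, post, alternative="two-sided"):
    d = [b - a for a, b in zip(pre, post) if b != a]
    ranks = oracle_ranks([abs(v) for v in d])
    t_plus = sum(r for r, v in zip(ranks, d) if v > 0)
    n = len(d)
    ge = le = total = 0
    for signs in itertools.product([1, -1], repeat=n):
        t = sum(r for r, s in zip(ranks, signs) if s > 0)
        if t >= t_plus - 1e-12:
            ge += 1
        if t <= t_plus + 1e-12:
            le += 1
        total += 1
    if alternative == "greater":
        p = ge / total
    elif alternative == "less":
        p = le / total
    else:
        p = min(1.0, 2.0 * min(ge, le) / total)
    w = min(t_plus, sum(ranks) - t_plus)
    return w, p


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def _metrics_df(rows):
    cols = ["participant", "session", *MEASURES]
    return pd.DataFrame(rows, columns=cols)


class TestSummaries:
    def test_mean_of_identical_rows_is_the_row(self):
        row = ["P1", 1] + list(np.linspace(0.1, 1.1, 11))
        df = _metrics_df([row] * 10)
        out = summarize_sessions(df)
        assert len(out) == 1
        for i, m in enumerate(MEASURES):
            assert out.loc[0, m] == pytest.approx(row[2 + i])
            assert out.loc[0, f"n_{m}"] == 10

    def test_missing_values_excluded_from_mean(self):
        rows = [["P1", 1] + [1.0] * 11, ["P1", 1] + [3.0] * 11]
        df = _metrics_df(rows)
        df.loc[1, "H4"] = np.nan
        out = summarize_sessions(df)
        assert out.loc[0, "H4"] == pytest.approx(1.0)
        assert out.loc[0, "n_H4"] == 1
        assert out.loc[0, "K1"] == pytest.approx(2.0)

    def test_grouping_shape(self):
        rows = [
            [p, s] + [0.5] * 11
            for p in ("P1", "P2")
            for s in (1, 6)
        ]
        assert len(summarize_sessions(_metrics_df(rows))) == 4


class TestChangeScores:
    def _summaries(self, values_by_ps):
        rows = []
        for (p, s), v in values_by_ps.items():
            rows.append([p, s] + [v] * 11)
        return summarize_sessions(_metrics_df(rows))

    def test_delta_is_last_minus_first(self):
        out = change_scores(
            self._summaries({("P1", 1): 0.30, ("P1", 6): 0.40})
        )
        assert out.loc[0, "K2"] == pytest.approx(0.10)

    def test_identical_sessions_give_zero(self):
        out = change_scores(self._summaries({("P1", 1): 0.5, ("P1", 6): 0.5}))
        assert all(out.loc[0, m] == pytest.approx(0.0) for m in MEASURES)

    def test_participant_missing_last_session_excluded(self):
        out = change_scores(
            self._summaries(
                {("P1", 1): 0.2, ("P1", 6): 0.3, ("P2", 1): 0.2}
            )
        )
        assert list(out["participant"]) == ["P1"]


# ---------------------------------------------------------------------------
# Statistical kernels
# ---------------------------------------------------------------------------


class TestSpearman:
    def test_monotone_increasing_is_plus_one(self):
        x = [1.0, 2.0, 5.0, 9.0, 12.0]
        y = [0.1, 0.4, 0.5, 2.0, 11.0]
        rho, _ = spearman_rho(x, y)
        assert rho == pytest.approx(1.0)

    def test_monotone_decreasing_is_minus_one(self):
        x = [1.0, 2.0, 5.0, 9.0]
        y = [4.0, 3.0, 2.0, 1.0]
        rho, _ = spearman_rho(x, y)
        assert rho == pytest.approx(-1.0)

    def test_ties_match_rank_oracle(self):
        x = [1, 2, 2, 3, 5, 5, 6]
        y = [10, 20, 20, 40, 10, 30, 50]
        rho, p = spearman_rho(x, y)
        rho_o, p_o = oracle_spearman(x, y)
        assert rho == pytest.approx(rho_o, abs=1e-12)
        assert p == pytest.approx(p_o, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_p_matches_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=7).tolist()
        y = rng.normal(size=7).tolist()
        rho, p = spearman_rho(x, y, method="exact")
        rho_o, p_o = oracle_spearman(x, y)
        assert rho == pytest.approx(rho_o, abs=1e-12)
        assert p == pytest.approx(p_o, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 9999))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        rho1, p1 = spearman_rho(x, y)
        rho2, p2 = spearman_rho(np.exp(x), y**3 + 2 * y)
        assert rho1 == pytest.approx(rho2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestWilcoxon:
    def test_uniform_shift_n6_one_sided(self):
        pre = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        post = [v + 1.0 for v in pre]
        w, z, p = wilcoxon_signed_rank(pre, post, alternative="greater")
        assert p == pytest.approx(1.0 / 64.0, abs=1e-12)
        assert w == pytest.approx(0.0)
        assert z < 0 or z > 0  # finite

    def test_no_change_is_degenerate(self):
        v = [1.0, 2.0, 3.0, 4.0, 5.0]
        with pytest.raises(UndefinedStatisticError):
            wilcoxon_signed_rank(v, v)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_enumeration_oracle_n8(self, seed):
        rng = np.random.default_rng(seed)
        pre = rng.normal(size=8).tolist()
        post = (np.array(pre) + rng.normal(0.3, 1.0, size=8)).tolist()
        w, _, p = wilcoxon_signed_rank(pre, post)
        w_o, p_o = oracle_wilcoxon(pre, post)
        assert w == pytest.approx(w_o, abs=1e-12)
        assert p == pytest.approx(p_o, abs=1e-12)

    def test_exact_distribution_sums_to_one(self):
        from gaitmetrics.session_stats import _exact_tplus_tail

        ranks = np.array(oracle_ranks([1.0, 2.0, 2.0, 3.0, 4.0, 5.0]))
        # P(T+ >= 0) covers the whole enumeration distribution
        assert _exact_tplus_tail(ranks, 0.0, "ge") == pytest.approx(1.0)

    def test_normal_approximation_reasonable_for_large_n(self):
        rng = np.random.default_rng(4)
        pre = rng.normal(size=40)
        post = pre + rng.normal(0.5, 1.0, size=40)
        _, z, p = wilcoxon_signed_rank(pre, post, method="approx")
        from scipy import stats as sst

        res = sst.wilcoxon(post, pre, correction=True, method="approx")
        assert p == pytest.approx(res.pvalue, rel=1e-6)


class TestCorrelationTable:
    def _changes(self, k2):
        rows = []
        for i, v in enumerate(k2):
            row = {"participant": f"P{i}"}
            row.update({m: v for m in MEASURES})
            rows.append(row)
        return pd.DataFrame(rows)

    def test_noiseless_monotone_outcome_gives_rho_one(self):
        k2 = [0.1, 0.3, 0.2, 0.5, 0.4, 0.6]
        changes = self._changes(k2)
        outcomes = pd.DataFrame(
            {"participant": [f"P{i}" for i in range(6)],
             "BOT2": [v * 10 + 1 for v in k2]}
        )
        table = correlation_table(changes, outcomes)
        cell = table[(table.measure == "K2") & (table.outcome == "BOT2")]
        assert cell.iloc[0].rho == pytest.approx(1.0)

    def test_independent_outcome_has_small_rho(self):
        rng = np.random.default_rng(5)
        changes = self._changes(rng.normal(size=10).tolist())
        outcomes = pd.DataFrame(
            {"participant": [f"P{i}" for i in range(10)],
             "DCCS": rng.normal(size=10)}
        )
        table = correlation_table(changes, outcomes)
        assert abs(table[table.measure == "K2"].iloc[0].rho) < 0.8

    def test_table_shape_is_measures_by_outcomes(self):
        changes = self._changes([0.1, 0.2, 0.3, 0.4, 0.5])
        outcomes = pd.DataFrame(
            {"participant": [f"P{i}" for i in range(5)],
             "BOT2": [1, 2, 3, 4, 5], "DCCS": [5, 4, 3, 2, 1]}
        )
        table = correlation_table(changes, outcomes)
        assert len(table) == 11 * 2

    def test_insufficient_cases_marked_missing(self):
        changes = self._changes([0.1, 0.2, 0.3])
        outcomes = pd.DataFrame(
            {"participant": ["P0", "P1", "P2"], "BOT2": [1, 2, 3]}
        )
        table = correlation_table(changes, outcomes)
        assert table["rho"].isna().all()
        assert (table["n"] == 3).all()
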