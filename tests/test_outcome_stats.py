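import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pharmphen.example_tables import ICU_EXAMPLE_POOLED, icu_demographics_example
from pharmphen.outcome_stats import (
    cluster_summary,
    fisher_exact_2x2,
    holm_adjust,
    pairwise_compare,
    phenotype_profile,
    pooled_summary,
    rank_sum_test,
)
from pharmphen.rbm_phenotyping import PhenotypeAssignment


def _enumerate_rank_sum_p(x, y):
    """Oracle: exact two-sided Mann-Whitney p by enumerating every
    assignment of the pooled values to the two groups."""
    pooled = np.concatenate([x, y])
    nx = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    n = len(pooled)
    us = []
    for comb in itertools.combinations(range(n), nx):
        xs = pooled[list(comb)]
        ys = np.delete(pooled, list(comb))
        us.append(sum(1 for xi in xs for yj in ys if xi > yj))
    us = np.array(us)
    mean_u = nx * (n - nx) / 2.0
    return np.mean(np.abs(us - mean_u) >= abs(u_obs - mean_u) - 1e-12)


class TestRankSum:
    def test_worked_example(self):
        """Fully separated samples of 3 vs 3: U = 0, exact two-sided
        p = 2 / C(6,3) = 0.1."""
        u, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)

    def test_identical_samples_give_p_one(self):
        _, p = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_exact_path_matches_enumeration_oracle(self, rng):
        """All tie-free splits up to pooled n = 10 agree with full
        enumeration."""
        for n in range(2, 11):
            values = np.sort(rng.standard_normal(n))
            for nx in range(1, n):
                for comb in itertools.combinations(range(n), nx):
                    if comb[0] != 0:  # cut the orbit: same p for complements
                        break
                    x = values[list(comb)]
                    y = np.delete(values, list(comb))
                    _, p = rank_sum_test(x, y)
                    assert p == pytest.approx(_enumerate_rank_sum_p(x, y), abs=1e-12)

    def test_large_sample_matches_normal_approximation_oracle(self, rng):
        """Tie-corrected, continuity-corrected normal approximation,
        written out from the textbook formula."""
        from scipy.stats import norm, rankdata

        x = np.round(rng.standard_normal(18), 1)  # rounding forces ties
        y = np.round(rng.standard_normal(14) + 0.4, 1)
        u, p = rank_sum_test(x, y)
        nx, ny = len(x), len(y)
        ranks = rankdata(np.concatenate([x, y]))
        u_oracle = ranks[:nx].sum() - nx * (nx + 1) / 2.0
        _, counts = np.unique(np.concatenate([x, y]), return_counts=True)
        n = nx + ny
        tie_term = (counts**3 - counts).sum() / (n * (n - 1))
        sd = math.sqrt(nx * ny / 12.0 * (n + 1 - tie_term))
        z = (abs(u_oracle - nx * ny / 2.0) - 0.5) / sd
        p_oracle = 2 * norm.sf(z)
        assert u == pytest.approx(u_oracle)
        assert p == pytest.approx(min(p_oracle, 1.0), abs=1e-6)

    def test_missing_values_dropped_and_empty_rejected(self):
        _, p = rank_sum_test([1.0, np.nan, 2.0], [3.0, 4.0])
        assert 0 < p <= 1
        with pytest.raises(ValueError):
            rank_sum_test([np.nan], [1.0])


def _enumerate_fisher_p(a, b, c, d):
    """Oracle: hypergeometric enumeration over the fixed margins with
    the point-probability two-sided rule."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def table_p(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = table_p(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = table_p(x)
        if px <= p_obs * (1 + 1e-7):
            total += px
    return min(total, 1.0)


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((3, 1, 1, 3), 34 / 70),
            ((0, 5, 0, 5), 1.0),
            ((5, 0, 0, 5), 2 / math.comb(10, 5)),
        ],
    )
    def test_worked_examples(self, table, expected):
        _, p = fisher_exact_2x2(*table)
        assert p == pytest.approx(expected, abs=1e-12)

    def test_odds_ratio_and_infinite_case(self):
        orat, _ = fisher_exact_2x2(6, 2, 3, 9)
        assert orat == pytest.approx(6 * 9 / (2 * 3))
        orat_inf, _ = fisher_exact_2x2(5, 0, 3, 5)
        assert np.isinf(orat_inf)

    def test_matches_enumeration_oracle_random_tables(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 31))
            cells = rng.multinomial(n, [0.25] * 4)
            a, b, c, d = (int(v) for v in cells)
            if (a + b == 0 and c + d == 0) or (a + c == 0 and b + d == 0):
                continue
            _, p = fisher_exact_2x2(a, b, c, d)
            assert p == pytest.approx(_enumerate_fisher_p(a, b, c, d), abs=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(1, -1, 2, 3)


def _textbook_holm(p):
    """Oracle: literal step-down definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 0.0
    for rank, i in enumerate(order):
        val = (m - rank) * p[i]
        prev = max(prev, val)
        adj[i] = min(1.0, prev)
    return adj


class TestHolm:
    def test_worked_example(self):
        np.testing.assert_allclose(
            holm_adjust([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06]
        )

    def test_single_p_unchanged(self):
        assert holm_adjust([0.2])[0] == pytest.approx(0.2)

    def test_matches_textbook_oracle_on_random_vectors(self, rng):
        for _ in range(1000):
            m = int(rng.integers(1, 12))
            p = rng.uniform(1e-6, 1.0, size=m)
            np.testing.assert_allclose(holm_adjust(p), _textbook_holm(list(p)),
                                       atol=1e-12)

    def test_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        p = rng.uniform(1e-4, 1.0, size=25)
        np.testing.assert_allclose(
            holm_adjust(p), sm.multipletests(p, method="holm")[1], atol=1e-12
        )

    def test_contract_adjusted_at_least_raw(self, rng):
        p = rng.uniform(1e-6, 1.0, size=20)
        adj = holm_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()

    def test_out_of_range_rejected(self):
        for bad in ([0.0, 0.5], [0.5, 1.2]):
            with pytest.raises(ValueError):
                holm_adjust(bad)

    @settings(max_examples=200, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1,
                    max_size=15))
    def test_properties_hold_for_any_vector(self, p):
        """Holm output is elementwise >= raw, <= 1, preserves the raw
        ordering, and equals the textbook step-down."""
        adj = holm_adjust(p)
        assert (adj >= np.asarray(p) - 1e-15).all() and (adj <= 1.0).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()
        np.testing.assert_allclose(adj, _textbook_holm(p), atol=1e-12)


def _toy_labels_outcomes(rng, n_clusters=5, per=40, shift_cluster=None,
                         shift=0.0):
    labels, rows = [], []
    for c in range(1, n_clusters + 1):
        for i in range(per):
            pid = f"c{c}p{i}"
            labels.append((pid, c))
            mu = shift if c == shift_cluster else 0.0
            rows.append({"patient_id": pid,
                         "score": rng.normal(mu, 1.0),
                         "event": int(rng.random() < 0.3)})
    labels = pd.Series(dict(labels))
    return labels, pd.DataFrame(rows)


class TestPairwiseCompare:
    SPEC = {"score": "continuous", "event": "categorical"}

    def test_five_clusters_give_ten_pairs_per_outcome(self, rng):
        labels, outcomes = _toy_labels_outcomes(rng)
        res = pairwise_compare(labels, outcomes, self.SPEC)
        assert len(res) == 10 * 2
        assert set(res["test"]) == {"rank_sum", "fisher_exact"}
        counts = res.groupby("outcome").size()
        assert (counts == 10).all()

    def test_identical_distributions_fully_adjusted_to_one(self):
        labels = pd.Series({f"p{i}": i % 3 + 1 for i in range(30)})
        outcomes = pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(30)],
            "score": [float(i % 10) for i in range(30)],  # same values per cluster
        })
        res = pairwise_compare(labels, outcomes, {"score": "continuous"})
        np.testing.assert_allclose(res["p_holm"], 1.0)

    def test_holm_applied_within_outcome_family(self, rng):
        labels, outcomes = _toy_labels_outcomes(rng)
        res = pairwise_compare(labels, outcomes, self.SPEC)
        for _, fam in res.groupby("outcome"):
            np.testing.assert_allclose(
                fam["p_holm"], holm_adjust(fam["p_raw"].tolist()), atol=1e-12
            )

    def test_planted_shift_dominates_smallest_p(self):
        """A +2 sd shift on one cluster's continuous outcome makes that
        cluster's pairs carry the smallest Holm-adjusted p (4/5 seeds)."""
        hits = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            labels, outcomes = _toy_labels_outcomes(
                r, per=100, shift_cluster=3, shift=2.0)
            res = pairwise_compare(labels, outcomes, {"score": "continuous"})
            best = res.loc[res["p_holm"].idxmin()]
            if 3 in (best["cluster_a"], best["cluster_b"]):
                hits += 1
        assert hits >= 4

    def test_empty_cluster_cell_not_computable(self, rng, caplog):
        labels = pd.Series({"a": 1, "b": 1, "c": 2, "d": 2})
        outcomes = pd.DataFrame({
            "patient_id": ["a", "b", "c", "d"],
            "score": [1.0, 2.0, np.nan, np.nan],
        })
        with caplog.at_level("WARNING"):
            res = pairwise_compare(labels, outcomes, {"score": "continuous"})
        assert res["p_raw"].isna().all()
        assert "not computable" in caplog.text

    def test_missing_outcome_column_rejected(self, rng):
        labels, outcomes = _toy_labels_outcomes(rng)
        with pytest.raises(KeyError):
            pairwise_compare(labels, outcomes, {"absent": "continuous"})


class TestSummaries:
    def test_pooled_reproduces_published_style_totals(self):
        pooled = pooled_summary(icu_demographics_example())
        for key, expected in ICU_EXAMPLE_POOLED.items():
            assert pooled[key] == pytest.approx(expected), key

    def test_single_cluster_pools_to_itself(self):
        df = pd.DataFrame({"cluster": [1], "n": [10], "x_mean": [2.34],
                           "y_count": [3], "y_denom": [9]})
        pooled = pooled_summary(df)
        assert pooled["n"] == 10
        assert pooled["x_mean"] == pytest.approx(2.3)
        assert pooled["y_pct"] == pytest.approx(round(100 * 3 / 9, 1))

    def test_missing_denominator_named(self):
        df = pd.DataFrame({"cluster": [1, 2], "n": [5, 5],
                           "e_count": [1, 2], "e_denom": [5, np.nan]})
        with pytest.raises(ValueError, match="e"):
            pooled_summary(df)

    def test_cluster_summary_counts_and_means(self, rng):
        labels, outcomes = _toy_labels_outcomes(rng, n_clusters=2, per=15)
        summ = cluster_summary(labels, outcomes, TestPairwiseCompare.SPEC)
        assert summ["n"].tolist() == [15, 15]
        out = outcomes.set_index("patient_id")
        for c in (1, 2):
            members = labels.index[labels == c]
            assert summ.loc[summ["cluster"] == c, "score_mean"].iloc[0] == \
                pytest.approx(out.loc[members, "score"].mean())
            assert summ.loc[summ["cluster"] == c, "event_count"].iloc[0] == \
                (out.loc[members, "event"] == 1).sum()


class TestPhenotypeProfile:
    def _assignment(self):
        return PhenotypeAssignment(
            {"k1": frozenset({1}), "k2": frozenset({1}), "k3": frozenset({3})},
            K=2, tau=0.5)

    def test_empty_annotations_all_unannotated(self):
        prof = phenotype_profile(self._assignment(), None)
        sub = prof[(prof["phenotype"] == 1)]
        assert sub["category"].tolist() == ["unannotated"]
        assert sub["pct"].iloc[0] == 100.0

    def test_toy_percentage(self):
        prof = phenotype_profile(self._assignment(), {"k1": ["antibiotic"]})
        sub = prof[prof["phenotype"] == 1].set_index("category")
        assert sub.loc["antibiotic", "n"] == 1
        assert sub.loc["antibiotic", "pct"] == 50.0

    def test_matches_groupby_oracle(self, rng):
        keys = [f"k{i}" for i in range(20)]
        member = {k: frozenset({int(rng.integers(1, 5))}) for k in keys}
        cats = ["a", "b", "c"]
        ann = {k: [cats[rng.integers(0, 3)]] for k in keys if rng.random() < 0.7}
        asg = PhenotypeAssignment(member, K=3, tau=0.5)
        prof = phenotype_profile(asg, ann)
        for lab in range(1, 5):
            members = [k for k, s in member.items() if lab in s]
            counts = {}
            for k in members:
                for cat in ann.get(k, ["unannotated"]):
                    counts[cat] = counts.get(cat, 0) + 1
            sub = prof[prof["phenotype"] == lab].set_index("category")["n"].to_dict()
            if members:
                assert sub == counts
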