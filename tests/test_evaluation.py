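"""P@K, AP and MAP: worked values, oracles, and metric invariants."""

import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from archeq import (
    EvalConfig,
    GoldEntry,
    QueryTerm,
    average_precision,
    delta,
    evaluate_run,
    load_gold,
    mean_average_precision,
    precision_at_k,
    save_gold,
)


def gold(query: str, *ids: str, tag: str = "low") -> GoldEntry:
    return GoldEntry(QueryTerm(query), frozenset(ids), level_tag=tag)


def aid(i: int) -> str:
    return f"openEHR-EHR-OBSERVATION.concept_{i}.v1"


def make_run(n_queries: int, hit_positions: dict[int, int]) -> tuple[dict, list]:
    """A run of ``n_queries``; query i's gold id is placed at 1-based
    position hit_positions[i] (absent -> never returned)."""
    run, golds = {}, []
    for i in range(n_queries):
        golds.append(gold(f"q{i}", aid(i)))
        returned = [aid(1000 + i * 10 + j) for j in range(10)]
        pos = hit_positions.get(i)
        if pos is not None:
            returned.insert(pos - 1, aid(i))
        run[f"q{i}"] = returned
    return run, golds


class TestDelta:
    def test_hit_at_first_position(self):
        g = gold("q", aid(1))
        assert delta([aid(1), aid(2), aid(3)], g, 3) == 1

    def test_boundary_between_cutoffs(self):
        g = gold("q", aid(1))
        returned = [aid(9), aid(8), aid(7), aid(1), aid(6)]
        assert delta(returned, g, 3) == 0
        assert delta(returned, g, 5) == 1

    def test_empty_result_list(self):
        assert delta([], gold("q", aid(1)), 5) == 0

    def test_equals_prefix_membership_oracle(self):
        """Random 10-id lists against a brute-force scan of the top-K
        prefix, for every K in 1..10."""
        rng = random.Random(13)
        for _ in range(50):
            ids = [aid(i) for i in rng.sample(range(30), 10)]
            g = gold("q", aid(rng.randrange(30)), aid(rng.randrange(30)))
            for K in range(1, 11):
                expected = int(any(x in g.acceptable_ids for x in ids[:K]))
                assert delta(ids, g, K) == expected


class TestPrecisionAtK:
    def test_39_of_40_gives_0_975(self):
        """40 queries with 39 acceptable results inside the top 5."""
        run, golds = make_run(40, {i: 1 for i in range(39)})
        assert precision_at_k(run, golds, 5) == pytest.approx(0.975)

    def test_2_of_40_gives_0_050(self):
        run, golds = make_run(40, {0: 1, 1: 5})
        assert precision_at_k(run, golds, 5) == pytest.approx(0.050)

    def test_all_hit_gives_one(self):
        run, golds = make_run(10, {i: 1 for i in range(10)})
        assert precision_at_k(run, golds, 3) == 1.0

    def test_missing_query_counts_zero(self):
        run, golds = make_run(4, {i: 1 for i in range(4)})
        del run["q0"]
        assert precision_at_k(run, golds, 3) == pytest.approx(0.75)

    def test_empty_gold_rejected(self):
        with pytest.raises(ValueError):
            precision_at_k({}, [], 3)


class TestAveragePrecision:
    def test_worked_values(self):
        """AP is the mean of P@3 and P@5: (0.525 + 0.750)/2 = 0.6375 and
        (0.950 + 0.975)/2 = 0.9625 (reports print 0.637 / 0.963)."""
        cfg = EvalConfig()
        assert average_precision({3: 0.525, 5: 0.750}, cfg) == pytest.approx(0.6375, abs=5e-4)
        assert average_precision({3: 0.950, 5: 0.975}, cfg) == pytest.approx(0.9625, abs=5e-4)

    def test_equal_inputs_identity(self):
        assert average_precision({3: 0.4, 5: 0.4}, EvalConfig()) == pytest.approx(0.4)

    def test_missing_cutoff_rejected(self):
        with pytest.raises(ValueError, match="5"):
            average_precision({3: 0.5}, EvalConfig())


class TestMeanAveragePrecision:
    def test_three_set_worked_value(self):
        """MAP over per-set APs (0.967, 0.883, 0.608) prints 0.819."""
        value = mean_average_precision([0.967, 0.883, 0.608])
        assert round(value, 3) == 0.819

    def test_single_set_is_identity(self):
        assert mean_average_precision([0.42]) == pytest.approx(0.42)

    def test_random_triples_match_arithmetic_oracle(self):
        rng = random.Random(5)
        for _ in range(30):
            xs = [rng.random() for _ in range(rng.randrange(1, 6))]
            assert mean_average_precision(xs) == pytest.approx(sum(xs) / len(xs))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_average_precision([])


def reference_report(run, golds, k_values):
    """Independent from-scratch re-implementation used as oracle."""
    p = {}
    for K in k_values:
        hits = 0
        for g in golds:
            returned = run.get(g.query.text, [])
            found = False
            for rid in returned[:K]:
                if rid in g.acceptable_ids:
                    found = True
            hits += 1 if found else 0
        p[K] = hits / len(golds)
    ap = sum(p.values()) / len(p)
    return p, ap


class TestEvaluateRun:
    def test_perfect_run(self):
        run, golds = make_run(8, {i: 1 for i in range(8)})
        report = evaluate_run(run, golds)
        assert report.p_at_k == {3: 1.0, 5: 1.0} and report.ap == 1.0

    def test_38_and_39_of_40(self):
        """38/40 hits at K=3 and 39/40 at K=5 yield the report
        (P@3 0.950, P@5 0.975, AP 0.9625)."""
        positions = {i: 1 for i in range(38)}
        positions[38] = 4  # inside top-5 only
        run, golds = make_run(40, positions)
        report = evaluate_run(run, golds)
        assert report.p_at_k[3] == pytest.approx(0.950)
        assert report.p_at_k[5] == pytest.approx(0.975)
        assert report.ap == pytest.approx(0.9625, abs=5e-4)

    def test_matches_reference_implementation_on_random_runs(self):
        rng = random.Random(99)
        for _ in range(200):
            n = rng.randrange(3, 15)
            positions = {
                i: rng.randrange(1, 9) for i in range(n) if rng.random() < 0.7
            }
            run, golds = make_run(n, positions)
            report = evaluate_run(run, golds)
            p_ref, ap_ref = reference_report(run, golds, (3, 5))
            assert report.p_at_k == pytest.approx(p_ref)
            assert report.ap == pytest.approx(ap_ref)

    def test_per_set_aps_and_map(self):
        golds = [
            gold("a", aid(1), tag="low"),
            gold("b", aid(2), tag="low"),
            gold("c", aid(3), tag="high"),
        ]
        run = {"a": [aid(1)], "b": [aid(99)], "c": [aid(3)]}
        report = evaluate_run(run, golds)
        assert report.per_set_aps == pytest.approx({"low": 0.5, "high": 1.0})
        assert report.map_value == pytest.approx(0.75)

    def test_missing_queries_listed(self):
        run, golds = make_run(3, {0: 1})
        del run["q2"]
        report = evaluate_run(run, golds)
        assert report.missing_queries == ["q2"]

    def test_gold_order_permutation_invariance(self):
        run, golds = make_run(10, {i: i % 7 + 1 for i in range(10)})
        report_fwd = evaluate_run(run, golds)
        report_rev = evaluate_run(run, list(reversed(golds)))
        assert report_fwd.p_at_k == report_rev.p_at_k
        assert report_fwd.ap == report_rev.ap

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_metric_monotonicity_under_added_hit(self, seed):
        """Promoting one query's gold id into its top-K never decreases
        any metric."""
        rng = random.Random(seed)
        n = rng.randrange(2, 10)
        positions = {i: rng.randrange(1, 10) for i in range(n) if rng.random() < 0.5}
        run, golds = make_run(n, positions)
        report = evaluate_run(run, golds)
        i = rng.randrange(n)
        improved = dict(run)
        improved[f"q{i}"] = [aid(i)] + run[f"q{i}"]
        report2 = evaluate_run(improved, golds)
        for K in (3, 5):
            assert report2.p_at_k[K] >= report.p_at_k[K]
        assert report2.ap >= report.ap

    def test_p5_not_less_than_p3(self):
        rng = random.Random(3)
        for trial in range(50):
            n = rng.randrange(2, 12)
            positions = {i: rng.randrange(1, 10) for i in range(n) if rng.random() < 0.6}
            run, golds = make_run(n, positions)
            report = evaluate_run(run, golds)
            assert report.p_at_k[5] >= report.p_at_k[3]
            assert min(report.p_at_k.values()) <= report.ap <= max(report.p_at_k.values())


class TestGoldIO:
    def test_round_trip(self, tmp_path):
        entries = [
            gold("query one", aid(1), aid(2), tag="low"),
            gold("query two", aid(3), tag="high"),
        ]
        path = tmp_path / "gold.tsv"
        save_gold(entries, path)
        loaded = load_gold(path)
        assert [e.query.text for e in loaded] == ["query one", "query two"]
        assert loaded[0].acceptable_ids == entries[0].acceptable_ids
        assert loaded[1].level_tag == "high"

    def test_invalid_id_rejected(self):
        with pytest.raises(ValueError, match="bogus"):
            gold("q", "bogus")

    def test_empty_acceptable_ids_rejected(self):
        with pytest.raises(ValueError):
            GoldEntry(QueryTerm("q"), frozenset())

    def test_malformed_line_reports_position(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("only-one-field\n", encoding="utf-8")
        with pytest.raises(ValueError, match=":1"):
            load_gold(path)
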