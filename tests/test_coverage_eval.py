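"""Relation parsing, epq filtering, quadratic coverage, bootstrap, Z-score."""

import json

import numpy as np
import pytest

from corblosum import (
    AnnotationError,
    BootstrapRun,
    Relation,
    SearchResultFormatError,
    SuperfamilyMap,
    bootstrap_coverage,
    draw_bootstrap_weights,
    epq_threshold,
    evaluate_run,
    parse_astral_annotations,
    parse_search_results,
    quadratic_coverage,
    z_score,
)
from corblosum.simulate import oracle_coverage


class TestParseSearchResults:
    LINE = "d1\td2\t90\t100\t0\t0\t1\t100\t1\t100\t1e-30\t200"

    def test_basic_line(self):
        rels = parse_search_results(self.LINE)
        assert rels == [Relation(1e-30, "d1", "d2")]

    def test_self_hits_dropped(self):
        line = self.LINE.replace("d2", "d1")
        assert parse_search_results(line) == []

    def test_duplicates_keep_smallest_evalue(self):
        text = self.LINE.replace("1e-30", "1e-5") + "\n" + \
            self.LINE.replace("1e-30", "1e-9")
        assert parse_search_results(text) == [Relation(1e-9, "d1", "d2")]

    def test_sorted_by_evalue_then_ids(self):
        lines = [
            "d3\td4\t0\t0\t0\t0\t0\t0\t0\t0\t1e-5\t1",
            "d1\td2\t0\t0\t0\t0\t0\t0\t0\t0\t1e-5\t1",
            "d9\td8\t0\t0\t0\t0\t0\t0\t0\t0\t1e-9\t1",
        ]
        rels = parse_search_results("\n".join(lines))
        assert [(r.query_id, r.subject_id) for r in rels] == \
            [("d9", "d8"), ("d1", "d2"), ("d3", "d4")]

    def test_non_numeric_evalue_reports_line_number(self):
        text = self.LINE + "\n" + self.LINE.replace("1e-30", "oops")
        with pytest.raises(SearchResultFormatError, match="line 2"):
            parse_search_results(text)


class TestParseAstralAnnotations:
    FASTA = """\
>d1dlwa_ a.1.1.1 (A:) myoglobin-like
MLSDGEWQL
>d1dlya_ a.1.1.2 (A:) another globin
MLSEGEWQL
>d2abca_ a.1.2.1 (A:) different superfamily
MKV
>dXXXXX_ no-sccs-here (A:) malformed header
MKV
"""

    def test_superfamily_is_first_three_sccs_fields(self):
        smap = parse_astral_annotations(self.FASTA)
        assert smap.label_of["d1dlwa_"] == "a.1.1"
        assert smap.label_of["d1dlya_"] == "a.1.1"
        assert smap.label_of["d2abca_"] == "a.1.2"

    def test_headers_without_sccs_are_skipped_and_counted(self):
        smap = parse_astral_annotations(self.FASTA)
        assert "dXXXXX_" not in smap.label_of
        assert smap.n_skipped == 1

    def test_sizes_and_database_size(self):
        smap = parse_astral_annotations(self.FASTA)
        assert smap.sizes == {"a.1.1": 2, "a.1.2": 1}
        assert smap.database_size == 3
        assert smap.eligible_superfamilies() == ["a.1.1"]


def _smap(labels: dict[str, str]) -> SuperfamilyMap:
    return SuperfamilyMap(dict(labels))


class TestEpqThreshold:
    def test_budget_example_with_interleaved_fp(self):
        # 100 queries at 0.01 epq -> FP budget exactly 1.0
        labels = {f"q{i:03d}": f"z.{i}.9" for i in range(96)}
        labels.update({"t1": "a.1.1", "t2": "a.1.1",
                       "u1": "a.2.1", "u2": "a.2.1"})
        smap = _smap(labels)
        rels = [
            Relation(1e-10, "t1", "t2"),   # TP
            Relation(1e-5, "t1", "u1"),    # FP (within budget)
            Relation(1e-4, "u1", "u2"),    # TP after the first FP
            Relation(1e-3, "u2", "t2"),    # FP (would exceed budget)
        ]
        cutoff, retained = epq_threshold(rels, smap, 0.01)
        assert retained == sorted(rels)[:3]
        assert cutoff == 1e-4

    def test_prefix_matches_brute_force_over_all_cutoffs(self, rng):
        from corblosum.simulate import ScenarioSpec, generate_scenario

        spec = ScenarioSpec((3, 4, 2, 1), (1.0, 0.5, 1.0, 0.0), 12,
                            seed=int(rng.integers(2**31)))
        rels, smap, _ = generate_scenario(spec)
        for epq in (0.05, 0.3, 1.0, 5.0):
            _, retained = epq_threshold(rels, smap, epq)
            q = quadratic_coverage(retained, smap).Q_quad
            assert q == pytest.approx(oracle_coverage(rels, smap, epq))

    def test_generous_budget_admits_everything(self):
        smap = _smap({"a": "a.1.1", "b": "a.1.1", "c": "b.1.1"})
        rels = [Relation(1e-3, "a", "b"), Relation(1e-2, "a", "c")]
        cutoff, retained = epq_threshold(rels, smap, 10.0)
        assert retained == rels
        assert cutoff == 1e-2

    def test_unannotated_id_is_an_error(self):
        smap = _smap({"a": "a.1.1", "b": "a.1.1"})
        with pytest.raises(AnnotationError, match="mystery"):
            epq_threshold([Relation(1e-3, "a", "mystery")], smap, 0.01)

    def test_coverage_monotone_in_epq(self, rng):
        from corblosum.simulate import ScenarioSpec, generate_scenario

        spec = ScenarioSpec((3, 3, 2), (1.0, 0.5, 1.0), 20,
                            seed=int(rng.integers(2**31)))
        rels, smap, _ = generate_scenario(spec)
        prev = -1.0
        for epq in (0.01, 0.1, 0.5, 2.0, 10.0):
            _, retained = epq_threshold(rels, smap, epq)
            q = quadratic_coverage(retained, smap).Q_quad
            assert q >= prev
            prev = q


class TestQuadraticCoverage:
    def test_perfect_recovery_of_one_superfamily(self):
        smap = _smap({"a": "a.1.1", "b": "a.1.1", "c": "a.1.1"})
        rels = [Relation(1e-9, q, s) for q in "abc" for s in "abc" if q != s]
        assert quadratic_coverage(rels, smap).Q_quad == 1.0

    def test_two_superfamily_average(self):
        # sizes {2, 3}: 2/2 and 3/6 retained -> (1 + 0.5)/2 = 0.75
        labels = {"a": "a.1.1", "b": "a.1.1",
                  "c": "a.2.1", "d": "a.2.1", "e": "a.2.1"}
        smap = _smap(labels)
        rels = [Relation(1e-9, "a", "b"), Relation(1e-9, "b", "a"),
                Relation(1e-8, "c", "d"), Relation(1e-8, "d", "c"),
                Relation(1e-8, "c", "e")]
        assert quadratic_coverage(rels, smap).Q_quad == 0.75

    def test_no_relations_gives_zero(self):
        smap = _smap({"a": "a.1.1", "b": "a.1.1"})
        assert quadratic_coverage([], smap).Q_quad == 0.0

    def test_singletons_excluded_from_average(self):
        smap = _smap({"a": "a.1.1", "b": "a.1.1", "lone": "z.9.9"})
        rels = [Relation(1e-9, "a", "b"), Relation(1e-9, "b", "a")]
        assert quadratic_coverage(rels, smap).Q_quad == 1.0

    def test_added_fp_never_increases_coverage(self, rng):
        from corblosum.simulate import ScenarioSpec, generate_scenario

        spec = ScenarioSpec((3, 3), (1.0, 0.5), 0,
                            seed=int(rng.integers(2**31)))
        rels, smap, _ = generate_scenario(spec)
        base = quadratic_coverage(rels, smap).Q_quad
        with_fp = rels + [Relation(1e-60, rels[0].query_id, "outsider")]
        smap2 = _smap({**smap.label_of, "outsider": "z.1.1"})
        assert quadratic_coverage(with_fp, smap2).Q_quad <= base


class TestBootstrapWeights:
    def test_vectors_sum_to_database_size(self):
        w = draw_bootstrap_weights(37, 20, seed=3)
        assert w.shape == (20, 37)
        assert np.allclose(w.sum(axis=1), 37, atol=1e-9)
        assert (w > 0).all()

    def test_seed_reproducibility(self):
        a = draw_bootstrap_weights(10, 5, seed=42)
        b = draw_bootstrap_weights(10, 5, seed=42)
        c = draw_bootstrap_weights(10, 5, seed=43)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_monte_carlo_mean_weight_is_one(self):
        # flat Dirichlet scaled by n: each weight has mean 1 and variance
        # ~ (n-1)/(n+1); check the empirical mean within 3 standard errors
        n, rounds = 8, 10_000
        w = draw_bootstrap_weights(n, rounds, seed=0)
        var = (n - 1) / (n + 1)
        se = np.sqrt(var / rounds)
        assert np.abs(w.mean(axis=0) - 1.0).max() < 3 * se * 1.5


class TestBootstrapCoverage:
    def test_unit_weights_reduce_to_point_coverage(self,
                                                   two_superfamily_scenario):
        rels, smap, _ = two_superfamily_scenario
        _, retained = epq_threshold(rels, smap, 0.5)
        point = quadratic_coverage(retained, smap).Q_quad
        ones = np.ones(smap.database_size)
        assert bootstrap_coverage(rels, smap, ones, 0.5) == point

    def test_matches_naive_double_loop_oracle(self, rng):
        from corblosum.simulate import ScenarioSpec, generate_scenario

        for trial in range(10):
            spec = ScenarioSpec((3, 2, 4), (1.0, 1.0, 0.5), 6,
                                seed=int(rng.integers(2**31)))
            rels, smap, _ = generate_scenario(spec)
            w = draw_bootstrap_weights(smap.database_size, 1,
                                       seed=int(rng.integers(2**31)))[0]
            wdict = dict(zip(smap.domains, w))
            ours = bootstrap_coverage(rels, smap, w, 0.5)
            assert ours == pytest.approx(
                oracle_coverage(rels, smap, 0.5, weights=wdict), abs=1e-12
            )

    def test_distribution_collapses_as_weights_approach_ones(
            self, two_superfamily_scenario):
        rels, smap, _ = two_superfamily_scenario
        _, retained = epq_threshold(rels, smap, 0.5)
        point = quadratic_coverage(retained, smap).Q_quad
        rng = np.random.default_rng(5)
        for eps in (1e-2, 1e-4, 1e-6):
            w = 1.0 + eps * rng.standard_normal(smap.database_size)
            w *= smap.database_size / w.sum()
            q = bootstrap_coverage(rels, smap, w, 0.5)
            assert abs(q - point) < 20 * eps


class TestZScore:
    def test_identical_distributions_give_zero(self):
        run = BootstrapRun(5, [0.1, 0.2, 0.3, 0.2, 0.1])
        res = z_score(run, run)
        assert res.z == 0.0
        assert not res.significant

    def test_hand_evaluated_example(self):
        # means 0.5 vs 0.4, variances 0.01, N=500 -> 0.1/sqrt(0.02/500)
        rng = np.random.default_rng(0)
        p = BootstrapRun(500, rng.normal(0.5, 0.1, 500))
        q = BootstrapRun(500, rng.normal(0.4, 0.1, 500))
        res = z_score(p, q)
        manual = (p.mean - q.mean) / np.sqrt((p.variance + q.variance) / 500)
        assert res.z == pytest.approx(manual)
        assert res.z == pytest.approx(15.81, abs=2.0)  # ~ the nominal value
        assert res.significant

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        p = BootstrapRun(100, rng.normal(0.5, 0.1, 100))
        q = BootstrapRun(100, rng.normal(0.45, 0.1, 100))
        assert z_score(p, q).z == pytest.approx(-z_score(q, p).z)

    def test_degenerate_variances(self):
        flat1 = BootstrapRun(3, [0.25, 0.25, 0.25])
        flat2 = BootstrapRun(3, [0.5, 0.5, 0.5])
        assert z_score(flat1, flat1).z == 0.0
        res = z_score(flat2, flat1)
        assert res.infinite and res.z == float("inf") and res.significant

    def test_unequal_rounds_rejected(self):
        with pytest.raises(ValueError):
            z_score(BootstrapRun(3, [0.1] * 3), BootstrapRun(4, [0.1] * 4))


class TestEvaluateRun:
    def test_planted_coverage_recovered(self, two_superfamily_scenario):
        rels, smap, planted = two_superfamily_scenario
        report = evaluate_run(rels, smap, epq_limit=1.0, n_rounds=10, seed=2)
        assert report["q_quad"] == planted

    def test_reports_are_deterministic(self, two_superfamily_scenario):
        from corblosum.simulate import annotations_to_fasta, \
            relations_to_tabular

        rels, smap, _ = two_superfamily_scenario
        results_text = relations_to_tabular(rels)
        fasta_text = annotations_to_fasta(smap)
        r1 = evaluate_run(results_text, fasta_text, epq_limit=0.5,
                          n_rounds=25, seed=9)
        r2 = evaluate_run(results_text, fasta_text, epq_limit=0.5,
                          n_rounds=25, seed=9)
        assert json.dumps(r1, sort_keys=True) == json.dumps(r2, sort_keys=True)

    def test_concerted_self_comparison_is_identically_zero(
            self, two_superfamily_scenario):
        rels, smap, _ = two_superfamily_scenario
        w = draw_bootstrap_weights(smap.database_size, 30, seed=4)
        ra = evaluate_run(rels, smap, epq_limit=0.5, n_rounds=30, weights=w)
        rb = evaluate_run(rels, smap, epq_limit=0.5, n_rounds=30, weights=w)
        diffs = np.array(ra["bootstrap"]["q_hats"]) - \
            np.array(rb["bootstrap"]["q_hats"])
        assert np.all(diffs == 0.0)
        run_a = BootstrapRun(30, ra["bootstrap"]["q_hats"])
        run_b = BootstrapRun(30, rb["bootstrap"]["q_hats"])
        assert z_score(run_a, run_b).z == 0.0

    def test_fixed_cutoff_mode_pins_prefix(self, two_superfamily_scenario):
        rels, smap, _ = two_superfamily_scenario
        ra = evaluate_run(rels, smap, epq_limit=0.5, n_rounds=10, seed=1,
                          fixed_cutoff=True)
        assert ra["config"]["fixed_cutoff"] is True
        assert len(ra["bootstrap"]["q_hats"]) == 10
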