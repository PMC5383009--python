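import itertools

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from netkit import enrichment as en
from netkit import synthetic_data as sd
from netkit.errors import (
    BackgroundMismatchError,
    CyclicOntologyError,
    EmptyInputError,
    InvalidCountsError,
    InvalidPValueError,
)

import oracles


class TestPropagation:
    def test_chain_closure(self):
        amap = en.AnnotationMap(
            protein_to_terms={"P1": {"t3"}},
            term_parents={"t3": {"t2"}, "t2": {"t1"}},
        )
        closed = en.propagate_annotations(amap)
        assert closed.protein_to_terms["P1"] == {"t1", "t2", "t3"}

    def test_empty_parent_table_identity(self):
        amap = en.AnnotationMap(protein_to_terms={"P1": {"a"}, "P2": {"b"}})
        closed = en.propagate_annotations(amap)
        assert closed.protein_to_terms == amap.protein_to_terms

    def test_random_dag_matches_reachability(self):
        rng = np.random.default_rng(3)
        terms = [f"t{i}" for i in range(15)]
        # parents only point to strictly smaller indices: acyclic by construction
        parents = {
            terms[i]: {terms[j] for j in range(i) if rng.random() < 0.25}
            for i in range(1, 15)
        }
        amap = en.AnnotationMap(
            protein_to_terms={"P": {terms[14], terms[9]}}, term_parents=parents
        )
        closed = en.propagate_annotations(amap)

        def reach(t, seen):
            for p in parents.get(t, ()):
                if p not in seen:
                    seen.add(p)
                    reach(p, seen)
            return seen

        expected = {terms[14], terms[9]}
        for t in (terms[14], terms[9]):
            expected |= reach(t, set())
        assert closed.protein_to_terms["P"] == expected

    def test_cycle_detected(self):
        amap = en.AnnotationMap(
            protein_to_terms={"P": {"a"}}, term_parents={"a": {"b"}, "b": {"a"}}
        )
        with pytest.raises(CyclicOntologyError):
            en.propagate_annotations(amap)


class TestHypergeometric:
    def test_zero_successes_certain(self):
        assert en.hypergeometric_upper_tail(0, 10, 5, 50) == 1.0

    def test_fully_annotated_background(self):
        assert en.hypergeometric_upper_tail(7, 50, 7, 50) == pytest.approx(1.0)

    def test_matches_exact_rational_tail_sum(self):
        p = en.hypergeometric_upper_tail(4, 10, 10, 50)
        exact = float(oracles.hypergeom_tail_exact(4, 10, 10, 50))
        assert p == pytest.approx(exact, abs=1e-12)

    def test_grid_against_exact_arithmetic(self):
        cases = 0
        for N in (20, 45, 70):
            for K in (3, 8, 15):
                for n in (5, 12, 20):
                    if n > N or K > N:
                        continue
                    for k in range(0, min(K, n) + 1):
                        exact = float(oracles.hypergeom_tail_exact(k, K, n, N))
                        mine = en.hypergeometric_upper_tail(k, K, n, N)
                        assert mine == pytest.approx(exact, abs=1e-12)
                        cases += 1
        assert cases >= 200

    def test_non_increasing_in_k(self):
        vals = [en.hypergeometric_upper_tail(k, 12, 15, 60) for k in range(0, 13)]
        assert all(a >= b - 1e-15 for a, b in zip(vals, vals[1:]))

    def test_invalid_counts(self):
        with pytest.raises(InvalidCountsError):
            en.hypergeometric_upper_tail(5, 4, 10, 50)


class TestBhAdjust:
    def test_all_equal_stay_equal(self):
        assert en.bh_adjust([0.03] * 5) == pytest.approx([0.03] * 5)

    def test_hand_applied_step_up(self):
        assert en.bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_value_unchanged(self):
        assert en.bh_adjust([0.2]) == [0.2]

    def test_matches_statsmodels_on_random_inputs(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            p = rng.random(rng.integers(1, 30)).tolist()
            mine = en.bh_adjust(p)
            ref = multipletests(p, method="fdr_bh")[1]
            assert mine == pytest.approx(ref.tolist(), abs=1e-12)

    def test_never_decreases_and_preserves_order(self):
        rng = np.random.default_rng(5)
        p = rng.random(25).tolist()
        adj = en.bh_adjust(p)
        assert all(a >= r for a, r in zip(adj, p))
        order_raw = np.argsort(p, kind="stable")
        assert sorted(np.array(adj)[order_raw].tolist()) == np.array(adj)[order_raw].tolist()

    def test_invalid_pvalue(self):
        with pytest.raises(InvalidPValueError):
            en.bh_adjust([0.5, 1.2])


class TestEnrich:
    def _amap(self, table):
        return en.annotations_from_frame(table)

    def test_planted_term_is_significant(self):
        g, gt = sd.generate_planted_partition([20, 180], 0.3, 0.05, seed=2)
        table = sd.generate_annotations(g, 30, 0.05, gt, 0.9, seed=2)
        amap = self._amap(table)
        planted_term, module, _ = gt.enriched_terms[0]
        study = sorted(
            v for v, m in gt.module_assignment.items()
            if m == module and v in amap.proteins()
        )
        background = sorted(amap.proteins())
        results = en.enrich(study, amap, background, alpha=0.05)
        by_term = {r.term: r for r in results}
        assert by_term[planted_term].significant

    def test_small_driver_terms_never_called(self):
        # a term carried by exactly 2 study proteins and nothing else in a
        # large background has a tiny p-value but must not be called
        p2t = {f"B{i}": {"common"} for i in range(100)}
        p2t["S1"] = {"rare", "common"}
        p2t["S2"] = {"rare", "common"}
        amap = en.AnnotationMap(protein_to_terms=p2t)
        results = en.enrich(["S1", "S2"], amap, alpha=0.05, min_drivers=3)
        rare = next(r for r in results if r.term == "rare")
        assert rare.p_adj < 0.05 and not rare.significant

    def test_study_equals_background_all_pvalues_one(self):
        p2t = {f"P{i}": {"t1", "t2"} for i in range(10)}
        amap = en.AnnotationMap(protein_to_terms=p2t)
        results = en.enrich(sorted(p2t), amap)
        assert all(r.p_raw == pytest.approx(1.0) for r in results)

    def test_result_invariant_to_listing_order(self):
        p2t = {"A": {"x"}, "B": {"x", "y"}, "C": {"y"}, "D": {"x"}}
        amap = en.AnnotationMap(protein_to_terms=p2t)
        r1 = en.enrich(["A", "B"], amap)
        r2 = en.enrich(["B", "A"], amap)
        assert [(r.term, r.p_raw, r.p_adj) for r in r1] == [
            (r.term, r.p_raw, r.p_adj) for r in r2
        ]

    def test_empty_study_and_background_mismatch(self):
        amap = en.AnnotationMap(protein_to_terms={"A": {"x"}})
        with pytest.raises(EmptyInputError):
            en.enrich([], amap)
        with pytest.raises(BackgroundMismatchError):
            en.enrich(["ZZZ"], amap)

    def test_null_calibration_false_positive_rate(self):
        """Under a background-only annotation model the BH-adjusted call rate
        across repeated random study sets stays at or below the nominal level."""
        g = sd.generate_scale_free(200, 2, seed=10)
        table = sd.generate_annotations(g, 50, 0.1, None, 0.5, seed=10)
        amap = en.annotations_from_frame(table)
        background = sorted(amap.proteins())
        rng = np.random.default_rng(10)
        fractions = []
        for _ in range(200):
            study = list(rng.choice(background, size=20, replace=False))
            results = en.enrich(study, amap, background, alpha=0.05, min_drivers=0)
            n_sig = sum(r.p_adj < 0.05 for r in results)
            fractions.append(n_sig / len(results) if results else 0.0)
        mean = float(np.mean(fractions))
        mc_se = float(np.std(fractions) / np.sqrt(len(fractions)))
        assert mean <= 0.05 + 3 * mc_se


class TestIO:
    def test_read_annotations_roundtrip(self, tmp_path):
        ann = tmp_path / "ann.tsv"
        ann.write_text("P1\tt1\nP1\tt2\nP2\tt1\n")
        par = tmp_path / "par.tsv"
        par.write_text("t2\tt1\n")
        amap = en.read_annotations(ann, par)
        assert amap.protein_to_terms == {"P1": {"t1", "t2"}, "P2": {"t1"}}
        assert amap.term_parents == {"t2": {"t1"}}

    def test_results_frame_columns(self):
        amap = en.AnnotationMap(protein_to_terms={"A": {"x"}, "B": {"x"}})
        frame = en.results_to_frame(en.enrich(["A"], amap))
        assert list(frame.columns) == [
            "term", "k", "K", "n", "N", "frequency", "p_raw", "p_adj", "significant",
        ]
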