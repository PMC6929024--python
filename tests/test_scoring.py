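import numpy as np
import pytest

from pharmens.core import Feature, Pharmacophore
from pharmens.scoring import (
    baseline_precision,
    cca_score,
    cha_score,
    complexity_filter,
    consensus_score,
    evaluate,
    precision_ef,
    select_top,
)


class TestChaCca:
    def test_cha_counts_matched_models(self):
        mat = np.zeros((10, 4), dtype=bool)
        mat[0, 1] = mat[3, 0] = mat[7, 2] = True
        assert cha_score(mat) == pytest.approx(30.0)

    def test_all_false_and_all_true(self):
        assert cha_score(np.zeros((5, 3), dtype=bool)) == 0.0
        assert cca_score(np.ones((5, 3), dtype=bool)) == 100.0

    def test_cca_counts_matched_conformers(self):
        mat = np.zeros((3, 4), dtype=bool)
        mat[1, 0] = mat[2, 0] = mat[0, 3] = True  # conformers 0 and 3 covered
        assert cca_score(mat) == pytest.approx(50.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_matrices_match_count_oracles(self, seed):
        rng = np.random.default_rng(seed)
        mat = rng.random((10, 4)) < 0.3
        # independent row/column-wise count oracles
        rows = sum(1 for r in range(10) if any(mat[r, c] for c in range(4)))
        cols = sum(1 for c in range(4) if any(mat[r, c] for r in range(10)))
        assert cha_score(mat) == pytest.approx(100.0 * rows / 10)
        assert cca_score(mat) == pytest.approx(100.0 * cols / 4)

    def test_row_column_order_invariance(self, rng):
        mat = rng.random((8, 6)) < 0.4
        perm_r, perm_c = rng.permutation(8), rng.permutation(6)
        assert cha_score(mat) == cha_score(mat[perm_r][:, perm_c])
        assert cca_score(mat) == cca_score(mat[perm_r][:, perm_c])

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            cha_score(np.zeros((0, 3), dtype=bool))
        with pytest.raises(ValueError):
            cca_score(np.zeros((3, 0), dtype=bool))


class TestConsensus:
    def test_mean_of_two_complexes(self):
        assert consensus_score({"c": [40.0, 60.0]})["c"] == pytest.approx(50.0)

    def test_single_complex_is_identity(self):
        scores = {"a": [12.5], "b": [80.0]}
        assert consensus_score(scores) == {"a": 12.5, "b": 80.0}

    def test_three_complex_fixture_matches_hand_average(self, rng):
        per = {f"c{i}": list(rng.uniform(0, 100, 3)) for i in range(20)}
        out = consensus_score(per)
        for cid, scores in per.items():
            assert out[cid] == pytest.approx(sum(scores) / 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            consensus_score({})
        with pytest.raises(ValueError):
            consensus_score({"a": []})


class TestSelectTop:
    def test_distinct_scores(self):
        scored = [(f"c{i}", 10.0 - i, False) for i in range(10)]
        assert len(select_top(scored, 20, 10)) == 2

    def test_tie_extension(self):
        """Scores (9,8,8,8,...): the 20% cut falls on a tie, so all compounds
        scoring 8 ride along -> 4 selected."""
        scores = [9, 8, 8, 8, 5, 4, 3, 2, 1, 0.5]
        scored = [(f"c{i}", s, False) for i, s in enumerate(scores)]
        assert len(select_top(scored, 20, 10)) == 4

    def test_under_retrieval(self):
        """Only 3 of 1000 compounds retrieved at p=5%: selection is exactly
        the retrieved set."""
        scored = [(f"c{i}", 0.0, False) for i in range(997)] + [
            ("a", 10.0, True), ("b", 5.0, True), ("c", 2.0, False)
        ]
        sel = select_top(scored, 5, 1000)
        assert sorted(t[0] for t in sel) == ["a", "b", "c"]

    def test_zero_scores_never_retrieved(self):
        scored = [("a", 1.0, True)] + [(f"c{i}", 0.0, False) for i in range(9)]
        sel = select_top(scored, 50, 10)
        assert [t[0] for t in sel] == ["a"]

    def test_idempotent_and_order_independent(self, rng):
        scored = [(f"c{i}", float(s), False) for i, s in enumerate(rng.integers(0, 5, 30))]
        sel = select_top(scored, 30, 30)
        again = select_top(sel, 100, len(sel))
        assert again == sel
        shuffled = [scored[i] for i in rng.permutation(30)]
        assert set(t[0] for t in select_top(shuffled, 30, 30)) == set(t[0] for t in sel)

    def test_bad_percent(self):
        with pytest.raises(ValueError):
            select_top([], 0, 10)
        with pytest.raises(ValueError):
            select_top([], 101, 10)


class TestPrecisionEF:
    BASE = 473 / (473 + 27853)

    def test_loose_single_model_case(self):
        """10 hits and 818 non-hits at the library baseline: enrichment 0.72."""
        sel = [(f"a{i}", 1.0, True) for i in range(10)] + [
            (f"d{i}", 1.0, False) for i in range(818)
        ]
        rep = precision_ef(sel, self.BASE)
        assert rep.precision == pytest.approx(0.0121, abs=5e-5)
        assert rep.enrichment_factor == pytest.approx(0.72, abs=5e-3)

    @pytest.mark.parametrize(
        "tp,fp,expected",
        [(178, 7931, 1.31), (471, 27413, 1.01), (430, 24832, 1.02),
         (180, 7565, 1.39)],
    )
    def test_whole_retrieved_set_efs(self, tp, fp, expected):
        sel = [(f"a{i}", 1.0, True) for i in range(tp)] + [
            (f"d{i}", 1.0, False) for i in range(fp)
        ]
        rep = precision_ef(sel, self.BASE)
        assert rep.enrichment_factor == pytest.approx(expected, abs=5e-3)

    def test_no_true_positives_gives_zero(self):
        sel = [(f"d{i}", 1.0, False) for i in range(50)]
        rep = precision_ef(sel, self.BASE)
        assert rep.enrichment_factor == 0.0 and rep.TP == 0

    def test_closed_form_on_distinct_labels(self, rng):
        sel = [(f"c{i}", 1.0, bool(rng.random() < 0.3)) for i in range(200)]
        base = 0.25
        rep = precision_ef(sel, base)
        tp = sum(1 for t in sel if t[2])
        assert rep.enrichment_factor == pytest.approx((tp / 200) / base)

    def test_bad_baseline(self):
        with pytest.raises(ValueError):
            precision_ef([], 0.0)


class TestBaseline:
    def test_reference_library_value(self):
        """473 actives vs 27,853 decoys: baseline precision 0.0167."""
        assert baseline_precision(473, 27853) == pytest.approx(0.0167, abs=5e-5)

    @pytest.mark.parametrize("a,d,expected", [(1, 1, 0.5), (0, 100, 0.0)])
    def test_simple_cases(self, a, d, expected):
        assert baseline_precision(a, d) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            baseline_precision(0, 0)


class TestComplexityFilter:
    def _models(self, sizes):
        out = []
        for s in sizes:
            feats = [Feature("A", (3.0 * i, 0.0, 0.0)) for i in range(s)]
            out.append(Pharmacophore(feats))
        return out

    def test_threshold(self):
        kept = complexity_filter(self._models([3, 4, 5, 6]), 5)
        assert sorted(len(m) for m in kept) == [5, 6]

    def test_min_one_is_identity(self):
        models = self._models([3, 4])
        assert complexity_filter(models, 1) == models

    def test_retrieval_shrinks_with_complexity(self, representatives):
        reps, _ = representatives
        sizes = [len(complexity_filter(reps, k)) for k in range(1, 8)]
        assert sizes == sorted(sizes, reverse=True)

    def test_empty_result_allowed_bad_min_rejected(self):
        assert complexity_filter(self._models([3]), 8) == []
        with pytest.raises(ValueError):
            complexity_filter([], 0)


class TestEvaluate:
    def test_grid_report(self):
        scored = [(f"a{i}", 50.0, True) for i in range(5)] + [
            (f"d{i}", 0.0, False) for i in range(95)
        ]
        rep = evaluate(scored, (1.0, 100.0))
        row1 = rep[rep.cutoff_percent == 1.0].iloc[0]
        # only 5 retrieved, all active, baseline 0.05 -> EF 20 at both cutoffs
        assert row1.n_selected == 5 and row1.TP == 5
        assert row1.enrichment_factor == pytest.approx(20.0)
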