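"""FDOSM: ideal solution, opinion matrices, scoring and group ranking."""

import numpy as np
import pandas as pd
import pytest

from asdbench.fdosm import (
    SCORE_BOUNDS,
    OpinionMatrix,
    auto_opinions,
    group_rank,
    ideal_solution,
    score_alternatives,
)
from asdbench.fuzzy import DIFFERENCE5
from asdbench.models import CRITERIA, DecisionMatrix
from asdbench.reference import reference_decision_matrix

ND, SD, D, BD, HD = DIFFERENCE5.labels


def _opinions(cells, alts=None, expert="E1", criteria=None):
    cells = np.asarray(cells, dtype=object)
    alts = alts or [f"A{i + 1}" for i in range(cells.shape[0])]
    criteria = criteria or [f"C{j + 1}" for j in range(cells.shape[1])]
    return OpinionMatrix(expert, pd.DataFrame(cells, index=alts, columns=criteria))


class TestIdealSolution:
    def test_reference_matrix_extrema(self):
        dm = reference_decision_matrix()
        ideal = ideal_solution(dm)
        assert ideal["C1"] == pytest.approx(0.13400)
        assert ideal["C2"] == pytest.approx(0.00001)
        assert ideal["C3"] == pytest.approx(0.99312)
        # benefit criteria take the column max, cost the min
        assert ideal["C4"] == dm.data["C4"].max()
        assert ideal["C1"] == dm.data["C1"].min()

    def test_each_entry_comes_from_its_column(self):
        dm = reference_decision_matrix()
        ideal = ideal_solution(dm)
        for crit in CRITERIA:
            assert (dm.data[crit] == ideal[crit]).any()

    def test_single_alternative_is_its_own_ideal(self):
        dm = reference_decision_matrix()
        one = DecisionMatrix(dm.data.iloc[[4]], dm.directions, dm.model_names)
        ideal = ideal_solution(one)
        assert ideal.tolist() == dm.data.iloc[4].tolist()

    def test_critical_value_override(self):
        dm = reference_decision_matrix()
        ideal = ideal_solution(dm, critical={"C3": 0.95})
        assert ideal["C3"] == 0.95
        assert ideal["C1"] == pytest.approx(0.134)


class TestAutoOpinions:
    @staticmethod
    def _small_dm():
        data = pd.DataFrame(
            {c: [0.5] * 3 for c in CRITERIA},
            index=["A1", "A2", "A3"],
        )
        data["C3"] = [1.0, 0.8, 0.0]  # ideal 1.0; gaps 0, 0.2, 1.0
        data["C1"] = [1.0, 2.0, 3.0]  # cost; ideal 1.0
        return DecisionMatrix(data)

    def test_gap_binning(self):
        op = auto_opinions(self._small_dm())
        assert op.terms.loc["A1", "C3"] == ND     # equals the ideal
        assert op.terms.loc["A2", "C3"] == SD     # g = 0.2
        assert op.terms.loc["A3", "C3"] == HD     # worst extreme
        assert op.terms.loc["A3", "C1"] == HD     # worst cost extreme

    def test_constant_column_all_no_difference(self):
        op = auto_opinions(self._small_dm())
        assert (op.terms["C4"] == ND).all()

    def test_unknown_term_rejected(self):
        with pytest.raises(ValueError, match="unknown linguistic"):
            _opinions([["Massive difference"]])


class TestScoring:
    def test_all_no_difference_hits_lower_bound(self):
        op = _opinions([[ND] * 7])
        assert score_alternatives(op).iloc[0] == pytest.approx(SCORE_BOUNDS[0])

    def test_all_huge_difference_hits_upper_bound(self):
        op = _opinions([[HD] * 7])
        assert score_alternatives(op).iloc[0] == pytest.approx(SCORE_BOUNDS[1])

    def test_published_top_model_score_composition(self):
        """18 'No difference' + 3 'Slight difference' over 3 experts x 7
        criteria reproduces the published best-model group score."""
        ops = [
            _opinions([[ND] * 7], expert="E1"),
            _opinions([[ND] * 7], expert="E2"),
            _opinions([[ND] * 4 + [SD] * 3], expert="E3"),
        ]
        score = group_rank(ops).scores.iloc[0]
        assert score == pytest.approx(0.157142829, abs=1e-6)

    def test_published_second_model_score_composition(self):
        ops = [
            _opinions([[ND] * 7], expert="E1"),
            _opinions([[ND] * 7], expert="E2"),
            _opinions([[ND] * 3 + [SD] * 3 + [D]], expert="E3"),
        ]
        score = group_rank(ops).scores.iloc[0]
        assert score == pytest.approx(0.175396799, abs=1e-6)

    def test_aggregation_order_equivalence(self):
        """Mean-of-TFNs-then-centroid == mean-of-centroids, and the flat
        mean over experts x criteria equals the mean of per-expert means."""
        rng = np.random.default_rng(0)
        labels = list(DIFFERENCE5.labels)
        cells = rng.choice(labels, size=(3, 7))
        ops = [_opinions([row], expert=f"E{i}") for i, row in enumerate(cells)]
        group = group_rank(ops).scores.iloc[0]
        flat = np.mean(
            [DIFFERENCE5.tfn_for_label(t).defuzzify() for t in cells.ravel()]
        )
        assert group == pytest.approx(flat, abs=1e-12)

    def test_monotone_in_severity(self):
        base = [[ND, SD, D, BD, ND, SD, D]]
        score0 = score_alternatives(_opinions(base)).iloc[0]
        for j, worse in [(0, SD), (1, D), (3, HD)]:
            cells = [list(base[0])]
            cells[0][j] = worse
            assert score_alternatives(_opinions(cells)).iloc[0] > score0

    def test_criteria_permutation_invariance(self):
        row = [ND, SD, D, BD, HD, ND, SD]
        a = score_alternatives(_opinions([row])).iloc[0]
        b = score_alternatives(_opinions([row[::-1]])).iloc[0]
        assert a == pytest.approx(b, abs=1e-12)


class TestGroupRank:
    def test_single_expert_group_equals_individual(self):
        op = _opinions([[ND] * 3, [D] * 3, [HD] * 3])
        result = group_rank([op])
        pd.testing.assert_series_equal(
            result.scores, score_alternatives(op), check_names=False
        )
        assert result.ranks.tolist() == [1, 2, 3]

    def test_identical_experts_average_to_same(self):
        op1 = _opinions([[SD] * 4, [BD] * 4], expert="E1")
        op2 = _opinions([[SD] * 4, [BD] * 4], expert="E2")
        result = group_rank([op1, op2])
        assert result.scores.tolist() == pytest.approx(
            score_alternatives(op1).tolist()
        )

    def test_expert_order_invariance(self):
        op1 = _opinions([[SD] * 3, [D] * 3], expert="E1")
        op2 = _opinions([[HD] * 3, [ND] * 3], expert="E2")
        a = group_rank([op1, op2]).scores
        b = group_rank([op2, op1]).scores
        pd.testing.assert_series_equal(a, b)

    def test_uniformly_less_severe_ranks_better(self):
        op = _opinions([[SD, D, SD], [D, BD, D]])
        result = group_rank([op])
        assert result.ranks["A1"] < result.ranks["A2"]

    def test_tied_alternatives_share_dense_rank(self):
        op = _opinions([[ND] * 3, [SD] * 3, [ND] * 3])
        result = group_rank([op])
        assert result.dense_ranks.tolist() == [1, 2, 1]
        assert sorted(result.ranks.tolist()) == [1, 2, 3]
        # ordinal ties broken by alternative order
        assert result.ranks["A1"] < result.ranks["A3"]

    def test_shape_mismatch_rejected(self):
        op1 = _opinions([[ND] * 3], expert="E1")
        op2 = _opinions([[ND] * 4], expert="E2")
        with pytest.raises(ValueError, match="E2"):
            group_rank([op1, op2])

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            group_rank([])

    def test_scores_always_within_bounds(self):
        rng = np.random.default_rng(5)
        labels = list(DIFFERENCE5.labels)
        for _ in range(10):
            cells = rng.choice(labels, size=(6, 7))
            scores = score_alternatives(_opinions(cells))
            assert ((scores >= SCORE_BOUNDS[0] - 1e-12)
                    & (scores <= SCORE_BOUNDS[1] + 1e-12)).all()

    def test_opinion_csv_roundtrip(self, tmp_path):
        op = _opinions([[ND, SD, D], [BD, HD, ND]], expert="panelist")
        path = tmp_path / "op.csv"
        op.write_csv(path)
        back = OpinionMatrix.read_csv(path)
        pd.testing.assert_frame_equal(back.terms, op.terms, check_names=False)
        assert back.expert == "op"  # expert id defaults to the file stem
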