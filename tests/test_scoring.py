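"""Pair assembly, per-pair scoring, and EQ scoring/imputation."""

import numpy as np
import pytest

from conftest import make_segment, make_track
from qrentrain import scoring
from qrentrain.errors import ValidationError
from qrentrain.io_formats import EQSheet, Keypoint, Role, Segment


def eq_sheet(pid="p", targets=None, fillers=None):
    scores = np.zeros(60)
    mask = np.zeros(60, dtype=bool)
    mask[:40] = True
    scores[:40] = targets if targets is not None else 0
    scores[40:] = fillers if fillers is not None else 0
    return EQSheet(participant_id=pid, item_scores=scores,
                   item_is_target=mask)


class TestBuildPairs:
    def segments(self):
        return [
            make_segment("q1", "d1", "a", Role.QUESTION, 0, 500),
            make_segment("q2", "d1", "a", Role.QUESTION, 1000, 1500),
            make_segment("q3", "d1", "b", Role.QUESTION, 3000, 3500),
            make_segment("r1", "d1", "b", Role.RESPONSE, 600, 900),
            make_segment("r2", "d1", "b", Role.RESPONSE, 1600, 2100),
            make_segment("q4", "d2", "c", Role.QUESTION, 0, 400),
            make_segment("r4", "d2", "d", Role.RESPONSE, 500, 900),
        ]

    def test_linked_rows_become_pairs_unlinked_dropped(self, caplog):
        pairs = scoring.build_pairs(self.segments(),
                                    [("q1", "r1"), ("q2", "r2")])
        assert [p.pair_id for p in pairs] == ["q1+r1", "q2+r2"]
        assert all(p.dyad_id == "d1" for p in pairs)

    def test_cross_dyad_link_rejected(self):
        with pytest.raises(ValidationError, match="across dyads"):
            scoring.build_pairs(self.segments(), [("q1", "r4")])

    def test_response_before_question_rejected(self):
        with pytest.raises(ValidationError, match="precedes"):
            scoring.build_pairs(self.segments(), [("q3", "r1")])

    def test_empty_table_gives_empty_output(self, caplog):
        assert scoring.build_pairs(self.segments(), []) == []


class TestScorePair:
    def _tracks(self, response_positions):
        q_pos = [(0, 0), (1, 0), (3, 0), (6, 0), (10, 0)]
        tracks = {
            "a": {kp: make_track(q_pos, speaker="a", keypoint=kp)
                  for kp in Keypoint},
            "b": {kp: make_track(response_positions, speaker="b",
                                 keypoint=kp)
                  for kp in Keypoint},
        }
        return tracks

    def _pair(self):
        q = make_segment("q", "d1", "a", Role.QUESTION, 0, 200)
        r = make_segment("r", "d1", "b", Role.RESPONSE, 0, 200)
        return scoring.QAPair("q+r", q, r, "d1")

    def test_exact_replay_scores_zero(self):
        tracks = self._tracks([(5, 5), (6, 5), (8, 5), (11, 5), (15, 5)])
        rec = scoring.score_pair(self._pair(), tracks)
        assert rec.head_distance == 0.0
        assert rec.hand_distance == 0.0
        assert rec.responder_id == "b"
        assert rec.condition == "real"

    def test_hand_distance_is_mean_of_left_and_right(self):
        tracks = self._tracks([(5, 5), (6, 5), (8, 5), (11, 5), (15, 5)])
        # make the left hand drift by +2 per step, right exact
        tracks["b"][Keypoint.LEFT_HAND] = make_track(
            [(0, 0), (3, 0), (7, 0), (12, 0), (18, 0)],
            speaker="b", keypoint=Keypoint.LEFT_HAND)
        rec = scoring.score_pair(self._pair(), tracks)
        left = scoring.segment_series(
            tracks, self._pair().response, Keypoint.LEFT_HAND)
        from qrentrain.dtw_core import pair_distance
        q_left = scoring.segment_series(
            tracks, self._pair().question, Keypoint.LEFT_HAND)
        expected_left = pair_distance(q_left, left)
        assert rec.hand_distance == pytest.approx((expected_left + 0.0) / 2)

    def test_unrecoverable_articulator_leaves_field_none(self):
        tracks = self._tracks([(5, 5), (6, 5), (8, 5), (11, 5), (15, 5)])
        bad = make_track(np.zeros((5, 2)), confidence=np.zeros(5),
                         speaker="b", keypoint=Keypoint.NOSE)
        tracks["b"][Keypoint.NOSE] = bad
        rec = scoring.score_pair(self._pair(), tracks)
        assert rec.head_distance is None
        assert rec.hand_distance is not None


class TestEQ:
    def test_maximal_sheet_totals_80(self):
        result = scoring.score_eq(eq_sheet(targets=2))
        assert result.total == 80

    def test_all_zero_and_alternating(self):
        assert scoring.score_eq(eq_sheet(targets=0)).total == 0
        alternating = np.tile([2.0, 0.0], 20)
        assert scoring.score_eq(eq_sheet(targets=alternating)).total == 40

    def test_fillers_never_count(self):
        assert scoring.score_eq(eq_sheet(targets=0, fillers=2)).total == 0

    def test_missing_target_requires_imputation_first(self):
        sheet = eq_sheet(targets=1)
        sheet.item_scores[3] = np.nan
        with pytest.raises(ValidationError, match="impute"):
            scoring.score_eq(sheet)

    def test_impute_uses_group_mean_rounded_half_up(self):
        # group scores {1, 2, 2} for item 1 -> mean 5/3 -> imputed 2
        sheets = [eq_sheet(str(i)) for i in range(4)]
        for sheet, v in zip(sheets[:3], (1.0, 2.0, 2.0)):
            sheet.item_scores[0] = v
        sheets[3].item_scores[0] = np.nan
        out = scoring.impute_eq(sheets)
        assert out[3].item_scores[0] == 2.0
        # {1, 1} with one missing -> 1
        sheets = [eq_sheet(str(i)) for i in range(3)]
        sheets[0].item_scores[5] = 1.0
        sheets[1].item_scores[5] = 1.0
        sheets[2].item_scores[5] = np.nan
        assert scoring.impute_eq(sheets)[2].item_scores[5] == 1.0

    def test_half_tie_rounds_up(self):
        sheets = [eq_sheet(str(i)) for i in range(3)]
        sheets[0].item_scores[0] = 1.0
        sheets[1].item_scores[0] = 2.0
        sheets[2].item_scores[0] = np.nan
        assert scoring.impute_eq(sheets)[2].item_scores[0] == 2.0  # 1.5 -> 2

    def test_no_missing_is_identity(self):
        sheets = [eq_sheet("a", targets=1), eq_sheet("b", targets=2)]
        out = scoring.impute_eq(sheets)
        for before, after in zip(sheets, out):
            assert np.array_equal(before.item_scores, after.item_scores)

    def test_item_missing_for_everyone_raises(self):
        sheets = [eq_sheet("a"), eq_sheet("b")]
        for s in sheets:
            s.item_scores[10] = np.nan
        with pytest.raises(Exception, match="impossible|skipped"):
            scoring.impute_eq(sheets)

    def test_eq_difference_symmetric_nonnegative(self, rng):
        for _ in range(20):
            a = scoring.EQResult("a", int(rng.integers(0, 81)))
            b = scoring.EQResult("b", int(rng.integers(0, 81)))
            d = scoring.eq_difference(a, b)
            assert d == scoring.eq_difference(b, a)
            assert d >= 0
        assert scoring.eq_difference(scoring.EQResult("a", 62),
                                     scoring.EQResult("b", 47)) == 15
        assert scoring.eq_difference(scoring.EQResult("a", 50),
                                     scoring.EQResult("b", 50)) == 0
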