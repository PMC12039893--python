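"""Generator: determinism, ground-truth consistency, coupling direction."""

import numpy as np
import pandas as pd
import pytest

from qrentrain import scoring, synthetic_data
from qrentrain.dtw_core import brute_force_dtw, dtw_distance
from qrentrain.io_formats import Keypoint, Role
from qrentrain.synthetic_data import SyntheticConfig, generate_study


def fast_config(**kw):
    base = dict(n_dyads=3, pairs_per_dyad=4, seed=5,
                duration_range_ms=(500, 1500),
                articulators=(Keypoint.NOSE,), generate_audio=False,
                calibration_probes=40)
    base.update(kw)
    return SyntheticConfig(**base)


class TestDeterminism:
    def test_same_seed_same_study(self):
        a = generate_study(fast_config())
        b = generate_study(fast_config())
        assert [s.segment_id for s in a.segments] == [
            s.segment_id for s in b.segments]
        for sp in a.tracks:
            for kp in a.tracks[sp]:
                assert np.array_equal(a.tracks[sp][kp].positions,
                                      b.tracks[sp][kp].positions)
        assert a.ground_truth.eq_totals == b.ground_truth.eq_totals

    def test_written_study_is_byte_stable(self, tmp_path):
        cfg = fast_config(generate_audio=True,
                          articulators=(Keypoint.NOSE,))
        d1, d2 = tmp_path / "a", tmp_path / "b"
        synthetic_data.write_study(generate_study(cfg), d1)
        synthetic_data.write_study(generate_study(cfg), d2)
        for p1 in sorted(d1.rglob("*")):
            if p1.is_file():
                p2 = d2 / p1.relative_to(d1)
                assert p1.read_bytes() == p2.read_bytes(), p1.name

    def test_different_seeds_differ(self):
        a = generate_study(fast_config(seed=1))
        b = generate_study(fast_config(seed=2))
        assert a.ground_truth.eq_totals != b.ground_truth.eq_totals


class TestStudyShape:
    def test_segments_frame_aligned_and_in_range(self):
        study = generate_study(fast_config())
        lo, hi = study.config.duration_range_ms
        for seg in study.segments:
            # frame-aligned onsets: slicing recovers exact generator frames
            assert seg.offset > seg.onset >= 0
        qs = [s for s in study.segments if s.role is Role.QUESTION]
        assert len(qs) == 3 * 4

    def test_pairing_table_links_within_dyads(self):
        study = generate_study(fast_config())
        by_id = {s.segment_id: s for s in study.segments}
        for q_id, r_id in study.pairing_table:
            assert by_id[q_id].dyad_id == by_id[r_id].dyad_id
            assert by_id[q_id].role is Role.QUESTION
            assert by_id[r_id].role is Role.RESPONSE

    def test_eq_totals_reproduced_by_scoring_when_complete(self):
        """With no skipped items, impute+score recovers planted totals."""
        study = generate_study(fast_config(p_missing_item=0.0))
        imputed = scoring.impute_eq(study.eq_sheets)
        for sheet in imputed:
            total = scoring.score_eq(sheet).total
            assert total == study.ground_truth.eq_totals[
                sheet.participant_id]

    def test_eq_totals_with_missingness_stay_in_range(self):
        study = generate_study(fast_config(p_missing_item=0.2))
        imputed = scoring.impute_eq(study.eq_sheets)
        for sheet in imputed:
            assert 0 <= scoring.score_eq(sheet).total <= 80


class TestCoupling:
    def test_perfect_coupling_limit_gives_near_zero_distances(self):
        """No noise, maximal coupling, equal lengths -> replayed motion."""
        cfg = fast_config(coupling_intercept=0.0,
                          coupling_slope_per_eq_point=0.0,
                          group_intercept_sd=0.0, noise_sd=0.0,
                          duration_range_ms=(1000, 1000))
        study = generate_study(cfg)
        by_id = {s.segment_id: s for s in study.segments}
        for q_id, r_id in study.pairing_table:
            q, r = by_id[q_id], by_id[r_id]
            qs = study.tracks[q.speaker_id][Keypoint.NOSE]
            rs = study.tracks[r.speaker_id][Keypoint.NOSE]
            from qrentrain.scoring import segment_series
            dq = segment_series(study.tracks, q, Keypoint.NOSE)
            dr = segment_series(study.tracks, r, Keypoint.NOSE)
            # with zero coupling target the response replays the question
            # exactly (up to the distance floor of the calibration grid)
            assert dtw_distance(dq, dr) < 0.1

    def test_mean_distance_ordering_follows_slope(self):
        """Across slopes {0, small, large}, mean real-pair distance
        ordering follows the slope ordering."""
        from qrentrain import pipeline

        means = []
        for slope in (0.0, 0.05, 0.15):
            cfg = fast_config(n_dyads=4, pairs_per_dyad=8,
                              coupling_slope_per_eq_point=slope, seed=9)
            real, _ = pipeline.score_synthetic(generate_study(cfg), seed=1)
            means.append(real.head_distance.mean())
        assert means[0] < means[1] < means[2]

    def test_calibrated_targets_match_measured_distances(self):
        """The planted per-pair expected distance predicts the realized
        distance approximately unbiasedly."""
        from qrentrain import pipeline

        cfg = fast_config(n_dyads=6, pairs_per_dyad=10, seed=17,
                          calibration_probes=120)
        study = generate_study(cfg)
        real, _ = pipeline.score_synthetic(study, seed=3)
        target = real.pair_id.map(study.ground_truth.pair_target)
        ratio = real.head_distance.mean() / target.mean()
        assert 0.85 < ratio < 1.15


class TestWorkedFixture:
    def test_expected_values_come_from_the_oracle(self):
        bundle = synthetic_data.generate_worked_fixture()
        for dyad, pairs in bundle["series"].items():
            for (q, r), expected in zip(
                    pairs, bundle["expected_normalized_distance"][dyad]):
                assert brute_force_dtw(q, r).normalized_distance == expected
                assert dtw_distance(q, r) == pytest.approx(expected,
                                                           abs=1e-12)

    def test_identical_series_pair_has_zero_distance(self):
        bundle = synthetic_data.generate_worked_fixture()
        assert bundle["expected_normalized_distance"]["dyadA"][0] == 0.0

    def test_fixture_is_deterministic(self):
        a = synthetic_data.generate_worked_fixture()
        b = synthetic_data.generate_worked_fixture()
        for dyad in a["series"]:
            assert a["expected_normalized_distance"][dyad] == \
                b["expected_normalized_distance"][dyad]


def test_worked_fixture_written_files_are_byte_identical(tmp_path):
    a, b = tmp_path / "a", tmp_path / "b"
    synthetic_data.generate_worked_fixture(a)
    synthetic_data.generate_worked_fixture(b)
    fa, fb = a / "worked_fixture.json", b / "worked_fixture.json"
    assert fa.exists()
    assert fa.read_bytes() == fb.read_bytes()
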