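"""End-to-end orchestration: raw inputs -> per-pair entrainment records.

The processing chain mirrors the study design: annotated question-response
windows select sub-tracks from each speaker's keypoint streams; sub-tracks
are confidence-repaired and reduced to displacement series; DTW scores the
question-vs-response similarity per articulator (head = nose; hand = mean
of left and right); the pitch tracker scores the F0 mismatch; EQ sheets
are imputed, scored, and differenced per dyad.  The same cached per-segment
series score both the real pairs and the within-dyad pseudo-pairs, so the
surrogate comparison never recomputes kinematics.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import inference, prosody, scoring
from .config import PipelineConfig
from .dtw_core import pair_distance
from .errors import QrentrainError
from .io_formats import AudioClip, EQSheet, Keypoint, KeypointTrack, Segment
from .scoring import QAPair
from .synthetic_data import SyntheticStudy

logger = logging.getLogger(__name__)

__all__ = ["score_study", "records_frame", "attach_group", "score_synthetic"]


class _SeriesCache:
    """Per-(segment, articulator) displacement series, computed once."""

    def __init__(self, tracks, cfg: PipelineConfig):
        self._tracks = tracks
        self._cfg = cfg
        self._store: dict[tuple[str, Keypoint], object] = {}
        self._speaker_scale: dict[str, float] = {}

    def get(self, segment: Segment, keypoint: Keypoint):
        key = (segment.segment_id, keypoint)
        if key not in self._store:
            try:
                series = scoring.segment_series(
                    self._tracks, segment, keypoint,
                    conf_threshold=self._cfg.kinematics.conf_threshold,
                    max_missing_fraction=(
                        self._cfg.kinematics.max_missing_fraction),
                    smoothing_window=self._cfg.kinematics.smoothing_window,
                )
            except KeyError:
                logger.info("segment %s: no %s track for speaker %s",
                            segment.segment_id, keypoint.value,
                            segment.speaker_id)
                series = None
            except QrentrainError as exc:
                logger.info("segment %s, %s: %s", segment.segment_id,
                            keypoint.value, exc)
                series = None
            self._store[key] = series
        return self._store[key]


class _PitchCache:
    def __init__(self, audio, cfg: PipelineConfig):
        self._audio = audio
        self._cfg = cfg
        self._store: dict[str, prosody.PitchResult | None] = {}

    def get(self, segment: Segment):
        if segment.segment_id not in self._store:
            p = self._cfg.prosody
            try:
                result = prosody.estimate_pitch(
                    self._audio[segment.speaker_id], segment,
                    floor=p.pitch_floor, ceiling=p.pitch_ceiling,
                    frame_step_ms=p.frame_step_ms,
                    voicing_threshold=p.voicing_threshold,
                )
            except QrentrainError as exc:
                logger.info("segment %s audio: %s", segment.segment_id, exc)
                result = None
            self._store[segment.segment_id] = result
        return self._store[segment.segment_id]


def _score_from_caches(
    pair: QAPair,
    series_cache: _SeriesCache,
    pitch_cache: _PitchCache | None,
    cfg: PipelineConfig,
    articulators: Sequence[Keypoint],
    condition: str,
) -> scoring.EntrainmentRecord:
    def dist(keypoint: Keypoint):
        if keypoint not in articulators:
            return None
        q = series_cache.get(pair.question, keypoint)
        r = series_cache.get(pair.response, keypoint)
        if q is None or r is None:
            return None
        return pair_distance(q, r, cfg.dtw.step_pattern, cfg.dtw.band)

    head = dist(Keypoint.NOSE)
    hands = [d for d in (dist(Keypoint.LEFT_HAND),
                         dist(Keypoint.RIGHT_HAND)) if d is not None]
    hand = float(np.mean(hands)) if hands else None

    f0_diff = None
    if pitch_cache is not None:
        qp = pitch_cache.get(pair.question)
        rp = pitch_cache.get(pair.response)
        if qp is not None and rp is not None:
            f0_diff = prosody.f0_mismatch(qp, rp, cfg.prosody.statistic)

    return scoring.EntrainmentRecord(
        pair_id=pair.pair_id, dyad_id=pair.dyad_id,
        responder_id=pair.response.speaker_id, condition=condition,
        head_distance=head, hand_distance=hand, f0_diff=f0_diff,
    )


def records_frame(records: Sequence[scoring.EntrainmentRecord]
                  ) -> pd.DataFrame:
    df = pd.DataFrame(
        [{"pair_id": r.pair_id, "dyad_id": r.dyad_id,
          "responder_id": r.responder_id, "condition": r.condition,
          "head_distance": r.head_distance, "hand_distance": r.hand_distance,
          "f0_diff": r.f0_diff, "eq_diff": r.eq_diff}
         for r in records]
    )
    return attach_group(df)


def attach_group(df: pd.DataFrame) -> pd.DataFrame:
    """The mixed-model grouping key: one identifier per dyad x responder."""
    df = df.copy()
    df["group"] = df["dyad_id"].astype(str) + ":" + df[
        "responder_id"].astype(str)
    return df


def score_study(
    segments: Sequence[Segment],
    pairing_table: Sequence[tuple[str, str]],
    tracks: Mapping[str, Mapping[Keypoint, KeypointTrack]],
    audio: Mapping[str, AudioClip] | None = None,
    eq_sheets: Sequence[EQSheet] | None = None,
    config: PipelineConfig | None = None,
    seed: int = 0,
    articulators: Sequence[Keypoint] = (
        Keypoint.NOSE, Keypoint.LEFT_HAND, Keypoint.RIGHT_HAND),
    n_shuffles: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every real pair and a within-dyad pseudo-pair counterpart.

    Returns ``(real_records, pseudo_records)`` DataFrames carrying the
    grouping key and, when EQ sheets are supplied, the dyad EQ difference.
    One pseudo dataset is built per seed; ``n_shuffles > 1`` instead
    averages each question's pseudo measures over that many independent
    derangements, reducing the Monte-Carlo noise of a single shuffle.
    """
    cfg = config or PipelineConfig()
    pairs = scoring.build_pairs(segments, pairing_table)
    series_cache = _SeriesCache(tracks, cfg)
    pitch_cache = _PitchCache(audio, cfg) if audio is not None else None

    real = [
        _score_from_caches(p, series_cache, pitch_cache, cfg, articulators,
                           "real")
        for p in pairs
    ]
    rng = np.random.default_rng(seed)
    pseudo_frames = []
    for _ in range(max(1, n_shuffles)):
        pseudo_pairs = inference.shuffle_pairs(pairs, rng)
        pseudo_frames.append(records_frame([
            _score_from_caches(p, series_cache, pitch_cache, cfg,
                               articulators, "pseudo")
            for p in pseudo_pairs
        ]))

    real_df = records_frame(real)
    if len(pseudo_frames) == 1:
        pseudo_df = pseudo_frames[0]
    else:
        # average each question's pseudo measures over the realizations;
        # the averaged record keeps the question's real-pair grouping so
        # the mixed model sees the same group structure in both conditions
        stacked = pd.concat(pseudo_frames, ignore_index=True)
        stacked["question_id"] = stacked.pair_id.str.split("+").str[0]
        means = (stacked.groupby(["question_id", "dyad_id"],
                                 as_index=False)
                 [["head_distance", "hand_distance", "f0_diff"]].mean())
        anchor = real_df.assign(
            question_id=real_df.pair_id.str.split("+").str[0]
        )[["question_id", "responder_id", "group"]]
        pseudo_df = means.merge(anchor, on="question_id", how="left")
        pseudo_df["condition"] = "pseudo"
        pseudo_df["pair_id"] = (pseudo_df.question_id
                                + f"+avg{len(pseudo_frames)}")
        pseudo_df = pseudo_df.drop(columns="question_id")
    if eq_sheets:
        imputed = scoring.impute_eq(list(eq_sheets))
        totals = {s.participant_id: scoring.score_eq(s).total
                  for s in imputed}
        by_dyad: dict[str, list[str]] = {}
        for seg in segments:
            members = by_dyad.setdefault(seg.dyad_id, [])
            if seg.speaker_id not in members:
                members.append(seg.speaker_id)
        eq_diff = {
            dyad: abs(totals[m[0]] - totals[m[1]])
            for dyad, m in by_dyad.items() if len(m) == 2
        }
        for df in (real_df, pseudo_df):
            df["eq_diff"] = df["dyad_id"].map(eq_diff).astype(float)
    return real_df, pseudo_df


def score_synthetic(
    study: SyntheticStudy,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: run the full pipeline on a generated study."""
    return score_study(
        study.segments, study.pairing_table, study.tracks, study.audio,
        study.eq_sheets, config, seed,
        articulators=study.config.articulators,
    )
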