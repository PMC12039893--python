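"""Pair assembly, per-pair entrainment scoring, and EQ questionnaire scoring.

A question and its response form an adjacency pair; entrainment is scored
per pair and per modality.  Head entrainment is the normalized DTW distance
between the questioner's nose displacement during the question and the
responder's nose displacement during the response; hand entrainment is the
mean of the left-hand and right-hand distances; prosodic matching is the
absolute F0 difference between the two turns.

Empathy-quotient sheets are scored out of 80 (40 target items, up to two
points each) after group-mean imputation of skipped items: a missing item
is replaced by the mean score of all respondents on that item, rounded to
the closest integer (half-up).  The dyad-level predictor is the absolute
difference between the two partners' totals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import kinematics, prosody
from .dtw_core import pair_distance
from .errors import (
    ImputationError,
    QrentrainError,
    ValidationError,
)
from .io_formats import (
    AudioClip,
    EQSheet,
    Keypoint,
    KeypointTrack,
    Role,
    Segment,
)

logger = logging.getLogger(__name__)

__all__ = [
    "QAPair",
    "EntrainmentRecord",
    "EQResult",
    "build_pairs",
    "segment_series",
    "score_pair",
    "score_eq",
    "impute_eq",
    "eq_difference",
]


@dataclass(frozen=True)
class QAPair:
    """A matched question-response adjacency pair within one dyad."""

    pair_id: str
    question: Segment
    response: Segment
    dyad_id: str
    #: surrogate pairs come from within-dyad shuffling, so the response
    #: need not follow its (artificial) question in time
    surrogate: bool = False

    def __post_init__(self) -> None:
        if self.question.role is not Role.QUESTION:
            raise ValidationError(
                f"pair {self.pair_id!r}: first segment is not a question"
            )
        if self.response.role is not Role.RESPONSE:
            raise ValidationError(
                f"pair {self.pair_id!r}: second segment is not a response"
            )
        if self.question.dyad_id != self.response.dyad_id:
            raise ValidationError(
                f"pair {self.pair_id!r} links segments across dyads "
                f"({self.question.dyad_id!r} vs {self.response.dyad_id!r})"
            )
        if self.dyad_id != self.question.dyad_id:
            raise ValidationError(
                f"pair {self.pair_id!r}: dyad_id disagrees with its segments"
            )
        if not self.surrogate and self.response.onset < self.question.onset:
            raise ValidationError(
                f"pair {self.pair_id!r}: response precedes its question"
            )


@dataclass
class EntrainmentRecord:
    """Per-pair, per-condition entrainment measures.

    Distances are normalized DTW distances (pixels per aligned step);
    ``f0_diff`` is in Hz.  A ``None`` measure means that modality could not
    be computed for this pair (e.g. unvoiced segment, rejected track).
    """

    pair_id: str
    dyad_id: str
    responder_id: str
    condition: str  # "real" or "pseudo"
    head_distance: float | None = None
    hand_distance: float | None = None
    f0_diff: float | None = None
    eq_diff: float | None = None

    def __post_init__(self) -> None:
        if self.condition not in ("real", "pseudo"):
            raise ValidationError(
                f"condition must be 'real' or 'pseudo', got "
                f"{self.condition!r}"
            )
        for name in ("head_distance", "hand_distance", "f0_diff", "eq_diff"):
            value = getattr(self, name)
            if value is not None and not np.isnan(value) and value < 0:
                raise ValidationError(f"{name} must be non-negative")


@dataclass(frozen=True)
class EQResult:
    """Scored empathy quotient for one participant."""

    participant_id: str
    total: int
    n_imputed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.total <= 80:
            raise ValidationError("EQ total must lie in [0, 80]")
        if self.n_imputed > 40:
            raise ValidationError("cannot impute more than 40 target items")


def build_pairs(
    segments: Sequence[Segment],
    pairing_table: Iterable[tuple[str, str]],
) -> list[QAPair]:
    """Link annotated questions to their responses.

    ``pairing_table`` rows are (question_segment_id, response_segment_id);
    questions without a linked response are dropped (with a logged count),
    mirroring the fact that not every question in conversation receives a
    response.
    """
    by_id = {s.segment_id: s for s in segments}
    pairs: list[QAPair] = []
    linked_questions = set()
    for q_id, r_id in pairing_table:
        if q_id not in by_id or r_id not in by_id:
            raise ValidationError(
                f"pairing table references unknown segment "
                f"({q_id!r}, {r_id!r})"
            )
        q, r = by_id[q_id], by_id[r_id]
        pairs.append(QAPair(pair_id=f"{q_id}+{r_id}", question=q,
                            response=r, dyad_id=q.dyad_id))
        linked_questions.add(q_id)
    n_questions = sum(1 for s in segments if s.role is Role.QUESTION)
    dropped = n_questions - len(linked_questions)
    if not pairs:
        logger.warning("empty pairing table: no question-response pairs")
    elif dropped:
        logger.info("%d of %d questions had no linked response and were "
                    "dropped", dropped, n_questions)
    return pairs


def segment_series(
    tracks: Mapping[str, Mapping[Keypoint, KeypointTrack]],
    segment: Segment,
    keypoint: Keypoint,
    conf_threshold: float = 0.3,
    max_missing_fraction: float = 0.5,
    smoothing_window: int = 0,
) -> kinematics.DisplacementSeries:
    """Displacement series of one articulator within one segment window."""
    track = tracks[segment.speaker_id][keypoint]
    sub = kinematics.slice_track(track, segment)
    sub = kinematics.repair_missing(sub, conf_threshold, max_missing_fraction)
    series = kinematics.displacement(sub, segment_id=segment.segment_id)
    return kinematics.smooth(series, smoothing_window)


def score_pair(
    pair: QAPair,
    tracks: Mapping[str, Mapping[Keypoint, KeypointTrack]],
    audio: Mapping[str, AudioClip] | None = None,
    config=None,
    condition: str = "real",
) -> EntrainmentRecord:
    """Score one question-response pair on all available modalities.

    An articulator (or the audio) that cannot be processed leaves its field
    ``None`` with the reason logged; the record is still emitted so the
    other modalities survive.
    """
    from .config import PipelineConfig  # local import to avoid cycle

    cfg = config or PipelineConfig()

    def series(segment: Segment, keypoint: Keypoint):
        return segment_series(
            tracks, segment, keypoint,
            conf_threshold=cfg.kinematics.conf_threshold,
            max_missing_fraction=cfg.kinematics.max_missing_fraction,
            smoothing_window=cfg.kinematics.smoothing_window,
        )

    def articulator_distance(keypoint: Keypoint) -> float | None:
        try:
            q = series(pair.question, keypoint)
            r = series(pair.response, keypoint)
        except QrentrainError as exc:
            logger.info("pair %s, %s: %s", pair.pair_id, keypoint.value, exc)
            return None
        return pair_distance(q, r, cfg.dtw.step_pattern, cfg.dtw.band)

    head = articulator_distance(Keypoint.NOSE)
    left = articulator_distance(Keypoint.LEFT_HAND)
    right = articulator_distance(Keypoint.RIGHT_HAND)
    hand = None
    present = [d for d in (left, right) if d is not None]
    if present:
        hand = float(np.mean(present))

    f0_diff = None
    if audio is not None:
        try:
            qp = prosody.estimate_pitch(
                audio[pair.question.speaker_id], pair.question,
                floor=cfg.prosody.pitch_floor,
                ceiling=cfg.prosody.pitch_ceiling,
                frame_step_ms=cfg.prosody.frame_step_ms,
                voicing_threshold=cfg.prosody.voicing_threshold,
            )
            rp = prosody.estimate_pitch(
                audio[pair.response.speaker_id], pair.response,
                floor=cfg.prosody.pitch_floor,
                ceiling=cfg.prosody.pitch_ceiling,
                frame_step_ms=cfg.prosody.frame_step_ms,
                voicing_threshold=cfg.prosody.voicing_threshold,
            )
            f0_diff = prosody.f0_mismatch(qp, rp, cfg.prosody.statistic)
            if f0_diff is None:
                logger.info("pair %s: unvoiced segment, dropped from "
                            "prosodic analyses", pair.pair_id)
        except QrentrainError as exc:
            logger.info("pair %s audio: %s", pair.pair_id, exc)

    return EntrainmentRecord(
        pair_id=pair.pair_id,
        dyad_id=pair.dyad_id,
        responder_id=pair.response.speaker_id,
        condition=condition,
        head_distance=head,
        hand_distance=hand,
        f0_diff=f0_diff,
    )


def impute_eq(sheets: Sequence[EQSheet]) -> list[EQSheet]:
    """Group-mean imputation of skipped items, rounded half-up to an integer.

    The imputation group is every respondent in the loaded dataset.  Items
    answered by nobody cannot be imputed and raise.
    """
    if not sheets:
        return []
    matrix = np.vstack([s.item_scores for s in sheets])
    answered = np.isfinite(matrix).any(axis=0)
    if not answered.all():
        missing_cols = np.flatnonzero(~answered)
        raise ImputationError(
            f"items {(missing_cols + 1).tolist()} were skipped by every "
            "respondent; group-mean imputation impossible"
        )
    col_means = np.nanmean(matrix, axis=0)
    imputed_values = np.floor(col_means + 0.5)  # round half up
    out = []
    for sheet in sheets:
        scores = sheet.item_scores.copy()
        gaps = ~np.isfinite(scores)
        scores[gaps] = imputed_values[gaps]
        out.append(replace(sheet, item_scores=scores))
    return out


def score_eq(sheet: EQSheet) -> EQResult:
    """Total over the 40 target items (0-80); filler items never count."""
    targets = sheet.item_scores[sheet.item_is_target]
    if not np.isfinite(targets).all():
        bad = np.flatnonzero(
            sheet.item_is_target & ~np.isfinite(sheet.item_scores))
        raise ValidationError(
            f"participant {sheet.participant_id!r}: target item(s) "
            f"{(bad + 1).tolist()} missing; run impute_eq first"
        )
    return EQResult(participant_id=sheet.participant_id,
                    total=int(targets.sum()))


def eq_difference(a: EQResult, b: EQResult) -> int:
    """Absolute EQ-score difference between two dyad partners."""
    return abs(a.total - b.total)
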