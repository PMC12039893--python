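"""Synthetic dyadic studies with known ground-truth coupling.

The raw conversational corpus behind this analysis cannot be shared, so the
pipeline is exercised end-to-end on generated studies that emulate its data
shapes: question/response annotations on a 25 fps timeline, 2D keypoint
tracks whose displacement magnitudes follow smooth autocorrelated
processes, harmonic speech tones with near-matched F0 within pairs, and
60-item EQ sheets with occasional skipped items.

The generative model, per dyad:

* Each participant receives an EQ total (truncated normal), decomposed into
  a 40-target-item sheet that sums to it; items are skipped at random with
  a small probability.  The dyad predictor is the absolute total difference
  after group-mean imputation (exactly what the pipeline recomputes).
* Each speaker's articulators move as independent smooth non-negative
  displacement processes (low-pass-filtered Gaussian noise around a
  positive baseline, rectified), converted to 2D positions by integration.
* During a response window the responder's movement is a time-rescaled copy
  of the source motion plus smooth noise whose amplitude is *calibrated*
  (by Monte Carlo probes at two amplitudes) so that the expected normalized
  DTW distance of the pair equals ``coupling_intercept +
  coupling_slope_per_eq_point * |dEQ| + responder offset``.  Ground truth
  is therefore expressed directly in the pipeline's dependent variable.
* With ``adjacency_specific=False`` the copied source is not the paired
  question: responses track a dyad-level latent motion (or, optionally, a
  randomly chosen *other* question of the dyad), preserving dyad-level
  similarity while destroying pair-specific coupling — the null of the
  surrogate test.
* Audio is a harmonic complex per segment: questioners speak at their own
  base F0, responders echo the question's F0 plus Normal(0, f0_match_sd)
  jitter.

Everything is deterministic under the config seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import io_formats, scoring
from .dtw_core import brute_force_dtw, dtw_distance
from .errors import ValidationError
from .io_formats import (
    AudioClip,
    EQSheet,
    Keypoint,
    KeypointTrack,
    Role,
    Segment,
)

logger = logging.getLogger(__name__)

__all__ = ["SyntheticConfig", "SyntheticStudy", "GroundTruth",
           "generate_study", "write_study", "generate_worked_fixture"]


class SyntheticConfig(BaseModel):
    """Study-level knobs of the generator (defaults are the study conditions)."""

    n_dyads: int = Field(20, ge=1)
    pairs_per_dyad: int = Field(30, ge=1)
    fps: float = Field(25.0, gt=0)
    duration_range_ms: tuple[int, int] = (500, 4000)
    coupling_intercept: float = 1.0      # expected distance at dEQ = 0
    coupling_slope_per_eq_point: float = 0.05  # distance units per EQ point
    adjacency_specific: bool = True
    null_style: Literal["independent", "dyad_latent",
                        "other_question"] = "independent"
    noise_sd: float = Field(0.05, ge=0)  # frame-level measurement jitter
    f0_base_range: tuple[float, float] = (90.0, 220.0)
    f0_match_sd: float = Field(5.0, ge=0)
    eq_mean: float = 44.0
    eq_sd: float = Field(10.0, ge=0)
    p_missing_item: float = Field(0.02, ge=0.0, le=1.0)
    seed: int = 0
    # data-shape details
    articulators: tuple[Keypoint, ...] = (
        Keypoint.NOSE, Keypoint.LEFT_HAND, Keypoint.RIGHT_HAND)
    generate_audio: bool = True
    audio_sample_rate: int = 16000
    p_dropout: float = Field(0.0, ge=0.0, le=1.0)
    gap_ms: int = 200
    # motion-process parameters
    base_mean: float = 20.0              # px/frame baseline displacement
    base_sd: float = 4.0
    smoothness_frames: int = 5
    group_intercept_sd: float = Field(0.3, ge=0)  # per-responder offset
    step_pattern: Literal["symmetric1", "symmetric2"] = "symmetric2"
    calibration_probes: int = Field(150, ge=10)

    @model_validator(mode="after")
    def _check_ranges(self):
        lo, hi = self.duration_range_ms
        if not (99 <= lo <= hi <= 13145):
            raise ValueError(
                "duration_range_ms must be ordered and lie within the "
                "observed corpus range [99, 13145] ms"
            )
        if self.f0_base_range[0] >= self.f0_base_range[1]:
            raise ValueError("f0_base_range must be ordered")
        return self


@dataclass
class GroundTruth:
    """What the generator actually planted, keyed for later recovery checks."""

    amp_grid: np.ndarray         # calibration amplitudes
    dist_grid: np.ndarray        # mean normalized distance at each amplitude
    eq_totals: dict[str, int]    # realized totals (post-imputation)
    delta_eq: dict[str, int]     # per dyad
    pair_target: dict[str, float]   # designed expected distance per pair
    segment_f0: dict[str, float]    # per segment
    responder_offset: dict[str, float]
    coupling_slope: float = 0.0
    coupling_intercept: float = 0.0


@dataclass
class SyntheticStudy:
    """A complete generated study in the pipeline's own input types."""

    config: SyntheticConfig
    segments: list[Segment]
    pairing_table: list[tuple[str, str]]
    tracks: dict[str, dict[Keypoint, KeypointTrack]]
    audio: Optional[dict[str, AudioClip]]
    eq_sheets: list[EQSheet]
    ground_truth: GroundTruth


def _smooth_unit_noise(n: int, window: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-variance, autocorrelated noise of length n."""
    if n <= 0:
        return np.empty(0)
    window = max(1, window)
    kernel = np.exp(-0.5 * ((np.arange(4 * window + 1) - 2 * window)
                            / window) ** 2)
    kernel /= np.linalg.norm(kernel)
    pad = len(kernel)
    white = rng.standard_normal(n + 2 * pad)
    return np.convolve(white, kernel, mode="same")[pad:pad + n]


def _baseline_series(n: int, cfg: SyntheticConfig,
                     rng: np.random.Generator) -> np.ndarray:
    """Smooth non-negative displacement process around the baseline level."""
    u = _smooth_unit_noise(n, cfg.smoothness_frames, rng)
    return np.maximum(0.0, cfg.base_mean + cfg.base_sd * u)


def _stretch(series: np.ndarray, n_out: int) -> np.ndarray:
    """Time-rescale a series to a new length by linear interpolation."""
    if len(series) == 1:
        return np.full(n_out, series[0])
    src = np.linspace(0.0, 1.0, len(series))
    dst = np.linspace(0.0, 1.0, n_out)
    return np.interp(dst, src, series)


def _coupled_response(source: np.ndarray, n_out: int, amplitude: float,
                      cfg: SyntheticConfig,
                      rng: np.random.Generator) -> np.ndarray:
    r = _stretch(source, n_out)
    r = r + amplitude * _smooth_unit_noise(n_out, cfg.smoothness_frames, rng)
    if cfg.noise_sd > 0:
        r = r + rng.normal(0.0, cfg.noise_sd, n_out)
    return np.maximum(0.0, r)


_CALIBRATION_AMPLITUDES = np.array(
    [0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 16.0, 24.0])


def _calibrate(cfg: SyntheticConfig,
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Measure the expected-distance-vs-noise-amplitude curve by Monte Carlo.

    Probe pairs are drawn from the same motion process and duration
    distribution as the study; the mean normalized DTW distance is measured
    on a grid of noise amplitudes.  Common random numbers across grid
    points (each probe keeps its source series and noise shape, only the
    amplitude changes) make the *shape* of the curve much more precise than
    its absolute level, which is what linear-in-dEQ coupling needs.
    Inverting the curve maps a target expected distance to the amplitude
    that produces it.
    """
    lo, hi = cfg.duration_range_ms
    amps = _CALIBRATION_AMPLITUDES
    dists = np.empty((cfg.calibration_probes, len(amps)))
    for i in range(cfg.calibration_probes):
        nq = max(2, int(round(rng.uniform(lo, hi) * cfg.fps / 1000.0)))
        nr = max(2, int(round(rng.uniform(lo, hi) * cfg.fps / 1000.0)))
        q = _baseline_series(nq - 1, cfg, rng)
        stretched = _stretch(q, nr - 1)
        u = _smooth_unit_noise(nr - 1, cfg.smoothness_frames, rng)
        jitter = (rng.normal(0.0, cfg.noise_sd, nr - 1)
                  if cfg.noise_sd > 0 else 0.0)
        for j, a in enumerate(amps):
            r = np.maximum(0.0, stretched + a * u + jitter)
            dists[i, j] = dtw_distance(q, r, cfg.step_pattern)
    curve = dists.mean(axis=0)
    if not np.all(np.diff(curve) > 0):
        raise ValidationError("calibration failed: mean distance is not "
                              "monotone in noise amplitude")
    return amps, curve


def _decompose_eq_total(total: int, rng: np.random.Generator) -> np.ndarray:
    """Random 40-vector over {0,1,2} summing exactly to ``total``."""
    if not 0 <= total <= 80:
        raise ValidationError(f"EQ total {total} is not achievable (0-80)")
    scores = np.zeros(io_formats.N_EQ_TARGETS, dtype=float)
    for _ in range(total):
        open_items = np.flatnonzero(scores < 2)
        scores[open_items[rng.integers(len(open_items))]] += 1
    return scores


def _make_eq_sheets(participants: Sequence[str], cfg: SyntheticConfig,
                    rng: np.random.Generator
                    ) -> tuple[list[EQSheet], dict[str, int]]:
    mask = np.zeros(io_formats.N_EQ_ITEMS, dtype=bool)
    target_idx = rng.choice(io_formats.N_EQ_ITEMS, io_formats.N_EQ_TARGETS,
                            replace=False)
    mask[target_idx] = True
    sheets = []
    for pid in participants:
        total = int(np.clip(round(rng.normal(cfg.eq_mean, cfg.eq_sd)), 0, 80))
        scores = np.empty(io_formats.N_EQ_ITEMS)
        scores[mask] = _decompose_eq_total(total, rng)
        scores[~mask] = rng.integers(0, 3, io_formats.N_EQ_ITEMS
                                     - io_formats.N_EQ_TARGETS).astype(float)
        if cfg.p_missing_item > 0:
            gaps = rng.random(io_formats.N_EQ_ITEMS) < cfg.p_missing_item
            scores[gaps] = np.nan
        sheets.append(EQSheet(participant_id=pid, item_scores=scores,
                              item_is_target=mask.copy()))
    imputed = scoring.impute_eq(sheets)
    totals = {s.participant_id: scoring.score_eq(s).total for s in imputed}
    return sheets, totals


def _frame_aligned_ms(frame: int, fps: float) -> int:
    """Smallest integer ms whose floor-mapped frame index equals ``frame``."""
    return int(np.ceil(frame * 1000.0 / fps))


def _harmonic_tone(f0: float, n: int, sr: int,
                   rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n) / sr
    tone = np.zeros(n)
    for k, amp in enumerate((1.0, 0.5, 0.25, 0.125), start=1):
        tone += amp * np.sin(2 * np.pi * k * f0 * t + rng.uniform(0, 2 * np.pi))
    return 0.25 * tone / np.abs(tone).max()


def generate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Generate a complete synthetic study (see module docstring)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    amp_grid, dist_grid = _calibrate(
        cfg, np.random.default_rng(rng.integers(2 ** 31)))

    dyads = [f"dyad{d:02d}" for d in range(cfg.n_dyads)]
    participants = {d: (f"{d}_p0", f"{d}_p1") for d in dyads}
    all_participants = [p for pair in participants.values() for p in pair]

    eq_sheets, totals = _make_eq_sheets(all_participants, cfg, rng)
    delta_eq = {d: abs(totals[a] - totals[b])
                for d, (a, b) in participants.items()}
    responder_offset = {
        p: float(rng.normal(0.0, cfg.group_intercept_sd))
        for p in all_participants
    }

    lo, hi = cfg.duration_range_ms
    segments: list[Segment] = []
    pairing: list[tuple[str, str]] = []
    tracks: dict[str, dict[Keypoint, KeypointTrack]] = {}
    audio: dict[str, AudioClip] | None = {} if cfg.generate_audio else None
    pair_target: dict[str, float] = {}
    segment_f0: dict[str, float] = {}
    gap_frames = max(1, int(round(cfg.gap_ms * cfg.fps / 1000.0)))

    for dyad in dyads:
        p0, p1 = participants[dyad]
        base_f0 = {p: float(rng.uniform(*cfg.f0_base_range))
                   for p in (p0, p1)}
        # lay out the dyad timeline: question window then response window
        windows = []  # (pair_idx, questioner, responder, qs, qe, rs, re)
        cursor = gap_frames
        for i in range(cfg.pairs_per_dyad):
            questioner, responder = (p0, p1) if i % 2 == 0 else (p1, p0)
            nq = max(2, int(round(rng.uniform(lo, hi) * cfg.fps / 1000.0)))
            nr = max(2, int(round(rng.uniform(lo, hi) * cfg.fps / 1000.0)))
            qs, qe = cursor, cursor + nq
            rs, re = qe + gap_frames, qe + gap_frames + nr
            windows.append((i, questioner, responder, qs, qe, rs, re))
            cursor = re + gap_frames
        n_frames = cursor + gap_frames

        # per-speaker, per-articulator session displacement processes
        session = {
            p: {kp: _baseline_series(n_frames - 1, cfg, rng)
                for kp in cfg.articulators}
            for p in (p0, p1)
        }
        latent = {kp: _baseline_series(
            max(2, int(round((lo + hi) / 2 * cfg.fps / 1000.0))) - 1,
            cfg, rng) for kp in cfg.articulators}

        for i, questioner, responder, qs, qe, rs, re in windows:
            target = max(
                0.0,
                cfg.coupling_intercept
                + cfg.coupling_slope_per_eq_point * delta_eq[dyad]
                + responder_offset[responder],
            )
            amplitude = float(np.interp(target, dist_grid, amp_grid))
            if not cfg.adjacency_specific and cfg.null_style == "other_question":
                others = [w for w in windows if w[0] != i]
                src_w = others[rng.integers(len(others))]
            else:
                src_w = None
            for kp in cfg.articulators:
                if cfg.adjacency_specific:
                    source = session[questioner][kp][qs:qe - 1]
                elif cfg.null_style == "independent":
                    source = _baseline_series(re - rs - 1, cfg, rng)
                elif cfg.null_style == "dyad_latent":
                    source = latent[kp]
                else:
                    _, src_q, _, sqs, sqe, _, _ = src_w
                    source = session[src_q][kp][sqs:sqe - 1]
                session[responder][kp][rs:re - 1] = _coupled_response(
                    source, re - rs - 1, amplitude, cfg, rng)

            q_id = f"{dyad}_pair{i:03d}_q"
            r_id = f"{dyad}_pair{i:03d}_r"
            q_seg = Segment(q_id, dyad, questioner, Role.QUESTION,
                            _frame_aligned_ms(qs, cfg.fps),
                            _frame_aligned_ms(qe, cfg.fps))
            r_seg = Segment(r_id, dyad, responder, Role.RESPONSE,
                            _frame_aligned_ms(rs, cfg.fps),
                            _frame_aligned_ms(re, cfg.fps))
            segments.extend([q_seg, r_seg])
            pairing.append((q_id, r_id))
            pair_target[f"{q_id}+{r_id}"] = target

        # displacement -> positions (motion along x; magnitudes preserved)
        for p in (p0, p1):
            tracks[p] = {}
            for kp in cfg.articulators:
                d = session[p][kp]
                x = np.concatenate([[0.0], np.cumsum(d)])
                positions = np.column_stack([x, np.zeros_like(x)])
                conf = np.ones(len(x))
                if cfg.p_dropout > 0:
                    drop = rng.random(len(x)) < cfg.p_dropout
                    conf[drop] = 0.0
                    positions[drop] = np.nan
                tracks[p][kp] = KeypointTrack(
                    speaker_id=p, keypoint=kp, positions=positions,
                    confidence=conf, frame_rate=cfg.fps)

        if audio is not None:
            sr = cfg.audio_sample_rate
            n_samples = int(np.ceil(n_frames / cfg.fps * sr)) + sr // 10
            clips = {p: np.zeros(n_samples, dtype=np.float32)
                     for p in (p0, p1)}
            for i, questioner, responder, qs, qe, rs, re in windows:
                f0_q = float(np.clip(
                    base_f0[questioner] + rng.normal(0.0, 2.0), 80.0, 290.0))
                f0_r = float(np.clip(
                    f0_q + rng.normal(0.0, cfg.f0_match_sd), 80.0, 290.0))
                for seg_frames, speaker, f0, suffix in (
                    ((qs, qe), questioner, f0_q, "q"),
                    ((rs, re), responder, f0_r, "r"),
                ):
                    s_ms = _frame_aligned_ms(seg_frames[0], cfg.fps)
                    e_ms = _frame_aligned_ms(seg_frames[1], cfg.fps)
                    i0 = int(round(s_ms * sr / 1000.0))
                    i1 = int(round(e_ms * sr / 1000.0))
                    clips[speaker][i0:i1] = _harmonic_tone(
                        f0, i1 - i0, sr, rng)
                    segment_f0[f"{dyad}_pair{i:03d}_{suffix}"] = f0
            for p in (p0, p1):
                audio[p] = AudioClip(samples=clips[p], sample_rate=sr,
                                     speaker_id=p)

    ground_truth = GroundTruth(
        amp_grid=amp_grid, dist_grid=dist_grid,
        eq_totals=totals, delta_eq=delta_eq,
        pair_target=pair_target, segment_f0=segment_f0,
        responder_offset=responder_offset,
        coupling_slope=cfg.coupling_slope_per_eq_point,
        coupling_intercept=cfg.coupling_intercept,
    )
    return SyntheticStudy(
        config=cfg, segments=segments, pairing_table=pairing,
        tracks=tracks, audio=audio, eq_sheets=eq_sheets,
        ground_truth=ground_truth,
    )


def write_study(study: SyntheticStudy, out_dir: str | Path) -> dict[str, Path]:
    """Export a study in exactly the dialects the readers consume.

    Returns the paths written: annotations TSV, flat keypoint CSV, EQ
    scores + key CSVs, and (if generated) one WAV per speaker.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    ann = pd.DataFrame(
        [{"segment_id": s.segment_id, "dyad": s.dyad_id,
          "speaker": s.speaker_id, "role": s.role.value,
          "onset_ms": s.onset, "offset_ms": s.offset}
         for s in study.segments]
    )
    paths["annotations"] = out / "annotations.tsv"
    ann.to_csv(paths["annotations"], sep="\t", index=False)

    pairs = pd.DataFrame(study.pairing_table,
                         columns=["question_id", "response_id"])
    paths["pairs"] = out / "pairs.tsv"
    pairs.to_csv(paths["pairs"], sep="\t", index=False)

    rows = []
    for speaker, by_kp in study.tracks.items():
        for kp, track in by_kp.items():
            for frame in range(len(track)):
                x, y = track.positions[frame]
                rows.append((frame, speaker, kp.value,
                             "" if np.isnan(x) else round(x, 4),
                             "" if np.isnan(y) else round(y, 4),
                             round(track.confidence[frame], 3)))
    kp_df = pd.DataFrame(
        rows, columns=["frame", "speaker", "keypoint", "x", "y",
                       "confidence"])
    paths["keypoints"] = out / "keypoints.csv"
    kp_df.to_csv(paths["keypoints"], index=False)

    eq_rows = []
    for sheet in study.eq_sheets:
        row = {"participant": sheet.participant_id}
        for i, v in enumerate(sheet.item_scores, start=1):
            row[f"item{i:02d}"] = "" if np.isnan(v) else int(v)
        eq_rows.append(row)
    paths["eq_scores"] = out / "eq_scores.csv"
    pd.DataFrame(eq_rows).to_csv(paths["eq_scores"], index=False)
    mask = study.eq_sheets[0].item_is_target
    paths["eq_key"] = out / "eq_key.csv"
    pd.DataFrame({"item": np.arange(1, 61),
                  "is_target": mask.astype(int)}).to_csv(
        paths["eq_key"], index=False)

    if study.audio:
        audio_dir = out / "audio"
        audio_dir.mkdir(exist_ok=True)
        for speaker, clip in study.audio.items():
            path = audio_dir / f"{speaker}.wav"
            io_formats.write_audio(clip, path)
            paths[f"audio/{speaker}"] = path
    return paths


def generate_worked_fixture(out_dir: str | Path | None = None) -> dict:
    """A hand-checkable miniature: 2 dyads x 4 pairs, series length <= 6.

    Every DTW distance is verified here against the brute-force enumeration
    oracle and returned alongside the series, so downstream tests can use
    the bundle as frozen expected values.  With ``out_dir`` the bundle is
    additionally written as JSON (byte-identical across calls).
    """
    series_pairs = {
        "dyadA": [
            (np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 3.0])),
            (np.array([0.0, 1.0, 2.0]), np.array([0.0, 2.0])),
            (np.array([1.0]), np.array([4.0])),
            (np.array([2.0, 0.0, 2.0, 0.0]), np.array([0.0, 2.0, 0.0])),
        ],
        "dyadB": [
            (np.array([5.0, 5.0]), np.array([5.0, 5.0, 5.0])),
            (np.array([0.0, 3.0, 0.0]), np.array([3.0, 0.0, 3.0])),
            (np.array([1.0, 1.0, 2.0, 2.0]), np.array([1.0, 2.0])),
            (np.array([0.5, 1.5, 2.5]), np.array([2.5, 1.5, 0.5])),
        ],
    }
    expected = {
        dyad: [brute_force_dtw(q, r).normalized_distance
               for q, r in pairs]
        for dyad, pairs in series_pairs.items()
    }
    bundle = {"series": series_pairs,
              "expected_normalized_distance": expected}
    if out_dir is not None:
        import json

        path = Path(out_dir)
        path.mkdir(parents=True, exist_ok=True)
        payload = {
            dyad: [{"question": q.tolist(), "response": r.tolist(),
                    "expected_normalized_distance": e}
                   for (q, r), e in zip(pairs, expected[dyad])]
            for dyad, pairs in series_pairs.items()
        }
        with open(path / "worked_fixture.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
    return bundle
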