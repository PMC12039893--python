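"""Dynamic time warping between two 1D displacement series.

DTW aligns two series by nonlinearly stretching time while preserving
temporal order; the minimal accumulated local cost along the warping path
is the raw distance, and dividing it by a length constant gives a
per-aligned-step distance that is comparable across question/response
windows of different durations.  Low values mean high similarity.

Two classical step patterns are supported:

* ``symmetric1`` — unit weight on every move; normalization constant N.
* ``symmetric2`` — diagonal moves weighted 2 (so a step consuming one frame
  of each series costs as much as two single-series steps); normalization
  constant N + M.  This is the default, matching the default of the widely
  used DTW packages.

Local cost is the absolute difference of the scalar displacements.  An
optional Sakoe–Chiba band constrains |i - j|.  ``brute_force_dtw``
re-derives the same quantity by exhaustive path enumeration and exists as
an independent oracle for the dynamic program.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .errors import ValidationError

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


__all__ = ["DtwResult", "dtw", "dtw_distance", "brute_force_dtw",
           "pair_distance", "STEP_PATTERNS"]

STEP_PATTERNS = ("symmetric1", "symmetric2")


@dataclass
class DtwResult:
    """Outcome of one DTW alignment."""

    raw_distance: float
    normalized_distance: float
    path: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.raw_distance < 0:
            raise ValidationError("DTW distance cannot be negative")


def _as_values(x) -> np.ndarray:
    values = getattr(x, "values", x)
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValidationError("cannot warp an empty series")
    if not np.isfinite(arr).all():
        raise ValidationError("series contains non-finite values")
    return arr


def _diag_weight(step_pattern: str) -> float:
    if step_pattern not in STEP_PATTERNS:
        raise ValidationError(
            f"step_pattern must be one of {STEP_PATTERNS}, "
            f"got {step_pattern!r}"
        )
    return 2.0 if step_pattern == "symmetric2" else 1.0


def _norm_constant(n: int, m: int, step_pattern: str) -> float:
    return float(n + m) if step_pattern == "symmetric2" else float(n)


@njit(cache=True)
def _cost_matrix(x, y, diag_weight, band):  # pragma: no cover - jitted
    n, m = len(x), len(y)
    big = np.inf
    D = np.full((n, m), big)
    D[0, 0] = abs(x[0] - y[0])
    for j in range(1, m):
        if band >= 0 and j > band:
            break
        D[0, j] = D[0, j - 1] + abs(x[0] - y[j])
    for i in range(1, n):
        if band >= 0 and i > band:
            break
        D[i, 0] = D[i - 1, 0] + abs(x[i] - y[0])
    for i in range(1, n):
        for j in range(1, m):
            if band >= 0 and abs(i - j) > band:
                continue
            c = abs(x[i] - y[j])
            best = D[i - 1, j - 1] + diag_weight * c
            up = D[i - 1, j] + c
            if up < best:
                best = up
            left = D[i, j - 1] + c
            if left < best:
                best = left
            D[i, j] = best
    return D


def _backtrack(D: np.ndarray, x: np.ndarray, y: np.ndarray,
               diag_weight: float) -> list[tuple[int, int]]:
    i, j = D.shape[0] - 1, D.shape[1] - 1
    path = [(i, j)]
    while (i, j) != (0, 0):
        c = abs(x[i] - y[j])
        candidates = []
        if i > 0 and j > 0:
            candidates.append((D[i - 1, j - 1] + diag_weight * c,
                               (i - 1, j - 1)))
        if i > 0:
            candidates.append((D[i - 1, j] + c, (i - 1, j)))
        if j > 0:
            candidates.append((D[i, j - 1] + c, (i, j - 1)))
        # prefer the diagonal on exact ties (listed first; min is stable)
        _, (i, j) = min(candidates, key=lambda t: t[0])
        path.append((i, j))
    path.reverse()
    return path


def dtw(x, y, step_pattern: str = "symmetric2",
        band: int | None = None) -> DtwResult:
    """Optimal warp between two series via dynamic programming.

    Parameters
    ----------
    x, y
        1D displacement series (arrays or ``DisplacementSeries``).
    step_pattern
        ``symmetric1`` or ``symmetric2`` (default).
    band
        Optional Sakoe–Chiba band half-width; ``None`` disables the window.
    """
    xv, yv = _as_values(x), _as_values(y)
    w = _diag_weight(step_pattern)
    b = -1 if band is None else int(band)
    if b >= 0 and abs(len(xv) - len(yv)) > b:
        raise ValidationError(
            "Sakoe-Chiba band narrower than the length difference; "
            "no admissible path exists"
        )
    D = _cost_matrix(xv, yv, w, b)
    raw = float(D[-1, -1])
    path = _backtrack(D, xv, yv, w)
    return DtwResult(
        raw_distance=raw,
        normalized_distance=raw / _norm_constant(len(xv), len(yv),
                                                 step_pattern),
        path=path,
    )


def dtw_distance(x, y, step_pattern: str = "symmetric2") -> float:
    """Normalized DTW distance without path reconstruction (fast path)."""
    xv, yv = _as_values(x), _as_values(y)
    w = _diag_weight(step_pattern)
    D = _cost_matrix(xv, yv, w, -1)
    return float(D[-1, -1]) / _norm_constant(len(xv), len(yv), step_pattern)


_BRUTE_FORCE_GUARD = 64


def brute_force_dtw(x, y, step_pattern: str = "symmetric2") -> DtwResult:
    """Exhaustive-enumeration oracle for :func:`dtw`.

    Walks every monotone, continuous path from (0, 0) to (N-1, M-1) with
    moves {down, right, diagonal} and returns the cheapest, using the same
    cost accumulation as the dynamic program.  Guarded to tiny inputs.
    """
    xv, yv = _as_values(x), _as_values(y)
    n, m = len(xv), len(yv)
    if n * m > _BRUTE_FORCE_GUARD:
        raise ValidationError(
            f"brute_force_dtw is an enumeration oracle; len(x)*len(y) must "
            f"be <= {_BRUTE_FORCE_GUARD} (got {n * m})"
        )
    w = _diag_weight(step_pattern)

    def explore(i: int, j: int) -> tuple[float, list[tuple[int, int]]]:
        if i == n - 1 and j == m - 1:
            return 0.0, [(i, j)]
        best_cost, best_path = np.inf, []
        moves = []
        if i + 1 < n and j + 1 < m:
            moves.append((i + 1, j + 1, w))
        if i + 1 < n:
            moves.append((i + 1, j, 1.0))
        if j + 1 < m:
            moves.append((i, j + 1, 1.0))
        for ni, nj, weight in moves:
            tail_cost, tail_path = explore(ni, nj)
            cost = weight * abs(xv[ni] - yv[nj]) + tail_cost
            if cost < best_cost:
                best_cost, best_path = cost, tail_path
        return best_cost, [(i, j)] + best_path

    tail, path = explore(0, 0)
    raw = abs(xv[0] - yv[0]) + tail
    return DtwResult(
        raw_distance=raw,
        normalized_distance=raw / _norm_constant(n, m, step_pattern),
        path=path,
    )


def pair_distance(q_series, r_series,
                  step_pattern: str = "symmetric2",
                  band: int | None = None) -> float:
    """Length-normalized DTW distance between a question and a response.

    This is the per-pair entrainment measure: low distance means the
    responder's movement profile closely tracks the questioner's.
    """
    if band is None:
        return dtw_distance(q_series, r_series, step_pattern)
    return dtw(q_series, r_series, step_pattern, band).normalized_distance
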