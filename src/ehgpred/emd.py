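"""Empirical mode decomposition by iterative sifting.

The decomposition splits a signal into intrinsic mode functions (IMFs),
ordered from high to low characteristic frequency, plus a residue:

    x(n) = sum_j IMF_j(n) + r(n)

Each sifting iteration fits cubic-spline envelopes through the local maxima
and minima, subtracts their mean from the candidate, and repeats until a
stopping criterion fires. Two criteria are available:

* ``"sd"`` (default): normalized squared difference between consecutive
  candidates, SD = sum((h_prev - h)^2) / sum(h_prev^2), stop when SD falls
  below the threshold;
* ``"envelope_mean"``: mean |envelope mean| over mean envelope half-width
  below the threshold — the literal "mean of the envelopes near zero"
  reading.

Both default the threshold to 0.2. Boundary effects are mitigated by
mirroring the two extrema nearest each end and pinning the signal endpoints
as extra knots when they protrude beyond the mirrored envelope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "ExtremaSet",
    "IMFDecomposition",
    "DecompositionTermination",
    "find_extrema",
    "envelopes",
    "sift",
    "is_imf",
    "decompose",
    "zero_crossing_count",
]

DEFAULT_SD_THRESHOLD = 0.2
DEFAULT_MAX_ITERATIONS = 100


class DecompositionTermination(Exception):
    """Raised when a signal has too few extrema to build envelopes; the
    caller treats the remaining signal as the residue."""


@dataclass(frozen=True)
class ExtremaSet:
    maxima_indices: np.ndarray
    minima_indices: np.ndarray


@dataclass
class IMFDecomposition:
    imfs: list[np.ndarray]
    residue: np.ndarray
    sift_counts: list[int] = field(default_factory=list)

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for imf in self.imfs:
            out += imf
        return out


def find_extrema(x: np.ndarray) -> ExtremaSet:
    """Interior local maxima and minima by neighbor comparison.

    A plateau of equal values contributes a single extremum at its midpoint
    (rounded down). Endpoints are never extrema.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError(f"need at least 3 samples, got {x.size}")
    # Collapse runs of equal values to single representatives, then compare
    # neighbors on the collapsed sequence.
    change = np.flatnonzero(np.diff(x) != 0)
    if change.size == 0:  # constant signal
        empty = np.empty(0, dtype=int)
        return ExtremaSet(empty, empty)
    starts = np.concatenate(([0], change + 1))          # run start indices
    ends = np.concatenate((change, [x.size - 1]))       # run end indices
    vals = x[starts]
    maxima, minima = [], []
    for i in range(1, len(vals) - 1):
        mid = (starts[i] + ends[i]) // 2
        if vals[i] > vals[i - 1] and vals[i] > vals[i + 1]:
            maxima.append(mid)
        elif vals[i] < vals[i - 1] and vals[i] < vals[i + 1]:
            minima.append(mid)
    return ExtremaSet(np.asarray(maxima, dtype=int), np.asarray(minima, dtype=int))


def zero_crossing_count(x: np.ndarray) -> int:
    """Count sign changes, treating exact zeros as belonging to neither sign."""
    s = np.sign(np.asarray(x, dtype=float))
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(s) != 0))


def _extend_knots(x: np.ndarray, idx: np.ndarray, kind: str) -> tuple[np.ndarray, np.ndarray]:
    """Mirror the two extrema nearest each boundary across the signal ends,
    pinning the endpoint itself as a knot when it protrudes beyond the
    mirrored envelope."""
    n = x.size
    t = idx.astype(float)
    v = x[idx]
    protrudes = (x[0] >= v[0]) if kind == "max" else (x[0] <= v[0])
    if protrudes:
        left_t, left_v = np.array([0.0]), np.array([x[0]])
    else:
        k = min(2, len(t))
        left_t, left_v = -t[:k][::-1], v[:k][::-1]
    protrudes = (x[-1] >= v[-1]) if kind == "max" else (x[-1] <= v[-1])
    if protrudes:
        right_t, right_v = np.array([float(n - 1)]), np.array([x[-1]])
    else:
        k = min(2, len(t))
        right_t = 2 * (n - 1) - t[-k:][::-1]
        right_v = v[-k:][::-1]
    return np.concatenate([left_t, t, right_t]), np.concatenate([left_v, v, right_v])


def envelopes(x: np.ndarray, extrema: ExtremaSet) -> tuple[np.ndarray, np.ndarray]:
    """Upper and lower cubic-spline envelopes evaluated at every sample.

    Raises :class:`DecompositionTermination` when fewer than 2 maxima or
    2 minima exist, which ends the decomposition for this signal.
    """
    x = np.asarray(x, dtype=float)
    if len(extrema.maxima_indices) < 2 or len(extrema.minima_indices) < 2:
        raise DecompositionTermination(
            f"{len(extrema.maxima_indices)} maxima / "
            f"{len(extrema.minima_indices)} minima: cannot build envelopes"
        )
    grid = np.arange(x.size, dtype=float)
    t_max, v_max = _extend_knots(x, extrema.maxima_indices, "max")
    t_min, v_min = _extend_knots(x, extrema.minima_indices, "min")
    upper = CubicSpline(t_max, v_max)(grid)
    lower = CubicSpline(t_min, v_min)(grid)
    return upper, lower


def _count_condition(x: np.ndarray) -> bool:
    """First IMF condition: extrema and zero-crossing counts differ by ≤ 1."""
    extrema = find_extrema(x)
    n_extrema = len(extrema.maxima_indices) + len(extrema.minima_indices)
    return abs(n_extrema - zero_crossing_count(x)) <= 1


def _envelope_mean_ratio(x: np.ndarray) -> float:
    upper, lower = envelopes(x, find_extrema(x))
    mean_env = 0.5 * (upper + lower)
    half_width = 0.5 * (upper - lower)
    denom = float(np.mean(np.abs(half_width)))
    if denom == 0.0:
        return np.inf
    return float(np.mean(np.abs(mean_env))) / denom


def sift(
    x: np.ndarray,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
    criterion: str = "sd",
) -> tuple[np.ndarray, int]:
    """Extract one IMF candidate by repeated local-mean subtraction.

    Returns ``(imf, iterations)``. Propagates
    :class:`DecompositionTermination` if the input has too few extrema for a
    first envelope pair.
    """
    if criterion not in ("sd", "envelope_mean"):
        raise ValueError(f"unknown sifting criterion {criterion!r}")
    h = np.asarray(x, dtype=float).copy()
    for iteration in range(1, max_iterations + 1):
        extrema = find_extrema(h)
        try:
            upper, lower = envelopes(h, extrema)
        except DecompositionTermination:
            if iteration == 1:
                raise
            return h, iteration - 1
        local_mean = 0.5 * (upper + lower)
        h_next = h - local_mean
        if criterion == "sd":
            denom = float(np.sum(h * h))
            crit_ok = (denom > 0.0
                       and float(np.sum((h - h_next) ** 2)) / denom < sd_threshold)
        h = h_next
        if criterion == "envelope_mean":
            try:
                crit_ok = _envelope_mean_ratio(h) < sd_threshold
            except DecompositionTermination:
                return h, iteration
        # a candidate is accepted only when it also satisfies the
        # extrema/zero-crossing count condition
        if crit_ok and _count_condition(h):
            return h, iteration
    return h, max_iterations


def is_imf(candidate: np.ndarray, tolerance: float = DEFAULT_SD_THRESHOLD) -> bool:
    """Check the two IMF conditions: extrema vs. zero-crossing counts differ
    by at most one, and the envelope mean is small relative to the envelope
    half-width."""
    candidate = np.asarray(candidate, dtype=float)
    if candidate.size < 3:
        raise ValueError("candidate too short")
    extrema = find_extrema(candidate)
    n_extrema = len(extrema.maxima_indices) + len(extrema.minima_indices)
    if abs(n_extrema - zero_crossing_count(candidate)) > 1:
        return False
    try:
        return _envelope_mean_ratio(candidate) < tolerance
    except DecompositionTermination:
        return False


def decompose(
    x: np.ndarray,
    n_imfs: int = 2,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
    criterion: str = "sd",
) -> IMFDecomposition:
    """Decompose a signal into up to ``n_imfs`` IMFs plus a residue.

    Early termination (too few extrema in a residue) yields fewer IMFs; the
    remaining content stays in the residue. The returned components always
    sum back to the input exactly up to floating-point rounding.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 10:
        raise ValueError(f"signal too short to decompose: {x.size} samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    imfs: list[np.ndarray] = []
    sift_counts: list[int] = []
    residue = x.copy()
    for _ in range(n_imfs):
        try:
            imf, iterations = sift(residue, sd_threshold=sd_threshold,
                                   max_iterations=max_iterations, criterion=criterion)
        except DecompositionTermination:
            break
        imfs.append(imf)
        sift_counts.append(iterations)
        residue = residue - imf
    return IMFDecomposition(imfs=imfs, residue=residue, sift_counts=sift_counts)
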