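"""Independent brute-force oracles for filter and detection equivalence.

Deliberately naive O(N*W) implementations, kept free of any code path from
the package under test.
"""

from __future__ import annotations

import numpy as np


def brute_running_median(x: np.ndarray, window: int) -> np.ndarray:
    """Centered running median with reflection padding, O(N*W log W)."""
    assert window % 2 == 1
    pad = window // 2
    xp = np.concatenate([x[pad:0:-1], x, x[-2 : -pad - 2 : -1]])
    return np.array(
        [np.median(xp[i : i + window]) for i in range(x.size)]
    )


def brute_moving_average(x: np.ndarray, points: int) -> np.ndarray:
    """Centered moving average with reflection padding."""
    assert points % 2 == 1
    pad = points // 2
    xp = np.concatenate([x[pad:0:-1], x, x[-2 : -pad - 2 : -1]])
    return np.array([np.mean(xp[i : i + points]) for i in range(x.size)])


def _local_maxima(y: np.ndarray) -> list[int]:
    """Strict local maxima; plateaus report their middle sample."""
    maxima = []
    i = 1
    n = y.size
    while i < n - 1:
        if y[i - 1] < y[i]:
            j = i
            while j < n - 1 and y[j + 1] == y[j]:
                j += 1
            if j < n - 1 and y[j + 1] < y[j]:
                maxima.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return maxima


def _prominence(y: np.ndarray, peak: int) -> float:
    left_min = y[peak]
    for j in range(peak - 1, -1, -1):
        if y[j] > y[peak]:
            break
        left_min = min(left_min, y[j])
    right_min = y[peak]
    for j in range(peak + 1, y.size):
        if y[j] > y[peak]:
            break
        right_min = min(right_min, y[j])
    return y[peak] - max(left_min, right_min)


def brute_find_peaks(
    y: np.ndarray,
    threshold: float,
    prominence: float,
    distance: int,
) -> list[int]:
    """Local maxima passing height, then distance, then prominence filters.

    Distance filtering keeps peaks highest-first (ties: rightmost first) and
    discards any unkept peak closer than ``distance`` samples, matching the
    conventional treatment.
    """
    peaks = [p for p in _local_maxima(y) if y[p] >= threshold]
    order = sorted(range(len(peaks)), key=lambda k: (y[peaks[k]], k), reverse=True)
    keep = [True] * len(peaks)
    for k in order:
        if not keep[k]:
            continue
        for m in range(len(peaks)):
            if m != k and keep[m] and abs(peaks[m] - peaks[k]) < distance:
                keep[m] = False
    survivors = [p for p, kept in zip(peaks, keep) if kept]
    return [p for p in survivors if _prominence(y, p) >= prominence]
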