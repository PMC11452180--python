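"""Independent brute-force oracles the fast implementations are checked against."""

from __future__ import annotations

import numpy as np


def local_maxima(x: np.ndarray) -> list[int]:
    """Interior local maxima; a plateau counts once, at its midpoint sample."""
    n = len(x)
    out = []
    i = 1
    while i < n - 1:
        if x[i - 1] < x[i]:
            j = i
            while j < n - 1 and x[j + 1] == x[i]:
                j += 1
            if j < n - 1 and x[j + 1] < x[i]:
                out.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return out


def contour_prominence(x: np.ndarray, peak: int) -> float:
    """Prominence by explicit contour descent.

    Walk away from the peak on each side while no sample exceeds the peak
    height; the higher of the two stretch-minima is the key-saddle base, and
    the prominence is the drop from the peak to it.
    """
    h = x[peak]
    left_min = h
    i = peak
    while i > 0 and x[i - 1] <= h:
        i -= 1
        left_min = min(left_min, x[i])
    right_min = h
    i = peak
    while i < len(x) - 1 and x[i + 1] <= h:
        i += 1
        right_min = min(right_min, x[i])
    return h - max(left_min, right_min)


def brute_force_peaks(
    x, h_min: float = 0.2, d_min: int = 8, p_min: float = 0.07
) -> list[tuple[int, float, float]]:
    """O(L^2) reference peak finder.

    Filters candidates in the standard order — height, then mutual distance
    (higher candidates win; the rightmost of an exact height tie has
    priority), then contour-descent prominence — and returns
    (0-based position, height, prominence) sorted by position.
    """
    x = np.asarray(x, dtype=float)
    cands = [c for c in local_maxima(x) if x[c] >= h_min]
    removed: set[int] = set()
    by_priority = sorted(range(len(cands)), key=lambda k: x[cands[k]])  # stable
    for k in reversed(by_priority):
        c = cands[k]
        if c in removed:
            continue
        for other in cands:
            if other != c and other not in removed and abs(other - c) < d_min:
                removed.add(other)
    kept = [c for c in cands if c not in removed]
    out = []
    for c in kept:
        prom = contour_prominence(x, c)
        if prom >= p_min:
            out.append((c, float(x[c]), float(prom)))
    return out


def savgol_window_fit(f: np.ndarray, i: int, window: int, polyorder: int) -> float:
    """Least-squares polynomial fit over the window centred at ``i``,
    evaluated at the centre — the defining property of the smoother for
    interior points."""
    h = window // 2
    seg = f[i - h : i + h + 1]
    t = np.arange(-h, h + 1, dtype=float)
    coef = np.polyfit(t, seg, polyorder)
    return float(np.polyval(coef, 0.0))


def savgol_edge_fit(f: np.ndarray, i: int, window: int, polyorder: int) -> float:
    """Edge convention: one polynomial fitted to the first/last window,
    evaluated at position ``i`` (0-based, may be near either end)."""
    L = len(f)
    if i < window:
        t = np.arange(window, dtype=float)
        coef = np.polyfit(t, f[:window], polyorder)
        return float(np.polyval(coef, float(i)))
    t = np.arange(L - window, L, dtype=float)
    coef = np.polyfit(t, f[-window:], polyorder)
    return float(np.polyval(coef, float(i)))
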