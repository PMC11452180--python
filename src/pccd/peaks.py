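"""Peak detection on smoothed frequency profiles and rank-axis partitioning.

A transcription factor expressed in one or two contiguous birth-order windows
produces one or two local maxima in its smoothed frequency profile.  Peaks
are retained when they clear a minimal height (h_min, default 0.2), a minimal
prominence (p_min, default 0.07 — the drop to the key saddle of the largest
region the peak dominates), and a minimal mutual separation (d_min, default 8
ranks; of two candidates closer than that, the higher survives).  The rank
axis is then split into one prevailing region per retained peak, cutting at
the valley minimum between neighbours, so every rank is attributed to
exactly one peak.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import signal

from .datamodel import Peak, PeakConfig, ValidationError

__all__ = ["find_peaks", "partition_regions"]


def find_peaks(profile: np.ndarray, cfg: PeakConfig | None = None) -> list[Peak]:
    """Detect retained local maxima of a smoothed frequency vector.

    Candidates are interior local maxima (plateaus count once, at their
    midpoint sample).  Filters are applied in the standard order: height,
    then separation (candidates sorted by descending height; a lower one
    within ``d_min`` of an accepted one is dropped), then prominence.
    Returned peaks are sorted by position and carry 1-based rank positions;
    ``region`` is left unset.  An empty list is a valid result.
    """
    cfg = cfg or PeakConfig()
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValidationError("profile must be a non-empty 1-D vector")
    idx, props = signal.find_peaks(
        x,
        height=cfg.h_min,
        distance=cfg.d_min if cfg.d_min >= 1 else None,
        prominence=cfg.p_min,
    )
    return [
        Peak(position=int(i) + 1, height=float(h), prominence=float(p))
        for i, h, p in zip(idx, props["peak_heights"], props["prominences"])
    ]


def _valley_rank(x: np.ndarray, left: int, right: int) -> int:
    """Boundary rank between two peaks at 1-based ranks ``left`` < ``right``.

    The cut falls at the minimum of the profile strictly between the peaks;
    a tied (flat) valley cuts at its midpoint rank.  The returned rank is the
    last rank belonging to the left peak's region.
    """
    inner = x[left : right - 1]  # ranks left+1 .. right-1 (0-based slice)
    if len(inner) == 0:
        return left  # adjacent peaks: boundary right after the left peak
    vmin = inner.min()
    tied = np.flatnonzero(inner <= vmin + 1e-15)
    first = left + 1 + int(tied[0])
    last = left + 1 + int(tied[-1])
    return (first + last) // 2


def partition_regions(peaks: Sequence[Peak], profile: np.ndarray) -> list[Peak]:
    """Split the rank axis [1, L] into one prevailing region per peak.

    Regions tile the axis exactly: they are pairwise disjoint, their union is
    [1, L], and each peak's position lies inside its own region.  The
    boundary rank between two peaks joins the left region.  Returns new Peak
    objects with ``region`` filled, sorted by position; an empty peak list
    yields an empty result.
    """
    x = np.asarray(profile, dtype=float)
    L = len(x)
    if not peaks:
        return []
    ordered = sorted(peaks, key=lambda p: p.position)
    if not all(1 <= p.position <= L for p in ordered):
        raise ValidationError("peak positions outside the profile")
    bounds = [0]  # last rank of the previous region
    for a, b in zip(ordered, ordered[1:]):
        bounds.append(_valley_rank(x, a.position, b.position))
    bounds.append(L)
    return [
        dataclasses.replace(p, region=(int(lo) + 1, int(hi)))
        for p, lo, hi in zip(ordered, bounds[:-1], bounds[1:])
    ]
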