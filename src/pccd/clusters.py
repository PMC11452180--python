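"""Positive-cell cluster placement and assembly of the combinatorial TF code.

Each retained peak of a TF's smoothed frequency profile is converted into a
*positive cell cluster*: the contiguous run of birth-order ranks inferred to
express the TF.  Its size is the cohort-mean number of positive cells ``n``
observed inside the peak's prevailing region; its position is found by
lowering a horizontal cut level from the peak apex until the contiguous
super-level set containing the peak is exactly ``n`` cells wide (widths are
measured with linear interpolation between ranks and clipped to the region).
Because ``n`` is real-valued the cut generally lands between ranks; the one
or two partially covered border ranks receive a fractional *coverage index*
so that per-rank coverages sum to exactly ``n``.

Clusters of all TFs are then assembled on a common birth-order axis
(default 1–29, the adult survivor count) to give the combinatorial TF code
of each motoneuron; supernumerary larval ranks are kept in an annex.
"""

from __future__ import annotations

import logging
import math
from typing import Optional, Sequence

import numpy as np

from .datamodel import (
    ClusterCall,
    FrequencyProfile,
    OrderedSequence,
    Peak,
    PeakConfig,
    SmoothingConfig,
    TFCodeMap,
    ValidationError,
)
from .frequency import frequency_profile, smooth_profile
from .peaks import find_peaks, partition_regions

logger = logging.getLogger(__name__)

__all__ = [
    "mean_positive_count",
    "place_cluster",
    "detect_clusters",
    "assemble_code_map",
    "compare_code_maps",
]


def mean_positive_count(
    sequences: Sequence[OrderedSequence], region: tuple[int, int]
) -> float:
    """Cohort-mean number of positive cells inside a rank region.

    Each sequence contributes the count of its positive calls at observed
    ranks within ``region`` (closed, 1-based); sequences too short to reach
    part of the region contribute only the ranks they actually observed.
    """
    lo, hi = region
    if hi < lo or lo < 1:
        raise ValidationError(f"empty or invalid region {region}")
    if not sequences:
        raise ValidationError("no sequences supplied")
    counts = [
        sum(1 for i in range(lo - 1, min(hi, len(s))) if s.calls[i])
        for s in sequences
    ]
    return float(np.mean(counts))


def _component_bounds(
    x: np.ndarray, p0: int, level: float, a0: int, b0: int
) -> tuple[float, float]:
    """Fractional 0-based bounds of the super-level set containing ``p0``.

    Walks outward from the peak while the profile stays >= ``level``; the
    crossing on a falling segment is located by linear interpolation; the
    component is clipped to the region [a0, b0].
    """
    i = p0
    while i > a0 and x[i - 1] >= level:
        i -= 1
    if i == a0 or x[i - 1] >= level:
        left = float(a0)
    else:
        left = (i - 1) + (level - x[i - 1]) / (x[i] - x[i - 1])
    j = p0
    while j < b0 and x[j + 1] >= level:
        j += 1
    if j == b0 or x[j + 1] >= level:
        right = float(b0)
    else:
        right = (j + 1) - (level - x[j + 1]) / (x[j] - x[j + 1])
    return left, right


def _width(x: np.ndarray, p0: int, level: float, a0: int, b0: int) -> float:
    left, right = _component_bounds(x, p0, level, a0, b0)
    return right - left + 1.0


def place_cluster(
    profile: np.ndarray, peak: Peak, n: float, tf: str = ""
) -> ClusterCall:
    """Place a cluster of mean size ``n`` under ``peak`` by level-set descent.

    A horizontal cut level is lowered from the peak apex; at each level the
    contiguous super-level set containing the peak has an interpolated width
    in cells, monotone in the level.  The level where the width equals ``n``
    defines the cluster: fully covered integer ranks form ``core_span`` and
    the fractional remainder is split across the two border ranks in
    proportion to the interpolated overhang on each side, so coverages sum
    to ``n`` exactly.  ``n = 0`` yields an empty call; ``n`` larger than the
    region saturates it (coverage 1 everywhere, with a warning).
    """
    if peak.region is None:
        raise ValidationError("peak has no prevailing region; run partition_regions")
    if n < 0:
        raise ValidationError(f"n must be non-negative, got {n}")
    x = np.asarray(profile, dtype=float)
    a0, b0 = peak.region[0] - 1, peak.region[1] - 1
    p0 = peak.position - 1
    if not a0 <= p0 <= b0:
        raise ValidationError("peak position outside its region")

    if n <= 1e-12:
        return ClusterCall(tf=tf, peak=peak, n=float(n), core_span=None, coverage={})
    capacity = b0 - a0 + 1
    if n >= capacity:
        if n > capacity + 1e-9:
            logger.warning(
                "TF %s: mean positive count %.3f exceeds region capacity %d; "
                "cluster saturates the region",
                tf,
                n,
                capacity,
            )
        cov = {r: 1.0 for r in range(peak.region[0], peak.region[1] + 1)}
        return ClusterCall(
            tf=tf,
            peak=peak,
            n=float(n),
            core_span=peak.region,
            coverage=cov,
            saturated=n > capacity + 1e-9,
        )

    apex = x[p0]
    w_apex = _width(x, p0, apex, a0, b0)
    if n <= w_apex:
        # the level set at the apex is already >= n cells wide (plateau):
        # centre a span of exactly n cells on the peak, clipped to the region
        left = p0 - (n - 1) / 2.0
        right = p0 + (n - 1) / 2.0
        if left < a0:
            left, right = float(a0), a0 + (n - 1)
        if right > b0:
            left, right = b0 - (n - 1), float(b0)
    else:
        lo_level = float(x[a0 : b0 + 1].min())
        hi_level = float(apex)
        for _ in range(100):  # bisect the cut level; width is monotone in level
            mid = 0.5 * (lo_level + hi_level)
            if _width(x, p0, mid, a0, b0) >= n:
                lo_level = mid
            else:
                hi_level = mid
        left, right = _component_bounds(x, p0, lo_level, a0, b0)
        w = right - left + 1.0
        if abs(w - n) > 1e-6:
            # plateau exactly at the cut level makes the width jump; trim the
            # overshoot symmetrically to restore width n
            trim = (w - n) / 2.0
            left += trim
            right -= trim

    return _coverage_from_bounds(x, peak, n, left, right, a0, b0, tf)


def _coverage_from_bounds(
    x: np.ndarray,
    peak: Peak,
    n: float,
    left: float,
    right: float,
    a0: int,
    b0: int,
    tf: str,
) -> ClusterCall:
    fl = math.ceil(left - 1e-9)
    fr = math.floor(right + 1e-9)
    coverage: dict[int, float] = {}
    core: Optional[tuple[int, int]] = None
    core_count = 0
    if fr >= fl:
        core = (fl + 1, fr + 1)  # back to 1-based ranks
        core_count = fr - fl + 1
        for r in range(fl, fr + 1):
            coverage[r + 1] = 1.0
    remainder = n - core_count
    if remainder > 1e-12:
        o_left = (fl - left) if fl > a0 else 0.0
        o_right = (right - fr) if fr < b0 else 0.0
        if o_left + o_right <= 1e-12:
            c_left = c_right = remainder / 2.0
        else:
            c_left = remainder * o_left / (o_left + o_right)
            c_right = remainder - c_left
        if c_left > 1e-12 and fl - 1 >= a0:
            coverage[fl] = float(min(1.0, c_left))  # rank fl == 0-based fl-1 + 1
        elif c_left > 1e-12:
            c_right += c_left
        if c_right > 1e-12 and fr + 1 <= b0:
            coverage[fr + 2] = float(min(1.0, c_right))
        elif c_right > 1e-12 and fl - 1 >= a0:
            coverage[fl] = float(min(1.0, coverage.get(fl, 0.0) + c_right))
    # absorb any residual rounding into the larger border so the sum is exact
    total = sum(coverage.values())
    if coverage and abs(total - n) > 1e-12:
        r_max = max(coverage, key=lambda r: (coverage[r] < 1.0, coverage[r]))
        borders = [r for r in coverage if coverage[r] < 1.0]
        target = max(borders, key=coverage.get) if borders else r_max
        coverage[target] = min(1.0, coverage[target] + (n - total))
    return ClusterCall(
        tf=tf, peak=peak, n=float(n), core_span=core, coverage=coverage
    )


def detect_clusters(
    sequences: Sequence[OrderedSequence],
    tf: str,
    smoothing: SmoothingConfig | None = None,
    peak_cfg: PeakConfig | None = None,
    mode: str = "relative",
) -> list[ClusterCall]:
    """Full single-TF pipeline: histogram, smooth, peaks, regions, clusters.

    Returns one ClusterCall per detected peak (possibly none).  With a single
    peak its region is the whole axis; with multiple peaks the axis is split
    into prevailing regions and each region gets its own mean count and
    cluster.
    """
    prof = smooth_profile(frequency_profile(sequences, tf, mode=mode), smoothing)
    found = find_peaks(prof.f_smooth, peak_cfg)
    if not found:
        logger.info("TF %s: no peaks detected; no positive cell cluster", tf)
        return []
    regions = partition_regions(found, prof.f_smooth)
    calls = []
    for pk in regions:
        n = mean_positive_count(sequences, pk.region)
        calls.append(place_cluster(prof.f_smooth, pk, n, tf=tf))
    return calls


def assemble_code_map(
    calls: Sequence[ClusterCall],
    max_birth_order: int = 29,
    condition: str = "control",
) -> TFCodeMap:
    """Assemble cluster calls of all TFs into one birth-order code map.

    Rank axis runs 1..max_birth_order; coverage at ranks beyond it (the
    supernumerary last-born cells destined for programmed cell death) is
    preserved in the annex.  Two calls of the same TF claiming the same rank
    are a conflict and raise.
    """
    entries: dict[str, dict[int, float]] = {}
    annex: dict[str, dict[int, float]] = {}
    for call in calls:
        ent = entries.setdefault(call.tf, {})
        ann = annex.setdefault(call.tf, {})
        for rank, cov in call.coverage.items():
            target = ent if rank <= max_birth_order else ann
            if rank in target:
                raise ValidationError(
                    f"conflicting duplicate cluster calls for TF {call.tf} at rank {rank}"
                )
            target[rank] = cov
    return TFCodeMap(
        condition=condition,
        max_birth_order=max_birth_order,
        entries=entries,
        annex={tf: col for tf, col in annex.items() if col},
        calls=list(calls),
    )


def _spans(codemap: TFCodeMap, tf: str) -> list[tuple[int, int]]:
    spans = [
        c.called_span for c in codemap.calls if c.tf == tf and c.called_span is not None
    ]
    if spans or any(c.tf == tf for c in codemap.calls):
        return sorted(spans)
    # fall back to runs of positive membership if calls were not retained
    ranks = sorted(
        r
        for col in (codemap.entries.get(tf, {}), codemap.annex.get(tf, {}))
        for r, v in col.items()
        if v > 0
    )
    out: list[tuple[int, int]] = []
    for r in ranks:
        if out and r == out[-1][1] + 1:
            out[-1] = (out[-1][0], r)
        else:
            out.append((r, r))
    return out


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def compare_code_maps(a: TFCodeMap, b: TFCodeMap) -> dict:
    """Per-TF shift report between two conditions sharing a TF panel.

    For each TF: total expected positives (sum of coverage) in each map,
    cluster spans in each, a per-rank coverage delta (b − a), and flags for
    clusters gained, lost, or extended between conditions.  Extension
    direction is reported along the birth-order axis: toward higher ranks is
    NB-proximal (into the last-born cells), toward lower ranks NB-distal.
    """
    if set(a.tfs) != set(b.tfs):
        raise ValidationError(
            f"TF panels differ: only in first {sorted(set(a.tfs) - set(b.tfs))}, "
            f"only in second {sorted(set(b.tfs) - set(a.tfs))}"
        )
    report: dict = {
        "condition_a": a.condition,
        "condition_b": b.condition,
        "tfs": {},
    }
    for tf in sorted(a.tfs):
        cov_a = {**a.entries.get(tf, {}), **a.annex.get(tf, {})}
        cov_b = {**b.entries.get(tf, {}), **b.annex.get(tf, {})}
        total_a, total_b = sum(cov_a.values()), sum(cov_b.values())
        spans_a, spans_b = _spans(a, tf), _spans(b, tf)
        lost = [s for s in spans_a if not any(_overlaps(s, t) for t in spans_b)]
        gained = [t for t in spans_b if not any(_overlaps(s, t) for s in spans_a)]
        extended = []
        for s in spans_a:
            for t in spans_b:
                if not _overlaps(s, t):
                    continue
                d_prox = t[1] - s[1]
                d_dist = s[0] - t[0]
                if d_prox > 0 or d_dist > 0:
                    direction = (
                        "both"
                        if d_prox > 0 and d_dist > 0
                        else ("NB-proximal" if d_prox > 0 else "NB-distal")
                    )
                    extended.append(
                        {
                            "span_a": list(s),
                            "span_b": list(t),
                            "added_ranks": max(d_prox, 0) + max(d_dist, 0),
                            "direction": direction,
                        }
                    )
        delta = {
            r: cov_b.get(r, 0.0) - cov_a.get(r, 0.0)
            for r in sorted(set(cov_a) | set(cov_b))
            if abs(cov_b.get(r, 0.0) - cov_a.get(r, 0.0)) > 1e-12
        }
        report["tfs"][tf] = {
            "total_a": total_a,
            "total_b": total_b,
            "delta_total": total_b - total_a,
            "spans_a": [list(s) for s in spans_a],
            "spans_b": [list(s) for s in spans_b],
            "lost_clusters": [list(s) for s in lost],
            "gained_clusters": [list(s) for s in gained],
            "extended": extended,
            "per_rank_delta": delta,
        }
    return report
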