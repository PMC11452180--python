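"""Per-rank frequency histograms across specimens, and their smoothing.

Specimens yield sequences of unequal length (fewer cells observed, or fewer
motoneurons altogether), so deep ranks are right-censored.  The *relative*
frequency at rank i is Pi/Ni — positives over the number of sequences long
enough to reach rank i — which is unbiased under random truncation.  The
*global* alternative Pi/N treats unobserved ranks as negative and is biased
low at deep ranks; it is kept for comparison only.  Profiles are smoothed
with a Savitzky–Golay filter (default window 11, polynomial order 3).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .datamodel import FrequencyProfile, OrderedSequence, SmoothingConfig, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["frequency_profile", "smooth_profile", "smooth_vector", "profile_to_frame"]


def frequency_profile(
    sequences: Sequence[OrderedSequence],
    tf: str,
    mode: str = "relative",
) -> FrequencyProfile:
    """Aggregate ordered sequences into a per-rank frequency histogram.

    Parameters
    ----------
    sequences
        Ordered call sequences, all for ``tf``.
    mode
        ``"relative"`` (default): f_i = Pi / Ni with Ni the number of
        sequences of length >= i.  ``"global"``: f_i = Pi / N with N the
        total number of sequences.
    """
    seqs = [s for s in sequences if len(s)]
    if not seqs:
        raise ValidationError(f"no non-empty sequences supplied for TF {tf!r}")
    bad = [s.specimen_id for s in seqs if s.tf != tf]
    if bad:
        raise ValidationError(f"sequences for wrong TF (expected {tf!r}): {bad}")
    L_max = max(len(s) for s in seqs)
    P = np.zeros(L_max)
    Ni = np.zeros(L_max)
    for s in seqs:
        calls = np.asarray(s.calls, dtype=float)
        P[: len(s)] += calls
        Ni[: len(s)] += 1
    return FrequencyProfile(tf=tf, P=P, Nseq=Ni, N_total=len(seqs), mode=mode)


def _effective_window(L: int, cfg: SmoothingConfig) -> tuple[int, int]:
    """Shrink the window to the largest odd number <= L and cap the order."""
    window = min(cfg.window, L if L % 2 == 1 else L - 1)
    polyorder = min(cfg.polyorder, window - 1)
    return window, polyorder


def smooth_vector(f: np.ndarray, cfg: SmoothingConfig | None = None) -> np.ndarray:
    """Savitzky–Golay smooth a frequency vector, clipped to [0, 1].

    Edges follow ``cfg.edge_mode``: ``polynomial_interp`` fits a single
    polynomial of degree ``polyorder`` to the first/last window and evaluates
    it at the edge ranks; ``mirror`` reflects the signal.  Sequences shorter
    than the window get a shrunken (odd) window; length-1 vectors are
    returned unsmoothed.
    """
    cfg = cfg or SmoothingConfig()
    f = np.asarray(f, dtype=float)
    L = len(f)
    if L < 2:
        logger.warning("sequence of length %d returned unsmoothed", L)
        return f.copy()
    window, polyorder = _effective_window(L, cfg)
    mode = "interp" if cfg.edge_mode == "polynomial_interp" else "mirror"
    out = savgol_filter(f, window_length=window, polyorder=polyorder, mode=mode)
    return np.clip(out, 0.0, 1.0)


def smooth_profile(
    profile: FrequencyProfile, cfg: SmoothingConfig | None = None
) -> FrequencyProfile:
    """Return a copy of ``profile`` with ``f_smooth`` filled in."""
    return dataclasses.replace(profile, f_smooth=smooth_vector(profile.f, cfg))


def profile_to_frame(profile: FrequencyProfile) -> pd.DataFrame:
    """Tidy export: one row per rank with Pi, Ni, raw and smoothed frequency."""
    return pd.DataFrame(
        {
            "tf": profile.tf,
            "rank": np.arange(1, profile.L_max + 1),
            "Pi": profile.P.astype(int),
            "Ni": profile.Nseq.astype(int),
            "f": profile.f,
            "f_smooth": profile.f_smooth
            if profile.f_smooth is not None
            else np.full(profile.L_max, np.nan),
        }
    )
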