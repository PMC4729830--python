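"""Dual-reporter (GFP/mCherry) quantification and growth-curve analysis.

Implements the fluorescence side of the multi-reporter bacterial one-hybrid
readout: background gates derived from a negative control, quadrant
classification of two-channel events, fold enrichment of a quadrant between
selection conditions, and doubling-time estimation from OD600 growth curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

QUADRANTS = ("Q1", "Q2", "Q3", "Q4")


@dataclass(frozen=True)
class GateSpec:
    """Per-channel background thresholds (arbitrary fluorescence units)."""

    gfp_threshold: float
    mcherry_threshold: float
    percentile: float  # fraction of the negative control below each threshold

    def __post_init__(self) -> None:
        if self.gfp_threshold <= 0 or self.mcherry_threshold <= 0:
            raise ValueError("gate thresholds must be positive")


@dataclass(frozen=True)
class QuadrantSummary:
    """Quadrant occupancy of one sample under a gate.

    Q1 = GFP-/mCherry+, Q2 = GFP+/mCherry+, Q3 = GFP-/mCherry-,
    Q4 = GFP+/mCherry-. An event is channel-positive iff its intensity is
    strictly above the threshold (boundary equality counts as negative).
    """

    counts: dict[str, int]
    fractions: dict[str, float]
    mean_gfp: float
    mean_mcherry: float
    n_total: int


def _channel(events: pd.DataFrame, col: str) -> np.ndarray:
    x = np.asarray(events[col], dtype=float)
    if len(x) == 0:
        raise ValueError("empty event table")
    if not np.all(np.isfinite(x)) or np.any(x <= 0):
        raise ValueError(f"{col} intensities must be finite and positive")
    return x


def derive_gates(negative_control: pd.DataFrame, percentile: float = 0.995) -> GateSpec:
    """Background gates from a negative-control sample.

    Each threshold is the empirical ``percentile`` of the control's channel
    intensities, taken as the order statistic at index ``ceil(p*n) - 1`` of
    the sorted array (``percentile=1.0`` gives the channel maximum).
    """
    if not 0.0 < percentile <= 1.0:
        raise ValueError("percentile must lie in (0, 1]")
    gfp = _channel(negative_control, "gfp")
    mch = _channel(negative_control, "mcherry")
    if len(gfp) < 100:
        raise ValueError("negative control needs at least 100 events")
    thr = [
        float(np.quantile(x, percentile, method="inverted_cdf"))
        for x in (gfp, mch)
    ]
    return GateSpec(gfp_threshold=thr[0], mcherry_threshold=thr[1],
                    percentile=percentile)


def classify_quadrants(events: pd.DataFrame, gates: GateSpec) -> QuadrantSummary:
    """Partition events into the four gate quadrants."""
    gfp = _channel(events, "gfp")
    mch = _channel(events, "mcherry")
    gfp_pos = gfp > gates.gfp_threshold
    mch_pos = mch > gates.mcherry_threshold
    counts = {
        "Q1": int(np.sum(~gfp_pos & mch_pos)),
        "Q2": int(np.sum(gfp_pos & mch_pos)),
        "Q3": int(np.sum(~gfp_pos & ~mch_pos)),
        "Q4": int(np.sum(gfp_pos & ~mch_pos)),
    }
    n = len(gfp)
    fractions = {q: counts[q] / n for q in QUADRANTS}
    return QuadrantSummary(counts=counts, fractions=fractions,
                           mean_gfp=float(gfp.mean()),
                           mean_mcherry=float(mch.mean()), n_total=n)


def enrichment_fold(sample: QuadrantSummary, reference: QuadrantSummary,
                    quadrant: str) -> float | None:
    """Fold change of a quadrant fraction relative to a reference condition.

    Returns ``None`` (undefined) when the reference fraction is zero rather
    than an infinite fold.
    """
    if quadrant not in QUADRANTS:
        raise ValueError(f"unknown quadrant {quadrant!r}")
    ref = reference.fractions[quadrant]
    if ref == 0.0:
        return None
    return sample.fractions[quadrant] / ref


@dataclass(frozen=True)
class GrowthFit:
    """Log-phase exponential fit of a blank-normalized growth curve."""

    doubling_time_min: float | None  # None flags "no growth"
    slope: float                     # doublings per minute
    n_points: int
    window: tuple[float, float]


def doubling_time(times_min: np.ndarray, od600: np.ndarray, blank: float = 0.0,
                  window: tuple[float, float] = (0.02, 0.4),
                  min_points: int = 5) -> GrowthFit:
    """Doubling time from the exponential window of an OD600 curve.

    Blank-subtracted OD values inside ``window`` are fit as
    ``log2(OD) = a + t/T`` by least squares; the doubling time ``T`` is the
    reciprocal slope in minutes. Non-positive slopes flag "no growth"
    (``doubling_time_min`` of ``None``). The estimate is invariant to a
    uniform time shift and to scaling the OD (up to the window selection).
    """
    t = np.asarray(times_min, dtype=float)
    od = np.asarray(od600, dtype=float) - blank
    keep = (od >= window[0]) & (od <= window[1])
    if int(keep.sum()) < min_points:
        raise ValueError(
            f"only {int(keep.sum())} points with blanked OD in {window}; "
            f"need at least {min_points}"
        )
    slope, _ = np.polyfit(t[keep], np.log2(od[keep]), deg=1)
    # slopes below one doubling per ~2000 years are numerical noise, not growth
    if slope <= 1e-9 or not math.isfinite(slope):
        return GrowthFit(None, float(slope), int(keep.sum()), window)
    return GrowthFit(1.0 / slope, float(slope), int(keep.sum()), window)
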