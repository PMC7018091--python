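"""Sliding-window nucleotide-diversity scans over whole-plastome alignments.

Used to locate divergence hotspots that can serve as lineage-specific
barcodes.  Window coordinates are alignment columns (1-based); the default
geometry (600 bp window, 200 bp step) follows common DnaSP practice for
plastome scans, and a trailing window shorter than the window length is
dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ParameterError, UndefinedInputError
from .seqio import Alignment, FeatureAnnotation
from .sitestats import nucleotide_diversity

DEFAULT_WINDOW = 600
DEFAULT_STEP = 200


@dataclass
class WindowProfile:
    """Per-window nucleotide diversity along an alignment."""

    window_length: int
    step: int
    starts: list[int]
    midpoints: list[int]
    pi_values: list[float]  # NaN where a window had no scorable column

    def __post_init__(self) -> None:
        if len(self.midpoints) != len(self.pi_values):
            raise ParameterError("midpoints and pi_values length mismatch")
        if any(b <= a for a, b in zip(self.midpoints, self.midpoints[1:])):
            raise ParameterError("window midpoints must be strictly increasing")


@dataclass
class RankedRegion:
    """A (possibly merged) top-ranking window span with overlapping features."""

    start: int
    end: int
    midpoint: int
    pi: float
    features: list[str]


def sliding_pi(
    alignment: Alignment,
    window_length: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> WindowProfile:
    """Scan an alignment, computing pi in windows of ``window_length`` columns.

    Windows start at columns 1, 1+step, ... and the last window must fit
    entirely; pi uses complete deletion within each window, and a window with
    no gap-free column records NaN.
    """
    if step < 1:
        raise ParameterError("step must be >= 1")
    if window_length < 1 or window_length > alignment.length:
        raise ParameterError(
            f"window length {window_length} outside 1..{alignment.length}"
        )
    starts, midpoints, pis = [], [], []
    start = 1
    while start + window_length - 1 <= alignment.length:
        window = alignment.slice_columns(start, start + window_length - 1)
        try:
            pi = nucleotide_diversity(window)
        except UndefinedInputError:
            pi = math.nan
        starts.append(start)
        midpoints.append(start + window_length // 2)
        pis.append(pi)
        start += step
    return WindowProfile(window_length, step, starts, midpoints, pis)


def top_regions(
    profile: WindowProfile,
    annotations: Sequence[FeatureAnnotation] = (),
    k: int = 7,
) -> list[RankedRegion]:
    """Top-k windows by pi, merged when they overlap, mapped to annotations.

    Ties in pi rank the smaller midpoint first; windows whose pi is missing
    are excluded from ranking.  Overlapping selected windows are merged into
    one region carrying the highest pi among its members.
    """
    if k <= 0:
        raise ParameterError("k must be positive")
    if not profile.midpoints:
        raise ParameterError("empty window profile")
    scored = [
        (pi, mid, start)
        for start, mid, pi in zip(profile.starts, profile.midpoints, profile.pi_values)
        if not math.isnan(pi)
    ]
    scored.sort(key=lambda t: (-t[0], t[1]))
    chosen = scored[:k]

    spans = sorted(
        (start, start + profile.window_length - 1, pi) for pi, _, start in chosen
    )
    merged: list[list[float]] = []
    for start, end, pi in spans:
        if merged and start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
            merged[-1][2] = max(merged[-1][2], pi)
        else:
            merged.append([start, end, pi])

    regions = []
    for start, end, pi in merged:
        start, end = int(start), int(end)
        features = [
            a.name for a in annotations if a.start <= end and a.end >= start
        ]
        regions.append(
            RankedRegion(
                start=start,
                end=end,
                midpoint=(start + end) // 2,
                pi=float(pi),
                features=features,
            )
        )
    regions.sort(key=lambda r: (-r.pi, r.midpoint))
    return regions


def profile_table(profile: WindowProfile) -> "np.ndarray":
    """(midpoint, pi) rows for TSV export."""
    return np.column_stack([profile.midpoints, profile.pi_values])
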