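"""Recruitment timing, positivity scoring and retention curves.

Arrival and departure of a reporter are defined by half-maximum
crossings of its fold-enrichment trace: the half level is
``1 + (peak - 1) / 2`` and crossing times are linearly interpolated
between frames.  Binary positive/negative scoring (used where events
were scored by eye in the original workflow) is made explicit by a
:class:`PositivityRule`: a vesicle or phagosome is positive while its
enrichment is at least ``threshold``-fold for at least
``min_consecutive_frames`` frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .rings import EnrichmentTrace, RingGeometry, make_ring_masks
from .segtrack import SegParams, segment_particles

__all__ = [
    "PositivityRule",
    "TimingSummary",
    "RetentionCurve",
    "extract_timing",
    "positive_intervals",
    "retention_curve",
    "count_vesicles_per_cell",
    "score_pulse_chase",
]


@dataclass(frozen=True)
class PositivityRule:
    """Reproducible replacement for by-eye positive/negative calls."""

    threshold: float = 1.5  # fold-enrichment cutoff
    min_consecutive_frames: int = 2

    def __post_init__(self):
        if self.threshold <= 1:
            raise ValueError("threshold must be > 1 (baseline is 1)")
        if self.min_consecutive_frames < 1:
            raise ValueError("min_consecutive_frames must be >= 1")


@dataclass
class TimingSummary:
    """Half-max arrival/peak/departure for one event.

    All times in seconds after engulfment.  ``positive`` is False for
    traces whose peak never reaches the positivity threshold; timings
    are then None.  ``censored`` marks traces still above half-max at
    the end of the movie: ``t_departure`` is then the last observed
    time and ``dwell`` a lower bound.
    """

    event_id: int
    positive: bool
    t_arrival: float | None = None
    t_peak: float | None = None
    t_departure: float | None = None
    censored: bool = False

    @property
    def dwell(self) -> float | None:
        if self.t_arrival is None or self.t_departure is None:
            return None
        return self.t_departure - self.t_arrival


def _cross_up(t, v, level, i):
    """Interpolated time where v crosses level between i-1 and i."""
    if i == 0:
        return float(t[0])
    t0, t1, v0, v1 = t[i - 1], t[i], v[i - 1], v[i]
    if v1 == v0:
        return float(t1)
    return float(t0 + (level - v0) / (v1 - v0) * (t1 - t0))


def extract_timing(
    trace: EnrichmentTrace, positivity_threshold: float = 1.5
) -> TimingSummary:
    """Half-max arrival, peak and departure of one enrichment trace."""
    t, v = trace.times, trace.values
    if t.size < 5:
        raise ValueError("trace too short: need >= 5 frames")
    peak = float(np.max(v))
    i_peak = int(np.argmax(v))
    if peak < positivity_threshold:
        return TimingSummary(event_id=trace.event_id, positive=False)
    half = 1.0 + (peak - 1.0) / 2.0
    above = v >= half
    # first upward crossing before (or at) the peak
    i_first = int(np.argmax(above))
    t_arrival = _cross_up(t, v, half, i_first)
    # last index above half-max
    i_last = int(np.nonzero(above)[0][-1])
    if i_last == t.size - 1:
        censored = True
        t_departure = float(t[-1])
    else:
        censored = False
        # downward crossing between i_last and i_last + 1
        t0, t1, v0, v1 = t[i_last], t[i_last + 1], v[i_last], v[i_last + 1]
        t_departure = float(t0 + (v0 - half) / (v0 - v1) * (t1 - t0)) if v0 != v1 else float(t1)
    return TimingSummary(
        event_id=trace.event_id,
        positive=True,
        t_arrival=t_arrival,
        t_peak=float(t[i_peak]),
        t_departure=t_departure,
        censored=censored,
    )


def positive_intervals(
    trace: EnrichmentTrace, rule: PositivityRule | None = None
) -> list[tuple[float, float]]:
    """Time intervals during which the trace satisfies the rule."""
    rule = rule or PositivityRule()
    above = trace.values >= rule.threshold
    intervals = []
    labels, n = ndimage.label(above)
    for lab in range(1, n + 1):
        idx = np.nonzero(labels == lab)[0]
        if idx.size >= rule.min_consecutive_frames:
            intervals.append((float(trace.times[idx[0]]), float(trace.times[idx[-1]])))
    return intervals


@dataclass
class RetentionCurve:
    """Proportion of events scored positive per time bin after engulfment."""

    bin_starts: np.ndarray  # s
    proportions: np.ndarray  # NaN where no events observed
    n_observed: np.ndarray
    bin_width: float

    def time_drops_below(self, level: float = 0.5) -> float | None:
        """Start time (s) of the first bin below ``level`` after the
        curve has been at or above it; None if it never drops."""
        seen_high = False
        for t, p, n in zip(self.bin_starts, self.proportions, self.n_observed):
            if n == 0 or not np.isfinite(p):
                continue
            if p >= level:
                seen_high = True
            elif seen_high:
                return float(t)
        return None

    def last_time_at_or_above(self, level: float = 0.5) -> float | None:
        """End time (s) of the last observed bin with proportion >= level."""
        out = None
        for t, p, n in zip(self.bin_starts, self.proportions, self.n_observed):
            if n > 0 and np.isfinite(p) and p >= level:
                out = float(t + self.bin_width)
        return out


def retention_curve(
    intervals_per_event: list[list[tuple[float, float]]],
    observation_end_per_event: list[float],
    bin_width: float = 60.0,
    t_max: float | None = None,
) -> RetentionCurve:
    """Proportion positive per bin, respecting right-censoring.

    An event counts toward a bin only while it is still observed
    (observation end at or after the bin start); it is positive in a
    bin if any of its positive intervals intersects the bin.
    """
    if not intervals_per_event:
        raise ValueError("no events supplied")
    if len(intervals_per_event) != len(observation_end_per_event):
        raise ValueError("need one observation end per event")
    if t_max is None:
        t_max = max(observation_end_per_event)
    edges = np.arange(0.0, t_max + bin_width / 2, bin_width)
    starts = edges[:-1] if edges.size > 1 else edges
    props = np.full(starts.size, np.nan)
    n_obs = np.zeros(starts.size, dtype=int)
    for k, b0 in enumerate(starts):
        b1 = b0 + bin_width
        observed = [
            ivs
            for ivs, end in zip(intervals_per_event, observation_end_per_event)
            if end >= b0
        ]
        n_obs[k] = len(observed)
        if not observed:
            continue
        pos = sum(
            1 for ivs in observed if any(i0 < b1 and i1 >= b0 for i0, i1 in ivs)
        )
        props[k] = pos / len(observed)
    return RetentionCurve(starts, props, n_obs, bin_width)


def count_vesicles_per_cell(
    reporter_image: np.ndarray,
    pixel_size: float,
    cell_mask: np.ndarray | None = None,
    min_area: float = 0.5,
    max_area: float = 20.0,
    contrast: float = 1.3,
) -> int | dict[int, int]:
    """Count ring/blob-like reporter objects per cell.

    Objects are pixels brighter than ``contrast`` times the cytosolic
    median, hole-filled (a ring encloses its lumen) and size-filtered
    to [min_area, max_area] um^2.  With a labeled ``cell_mask`` the
    counts are returned per cell label; otherwise the whole field is
    treated as one cell and a single count returned.
    """
    img = np.asarray(reporter_image, dtype=float)
    region = np.ones_like(img, bool) if cell_mask is None else cell_mask > 0
    med = np.median(img[region])
    binary = (img > contrast * med) & region
    from scipy.ndimage import binary_fill_holes, label

    binary = binary_fill_holes(binary)
    labels, n = label(binary)
    px = pixel_size**2
    good_centroids = []
    for lab in range(1, n + 1):
        m = labels == lab
        area = m.sum() * px
        if min_area <= area <= max_area:
            rows, cols = np.nonzero(m)
            good_centroids.append((int(round(rows.mean())), int(round(cols.mean()))))
    if cell_mask is None:
        return len(good_centroids)
    counts: dict[int, int] = {int(l): 0 for l in np.unique(cell_mask) if l > 0}
    for r, c in good_centroids:
        lab = int(cell_mask[r, c])
        if lab > 0:
            counts[lab] += 1
    return counts


def score_pulse_chase(
    fields_by_timepoint: dict[float, list[np.ndarray]],
    pixel_size: float,
    rule: PositivityRule | None = None,
    geometry: RingGeometry | None = None,
    seg_params: SegParams | None = None,
) -> pd.DataFrame:
    """Fraction of dextran-marked vesicles positive for the reporter.

    Each field is (2, H, W) with channel 0 the vesicle (dextran) marker
    and channel 1 the reporter.  Vesicles are segmented on channel 0;
    a vesicle is positive when its inner/outer ring ratio in the
    reporter channel is at least ``rule.threshold``.  Timepoints with
    zero vesicles get NaN.
    """
    rule = rule or PositivityRule()
    geometry = geometry or RingGeometry()
    seg_params = seg_params or SegParams()
    rows = []
    for tp in sorted(fields_by_timepoint):
        n_total = 0
        n_pos = 0
        for img in fields_by_timepoint[tp]:
            dets = segment_particles(img[0], pixel_size, seg_params)
            for det in dets:
                mask = det.full_mask(img[0].shape)
                inner, outer, clipped = make_ring_masks(mask, geometry, pixel_size)
                if clipped > geometry.max_clipped_fraction:
                    continue
                ratio = img[1][inner].mean() / img[1][outer].mean()
                n_total += 1
                n_pos += ratio >= rule.threshold
        rows.append(
            {
                "timepoint_min": tp,
                "n_vesicles": n_total,
                "fraction_positive": n_pos / n_total if n_total else np.nan,
            }
        )
    return pd.DataFrame(rows)
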