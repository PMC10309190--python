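"""Particle segmentation and frame-to-frame linking.

The engulfed-particle (yeast) channel is thresholded, connected
components above a minimum physical area (default 1.5 um^2) are kept as
detections, and detections on time-adjacent frames are linked into
phagocytic events by a position + size similarity cost solved as a
minimum-cost assignment.

Engulfment time is never inferred: it is annotated from synthetic
ground truth or a user-supplied table, mirroring the manual selection
of engulfment in live experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label

__all__ = [
    "SegParams",
    "LinkParams",
    "Detection",
    "PhagosomeEvent",
    "segment_particles",
    "link_frames",
    "build_events",
    "assign_engulfment",
]


@dataclass(frozen=True)
class SegParams:
    """Particle segmentation parameters.

    ``threshold`` is "otsu" or a fixed intensity value; ``min_area`` is
    the physical size filter in um^2 (detections below it are dropped).
    """

    threshold: str | float = "otsu"
    min_area: float = 1.5
    fill_holes: bool = True

    def __post_init__(self):
        if self.min_area <= 0:
            raise ValueError("min_area must be > 0")


@dataclass(frozen=True)
class LinkParams:
    max_displacement: float = 2.0  # um per frame gap
    area_weight: float = 1.0
    cost_threshold: float = 1.5
    max_frame_gap: int = 1
    min_event_length: int = 3

    def __post_init__(self):
        if min(self.max_displacement, self.area_weight, self.cost_threshold) < 0:
            raise ValueError("link parameters must be >= 0")
        if self.max_frame_gap < 1:
            raise ValueError("max_frame_gap must be >= 1")


@dataclass
class Detection:
    """One segmented particle on one frame.

    ``centroid_um`` is (x, y) in um from the top-left pixel center; the
    mask is stored as a local boolean patch plus its (row, col) offset.
    """

    frame_index: int
    centroid_um: tuple[float, float]
    area_um2: float
    mean_intensity: float
    bbox_offset: tuple[int, int]
    local_mask: np.ndarray

    def full_mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        r0, c0 = self.bbox_offset
        h, w = self.local_mask.shape
        out[r0 : r0 + h, c0 : c0 + w] = self.local_mask
        return out

    @property
    def n_pixels(self) -> int:
        return int(self.local_mask.sum())


@dataclass
class PhagosomeEvent:
    """A particle tracked across frames, anchored at its engulfment frame."""

    event_id: int
    detections: list[Detection]
    engulfment_frame: int | None = None
    accepted: bool = True  # manual-screen hook: reject to drop from analysis

    @property
    def frames(self) -> list[int]:
        return [d.frame_index for d in self.detections]

    def centroid_median_um(self) -> tuple[float, float]:
        xs = np.median([d.centroid_um[0] for d in self.detections])
        ys = np.median([d.centroid_um[1] for d in self.detections])
        return float(xs), float(ys)


def segment_particles(
    image: np.ndarray, pixel_size: float, params: SegParams | None = None
) -> list[Detection]:
    """Threshold one grayscale frame and return size-filtered detections.

    A constant image under Otsu yields no detections (empty list, not an
    error).  Returned masks are pairwise disjoint 8-connected components
    with area >= ``params.min_area`` um^2.
    """
    params = params or SegParams()
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    img = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    if params.threshold == "otsu":
        if np.ptp(img) == 0:
            return []
        thr = threshold_otsu(img)
    else:
        thr = float(params.threshold)
    binary = img > thr
    if params.fill_holes:
        binary = ndimage.binary_fill_holes(binary)
    labels = sk_label(binary, connectivity=2)
    px_area = pixel_size**2
    min_px = params.min_area / px_area
    detections = []
    n = labels.max()
    slices = ndimage.find_objects(labels)
    for lab in range(1, n + 1):
        sl = slices[lab - 1]
        if sl is None:
            continue
        local = labels[sl] == lab
        n_px = int(local.sum())
        if n_px < min_px:
            continue
        rows, cols = np.nonzero(local)
        r0, c0 = sl[0].start, sl[1].start
        cy = (rows.mean() + r0) * pixel_size
        cx = (cols.mean() + c0) * pixel_size
        mean_int = float(img[sl][local].mean())
        detections.append(
            Detection(
                frame_index=0,
                centroid_um=(float(cx), float(cy)),
                area_um2=n_px * px_area,
                mean_intensity=mean_int,
                bbox_offset=(r0, c0),
                local_mask=local,
            )
        )
    return detections


def link_cost(a: Detection, b: Detection, params: LinkParams, frame_gap: int = 1) -> float:
    """Similarity cost: scaled centroid distance + log-area change."""
    dist = float(np.hypot(a.centroid_um[0] - b.centroid_um[0],
                          a.centroid_um[1] - b.centroid_um[1]))
    max_d = params.max_displacement * frame_gap
    if max_d <= 0:
        return np.inf if dist > 0 else params.area_weight * abs(
            np.log(b.area_um2 / a.area_um2)
        )
    return dist / max_d + params.area_weight * abs(np.log(b.area_um2 / a.area_um2))


def link_frames(
    a: list[Detection],
    b: list[Detection],
    params: LinkParams | None = None,
    frame_gap: int = 1,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """One-to-one matching between two detection lists.

    Solves the minimum-total-cost assignment (Hungarian algorithm) with
    gating: pairs whose cost exceeds ``cost_threshold`` are never
    matched.  Returns (matched index pairs, unmatched indices in ``a``,
    unmatched indices in ``b``).
    """
    params = params or LinkParams()
    if not a or not b:
        return [], list(range(len(a))), list(range(len(b)))
    cost = np.array([[link_cost(da, db, params, frame_gap) for db in b] for da in a])
    gated = np.where(cost <= params.cost_threshold, cost, 1e9)
    ri, ci = linear_sum_assignment(gated)
    pairs = [(int(i), int(j)) for i, j in zip(ri, ci) if cost[i, j] <= params.cost_threshold]
    ma = {i for i, _ in pairs}
    mb = {j for _, j in pairs}
    return pairs, [i for i in range(len(a)) if i not in ma], [j for j in range(len(b)) if j not in mb]


def build_events(
    detections_by_frame: dict[int, list[Detection]],
    params: LinkParams | None = None,
) -> list[PhagosomeEvent]:
    """Chain per-frame detections into events.

    Tracks are extended while the frame gap stays within
    ``max_frame_gap``; a particle that vanishes for longer starts a new
    event when it reappears.  Events shorter than ``min_event_length``
    frames are discarded.  Each event still carries ``accepted`` as a
    review hook so individual events can be rejected after inspection.
    """
    params = params or LinkParams()
    frames = sorted(detections_by_frame)
    for f, dets in detections_by_frame.items():
        for d in dets:
            d.frame_index = f
    active: list[list[Detection]] = []
    finished: list[list[Detection]] = []
    for f in frames:
        dets = detections_by_frame[f]
        # retire tracks that have fallen too far behind
        still = []
        for tr in active:
            if f - tr[-1].frame_index > params.max_frame_gap:
                finished.append(tr)
            else:
                still.append(tr)
        active = still
        if not dets:
            continue
        lasts = [tr[-1] for tr in active]
        # link each active track's last detection to this frame's detections;
        # gating distance scales with the actual frame gap per track
        if lasts:
            cost = np.array(
                [
                    [
                        link_cost(da, db, params, f - da.frame_index)
                        for db in dets
                    ]
                    for da in lasts
                ]
            )
            gated = np.where(cost <= params.cost_threshold, cost, 1e9)
            ri, ci = linear_sum_assignment(gated)
            matched_b = set()
            for i, j in zip(ri, ci):
                if cost[i, j] <= params.cost_threshold:
                    active[i].append(dets[j])
                    matched_b.add(j)
        else:
            matched_b = set()
        for j, d in enumerate(dets):
            if j not in matched_b:
                active.append([d])
    finished.extend(active)
    finished = [tr for tr in finished if len(tr) >= params.min_event_length]
    finished.sort(key=lambda tr: (tr[0].frame_index, tr[0].centroid_um))
    return [PhagosomeEvent(event_id=i, detections=tr) for i, tr in enumerate(finished)]


def assign_engulfment(
    events: list[PhagosomeEvent],
    annotations: list[dict],
    max_distance_um: float = 3.0,
) -> list[PhagosomeEvent]:
    """Attach engulfment frames from an annotation table.

    Each annotation is ``{"x_um": ..., "y_um": ..., "engulfment_frame": int}``;
    it is assigned to the nearest event (median track centroid) within
    ``max_distance_um``.  An annotation whose frame is outside the
    event's observed range, or that matches no event, raises ValueError.
    Events without an annotation keep ``engulfment_frame=None`` and are
    excluded from trace analysis downstream.
    """
    if not events:
        return events
    med = np.array([ev.centroid_median_um() for ev in events])
    for ann in annotations:
        d = np.hypot(med[:, 0] - ann["x_um"], med[:, 1] - ann["y_um"])
        k = int(np.argmin(d))
        if d[k] > max_distance_um:
            raise ValueError(
                f"annotation at ({ann['x_um']:.2f}, {ann['y_um']:.2f}) um matches "
                f"no event (nearest {d[k]:.2f} um away)"
            )
        ef = int(ann["engulfment_frame"])
        ev = events[k]
        if ef < 0 or ef > ev.frames[-1]:
            raise ValueError(
                f"engulfment frame {ef} outside event {ev.event_id}'s frames "
                f"[{ev.frames[0]}, {ev.frames[-1]}]"
            )
        ev.engulfment_frame = ef
    return events
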