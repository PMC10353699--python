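"""Per-frame particle detection and trajectory linking.

Detection uses the circular Hough transform (accumulator-based circle
detector returning centers and radii), which works well for spherical
microspheres; non-spherical cells are detected on a best-effort basis.
Linking follows the closest-position rule: for each existing trajectory,
the nearest detection in the next frame is attached, greedily, with links
longer than ``max_link_distance`` rejected.  Trajectories that fail the
in-focus duration filter are removed afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.feature import canny
from skimage.transform import hough_circle, hough_circle_peaks

from .io import ImageStack

__all__ = [
    "Detection",
    "Trajectory",
    "to_grayscale",
    "detect_particles",
    "detect_stack",
    "link_trajectories",
    "reject_out_of_frame",
    "track_stack",
]

logger = logging.getLogger(__name__)

# ITU-R BT.709 luminance weights (same convention as skimage.color.rgb2gray)
_LUMA = np.array([0.2125, 0.7154, 0.0721])


@dataclass(frozen=True)
class Detection:
    frame_index: int
    center: tuple[float, float]    # (x, y) px, sub-pixel allowed
    radius: float                  # px
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")


@dataclass
class Trajectory:
    particle_id: int
    detections: list[Detection] = field(default_factory=list)

    @property
    def start_frame(self) -> int:
        return self.detections[0].frame_index

    @property
    def end_frame(self) -> int:
        return self.detections[-1].frame_index

    def __len__(self) -> int:
        return len(self.detections)

    @property
    def centers(self) -> np.ndarray:
        """(L, 2) array of (x, y) pixel centers in frame order."""
        return np.array([d.center for d in self.detections])

    @property
    def frames(self) -> np.ndarray:
        return np.array([d.frame_index for d in self.detections])


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Luminance conversion of an RGB frame; grayscale input is returned
    unchanged (idempotent).  Output keeps the 0–255 intensity scale."""
    frame = np.asarray(frame)
    if frame.size == 0:
        raise ValueError("empty frame")
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3 and frame.shape[-1] == 3:
        return frame.astype(float) @ _LUMA
    raise ValueError(f"expected (H, W) or (H, W, 3) frame, got {frame.shape}")


def _refine_center(frame: np.ndarray, cx: int, cy: int, r: float) -> tuple[float, float]:
    """Sub-pixel refinement: intensity-weighted centroid of darkness in a
    box around the accumulator peak.  Dark particles on a bright field, so
    the weight is background minus intensity, floored at zero."""
    h, w = frame.shape
    half = int(np.ceil(r)) + 1
    x0, x1 = max(cx - half, 0), min(cx + half + 1, w)
    y0, y1 = max(cy - half, 0), min(cy + half + 1, h)
    patch = frame[y0:y1, x0:x1].astype(float)
    bg = float(np.median(frame))
    weight = np.clip(bg - patch, 0.0, None)
    total = weight.sum()
    if total <= 0:
        return float(cx), float(cy)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    return float((weight * xx).sum() / total), float((weight * yy).sum() / total)


def detect_particles(
    frame: np.ndarray,
    radius_range: tuple[int, int],
    sensitivity: float = 0.4,
    refine: bool = True,
    canny_sigma: float = 1.6,
) -> list[Detection]:
    """Detect dark circular particles in one grayscale frame.

    ``sensitivity`` is the threshold on the normalized Hough accumulator
    (fraction of the circle perimeter supported by edge pixels); lower
    values admit weaker circles.  Duplicate peaks are suppressed with a
    minimum center separation equal to the minimum search radius.
    Detections are returned sorted by accumulator score, descending.
    """
    frame = to_grayscale(frame)
    rmin, rmax = radius_range
    if not (0 < rmin <= rmax):
        raise ValueError("radius_range must satisfy 0 < min <= max")
    if rmax * 2 >= min(frame.shape):
        raise ValueError("radius_range wider than the frame allows")

    edges = canny(frame.astype(float) / 255.0, sigma=canny_sigma)
    radii = np.arange(rmin, rmax + 1)
    accum = hough_circle(edges, radii)
    scores, cx, cy, rr = hough_circle_peaks(
        accum, radii,
        min_xdistance=rmin, min_ydistance=rmin,
        threshold=sensitivity,
        total_num_peaks=np.inf,
    )
    detections = []
    frame_idx = 0
    for s, x, y, r in zip(scores, cx, cy, rr):
        center = (float(x), float(y))
        if refine:
            center = _refine_center(frame, int(x), int(y), float(r))
        h, w = frame.shape
        if not (0 <= center[0] < w and 0 <= center[1] < h):
            continue
        detections.append(Detection(frame_index=frame_idx, center=center,
                                    radius=float(r), score=float(s)))
    detections.sort(key=lambda d: -d.score)
    return detections


def detect_stack(stack: ImageStack, radius_range: tuple[int, int],
                 sensitivity: float = 0.4, refine: bool = True,
                 canny_sigma: float = 1.6) -> list[list[Detection]]:
    """Run :func:`detect_particles` on every frame; frame indices are set."""
    per_frame: list[list[Detection]] = []
    for i in range(stack.n_frames):
        dets = detect_particles(to_grayscale(stack.frames[i]), radius_range,
                                sensitivity=sensitivity, refine=refine,
                                canny_sigma=canny_sigma)
        per_frame.append([Detection(frame_index=i, center=d.center,
                                    radius=d.radius, score=d.score)
                          for d in dets])
    return per_frame


def link_trajectories(
    detections_per_frame: Sequence[Sequence[Detection]],
    max_link_distance: float | None = None,
    max_gap: int = 0,
) -> list[Trajectory]:
    """Greedy closest-position linking across consecutive frames.

    The first frame is the reference frame: every detection there seeds a
    trajectory.  For each subsequent frame, active trajectories (processed
    in descending order of their head-detection score) claim their nearest
    unassigned detection, provided it lies within ``max_link_distance``
    (default 2 × the largest detected radius).  Unclaimed detections start
    new trajectories; unmatched trajectories terminate, or survive up to
    ``max_gap`` missing frames when gap bridging is enabled.

    Equidistant candidates are broken by lowest detection index, with a
    logged warning (closest-position matching does not define the tie).
    """
    if len(detections_per_frame) == 0:
        raise ValueError("empty detection input")
    if max_link_distance is None:
        all_r = [d.radius for frame in detections_per_frame for d in frame]
        max_link_distance = 2.0 * max(all_r) if all_r else np.inf

    next_id = 0
    active: list[Trajectory] = []
    gap_count: dict[int, int] = {}
    done: list[Trajectory] = []

    for det in detections_per_frame[0]:
        active.append(Trajectory(particle_id=next_id, detections=[det]))
        gap_count[next_id] = 0
        next_id += 1

    for dets in detections_per_frame[1:]:
        dets = list(dets)
        claimed = np.zeros(len(dets), dtype=bool)
        survivors: list[Trajectory] = []
        order = sorted(active, key=lambda t: -t.detections[-1].score)
        for traj in order:
            head = np.array(traj.detections[-1].center)
            best_j, best_d = -1, np.inf
            for j, d in enumerate(dets):
                if claimed[j]:
                    continue
                dist = float(np.hypot(*(np.array(d.center) - head)))
                if dist < best_d - 1e-12:
                    best_j, best_d = j, dist
                elif abs(dist - best_d) <= 1e-12 and best_j >= 0 and j != best_j:
                    logger.warning(
                        "tie at distance %.3f px between detections %d and %d; "
                        "keeping lowest index %d", dist, best_j, j, min(best_j, j))
                    best_j = min(best_j, j)
            if best_j >= 0 and best_d <= max_link_distance:
                claimed[best_j] = True
                traj.detections.append(dets[best_j])
                gap_count[traj.particle_id] = 0
                survivors.append(traj)
            elif gap_count[traj.particle_id] < max_gap:
                gap_count[traj.particle_id] += 1
                survivors.append(traj)
            else:
                done.append(traj)
        for j, d in enumerate(dets):
            if not claimed[j]:
                t = Trajectory(particle_id=next_id, detections=[d])
                gap_count[next_id] = 0
                next_id += 1
                survivors.append(t)
        active = survivors

    done.extend(active)
    done.sort(key=lambda t: t.particle_id)
    return done


def reject_out_of_frame(trajectories: Sequence[Trajectory],
                        min_length_fraction: float,
                        total_frames: int) -> list[Trajectory]:
    """Keep trajectories present for at least ``min_length_fraction`` of the
    recording — the out-of-focal-plane rejection step."""
    if not (0 < min_length_fraction <= 1):
        raise ValueError("min_length_fraction must be in (0, 1]")
    min_len = min_length_fraction * total_frames
    return [t for t in trajectories if len(t) >= min_len]


def track_stack(stack: ImageStack, radius_range: tuple[int, int],
                sensitivity: float = 0.4, min_length_fraction: float = 0.9,
                max_link_distance: float | None = None,
                max_gap: int = 0) -> list[Trajectory]:
    """Detect + link + filter in one call (the Fig-style pipeline order:
    grayscale → detection → linking → out-of-frame rejection)."""
    per_frame = detect_stack(stack, radius_range, sensitivity=sensitivity)
    trajs = link_trajectories(per_frame, max_link_distance=max_link_distance,
                              max_gap=max_gap)
    return reject_out_of_frame(trajs, min_length_fraction, stack.n_frames)
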