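"""Spot detection, frame-to-frame linking and nucleus traces.

Replaces the commercial segmentation step of the original workflow with a
transparent detector: median/Gaussian denoising, local-maximum detection
with non-maximum suppression, sub-pixel refinement by intensity-weighted
centroid, and greedy mutual-nearest-neighbour linking without gap closing.

Coordinate convention: the centre of pixel (0, 0) is the origin; a pixel
index times the pixel size gives the position in µm, with image columns
along x and rows along y.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu

from .tracks import Track, NucleusTrace, TrackSet, uniform_times


@dataclass
class SpotDetection:
    """One sub-pixel detection in one frame."""

    frame: int
    xy_um: np.ndarray              # (x, y) in µm
    peak_intensity: float
    integrated_intensity: float


def median_filter_3x3(image: np.ndarray) -> np.ndarray:
    """3x3 median filter with reflected edges (standard denoising step)."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2D image, got {image.ndim} dimensions")
    return ndimage.median_filter(image, size=3, mode="reflect")


def _refine_centroid(image: np.ndarray, peak_rc: tuple[int, int],
                     half_width: int) -> tuple[np.ndarray, float]:
    """Background-subtracted intensity-weighted centroid in a window.

    The local background is the median of the window border, so a constant
    offset does not bias the centroid toward the window centre.
    """
    h, w = image.shape
    r0 = max(peak_rc[0] - half_width, 0)
    r1 = min(peak_rc[0] + half_width + 1, h)
    c0 = max(peak_rc[1] - half_width, 0)
    c1 = min(peak_rc[1] + half_width + 1, w)
    win = image[r0:r1, c0:c1].astype(float)
    border = np.concatenate([win[0, :], win[-1, :], win[1:-1, 0], win[1:-1, -1]])
    weights = np.clip(win - np.median(border), 0.0, None)
    total = weights.sum()
    if total <= 0:
        return np.array([float(peak_rc[0]), float(peak_rc[1])]), 0.0
    rows = np.arange(r0, r1)[:, None]
    cols = np.arange(c0, c1)[None, :]
    row = (weights * rows).sum() / total
    col = (weights * cols).sum() / total
    return np.array([row, col]), float(total)


def detect_spots(image: np.ndarray, *, pixel_size_um: float,
                 smoothing_sigma_um: float, threshold: float,
                 min_separation_um: float) -> list[SpotDetection]:
    """Detect bright spots in one frame with sub-pixel localisation.

    Local maxima of the Gaussian-smoothed image above ``threshold`` are
    kept, suppressing any maximum within ``min_separation_um`` of a
    brighter one; positions are refined by an intensity-weighted centroid
    in a window of half-width ``2 * smoothing_sigma``.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("detect_spots expects a single 2D frame")
    sigma_px = smoothing_sigma_um / pixel_size_um
    smoothed = ndimage.gaussian_filter(image, sigma_px)
    min_dist_px = max(1, int(round(min_separation_um / pixel_size_um)))
    peaks = peak_local_max(smoothed, min_distance=min_dist_px,
                           threshold_abs=threshold, exclude_border=False)
    half = max(2, int(round(2.0 * sigma_px)))
    detections = []
    for peak in peaks:
        rc, integrated = _refine_centroid(image, tuple(peak), half)
        detections.append(SpotDetection(
            frame=0,
            xy_um=np.array([rc[1], rc[0]]) * pixel_size_um,
            peak_intensity=float(image[peak[0], peak[1]]),
            integrated_intensity=integrated))
    detections.sort(key=lambda d: (d.xy_um[0], d.xy_um[1]))
    return detections


def detect_stack(stack: np.ndarray, *, pixel_size_um: float,
                 smoothing_sigma_um: float, threshold: float,
                 min_separation_um: float,
                 median_prefilter: bool = True) -> list[list[SpotDetection]]:
    """Run :func:`detect_spots` on every frame of a stack."""
    per_frame = []
    for k, frame in enumerate(np.asarray(stack, dtype=float)):
        if median_prefilter:
            frame = median_filter_3x3(frame)
        dets = detect_spots(frame, pixel_size_um=pixel_size_um,
                            smoothing_sigma_um=smoothing_sigma_um,
                            threshold=threshold,
                            min_separation_um=min_separation_um)
        for d in dets:
            d.frame = k
        per_frame.append(dets)
    return per_frame


def link_detections(per_frame: list[list[SpotDetection]], *,
                    max_displacement_um: float, frame_interval_s: float = 1.0,
                    nucleus_id: int = 0) -> list[Track]:
    """Greedy mutual-nearest-neighbour linking into tracks.

    A detection links to the next frame only if the two are each other's
    nearest neighbours and closer than ``max_displacement_um``; ties are
    broken toward the smaller current track id.  Unmatched detections
    start new tracks and tracks end when unmatched (no gap closing).
    """
    if max_displacement_um <= 0:
        raise ValueError("max_displacement_um must be positive")
    next_id = 0
    # active: track_id -> (list of (frame, detection))
    active: dict[int, list[SpotDetection]] = {}
    finished: dict[int, list[SpotDetection]] = {}
    prev_assignment: dict[int, int] = {}   # index in previous frame -> track id

    for k, dets in enumerate(per_frame):
        if k == 0:
            for i, d in enumerate(dets):
                active[next_id] = [d]
                prev_assignment[i] = next_id
                next_id += 1
            continue
        prev_dets = per_frame[k - 1]
        links: dict[int, int] = {}
        if prev_dets and dets:
            prev_xy = np.array([d.xy_um for d in prev_dets])
            cur_xy = np.array([d.xy_um for d in dets])
            dist = np.linalg.norm(prev_xy[:, None, :] - cur_xy[None, :, :], axis=2)
            nearest_cur = dist.argmin(axis=1)
            nearest_prev = dist.argmin(axis=0)
            order = sorted(range(len(prev_dets)),
                           key=lambda i: prev_assignment.get(i, np.inf))
            for i in order:
                j = int(nearest_cur[i])
                if int(nearest_prev[j]) == i and dist[i, j] <= max_displacement_um \
                        and j not in links.values():
                    links[i] = j
        new_assignment: dict[int, int] = {}
        linked_cur = set(links.values())
        for i, tid in prev_assignment.items():
            if i in links:
                active[tid].append(dets[links[i]])
                new_assignment[links[i]] = tid
            else:
                finished[tid] = active.pop(tid)
        for j, d in enumerate(dets):
            if j not in linked_cur:
                active[next_id] = [d]
                new_assignment[j] = next_id
                next_id += 1
        prev_assignment = new_assignment
    finished.update(active)

    tracks = []
    for tid in sorted(finished):
        dets = finished[tid]
        frames = np.array([d.frame for d in dets])
        xy = np.array([d.xy_um for d in dets])
        inten = np.array([d.peak_intensity for d in dets])
        tracks.append(Track(object_id=tid, nucleus_id=nucleus_id,
                            t_s=frames * frame_interval_s, xy_um=xy,
                            intensity=inten))
    return tracks


def nucleus_center_trace(stack: np.ndarray, *, pixel_size_um: float,
                         frame_interval_s: float, nucleus_id: int = 0,
                         threshold: float | None = None) -> NucleusTrace:
    """Per-frame intensity-weighted centre of mass of one cropped nucleus.

    Foreground is the image above an Otsu threshold (overridable); the
    area is the foreground pixel count times the pixel area.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    centers, areas = [], []
    for frame in stack:
        thr = threshold_otsu(frame) if threshold is None else threshold
        mask = frame > thr
        if not mask.any():
            raise ValueError("empty nucleus foreground; lower the threshold")
        weights = np.where(mask, frame, 0.0)
        total = weights.sum()
        rows = np.arange(frame.shape[0])[:, None]
        cols = np.arange(frame.shape[1])[None, :]
        row = (weights * rows).sum() / total
        col = (weights * cols).sum() / total
        centers.append([col * pixel_size_um, row * pixel_size_um])
        areas.append(mask.sum() * pixel_size_um ** 2)
    n = stack.shape[0]
    return NucleusTrace(nucleus_id=nucleus_id,
                        t_s=uniform_times(n, frame_interval_s),
                        center_um=np.array(centers),
                        area_um2=np.array(areas))


def to_relative(tracks: list[Track] | TrackSet,
                nucleus_trace: NucleusTrace | dict[int, NucleusTrace]
                ) -> list[Track]:
    """Express tracks in nucleus-centred coordinates (position - centre).

    Used for MSD and track visualisation; pairwise distance-change (MSC)
    statistics are computed on absolute coordinates instead, because they
    are insensitive to nuclear drift by construction.
    """
    track_list = list(tracks.tracks) if isinstance(tracks, TrackSet) else list(tracks)
    if isinstance(nucleus_trace, NucleusTrace):
        traces = {nucleus_trace.nucleus_id: nucleus_trace}
    else:
        traces = nucleus_trace
    out = []
    for tr in track_list:
        trace = traces[tr.nucleus_id]
        if trace.t_s.shape != tr.t_s.shape or np.any(
                np.abs(trace.t_s - tr.t_s) > 1e-6):
            raise ValueError(f"track {tr.object_id} and nucleus trace frames differ")
        xy = tr.xy_um.copy()
        xy[:, :2] = xy[:, :2] - trace.center_um
        out.append(tr.with_positions(xy))
    return out


def drop_z(tracks: list[Track] | TrackSet) -> list[Track]:
    """Discard any z coordinate; all downstream statistics are 2D."""
    track_list = list(tracks.tracks) if isinstance(tracks, TrackSet) else list(tracks)
    return [tr if tr.ndim == 2 else tr.with_positions(tr.xy_um[:, :2])
            for tr in track_list]
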