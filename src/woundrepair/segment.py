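"""Wound segmentation and actin-ring edge detection.

Replaces the manual Fiji measurements with deterministic operations: a
per-frame wound mask (the low-intensity membrane-plug interior enclosed by
the bright actomyosin ring), the per-frame area trace, and the ring's inner
and outer half-maximum edges from the radial intensity profile about the
wound centroid.

Segmentation recipe: Gaussian blur (σ=1 px) → Otsu threshold (optionally
restricted to a neighbourhood of the previous frame's mask, or a hint point)
→ largest enclosed dark connected component → threshold refinement at the
midpoint of the interior level and the adjacent ring peak, applied at full
resolution → morphological closing (3 px).  The refinement stage pins the
recovered boundary to the wound-edge midpoint, removing the sub-pixel bias
an Otsu cut between the cortex and ring intensity classes would leave.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage import filters, measure, morphology


class RingNotFoundError(ValueError):
    """No radial intensity peak above the cortex baseline."""


# --------------------------------------------------------------------------
# data containers
# --------------------------------------------------------------------------

@dataclass
class ImageStack:
    """Timestamped single-channel frame sequence with physical pixel size."""

    frames: np.ndarray              # T x H x W, nonnegative intensities
    frame_times: np.ndarray         # seconds, t=0 = wounding
    pixel_size: float               # μm/px
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be T x H x W")
        if len(self.frame_times) != len(self.frames):
            raise ValueError("frame_times length must match frame count")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    def __len__(self) -> int:
        return len(self.frames)

    def frame_nearest(self, t: float) -> int:
        return int(np.argmin(np.abs(self.frame_times - t)))


@dataclass
class WoundMask:
    mask: np.ndarray                # H x W bool
    pixel_size: float
    frame_time: float | None = None

    @property
    def area_um2(self) -> float:
        return float(self.mask.sum()) * self.pixel_size ** 2

    @property
    def empty(self) -> bool:
        return not bool(self.mask.any())

    def boundary(self) -> np.ndarray:
        """(N, 2) row/col coordinates of boundary pixels."""
        if self.empty:
            return np.empty((0, 2), dtype=int)
        interior = ndimage.binary_erosion(self.mask)
        return np.argwhere(self.mask & ~interior)

    def centroid(self) -> tuple[float, float]:
        if self.empty:
            raise ValueError("empty mask has no centroid")
        rr, cc = np.nonzero(self.mask)
        return float(rr.mean()), float(cc.mean())


@dataclass
class WoundTrace:
    """Per-frame wound areas (μm²) with masks and closure flags."""

    frame_times: np.ndarray
    areas: np.ndarray               # μm²
    masks: list[WoundMask]
    closed: np.ndarray              # bool per frame
    pixel_size: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame_time_s": self.frame_times,
            "area_um2": self.areas,
            "closed_flag": self.closed,
        })


@dataclass
class RingGeometry:
    """Outer/inner ring-edge regions with Feret diameters, areas and
    integrated intensities at one timepoint."""

    outer_mask: np.ndarray
    inner_mask: np.ndarray
    outer_feret: float              # μm
    inner_feret: float              # μm
    outer_area: float               # μm²
    inner_area: float               # μm²
    outer_integrated_intensity: float   # intensity · px
    inner_integrated_intensity: float   # intensity · px
    pixel_size: float
    frame_time: float | None = None


# --------------------------------------------------------------------------
# wound segmentation
# --------------------------------------------------------------------------

def segment_wound(frame: np.ndarray, pixel_size: float,
                  hint: tuple[int, int] | None = None,
                  search_mask: np.ndarray | None = None,
                  min_area_px: int = 5,
                  blur_sigma: float = 1.0,
                  closing_radius: int = 3,
                  darkness_factor: float = 0.6,
                  frame_time: float | None = None) -> WoundMask:
    """Segment the dark wound interior enclosed by the bright ring.

    Returns an empty mask when no enclosed dark region passes the minimum
    area and darkness checks (e.g. a uniform pre-wound frame).  ``hint`` is
    only a disambiguator when several candidate regions exist.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    if hint is not None:
        hr, hc = hint
        if not (0 <= hr < frame.shape[0] and 0 <= hc < frame.shape[1]):
            raise ValueError(f"hint {hint} outside image {frame.shape}")

    empty = WoundMask(np.zeros(frame.shape, dtype=bool), pixel_size, frame_time)

    blurred = ndimage.gaussian_filter(frame, blur_sigma)
    span = float(blurred.max() - blurred.min())
    if span <= 1e-9 * max(1.0, abs(float(blurred.mean()))):
        return empty  # constant frame: nothing to segment

    region = np.ones(frame.shape, dtype=bool) if search_mask is None \
        else np.asarray(search_mask, dtype=bool)
    if not region.any():
        region = np.ones(frame.shape, dtype=bool)

    thr = filters.threshold_otsu(blurred[region])
    dark = (blurred < thr) & region

    labels = measure.label(dark, connectivity=1)
    if labels.max() == 0:
        return empty
    # enclosed components only: drop any touching the image border
    border_labels = np.unique(np.concatenate([
        labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]))
    frame_median = float(np.median(blurred))
    candidates = []
    for r in measure.regionprops(labels):
        if r.label in border_labels:
            continue
        if r.area < min_area_px:
            continue
        min_in = float(blurred[labels == r.label].min())
        if min_in > darkness_factor * frame_median:
            continue  # not dark enough to be a membrane plug
        candidates.append(r)
    if not candidates:
        return empty

    chosen = None
    if hint is not None:
        lab = labels[hint[0], hint[1]]
        for r in candidates:
            if r.label == lab:
                chosen = r
                break
    if chosen is None:
        chosen = max(candidates, key=lambda r: r.area)
    core = labels == chosen.label

    # refinement: re-threshold at the midpoint of interior level and the
    # adjacent ring peak, at full resolution (pins the edge at half-rise)
    neighborhood = ndimage.binary_dilation(
        core, morphology.disk(3 * closing_radius))
    interior_level = float(np.median(frame[core]))
    ring_peak = float(blurred[neighborhood].max())
    thr2 = 0.5 * (interior_level + ring_peak)
    refined = (frame < thr2) & neighborhood
    lab2 = measure.label(refined, connectivity=1)
    rr, cc = np.nonzero(core)
    keep = np.bincount(lab2[rr, cc].ravel()).argmax()
    if keep == 0:  # refinement lost the core; fall back to the Otsu component
        mask = core
    else:
        mask = lab2 == keep

    mask = ndimage.binary_closing(mask, structure=morphology.disk(closing_radius))
    mask = ndimage.binary_fill_holes(mask)
    if mask.sum() < min_area_px:
        return empty
    return WoundMask(mask, pixel_size, frame_time)


def trace_wound_areas(stack: ImageStack,
                      closure_threshold_um2: float = 1.0,
                      track: bool = True,
                      **segment_kwargs) -> WoundTrace:
    """Segment every frame of a stack into a :class:`WoundTrace`.

    ``track=True`` restricts each frame's threshold search to a dilated
    neighbourhood of the previous nonempty mask (the spec'd Fiji-style
    workflow); segmentation itself stays per-frame and deterministic.
    A frame is flagged closed once the area falls below
    ``closure_threshold_um2`` and stays below it for the rest of the trace.
    """
    if len(stack) == 0:
        raise ValueError("empty stack")
    masks: list[WoundMask] = []
    prev: WoundMask | None = None
    for i in range(len(stack)):
        search = None
        if track and prev is not None and not prev.empty:
            search = ndimage.binary_dilation(prev.mask, morphology.disk(15))
        m = segment_wound(stack.frames[i], stack.pixel_size,
                          search_mask=search,
                          frame_time=float(stack.frame_times[i]),
                          **segment_kwargs)
        if m.empty and search is not None:
            # wound may have moved/vanished; retry globally before accepting 0
            m = segment_wound(stack.frames[i], stack.pixel_size,
                              frame_time=float(stack.frame_times[i]),
                              **segment_kwargs)
        masks.append(m)
        prev = m

    areas = np.array([m.area_um2 for m in masks])
    below = areas < closure_threshold_um2
    closed = np.zeros(len(masks), dtype=bool)
    # closed from the first frame after which the area never recovers
    for i in range(len(masks)):
        if below[i:].all() and (len(masks) - i >= 2 or i == len(masks) - 1):
            closed[i:] = True
            break
    # pre-wound frames are not "closed" wounds
    closed[stack.frame_times < 0] = False
    return WoundTrace(frame_times=stack.frame_times.copy(), areas=areas,
                      masks=masks, closed=closed, pixel_size=stack.pixel_size)


# --------------------------------------------------------------------------
# ring edge detection
# --------------------------------------------------------------------------

def radial_profile(frame: np.ndarray, center: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Mean intensity in 1-px radial bins about ``center`` (row, col).

    Restricted to radii fully inside the image so bin means are unbiased.
    Returns (radii_px, mean_intensity).
    """
    h, w = frame.shape
    cr, cc = center
    max_r = int(min(cr, cc, h - 1 - cr, w - 1 - cc))
    if max_r < 2:
        raise ValueError("center too close to the image border")
    rows = (np.arange(h) - cr)[:, None]
    cols = (np.arange(w) - cc)[None, :]
    dist = np.hypot(rows, cols)
    bins = np.rint(dist).astype(int)
    inside = bins <= max_r
    sums = np.bincount(bins[inside].ravel(), weights=frame[inside].ravel(),
                       minlength=max_r + 1)
    counts = np.bincount(bins[inside].ravel(), minlength=max_r + 1)
    prof = sums / np.maximum(counts, 1)
    return np.arange(max_r + 1, dtype=float), prof


def detect_ring_edges(frame: np.ndarray, wound_mask: WoundMask,
                      pixel_size: float,
                      baseline: float | None = None,
                      peak_margin: float = 0.05,
                      frame_time: float | None = None) -> RingGeometry:
    """Locate the ring's inner and outer half-maximum edges.

    The inner edge is where the radial intensity profile (about the wound
    centroid) first exceeds the half-maximum of the ring peak moving
    outward; the outer edge is where it last exceeds it.  The regions are
    the filled areas enclosed by each edge; Feret diameters, areas and
    integrated intensities are measured on those pixel regions.
    """
    from .metrics import feret_diameter

    if wound_mask.empty:
        raise ValueError("wound_mask must be nonempty")
    frame = np.asarray(frame, dtype=float)
    center = wound_mask.centroid()
    radii, prof = radial_profile(frame, center)

    if baseline is None:
        baseline = float(np.median(frame))
    peak_idx = int(np.argmax(prof))
    peak = float(prof[peak_idx])
    if peak < baseline * (1.0 + peak_margin):
        raise RingNotFoundError(
            f"no radial peak above cortex baseline "
            f"(peak {peak:.1f} vs baseline {baseline:.1f})")
    half = baseline + (peak - baseline) / 2.0

    above = prof >= half
    idx_above = np.nonzero(above)[0]
    first, last = int(idx_above[0]), int(idx_above[-1])

    def interp_in(i):  # crossing between i-1 (below) and i (above)
        if i == 0:
            return 0.0
        lo, hi = prof[i - 1], prof[i]
        return (i - 1) + (half - lo) / (hi - lo)

    def interp_out(i):  # crossing between i (above) and i+1 (below)
        if i >= len(prof) - 1:
            return float(i)
        hi, lo = prof[i], prof[i + 1]
        return i + (hi - half) / (hi - lo)

    r_in = interp_in(first)
    r_out = interp_out(last)

    h_, w_ = frame.shape
    rows = (np.arange(h_) - center[0])[:, None]
    cols = (np.arange(w_) - center[1])[None, :]
    dist = np.hypot(rows, cols)
    outer = dist <= r_out
    inner = dist <= r_in
    if not inner.any():
        inner = dist <= max(r_in, 0.5)  # degenerate: keep at least the center px

    return RingGeometry(
        outer_mask=outer, inner_mask=inner,
        outer_feret=feret_diameter(outer, pixel_size),
        inner_feret=feret_diameter(inner, pixel_size),
        outer_area=float(outer.sum()) * pixel_size ** 2,
        inner_area=float(inner.sum()) * pixel_size ** 2,
        outer_integrated_intensity=float(frame[outer].sum()),
        inner_integrated_intensity=float(frame[inner].sum()),
        pixel_size=pixel_size,
        frame_time=frame_time,
    )


# --------------------------------------------------------------------------
# stack I/O: multi-page TIFF (uint16) + JSON sidecar
# --------------------------------------------------------------------------

def write_stack(stack: ImageStack, path: str | Path,
                extra_meta: dict | None = None) -> Path:
    path = Path(path)
    data = np.clip(np.rint(stack.frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data)
    meta = {
        "frame_times": [float(t) for t in stack.frame_times],
        "pixel_size": stack.pixel_size,
        "channel_label": stack.channel_label,
    }
    if extra_meta:
        meta.update(extra_meta)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path


def read_stack(path: str | Path) -> ImageStack:
    path = Path(path)
    frames = tifffile.imread(path).astype(float)
    if frames.ndim == 2:
        frames = frames[None]
    meta = json.loads(path.with_suffix(".json").read_text())
    return ImageStack(frames=frames,
                      frame_times=np.asarray(meta["frame_times"], dtype=float),
                      pixel_size=float(meta["pixel_size"]),
                      channel_label=meta.get("channel_label", ""))


def write_masks(trace: WoundTrace, path: str | Path) -> Path:
    path = Path(path)
    data = np.stack([m.mask.astype(np.uint16) * 65535 for m in trace.masks])
    tifffile.imwrite(path, data)
    return path


__all__ = [
    "ImageStack", "WoundMask", "WoundTrace", "RingGeometry",
    "RingNotFoundError", "segment_wound", "trace_wound_areas",
    "radial_profile", "detect_ring_edges", "write_stack", "read_stack",
    "write_masks",
]
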