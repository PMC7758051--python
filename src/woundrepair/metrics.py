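"""Repair statistics: Feret diameters, ring width and intensity, wound
expansion, and contraction rate.

Definitions (all measured on the segmented trace and ring geometry):

* **Feret diameter** — maximum caliper width of a region: the largest
  pairwise Euclidean distance between boundary-pixel centers, computed via
  convex hull + rotating calipers.  Pixel-center convention: a single pixel
  has Feret 0.
* **ring width** = (outer Feret − inner Feret) / 2 at the reference
  timepoint (120 s post-wounding by default).
* **ring mean intensity** = (outer integrated intensity − inner integrated
  intensity) / (outer area − inner area), i.e. the mean over the annulus.
* **relative ring intensity** — ring mean intensity divided by the
  unwounded (UW) baseline: the mean of a centered 50×50 px window of the
  pre-wound frame.
* **expansion fold** = max wound area / area of the first post-wound frame.
* **t_max / t_half** — time of maximal area (earliest on ties) and the
  earliest subsequent time at which the area falls to a stated fraction
  (0.35–0.5) of the maximum.
* **contraction rate** = (A(t_max) − A(t_half)) / (t_half − t_max),
  reported as a positive magnitude (an average closure speed in μm²/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import ConvexHull, QhullError

from .segment import (ImageStack, RingGeometry, RingNotFoundError, WoundTrace,
                      detect_ring_edges, trace_wound_areas)


class StageError(RuntimeError):
    """Pipeline failure carrying the name of the stage that failed."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


# --------------------------------------------------------------------------
# Feret diameter
# --------------------------------------------------------------------------

def _rotating_calipers(points: np.ndarray) -> float:
    """Diameter of a point set via antipodal pairs on its convex hull.

    ``points``: (N, 2) float array.  Falls back to the direct pairwise
    maximum for degenerate (collinear) sets.
    """
    pts = np.unique(points, axis=0).astype(float)
    n = len(pts)
    if n == 1:
        return 0.0
    if n == 2:
        return float(np.hypot(*(pts[0] - pts[1])))
    try:
        hull = ConvexHull(pts)
    except QhullError:
        # collinear: diameter is the extent along the common direction
        d = pts - pts[0]
        proj = d @ (d[np.argmax(np.hypot(d[:, 0], d[:, 1]))])
        return float(np.hypot(*(pts[np.argmax(proj)] - pts[np.argmin(proj)])))
    v = pts[hull.vertices]          # counter-clockwise
    m = len(v)
    if m == 2:
        return float(np.hypot(*(v[0] - v[1])))

    def area2(a, b, c):             # twice the signed triangle area
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

    best = 0.0
    j = 1
    for i in range(m):
        ni = (i + 1) % m
        # advance the caliper to the vertex farthest from edge (i, i+1)
        while area2(v[i], v[ni], v[(j + 1) % m]) > area2(v[i], v[ni], v[j]):
            j = (j + 1) % m
        for p in (v[j], v[(j + 1) % m]):
            best = max(best,
                       float(np.hypot(*(v[i] - p))),
                       float(np.hypot(*(v[ni] - p))))
    return best


def feret_diameter(mask: np.ndarray, pixel_size: float = 1.0) -> float:
    """Maximum caliper width of a binary mask in μm (pixel-center convention)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask has no Feret diameter")
    from scipy import ndimage
    boundary = mask & ~ndimage.binary_erosion(mask)
    pts = np.argwhere(boundary).astype(float)
    return _rotating_calipers(pts) * pixel_size


# --------------------------------------------------------------------------
# ring statistics
# --------------------------------------------------------------------------

def ring_width(geometry: RingGeometry) -> float:
    """(outer Feret − inner Feret) / 2, in μm."""
    if geometry.outer_feret < geometry.inner_feret:
        raise ValueError("outer Feret smaller than inner Feret")
    return (geometry.outer_feret - geometry.inner_feret) / 2.0


def ring_mean_intensity(frame: np.ndarray, geometry: RingGeometry) -> float:
    """(ΔI)/(ΔA): mean intensity over the annulus between the ring edges."""
    area_px = (geometry.outer_area - geometry.inner_area) / geometry.pixel_size ** 2
    if area_px <= 0:
        raise ZeroDivisionError("outer and inner regions have equal area")
    di = geometry.outer_integrated_intensity - geometry.inner_integrated_intensity
    return di / area_px


def uw_baseline(pre_wound_frame: np.ndarray, window: int = 50) -> float:
    """Mean of the centered ``window``×``window`` px region of the unwounded frame."""
    frame = np.asarray(pre_wound_frame, dtype=float)
    h, w = frame.shape
    if h < window or w < window:
        raise ValueError(f"frame {frame.shape} smaller than {window}x{window} window")
    r0 = (h - window) // 2
    c0 = (w - window) // 2
    return float(frame[r0:r0 + window, c0:c0 + window].mean())


def relative_ring_intensity(ring_series, baseline: float):
    """Ring mean intensity at each timepoint divided by the UW baseline."""
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    return np.asarray(ring_series, dtype=float) / baseline


# --------------------------------------------------------------------------
# wound dynamics
# --------------------------------------------------------------------------

def _post_wound(trace: WoundTrace) -> tuple[np.ndarray, np.ndarray]:
    sel = trace.frame_times >= 0
    return trace.frame_times[sel], trace.areas[sel]


def expansion_fold(trace: WoundTrace) -> float:
    """Max post-wound area / area of the first post-wound frame."""
    t, a = _post_wound(trace)
    if len(a) == 0 or a[0] <= 0:
        raise ValueError("first post-wound area is zero; expansion fold undefined")
    return float(a.max() / a[0])


def find_tmax_thalf(trace: WoundTrace, fraction: float = 0.5) -> tuple[float, float]:
    """Time of maximal area (earliest on ties) and earliest subsequent time
    with area ≤ fraction·max."""
    if not (0.35 <= fraction <= 0.5):
        raise ValueError("fraction must lie in [0.35, 0.5]")
    t, a = _post_wound(trace)
    if len(a) == 0:
        raise ValueError("trace has no post-wound frames")
    i_max = int(np.argmax(a))  # argmax returns the earliest maximum
    t_max = float(t[i_max])
    target = fraction * a[i_max]
    after = np.nonzero((t >= t_max) & (a <= target))[0]
    after = after[after > i_max]
    if after.size == 0:
        raise ValueError(
            f"wound did not contract to {fraction:.0%} of its maximum")
    j = int(after[0])
    return t_max, float(t[j])


def contraction_rate(trace: WoundTrace, fraction: float = 0.5) -> float:
    """Average closure speed (A(t_max) − A(t_half)) / (t_half − t_max), μm²/s."""
    t_max, t_half = find_tmax_thalf(trace, fraction)
    t, a = _post_wound(trace)
    a_max = float(a[t == t_max][0])
    a_half = float(a[t == t_half][0])
    return (a_max - a_half) / (t_half - t_max)


# --------------------------------------------------------------------------
# full-stack summary
# --------------------------------------------------------------------------

@dataclass
class RepairMetrics:
    expansion_fold: float
    t_max: float                    # s
    t_half: float                   # s
    contraction_rate: float         # μm²/s, positive magnitude
    ring_width: float               # μm at the reference timepoint
    ring_mean_intensity: float
    uw_baseline: float
    ring_rel_intensity_ref: float   # at the reference timepoint
    ring_reference_time: float
    relative_intensity_times: np.ndarray = field(default_factory=lambda: np.array([]))
    relative_intensity_series: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_row(self, stack_id: str = "") -> dict:
        return {
            "stack_id": stack_id,
            "expansion_fold": self.expansion_fold,
            "t_max_s": self.t_max,
            "t_half_s": self.t_half,
            "contraction_rate_um2_per_s": self.contraction_rate,
            "ring_width_um": self.ring_width,
            "ring_rel_intensity_120s": self.ring_rel_intensity_ref,
        }


def summarize_repair(stack: ImageStack,
                     ring_reference_time: float = 120.0,
                     t_half_fraction: float = 0.5,
                     compute_series: bool = True,
                     trace: WoundTrace | None = None) -> RepairMetrics:
    """Run the full imaging pipeline on one stack.

    Segments every frame, derives expansion/contraction statistics, and
    evaluates the ring geometry at the frame nearest ``ring_reference_time``
    (120 s post-wounding by default).  Requires a pre-wound frame for the UW
    baseline.  Any stage failure is re-raised as :class:`StageError` naming
    the stage.
    """
    pre = np.nonzero(stack.frame_times < 0)[0]
    if pre.size == 0:
        raise StageError("uw_baseline",
                         "stack has no pre-wound frame; UW baseline undefined")
    try:
        baseline = uw_baseline(stack.frames[pre[0]])
    except ValueError as e:
        raise StageError("uw_baseline", str(e)) from e

    try:
        if trace is None:
            trace = trace_wound_areas(stack)
    except Exception as e:
        raise StageError("trace_wound_areas", str(e)) from e

    try:
        fold = expansion_fold(trace)
        t_max, t_half = find_tmax_thalf(trace, t_half_fraction)
        rate = contraction_rate(trace, t_half_fraction)
    except ValueError as e:
        raise StageError("wound_dynamics", str(e)) from e

    ref_idx = stack.frame_nearest(ring_reference_time)
    try:
        geo = detect_ring_edges(stack.frames[ref_idx], trace.masks[ref_idx],
                                stack.pixel_size,
                                frame_time=float(stack.frame_times[ref_idx]))
        width = ring_width(geo)
        mean_int = ring_mean_intensity(stack.frames[ref_idx], geo)
    except (RingNotFoundError, ValueError) as e:
        raise StageError("ring_geometry", str(e)) from e

    times, series = [], []
    if compute_series:
        for i in range(len(stack)):
            if stack.frame_times[i] < 0 or trace.masks[i].empty:
                continue
            try:
                g = detect_ring_edges(stack.frames[i], trace.masks[i],
                                      stack.pixel_size)
                series.append(ring_mean_intensity(stack.frames[i], g))
                times.append(float(stack.frame_times[i]))
            except (RingNotFoundError, ValueError, ZeroDivisionError):
                continue  # ring not measurable on this frame

    rel = relative_ring_intensity(series, baseline) if series else np.array([])
    return RepairMetrics(
        expansion_fold=fold, t_max=t_max, t_half=t_half,
        contraction_rate=rate, ring_width=width,
        ring_mean_intensity=mean_int, uw_baseline=baseline,
        ring_rel_intensity_ref=mean_int / baseline,
        ring_reference_time=float(stack.frame_times[ref_idx]),
        relative_intensity_times=np.asarray(times),
        relative_intensity_series=rel,
    )


# --------------------------------------------------------------------------
# cohort aggregation
# --------------------------------------------------------------------------

def cohort_summary(rows: pd.DataFrame, group_col: str = "genotype",
                   control: str | None = None) -> pd.DataFrame:
    """Mean ± SEM per group for each metric column, with an optional
    two-sample Student's t-test p-value against the control group."""
    metric_cols = [c for c in rows.columns
                   if c not in (group_col, "stack_id")
                   and np.issubdtype(rows[c].dtype, np.number)]
    out = []
    for g, sub in rows.groupby(group_col):
        rec = {group_col: g, "n": len(sub)}
        for c in metric_cols:
            rec[f"{c}_mean"] = sub[c].mean()
            rec[f"{c}_sem"] = sub[c].sem()
            if control is not None and g != control:
                ctrl = rows.loc[rows[group_col] == control, c]
                rec[f"{c}_p"] = stats.ttest_ind(sub[c], ctrl).pvalue
        out.append(rec)
    return pd.DataFrame(out)


__all__ = [
    "StageError", "RepairMetrics", "feret_diameter", "ring_width",
    "ring_mean_intensity", "uw_baseline", "relative_ring_intensity",
    "expansion_fold", "find_tmax_thalf", "contraction_rate",
    "summarize_repair", "cohort_summary",
]
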