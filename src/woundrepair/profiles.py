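"""Line profiles, dynamic (concatenated) profiles, and kymographs.

A line profile averages a band of parallel pixel lines (10 px wide by
default) across the wound and reports, per position along the axis, the
mean fluorescence with a 95% confidence interval computed from the spread
across the band lines.  A kymograph averages a rectangular ROI band
(5.3 × 94.9 μm by default) down to one spatial column per frame and
concatenates the columns over time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .segment import ImageStack


@dataclass
class ProfileResult:
    positions_um: np.ndarray      # evenly spaced at pixel_size
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_lines: int
    frame_time: float | None = None


@dataclass
class Kymograph:
    data: np.ndarray              # space x time
    positions_um: np.ndarray
    frame_times: np.ndarray
    roi_center: tuple[float, float]
    roi_length_um: float
    roi_width_um: float


def _band_rows(center: int, width: int, limit: int, what: str) -> slice:
    start = center - (width - 1) // 2
    stop = start + width
    if start < 0 or stop > limit:
        raise ValueError(f"{what} band [{start}, {stop}) extends outside the frame")
    return slice(start, stop)


def line_profile(frame: np.ndarray,
                 center: tuple[int, int] | None = None,
                 orientation: str = "horizontal",
                 width_px: int = 10,
                 pixel_size: float = 1.0,
                 ci_method: str = "t",
                 smooth_window: int | None = None,
                 frame_time: float | None = None) -> ProfileResult:
    """Averaged line profile through ``center`` with a 95% CI per position.

    The CI is mean ± crit·sd/√width_px with the band lines treated as
    independent samples; ``ci_method='t'`` (default) uses the Student-t
    critical value for width_px−1 degrees of freedom, ``'z'`` uses 1.96.
    ``smooth_window`` applies an optional moving average along the axis
    (off by default).
    """
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape
    if center is None:
        center = (h // 2, w // 2)
    if width_px < 2:
        raise ValueError("width_px must be >= 2")

    if orientation == "horizontal":
        rows = _band_rows(center[0], width_px, h, "profile")
        band = frame[rows, :]                      # width x length
    elif orientation == "vertical":
        cols = _band_rows(center[1], width_px, w, "profile")
        band = frame[:, cols].T
    else:
        raise ValueError("orientation must be 'horizontal' or 'vertical'")

    mean = band.mean(axis=0)
    sd = band.std(axis=0, ddof=1)
    if ci_method == "t":
        crit = float(stats.t.ppf(0.975, width_px - 1))
    elif ci_method == "z":
        crit = 1.96
    else:
        raise ValueError("ci_method must be 't' or 'z'")
    half = crit * sd / np.sqrt(width_px)

    if smooth_window:
        from scipy.ndimage import uniform_filter1d
        mean = uniform_filter1d(mean, smooth_window, mode="nearest")
        half = uniform_filter1d(half, smooth_window, mode="nearest")

    positions = np.arange(band.shape[1]) * pixel_size
    return ProfileResult(positions_um=positions, mean=mean,
                         ci_low=mean - half, ci_high=mean + half,
                         n_lines=width_px, frame_time=frame_time)


def dynamic_profile(stack: ImageStack,
                    center: tuple[int, int] | None = None,
                    orientation: str = "horizontal",
                    width_px: int = 10,
                    **kwargs) -> list[ProfileResult]:
    """Per-frame line profiles concatenated in time order (identical to
    calling :func:`line_profile` frame-wise)."""
    return [
        line_profile(stack.frames[i], center=center, orientation=orientation,
                     width_px=width_px, pixel_size=stack.pixel_size,
                     frame_time=float(stack.frame_times[i]), **kwargs)
        for i in range(len(stack))
    ]


def kymograph(stack: ImageStack,
              center: tuple[int, int] | None = None,
              length_um: float = 94.9,
              width_um: float = 5.3,
              orientation: str = "horizontal",
              uniform_time: bool = False) -> Kymograph:
    """Space × time image from a band ROI averaged across its width.

    One column per frame by default regardless of the cadence change;
    ``uniform_time=True`` linearly interpolates columns onto a uniform time
    grid at the finest acquisition interval.
    """
    ps = stack.pixel_size
    h, w = stack.frames.shape[1:]
    if center is None:
        center = (h // 2, w // 2)
    length_px = max(int(round(length_um / ps)), 1)
    width_px = max(int(round(width_um / ps)), 1)

    if orientation == "horizontal":
        rows = _band_rows(center[0], width_px, h, "kymograph width")
        cols = _band_rows(center[1], length_px, w, "kymograph length")
        columns = stack.frames[:, rows, cols].mean(axis=1)   # T x length
    elif orientation == "vertical":
        rows = _band_rows(center[0], length_px, h, "kymograph length")
        cols = _band_rows(center[1], width_px, w, "kymograph width")
        columns = stack.frames[:, rows, cols].mean(axis=2)
    else:
        raise ValueError("orientation must be 'horizontal' or 'vertical'")

    data = columns.T                                         # space x time
    times = stack.frame_times.copy()
    if uniform_time and len(times) > 1:
        dt = float(np.min(np.diff(times)))
        grid = np.arange(times[0], times[-1] + dt / 2, dt)
        data = np.stack(
            [np.interp(grid, times, data[i]) for i in range(data.shape[0])])
        times = grid

    return Kymograph(data=data,
                     positions_um=np.arange(data.shape[0]) * ps,
                     frame_times=times,
                     roi_center=(float(center[0]), float(center[1])),
                     roi_length_um=length_um, roi_width_um=width_um)


def profile_to_frame(result: ProfileResult):
    """Tabular (CSV-ready) view of a profile."""
    import pandas as pd
    return pd.DataFrame({
        "position_um": result.positions_um,
        "mean": result.mean,
        "ci_low": result.ci_low,
        "ci_high": result.ci_high,
    })


def plot_profile(result: ProfileResult, ax=None):
    """Render mean line with shaded 95% CI band (matplotlib, optional)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(result.positions_um, result.mean, color="k", lw=1)
    ax.fill_between(result.positions_um, result.ci_low, result.ci_high,
                    color="0.7", alpha=0.7, lw=0)
    ax.set_xlabel("position (μm)")
    ax.set_ylabel("fluorescence (a.u.)")
    return ax


__all__ = ["ProfileResult", "Kymograph", "line_profile", "dynamic_profile",
           "kymograph", "profile_to_frame", "plot_profile"]
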