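"""Synthetic wound-repair movies and expression studies with known ground truth.

The imaging half of the package quantifies laser-wound repair in the syncytial
*Drosophila* embryo: upon ablation the wound expands under cortical tension,
an actomyosin ring assembles at the wound edge (with a diffuse actin "halo"
along its outer periphery), and the ring translocates inward until closure.
This module renders that phenomenology — a dark membrane-plug interior, a
bright annular ring abutting the wound edge, an outer halo, and a uniform
cortex — as a timestamped single-channel stack, together with the exact
per-frame geometry (:class:`GroundTruth`) so every downstream measurement can
be tested against a known answer.

The expression half emulates a 4-replicate wounded-vs-unwounded two-colour
array study: planted up/down genes with log2 effects on a null background,
per-gene sizes and TAD assignments, and a spot-level table containing a
configurable fraction of spots violating each quality-filter rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import integrate, optimize
from scipy.special import expit


# --------------------------------------------------------------------------
# frame grids
# --------------------------------------------------------------------------

def default_frame_times() -> np.ndarray:
    """Acquisition grid: one pre-wound frame at -30 s, then every 30 s to
    900 s, then every 60 s to 2400 s."""
    return np.concatenate([
        [-30.0],
        np.arange(0.0, 901.0, 30.0),
        np.arange(960.0, 2401.0, 60.0),
    ])


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------

class GeometryError(ValueError):
    """Simulated wound (plus ring and halo) does not fit in the frame."""


@dataclass
class WoundSimParams:
    """Parameters of a simulated wound-repair movie.

    Lengths are in μm, times in seconds relative to wounding, intensities in
    arbitrary camera units.  The defaults mirror the study conditions: a
    ~16×15.5 μm ablation target (``r0`` = 7.9 μm equivalent-circle radius),
    1.5-fold expansion peaking at 60 s, linear closure at 0.2 μm²/s, a 2 μm
    ring over a 100-unit cortex with a 3 μm halo, and the acquisition cadence
    of :func:`default_frame_times`.
    """

    image_shape: tuple[int, int] = (432, 432)
    pixel_size: float = 0.22            # μm/px; typical for a 63x/1.4 NA EMCCD setup
    frame_times: np.ndarray = field(default_factory=default_frame_times)
    r0: float = 7.9                     # μm, initial (t=0) wound radius
    expansion_fold_true: float = 1.5
    t_max_true: float = 60.0            # s, time of maximal area
    closure_rate_true: float = 0.2      # μm²/s, magnitude of post-peak linear decay
    late_rate_factor: float | None = None  # optional shallower slope after t_half
    ring_width_true: float = 2.0        # μm
    ring_amplitude: float = 300.0
    halo_width: float = 3.0             # μm
    halo_amplitude: float = 80.0
    cortex_baseline: float = 100.0
    edge_softness: float = 0.15         # μm, logistic edge scale of the renderer
    noise_model: str = "gaussian"       # none | gaussian | poisson
    noise_sigma: float = 15.0           # gaussian sigma (5% of ring amplitude)
    poisson_gain: float = 1.0
    rng_seed: int = 0
    wound_center: tuple[float, float] | None = None  # (row, col) px; default image center

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.expansion_fold_true < 1:
            raise ValueError("expansion_fold_true must be >= 1")
        if not (self.ring_amplitude > self.cortex_baseline > 0):
            raise ValueError("require ring_amplitude > cortex_baseline > 0")
        for name in ("pixel_size", "r0", "ring_width_true", "halo_width",
                     "edge_softness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.closure_rate_true < 0:
            raise ValueError("closure_rate_true must be >= 0")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        if int(np.sum(self.frame_times < 0)) != 1:
            raise ValueError("frame_times must contain exactly one pre-wound frame")
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")

    # convenience
    @property
    def initial_area(self) -> float:
        return math.pi * self.r0 ** 2

    def center_px(self) -> tuple[float, float]:
        if self.wound_center is not None:
            return self.wound_center
        return (self.image_shape[0] / 2.0, self.image_shape[1] / 2.0)


# --------------------------------------------------------------------------
# area trajectory
# --------------------------------------------------------------------------

def area_trajectory(params: WoundSimParams, t) -> np.ndarray | float:
    """Noiseless wound area A(t) in μm².

    A(t<0)=0; a half-cosine ramp carries A from π·r0² at t=0 to
    fold·π·r0² at ``t_max_true``; afterwards A decays linearly at
    ``closure_rate_true`` (optionally switching to a shallower slope after
    the area halves), clamped at zero.  Continuous everywhere.
    """
    t_arr = np.asarray(t, dtype=float)
    lo, hi = params.frame_times[0], params.frame_times[-1]
    if np.any(t_arr < lo) or np.any(t_arr > hi):
        raise ValueError(
            f"t outside simulated range [{lo}, {hi}]")

    a0 = params.initial_area
    amax = params.expansion_fold_true * a0
    tm = params.t_max_true
    rate = params.closure_rate_true

    area = np.empty_like(t_arr)
    pre = t_arr < 0
    ramp = (~pre) & (t_arr <= tm)
    decay = t_arr > tm

    area[pre] = 0.0
    # half-cosine ramp, smooth and monotone between a0 and amax
    area[ramp] = a0 + (amax - a0) * 0.5 * (1 - np.cos(np.pi * t_arr[ramp] / tm))

    td = t_arr[decay] - tm
    a_lin = amax - rate * td
    if params.late_rate_factor is not None and rate > 0:
        # slope change after the area halves (exercises the secant estimator)
        t_half = (amax / 2.0) / rate
        late = amax / 2.0 - rate * params.late_rate_factor * (td - t_half)
        a_lin = np.where(td > t_half, late, a_lin)
    area[decay] = np.maximum(a_lin, 0.0)
    return area if np.ndim(t) else float(area)


def _radius_at(params: WoundSimParams, t: float) -> float:
    a = float(area_trajectory(params, t))
    return math.sqrt(a / math.pi) if a > 0 else 0.0


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def radial_intensity(params: WoundSimParams, wound_radius: float, r) -> np.ndarray:
    """Analytic noiseless radial profile I(r) for a given wound radius (μm).

    Composed of logistic steps with scale ``edge_softness``: ~0 inside the
    wound (membrane plug), cortex baseline outside, a ring of amplitude
    ``ring_amplitude`` over [R, R+w], and a halo over [R+w, R+w+h].
    """
    r = np.asarray(r, dtype=float)
    if wound_radius <= 0:
        return np.full_like(r, params.cortex_baseline)
    s = params.edge_softness
    R = wound_radius
    w = params.ring_width_true
    h = params.halo_width
    step_R = expit((r - R) / s)
    step_Rw = expit((r - R - w) / s)
    step_Rwh = expit((r - R - w - h) / s)
    return (params.cortex_baseline * step_R
            + params.ring_amplitude * (step_R - step_Rw)
            + params.halo_amplitude * (step_Rw - step_Rwh))


def render_frame(params: WoundSimParams, wound_radius: float) -> np.ndarray:
    h, w = params.image_shape
    cr, cc = params.center_px()
    rows = (np.arange(h) - cr)[:, None]
    cols = (np.arange(w) - cc)[None, :]
    dist = np.hypot(rows, cols) * params.pixel_size
    return radial_intensity(params, wound_radius, dist)


# --------------------------------------------------------------------------
# ground truth
# --------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Exact per-frame geometry plus the metrics the measurement formulas
    return when applied to the noiseless trajectory."""

    frame_times: np.ndarray
    wound_radius: np.ndarray            # μm per frame
    ring_inner_radius: np.ndarray       # μm per frame (= wound_radius while open)
    ring_outer_radius: np.ndarray       # μm per frame
    implied_area: np.ndarray            # μm² per frame (= π r²)
    implied_expansion_fold: float
    implied_t_max: float
    implied_t_half: float
    implied_contraction_rate: float     # μm²/s
    implied_ring_width: float           # μm, half-max construction at reference time
    implied_ring_mean_intensity: float
    implied_relative_ring_intensity: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame_time_s": self.frame_times,
            "wound_radius_um": self.wound_radius,
            "ring_inner_radius_um": self.ring_inner_radius,
            "ring_outer_radius_um": self.ring_outer_radius,
            "implied_area_um2": self.implied_area,
        })


def _halfmax_crossings(params: WoundSimParams, wound_radius: float) -> tuple[float, float]:
    """Closed-form inner/outer half-maximum radii of the noiseless profile."""
    baseline = params.cortex_baseline
    r_hi = wound_radius + params.ring_width_true + params.halo_width + 10 * params.edge_softness

    def f(r):
        return radial_intensity(params, wound_radius, r)

    grid = np.linspace(0, r_hi, 4000)
    vals = f(grid)
    peak = float(vals.max())
    r_peak = float(grid[int(vals.argmax())])
    half = baseline + (peak - baseline) / 2.0
    g = lambda r: f(r) - half
    r_in = optimize.brentq(g, 1e-9, r_peak)
    r_out = optimize.brentq(g, r_peak, r_hi)
    return float(r_in), float(r_out)


def _annulus_mean(params: WoundSimParams, wound_radius: float,
                  r_in: float, r_out: float) -> float:
    num, _ = integrate.quad(
        lambda r: radial_intensity(params, wound_radius, r) * 2 * math.pi * r,
        r_in, r_out, limit=200)
    return num / (math.pi * (r_out ** 2 - r_in ** 2))


def ground_truth(params: WoundSimParams,
                 ring_reference_time: float = 120.0,
                 t_half_fraction: float = 0.5) -> GroundTruth:
    """Evaluate the measurement formulas on the noiseless trajectory."""
    times = params.frame_times
    areas = area_trajectory(params, times)
    radii = np.sqrt(np.maximum(areas, 0.0) / math.pi)
    inner = radii.copy()
    outer = np.where(radii > 0, radii + params.ring_width_true, 0.0)

    post = times >= 0
    post_t = times[post]
    post_a = areas[post]
    fold = float(post_a.max() / post_a[0])
    i_max = int(np.argmax(post_a))          # earliest max (argmax returns first)
    t_max = float(post_t[i_max])
    target = t_half_fraction * post_a[i_max]
    after = np.nonzero((post_t >= t_max) & (post_a <= target))[0]
    if after.size == 0:
        t_half = math.nan
        rate = math.nan
    else:
        j = int(after[0])
        t_half = float(post_t[j])
        rate = float((post_a[i_max] - post_a[j]) / (t_half - t_max))

    # ring metrics at the frame nearest the reference time, half-max construction
    ref_idx = int(np.argmin(np.abs(times - ring_reference_time)))
    R_ref = radii[ref_idx]
    r_in, r_out = _halfmax_crossings(params, R_ref)
    ring_width = (2 * r_out - 2 * r_in) / 2.0   # (outer feret - inner feret)/2
    ring_mean = _annulus_mean(params, R_ref, r_in, r_out)

    return GroundTruth(
        frame_times=times,
        wound_radius=radii,
        ring_inner_radius=inner,
        ring_outer_radius=outer,
        implied_area=areas,
        implied_expansion_fold=fold,
        implied_t_max=t_max,
        implied_t_half=t_half,
        implied_contraction_rate=rate,
        implied_ring_width=float(ring_width),
        implied_ring_mean_intensity=float(ring_mean),
        implied_relative_ring_intensity=float(ring_mean / params.cortex_baseline),
    )


# --------------------------------------------------------------------------
# stack simulation
# --------------------------------------------------------------------------

def simulate_wound_stack(params: WoundSimParams):
    """Render the full time-lapse stack; returns ``(ImageStack, GroundTruth)``.

    Deterministic for identical params+seed.  Raises :class:`GeometryError`
    when the wound plus ring and halo would not fit inside the frame.
    """
    from .segment import ImageStack  # local import to avoid a cycle

    times = params.frame_times
    areas = area_trajectory(params, times)
    r_max = math.sqrt(float(np.max(areas)) / math.pi)
    margin = params.ring_width_true + params.halo_width + 5 * params.edge_softness
    cr, cc = params.center_px()
    h, w = params.image_shape
    half_extent = min(cr, cc, h - 1 - cr, w - 1 - cc) * params.pixel_size
    if r_max + margin > half_extent:
        raise GeometryError(
            f"wound radius {r_max:.1f} μm + ring/halo margin {margin:.1f} μm "
            f"exceeds frame half-extent {half_extent:.1f} μm")

    frames = np.empty((len(times), h, w), dtype=float)
    for i, a in enumerate(areas):
        radius = math.sqrt(a / math.pi) if a > 0 else 0.0
        frames[i] = render_frame(params, radius)

    rng = np.random.default_rng(params.rng_seed)
    if params.noise_model == "gaussian":
        frames = frames + rng.normal(0.0, params.noise_sigma, frames.shape)
    elif params.noise_model == "poisson":
        frames = rng.poisson(np.maximum(frames, 0) / params.poisson_gain) \
            * params.poisson_gain
    frames = np.clip(frames, 0.0, None)

    stack = ImageStack(frames=frames, frame_times=times,
                       pixel_size=params.pixel_size, channel_label="actin")
    return stack, ground_truth(params)


# --------------------------------------------------------------------------
# expression study simulation
# --------------------------------------------------------------------------

@dataclass
class ExprSimParams:
    """Parameters of a synthetic wounded-vs-unwounded expression study.

    Defaults are the study conditions: ~8000 genes on the array, 4 biological
    replicates, 80 up- and 173 down-regulated genes planted with |log2FC|
    drawn uniformly from [1.0, 1.4] (the magnitude range of the top regulated
    genes), replicate noise σ=0.1, gene sizes log-normal with group means of
    3.7 kb (up), 1.9 kb (down) and 2.5 kb (background), and 1169 TADs
    assigned as contiguous gene blocks.
    """

    n_genes: int = 8000
    n_replicates: int = 4
    n_up: int = 80
    n_down: int = 173
    effect_low: float = 1.0             # min planted |log2FC|
    effect_high: float = 1.4
    noise_sigma: float = 0.1            # SD of replicate log2 ratios about the effect
    gene_size_mean_kb: float = 2.5      # background group mean
    gene_size_mean_up_kb: float = 3.7
    gene_size_mean_down_kb: float = 1.9
    gene_size_sigma_log: float = 0.6
    n_tads: int = 1169
    tad_clustering: bool = False        # concentrate planted genes in few TADs
    tad_cluster_size: int = 50          # genes per TAD when clustering
    # spot-table rule violations (fractions of spots)
    frac_fail_bg3sd: float = 0.02
    frac_fail_low_signal: float = 0.02
    frac_flagged: float = 0.01
    spot_background_mean: float = 100.0
    spot_background_sd: float = 10.0
    spot_signal: float = 1000.0         # foreground excess over background for good spots
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_up + self.n_down > self.n_genes:
            raise ValueError("n_up + n_down must be <= n_genes")
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be > 0")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates")


def _assign_tads(params: ExprSimParams, truth: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Gene→TAD map: contiguous blocks of (genome-ordered) genes, or, with
    ``tad_clustering``, planted genes packed into the fewest TADs of
    ``tad_cluster_size`` genes each (padded with unaffected genes)."""
    n, k = params.n_genes, params.n_tads
    if not params.tad_clustering:
        return (np.arange(n) * k) // n  # block sizes differ by <= 1
    tad = np.empty(n, dtype=int)
    planted = np.nonzero(truth != "unaffected")[0]
    nulls = list(np.nonzero(truth == "unaffected")[0])
    size = params.tad_cluster_size
    n_cluster = max(1, math.ceil(len(planted) / size))
    for i, g in enumerate(planted):
        tad[g] = i // size
    # pad each cluster TAD to its nominal size with unaffected genes
    n_pad = min(len(nulls), n_cluster * size - len(planted))
    pad = [nulls.pop() for _ in range(n_pad)]
    for i, g in enumerate(pad):
        tad[g] = (len(planted) + i) // size
    rest = max(k - n_cluster, 1)
    nulls_arr = np.asarray(nulls, dtype=int)
    tad[nulls_arr] = n_cluster + (np.arange(len(nulls_arr)) * rest) // len(nulls_arr)
    return tad


def simulate_expression_study(params: ExprSimParams):
    """Generate ``(spots, expression)`` tables with truth labels.

    ``expression`` columns: gene_id, rep_1..rep_n (log2 wounded/unwounded
    ratios), gene_size_kb, tad_id, truth.  ``spots`` columns: spot_id,
    fg_ch1/bg_ch1/bg_sd_ch1, same for ch2, qc_flag, fails_* truth columns.
    Seed-deterministic.
    """
    rng = np.random.default_rng(params.rng_seed)
    n = params.n_genes

    truth = np.array(["unaffected"] * n, dtype=object)
    idx = rng.permutation(n)
    up_idx = idx[:params.n_up]
    down_idx = idx[params.n_up:params.n_up + params.n_down]
    truth[up_idx] = "up"
    truth[down_idx] = "down"

    effects = np.zeros(n)
    effects[up_idx] = rng.uniform(params.effect_low, params.effect_high,
                                  params.n_up)
    effects[down_idx] = -rng.uniform(params.effect_low, params.effect_high,
                                     params.n_down)

    reps = effects[:, None] + rng.normal(
        0.0, params.noise_sigma, (n, params.n_replicates))

    # log-normal gene sizes with group-specific means
    sig = params.gene_size_sigma_log
    mean_to_mu = lambda m: math.log(m) - sig ** 2 / 2.0
    mu = np.full(n, mean_to_mu(params.gene_size_mean_kb))
    mu[up_idx] = mean_to_mu(params.gene_size_mean_up_kb)
    mu[down_idx] = mean_to_mu(params.gene_size_mean_down_kb)
    sizes = np.exp(rng.normal(mu, sig))

    tad = _assign_tads(params, truth, rng)

    expr = pd.DataFrame({"gene_id": [f"gene_{i:05d}" for i in range(n)]})
    for j in range(params.n_replicates):
        expr[f"rep_{j + 1}"] = reps[:, j]
    expr["gene_size_kb"] = sizes
    expr["tad_id"] = tad
    expr["truth"] = truth

    spots = _simulate_spots(params, rng)
    return spots, expr


def _simulate_spots(params: ExprSimParams, rng: np.random.Generator) -> pd.DataFrame:
    n = params.n_genes
    bg = params.spot_background_mean
    sd = params.spot_background_sd
    fg_good = bg + params.spot_signal

    fg1 = np.full(n, fg_good) + rng.normal(0, sd, n)
    fg2 = np.full(n, fg_good) + rng.normal(0, sd, n)
    bg1 = np.full(n, bg)
    bg2 = np.full(n, bg)
    sd1 = np.full(n, sd)
    sd2 = np.full(n, sd)
    flag = np.zeros(n, dtype=bool)

    order = rng.permutation(n)
    n1 = int(round(params.frac_fail_bg3sd * n))
    n2 = int(round(params.frac_fail_low_signal * n))
    n3 = int(round(params.frac_flagged * n))
    i1, i2, i3 = order[:n1], order[n1:n1 + n2], order[n1 + n2:n1 + n2 + n3]

    # rule 1 violators: foreground within 3 SD of background in channel 1
    fg1[i1] = bg + 2.0 * sd
    # rule 2 violators: background-subtracted signal < 100 in BOTH channels
    fg1[i2] = bg + 99.0
    fg2[i2] = bg + 99.0
    # rule 3 violators: flagged questionable
    flag[i3] = True

    return pd.DataFrame({
        "spot_id": [f"spot_{i:05d}" for i in range(n)],
        "fg_ch1": fg1, "bg_ch1": bg1, "bg_sd_ch1": sd1,
        "fg_ch2": fg2, "bg_ch2": bg2, "bg_sd_ch2": sd2,
        "qc_flag": flag,
        "fails_bg3sd": np.isin(np.arange(n), i1),
        "fails_low_signal": np.isin(np.arange(n), i2),
        "fails_flag": np.isin(np.arange(n), i3),
    })


__all__ = [
    "WoundSimParams", "ExprSimParams", "GroundTruth", "GeometryError",
    "default_frame_times", "area_trajectory", "radial_intensity",
    "render_frame", "ground_truth", "simulate_wound_stack",
    "simulate_expression_study", "replace",
]
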