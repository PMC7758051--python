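"""Validation experiments: recovery of known truths from synthetic data.

These drive the package's self-checks: simulate studies whose ground truth
is known exactly, run the full measurement pipeline, and report recovery
errors and calibration rates.  All experiments are seed-deterministic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import exprstats, metrics, profiles, simkit


def recovery_frame_times() -> np.ndarray:
    """Acquisition grid truncated at 1560 s — long enough for the slowest
    simulated closure (0.1 μm²/s from a doubled 200 μm² wound) to reach
    half of its maximal area."""
    return np.concatenate([
        [-30.0], np.arange(0.0, 901.0, 30.0), np.arange(960.0, 1561.0, 60.0)])


def parameter_recovery(n_stacks: int = 20, seed: int = 0,
                       noise_frac: float = 0.05) -> pd.DataFrame:
    """Simulate ``n_stacks`` wound movies spanning expansion folds in
    [1, 2], contraction rates in [0.1, 1] μm²/s and ring widths in
    [1, 4] μm at ``noise_frac`` gaussian noise, quantify each, and return
    per-stack truths, estimates and errors."""
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_stacks):
        fold = float(rng.uniform(1.0, 2.0))
        rate = float(rng.uniform(0.1, 1.0))
        width = float(rng.uniform(1.0, 4.0))
        params = simkit.WoundSimParams(
            image_shape=(192, 192),
            pixel_size=0.22,
            frame_times=recovery_frame_times(),
            r0=float(np.sqrt(100.0 / np.pi)),
            expansion_fold_true=fold,
            t_max_true=60.0,
            closure_rate_true=rate,
            ring_width_true=width,
            noise_sigma=noise_frac * 300.0,
            rng_seed=int(rng.integers(2 ** 31)),
        )
        stack, truth = simkit.simulate_wound_stack(params)
        m = metrics.summarize_repair(stack, compute_series=False)
        rows.append({
            "fold_true": truth.implied_expansion_fold,
            "fold_est": m.expansion_fold,
            "rate_true": truth.implied_contraction_rate,
            "rate_est": m.contraction_rate,
            "width_true_um": truth.implied_ring_width,
            "width_est_um": m.ring_width,
            "rel_int_true": truth.implied_relative_ring_intensity,
            "rel_int_est": m.ring_rel_intensity_ref,
        })
    df = pd.DataFrame(rows)
    df["fold_rel_err"] = np.abs(df.fold_est - df.fold_true) / df.fold_true
    df["rate_rel_err"] = np.abs(df.rate_est - df.rate_true) / df.rate_true
    df["width_err_px"] = np.abs(df.width_est_um - df.width_true_um) / 0.22
    df["rel_int_rel_err"] = np.abs(df.rel_int_est - df.rel_int_true) \
        / df.rel_int_true
    return df


def random_connected_mask(rng: np.random.Generator, shape=(40, 40),
                          n_steps: int = 80) -> np.ndarray:
    """Random connected blob (dilated random walk) for geometry checks."""
    from scipy import ndimage
    mask = np.zeros(shape, dtype=bool)
    r, c = shape[0] // 2, shape[1] // 2
    mask[r, c] = True
    for _ in range(n_steps):
        dr, dc = rng.choice([(0, 1), (0, -1), (1, 0), (-1, 0)])
        r = int(np.clip(r + dr, 1, shape[0] - 2))
        c = int(np.clip(c + dc, 1, shape[1] - 2))
        mask[r, c] = True
    return ndimage.binary_dilation(mask)


def feret_agreement(n_masks: int = 100, seed: int = 0) -> float:
    """Max |rotating-calipers − brute-force pairwise| Feret discrepancy
    over random connected masks (should be exactly zero)."""
    from scipy import ndimage
    from scipy.spatial.distance import pdist
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_masks):
        mask = random_connected_mask(rng)
        boundary = mask & ~ndimage.binary_erosion(mask)
        pts = np.argwhere(boundary).astype(float)
        brute = float(pdist(pts).max()) if len(pts) > 1 else 0.0
        worst = max(worst, abs(metrics.feret_diameter(mask) - brute))
    return worst


def ci_coverage(n_positions: int = 2000, width_px: int = 10,
                seed: int = 0, mu: float = 50.0, sigma: float = 5.0) -> float:
    """Empirical coverage of the profile 95% CI on i.i.d. gaussian pixels."""
    rng = np.random.default_rng(seed)
    frame = rng.normal(mu, sigma, (width_px, n_positions))
    res = profiles.line_profile(frame, center=(width_px // 2 - (width_px % 2 == 0), 0),
                                width_px=width_px)
    covered = (res.ci_low <= mu) & (mu <= res.ci_high)
    return float(covered.mean())


def null_false_call_rate(n_sims: int = 200, n_genes: int = 800,
                         noise_sigma: float = 1.0,
                         seed: int = 0) -> tuple[float, float]:
    """Mean per-study false-call proportion of the DE filter under the
    global null (no planted genes), with its Monte-Carlo standard error."""
    rng = np.random.default_rng(seed)
    fdps = []
    for _ in range(n_sims):
        params = simkit.ExprSimParams(
            n_genes=n_genes, n_up=0, n_down=0, noise_sigma=noise_sigma,
            rng_seed=int(rng.integers(2 ** 31)))
        _, expr = simkit.simulate_expression_study(params)
        de = exprstats.de_filter(exprstats.gene_statistics(expr))
        n_called = de.n_total_called
        fdps.append(0.0 if n_called == 0 else 1.0)  # every null call is false
    fdps = np.asarray(fdps)
    return float(fdps.mean()), float(fdps.std(ddof=1) / np.sqrt(n_sims))


def bootstrap_ci_coverage(n_sims: int = 500, n: int = 200,
                          median_kb: float = 2.5, sigma_log: float = 0.6,
                          n_boot: int = 1000, seed: int = 0) -> float:
    """Fraction of simulated log-normal gene-size samples whose bootstrap
    median CI covers the true median."""
    rng = np.random.default_rng(seed)
    mu = np.log(median_kb)
    hits = 0
    for i in range(n_sims):
        x = np.exp(rng.normal(mu, sigma_log, n))
        _, lo, hi = exprstats.bootstrap_median(
            x, n_boot=n_boot, seed=int(rng.integers(2 ** 31)))
        hits += lo <= median_kb <= hi
    return hits / n_sims


__all__ = ["recovery_frame_times", "parameter_recovery", "ci_coverage",
           "null_false_call_rate", "bootstrap_ci_coverage"]
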