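"""Post-wounding expression statistics.

Implements the array-analysis chain for a wounded-vs-unwounded two-colour
study: spot-level quality filtering, per-gene replicate statistics, the
differential-expression significance filter (|log2 ratio| ≥ 0.585, i.e.
±1.5-fold, at 5% FDR with Benjamini–Hochberg adjustment), Fisher's exact
test of regulated-gene independence across topologically associating
domains (TADs), a bootstrap median (1000 resamples) with percentile 95% CI
for gene sizes, and ΔΔCq knockdown efficiency for qPCR validation.

The per-gene statistic here is a plain one-sample t-test on replicate log2
ratios — a deliberately simple stand-in used for synthetic data; measured
studies normally arrive with per-gene moderated statistics already
computed, which the DE filter ingests directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests


# --------------------------------------------------------------------------
# spot filtering
# --------------------------------------------------------------------------

SPOT_RULES = ("bg3sd", "low_signal", "flagged")


def filter_spots(spots: pd.DataFrame,
                 min_signal: float = 100.0,
                 n_sd: float = 3.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove low-quality spots; returns (kept, removal_log).

    A spot is removed if its foreground does not exceed ``n_sd`` background
    SDs above the background in a channel, if the background-subtracted
    signal is below ``min_signal`` in *both* channels, or if it carries a
    QC flag.  The removal log states which rule fired first
    (bg3sd → low_signal → flagged precedence).
    """
    fg1, bg1, sd1 = spots["fg_ch1"], spots["bg_ch1"], spots["bg_sd_ch1"]
    fg2, bg2, sd2 = spots["fg_ch2"], spots["bg_ch2"], spots["bg_sd_ch2"]

    r_bg3sd = (fg1 <= bg1 + n_sd * sd1) | (fg2 <= bg2 + n_sd * sd2)
    r_low = ((fg1 - bg1) < min_signal) & ((fg2 - bg2) < min_signal)
    r_flag = spots["qc_flag"].astype(bool)

    removed = r_bg3sd | r_low | r_flag
    rule = np.select([r_bg3sd, r_low, r_flag],
                     ["bg3sd", "low_signal", "flagged"], default="")
    log = spots.loc[removed, ["spot_id"]].copy() if "spot_id" in spots \
        else pd.DataFrame(index=spots.index[removed])
    log["rule"] = rule[removed]
    kept = spots.loc[~removed].copy()
    return kept, log.reset_index(drop=True)


# --------------------------------------------------------------------------
# per-gene statistics
# --------------------------------------------------------------------------

def gene_statistics(table: pd.DataFrame,
                    rep_cols: list[str] | None = None) -> pd.DataFrame:
    """Mean log2 ratio and two-sided one-sample t-test p-value per gene.

    Zero-variance convention: replicates identical and nonzero → p = 0
    (infinitely strong evidence at face value); identical and zero → p = 1.
    Requires ≥ 2 replicate columns.
    """
    if rep_cols is None:
        rep_cols = [c for c in table.columns if c.startswith("rep_")]
    if len(rep_cols) < 2:
        raise ValueError("need at least 2 replicate columns")
    x = table[rep_cols].to_numpy(dtype=float)
    mean = x.mean(axis=1)
    import warnings
    with warnings.catch_warnings():
        # zero-variance rows are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_1samp(x, 0.0, axis=1)
    p = np.asarray(res.pvalue, dtype=float)
    zero_var = x.std(axis=1, ddof=1) == 0
    p[zero_var & (mean != 0)] = 0.0
    p[zero_var & (mean == 0)] = 1.0
    out = table.copy()
    out["logFC"] = mean
    out["p_value"] = p
    return out


# --------------------------------------------------------------------------
# DE significance filter
# --------------------------------------------------------------------------

@dataclass
class DEResult:
    table: pd.DataFrame             # gene_id, logFC, p, p_adj, call
    n_up: int
    n_down: int

    @property
    def n_total_called(self) -> int:
        return self.n_up + self.n_down


def de_filter(table: pd.DataFrame, fdr: float = 0.05,
              lfc_threshold: float = 0.585,
              logfc_col: str = "logFC",
              p_col: str = "p_value") -> DEResult:
    """Benjamini–Hochberg FDR + fold-change significance filter.

    call = up if adjusted p ≤ fdr and logFC ≥ lfc_threshold; down if
    adjusted p ≤ fdr and logFC ≤ −lfc_threshold; otherwise unaffected.
    The default 0.585 log2 threshold is the ±1.5-fold cut
    (log2 1.5 ≈ 0.585).
    """
    if not (0 < fdr < 1):
        raise ValueError("fdr must lie in (0, 1)")
    p = table[p_col].to_numpy(dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    lfc = table[logfc_col].to_numpy(dtype=float)
    reject, p_adj, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")

    call = np.where(reject & (lfc >= lfc_threshold), "up",
                    np.where(reject & (lfc <= -lfc_threshold), "down",
                             "unaffected"))
    out = table.copy()
    out["p_adj"] = p_adj
    out["call"] = call
    return DEResult(table=out,
                    n_up=int((call == "up").sum()),
                    n_down=int((call == "down").sum()))


# --------------------------------------------------------------------------
# TAD enrichment (Fisher's exact test of independence)
# --------------------------------------------------------------------------

@dataclass
class FisherResult:
    p_value: float
    method: str                     # "exact-2x2" | "monte-carlo"
    mc_se: float | None = None
    table: np.ndarray | None = None
    n_unmapped: int = 0


def _rxc_log_pmf(counts: np.ndarray, tad_totals: np.ndarray, k_total: int) -> np.ndarray:
    """Log multivariate-hypergeometric probability of R×2 tables with the
    observed margins; ``counts``: (..., R) regulated counts per TAD."""
    n_total = int(tad_totals.sum())

    def logC(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    return (logC(tad_totals, counts).sum(axis=-1)
            - logC(n_total, k_total))


def tad_enrichment(calls: pd.Series | np.ndarray,
                   tad_ids: pd.Series | np.ndarray,
                   which: str = "any",
                   n_mc: int = 10000,
                   seed: int = 0) -> FisherResult:
    """Fisher's exact test that regulated genes are distributed
    independently of TAD membership.

    Builds the TAD × {regulated, unaffected} contingency table over genes
    expressed on the array (genes without a TAD are excluded and counted in
    ``n_unmapped``).  ``which`` selects which calls count as regulated:
    'any' (up or down), 'up', or 'down'.  2×2 tables are tested exactly;
    R×2 tables by Monte-Carlo (≥ ``n_mc`` tables drawn conditional on the
    margins, fixed seed), with the MC standard error reported.
    """
    calls = np.asarray(calls, dtype=object)
    tads = pd.Series(tad_ids)
    mapped = tads.notna().to_numpy()
    n_unmapped = int((~mapped).sum())
    calls = calls[mapped]
    tads = tads[mapped].to_numpy()
    if calls.size == 0:
        raise ValueError("empty contingency: no genes mapped to TADs")

    if which == "any":
        reg = calls != "unaffected"
    elif which in ("up", "down"):
        reg = calls == which
    else:
        raise ValueError("which must be 'any', 'up' or 'down'")

    uniq, tad_idx = np.unique(tads, return_inverse=True)
    r = len(uniq)
    tad_totals = np.bincount(tad_idx, minlength=r)
    k_obs = np.bincount(tad_idx[reg], minlength=r)
    k_total = int(reg.sum())
    table = np.column_stack([k_obs, tad_totals - k_obs])

    if k_total == 0 or k_total == len(calls):
        # degenerate column: only one outcome observed
        return FisherResult(p_value=1.0, method="degenerate", table=table,
                            n_unmapped=n_unmapped)

    if r == 2:
        _, p = stats.fisher_exact(table, alternative="two-sided")
        return FisherResult(p_value=float(p), method="exact-2x2",
                            table=table, n_unmapped=n_unmapped)

    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(tad_totals, k_total,
                                            size=n_mc, method="marginals")
    logp_obs = _rxc_log_pmf(k_obs, tad_totals, k_total)
    logp = _rxc_log_pmf(draws, tad_totals, k_total)
    hits = int((logp <= logp_obs + 1e-9).sum())
    p = (1 + hits) / (1 + n_mc)
    se = float(np.sqrt(p * (1 - p) / n_mc))
    return FisherResult(p_value=float(p), method="monte-carlo", mc_se=se,
                        table=table, n_unmapped=n_unmapped)


# --------------------------------------------------------------------------
# gene-size bootstrap
# --------------------------------------------------------------------------

def bootstrap_median(values, n_boot: int = 1000, seed: int = 0,
                     ci: float = 0.95) -> tuple[float, float, float]:
    """Sample median plus percentile bootstrap CI from ``n_boot`` resamples."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to bootstrap")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    meds = np.median(x[idx], axis=1)
    alpha = (1 - ci) / 2
    lo, hi = np.quantile(meds, [alpha, 1 - alpha])
    return float(np.median(x)), float(lo), float(hi)


# --------------------------------------------------------------------------
# ΔΔCq knockdown efficiency
# --------------------------------------------------------------------------

@dataclass
class DdCqResult:
    delta_cq_knockdown: float
    delta_cq_control: float
    delta_delta_cq: float
    relative_expression: float      # 2^-ΔΔCq
    efficiency_pct: float           # (1 - 2^-ΔΔCq) * 100


def delta_delta_cq(cq_table: pd.DataFrame,
                   condition_col: str = "condition",
                   role_col: str = "role",
                   cq_col: str = "cq",
                   knockdown: str = "knockdown",
                   control: str = "control",
                   target: str = "target",
                   reference: str = "reference") -> DdCqResult:
    """Knockdown efficiency by the ΔΔCq method.

    Technical replicates are averaged first; then
    ΔCq = Cq_target − Cq_reference per condition,
    ΔΔCq = ΔCq_knockdown − ΔCq_control, relative expression = 2^−ΔΔCq and
    efficiency % = (1 − 2^−ΔΔCq)·100.
    """
    means = cq_table.groupby([condition_col, role_col])[cq_col].mean()

    def get(cond, role):
        try:
            v = means.loc[(cond, role)]
        except KeyError as e:
            raise ValueError(f"missing Cq for ({cond}, {role})") from e
        if pd.isna(v):
            raise ValueError(f"missing Cq for ({cond}, {role})")
        return float(v)

    d_kd = get(knockdown, target) - get(knockdown, reference)
    d_ctrl = get(control, target) - get(control, reference)
    ddcq = d_kd - d_ctrl
    rel = 2.0 ** (-ddcq)
    return DdCqResult(delta_cq_knockdown=d_kd, delta_cq_control=d_ctrl,
                      delta_delta_cq=ddcq, relative_expression=rel,
                      efficiency_pct=(1.0 - rel) * 100.0)


__all__ = [
    "SPOT_RULES", "DEResult", "FisherResult", "DdCqResult",
    "filter_spots", "gene_statistics", "de_filter", "tad_enrichment",
    "bootstrap_median", "delta_delta_cq",
]
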