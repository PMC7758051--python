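"""Pipeline configuration, runners, format plumbing and the CLI.

Everything is driven by :class:`PipelineConfig`; each runner logs one
structured line per stage, echoes the configuration into every CSV it
writes as ``# key: value`` provenance comment lines, and keeps partial
outputs (plus an ``error_manifest.json`` naming the failed stage) when a
stage fails.  All randomness flows from the config seeds.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import exprstats, metrics, profiles, segment, simkit

log = logging.getLogger("woundrepair")


@dataclass
class PipelineConfig:
    """Defaults mirror the quantification constants of the study design."""

    pixel_size: float = 0.22            # μm/px
    ring_reference_time: float = 120.0  # s post-wounding
    t_half_fraction: float = 0.5        # in [0.35, 0.5]
    profile_width_px: int = 10
    kymo_length_um: float = 94.9
    kymo_width_um: float = 5.3
    fdr: float = 0.05
    lfc_threshold: float = 0.585        # log2(1.5)
    n_boot: int = 1000
    sim_seed: int = 0
    stats_seed: int = 0
    closure_threshold_um2: float = 1.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def provenance_lines(self) -> list[str]:
        return [f"# {k}: {v}" for k, v in sorted(self.to_dict().items())]


def write_csv(df: pd.DataFrame, path: str | Path,
              config: PipelineConfig | None = None) -> Path:
    """CSV with provenance comment header."""
    path = Path(path)
    with open(path, "w") as fh:
        if config is not None:
            fh.write("\n".join(config.provenance_lines()) + "\n")
        df.to_csv(fh, index=False)
    return path


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# --------------------------------------------------------------------------
# runners
# --------------------------------------------------------------------------

def run_simulate(config: PipelineConfig, outdir: str | Path,
                 params: simkit.WoundSimParams | None = None) -> dict[str, Path]:
    """Simulate a wound stack, write TIFF + sidecar + ground-truth CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if params is None:
        params = simkit.WoundSimParams(pixel_size=config.pixel_size,
                                       rng_seed=config.sim_seed)
    log.info("simulate: shape=%s frames=%d seed=%d",
             params.image_shape, len(params.frame_times), params.rng_seed)
    stack, truth = simkit.simulate_wound_stack(params)
    stack_path = segment.write_stack(
        stack, outdir / "stack.tif",
        extra_meta={"seed": params.rng_seed,
                    "params": {k: (list(v) if isinstance(v, (tuple, np.ndarray)) else v)
                               for k, v in dataclasses.asdict(params).items()
                               if k != "frame_times"}})
    truth_path = write_csv(truth.to_frame(), outdir / "ground_truth.csv", config)
    scalars = {
        "implied_expansion_fold": truth.implied_expansion_fold,
        "implied_t_max_s": truth.implied_t_max,
        "implied_t_half_s": truth.implied_t_half,
        "implied_contraction_rate_um2_per_s": truth.implied_contraction_rate,
        "implied_ring_width_um": truth.implied_ring_width,
        "implied_ring_mean_intensity": truth.implied_ring_mean_intensity,
        "implied_relative_ring_intensity": truth.implied_relative_ring_intensity,
    }
    (outdir / "ground_truth_metrics.json").write_text(json.dumps(scalars, indent=2))
    log.info("simulate: wrote %s (%d frames)", stack_path, len(stack))
    return {"stack": stack_path, "ground_truth": truth_path}


def run_quantify(config: PipelineConfig, stack_path: str | Path,
                 outdir: str | Path) -> dict[str, Path]:
    """Full imaging pipeline: trace + repair metrics + profiles + kymograph.

    Partial outputs are retained on stage failure, with an error manifest
    naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stack = segment.read_stack(stack_path)
    log.info("quantify: %s frames=%d px=%.3g μm", stack_path, len(stack),
             stack.pixel_size)
    try:
        trace = segment.trace_wound_areas(
            stack, closure_threshold_um2=config.closure_threshold_um2)
        outputs["trace"] = write_csv(trace.to_frame(), outdir / "trace.csv", config)
        log.info("quantify: traced %d frames, peak area %.1f μm²",
                 len(trace.areas), float(np.max(trace.areas)))

        rm = metrics.summarize_repair(
            stack, ring_reference_time=config.ring_reference_time,
            t_half_fraction=config.t_half_fraction, trace=trace)
        row = pd.DataFrame([rm.to_row(stack_id=Path(stack_path).stem)])
        outputs["metrics"] = write_csv(row, outdir / "repair_metrics.csv", config)
        series = pd.DataFrame({
            "frame_time_s": rm.relative_intensity_times,
            "relative_ring_intensity": rm.relative_intensity_series,
        })
        outputs["ring_series"] = write_csv(
            series, outdir / "relative_ring_intensity.csv", config)
        log.info("quantify: fold=%.3f rate=%.3f μm²/s width=%.2f μm",
                 rm.expansion_fold, rm.contraction_rate, rm.ring_width)

        prof = profiles.dynamic_profile(stack, width_px=config.profile_width_px)
        frames = []
        for p in prof:
            df = profiles.profile_to_frame(p)
            df.insert(0, "frame_time_s", p.frame_time)
            frames.append(df)
        outputs["profiles"] = write_csv(
            pd.concat(frames, ignore_index=True), outdir / "profiles.csv", config)

        h, w = stack.frames.shape[1:]
        length = min(config.kymo_length_um, (w - 2) * stack.pixel_size)
        width = min(config.kymo_width_um, (h - 2) * stack.pixel_size)
        if (length, width) != (config.kymo_length_um, config.kymo_width_um):
            log.info("quantify: kymograph ROI shrunk to %.1f x %.1f μm to fit frame",
                     length, width)
        kym = profiles.kymograph(stack, length_um=length, width_um=width)
        kdf = pd.DataFrame(kym.data, index=kym.positions_um,
                           columns=kym.frame_times)
        kdf.index.name = "position_um"
        kpath = outdir / "kymograph.csv"
        with open(kpath, "w") as fh:
            fh.write("\n".join(config.provenance_lines()) + "\n")
            kdf.to_csv(fh)
        outputs["kymograph"] = kpath
    except metrics.StageError as e:
        _write_manifest(outdir, e.stage, str(e))
        raise
    except Exception as e:  # noqa: BLE001 - stage unknown, still manifest it
        _write_manifest(outdir, "unknown", str(e))
        raise
    return outputs


def _write_manifest(outdir: Path, stage: str, message: str) -> None:
    (outdir / "error_manifest.json").write_text(
        json.dumps({"failed_stage": stage, "error": message}, indent=2))
    log.error("stage %s failed: %s", stage, message)


def run_expression(config: PipelineConfig, outdir: str | Path,
                   spots: pd.DataFrame | None = None,
                   expr: pd.DataFrame | None = None,
                   params: simkit.ExprSimParams | None = None) -> dict:
    """Spot filter → gene statistics → DE filter → TAD test → gene-size report.

    With no input tables, simulates the default synthetic study.  The
    report reconciles row counts through every filter (kept + removed =
    input).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if spots is None or expr is None:
        if params is None:
            params = simkit.ExprSimParams(rng_seed=config.sim_seed)
        spots, expr = simkit.simulate_expression_study(params)
        log.info("expression: simulated %d genes x %d replicates",
                 params.n_genes, params.n_replicates)

    kept, removed = exprstats.filter_spots(spots)
    assert len(kept) + len(removed) == len(spots), "spot filter lost rows"
    log.info("expression: spot filter kept %d / removed %d of %d",
             len(kept), len(removed), len(spots))

    stats_tab = exprstats.gene_statistics(expr)
    de = exprstats.de_filter(stats_tab, fdr=config.fdr,
                             lfc_threshold=config.lfc_threshold)
    log.info("expression: %d up / %d down of %d genes",
             de.n_up, de.n_down, len(de.table))

    fisher = exprstats.tad_enrichment(de.table["call"], de.table["tad_id"],
                                      seed=config.stats_seed)

    sizes = {}
    for group in ("up", "down", "unaffected"):
        vals = de.table.loc[de.table["call"] == group, "gene_size_kb"]
        if len(vals) >= 2:
            med, lo, hi = exprstats.bootstrap_median(
                vals, n_boot=config.n_boot, seed=config.stats_seed)
            sizes[group] = {"n": int(len(vals)), "mean_kb": float(vals.mean()),
                            "median_kb": med, "ci_low_kb": lo, "ci_high_kb": hi}

    out_cols = ["gene_id", "logFC", "p_value", "p_adj", "call"]
    write_csv(de.table[out_cols], outdir / "de_result.csv", config)
    write_csv(removed, outdir / "spot_removal_log.csv", config)
    report = {
        "n_spots_in": int(len(spots)),
        "n_spots_kept": int(len(kept)),
        "n_spots_removed": int(len(removed)),
        "removal_by_rule": removed["rule"].value_counts().to_dict()
        if len(removed) else {},
        "n_genes": int(len(de.table)),
        "n_up": de.n_up,
        "n_down": de.n_down,
        "n_total_called": de.n_total_called,
        "tad_fisher_p": fisher.p_value,
        "tad_fisher_method": fisher.method,
        "tad_fisher_mc_se": fisher.mc_se,
        "gene_size_kb": sizes,
    }
    (outdir / "expression_report.json").write_text(json.dumps(report, indent=2))
    return report


# --------------------------------------------------------------------------
# CLI
# --------------------------------------------------------------------------

def _build_cli():
    import click

    def _cfg(config_path, **overrides):
        cfg = PipelineConfig.from_yaml(config_path) if config_path \
            else PipelineConfig()
        for k, v in overrides.items():
            if v is not None:
                setattr(cfg, k, v)
        return cfg

    @click.group()
    @click.option("-v", "--verbose", is_flag=True)
    def cli(verbose):
        """Wound-repair quantification pipeline."""
        logging.basicConfig(
            level=logging.INFO if verbose else logging.WARNING,
            format="%(name)s %(levelname)s %(message)s")

    common = [
        click.option("--config", "config_path", type=click.Path(exists=True),
                     default=None, help="YAML config overriding the defaults"),
        click.option("--out", "outdir", type=click.Path(), required=True),
    ]

    def add_common(f):
        for opt in reversed(common):
            f = opt(f)
        return f

    @cli.command()
    @add_common
    @click.option("--seed", type=int, default=None)
    def simulate(config_path, outdir, seed):
        """Simulate a wound-repair stack with ground truth."""
        cfg = _cfg(config_path, sim_seed=seed)
        run_simulate(cfg, outdir)

    @cli.command()
    @add_common
    @click.argument("stack", type=click.Path(exists=True))
    def quantify(config_path, outdir, stack):
        """Quantify a stack: trace, repair metrics, profiles, kymograph."""
        run_quantify(_cfg(config_path), stack, outdir)

    @cli.command()
    @add_common
    @click.argument("stack", type=click.Path(exists=True))
    @click.option("--width-px", type=int, default=None)
    def profile(config_path, outdir, stack, width_px):
        """Dynamic line profiles only."""
        cfg = _cfg(config_path, profile_width_px=width_px)
        st = segment.read_stack(stack)
        prof = profiles.dynamic_profile(st, width_px=cfg.profile_width_px)
        frames = []
        for p in prof:
            df = profiles.profile_to_frame(p)
            df.insert(0, "frame_time_s", p.frame_time)
            frames.append(df)
        Path(outdir).mkdir(parents=True, exist_ok=True)
        write_csv(pd.concat(frames, ignore_index=True),
                  Path(outdir) / "profiles.csv", cfg)

    @cli.command()
    @add_common
    @click.argument("stack", type=click.Path(exists=True))
    def kymo(config_path, outdir, stack):
        """Kymograph only."""
        cfg = _cfg(config_path)
        st = segment.read_stack(stack)
        kym = profiles.kymograph(st, length_um=cfg.kymo_length_um,
                                 width_um=cfg.kymo_width_um)
        Path(outdir).mkdir(parents=True, exist_ok=True)
        kdf = pd.DataFrame(kym.data, index=kym.positions_um,
                           columns=kym.frame_times)
        kdf.index.name = "position_um"
        kdf.to_csv(Path(outdir) / "kymograph.csv")

    @cli.command()
    @add_common
    @click.option("--spots", type=click.Path(exists=True), default=None)
    @click.option("--expr", "expr_path", type=click.Path(exists=True), default=None)
    @click.option("--seed", type=int, default=None)
    def expr(config_path, outdir, spots, expr_path, seed):
        """Expression statistics (synthetic study if no tables given)."""
        cfg = _cfg(config_path, sim_seed=seed)
        spots_df = read_csv(spots) if spots else None
        expr_df = read_csv(expr_path) if expr_path else None
        run_expression(cfg, outdir, spots=spots_df, expr=expr_df)

    @cli.command(name="all")
    @add_common
    @click.option("--seed", type=int, default=None)
    def run_all(config_path, outdir, seed):
        """simulate → quantify → expression, one output tree."""
        cfg = _cfg(config_path, sim_seed=seed)
        outdir = Path(outdir)
        paths = run_simulate(cfg, outdir / "sim")
        run_quantify(cfg, paths["stack"], outdir / "quant")
        run_expression(cfg, outdir / "expr")

    return cli


def main():
    _build_cli()(prog_name="woundrepair")


__all__ = ["PipelineConfig", "write_csv", "read_csv", "run_simulate",
           "run_quantify", "run_expression", "main"]
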