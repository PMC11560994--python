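"""End-to-end analysis pipeline: read -> means -> ANOVA -> AMMI -> stability -> biplots.

The pipeline is a pure function of its configuration and input bytes:
identical inputs produce identical outputs, including the JSON summary.
Each stage logs its parameters and headline numbers through the standard
``logging`` machinery.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .ammi import export_fit, fit_ammi, gollob_test
from .anova import AnovaTable, partition_means, partition_rcbd
from .biplot import ammi1_coords, ammi2_coords, per_environment_selections
from .datasets import load_maize_trial
from .exceptions import AmmistabError, DegenerateFitError
from .stability import stability_from_fit
from .trial import cell_means, read_means_wide, read_trial_long

log = logging.getLogger("ammistab.pipeline")


@dataclass
class PipelineConfig:
    """Run configuration; every field maps to a CLI flag."""

    input: str = "fixture"  # long/wide CSV path, or the packaged maize trial
    input_format: str = "auto"  # "long", "wide" or "auto" (by header)
    replicate_count: int = 1  # used for wide input only
    n_axes: int | str = "auto"
    error_ms: float | None = None
    error_df: int | None = None
    block_ms: float | None = None
    block_df: int | None = None
    alpha_level: float = 0.05
    top_k: int = 4
    orient: str = "max_env"
    column_map: dict | None = None
    out_dir: str = "ammistab_out"
    write_plots: bool = False
    seed: int | None = None  # recorded in the summary; the fit itself is deterministic

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """Load YAML or JSON config; keyword overrides win."""
        import yaml

        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        payload.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**payload)


@dataclass
class PipelineResult:
    summary: dict
    report: str
    anova: AnovaTable
    out_dir: Path


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except AmmistabError as exc:
                raise AmmistabError(
                    f"stage {name!r} failed: {exc} "
                    f"(check the input table and the {name} options)"
                ) from exc
        return wrapped
    return deco


@_stage("input")
def _load_means(cfg: PipelineConfig):
    if cfg.input == "fixture":
        log.info("loading packaged maize trial (69 genotypes x 5 environments, r=3)")
        return load_maize_trial().means, None
    path = Path(cfg.input)
    fmt = cfg.input_format
    if fmt == "auto":
        import csv

        with open(path, encoding="utf-8") as fh:
            header = next(csv.reader(fh))
        mapped = set((cfg.column_map or {}).values()) | {"genotype", "environment",
                                                         "block", "yield"}
        fmt = "long" if len(set(header) & mapped) >= 3 else "wide"
    if fmt == "long":
        log.info("reading long-format plot records from %s", path)
        trial = read_trial_long(path, column_map=cfg.column_map)
        return cell_means(trial), trial
    log.info("reading wide cell-mean table from %s (r=%d)", path, cfg.replicate_count)
    return read_means_wide(path, replicate_count=cfg.replicate_count), None


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the full analysis and write the report bundle to ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    means, trial = _load_means(cfg)
    means.to_wide_csv(out / "cell_means.csv", include_mean=True)

    if trial is not None and means.replicate_count >= 2:
        anova = partition_rcbd(trial)
        error_ms = float(anova["error"]["ms"])
        error_df = int(anova["error"]["df"])
        block_ms = float(anova["blocks_within_environments"]["ms"])
    else:
        anova = partition_means(
            means, error_ms=cfg.error_ms, error_df=cfg.error_df,
            block_ms=cfg.block_ms, block_df=cfg.block_df,
        )
        error_ms, error_df = cfg.error_ms, cfg.error_df
        block_ms = cfg.block_ms
    if error_ms is not None and error_ms <= 0:
        log.warning("error MS is zero (noise-free data); F-tests disabled")
        error_ms = error_df = None
    log.info("ANOVA: SS_G=%.1f SS_E=%.1f SS_GxE=%.1f",
             anova["genotypes"]["ss"], anova["environments"]["ss"], anova["gxe"]["ss"])
    anova.to_csv(out / "anova.csv")

    fit = fit_ammi(
        means, n_axes=cfg.n_axes, error_ms=error_ms, error_df=error_df,
        alpha_level=cfg.alpha_level, orient=cfg.orient,
    )
    log.info("AMMI: %d axes available, %d retained; explained%%=%s",
             fit.n_axes_available, fit.n_axes,
             np.round(fit.explained_pct, 2).tolist())
    export_fit(fit, out)

    gollob = None
    if error_ms is not None and error_df is not None:
        gollob = gollob_test(fit, alpha_level=cfg.alpha_level)
        gollob.table.to_csv(out / "gollob.csv", index_label="axis")

    stability_note = None
    stab = None
    try:
        stab = stability_from_fit(fit)
        stab.to_csv(out / "stability.csv")
    except DegenerateFitError as exc:
        stability_note = str(exc)
        log.warning("stability skipped: %s", exc)

    coords1 = ammi1_coords(fit)
    coords1.to_csv(out / "ammi1_coords.csv")
    if fit.n_axes_available >= 2:
        coords2 = ammi2_coords(fit)
        coords2.to_csv(out / "ammi2_coords.csv")
    sel_axes = fit.n_axes
    selections = per_environment_selections(
        fit, n_axes=sel_axes, top_k=min(cfg.top_k, len(fit.genotypes))
    )
    selections.to_csv(out / "selections.csv", index=False)

    if cfg.write_plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        from .biplot import plot_biplot

        ax = plot_biplot(coords1)
        ax.figure.savefig(out / "ammi1_biplot.svg")
        plt.close(ax.figure)
        if fit.n_axes_available >= 2:
            ax = plot_biplot(coords2)
            ax.figure.savefig(out / "ammi2_biplot.svg")
            plt.close(ax.figure)

    summary = {
        "version": __version__,
        "config": {k: v for k, v in dataclasses.asdict(cfg).items()},
        "n_genotypes": len(fit.genotypes),
        "n_environments": len(fit.environments),
        "replicate_count": means.replicate_count,
        "grand_mean": round(fit.mu, 6),
        "anova": {
            src: {k: (None if v != v else round(float(v), 6))
                  for k, v in row.items()}
            for src, row in anova.table.iterrows()
        },
        "singular_values": np.round(fit.singular_values, 6).tolist(),
        "axis_ss_plot_basis": np.round(fit.axis_ss, 6).tolist(),
        "explained_pct": np.round(fit.explained_pct, 6).tolist(),
        "n_axes_retained": fit.n_axes,
        "gollob_recommended_n": gollob.recommended_n if gollob else None,
        "stability_skipped": stability_note,
        "best_gsi": (
            None if stab is None
            else {
                "genotype": str(stab.sorted("gsi").index[0]),
                "gsi": int(stab.sorted("gsi")["gsi"].iloc[0]),
            }
        ),
        "selections": {
            env: grp.sort_values("rank")["genotype"].tolist()
            for env, grp in selections.groupby("environment", sort=False)
        },
    }
    report = _format_report(anova, fit, gollob, stab, stability_note, selections)
    (out / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    (out / "report.txt").write_text(report, encoding="utf-8")
    log.info("report bundle written to %s", out)
    return PipelineResult(summary=summary, report=report, anova=anova, out_dir=out)


def _format_report(anova, fit, gollob, stab, stability_note, selections) -> str:
    lines = ["AMMI multi-environment trial analysis", "=" * 38, ""]
    lines += ["Analysis of variance (plot basis)", str(anova), ""]
    lines += [
        f"Grand mean: {fit.mu:.2f} t/ha",
        f"Interaction axes: {fit.n_axes_available} available, {fit.n_axes} retained",
        "Per-axis interaction decomposition:",
        fit.axis_table().to_string(float_format=lambda v: f"{v:.4g}"),
        "",
    ]
    if gollob is not None:
        lines += [f"Gollob-recommended axes: {gollob.recommended_n}", ""]
    if stab is not None:
        lines += [
            f"ASV weight (SS_IPCA1/SS_IPCA2): {stab.weight:.4f}",
            "Best genotypes by selection index (yield rank + ASV rank):",
            stab.best(5).to_string(float_format=lambda v: f"{v:.3f}"),
            "",
        ]
    else:
        lines += [f"Stability: skipped ({stability_note})", ""]
    lines += ["AMMI selections per environment (fitted-yield order):"]
    for env, grp in selections.groupby("environment", sort=False):
        picks = ", ".join(grp.sort_values("rank")["genotype"])
        lines.append(f"  {env}: {picks}")
    lines.append("")
    return "\n".join(lines)
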