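"""Biplot coordinates, AMMI fitted values and per-environment selections.

Two biplots are standard in multi-environment trial reports.  The AMMI1
biplot plots mean yield (x) against the first interaction axis (y) for
genotypes and environments jointly, with a vertical reference at the
grand mean; points near y = 0 behave additively.  The AMMI2 biplot plots
the first two interaction axes against each other; the four quadrants
group genotypes (and environments) by the sign pattern of their
interaction, i.e. by specific adaptation.

Fitted values truncate the multiplicative sum after N axes,

    yhat_ge = mu + alpha_g + beta_e + sum_{n<=N} IPCA_n(g) * IPCA_n(e),

(the sqrt-scaled score product equals d_n u_gn v_en).  Sorting fitted
values within an environment gives the AMMI selections — the genotypes
the model predicts to win there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ammi import AmmiFit


@dataclass
class BiplotCoords:
    """Joint genotype/environment coordinates for one biplot kind."""

    kind: str  # "AMMI1" or "AMMI2"
    points: pd.DataFrame  # label, role, x, y [, quadrant]
    references: dict  # reference lines, e.g. {"grand_mean": mu}

    def to_csv(self, path) -> None:
        self.points.to_csv(path, index=False)


def ammi1_coords(fit: AmmiFit) -> BiplotCoords:
    """Mean yield vs IPCA1 for genotypes and environments."""
    if fit.genotype_scores.shape[1] < 1:
        raise ValueError("AMMI1 biplot needs at least one interaction axis")
    gpts = pd.DataFrame(
        {
            "label": fit.genotypes,
            "role": "genotype",
            "x": (fit.mu + fit.alpha).to_numpy(),
            "y": fit.genotype_scores["IPCA1"].to_numpy(),
        }
    )
    epts = pd.DataFrame(
        {
            "label": fit.environments,
            "role": "environment",
            "x": (fit.mu + fit.beta).to_numpy(),
            "y": fit.environment_scores["IPCA1"].to_numpy(),
        }
    )
    return BiplotCoords(
        kind="AMMI1",
        points=pd.concat([gpts, epts], ignore_index=True),
        references={"grand_mean": fit.mu},
    )


def _quadrant(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    # a coordinate of exactly 0 counts as positive (deterministic rule)
    out = np.where(
        x >= 0, np.where(y >= 0, "Q1", "Q4"), np.where(y >= 0, "Q2", "Q3")
    )
    return out


def ammi2_coords(fit: AmmiFit) -> BiplotCoords:
    """IPCA1 vs IPCA2 with quadrant (sector) labels."""
    if fit.genotype_scores.shape[1] < 2:
        raise ValueError("AMMI2 biplot needs at least two interaction axes")
    frames = []
    for role, scores in (
        ("genotype", fit.genotype_scores),
        ("environment", fit.environment_scores),
    ):
        x = scores["IPCA1"].to_numpy()
        y = scores["IPCA2"].to_numpy()
        frames.append(
            pd.DataFrame(
                {"label": scores.index, "role": role, "x": x, "y": y,
                 "quadrant": _quadrant(x, y)}
            )
        )
    return BiplotCoords(
        kind="AMMI2",
        points=pd.concat(frames, ignore_index=True),
        references={"origin": (0.0, 0.0)},
    )


def fitted_matrix(fit: AmmiFit, n_axes: int | None = None) -> pd.DataFrame:
    """AMMI-estimated cell means using the first ``n_axes`` terms.

    ``n_axes=None`` uses the fit's retained count; with all axes the
    original cell means are reproduced exactly.
    """
    n = fit.n_axes if n_axes is None else int(n_axes)
    if not 0 <= n <= fit.genotype_scores.shape[1]:
        raise ValueError(
            f"n_axes must be in 0..{fit.genotype_scores.shape[1]}, got {n}"
        )
    additive = (
        fit.mu
        + fit.alpha.to_numpy()[:, None]
        + fit.beta.to_numpy()[None, :]
    )
    inter = fit.genotype_scores.iloc[:, :n].to_numpy() @ (
        fit.environment_scores.iloc[:, :n].to_numpy().T
    )
    return pd.DataFrame(
        additive + inter, index=fit.genotype_scores.index,
        columns=fit.environment_scores.index,
    )


def per_environment_selections(
    fit: AmmiFit, n_axes: int | None = None, top_k: int = 4
) -> pd.DataFrame:
    """Top-k genotypes per environment by AMMI fitted yield.

    Returns a long DataFrame (environment, rank, genotype, fitted_yield)
    with rank 1 the predicted winner.  ``n_axes=None`` uses the fit's
    retained axis count.
    """
    if top_k > len(fit.genotypes):
        raise ValueError("top_k cannot exceed the number of genotypes")
    fitted = fitted_matrix(fit, n_axes)
    rows = []
    for env in fitted.columns:
        # stable mergesort keeps input genotype order on exact ties
        order = fitted[env].sort_values(ascending=False, kind="stable")
        for rank, (geno, value) in enumerate(order.head(top_k).items(), start=1):
            rows.append((env, rank, geno, value))
    return pd.DataFrame(rows, columns=["environment", "rank", "genotype", "fitted_yield"])


def selection_scan(
    fit: AmmiFit, top_k: int = 4, axes: range | None = None
) -> dict[int, pd.DataFrame]:
    """Per-environment selections for a range of retained-axis counts.

    Useful when the axis count behind a published selection list is
    unknown: scan and compare.
    """
    if axes is None:
        axes = range(0, fit.genotype_scores.shape[1] + 1)
    return {n: per_environment_selections(fit, n_axes=n, top_k=top_k) for n in axes}


def plot_biplot(coords: BiplotCoords, ax=None, annotate: bool = True):
    """Render a biplot with matplotlib (optional; data contract is the CSV)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 6))
    for role, marker, color in (("genotype", "o", "tab:blue"),
                                ("environment", "^", "tab:red")):
        sub = coords.points[coords.points["role"] == role]
        ax.scatter(sub["x"], sub["y"], marker=marker, c=color, s=25, label=role)
        if annotate:
            for _, row in sub.iterrows():
                ax.annotate(str(row["label"]), (row["x"], row["y"]), fontsize=6)
    if coords.kind == "AMMI1":
        ax.axvline(coords.references["grand_mean"], color="grey", lw=0.8)
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_xlabel("mean yield (t/ha)")
        ax.set_ylabel("IPCA1")
    else:
        ax.axvline(0.0, color="grey", lw=0.8)
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_xlabel("IPCA1")
        ax.set_ylabel("IPCA2")
    ax.legend(frameon=False)
    ax.set_title(f"{coords.kind} biplot")
    return ax
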