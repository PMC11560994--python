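"""Stratified two-way ANOVA for RCBD multi-environment trials.

The balanced fixed-effects partition for yield ``y[g,e,k]`` (genotype g,
environment e, block k nested in e) splits the total plot-basis sum of
squares into environments, blocks-within-environments, genotypes,
genotype-by-environment interaction (GEI), and plot error:

    SS_E   = G*r * sum_e (ybar_e - ybar)^2
    SS_B(E)= G   * sum_{e,k} (ybar_ek - ybar_e)^2
    SS_G   = E*r * sum_g (ybar_g - ybar)^2
    SS_GxE = r   * sum_{g,e} (ybar_ge - ybar_g - ybar_e + ybar)^2
    SS_err = SS_total - all of the above

F-tests follow standard RCBD practice for a multi-location trial:
genotypes and GEI are tested against the plot-error mean square, while
environments are tested against the blocks-within-environments mean
square (locations are replicated by blocks, not plots).

Explained % is SS / SS_total x 100, total including blocks and error.
When only cell means are available (:func:`partition_means`), blocks and
error cannot be recovered; an externally supplied error (and optionally
block) mean square lets the F-tests be reproduced, and explained % is
relative to the sum of the strata present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DesignError
from .trial import CellMeansMatrix, TrialData, cell_means

_COLS = ["df", "ss", "ms", "f", "p", "explained_pct"]


@dataclass
class AnovaTable:
    """ANOVA strata with plot-basis SS, mean squares, F, p and explained %."""

    table: pd.DataFrame  # index: stratum label; columns: _COLS

    def __post_init__(self):
        self.table = self.table.reindex(columns=_COLS)

    def __getitem__(self, stratum: str) -> pd.Series:
        return self.table.loc[stratum]

    @property
    def total_ss(self) -> float:
        return float(self.table["ss"].sum())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="source")

    def __str__(self) -> str:
        """Pretty text in the style of a published trial ANOVA table."""
        lines = [
            f"{'Source of variation':<28}{'d.f.':>6}{'SS':>10}{'MS':>9}"
            f"{'F':>12}{'Expl.%':>8}"
        ]
        for name, row in self.table.iterrows():
            fstat = "" if pd.isna(row["f"]) else f"{row['f']:.2f}"
            stars = "***" if (not pd.isna(row["p"]) and row["p"] < 0.001) else ""
            expl = "" if pd.isna(row["explained_pct"]) else f"{row['explained_pct']:.2f}"
            lines.append(
                f"{name:<28}{int(row['df']):>6}{row['ss']:>10.1f}{row['ms']:>9.2f}"
                f"{fstat + stars:>12}{expl:>8}"
            )
        return "\n".join(lines)


def _f_test(ms: float, denom_ms: float, df: int, denom_df: int) -> tuple[float, float]:
    if denom_ms == 0:  # degenerate (e.g. constant data): F undefined
        return np.nan, np.nan
    f = ms / denom_ms
    return f, float(stats.f.sf(f, df, denom_df))


def partition_rcbd(data: TrialData) -> AnovaTable:
    """Full stratified ANOVA from plot records of a balanced RCBD trial.

    Requires a complete, balanced trial with r >= 2 replicates (with
    r = 1 there is no plot-error stratum; use :func:`partition_means`).
    """
    means = cell_means(data)  # also validates completeness/balance
    r = means.replicate_count
    if r < 2:
        raise DesignError(
            "one replicate leaves no error stratum; partition cell means "
            "with partition_means() instead"
        )
    G, E = means.shape
    y = data.records["yield"].to_numpy()
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    gmeans = means.genotype_means().to_numpy()
    emeans = means.environment_means().to_numpy()
    cellm = means.values.to_numpy()
    # block (within environment) means over genotypes
    ebk = data.records.groupby(["environment", "block"], sort=False)["yield"].mean()
    env_of_block = ebk.index.get_level_values(0)
    emean_of_block = means.environment_means().reindex(env_of_block).to_numpy()

    ss_e = G * r * float(((emeans - grand) ** 2).sum())
    ss_blocks = G * float(((ebk.to_numpy() - emean_of_block) ** 2).sum())
    ss_g = E * r * float(((gmeans - grand) ** 2).sum())
    centered = cellm - gmeans[:, None] - emeans[None, :] + grand
    ss_ge = r * float((centered**2).sum())
    ss_err = ss_total - ss_e - ss_blocks - ss_g - ss_ge

    df_e, df_b, df_g = E - 1, E * (r - 1), G - 1
    df_ge, df_err = (G - 1) * (E - 1), E * (r - 1) * (G - 1)
    ms = {
        "environments": ss_e / df_e,
        "blocks_within_environments": ss_blocks / df_b,
        "genotypes": ss_g / df_g,
        "gxe": ss_ge / df_ge,
        "error": ss_err / df_err,
    }
    if ss_total == 0:  # constant data: percentages undefined
        ss_total = np.nan
    f_e, p_e = _f_test(ms["environments"], ms["blocks_within_environments"], df_e, df_b)
    f_g, p_g = _f_test(ms["genotypes"], ms["error"], df_g, df_err)
    f_ge, p_ge = _f_test(ms["gxe"], ms["error"], df_ge, df_err)

    rows = {
        "environments": (df_e, ss_e, ms["environments"], f_e, p_e, 100 * ss_e / ss_total),
        "blocks_within_environments": (
            df_b, ss_blocks, ms["blocks_within_environments"], np.nan, np.nan,
            100 * ss_blocks / ss_total),
        "genotypes": (df_g, ss_g, ms["genotypes"], f_g, p_g, 100 * ss_g / ss_total),
        "gxe": (df_ge, ss_ge, ms["gxe"], f_ge, p_ge, 100 * ss_ge / ss_total),
        "error": (df_err, ss_err, ms["error"], np.nan, np.nan, 100 * ss_err / ss_total),
    }
    return AnovaTable(pd.DataFrame.from_dict(rows, orient="index", columns=_COLS))


def partition_means(
    means: CellMeansMatrix,
    error_ms: float | None = None,
    error_df: int | None = None,
    block_ms: float | None = None,
    block_df: int | None = None,
) -> AnovaTable:
    """G / E / GxE strata from a cell-mean table alone (plot basis, x r).

    The blocks and error strata are not recoverable from means; pass
    ``error_ms``/``error_df`` (e.g. from a published ANOVA) to obtain F
    statistics, and optionally ``block_ms``/``block_df`` as the
    denominator for the environment test (otherwise error MS is used).
    """
    if error_ms is not None and error_ms < 0:
        raise ValueError("error_ms must be nonnegative")
    G, E = means.shape
    r = means.replicate_count
    grand = means.grand_mean
    gmeans = means.genotype_means().to_numpy()
    emeans = means.environment_means().to_numpy()
    cellm = means.values.to_numpy()

    ss_g = r * E * float(((gmeans - grand) ** 2).sum())
    ss_e = r * G * float(((emeans - grand) ** 2).sum())
    centered = cellm - gmeans[:, None] - emeans[None, :] + grand
    ss_ge = r * float((centered**2).sum())

    df_g, df_e, df_ge = G - 1, E - 1, (G - 1) * (E - 1)
    rows = {
        "genotypes": [df_g, ss_g, ss_g / df_g, np.nan, np.nan, np.nan],
        "environments": [df_e, ss_e, ss_e / df_e, np.nan, np.nan, np.nan],
        "gxe": [df_ge, ss_ge, ss_ge / df_ge, np.nan, np.nan, np.nan],
    }
    denom_total = ss_g + ss_e + ss_ge
    if error_ms is not None and error_df is not None:
        rows["genotypes"][3:5] = _f_test(ss_g / df_g, error_ms, df_g, error_df)
        rows["gxe"][3:5] = _f_test(ss_ge / df_ge, error_ms, df_ge, error_df)
        e_denom_ms = block_ms if block_ms is not None else error_ms
        e_denom_df = block_df if block_df is not None else error_df
        rows["environments"][3:5] = _f_test(ss_e / df_e, e_denom_ms, df_e, e_denom_df)
        rows["error"] = [error_df, error_ms * error_df, error_ms, np.nan, np.nan, np.nan]
        denom_total += error_ms * error_df
        if block_ms is not None and block_df is not None:
            rows["blocks_within_environments"] = [
                block_df, block_ms * block_df, block_ms, np.nan, np.nan, np.nan]
            denom_total += block_ms * block_df
    if denom_total == 0:  # constant data: percentages undefined
        denom_total = np.nan
    for row in rows.values():
        row[5] = 100 * row[1] / denom_total
    return AnovaTable(pd.DataFrame.from_dict(rows, orient="index", columns=_COLS))
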