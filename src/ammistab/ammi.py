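"""AMMI core: double-centering, SVD of the interaction, Gollob tests.

The additive main effects and multiplicative interaction (AMMI) model for
a genotype x environment table of mean yields is

    y_ge = mu + alpha_g + beta_e + sum_n d_n u_gn v_en + q_ge,

where mu, alpha, beta come from double-centering the table and the
multiplicative terms are the singular triplets (d_n, u_n, v_n) of the
double-centered interaction matrix.  Scores are reported in the symmetric
square-root scaling

    genotype score IPCA_n(g)    = u_gn * sqrt(d_n)
    environment score IPCA_n(e) = v_en * sqrt(d_n)

so that the outer product of the scaled score vectors reconstructs the
n-th interaction term exactly and the sum of squared scores on either
side equals d_n.  Per-axis interaction sums of squares are reported on
the plot basis, SS_n = r * d_n^2, matching how trial ANOVA tables are
printed, and each axis carries the Gollob degrees of freedom
G + E - 1 - 2n for its approximate F-test against the plot-error mean
square.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .trial import CellMeansMatrix

#: relative threshold under which trailing singular values count as zero
RANK_TOL = 1e-10


class DoubleCentered(NamedTuple):
    mu: float
    alpha: pd.Series
    beta: pd.Series
    centered: pd.DataFrame


def double_center(means: CellMeansMatrix) -> DoubleCentered:
    """Split a cell-mean table into grand mean, main effects and interaction.

    ``centered[g, e] = y_ge - ybar_g - ybar_e + ybar``; every row and
    column of the result sums to zero.
    """
    mu = means.grand_mean
    alpha = means.genotype_means() - mu
    beta = means.environment_means() - mu
    centered = means.values.sub(means.genotype_means(), axis=0).sub(
        means.environment_means(), axis=1
    ) + mu
    return DoubleCentered(mu=mu, alpha=alpha, beta=beta, centered=centered)


def gollob_df(n: int, G: int, E: int) -> int:
    """Gollob degrees of freedom G + E - 1 - 2n for interaction axis n (1-based)."""
    if not 1 <= n <= min(G - 1, E - 1):
        raise ValueError(f"axis {n} out of range 1..{min(G - 1, E - 1)}")
    return G + E - 1 - 2 * n


@dataclass
class AmmiFit:
    """Fitted AMMI decomposition of a cell-mean table.

    Score matrices cover every structural axis (min(G-1, E-1) of them);
    ``n_axes`` marks how many are retained for the residual and for
    fitted values.  ``axis_ss`` is plot-basis (r * d_n^2).
    """

    mu: float
    alpha: pd.Series
    beta: pd.Series
    singular_values: np.ndarray
    genotype_scores: pd.DataFrame
    environment_scores: pd.DataFrame
    n_axes: int
    residual: pd.DataFrame
    replicate_count: int
    axis_ss: np.ndarray = field(repr=False, default=None)
    gollob_dfs: np.ndarray = field(repr=False, default=None)
    f_statistics: np.ndarray | None = field(repr=False, default=None)
    p_values: np.ndarray | None = field(repr=False, default=None)
    error_ms: float | None = None
    error_df: int | None = None
    #: absolute floor (data-scale dependent) under which a singular value
    #: counts as numerically zero
    zero_threshold: float = 0.0

    @property
    def genotypes(self) -> list[str]:
        return list(self.genotype_scores.index)

    @property
    def environments(self) -> list[str]:
        return list(self.environment_scores.index)

    @property
    def n_axes_available(self) -> int:
        """Structural axis count, discounting numerically zero singular values."""
        d = self.singular_values
        if len(d) == 0 or d[0] <= self.zero_threshold:
            return 0
        return int((d > max(RANK_TOL * d[0], self.zero_threshold)).sum())

    @property
    def explained_pct(self) -> np.ndarray:
        """Per-axis share of the interaction SS, in percent."""
        d2 = self.singular_values**2
        total = d2.sum()
        if total == 0:
            return np.zeros_like(d2)
        return 100 * d2 / total

    @property
    def interaction_ss(self) -> float:
        """Plot-basis GEI sum of squares represented by all axes."""
        return float(self.replicate_count * (self.singular_values**2).sum())

    def axis_table(self) -> pd.DataFrame:
        """Per-axis SS (plot basis), Gollob df, MS, F, p, explained %."""
        n = len(self.singular_values)
        tab = pd.DataFrame(
            {
                "df": self.gollob_dfs,
                "ss": self.axis_ss,
                "ms": self.axis_ss / self.gollob_dfs,
                "f": self.f_statistics if self.f_statistics is not None else np.nan,
                "p": self.p_values if self.p_values is not None else np.nan,
                "explained_pct": self.explained_pct,
            },
            index=[f"IPCA{k}" for k in range(1, n + 1)],
        )
        return tab


def fit_ammi(
    means: CellMeansMatrix,
    n_axes: int | str = "auto",
    error_ms: float | None = None,
    error_df: int | None = None,
    alpha_level: float = 0.05,
    orient: str = "max_env",
) -> AmmiFit:
    """Fit the AMMI model to a cell-mean table.

    Parameters
    ----------
    means
        Complete G x E table with G >= 3 and E >= 3.
    n_axes
        Retained multiplicative terms: an integer, ``"all"``, or
        ``"auto"`` (Gollob-significant axes at ``alpha_level`` when error
        information is supplied, else 2, the biplot convention).
    error_ms, error_df
        Plot-error mean square and degrees of freedom for the Gollob
        F-tests (optional).
    orient
        ``"max_env"`` flips each axis so the environment with the largest
        absolute score is positive (SVD signs are arbitrary);
        ``"none"`` keeps raw SVD signs.
    """
    G, E = means.shape
    if G < 3 or E < 3:
        raise ValueError(f"AMMI needs at least a 3 x 3 table, got {G} x {E}")
    r = means.replicate_count
    mu, alpha, beta, centered = double_center(means)
    n_struct = min(G - 1, E - 1)
    U, d, Vt = np.linalg.svd(centered.to_numpy(), full_matrices=False)
    U, d, V = U[:, :n_struct], d[:n_struct], Vt[:n_struct].T

    if orient == "max_env":
        for n in range(n_struct):
            j = int(np.argmax(np.abs(V[:, n])))
            if V[j, n] < 0:
                V[:, n] *= -1
                U[:, n] *= -1
    elif orient != "none":
        raise ValueError(f"unknown orientation rule {orient!r}")

    scale = np.sqrt(d)
    cols = [f"IPCA{k}" for k in range(1, n_struct + 1)]
    gscores = pd.DataFrame(U * scale, index=means.values.index, columns=cols)
    escores = pd.DataFrame(V * scale, index=means.values.columns, columns=cols)

    axis_ss = r * d**2
    dfs = np.array([gollob_df(k, G, E) for k in range(1, n_struct + 1)])
    f_stats = p_vals = None
    if error_ms is not None and error_df is not None:
        if error_ms <= 0:
            raise ValueError("error_ms must be positive")
        f_stats = (axis_ss / dfs) / error_ms
        p_vals = stats.f.sf(f_stats, dfs, error_df)

    # numerical-zero floor tied to the data scale, so an exactly additive
    # table reports zero available axes instead of machine noise
    zero_threshold = 1e-12 * float(np.linalg.norm(means.values.to_numpy()))
    if d[0] <= zero_threshold:
        n_avail = 0
    else:
        n_avail = int((d > max(RANK_TOL * d[0], zero_threshold)).sum())
    if n_axes == "all":
        n_keep = n_avail
    elif n_axes == "auto":
        if p_vals is not None:
            n_keep = _leading_significant(p_vals, alpha_level)
        else:
            n_keep = min(2, n_avail)
    else:
        n_keep = int(n_axes)
        if not 0 <= n_keep <= n_struct:
            raise ValueError(f"n_axes must be in 0..{n_struct}, got {n_keep}")

    recon = (U[:, :n_keep] * d[:n_keep]) @ V[:, :n_keep].T
    residual = centered - recon

    return AmmiFit(
        mu=mu, alpha=alpha, beta=beta, singular_values=d,
        genotype_scores=gscores, environment_scores=escores,
        n_axes=n_keep, residual=residual, replicate_count=r,
        axis_ss=axis_ss, gollob_dfs=dfs,
        f_statistics=f_stats, p_values=p_vals,
        error_ms=error_ms, error_df=error_df,
        zero_threshold=zero_threshold,
    )


def _leading_significant(p_vals: np.ndarray, alpha_level: float) -> int:
    n = 0
    for p in p_vals:
        if p < alpha_level:
            n += 1
        else:
            break
    return n


class GollobResult(NamedTuple):
    table: pd.DataFrame  # per-axis df, ss, ms, f, p, significant
    recommended_n: int


def gollob_test(
    fit: AmmiFit,
    error_ms: float | None = None,
    error_df: int | None = None,
    alpha_level: float = 0.05,
) -> GollobResult:
    """Approximate per-axis F-tests with Gollob degrees of freedom.

    Each axis n gets MS_n = (r * d_n^2) / (G + E - 1 - 2n) and
    F_n = MS_n / error MS with p from the upper tail of
    F(df_n, error_df).  The recommended number of multiplicative terms is
    the count of leading consecutive significant axes at ``alpha_level``.
    """
    error_ms = error_ms if error_ms is not None else fit.error_ms
    error_df = error_df if error_df is not None else fit.error_df
    if error_ms is None or error_df is None:
        raise ValueError("error_ms and error_df are required for the Gollob test")
    if error_ms <= 0:
        raise ValueError("error_ms must be positive")
    if error_df < 1:
        raise ValueError("error_df must be at least 1")
    ms = fit.axis_ss / fit.gollob_dfs
    f = ms / error_ms
    p = stats.f.sf(f, fit.gollob_dfs, error_df)
    tab = pd.DataFrame(
        {
            "df": fit.gollob_dfs,
            "ss": fit.axis_ss,
            "ms": ms,
            "f": f,
            "p": p,
            "significant": p < alpha_level,
        },
        index=[f"IPCA{k}" for k in range(1, len(f) + 1)],
    )
    return GollobResult(table=tab, recommended_n=_leading_significant(p, alpha_level))


def export_fit(fit: AmmiFit, out_dir) -> dict:
    """Write genotype/environment score CSVs and the per-axis table.

    Returns the mapping of logical name to written path.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    g = fit.genotype_scores.copy()
    g.insert(0, "mean", fit.mu + fit.alpha)
    paths["genotype_scores"] = out / "genotype_scores.csv"
    g.to_csv(paths["genotype_scores"], index_label="genotype")
    e = fit.environment_scores.copy()
    e.insert(0, "mean", fit.mu + fit.beta)
    paths["environment_scores"] = out / "environment_scores.csv"
    e.to_csv(paths["environment_scores"], index_label="environment")
    paths["axes"] = out / "axes.csv"
    fit.axis_table().to_csv(paths["axes"], index_label="axis")
    return paths
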