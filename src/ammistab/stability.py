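"""Yield-stability statistics: ASV and the genotype selection index.

The AMMI stability value of a genotype with first- and second-axis
interaction scores (s1, s2) is

    ASV = sqrt((w * s1)^2 + s2^2),    w = SS_IPCA1 / SS_IPCA2,

a weighted distance from the biplot origin; the weight compensates for
the first axis carrying more of the interaction than the second.  Since
SS_n = r * d_n^2 on the plot basis, w = (d_1/d_2)^2 on any basis — the
replicate factor cancels.  Lower ASV means a flatter interaction profile,
i.e. a more stable genotype.

The genotype selection index combines yield level and stability:
GSI = rank of mean yield (descending, best = 1) + rank of ASV
(ascending, most stable = 1).  Ranks are competition ("min") ranks: ties
share the smallest applicable rank, so GSI stays integer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .ammi import AmmiFit
from .exceptions import DegenerateFitError


def asv_from_scores(ipca1, ipca2, weight: float) -> np.ndarray:
    """ASV from explicit axis-1/axis-2 score vectors and SS-ratio weight."""
    if weight <= 0:
        raise ValueError("weight must be positive")
    s1 = np.asarray(ipca1, dtype=float)
    s2 = np.asarray(ipca2, dtype=float)
    return np.sqrt((weight * s1) ** 2 + s2**2)


def asv_weight(fit: AmmiFit) -> float:
    """SS_IPCA1 / SS_IPCA2 from a fit; requires a nonzero second axis."""
    if fit.n_axes_available < 2:
        raise DegenerateFitError(
            "ASV needs two interaction axes with nonzero singular values; "
            "the interaction of this fit is (numerically) of rank "
            f"{fit.n_axes_available}"
        )
    d = fit.singular_values
    return float((d[0] / d[1]) ** 2)


def asv(fit: AmmiFit) -> pd.Series:
    """Per-genotype AMMI stability value from a fitted decomposition."""
    w = asv_weight(fit)
    values = asv_from_scores(
        fit.genotype_scores["IPCA1"], fit.genotype_scores["IPCA2"], w
    )
    return pd.Series(values, index=fit.genotype_scores.index, name="asv")


def rank_values(values, direction: str = "ascending") -> np.ndarray:
    """Competition (minimum) ranks; ties share the smallest applicable rank."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot rank an empty vector")
    if direction == "descending":
        arr = -arr
    elif direction != "ascending":
        raise ValueError(f"direction must be 'ascending' or 'descending', got {direction!r}")
    return rankdata(arr, method="min").astype(int)


@dataclass
class StabilityTable:
    """Per-genotype mean yield, interaction scores, ASV, ranks and GSI."""

    table: pd.DataFrame  # index genotype; mean_yield, ipca1, ipca2, asv, rank_yield, rank_asv, gsi
    weight: float  # the SS ratio used for ASV, kept for auditability

    def sorted(self, by: str = "gsi") -> pd.DataFrame:
        return self.table.sort_values(by, kind="stable")

    def best(self, k: int = 5) -> pd.DataFrame:
        """The k genotypes with the lowest (best) GSI."""
        return self.sorted("gsi").head(k)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="genotype")


def genotype_selection_index(
    mean_yield: pd.Series,
    asv_values: pd.Series,
    ipca1: pd.Series | None = None,
    ipca2: pd.Series | None = None,
    weight: float = np.nan,
) -> StabilityTable:
    """Build a stability table from mean yields and ASVs.

    GSI = yield rank (descending) + ASV rank (ascending); low GSI flags
    genotypes that are jointly high-yielding and stable.
    """
    ry = rank_values(mean_yield.to_numpy(), "descending")
    rasv = rank_values(asv_values.to_numpy(), "ascending")
    table = pd.DataFrame(
        {
            "mean_yield": mean_yield,
            "ipca1": ipca1 if ipca1 is not None else np.nan,
            "ipca2": ipca2 if ipca2 is not None else np.nan,
            "asv": asv_values,
            "rank_yield": ry,
            "rank_asv": rasv,
            "gsi": ry + rasv,
        },
        index=mean_yield.index,
    )
    return StabilityTable(table=table, weight=float(weight))


def stability_from_fit(fit: AmmiFit) -> StabilityTable:
    """Stability table straight from an :class:`AmmiFit`."""
    w = asv_weight(fit)
    return genotype_selection_index(
        mean_yield=(fit.mu + fit.alpha).rename("mean_yield"),
        asv_values=asv(fit),
        ipca1=fit.genotype_scores["IPCA1"],
        ipca2=fit.genotype_scores["IPCA2"],
        weight=w,
    )
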