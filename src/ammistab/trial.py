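"""Replicate-level trial data and genotype x environment cell means.

A multi-environment trial (MET) in a randomized complete block design
(RCBD) is a set of plot records ``(genotype, environment, block, yield)``
with blocks nested within environments.  :class:`TrialData` holds the raw
plot records; :func:`cell_means` collapses them to the genotype x
environment table of mean yields (:class:`CellMeansMatrix`) that the AMMI
machinery operates on.

Genotype and environment order is always first-appearance order of the
input; nothing is re-sorted alphabetically, so the order of a published
table survives a read/write round trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    DuplicateRecordError,
    IncompleteTrialError,
    TrialFormatError,
    UnbalancedTrialError,
)

#: canonical long-format column names
LONG_COLUMNS = ("genotype", "environment", "block", "yield")


@dataclass
class TrialData:
    """Plot-level records of an RCBD multi-environment trial.

    Parameters
    ----------
    records
        DataFrame with columns ``genotype, environment, block, yield``
        (yield in t/ha, one row per plot).
    genotypes, environments
        Explicit ordered label lists.  Default: first-appearance order.
    """

    records: pd.DataFrame
    genotypes: list[str] = field(default=None)
    environments: list[str] = field(default=None)

    def __post_init__(self):
        missing = [c for c in LONG_COLUMNS if c not in self.records.columns]
        if missing:
            raise TrialFormatError(f"records lack required columns: {missing}")
        self.records = self.records.loc[:, list(LONG_COLUMNS)].reset_index(drop=True)
        if not np.issubdtype(self.records["yield"].dtype, np.number):
            raise TrialFormatError("'yield' column must be numeric")
        if (self.records["yield"] <= 0).any():
            bad = int(self.records.index[self.records["yield"] <= 0][0])
            raise TrialFormatError(f"nonpositive yield in record {bad}; yields must be > 0 t/ha")
        dup = self.records.duplicated(subset=["genotype", "environment", "block"])
        if dup.any():
            g, e, b = self.records.loc[dup.idxmax(), ["genotype", "environment", "block"]]
            raise DuplicateRecordError(
                f"duplicate plot record for genotype={g!r}, environment={e!r}, block={b!r}"
            )
        if self.genotypes is None:
            self.genotypes = list(dict.fromkeys(self.records["genotype"]))
        if self.environments is None:
            self.environments = list(dict.fromkeys(self.records["environment"]))

    @property
    def n_genotypes(self) -> int:
        return len(self.genotypes)

    @property
    def n_environments(self) -> int:
        return len(self.environments)

    def __len__(self) -> int:
        return len(self.records)

    def is_complete(self) -> bool:
        """True when every genotype x environment cell has at least one plot."""
        cells = self.records.groupby(["genotype", "environment"], sort=False).size()
        return len(cells) == self.n_genotypes * self.n_environments

    def replicate_counts(self) -> pd.Series:
        """Plot count per genotype x environment cell."""
        return self.records.groupby(["genotype", "environment"], sort=False).size()


def read_trial_long(path, column_map: dict | None = None) -> TrialData:
    """Read a long-format replicate-level trial CSV.

    Parameters
    ----------
    path
        CSV file with a header row.
    column_map
        Optional mapping from canonical names (``genotype``,
        ``environment``, ``block``, ``yield``) to the column names used in
        the file, e.g. ``{"yield": "GY_t_ha"}``.
    """
    raw = pd.read_csv(path, dtype=str)
    colmap = dict(zip(LONG_COLUMNS, LONG_COLUMNS))
    if column_map:
        colmap.update(column_map)
    for canonical, actual in colmap.items():
        if actual not in raw.columns:
            raise TrialFormatError(
                f"column {actual!r} (mapped to {canonical!r}) not found in {path}"
            )
    frame = pd.DataFrame({canon: raw[actual] for canon, actual in colmap.items()})
    parsed = pd.to_numeric(frame["yield"], errors="coerce")
    if parsed.isna().any():
        row = int(parsed.index[parsed.isna()][0])
        raise TrialFormatError(
            f"non-numeric yield {frame['yield'][row]!r} in data row {row + 1} of {path}"
        )
    frame["yield"] = parsed.astype(float)
    return TrialData(frame)


def write_trial_long(data: TrialData, path, column_map: dict | None = None) -> None:
    """Write a :class:`TrialData` back to long CSV (inverse of read)."""
    out = data.records.copy()
    if column_map:
        out = out.rename(columns=column_map)
    out.to_csv(path, index=False)


@dataclass
class CellMeansMatrix:
    """Genotype x environment table of mean yields (t/ha).

    ``values`` is a DataFrame with genotype rows and environment columns,
    every cell present.  ``replicate_count`` is the common number of
    replicates r behind each cell; it converts mean-basis sums of squares
    to the plot basis (x r) used in ANOVA tables.
    """

    values: pd.DataFrame
    replicate_count: int = 1

    def __post_init__(self):
        self.values = self.values.astype(float)
        if self.values.isna().any().any():
            raise IncompleteTrialError(
                [(g, e) for g, e in self.values.stack(future_stack=True)[
                    self.values.stack(future_stack=True).isna()].index]
            )
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be a positive integer")

    @property
    def genotypes(self) -> list[str]:
        return list(self.values.index)

    @property
    def environments(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def grand_mean(self) -> float:
        return float(self.values.to_numpy().mean())

    def genotype_means(self) -> pd.Series:
        return self.values.mean(axis=1)

    def environment_means(self) -> pd.Series:
        return self.values.mean(axis=0)

    def to_wide_csv(self, path, include_mean: bool = False) -> None:
        out = self.values.copy()
        if include_mean:
            out["mean"] = out.mean(axis=1)
        out.to_csv(path, index_label="genotype")


def read_means_wide(path, replicate_count: int = 1) -> CellMeansMatrix:
    """Read a wide genotype x environment mean table.

    First column holds genotype ids, remaining columns one environment
    each.  A trailing ``mean`` column (any capitalisation) is ignored.
    """
    frame = pd.read_csv(path, index_col=0)
    drop = [c for c in frame.columns if c.strip().lower() == "mean"]
    frame = frame.drop(columns=drop)
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        raise TrialFormatError(f"non-numeric cell in {path}: {exc}") from exc
    return CellMeansMatrix(frame, replicate_count=replicate_count)


def cell_means(data: TrialData) -> CellMeansMatrix:
    """Collapse plot records to per-cell mean yields.

    Requires a complete table (every genotype x environment cell observed)
    and balanced replication (a common replicate count r across cells);
    the plot-basis sum-of-squares conversion assumes a common r.
    """
    counts = data.replicate_counts()
    observed = set(counts.index)
    missing = [
        (g, e)
        for g in data.genotypes
        for e in data.environments
        if (g, e) not in observed
    ]
    if missing:
        raise IncompleteTrialError(missing)
    r = int(counts.iloc[0])
    if (counts != r).any():
        raise UnbalancedTrialError(
            f"replicate counts vary between cells (found {sorted(counts.unique())}); "
            "a common replicate count is required"
        )
    table = (
        data.records.pivot_table(
            index="genotype", columns="environment", values="yield", aggfunc="mean"
        )
        .reindex(index=data.genotypes, columns=data.environments)
    )
    table.index.name = "genotype"
    table.columns.name = "environment"
    return CellMeansMatrix(table, replicate_count=r)
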