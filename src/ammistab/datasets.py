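"""Packaged reference dataset: a published Polish maize hybrid trial.

The dataset is the complete published cell-mean table of a 2017
multi-environment grain-yield trial run by the Smolice maize breeding
programme: 69 hybrids (66 experimental flint/dent hybrids plus the check
cultivars NK Ravello, Ricardinio and ES Gallery) grown at five locations
in Poland (Kobierzyce, Mikulice, Płaczkowo, Radzików, Smolice) in a
randomized complete block design with three replicates.  Yields are in
t/ha at 14% moisture, printed to two decimal places.

Alongside the cell means, the published per-genotype interaction scores
(IPCA1/IPCA2), AMMI stability values (ASV) and genotype selection index
(GSI), and the per-environment means and IPCA scores are packaged for
regression testing.  These reference columns are stored exactly as
printed; the known internal inconsistency of the printed GSI column around
genotype SMH_1724 is preserved as-is.
"""

from __future__ import annotations

import importlib.resources
from typing import NamedTuple

import pandas as pd

from .trial import CellMeansMatrix


class MaizeTrial(NamedTuple):
    """Packaged maize trial: cell means plus published reference values."""

    means: CellMeansMatrix
    genotype_reference: pd.DataFrame  # code, mean, ipca1, ipca2, asv, gsi per genotype
    environment_reference: pd.DataFrame  # mean, ipca1, ipca2 per environment


def _data_path(name: str):
    return importlib.resources.files("ammistab").joinpath("data", name)


def load_maize_trial() -> MaizeTrial:
    """Load the packaged 69 x 5 maize cell-mean table and reference scores.

    Returns
    -------
    MaizeTrial
        ``means`` is the 69 x 5 :class:`~ammistab.trial.CellMeansMatrix`
        (replicate_count 3); ``genotype_reference`` and
        ``environment_reference`` carry the published means, IPCA scores,
        ASV and GSI for regression tests.
    """
    with _data_path("maize_grain_yield.csv").open("r", encoding="utf-8") as fh:
        wide = pd.read_csv(fh)
    means = CellMeansMatrix(
        wide.drop(columns=["code"]).set_index("genotype"), replicate_count=3
    )
    means.values.columns.name = "environment"
    with _data_path("maize_reference_scores.csv").open("r", encoding="utf-8") as fh:
        gref = pd.read_csv(fh).set_index("genotype")
    with _data_path("maize_reference_environments.csv").open("r", encoding="utf-8") as fh:
        eref = pd.read_csv(fh).set_index("environment")
    return MaizeTrial(means=means, genotype_reference=gref, environment_reference=eref)


#: Error stratum of the published ANOVA for the maize trial (plot basis).
#: The plot-level data behind it are not published, so the error mean
#: square and its degrees of freedom are carried as constants to allow the
#: published F-tests to be reproduced from the cell means.
MAIZE_ERROR_MS = 432.9 / 680
MAIZE_ERROR_DF = 680
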