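"""Quantitative trait replicates and covariates.

A :class:`TraitTable` holds one trait value per (individual, replicate) plus
per-individual covariates (sex, age, medication).  The on-disk format is a
long TSV with columns ``individual_id  replicate  trait  sex  age
medication``; sex is coded 1 = male, 0 = female.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

COVARIATE_COLUMNS = ("sex", "age", "medication")


@dataclass
class TraitTable:
    """Trait values (individuals x replicates) with covariates.

    ``values``: DataFrame indexed by individual_id, one column per replicate
    id (integers 1..R).  ``covariates``: DataFrame indexed by individual_id
    with numeric columns sex (1=male, 0=female), age, medication (0/1).
    """

    values: pd.DataFrame
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.covariates.index):
            self.covariates = self.covariates.reindex(self.values.index)
        self.values.columns = [int(c) for c in self.values.columns]

    @property
    def replicate_ids(self) -> list[int]:
        return list(self.values.columns)

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1]

    @property
    def individual_ids(self) -> list[str]:
        return list(self.values.index)

    def replicate(self, r: int) -> pd.Series:
        return self.values[int(r)]

    def subset_replicates(self, replicate_ids) -> "TraitTable":
        return TraitTable(self.values[[int(r) for r in replicate_ids]].copy(), self.covariates.copy())

    def with_values(self, values: pd.DataFrame) -> "TraitTable":
        return TraitTable(values, self.covariates.copy())


def write_trait_table(traits: TraitTable, path: str | Path) -> None:
    long = traits.values.reset_index(names="individual_id").melt(
        id_vars="individual_id", var_name="replicate", value_name="trait"
    )
    long = long.merge(
        traits.covariates.reset_index(names="individual_id"), on="individual_id", how="left"
    )
    long = long.sort_values(["replicate", "individual_id"], kind="stable")
    long.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_trait_table(path: str | Path) -> TraitTable:
    long = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    required = {"individual_id", "replicate", "trait"}
    missing = required - set(long.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    values = long.pivot(index="individual_id", columns="replicate", values="trait")
    values = values[sorted(values.columns)]
    cov_cols = [c for c in COVARIATE_COLUMNS if c in long.columns]
    cov = (
        long.drop_duplicates("individual_id").set_index("individual_id")[cov_cols]
        if cov_cols
        else pd.DataFrame(index=values.index)
    )
    cov = cov.reindex(values.index).astype(float)
    return TraitTable(values.astype(float), cov)
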