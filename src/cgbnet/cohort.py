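"""Rectangular cohort container: individuals x variables with per-column kinds.

Every analysis stage (regression scans, network learning, the simulator's
output) speaks :class:`CohortTable`: a pandas DataFrame of one row per
individual plus a sidecar mapping each column to one of three kinds --
``continuous`` (TG levels, age, CpG beta-values, principal components),
``discrete`` (sex, center) or ``genotype`` (minor-allele dosage 0/1/2).
Missing values are NaN in memory and ``NA`` on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

KINDS = ("continuous", "discrete", "genotype")


class SchemaError(ValueError):
    """A table, sidecar or constraint file does not match its contract."""


@dataclass
class CohortTable:
    """Individuals x variables table with typed columns.

    Parameters
    ----------
    data
        One row per individual; the index identifies individuals and is
        written/read as the ``id`` column.
    kinds
        Mapping from every column name to ``continuous``/``discrete``/
        ``genotype``.
    """

    data: pd.DataFrame
    kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.shape[0] == 0:
            raise SchemaError("cohort table has no rows")
        missing = [c for c in self.data.columns if c not in self.kinds]
        if missing:
            raise SchemaError(f"no kind declared for columns: {missing}")
        bad = {c: k for c, k in self.kinds.items() if k not in KINDS}
        if bad:
            raise SchemaError(f"unknown column kinds: {bad} (expected one of {KINDS})")
        extra = [c for c in self.kinds if c not in self.data.columns]
        if extra:
            raise SchemaError(f"kinds declared for absent columns: {extra}")
        for col in self.columns_of_kind("genotype"):
            vals = self.data[col].dropna().unique()
            if not np.isin(vals, [0, 1, 2]).all():
                raise SchemaError(f"genotype column {col!r} has values outside {{0,1,2}}")

    # -- basic accessors -------------------------------------------------

    @property
    def n(self) -> int:
        return int(self.data.shape[0])

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def columns_of_kind(self, kind: str) -> list[str]:
        return [c for c in self.data.columns if self.kinds[c] == kind]

    def select(self, columns: list[str]) -> "CohortTable":
        """Sub-table restricted to ``columns`` (order preserved)."""
        absent = [c for c in columns if c not in self.data.columns]
        if absent:
            raise SchemaError(f"columns not in table: {absent}")
        return CohortTable(self.data[columns].copy(), {c: self.kinds[c] for c in columns})

    def resample(self, rng: np.random.Generator) -> "CohortTable":
        """Bootstrap resample: n rows drawn with replacement."""
        idx = rng.integers(0, self.n, self.n)
        out = self.data.iloc[idx].reset_index(drop=True)
        return CohortTable(out, dict(self.kinds))

    # -- disk format -----------------------------------------------------

    def to_tsv(self, path: str | Path, types_path: str | Path) -> None:
        """Write the table and its column-type sidecar as TSV.

        The table carries a leading ``id`` column taken from the index;
        missing cells are written as ``NA``; floats at full precision.
        """
        self.data.to_csv(path, sep="\t", na_rep="NA", index=True, index_label="id")
        sidecar = pd.DataFrame(
            {"column": list(self.data.columns), "kind": [self.kinds[c] for c in self.data.columns]}
        )
        sidecar.to_csv(types_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, types_path: str | Path) -> "CohortTable":
        try:
            df = pd.read_csv(path, sep="\t", na_values=["NA"])
        except pd.errors.EmptyDataError as exc:
            raise SchemaError(f"empty cohort file: {path}") from exc
        if "id" in df.columns:
            df = df.set_index("id")
        sidecar = pd.read_csv(types_path, sep="\t")
        if not {"column", "kind"} <= set(sidecar.columns):
            raise SchemaError(f"type sidecar {types_path} must have 'column' and 'kind' columns")
        kinds = dict(zip(sidecar["column"].astype(str), sidecar["kind"].astype(str)))
        return cls(df, kinds)
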