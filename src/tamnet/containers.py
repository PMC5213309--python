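"""Core in-memory containers shared across the pipeline.

The pipeline operates on a gene-by-sample expression matrix together with a
per-sample factor table describing a two-condition, two-timepoint, paired-donor
design (four condition-groups).  Both containers are thin, validated wrappers
around :class:`pandas.DataFrame`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SCALES = ("counts", "cpm", "log2cpm")


@dataclass
class ExpressionMatrix:
    """Gene x sample numeric matrix with an explicit scale tag.

    Parameters
    ----------
    values:
        DataFrame indexed by gene identifier with sample identifiers as
        columns.  Gene and sample identifiers are opaque, case-sensitive
        strings.
    scale:
        One of ``"counts"`` (non-negative raw counts), ``"cpm"`` or
        ``"log2cpm"``.  Scale transitions happen only through declared
        operations (:func:`tamnet.preprocess.normalize_log_cpm` etc.).
    """

    values: pd.DataFrame
    scale: str = "counts"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression matrix must be numeric")
        if not np.isfinite(arr).all():
            raise ValueError("expression matrix contains non-finite values")
        if self.scale == "counts" and (arr < 0).any():
            raise ValueError("counts-scale matrix contains negative values")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.scale)


@dataclass
class SampleDesign:
    """Per-sample factor table: condition, time and donor labels.

    The derived ``group`` of a sample is ``"<condition>_<time>"``; the default
    paired design has two conditions x two times x four donors, i.e. four
    groups of four samples each with every donor represented once per group.
    """

    table: pd.DataFrame = field()

    def __post_init__(self) -> None:
        required = {"condition", "time", "donor"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            raise ValueError("duplicate sample identifiers in sample sheet")
        self.table = self.table.astype(str)

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.table["condition"]))

    @property
    def times(self) -> list[str]:
        return list(dict.fromkeys(self.table["time"]))

    @property
    def donors(self) -> list[str]:
        return list(dict.fromkeys(self.table["donor"]))

    @property
    def group(self) -> pd.Series:
        """Sample -> group label ("<condition>_<time>")."""
        return self.table["condition"] + "_" + self.table["time"]

    @property
    def group_names(self) -> list[str]:
        """Group labels in condition-major, time-minor order."""
        return [f"{c}_{t}" for c in self.conditions for t in self.times]

    @property
    def groups(self) -> dict[str, list[str]]:
        """Group label -> ordered list of member samples; all groups non-empty."""
        grp = self.group
        out = {g: [s for s in self.samples if grp[s] == g] for g in self.group_names}
        empty = [g for g, members in out.items() if not members]
        if empty:
            raise ValueError(f"empty condition-groups: {empty}")
        return out

    def samples_of(self, condition: str | None = None, time: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.table.index)
        if condition is not None:
            mask &= self.table["condition"] == condition
        if time is not None:
            mask &= self.table["time"] == time
        return list(self.table.index[mask])

    def is_balanced(self) -> bool:
        """True when every condition x time cell holds the same sample count."""
        sizes = {len(v) for v in self.groups.values()}
        return len(sizes) == 1
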