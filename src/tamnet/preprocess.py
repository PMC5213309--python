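"""Presence filtering, CPM normalization, fold-change-over-mean overlays and
variable-gene ranking.

"Present throughout all conditions" is operationalized as a median CPM of at
least ``min_cpm`` (default 1) within every one of the four condition-groups;
the median is robust to a single dropout donor.  The fold-change overlay
compares each group mean to the grand mean of the four *group means* (not of
raw samples), so all groups weigh equally even under unbalanced designs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, SampleDesign

logger = logging.getLogger(__name__)

__all__ = [
    "FCOverlay",
    "cpm",
    "filter_present",
    "normalize_log_cpm",
    "fc_over_mean",
    "top_variable_genes",
    "group_mean_profiles",
]


def cpm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Counts-per-million per sample (no log)."""
    _require_scale(counts, "counts")
    lib = counts.values.sum(axis=0)
    zero = lib.index[lib == 0].tolist()
    if zero:
        raise ValueError(f"zero library size for samples: {zero}")
    return ExpressionMatrix(counts.values * 1e6 / lib, scale="cpm")


def filter_present(
    counts: ExpressionMatrix, design: SampleDesign, min_cpm: float = 1.0
) -> ExpressionMatrix:
    """Keep genes with median CPM >= ``min_cpm`` in *every* condition-group.

    The comparison is inclusive; row order of surviving genes is preserved.
    An empty result is legal and only warned about.
    """
    cpm_vals = cpm(counts).values
    keep = pd.Series(True, index=cpm_vals.index)
    for _, samples in design.groups.items():
        keep &= cpm_vals[samples].median(axis=1) >= min_cpm
    if not keep.any():
        logger.warning("presence filter removed every gene (min_cpm=%g)", min_cpm)
    return ExpressionMatrix(counts.values.loc[keep], scale="counts")


def normalize_log_cpm(counts: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(1e6 * count / library_size + pseudocount); zeros map to log2(pseudocount)."""
    cpm_vals = cpm(counts).values
    return ExpressionMatrix(np.log2(cpm_vals + pseudocount), scale="log2cpm")


@dataclass
class FCOverlay:
    """Per-gene, per-group fold change over the grand mean of group means.

    ``log2`` holds group mean minus grand mean on the log2 scale (genes x
    groups); the linear ratio is ``2**log2``, so a gene is "elevated" in a
    group exactly when its linear ratio is >= 1.
    """

    log2: pd.DataFrame

    @property
    def linear(self) -> pd.DataFrame:
        return np.exp2(self.log2)

    def elevated(self, group: str) -> pd.Index:
        """Genes whose linear FC over mean is >= 1 in the given group."""
        return self.log2.index[self.log2[group] >= 0.0]

    def to_table(self) -> pd.DataFrame:
        """Long-format table: gene, group, linear_fc, log2_fc."""
        long = self.log2.stack().rename("log2_fc").reset_index()
        long.columns = ["gene", "group", "log2_fc"]
        long["linear_fc"] = np.exp2(long["log2_fc"])
        return long[["gene", "group", "linear_fc", "log2_fc"]]


def group_mean_profiles(log_expr: ExpressionMatrix, design: SampleDesign) -> pd.DataFrame:
    """Genes x groups matrix of mean log2 expression per condition-group."""
    _require_scale(log_expr, "log2cpm")
    return pd.DataFrame(
        {g: log_expr.values[s].mean(axis=1) for g, s in design.groups.items()}
    )


def fc_over_mean(log_expr: ExpressionMatrix, design: SampleDesign) -> FCOverlay:
    """Fold change of each group mean over the grand mean of the group means."""
    means = group_mean_profiles(log_expr, design)
    grand = means.mean(axis=1)
    return FCOverlay(means.sub(grand, axis=0))


def top_variable_genes(log_expr: ExpressionMatrix, n: int) -> list[str]:
    """The ``n`` genes of largest log2-expression sample variance.

    Sorted by decreasing variance; exact ties broken by lexicographic gene id
    so the ranking is deterministic.
    """
    _require_scale(log_expr, "log2cpm")
    if n > log_expr.n_genes:
        raise ValueError(f"requested {n} genes but matrix has {log_expr.n_genes}")
    var = log_expr.values.var(axis=1, ddof=1)
    order = sorted(var.index, key=lambda g: (-var[g], g))
    return order[:n]


def _require_scale(matrix: ExpressionMatrix, scale: str) -> None:
    if matrix.scale != scale:
        raise ValueError(f"expected a {scale}-scale matrix, got {matrix.scale!r}")
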