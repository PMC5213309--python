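"""Batch self-organizing map over per-gene condition-group profiles.

The SOM is trained on each gene's z-scored vector of four group means, not on
the sixteen raw samples: the quantity of interest is condition specificity,
and averaging over donors removes pairing noise (sample-level training remains
available by passing any profile matrix).  Batch updates — assign every gene
to its best-matching unit, then recompute each codebook as the Gaussian
neighborhood-weighted mean — are used instead of online updates so results are
deterministic for a fixed seed and independent of gene input order.

The neighborhood radius decays linearly to zero over the epochs; once it
reaches zero an epoch is exactly one k-means step, so the quantization error
is non-increasing from that point on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, SampleDesign
from .preprocess import group_mean_profiles

__all__ = ["SOMGrid", "zscore_profiles", "train_som", "label_and_select"]


@dataclass
class SOMGrid:
    """Trained SOM: grid shape, codebook vectors and the gene -> BMU map.

    ``codebook`` has one row per unit (row-major grid order) and one column
    per condition-group; ``bmu`` maps each gene to its unit index.
    """

    shape: tuple[int, int]
    codebook: np.ndarray
    bmu: pd.Series
    columns: list[str]

    def unit_position(self, unit: int) -> tuple[int, int]:
        return divmod(unit, self.shape[1])

    @property
    def quantization_error(self) -> float:
        """Mean squared distance of each profile to its BMU codebook (set at
        training time)."""
        return self._qe

    def to_table(self) -> pd.DataFrame:
        rows, cols = np.divmod(self.bmu.to_numpy(), self.shape[1])
        return pd.DataFrame(
            {"bmu_row": rows, "bmu_col": cols, "bmu": self.bmu.to_numpy()},
            index=self.bmu.index,
        )


def zscore_profiles(log_expr: ExpressionMatrix, design: SampleDesign) -> pd.DataFrame:
    """Per-gene z-scored group-mean profiles (genes x groups).

    Genes whose four group means are identical carry no profile shape and are
    dropped.
    """
    means = group_mean_profiles(log_expr, design)
    sd = means.std(axis=1, ddof=0)
    keep = sd > 0
    means = means.loc[keep]
    return means.sub(means.mean(axis=1), axis=0).div(sd[keep], axis=0)


def _grid_distances(shape: tuple[int, int]) -> np.ndarray:
    rows, cols = shape
    pos = np.array([(r, c) for r in range(rows) for c in range(cols)], dtype=float)
    diff = pos[:, None, :] - pos[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def _linear_init(X: np.ndarray, grid: tuple[int, int]) -> np.ndarray:
    """Spread codebooks over the plane of the first two principal components.

    The grid columns span PC1 and the rows PC2 (when the grid has more than
    one row), each over +/- 2 standard deviations around the data mean — the
    classic deterministic initialization that avoids dead units."""
    rows, cols = grid
    mean = X.mean(axis=0)
    Xc = X - mean
    _, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    sd = S / np.sqrt(max(X.shape[0] - 1, 1))

    def coords(n):
        if n == 1:
            return np.zeros(1)
        return np.linspace(-1.0, 1.0, n)

    cb = np.tile(mean, (rows * cols, 1))
    c1 = coords(cols)
    for r in range(rows):
        for c in range(cols):
            cb[r * cols + c] += 2.0 * sd[0] * c1[c] * Vt[0]
    if rows > 1 and len(sd) > 1:
        c2 = coords(rows)
        for r in range(rows):
            for c in range(cols):
                cb[r * cols + c] += 2.0 * sd[1] * c2[r] * Vt[1]
    return cb


def train_som(
    profiles: pd.DataFrame,
    grid: tuple[int, int] = (8, 8),
    epochs: int = 20,
    seed: int = 0,
    init: str = "linear",
) -> SOMGrid:
    """Train a batch SOM on the given profile matrix.

    ``init="linear"`` (default) lays the initial codebooks out on the plane of
    the first two principal components, the deterministic textbook choice that
    avoids dead units; ``init="sample"`` draws random gene profiles using
    ``seed``.  Each epoch assigns genes to their nearest (Euclidean) unit,
    breaking ties toward the lower unit index, then replaces every codebook by
    the neighborhood-weighted mean of all profiles (Gaussian kernel on grid
    distance, sigma = current radius).  Units that attract no weight keep
    their previous codebook.
    """
    if profiles.shape[0] < 1:
        raise ValueError("need at least one profile to train")
    X = profiles.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("profiles contain non-finite values")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    n_units = grid[0] * grid[1]
    if init == "linear":
        codebook = _linear_init(X, grid)
    elif init == "sample":
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        init_idx = rng.choice(X.shape[0], size=n_units, replace=X.shape[0] < n_units)
        codebook = X[init_idx].astype(float).copy()
    else:
        raise ValueError(f"unknown init {init!r}")
    grid_d = _grid_distances(grid)
    r0 = max(grid) / 2.0

    bmu = np.zeros(X.shape[0], dtype=int)
    for epoch in range(epochs):
        radius = r0 * (epochs - 1 - epoch) / max(epochs - 1, 1)
        d2 = ((X[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2)
        bmu = d2.argmin(axis=1)  # argmin takes the lowest index on ties
        if radius > 0:
            H = np.exp(-(grid_d**2) / (2.0 * radius**2))
        else:
            H = np.eye(n_units)
        W = H[:, bmu]  # units x genes neighborhood weights
        totals = W.sum(axis=1)
        hit = totals > 0
        codebook[hit] = (W[hit] @ X) / totals[hit, None]

    d2 = ((X[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2)
    bmu = d2.argmin(axis=1)
    som = SOMGrid(
        shape=grid,
        codebook=codebook,
        bmu=pd.Series(bmu, index=profiles.index),
        columns=list(profiles.columns),
    )
    som._qe = float(d2[np.arange(X.shape[0]), bmu].mean())
    return som


def quantization_error(X: np.ndarray, codebook: np.ndarray) -> float:
    d2 = ((X[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2)
    return float(d2.min(axis=1).mean())


def label_and_select(som: SOMGrid, margin: float = 0.5) -> pd.DataFrame:
    """Assign each unit the group of its largest codebook value and flag genes
    as condition-specific when that maximum clears the runner-up by ``margin``
    (z-units).

    Returns a table per gene: unit, unit_label, specific flag, and the gene's
    resulting label (its unit's group when specific, else "unspecific").
    """
    cb = som.codebook
    order = np.argsort(-cb, axis=1)
    top = cb[np.arange(cb.shape[0]), order[:, 0]]
    second = (
        cb[np.arange(cb.shape[0]), order[:, 1]] if cb.shape[1] > 1 else np.full(len(cb), -np.inf)
    )
    unit_label = np.array([som.columns[i] for i in order[:, 0]])
    unit_specific = (top - second) >= margin

    units = som.bmu.to_numpy()
    table = som.to_table()
    table["unit_label"] = unit_label[units]
    table["specific"] = unit_specific[units]
    table["label"] = np.where(table["specific"], table["unit_label"], "unspecific")
    return table
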