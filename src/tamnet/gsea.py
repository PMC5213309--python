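"""Gene-set enrichment analysis from first principles: signal-to-noise gene
ranking, the weighted Kolmogorov-Smirnov running-sum enrichment score,
permutation nulls with NES normalization, and volcano-plot classing.

The running statistic walks the ranked list; set members ("hits") add their
|metric|^p share of the set total and non-members subtract 1/(N - Nh).  The
enrichment score is the signed maximal deviation of this walk; with weight
p = 0 it reduces to the classical two-sample KS statistic.

The default null permutes gene labels (random same-size sets on the fixed
ranking) rather than phenotypes: with four donors per group, the phenotype
permutation space (70 relabelings, fewer when respecting pairing) is far too
small for stable p-values.  Phenotype permutation is implemented for larger
designs.  The normalized score NES divides each ES by the mean |null ES| of
matching sign, and nominal p-values use the (k+1)/(m+1) add-one rule so no
p is exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, SampleDesign
from .io import GeneSetCollection
from .preprocess import _require_scale

__all__ = [
    "RankedList",
    "GseaResult",
    "rank_genes",
    "enrichment_score",
    "permutation_test",
    "volcano_table",
]


@dataclass
class RankedList:
    """Genes in decreasing metric order (ties broken by gene id)."""

    genes: list[str]
    metric: np.ndarray
    groups: tuple[str, str]

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.metric):
            raise ValueError("genes and metric lengths differ")
        if not np.isfinite(self.metric).all():
            raise ValueError("ranking metric contains non-finite values")
        self._pos = {g: i for i, g in enumerate(self.genes)}

    def __len__(self) -> int:
        return len(self.genes)

    def positions(self, gene_set) -> np.ndarray:
        """Sorted rank positions of the set members present in the list."""
        return np.array(sorted(self._pos[g] for g in set(gene_set) if g in self._pos), dtype=int)


def signal_to_noise(
    a: np.ndarray, b: np.ndarray, sd_floor_frac: float = 0.2, sd_floor_abs: float = 1e-8
) -> np.ndarray:
    """(mean_a - mean_b) / (sd_a' + sd_b') with sd' = max(sd, 0.2|mean|, 1e-8).

    The proportional floor is the classic convention; it keeps the
    denominator meaningful at very small group sizes.
    """
    mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
    sd_a = np.maximum.reduce([a.std(axis=1, ddof=1), sd_floor_frac * np.abs(mu_a),
                              np.full_like(mu_a, sd_floor_abs)])
    sd_b = np.maximum.reduce([b.std(axis=1, ddof=1), sd_floor_frac * np.abs(mu_b),
                              np.full_like(mu_b, sd_floor_abs)])
    return (mu_a - mu_b) / (sd_a + sd_b)


def rank_genes(
    log_expr: ExpressionMatrix,
    design: SampleDesign,
    group_a: str,
    group_b: str,
    metric: str = "signal_to_noise",
) -> RankedList:
    """Rank all genes by a two-group metric, decreasing; ties by gene id."""
    _require_scale(log_expr, "log2cpm")
    groups = design.groups
    for g in (group_a, group_b):
        if g not in groups:
            raise ValueError(f"unknown group {g!r}; design has {list(groups)}")
    A = log_expr.values[groups[group_a]].to_numpy(dtype=float)
    B = log_expr.values[groups[group_b]].to_numpy(dtype=float)
    if metric == "signal_to_noise":
        if A.shape[1] < 2 or B.shape[1] < 2:
            raise ValueError("signal_to_noise needs >= 2 samples per group")
        m = signal_to_noise(A, B)
    elif metric == "mean_difference":
        m = A.mean(axis=1) - B.mean(axis=1)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    genes = log_expr.genes
    order = sorted(range(len(genes)), key=lambda i: (-m[i], genes[i]))
    return RankedList([genes[i] for i in order], m[order], (group_a, group_b))


def enrichment_score(
    ranked: RankedList, gene_set, weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score and the full running sum.

    Hits contribute |metric|^weight normalized by the in-set total (equal
    steps when that total is zero); misses subtract 1/(N - Nh).  The score is
    the running-sum value of maximal absolute deviation, sign retained
    (positive preferred on an exact tie).
    """
    N = len(ranked)
    pos = ranked.positions(gene_set)
    Nh = len(pos)
    if Nh == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if Nh == N:
        raise ValueError("gene set equals the whole ranked list; miss penalty undefined")
    hit = np.zeros(N, dtype=bool)
    hit[pos] = True
    w = np.abs(ranked.metric) ** weight
    w_hit = w[hit]
    total = w_hit.sum()
    steps = np.full(N, -1.0 / (N - Nh))
    steps[hit] = w_hit / total if total > 0 else 1.0 / Nh
    running = np.cumsum(steps)
    hi, lo = running.max(), running.min()
    es = hi if hi >= -lo else lo
    return float(es), running


def _es_from_positions(
    P: np.ndarray, w: np.ndarray, N: int
) -> np.ndarray:
    """Vectorized ES for rows of sorted hit positions.

    ``P``: (m, k) sorted rank positions; ``w``: length-N per-position weights
    (|metric|^p).  Evaluates the running sum only at its candidate extrema —
    immediately after each hit (local maxima) and immediately before each hit
    (local minima) — which is exact because the walk only rises at hits.
    """
    m, k = P.shape
    wv = w[P]
    tot = wv.sum(axis=1, keepdims=True)
    wn = np.where(tot > 0, wv / np.where(tot == 0, 1.0, tot), 1.0 / k)
    cum = np.cumsum(wn, axis=1)
    miss = 1.0 / (N - k)
    j = np.arange(k)
    after = cum - (P - j) * miss
    before = (cum - wn) - (P - j) * miss
    hi = after.max(axis=1)
    lo = before.min(axis=1)
    return np.where(hi >= -lo, hi, lo)


@dataclass
class GseaResult:
    """Per-set enrichment table plus skip notes.

    ``table`` columns: size, es, nes, p, q, class (after volcano classing),
    leading_edge.
    """

    table: pd.DataFrame
    n_perm: int
    mode: str
    skipped: dict[str, str] = field(default_factory=dict)


def _leading_edge(ranked: RankedList, pos: np.ndarray, running: np.ndarray, es: float):
    if es >= 0:
        peak = int(np.argmax(running))
        lead = [ranked.genes[i] for i in pos if i <= peak]
    else:
        trough = int(np.argmin(running))
        lead = [ranked.genes[i] for i in pos if i >= trough]
    return lead


def permutation_test(
    ranked: RankedList,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    mode: str = "gene_set",
    weight: float = 1.0,
    seed: int = 0,
    min_size: int = 5,
    log_expr: ExpressionMatrix | None = None,
    design: SampleDesign | None = None,
) -> GseaResult:
    """ES/NES/p/FDR for every gene set against a permutation null.

    ``gene_set`` mode draws random same-size sets on the fixed ranking;
    ``phenotype`` mode re-ranks under permuted group labels (requires
    ``log_expr`` and ``design``).  Sets smaller than ``min_size`` after
    intersection with the ranking are skipped with a note.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if mode not in ("gene_set", "phenotype"):
        raise ValueError(f"unknown permutation mode {mode!r}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    N = len(ranked)
    w = np.abs(ranked.metric) ** weight

    kept: list[str] = []
    skipped: dict[str, str] = {}
    positions: dict[str, np.ndarray] = {}
    for name in sets.names():
        pos = ranked.positions(sets.genes_of(name))
        if len(pos) < min_size:
            skipped[name] = f"only {len(pos)} of {len(sets.genes_of(name))} members in ranking"
        elif len(pos) == N:
            skipped[name] = "set covers the whole ranking"
        else:
            kept.append(name)
            positions[name] = pos

    if mode == "phenotype":
        null_by_set = _phenotype_null(
            ranked, positions, kept, n_perm, weight, rng, log_expr, design
        )
    else:
        # independent null draws per set (even at equal sizes) so p-values of
        # different sets are independent under the null
        null_by_set = {
            name: _random_set_null(w, N, len(positions[name]), n_perm, rng)
            for name in kept
        }

    rows = []
    all_null_nes: list[np.ndarray] = []
    for name in kept:
        pos = positions[name]
        es = float(_es_from_positions(pos[None, :], w, N)[0])
        null = null_by_set[name]
        pos_null = null[null >= 0]
        neg_null = null[null < 0]
        mean_pos = pos_null.mean() if pos_null.size else np.abs(null).mean()
        mean_neg = np.abs(neg_null).mean() if neg_null.size else np.abs(null).mean()
        nes = es / mean_pos if es >= 0 else es / mean_neg
        same = pos_null if es >= 0 else neg_null
        extreme = int((np.abs(same) >= abs(es)).sum())
        p = (extreme + 1) / (len(same) + 1)
        null_nes = np.where(null >= 0, null / mean_pos, null / mean_neg)
        all_null_nes.append(null_nes)
        _, running = enrichment_score(ranked, sets.genes_of(name), weight)
        lead = _leading_edge(ranked, pos, running, es)
        rows.append(
            {"set": name, "size": len(pos), "es": es, "nes": nes, "p": p,
             "leading_edge": ",".join(lead)}
        )

    table = pd.DataFrame(rows).set_index("set") if rows else pd.DataFrame(
        columns=["size", "es", "nes", "p", "leading_edge"]
    )
    if rows:
        table["q"] = _nes_fdr(table["nes"].to_numpy(), np.concatenate(all_null_nes))
        table = table[["size", "es", "nes", "p", "q", "leading_edge"]]
    return GseaResult(table=table, n_perm=n_perm, mode=mode, skipped=skipped)


def _random_set_null(w: np.ndarray, N: int, k: int, n_perm: int, rng) -> np.ndarray:
    """Null ES from ``n_perm`` uniformly drawn size-``k`` gene sets."""
    # sample without replacement per row via argpartition of random keys
    keys = rng.random((n_perm, N))
    P = np.argpartition(keys, k, axis=1)[:, :k]
    P.sort(axis=1)
    return _es_from_positions(P, w, N)


def _phenotype_null(ranked, positions, kept, n_perm, weight, rng, log_expr, design):
    if log_expr is None or design is None:
        raise ValueError("phenotype mode needs log_expr and design")
    ga, gb = ranked.groups
    groups = design.groups
    cols = groups[ga] + groups[gb]
    na = len(groups[ga])
    X = log_expr.values[cols].to_numpy(dtype=float)
    genes = log_expr.genes
    null = {name: np.empty(n_perm) for name in kept}
    for it in range(n_perm):
        perm = rng.permutation(len(cols))
        A, B = X[:, perm[:na]], X[:, perm[na:]]
        m = signal_to_noise(A, B)
        order = sorted(range(len(genes)), key=lambda i: (-m[i], genes[i]))
        rl = RankedList([genes[i] for i in order], m[order], (ga, gb))
        w = np.abs(rl.metric) ** weight
        for name in kept:
            pos = rl.positions([ranked.genes[i] for i in positions[name]])
            null[name][it] = _es_from_positions(pos[None, :], w, len(rl))[0]
    return null


def _nes_fdr(nes: np.ndarray, null_nes: np.ndarray) -> np.ndarray:
    """Standard GSEA FDR: ratio of null to observed tail fractions at each NES."""
    q = np.empty_like(nes)
    pos_null, neg_null = null_nes[null_nes >= 0], null_nes[null_nes < 0]
    pos_obs, neg_obs = nes[nes >= 0], nes[nes < 0]
    for i, v in enumerate(nes):
        if v >= 0:
            num = (pos_null >= v).mean() if pos_null.size else 1.0
            den = (pos_obs >= v).mean() if pos_obs.size else 1.0
        else:
            num = (neg_null <= v).mean() if neg_null.size else 1.0
            den = (neg_obs <= v).mean() if neg_obs.size else 1.0
        q[i] = min(1.0, num / den) if den > 0 else 1.0
    return q


def volcano_table(
    result: GseaResult | pd.DataFrame,
    nes_min: float = 1.0,
    p_dark: float = 0.05,
    p_light: float = 0.1,
) -> pd.DataFrame:
    """Class each set for the volcano plot.

    dark_red: NES >= 1 and p <= 0.05; light_red: NES >= 1 and 0.05 < p <= 0.1;
    dark_blue / light_blue mirrored at NES <= -1; everything else unclassed.
    """
    table = result.table.copy() if isinstance(result, GseaResult) else result.copy()
    nes, p = table["nes"], table["p"]
    cls = pd.Series("unclassed", index=table.index)
    cls[(nes >= nes_min) & (p <= p_dark)] = "dark_red"
    cls[(nes >= nes_min) & (p > p_dark) & (p <= p_light)] = "light_red"
    cls[(nes <= -nes_min) & (p <= p_dark)] = "dark_blue"
    cls[(nes <= -nes_min) & (p > p_dark) & (p <= p_light)] = "light_blue"
    table["class"] = cls
    return table
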