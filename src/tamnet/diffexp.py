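"""Per-gene two-way ANOVA (condition x time, optional additive donor block)
with per-time condition contrasts and Benjamini-Hochberg FDR.

The decomposition is the classical fixed-effects one on a balanced design,
computed vectorized across genes from group means:

    SS_effect = sum_l n_l (mean_l - grand)^2        (condition, time, donor)
    SS_int    = SS_cells - SS_condition - SS_time
    SS_resid  = SS_total - all modeled SS
    F         = MS_effect / MS_resid,   p from F(df_effect, df_resid)

With ``block_donor`` the paired donor enters as an additive factor, removing
its sum of squares (and df) from the residual.  Contrasts (co-culture minus
control within one time point) use the pooled ANOVA residual mean square by
default — at four donors per cell the pooled estimate is markedly more stable
than a per-cell variance.

Zero-residual-variance genes are flagged degenerate: a completely flat gene
gets p = 1 (no effect claimed, and the BH denominator stays honest), while a
gene whose variation is fully explained by the effect gets p = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, SampleDesign
from .preprocess import _require_scale

__all__ = [
    "DEResult",
    "fit_two_way_anova",
    "contrast_at_time",
    "adjust_bh",
    "select_de",
    "run_diffexp",
]

_DEGENERATE_TOL = 1e-12


@dataclass
class DEResult:
    """Per-gene ANOVA table plus per-time contrast tables.

    ``anova`` columns: ss_/F_/p_ for condition, time, interaction (and donor
    when blocked), ss_residual, ss_total, degenerate flag.  ``contrasts`` maps
    each time label to a table with log2fc, t, p and BH q.
    """

    anova: pd.DataFrame
    df_resid: int
    ms_resid: pd.Series
    contrasts: dict[str, pd.DataFrame] = field(default_factory=dict)
    blocked: bool = True


def _effect_ss(Y: np.ndarray, labels: list[str], grand: np.ndarray):
    """Sum over samples of (level mean - grand mean)^2, per gene."""
    lab = np.asarray(labels)
    ss = np.zeros(Y.shape[0])
    for lev in dict.fromkeys(labels):
        cols = lab == lev
        m = Y[:, cols].mean(axis=1)
        ss += cols.sum() * (m - grand) ** 2
    return ss


def fit_two_way_anova(
    log_expr: ExpressionMatrix, design: SampleDesign, block_donor: bool = True
) -> DEResult:
    """Fit the gene-wise condition x time ANOVA on a balanced design."""
    _require_scale(log_expr, "log2cpm")
    groups = design.groups
    sizes = {len(v) for v in groups.values()}
    if len(sizes) != 1:
        raise ValueError("only balanced designs are supported for the interaction model")
    if min(sizes) < 2:
        raise ValueError("need >= 2 samples per condition-group")

    samples = design.samples
    Y = log_expr.values[samples].to_numpy(dtype=float)
    n = len(samples)
    cond = list(design.table.loc[samples, "condition"])
    time = list(design.table.loc[samples, "time"])
    cell = [f"{c}|{t}" for c, t in zip(cond, time)]
    donor = list(design.table.loc[samples, "donor"])

    grand = Y.mean(axis=1)
    ss_total = ((Y - grand[:, None]) ** 2).sum(axis=1)
    ss_cond = _effect_ss(Y, cond, grand)
    ss_time = _effect_ss(Y, time, grand)
    ss_cells = _effect_ss(Y, cell, grand)
    ss_int = np.maximum(ss_cells - ss_cond - ss_time, 0.0)

    df_cond = len(design.conditions) - 1
    df_time = len(design.times) - 1
    df_int = df_cond * df_time
    modeled = ss_cells.copy()
    df_model = df_cond + df_time + df_int

    out = {
        "ss_condition": ss_cond,
        "ss_time": ss_time,
        "ss_interaction": ss_int,
    }
    if block_donor:
        counts = pd.crosstab(pd.Series(donor), pd.Series(cell))
        if len(np.unique(counts.to_numpy())) != 1:
            raise ValueError(
                "donor blocking requires every donor equally represented in every "
                "condition x time cell"
            )
        ss_donor = _effect_ss(Y, donor, grand)
        df_donor = len(design.donors) - 1
        modeled = modeled + ss_donor
        df_model += df_donor
        out["ss_donor"] = ss_donor

    ss_resid = np.maximum(ss_total - modeled, 0.0)
    df_resid = n - 1 - df_model
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom left")
    ms_resid = ss_resid / df_resid

    degenerate = ms_resid <= _DEGENERATE_TOL * np.maximum(ss_total, 1.0)

    def f_and_p(ss_eff: np.ndarray, df_eff: int):
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (ss_eff / df_eff) / ms_resid
        p = stats.f.sf(F, df_eff, df_resid)
        flat = degenerate & (ss_eff <= _DEGENERATE_TOL * np.maximum(ss_total, 1.0))
        p = np.where(degenerate, np.where(flat, 1.0, 0.0), p)
        F = np.where(degenerate, np.where(flat, 0.0, np.inf), F)
        return F, p

    for name, ss_eff, df_eff in (
        ("condition", ss_cond, df_cond),
        ("time", ss_time, df_time),
        ("interaction", ss_int, df_int),
    ):
        F, p = f_and_p(ss_eff, df_eff)
        out[f"F_{name}"] = F
        out[f"p_{name}"] = p
    if block_donor:
        F, p = f_and_p(out["ss_donor"], len(design.donors) - 1)
        out["F_donor"] = F
        out["p_donor"] = p

    out["ss_residual"] = ss_resid
    out["ss_total"] = ss_total
    out["degenerate"] = degenerate
    table = pd.DataFrame(out, index=log_expr.genes)
    return DEResult(
        anova=table,
        df_resid=df_resid,
        ms_resid=pd.Series(ms_resid, index=log_expr.genes),
        blocked=block_donor,
    )


def contrast_at_time(
    log_expr: ExpressionMatrix,
    design: SampleDesign,
    time: str,
    anova: DEResult | None = None,
    block_donor: bool = True,
    pooled: bool = True,
) -> pd.DataFrame:
    """Condition contrast (first condition minus second) within one time point.

    ``pooled=True`` (default) uses the full ANOVA residual mean square and its
    df for the t statistic; ``pooled=False`` recomputes a classical pooled
    two-sample variance from the two cells at that time only.
    """
    _require_scale(log_expr, "log2cpm")
    if time not in design.times:
        raise ValueError(f"unknown time {time!r}; design has {design.times}")
    cond_a, cond_b = design.conditions[:2]
    sa = design.samples_of(condition=cond_a, time=time)
    sb = design.samples_of(condition=cond_b, time=time)
    if not sa or not sb:
        raise ValueError(f"missing condition cell at time {time!r}")
    Ya = log_expr.values[sa].to_numpy(dtype=float)
    Yb = log_expr.values[sb].to_numpy(dtype=float)
    na, nb = Ya.shape[1], Yb.shape[1]
    lfc = Ya.mean(axis=1) - Yb.mean(axis=1)

    if pooled:
        if anova is None:
            anova = fit_two_way_anova(log_expr, design, block_donor=block_donor)
        ms = anova.ms_resid.to_numpy()
        df = anova.df_resid
    else:
        ssa = ((Ya - Ya.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        ssb = ((Yb - Yb.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        df = na + nb - 2
        if df < 1:
            raise ValueError("per-subset contrast needs >= 2 samples per cell")
        ms = (ssa + ssb) / df

    se = np.sqrt(ms * (1.0 / na + 1.0 / nb))
    t = np.divide(lfc, se, out=np.zeros_like(lfc), where=se > 0)
    infinite = (se == 0) & (lfc != 0)
    t[infinite] = np.sign(lfc[infinite]) * np.inf
    p = np.where(infinite, 0.0, 2.0 * stats.t.sf(np.abs(np.where(infinite, 0.0, t)), df))
    return pd.DataFrame({"log2fc": lfc, "t": t, "p": p}, index=log_expr.genes)


def adjust_bh(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any() or np.isnan(p).any()):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def run_diffexp(
    log_expr: ExpressionMatrix, design: SampleDesign, block_donor: bool = True
) -> DEResult:
    """ANOVA plus per-time contrasts with BH q-values, in one call."""
    result = fit_two_way_anova(log_expr, design, block_donor=block_donor)
    for time in design.times:
        tab = contrast_at_time(log_expr, design, time, anova=result)
        tab["q"] = adjust_bh(tab["p"].to_numpy())
        result.contrasts[time] = tab
    return result


def select_de(
    result: DEResult, q_max: float = 0.05, min_abs_log2fc: float = 1.0
) -> dict[str, list[str]]:
    """Genes passing q <= q_max and |log2FC| >= min_abs_log2fc per contrast.

    Output order is deterministic: increasing q, then gene id.
    """
    out: dict[str, list[str]] = {}
    for time, tab in result.contrasts.items():
        hit = tab[(tab["q"] <= q_max) & (tab["log2fc"].abs() >= min_abs_log2fc)]
        out[time] = sorted(hit.index, key=lambda g: (hit.loc[g, "q"], g))
    return out
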