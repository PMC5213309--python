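"""End-to-end orchestration: simulate (optional) -> preprocess -> differential
expression -> co-regulation network (+ heatmap clustering) -> SOM overlay ->
GSEA -> GO over-representation -> report.

Every stage reads its inputs from, and writes its artifacts to, a single
output directory as plain TSV/GMT/GraphML/JSON, so any stage can be re-run or
replaced independently and chained stage invocations reproduce the monolithic
run bit-for-bit (the monolithic runner literally calls the stage functions in
sequence through the same files).  All randomness derives from the single
configuration seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexp, goea, gsea, io, network, preprocess, simulate, som

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "ReportBundle", "run_pipeline", "STAGES"]


class PipelineError(RuntimeError):
    """Raised when a stage fails; message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """All paths and stage parameters of one pipeline run.

    Input paths left as None default to the artifacts a previous stage wrote
    into ``out_dir`` (so a simulated run needs no external inputs at all).
    """

    out_dir: str = "tamnet_out"
    # external inputs (optional when simulating)
    counts: str | None = None
    sample_sheet: str | None = None
    gmt: str | None = None
    annotations: str | None = None
    tr_list: str | None = None
    # simulation
    simulate: bool = True
    sim: dict = field(default_factory=dict)
    # preprocessing
    min_cpm: float = 1.0
    n_hc_genes: int = 1000
    n_network_genes: int = 500
    # differential expression
    block_donor: bool = True
    de_q_max: float = 0.05
    de_min_abs_log2fc: float = 1.0
    # network
    r_min: float = 0.7
    # SOM
    som_grid: tuple[int, int] = (8, 8)
    som_epochs: int = 20
    som_margin: float = 0.5
    # GSEA
    gsea_n_perm: int = 1000
    gsea_weight: float = 1.0
    gsea_min_size: int = 5
    gsea_mode: str = "gene_set"
    # GOEA
    goea_q_max: float = 0.05
    overlap_min: float = 0.5
    goea_group: str | None = None  # study list group; default: co-culture at last time
    # global
    seed: int = 0
    plots: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.som_grid = tuple(cfg.som_grid)
        return cfg

    def sim_config(self) -> simulate.SimulationConfig:
        cfg = simulate.default_config(seed=self.seed)
        overrides = dict(self.sim)
        modules = overrides.pop("modules", None)
        for key, val in overrides.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown simulation key {key!r}")
            setattr(cfg, key, val)
        if modules is not None:
            cfg.modules = [simulate.ModuleSpec(**m) for m in modules]
        cfg.seed = self.seed
        return cfg

    def path(self, name: str, default: str) -> Path:
        explicit = getattr(self, name, None)
        return Path(explicit) if explicit else Path(self.out_dir) / default


@dataclass
class ReportBundle:
    summary: dict
    out_dir: Path


# --------------------------------------------------------------------- stages


def stage_simulate(cfg: PipelineConfig) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = cfg.sim_config()
    matrix, design, truth = simulate.generate_dataset(sim_cfg)
    io.write_counts(matrix, out / "counts.tsv")
    io.write_sample_sheet(design, out / "samples.tsv")
    truth.to_json(out / "truth.json")
    sets = simulate.generate_gene_sets(truth, seed=sim_cfg.seed)
    io.write_gmt(sets, out / "gene_sets.gmt")
    ann = simulate.generate_annotations(truth, seed=sim_cfg.seed)
    io.write_annotations(ann, out / "annotations.tsv")
    _write_tr_list(truth, sim_cfg.seed, out / "tr_list.txt")
    logger.info("simulate: %d genes x %d samples", matrix.n_genes, matrix.n_samples)


def _write_tr_list(truth, seed: int, path: Path) -> None:
    # synthetic regulator list: mostly members of the repressed module plus a
    # few from the induced ones, emulating down- and up-regulated regulators
    rng = np.random.default_rng(np.random.SeedSequence([seed, 97]))
    trs: list[str] = []
    for spec in truth.module_specs:
        members = truth.module_members(spec.name)
        down = all(v <= 0 for v in spec.activity.values()) and any(
            v < 0 for v in spec.activity.values()
        )
        n_pick = min(15 if down else 4, len(members))
        trs += list(rng.choice(members, size=n_pick, replace=False))
    background = sorted(set(truth.genes) - set(truth.module_of))
    trs += list(rng.choice(background, size=min(10, len(background)), replace=False))
    path.write_text("\n".join(dict.fromkeys(trs)) + "\n", encoding="utf-8")


def _load_inputs(cfg: PipelineConfig):
    counts = io.read_counts(cfg.path("counts", "counts.tsv"))
    design = io.read_sample_sheet(cfg.path("sample_sheet", "samples.tsv"))
    return counts, design


def stage_preprocess(cfg: PipelineConfig) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts, design = _load_inputs(cfg)
    filtered = preprocess.filter_present(counts, design, min_cpm=cfg.min_cpm)
    io.write_counts(filtered, out / "filtered_counts.tsv")
    log_expr = preprocess.normalize_log_cpm(filtered)
    fc = preprocess.fc_over_mean(log_expr, design)
    fc.to_table().to_csv(out / "fc_overlay.tsv", sep="\t", index=False, float_format="%.10g")
    n_hc = min(cfg.n_hc_genes, filtered.n_genes)
    n_net = min(cfg.n_network_genes, filtered.n_genes)
    payload = {
        "hc_genes": preprocess.top_variable_genes(log_expr, n_hc),
        "network_genes": preprocess.top_variable_genes(log_expr, n_net),
    }
    (out / "variable_genes.json").write_text(
        json.dumps(payload, indent=1, sort_keys=True), encoding="utf-8"
    )
    logger.info("preprocess: %d/%d genes present", filtered.n_genes, counts.n_genes)


def _load_filtered(cfg: PipelineConfig):
    out = Path(cfg.out_dir)
    filtered = io.read_counts(out / "filtered_counts.tsv")
    design = io.read_sample_sheet(cfg.path("sample_sheet", "samples.tsv"))
    log_expr = preprocess.normalize_log_cpm(filtered)
    return filtered, design, log_expr


def stage_de(cfg: PipelineConfig) -> None:
    out = Path(cfg.out_dir)
    _, design, log_expr = _load_filtered(cfg)
    result = diffexp.run_diffexp(log_expr, design, block_donor=cfg.block_donor)
    table = result.anova.copy()
    for time, tab in result.contrasts.items():
        for col in tab.columns:
            table[f"{col}_{time}"] = tab[col]
    table.to_csv(out / "de_table.tsv", sep="\t", index_label="gene", float_format="%.10g")
    selected = diffexp.select_de(result, cfg.de_q_max, cfg.de_min_abs_log2fc)
    (out / "de_selected.json").write_text(
        json.dumps(selected, indent=1, sort_keys=True), encoding="utf-8"
    )
    logger.info(
        "diffexp: selected %s DE genes", {t: len(g) for t, g in selected.items()}
    )


def stage_network(cfg: PipelineConfig) -> None:
    out = Path(cfg.out_dir)
    _, design, log_expr = _load_filtered(cfg)
    var = json.loads((out / "variable_genes.json").read_text(encoding="utf-8"))
    fc = preprocess.fc_over_mean(log_expr, design)

    net = network.build_cra_network(log_expr, var["network_genes"], r_min=cfg.r_min)
    network.detect_clusters(net)
    network.annotate_fc(net, fc)

    summaries = []
    gmt_path = cfg.path("gmt", "gene_sets.gmt")
    if gmt_path.exists():
        sets = io.read_gmt(gmt_path)
        for name in sets.names():
            summaries.append(network.map_gene_set(net, fc, sets.genes_of(name), name))
    tr_path = cfg.path("tr_list", "tr_list.txt")
    if tr_path.exists():
        trs = [l for l in tr_path.read_text(encoding="utf-8").splitlines() if l.strip()]
        summaries.append(network.map_gene_set(net, fc, trs, "TR"))
    if summaries:
        pd.DataFrame([s.to_row() for s in summaries]).to_csv(
            out / "mapping_summary.tsv", sep="\t", index=False
        )

    io.write_network(net.graph, out / "network.graphml", format="graphml")
    io.write_network(net.graph, out / "network_edges.tsv", format="edgelist")
    clusters = pd.DataFrame(
        {
            "gene": list(net.graph.nodes),
            "cluster": [net.graph.nodes[g].get("cluster", "?") for g in net.graph.nodes],
            "subcluster": [net.graph.nodes[g].get("subcluster", "?") for g in net.graph.nodes],
        }
    )
    clusters.to_csv(out / "clusters.tsv", sep="\t", index=False)

    hc = network.hierarchical_cluster(log_expr, var["hc_genes"])
    (out / "hc_orders.json").write_text(
        json.dumps(
            {"gene_order": hc.gene_order, "sample_order": hc.sample_order},
            indent=1, sort_keys=True,
        ),
        encoding="utf-8",
    )
    if cfg.plots:
        _plot_heatmap(hc, out / "plots" / "heatmap.png")
        _plot_network(net, out / "plots" / "network.png", seed=cfg.seed)
    logger.info(
        "network: %d nodes, %d edges, %d clusters",
        net.graph.number_of_nodes(), net.graph.number_of_edges(), len(net.clusters()),
    )


def stage_som(cfg: PipelineConfig) -> None:
    out = Path(cfg.out_dir)
    _, design, log_expr = _load_filtered(cfg)
    profiles = som.zscore_profiles(log_expr, design)
    grid = som.train_som(
        profiles, grid=cfg.som_grid, epochs=cfg.som_epochs, seed=cfg.seed
    )
    table = som.label_and_select(grid, margin=cfg.som_margin)
    table.to_csv(out / "som.tsv", sep="\t", index_label="gene", float_format="%.10g")
    logger.info(
        "som: %d/%d genes condition-specific", int(table["specific"].sum()), len(table)
    )


def stage_gsea(cfg: PipelineConfig) -> None:
    out = Path(cfg.out_dir)
    _, design, log_expr = _load_filtered(cfg)
    gmt_path = cfg.path("gmt", "gene_sets.gmt")
    if not gmt_path.exists():
        raise FileNotFoundError(f"GSEA needs a GMT gene-set file; none at {gmt_path}")
    sets = io.read_gmt(gmt_path)
    cond_a, cond_b = design.conditions[:2]
    for time in design.times:
        ranked = gsea.rank_genes(log_expr, design, f"{cond_a}_{time}", f"{cond_b}_{time}")
        result = gsea.permutation_test(
            ranked, sets, n_perm=cfg.gsea_n_perm, mode=cfg.gsea_mode,
            weight=cfg.gsea_weight, seed=cfg.seed, min_size=cfg.gsea_min_size,
            log_expr=log_expr, design=design,
        )
        table = gsea.volcano_table(result)
        table.to_csv(out / f"gsea_{time}.tsv", sep="\t", index_label="set",
                     float_format="%.10g")
        if cfg.plots:
            _plot_volcano(table, out / "plots" / f"volcano_{time}.png", time)
    logger.info("gsea: tested %d sets per time point", len(sets))


def stage_goea(cfg: PipelineConfig) -> None:
    out = Path(cfg.out_dir)
    filtered, design, log_expr = _load_filtered(cfg)
    ann_path = cfg.path("annotations", "annotations.tsv")
    if not ann_path.exists():
        raise FileNotFoundError(f"GOEA needs an annotation table; none at {ann_path}")
    annotations = io.read_annotations(ann_path)
    fc = preprocess.fc_over_mean(log_expr, design)
    net_genes = set(
        pd.read_csv(out / "clusters.tsv", sep="\t", dtype=str)["gene"]
    )
    group = cfg.goea_group or f"{design.conditions[0]}_{design.times[-1]}"
    study = sorted(set(fc.elevated(group)) & net_genes)
    result = goea.run_goea(study, annotations, filtered.genes, q_max=cfg.goea_q_max)
    result.table.to_csv(out / "goea.tsv", sep="\t", index_label="term",
                        float_format="%.10g")
    emap = goea.build_enrichment_map(result, annotations, overlap_min=cfg.overlap_min)
    io.write_network(emap, out / "enrichment_map.graphml", format="graphml")
    if cfg.plots:
        _plot_enrichment_map(emap, out / "plots" / "enrichment_map.png", seed=cfg.seed)
    logger.info(
        "goea: %d study genes (%s), %d enriched terms",
        len(study), group, len(result.enriched_terms()),
    )


def stage_report(cfg: PipelineConfig) -> dict:
    """Machine-readable run summary built purely from the stage artifacts."""
    out = Path(cfg.out_dir)
    counts = io.read_counts(cfg.path("counts", "counts.tsv"))
    filtered = io.read_counts(out / "filtered_counts.tsv")
    design = io.read_sample_sheet(cfg.path("sample_sheet", "samples.tsv"))
    selected = json.loads((out / "de_selected.json").read_text(encoding="utf-8"))
    clusters = pd.read_csv(out / "clusters.tsv", sep="\t", dtype=str)
    edges = pd.read_csv(out / "network_edges.tsv", sep="\t")
    som_tab = pd.read_csv(out / "som.tsv", sep="\t")
    summary = {
        "seed": cfg.seed,
        "n_samples": counts.n_samples,
        "n_groups": len(design.groups),
        "n_genes_total": counts.n_genes,
        "n_genes_present": filtered.n_genes,
        "n_de": {t: len(g) for t, g in sorted(selected.items())},
        "network": {
            "n_nodes": int(len(clusters)),
            "n_edges": int(len(edges)),
            "clusters": clusters.groupby("cluster").size().to_dict(),
            "subclusters": clusters.groupby("subcluster").size().to_dict(),
        },
        "som": {
            "n_specific": int(som_tab["specific"].sum()),
            "per_label": som_tab[som_tab["specific"]]
            .groupby("label").size().to_dict(),
        },
        "gsea": {},
        "parameters": {
            "min_cpm": cfg.min_cpm,
            "n_hc_genes": cfg.n_hc_genes,
            "n_network_genes": cfg.n_network_genes,
            "r_min": cfg.r_min,
            "de_q_max": cfg.de_q_max,
            "de_min_abs_log2fc": cfg.de_min_abs_log2fc,
            "block_donor": cfg.block_donor,
            "som_grid": list(cfg.som_grid),
            "som_epochs": cfg.som_epochs,
            "gsea_n_perm": cfg.gsea_n_perm,
            "goea_q_max": cfg.goea_q_max,
            "overlap_min": cfg.overlap_min,
        },
    }
    for time in design.times:
        gtab = pd.read_csv(out / f"gsea_{time}.tsv", sep="\t")
        summary["gsea"][time] = gtab.groupby("class").size().to_dict()
    goea_tab = pd.read_csv(out / "goea.tsv", sep="\t")
    summary["goea"] = {"n_tested": int(len(goea_tab)),
                       "n_enriched": int(goea_tab["enriched"].sum())}
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return summary


STAGES = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "de": stage_de,
    "network": stage_network,
    "som": stage_som,
    "gsea": stage_gsea,
    "goea": stage_goea,
    "report": stage_report,
}


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    """Run every stage in order through the shared output directory."""
    order = ["simulate", "preprocess", "de", "network", "som", "gsea", "goea", "report"]
    if not cfg.simulate:
        order = order[1:]
        if cfg.counts is None or cfg.sample_sheet is None:
            raise PipelineError(
                "stage preprocess failed: counts and sample_sheet paths are "
                "required when simulation is disabled"
            )
    summary: dict = {}
    for name in order:
        logger.info("=== stage %s ===", name)
        try:
            result = STAGES[name](cfg)
        except Exception as exc:  # noqa: BLE001 — re-raise with stage context
            raise PipelineError(f"stage {name} failed: {exc}") from exc
        if name == "report":
            summary = result
    return ReportBundle(summary=summary, out_dir=Path(cfg.out_dir))


# ---------------------------------------------------------------------- plots


def _mpl():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def _plot_heatmap(hc, path: Path) -> None:
    plt = _mpl()
    path.parent.mkdir(parents=True, exist_ok=True)
    Z = hc.zscores.loc[hc.gene_order, hc.sample_order]
    fig, ax = plt.subplots(figsize=(6, 8))
    im = ax.imshow(Z.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-3, vmax=3)
    ax.set_xticks(range(len(Z.columns)))
    ax.set_xticklabels(Z.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_title(f"top {Z.shape[0]} variable genes (z-score)")
    fig.colorbar(im, ax=ax, shrink=0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_network(net, path: Path, seed: int = 0) -> None:
    import networkx as nx

    plt = _mpl()
    path.parent.mkdir(parents=True, exist_ok=True)
    G = net.graph
    pos = nx.spring_layout(G, seed=seed)
    clusters = sorted({d.get("cluster", "?") for _, d in G.nodes(data=True)})
    cmap = dict(zip(clusters, ["tab:red", "tab:blue", "tab:green", "tab:orange",
                               "tab:purple", "tab:gray"] * (1 + len(clusters) // 6)))
    colors = [cmap[G.nodes[n].get("cluster", "?")] for n in G.nodes]
    fig, ax = plt.subplots(figsize=(7, 7))
    nx.draw_networkx_edges(G, pos, ax=ax, alpha=0.2)
    nx.draw_networkx_nodes(G, pos, ax=ax, node_size=20, node_color=colors)
    ax.set_title(f"CRA network (r >= {net.r_min})")
    ax.axis("off")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_volcano(table, path: Path, time: str) -> None:
    plt = _mpl()
    path.parent.mkdir(parents=True, exist_ok=True)
    colors = {"dark_red": "#b2182b", "light_red": "#ef8a62", "dark_blue": "#2166ac",
              "light_blue": "#67a9cf", "unclassed": "#bbbbbb"}
    fig, ax = plt.subplots(figsize=(5, 5))
    with np.errstate(divide="ignore"):
        y = -np.log10(table["p"])
    ax.scatter(table["nes"], y, c=[colors[c] for c in table["class"]], s=30)
    ax.axvline(1, ls=":", c="k", lw=0.5)
    ax.axvline(-1, ls=":", c="k", lw=0.5)
    ax.axhline(-np.log10(0.05), ls=":", c="k", lw=0.5)
    ax.set_xlabel("NES")
    ax.set_ylabel("-log10 p")
    ax.set_title(f"GSEA {time}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_enrichment_map(G, path: Path, seed: int = 0) -> None:
    import networkx as nx

    plt = _mpl()
    path.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(6, 6))
    if G.number_of_nodes():
        pos = nx.spring_layout(G, seed=seed)
        qs = np.array([G.nodes[n]["q"] for n in G.nodes])
        sizes = 60 + 240 * (1 - qs / max(qs.max(), 1e-9))
        nx.draw_networkx_edges(G, pos, ax=ax, alpha=0.4)
        nx.draw_networkx_nodes(G, pos, ax=ax, node_size=sizes, node_color="#b2182b")
        nx.draw_networkx_labels(G, pos, ax=ax, font_size=6)
    ax.set_title("enrichment map")
    ax.axis("off")
    fig.savefig(path, dpi=120)
    plt.close(fig)
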