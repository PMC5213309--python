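"""Synthetic RNA-seq count data with planted differential expression and
planted co-regulated gene modules.

The generator emulates the study design the rest of the package analyses: two
culture conditions (tumor co-culture vs. plain-medium control) observed at two
release time points in four paired donors, i.e. four condition-groups and
sixteen samples.  Counts are negative-binomial around a library-size-scaled
mean whose log2 is::

    baseline_g + de_offset(g, group) + donor_offset(d)
               + activity_m(group) + loading_m * factor_{m, sample}

The latent-factor module model (one shared standard-normal factor per module
per sample, scaled by a loading in (0, 1]) plants positive pairwise
correlation among module members without building an explicit covariance
matrix, so simulation stays O(genes) and the implied structure is always
positive-definite.  Module ``activity`` (a log2 offset per condition-group)
makes a module "on" in specific groups, the analogue of time-specific network
clusters.

Everything downstream can be scored against the returned
:class:`SyntheticTruth` without re-reading the configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, SampleDesign

__all__ = [
    "ModuleSpec",
    "SimulationConfig",
    "SyntheticTruth",
    "default_config",
    "generate_dataset",
    "generate_gene_sets",
    "generate_annotations",
]


@dataclass
class ModuleSpec:
    """A planted co-regulated gene module.

    Parameters
    ----------
    size:
        Number of member genes (>= 3).
    activity:
        Log2 expression offset per condition-group label; groups absent from
        the mapping get offset 0.  Defines when the module is "on".
    within_loading:
        Loading in (0, 1] on the shared per-sample standard-normal factor;
        larger values give tighter member co-expression.
    name:
        Module label used in the truth object (defaults assigned M1, M2, ...).
    """

    size: int
    activity: dict[str, float] = field(default_factory=dict)
    within_loading: float = 0.9
    name: str = ""

    def validate(self) -> None:
        if self.size < 3:
            raise ValueError(f"module size must be >= 3, got {self.size}")
        if not (0 < self.within_loading <= 1):
            raise ValueError("within_loading must lie in (0, 1]")
        for g, a in self.activity.items():
            if not np.isfinite(a):
                raise ValueError(f"non-finite activity for group {g!r}")


@dataclass
class SimulationConfig:
    """Full description of one synthetic dataset.

    Defaults emulate the modeled experiment: 2 conditions x 2 times x 4
    paired donors = 16 samples, three time-specific modules and 50 planted
    differentially expressed genes per time contrast at |log2FC| = 2.
    """

    n_genes: int = 2000
    n_donors: int = 4
    conditions: tuple[str, str] = ("TPC1", "RPMI")
    times: tuple[str, str] = ("4h", "24h")
    n_de_per_contrast: int = 50
    de_log2fc: float = 2.0
    modules: list[ModuleSpec] = field(default_factory=list)
    nb_dispersion: float = 0.1
    donor_sd: float = 0.25
    lib_size_meanlog: float = float(np.log(5e6))
    lib_size_sdlog: float = 0.2
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_donors < 1:
            raise ValueError("n_genes and n_donors must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.donor_sd < 0:
            raise ValueError("donor_sd must be >= 0")
        if self.de_log2fc < 0:
            raise ValueError("de_log2fc must be >= 0")
        if len(self.conditions) != 2 or len(self.times) != 2:
            raise ValueError("exactly two conditions and two times are supported")
        for m in self.modules:
            m.validate()
        committed = sum(m.size for m in self.modules) + 2 * self.n_de_per_contrast
        if committed > self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} too small for "
                f"{sum(m.size for m in self.modules)} module genes plus "
                f"{2 * self.n_de_per_contrast} DE genes"
            )

    @property
    def group_names(self) -> list[str]:
        return [f"{c}_{t}" for c in self.conditions for t in self.times]


def default_config(seed: int = 0) -> SimulationConfig:
    """The stated default world: three modules analogous to an early-response
    cluster (on in co-culture at 4 h), a late-response cluster (on at 24 h) and
    a repressed cluster (down in co-culture at both times)."""
    cfg = SimulationConfig(seed=seed)
    tpc, rpmi = cfg.conditions
    t4, t24 = cfg.times
    cfg.modules = [
        ModuleSpec(50, {f"{tpc}_{t4}": 2.0}, 0.9, name="M_early"),
        ModuleSpec(50, {f"{tpc}_{t24}": 2.0}, 0.9, name="M_late"),
        ModuleSpec(
            50,
            {f"{tpc}_{t4}": -2.0, f"{tpc}_{t24}": -2.0},
            0.9,
            name="M_down",
        ),
    ]
    return cfg


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated dataset.

    ``de_genes`` maps each time contrast (condition effect within a time) to
    its planted gene set; ``de_log2fc`` carries the signed planted effect.
    ``module_of`` maps member genes to a module label; assignments are
    disjoint and DE genes are never module members.
    """

    genes: list[str]
    de_genes: dict[str, list[str]]
    de_log2fc: dict[str, float]
    module_of: dict[str, str]
    module_specs: list[ModuleSpec]

    def module_members(self, name: str) -> list[str]:
        return [g for g, m in self.module_of.items() if m == name]

    def to_json(self, path) -> None:
        payload = {
            "genes": self.genes,
            "de_genes": self.de_genes,
            "de_log2fc": self.de_log2fc,
            "module_of": self.module_of,
            "module_specs": [asdict(m) for m in self.module_specs],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        specs = [ModuleSpec(**m) for m in payload["module_specs"]]
        return cls(
            genes=payload["genes"],
            de_genes=payload["de_genes"],
            de_log2fc=payload["de_log2fc"],
            module_of=payload["module_of"],
            module_specs=specs,
        )


def _design_table(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for cond in config.conditions:
        for time in config.times:
            for d in range(1, config.n_donors + 1):
                donor = f"D{d}"
                rows.append((f"{cond}_{time}_{donor}", cond, time, donor))
    tab = pd.DataFrame(rows, columns=["sample", "condition", "time", "donor"])
    return tab.set_index("sample")


def generate_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleDesign, SyntheticTruth]:
    """Draw one seeded dataset: counts matrix, sample design and ground truth.

    All randomness flows from ``config.seed`` through deterministically
    derived per-stage substreams, so the same configuration always yields a
    byte-identical matrix.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    # fixed substream order: baseline/dispersion, donors, DE, modules, library, counts
    streams = [np.random.default_rng(s) for s in ss.spawn(6)]
    rng_base, rng_donor, rng_de, rng_mod, rng_lib, rng_counts = streams

    design = SampleDesign(_design_table(config))
    samples = design.samples
    n_samples = len(samples)
    genes = [f"G{i:05d}" for i in range(1, config.n_genes + 1)]
    group_of = design.group

    baseline = rng_base.normal(
        config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes
    )
    # gene-wise dispersion: inverse-gamma-like spread around nb_dispersion
    disp = 3.0 * config.nb_dispersion / rng_base.gamma(4.0, 1.0, config.n_genes)
    disp = np.clip(disp, 1e-4, None)

    donor_offset = {
        d: rng_donor.normal(0.0, config.donor_sd) if config.donor_sd > 0 else 0.0
        for d in design.donors
    }

    log2_mu = np.tile(baseline[:, None], (1, n_samples))
    for j, s in enumerate(samples):
        log2_mu[:, j] += donor_offset[design.table.loc[s, "donor"]]

    # planted DE genes: distinct genes per time contrast, alternating sign,
    # offset applied to the first (co-culture) condition at that time only
    pool = list(range(config.n_genes))
    de_genes: dict[str, list[str]] = {}
    de_lfc: dict[str, float] = {}
    cursor = 0
    tumor = config.conditions[0]
    for time in config.times:
        idx = pool[cursor : cursor + config.n_de_per_contrast]
        cursor += config.n_de_per_contrast
        de_genes[time] = [genes[i] for i in idx]
        cols = [j for j, s in enumerate(samples)
                if group_of[s] == f"{tumor}_{time}"]
        for rank, i in enumerate(idx):
            sign = 1.0 if rank % 2 == 0 else -1.0
            log2_mu[i, cols] += sign * config.de_log2fc
            de_lfc[genes[i]] = sign * config.de_log2fc
    del rng_de  # reserved substream (kept for layout stability)

    # planted modules: shared per-sample factor plus group activity offsets
    module_of: dict[str, str] = {}
    for k, spec in enumerate(config.modules):
        name = spec.name or f"M{k + 1}"
        spec.name = name
        idx = pool[cursor : cursor + spec.size]
        cursor += spec.size
        for i in idx:
            module_of[genes[i]] = name
        factor = rng_mod.standard_normal(n_samples)
        activity = np.array(
            [spec.activity.get(group_of[s], 0.0) for s in samples]
        )
        log2_mu[idx, :] += activity[None, :] + spec.within_loading * factor[None, :]

    lib_sizes = rng_lib.lognormal(
        config.lib_size_meanlog, config.lib_size_sdlog, n_samples
    )

    rel = np.exp2(log2_mu)
    frac = rel / rel.sum(axis=0, keepdims=True)
    mu = frac * lib_sizes[None, :]
    # NB with var = mu + disp * mu^2
    r = 1.0 / disp[:, None]
    p = r / (r + mu)
    counts = rng_counts.negative_binomial(np.broadcast_to(r, mu.shape), p)

    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=genes, columns=samples), scale="counts"
    )
    truth = SyntheticTruth(
        genes=genes,
        de_genes=de_genes,
        de_log2fc=de_lfc,
        module_of=module_of,
        module_specs=list(config.modules),
    )
    return matrix, design, truth


def generate_gene_sets(
    truth: SyntheticTruth,
    n_random_sets: int = 20,
    set_size_range: tuple[int, int] = (15, 50),
    seed: int = 0,
    decoy_fraction: float = 0.2,
):
    """Gene-set collection with one "true" set per planted module plus random sets.

    Each true set keeps ``1 - decoy_fraction`` of its members from the module
    and fills the rest with decoys drawn from outside the module, mimicking the
    partial overlap between curated pathway sets and the co-regulated genes
    they describe.  Random sets are drawn uniformly from the gene universe.
    """
    from .io import GeneSetCollection

    if not truth.genes:
        raise ValueError("empty gene universe")
    lo, hi = set_size_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid set_size_range {set_size_range}")
    if hi > len(truth.genes):
        raise ValueError("set size exceeds universe size")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    universe = np.array(truth.genes)
    sets: dict[str, tuple[str, list[str]]] = {}
    for spec in truth.module_specs:
        members = truth.module_members(spec.name)
        n_true = int(round((1.0 - decoy_fraction) * spec.size))
        chosen = list(rng.choice(members, size=n_true, replace=False))
        outside = np.array(sorted(set(truth.genes) - set(members)))
        n_decoy = spec.size - n_true
        if n_decoy > 0:
            chosen += list(rng.choice(outside, size=n_decoy, replace=False))
        sets[f"TRUE_{spec.name}"] = (f"planted module {spec.name}", chosen)
    for k in range(n_random_sets):
        size = int(rng.integers(lo, hi + 1))
        members = list(rng.choice(universe, size=size, replace=False))
        sets[f"RANDOM_{k + 1:03d}"] = ("random set", members)
    return GeneSetCollection(sets)


def generate_annotations(
    truth: SyntheticTruth,
    n_terms: int = 50,
    seed: int = 0,
    term_size_range: tuple[int, int] = (15, 50),
    module_fraction: float = 0.8,
):
    """Flat term -> gene annotation table with one term per planted module.

    Module terms take ``module_fraction`` of their genes from the module (so
    they are enriched by construction in a study list drawn from the module)
    and the rest from elsewhere; remaining terms are uniform random draws.
    """
    from .io import TermAnnotation

    if not truth.genes:
        raise ValueError("empty gene universe")
    lo, hi = term_size_range
    if hi > len(truth.genes) or lo < 1 or hi < lo:
        raise ValueError(f"invalid term_size_range {term_size_range}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    universe = np.array(truth.genes)
    terms: dict[str, tuple[str, set[str]]] = {}
    for spec in truth.module_specs:
        members = truth.module_members(spec.name)
        n_in = int(round(module_fraction * spec.size))
        chosen = set(rng.choice(members, size=n_in, replace=False))
        outside = np.array(sorted(set(truth.genes) - set(members)))
        n_out = max(spec.size - n_in, 0)
        if n_out > 0:
            chosen |= set(rng.choice(outside, size=n_out, replace=False))
        tid = f"T_{spec.name}"
        terms[tid] = (f"planted term for {spec.name}", chosen)
    n_random = max(n_terms - len(terms), 0)
    for k in range(n_random):
        size = int(rng.integers(lo, hi + 1))
        tid = f"T{k + 1:04d}"
        terms[tid] = ("random term", set(rng.choice(universe, size=size, replace=False)))
    return TermAnnotation(terms)
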