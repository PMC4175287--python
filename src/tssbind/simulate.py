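"""Seeded synthetic-data generators with planted ground truth.

Every input the analysis pipeline consumes can be generated here with a
known latent state, so each module's output can be checked against what was
planted rather than against itself:

* a genome layout and genes with CAGE-like log-normal expression (a
  configurable fraction silent);
* TSS-centred ChIP peaks whose per-gene binding probability is logistic in
  log-expression, with replicate-level reproducibility, positional jitter
  and uniform background peaks;
* a compendium of weight tracks drawn from archetypes — polymerase-like
  tracks weighted by expression at TSSs, open-chromatin-like variants,
  repressive (anti-expression) tracks covering silent genes, and uniformly
  random tracks;
* methylation probes with a planted beta shift at bound genes;
* a two-construct knockdown experiment with bidirectional effects planted
  in disjoint subsets of bound genes;
* a hub-structured linear co-expression model Y = XB + E over a declared
  TF set.

Generators are pure functions of (config, seed): each pipeline stage draws
from its own child stream of one root seed, so regenerating one input never
perturbs the others.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .genome import GeneAnnotation, GenomeLayout, Peak, PeakSet
from .tracks import TrackLabel, WeightTrack, track_from_peaks

__all__ = [
    "SimulationConfig",
    "World",
    "paperlike_small",
    "generate_world",
    "generate_peaks",
    "generate_track",
    "generate_compendium",
    "generate_methylation",
    "generate_knockdown",
    "generate_expression_matrix",
    "load_config",
    "save_config",
]


@dataclass
class GenomeConfig:
    n_chromosomes: int = 2
    chromosome_length: int = 5_000_000


@dataclass
class ExpressionConfig:
    """Log-normal CAGE tag counts with a point mass at zero."""

    mu: float = 2.5
    sigma: float = 2.0
    zero_fraction: float = 0.25


@dataclass
class BindingConfig:
    """P(bound) = sigmoid(intercept + slope * log10(1 + expression))."""

    slope: float = 2.0
    intercept: float = -3.0
    jitter_sd: float = 300.0
    peak_width_mean: float = 400.0
    peak_width_sd: float = 100.0
    background_per_mb: float = 5.0
    reproducibility: float = 0.85


@dataclass
class TrackArchetype:
    """One compendium archetype: how tracks of this factor place weight."""

    factor: str
    mode: str  # expression_weighted | uniform | anti_expression | random
    width: int = 400
    count: int = 1
    cell_type: str = "synthetic"
    n_random_intervals: int = 2000

    def __post_init__(self) -> None:
        allowed = {"expression_weighted", "uniform", "anti_expression", "random"}
        if self.mode not in allowed:
            raise ValueError(f"unknown archetype mode {self.mode!r}")


@dataclass
class CompendiumConfig:
    archetypes: list[TrackArchetype] = field(
        default_factory=lambda: [
            TrackArchetype("POL2", "expression_weighted", width=400, count=10),
            TrackArchetype("OpenChromSynth", "expression_weighted", width=800, count=5),
            TrackArchetype("H3K9me3", "anti_expression", width=800, count=5),
            TrackArchetype("RANDOM", "random", width=400, count=30),
        ]
    )
    query: TrackArchetype = field(
        default_factory=lambda: TrackArchetype("DEK", "expression_weighted", width=400)
    )
    track_noise_sd: float = 0.5  # per-gene lognormal height noise
    keep_fraction: float = 0.9  # genes retained per track


@dataclass
class MethylationConfig:
    beta_a: float = 4.0
    beta_b: float = 2.0
    bound_delta: float = -0.2
    probe_sd: float = 0.1
    probes_per_gene: float = 3.0  # Poisson mean, floored at 1


@dataclass
class KnockdownConfig:
    n_genes: int = 15_000
    n_bound: int = 1_500
    frac_up: float = 0.3
    frac_down: float = 0.3
    effect_log2: float = 1.0
    replicate_sd: float = 0.2
    n_replicates: int = 3
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0


@dataclass
class NetworkConfig:
    n_tfs: int = 20
    n_targets: int = 200
    n_samples: int = 300
    hub_degree: int = 50
    other_degree: int = 5
    coef_scale: float = 1.0
    noise_sd: float = 0.5
    hub_tf: str = "TF00"


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 5_000
    min_spacing: int = 1_500
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    binding: BindingConfig = field(default_factory=BindingConfig)
    compendium: CompendiumConfig = field(default_factory=CompendiumConfig)
    methylation: MethylationConfig = field(default_factory=MethylationConfig)
    knockdown: KnockdownConfig = field(default_factory=KnockdownConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        comp = d.get("compendium")
        if comp is not None:
            comp = dict(comp)
            comp["archetypes"] = [TrackArchetype(**a) for a in comp.get("archetypes", [])]
            if isinstance(comp.get("query"), dict):
                comp["query"] = TrackArchetype(**comp["query"])
            d["compendium"] = CompendiumConfig(**comp)
        for key, sub in (
            ("genome", GenomeConfig),
            ("expression", ExpressionConfig),
            ("binding", BindingConfig),
            ("methylation", MethylationConfig),
            ("knockdown", KnockdownConfig),
            ("network", NetworkConfig),
        ):
            if isinstance(d.get(key), dict):
                d[key] = sub(**d[key])
        return cls(**d)


def paperlike_small(seed: int = 0) -> SimulationConfig:
    """The packaged default scale: a desk-sized stand-in for the real study.

    Two 5-Mb chromosomes carrying 5000 genes, a 50-track compendium plus one
    query, a 15000-gene knockdown universe and a 20 TF x 200 target x 300
    sample co-expression model. The whole pipeline runs in minutes on one
    CPU at this scale.
    """
    return SimulationConfig(seed=seed)


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        return SimulationConfig.from_dict(yaml.safe_load(fh))


def save_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


@dataclass
class World:
    """A generated genome, its genes, and the latent truth record."""

    layout: GenomeLayout
    genes: list[GeneAnnotation]
    truth: dict
    config: SimulationConfig

    @property
    def bound_genes(self) -> set[str]:
        return self.truth["bound_genes"]


# module-indexed child streams of the root seed, so regenerating one input
# never shifts the randomness of another
_STREAMS = {
    "world": 0,
    "peaks": 1,
    "tracks": 2,
    "methylation": 3,
    "knockdown": 4,
    "network": 5,
}


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(_STREAMS[stream],))
    )


def generate_world(config: SimulationConfig) -> World:
    """Place genes uniformly with minimum spacing; draw expression and binding.

    The truth record stores the per-gene binding probability, the realised
    bound set and the expression category mixture, which downstream recovery
    tests consume directly.
    """
    rng = _rng(config, "world")
    g = config.genome
    layout = GenomeLayout(
        tuple((f"chr{i + 1}", g.chromosome_length) for i in range(g.n_chromosomes))
    )
    lengths = np.array([l for _, l in layout.chromosomes], dtype=float)
    # genes allocated to chromosomes proportional to length
    alloc = np.floor(lengths / lengths.sum() * config.n_genes).astype(int)
    alloc[0] += config.n_genes - alloc.sum()
    genes: list[GeneAnnotation] = []
    gid = 0
    for (chrom, L), n_c in zip(layout.chromosomes, alloc):
        span = L - n_c * config.min_spacing
        if span <= 0:
            raise ValueError(
                f"{n_c} genes at spacing {config.min_spacing} do not fit {chrom} ({L} bp)"
            )
        # uniform order statistics + cumulative spacing = uniform with min gap
        base = np.sort(rng.random(n_c)) * span
        tss = (base + np.arange(n_c) * config.min_spacing).astype(int)
        strands = rng.choice(["+", "-"], size=n_c)
        for t, s in zip(tss, strands):
            genes.append(GeneAnnotation(f"g{gid:05d}", chrom, str(s), int(t)))
            gid += 1

    e = config.expression
    silent = rng.random(len(genes)) < e.zero_fraction
    expr = np.where(silent, 0.0, rng.lognormal(e.mu, e.sigma, size=len(genes)))
    b = config.binding
    p_bound = 1.0 / (1.0 + np.exp(-(b.intercept + b.slope * np.log10(1 + expr))))
    is_bound = rng.random(len(genes)) < p_bound
    for gene, x, flag in zip(genes, expr, is_bound):
        gene.expression = float(np.round(x, 3))
        gene.bound = bool(flag)
    truth = {
        "bound_genes": {g_.gene_id for g_, f in zip(genes, is_bound) if f},
        "p_bound": {g_.gene_id: float(p) for g_, p in zip(genes, p_bound)},
        "zero_fraction_realised": float(silent.mean()),
    }
    return World(layout=layout, genes=genes, truth=truth, config=config)


def _peak_at(
    layout: GenomeLayout,
    chrom: str,
    mid: float,
    width: float,
    score: float | None = None,
) -> Peak | None:
    L = layout.length(chrom)
    w = max(int(round(width)), 10)
    start = int(round(mid)) - w // 2
    start = min(max(start, 0), L - w)
    if start < 0:
        return None
    return Peak(chrom, start, start + w, score)


def generate_peaks(
    world: World, config: SimulationConfig | None = None
) -> tuple[PeakSet, PeakSet, set[str]]:
    """Two replicate peak sets plus the true bound set.

    Each truly bound gene gets a TSS-centred peak in each replicate
    independently with probability ``reproducibility``, jittered by
    Normal(0, jitter_sd); background peaks land uniformly at the configured
    per-Mb rate.
    """
    config = config or world.config
    rng = _rng(config, "peaks")
    b = config.binding
    replicates = []
    for _ in range(2):
        peaks: list[Peak] = []
        for gene in world.genes:
            if not gene.bound:
                continue
            if rng.random() >= b.reproducibility:
                continue
            mid = gene.tss + rng.normal(0, b.jitter_sd) if b.jitter_sd > 0 else gene.tss
            width = max(rng.normal(b.peak_width_mean, b.peak_width_sd), 50)
            p = _peak_at(world.layout, gene.chrom, mid, width)
            if p is not None:
                peaks.append(p)
        n_bg = rng.poisson(b.background_per_mb * world.layout.n_basepairs / 1e6)
        lengths = np.array([world.layout.length(c) for c in world.layout.names], float)
        ci = rng.choice(len(lengths), size=n_bg, p=lengths / lengths.sum())
        for c in ci:
            chrom = world.layout.names[int(c)]
            width = max(rng.normal(b.peak_width_mean, b.peak_width_sd), 50)
            mid = rng.random() * lengths[int(c)]
            p = _peak_at(world.layout, chrom, mid, width)
            if p is not None:
                peaks.append(p)
        replicates.append(PeakSet(peaks, layout=world.layout))
    return replicates[0], replicates[1], set(world.bound_genes)


def generate_track(
    world: World,
    archetype: TrackArchetype,
    rng: np.random.Generator,
    experiment_id: str = "",
    track_noise_sd: float = 0.5,
    keep_fraction: float = 0.9,
) -> WeightTrack:
    """One weight track drawn from an archetype.

    ``expression_weighted`` places weight at each expressed gene's TSS with
    height proportional to log(1 + expression); ``uniform`` covers every TSS
    equally; ``anti_expression`` covers only silent genes (a repressive-mark
    surrogate); ``random`` scatters intervals uniformly. Per-gene lognormal
    height noise and random gene dropout make tracks of one archetype
    resemble, not duplicate, each other.
    """
    label = TrackLabel(archetype.factor, archetype.cell_type, experiment_id)
    if archetype.width <= 0:
        return WeightTrack(world.layout, {}, label=label)
    peaks: list[Peak] = []
    if archetype.mode == "random":
        lengths = np.array([world.layout.length(c) for c in world.layout.names], float)
        ci = rng.choice(len(lengths), size=archetype.n_random_intervals, p=lengths / lengths.sum())
        for c in ci:
            chrom = world.layout.names[int(c)]
            mid = rng.random() * lengths[int(c)]
            h = float(rng.lognormal(0, 1))
            p = _peak_at(world.layout, chrom, mid, 2 * archetype.width, score=h)
            if p is not None:
                peaks.append(p)
    else:
        for gene in world.genes:
            if archetype.mode == "expression_weighted":
                if gene.expression <= 0:
                    continue
                height = float(np.log1p(gene.expression))
            elif archetype.mode == "anti_expression":
                if gene.expression > 0:
                    continue
                height = 1.0
            else:  # uniform
                height = 1.0
            if rng.random() >= keep_fraction:
                continue
            height *= float(rng.lognormal(0, track_noise_sd))
            p = _peak_at(
                world.layout, gene.chrom, gene.tss, 2 * archetype.width, score=height
            )
            if p is not None:
                peaks.append(p)
    return track_from_peaks(PeakSet(peaks, layout=world.layout), world.layout, label=label)


def generate_compendium(
    world: World, config: SimulationConfig | None = None
) -> tuple[WeightTrack, list[WeightTrack]]:
    """The query track plus the full archetype compendium."""
    config = config or world.config
    rng = _rng(config, "tracks")
    comp = config.compendium
    query = generate_track(
        world,
        comp.query,
        rng,
        experiment_id="QUERY",
        track_noise_sd=comp.track_noise_sd,
        keep_fraction=comp.keep_fraction,
    )
    tracks = []
    for arch in comp.archetypes:
        for i in range(arch.count):
            tracks.append(
                generate_track(
                    world,
                    arch,
                    rng,
                    experiment_id=f"{arch.factor}_{i:02d}",
                    track_noise_sd=comp.track_noise_sd,
                    keep_fraction=comp.keep_fraction,
                )
            )
    return query, tracks


def generate_methylation(
    world: World, config: SimulationConfig | None = None
) -> tuple[pd.DataFrame, dict]:
    """Probe-level beta values with a planted shift at bound genes.

    Each gene draws a baseline grade from Beta(a, b); bound genes are
    shifted by ``bound_delta``; probes add Normal(0, probe_sd) noise and are
    clipped to [0, 1]. Probe counts are Poisson, floored at one.
    """
    config = config or world.config
    rng = _rng(config, "methylation")
    m = config.methylation
    rows = []
    gene_base = {}
    pid = 0
    for gene in world.genes:
        base = rng.beta(m.beta_a, m.beta_b)
        if gene.bound:
            base += m.bound_delta
        base = float(np.clip(base, 0, 1))
        gene_base[gene.gene_id] = base
        n_probes = max(1, int(rng.poisson(m.probes_per_gene)))
        betas = np.clip(rng.normal(base, m.probe_sd, size=n_probes), 0, 1)
        for b_ in betas:
            rows.append((f"p{pid:06d}", gene.gene_id, float(b_)))
            pid += 1
    probes = pd.DataFrame(rows, columns=["probe_id", "gene_id", "beta"])
    return probes, {"gene_base": gene_base, "bound_delta": m.bound_delta}


def generate_knockdown(
    world: World, config: SimulationConfig | None = None
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Two-construct knockdown expression matrices with planted effects.

    The measured universe is array-scale: the world's genes plus unbound
    filler genes up to ``n_genes``. The bound subset is the world's true
    bound set, padded (or subsampled) to ``n_bound``. Disjoint fractions of
    the bound genes are shifted up and down by ``effect_log2`` in both
    constructs; everything else is null. Values are log2 intensities.
    """
    config = config or world.config
    rng = _rng(config, "knockdown")
    k = config.knockdown
    gene_ids = [g.gene_id for g in world.genes]
    if len(gene_ids) > k.n_genes:
        gene_ids = gene_ids[: k.n_genes]
    filler = [f"x{j:05d}" for j in range(k.n_genes - len(gene_ids))]
    universe = gene_ids + filler

    world_bound = sorted(world.bound_genes & set(universe))
    if len(world_bound) >= k.n_bound:
        bound = set(rng.choice(world_bound, size=k.n_bound, replace=False))
    else:
        extra_pool = [g for g in universe if g not in world.bound_genes]
        extra = rng.choice(extra_pool, size=k.n_bound - len(world_bound), replace=False)
        bound = set(world_bound) | set(map(str, extra))

    bound_sorted = sorted(bound)
    n_up = int(round(k.frac_up * len(bound_sorted)))
    n_down = int(round(k.frac_down * len(bound_sorted)))
    chosen = rng.choice(bound_sorted, size=n_up + n_down, replace=False)
    up, down = set(map(str, chosen[:n_up])), set(map(str, chosen[n_up:]))

    baseline = rng.normal(k.baseline_mean, k.baseline_sd, size=len(universe))
    effect = np.array(
        [
            k.effect_log2 if g in up else -k.effect_log2 if g in down else 0.0
            for g in universe
        ]
    )
    matrices: dict[str, pd.DataFrame] = {}
    for construct in ("sh1", "sh2"):
        for arm, shift in (("ctrl", 0.0), ("kd", 1.0)):
            cols = {}
            for r in range(k.n_replicates):
                cols[f"{construct}_{arm}_r{r + 1}"] = (
                    baseline + shift * effect + rng.normal(0, k.replicate_sd, len(universe))
                )
            matrices[f"{construct}_{arm}"] = pd.DataFrame(cols, index=universe)
    truth = {"up": up, "down": down, "bound": bound, "universe": universe}
    return matrices, truth


def generate_expression_matrix(
    world: World, config: SimulationConfig | None = None
) -> tuple[pd.DataFrame, list[str], dict]:
    """Samples x genes matrix from a hub-structured linear model Y = XB + E.

    One hub TF drives ``hub_degree`` targets; every other TF drives
    ``other_degree``. TF expressions are independent standard normals;
    coefficients have magnitude Uniform(0.5, 1.5) * coef_scale with random
    sign. Returns (matrix, tf_list, truth) where truth holds the planted
    coefficient matrix.
    """
    config = config or world.config
    rng = _rng(config, "network")
    n = config.network
    tf_ids = [f"TF{i:02d}" for i in range(n.n_tfs)]
    if n.hub_tf not in tf_ids:
        raise ValueError(f"hub_tf {n.hub_tf!r} not among generated TFs")
    target_ids = [f"tg{i:03d}" for i in range(n.n_targets)]
    X = rng.standard_normal((n.n_samples, n.n_tfs))
    B = np.zeros((n.n_tfs, n.n_targets))
    for i, tf in enumerate(tf_ids):
        deg = n.hub_degree if tf == n.hub_tf else n.other_degree
        targets = rng.choice(n.n_targets, size=deg, replace=False)
        signs = rng.choice([-1.0, 1.0], size=deg)
        B[i, targets] = signs * rng.uniform(0.5, 1.5, size=deg) * n.coef_scale
    Y = X @ B + rng.normal(0, n.noise_sd, size=(n.n_samples, n.n_targets))
    data = pd.DataFrame(
        np.hstack([X, Y]),
        index=[f"s{j:04d}" for j in range(n.n_samples)],
        columns=tf_ids + target_ids,
    )
    truth = {
        "B": pd.DataFrame(B, index=tf_ids, columns=target_ids),
        "hub_tf": n.hub_tf,
        "true_edges": {
            (tf_ids[i], target_ids[j]) for i, j in zip(*np.nonzero(B))
        },
    }
    return data, tf_ids, truth
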