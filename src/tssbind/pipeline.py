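"""End-to-end orchestration: simulate inputs, run every analysis, manifest.

``write_simulation_inputs`` materialises a synthetic study as plain-text
files (BED peaks, bedGraph tracks + manifest, TSV tables, truth.json);
``run_all`` consumes such a directory — or any directory holding the same
files derived from real data — resolves every input up front, executes the
stages in dependency order and writes figure/table surrogates plus a JSON
run manifest with per-output checksums.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import enrichment as enr
from . import expression as expr
from . import genome as gm
from . import io as tio
from . import knockdown as kd
from . import network as net
from . import simulate as sim
from . import tracks as trk

__all__ = ["RunManifest", "write_simulation_inputs", "run_all"]

INPUT_FILES = {
    "genome": "genome.chrom.sizes",
    "peaks_rep1": "peaks_rep1.bed",
    "peaks_rep2": "peaks_rep2.bed",
    "genes": "genes.tsv",
    "compendium_manifest": "compendium/manifest.tsv",
    "probes": "methylation_probes.tsv",
    "kd_sh1_ctrl": "kd_sh1_ctrl.tsv",
    "kd_sh1_kd": "kd_sh1_kd.tsv",
    "kd_sh2_ctrl": "kd_sh2_ctrl.tsv",
    "kd_sh2_kd": "kd_sh2_kd.tsv",
    "expression_matrix": "expression_matrix.tsv",
    "tf_list": "tf_list.txt",
    "annotation": "term_annotation.tsv",
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    seed: int
    stages: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    def record(self, stage: str, outputs: list[Path]) -> None:
        self.stages[stage] = {str(p): _sha256(p) for p in outputs}

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "seed": self.seed,
                    "stages": self.stages,
                    "summary": self.summary,
                },
                fh,
                indent=2,
                default=str,
            )


def _synthetic_term_annotation(
    world: sim.World, rng: np.random.Generator, n_random_terms: int = 10
) -> pd.DataFrame:
    """A gene -> term map with one term planted to overlap the bound set."""
    ids = [g.gene_id for g in world.genes]
    bound = sorted(world.bound_genes)
    rows = []
    planted = set(rng.choice(bound, size=int(0.6 * len(bound)), replace=False)) | set(
        rng.choice(ids, size=int(0.02 * len(ids)), replace=False)
    )
    for g in sorted(planted):
        rows.append((g, "TERM_PLANTED"))
    for t in range(n_random_terms):
        size = min(int(rng.integers(50, 400)), len(ids) // 2)
        for g in rng.choice(ids, size=size, replace=False):
            rows.append((str(g), f"TERM_R{t:02d}"))
    return pd.DataFrame(rows, columns=["gene_id", "term_id"])


def write_simulation_inputs(config: sim.SimulationConfig, out_dir) -> dict[str, Path]:
    """Generate a full synthetic study and write it as pipeline input files."""
    out = Path(out_dir)
    (out / "compendium").mkdir(parents=True, exist_ok=True)
    world = sim.generate_world(config)
    paths = {k: out / v for k, v in INPUT_FILES.items()}

    world.layout.to_chrom_sizes(paths["genome"])
    rep1, rep2, _ = sim.generate_peaks(world)
    tio.write_bed(rep1, paths["peaks_rep1"])
    tio.write_bed(rep2, paths["peaks_rep2"])
    tio.write_tss_table(world.genes, paths["genes"])

    query, compendium = sim.generate_compendium(world)
    manifest_rows = []
    for track in [query] + compendium:
        fname = f"{track.label.experiment_id}.bedgraph"
        tio.write_bedgraph(track.intervals(), out / "compendium" / fname)
        manifest_rows.append(
            {
                "experiment_id": track.label.experiment_id,
                "factor": track.label.factor,
                "cell_type": track.label.cell_type,
                "path": fname,
                "genome": "../genome.chrom.sizes",
            }
        )
    pd.DataFrame(manifest_rows).to_csv(
        paths["compendium_manifest"], sep="\t", index=False
    )

    probes, meth_truth = sim.generate_methylation(world)
    probes.to_csv(paths["probes"], sep="\t", index=False)

    matrices, kd_truth = sim.generate_knockdown(world)
    for key, df in matrices.items():
        df.round(4).to_csv(out / f"kd_{key}.tsv", sep="\t")

    data, tf_ids, net_truth = sim.generate_expression_matrix(world)
    data.T.round(4).to_csv(paths["expression_matrix"], sep="\t")  # genes in rows
    with open(paths["tf_list"], "w") as fh:
        fh.write("\n".join(tf_ids) + "\n")

    ann = _synthetic_term_annotation(world, sim._rng(config, "world"))
    ann.to_csv(paths["annotation"], sep="\t", index=False, header=False)

    truth = {
        "bound_genes": sorted(world.bound_genes),
        "kd_up": sorted(kd_truth["up"]),
        "kd_down": sorted(kd_truth["down"]),
        "kd_bound": sorted(kd_truth["bound"]),
        "hub_tf": net_truth["hub_tf"],
        "true_edges": sorted(f"{a}->{b}" for a, b in net_truth["true_edges"]),
        "bound_delta": meth_truth["bound_delta"],
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    paths["truth"] = out / "truth.json"
    return paths


def run_all(
    input_dir,
    out_dir,
    config: sim.SimulationConfig | None = None,
    seed: int = 0,
    mode: str = "cosine",
    n_perm: int = 20_000,
    label_factor: str = "POL2",
    k_top: int = 1000,
) -> RunManifest:
    """Run the full analysis workflow on a directory of input files.

    Stages: replicate intersection -> TSS profiling and element annotation
    -> bound genes -> expression bins and category profiles -> methylation
    comparison -> track similarity ranking, label enrichment and
    median-label-rank profile -> knockdown classification and bound-gene
    enrichment -> permutation-calibrated LASSO network and hubs -> term
    enrichment. Every output file is checksummed into the manifest.
    """
    inp = Path(input_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    missing = [str(inp / v) for v in INPUT_FILES.values() if not (inp / v).exists()]
    if missing:
        raise FileNotFoundError(f"missing input files: {missing}")

    manifest = RunManifest(
        config={
            "input_dir": str(inp),
            "mode": mode,
            "n_perm": n_perm,
            "label_factor": label_factor,
            "k_top": k_top,
            "combined_p_method": "fisher",
            "simulation": config.to_dict() if config else None,
        },
        seed=seed,
    )
    S = manifest.summary

    # --- peaks ---------------------------------------------------------
    layout = gm.GenomeLayout.from_chrom_sizes(inp / INPUT_FILES["genome"])
    rep1 = tio.read_bed(inp / INPUT_FILES["peaks_rep1"], layout)
    rep2 = tio.read_bed(inp / INPUT_FILES["peaks_rep2"], layout)
    genes = tio.read_tss_table(inp / INPUT_FILES["genes"])
    peaks = gm.intersect_replicates(rep1, rep2)
    tio.write_bed(peaks, out / "reproducible_peaks.bed")
    S["n_peaks_rep1"] = len(rep1)
    S["n_peaks_rep2"] = len(rep2)
    S["n_reproducible_peaks"] = len(peaks)

    dist = gm.distances_to_nearest_tss(peaks, genes)
    for name, (half, width) in {
        "tss_distance_150kb": (75_000, 1000),
        "tss_distance_4kb": (2_000, 100),
    }.items():
        hist = gm.tss_distance_histogram(dist["distance"], half, width)
        tio.write_histogram(hist, out / f"{name}.tsv")
    S["frac_peaks_within_1kb"] = float((dist["distance"].abs() <= 1000).mean())

    elements = gm.annotate_elements(peaks, genes)
    elements.table.to_csv(out / "element_annotation.tsv", sep="\t", index=False)
    rng_ctrl = np.random.default_rng(seed)
    control = gm.random_control_peaks(max(len(peaks), 1000), peaks, layout, rng_ctrl)
    ctrl_elements = gm.annotate_elements(control, genes)
    pd.DataFrame(
        {
            "category": list(elements.frequencies),
            "observed": list(elements.frequencies.values()),
            "random_control": [
                ctrl_elements.frequencies[c] for c in elements.frequencies
            ],
        }
    ).to_csv(out / "element_frequencies.tsv", sep="\t", index=False)
    S["promoter_fraction"] = elements.frequencies["promoter"]
    S["promoter_fraction_random"] = ctrl_elements.frequencies["promoter"]
    manifest.record(
        "peaks",
        [
            out / "reproducible_peaks.bed",
            out / "tss_distance_150kb.tsv",
            out / "tss_distance_4kb.tsv",
            out / "element_annotation.tsv",
            out / "element_frequencies.tsv",
        ],
    )

    # --- bound genes and expression stratification ---------------------
    bound = gm.bound_genes(peaks, genes, window=1000)
    (out / "bound_genes.txt").write_text("\n".join(sorted(bound)) + "\n")
    S["n_bound_genes"] = len(bound)

    bins = expr.binding_by_expression_bins(genes, bound, bin_size=k_top)
    bins_df = pd.DataFrame(
        {
            "bin": [b.index for b in bins],
            "n_genes": [len(b.gene_ids) for b in bins],
            "bound": [b.bound_count for b in bins],
            "proportion_bound": [b.proportion_bound for b in bins],
        }
    )
    bins_df.to_csv(out / "expression_bins.tsv", sep="\t", index=False)
    if len(bins_df) >= 3:
        rho, _ = sps.spearmanr(bins_df["bin"], bins_df["proportion_bound"])
        S["spearman_bin_vs_bound"] = float(rho)

    categories = expr.categorize_expression(genes)
    profiles = expr.category_tss_profiles(peaks, genes, categories)
    for cat, hist in profiles.items():
        tio.write_histogram(hist, out / f"tss_profile_{cat}.tsv")
    counts = expr.category_counts(categories)
    S["category_counts"] = counts
    manifest.record(
        "expression",
        [out / "bound_genes.txt", out / "expression_bins.tsv"]
        + [out / f"tss_profile_{c}.tsv" for c in profiles],
    )

    # --- methylation ---------------------------------------------------
    probes = tio.read_probe_table(inp / INPUT_FILES["probes"])
    grades = expr.gene_methylation_grade(probes)
    meth = expr.compare_methylation(bound, grades)
    meth["ecdf_bound"].to_csv(out / "methylation_ecdf_bound.tsv", sep="\t", index=False)
    meth["ecdf_all"].to_csv(out / "methylation_ecdf_all.tsv", sep="\t", index=False)
    S["methylation_mean_difference"] = meth["mean_difference"]
    S["methylation_ks_p"] = meth["ks_p"]
    manifest.record(
        "methylation",
        [out / "methylation_ecdf_bound.tsv", out / "methylation_ecdf_all.tsv"],
    )

    # --- track similarity ---------------------------------------------
    all_tracks = trk.load_compendium(inp / INPUT_FILES["compendium_manifest"])
    query = next(t for t in all_tracks if t.label.experiment_id == "QUERY")
    compendium = [t for t in all_tracks if t.label.experiment_id != "QUERY"]
    ranking = trk.rank_compendium(query, compendium, mode=mode)
    ranking.to_frame().to_csv(out / "similarity_ranking.tsv", sep="\t", index=False)
    label_ids = {
        t.label.experiment_id for t in compendium if t.label.factor == label_factor
    }
    if label_ids:
        enrich = trk.rank_label_enrichment(
            ranking, label_ids, n_perm=n_perm, seed=seed
        )
        S["label_enrichment"] = enrich
    profile = trk.median_label_rank_profile([query] + compendium, label_factor, mode=mode)
    profile.to_csv(out / "median_label_rank.tsv", sep="\t", index=False)
    q_row = profile[profile["experiment_id"] == "QUERY"]
    S["query_median_label_rank"] = float(q_row["median_label_rank"].iloc[0])
    S["query_median_rank_position"] = int(q_row.index[0]) + 1
    manifest.record(
        "tracks", [out / "similarity_ranking.tsv", out / "median_label_rank.tsv"]
    )

    # --- knockdown -----------------------------------------------------
    mats = {
        key: tio.read_expression_matrix(inp / INPUT_FILES[f"kd_{key}"])
        for key in ("sh1_ctrl", "sh1_kd", "sh2_ctrl", "sh2_kd")
    }
    stats1 = kd.per_construct_stats(mats["sh1_kd"], mats["sh1_ctrl"])
    stats2 = kd.per_construct_stats(mats["sh2_kd"], mats["sh2_ctrl"])
    table = kd.combine_constructs(stats1, stats2, method="fisher")
    table.round(6).to_csv(out / "regulation_table.tsv", sep="\t")
    # the knockdown universe is array-scale; when the simulated truth names
    # its own (padded) bound set, use it, otherwise fall back to the ChIP call
    kd_bound = {g for g in table.index.astype(str) if g in bound}
    truth_path = inp / "truth.json"
    if truth_path.exists():
        with open(truth_path) as fh:
            kd_bound = set(json.load(fh)["kd_bound"])
    for by in ("fold", "p"):
        cats = kd.classify_top_k(table, k=k_top, by=by)
        res = kd.bound_enrichment_by_category(cats, kd_bound)
        S[f"kd_enrichment_by_{by}"] = {
            "proportions": res["proportions"],
            "chi2_p": res["chi2_p"],
            "z_p_up": res["z_p_up_vs_unaffected"],
            "z_p_down": res["z_p_down_vs_unaffected"],
        }
    cdf = kd.fold_change_cdf(table, kd_bound)
    cdf.round(6).to_csv(out / "fold_change_cdf.tsv", sep="\t", index=False)
    manifest.record(
        "knockdown", [out / "regulation_table.tsv", out / "fold_change_cdf.tsv"]
    )

    # --- co-expression network ----------------------------------------
    xdf = tio.read_expression_matrix(inp / INPUT_FILES["expression_matrix"]).T
    tf_list = tio.read_tf_list(inp / INPUT_FILES["tf_list"])
    xmat = net.ExpressionMatrix(xdf, tf_list)
    calib = net.calibrate_lambda_by_permutation(xmat, n_perm=5, seed=seed)
    model = net.fit_lasso_network(xmat, calib["lambda_star"])
    model.edges.round(6).to_csv(out / "network_edges.tsv", sep="\t", index=False)
    hubs = net.hub_ranking(model)
    hubs.to_csv(out / "hub_table.tsv", sep="\t", index=False)
    S["lambda_star"] = calib["lambda_star"]
    S["n_network_edges"] = model.n_edges
    S["top_hub"] = hubs["tf"].iloc[0] if len(hubs) else None
    S["top_hub_connections"] = int(hubs["connections"].iloc[0]) if len(hubs) else 0
    if truth_path.exists():
        with open(truth_path) as fh:
            tr = json.load(fh)
        true_edges = {tuple(e.split("->")) for e in tr["true_edges"]}
        found = {(r.tf, r.target) for r in model.edges.itertuples()}
        tp = len(found & true_edges)
        S["edge_precision"] = tp / len(found) if found else np.nan
        S["edge_recall"] = tp / len(true_edges) if true_edges else np.nan
        hub_rank = hubs[hubs["tf"] == tr["hub_tf"]]["rank"]
        S["planted_hub_rank"] = int(hub_rank.iloc[0]) if len(hub_rank) else None
    manifest.record("network", [out / "network_edges.tsv", out / "hub_table.tsv"])

    # --- term enrichment ----------------------------------------------
    annotation = tio.read_annotation_map(inp / INPUT_FILES["annotation"])
    universe = {g.gene_id for g in genes}
    gene_set = bound & universe
    if gene_set:
        terms = enr.fold_enrichment(gene_set, annotation, universe)
        filtered = enr.filter_terms(terms)
        terms.drop(columns="genes").to_csv(
            out / "term_enrichment.tsv", sep="\t", index=False
        )
        filtered.drop(columns="genes").to_csv(
            out / "term_enrichment_filtered.tsv", sep="\t", index=False
        )
        if len(filtered):
            S["top_term"] = str(filtered["term_id"].iloc[0])
            S["top_term_fold"] = float(filtered["fold_enrichment"].iloc[0])
            S["top_term_p"] = float(filtered["p"].iloc[0])
        manifest.record(
            "terms",
            [out / "term_enrichment.tsv", out / "term_enrichment_filtered.tsv"],
        )

    manifest.write(out / "manifest.json")
    return manifest
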