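"""End-to-end pipeline orchestration with a single plain-text config.

The pipeline is linear: enrichment -> states -> transitions -> breadth ->
correlation -> clustering -> super-enhancers -> motif ensembles -> report.
Every stage reads and writes TSV/JSON through :mod:`chromdyn.io_genomics`,
parameters all default to the published values, the config is serialized
into the output directory, and a manifest records SHA-256 checksums of all
inputs and outputs so a rerun with identical inputs is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import (
    breadth_expression,
    enhancer_ranking,
    io_genomics,
    kmeans_clustering,
    motif_ensembles,
    peak_annotation,
    state_transitions,
    synthetic_data,
)
from .io_genomics import MARKS

logger = logging.getLogger("chromdyn")


@dataclass
class PipelineConfig:
    """All stage parameters (defaults are the published settings) plus
    input file names, resolved relative to the input directory."""

    # inputs
    peaks_dir: str = "peaks"
    regions_bed: str = "regions.bed"
    enrichment_raw: str = "enrichment_raw.tsv"
    genes: str = "genes.tsv"
    expression: str = "expression.tsv"
    motif_hits: str = "motif_hits.tsv"
    string_edges: str = "string_edges.tsv"
    truth_states: str = ""
    truth_groups: str = ""
    # parameters
    timepoints: list[int] = field(default_factory=lambda: list(synthetic_data.DEFAULT_TIMEPOINTS))
    gap: int = 100
    promoter_window: int = 2000
    rho_cut: float = 0.3
    p_cut: float = 0.35
    k: int = 6
    stitch: int = 12_500
    resolution: float = 0.5
    min_pct: float = 0.10
    logfc: float = 0.09
    k_neighbors: int = 30
    n_pcs: int = 10
    reference_timepoint: int = 1
    se_timepoint: int = 1
    cluster_mark: str = "H3K27ac"
    ensemble_group: str = "dynamic"  # a transition group, or 'dynamic' = all non-static
    seed: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixtures(
    out_dir: str | Path,
    n_regions: int = 1000,
    noise_sigma: float = 0.2,
    seed: int = 1,
    config: PipelineConfig | None = None,
) -> Path:
    """Materialize a complete synthetic demo dataset (plus truth tables)
    that :func:`run_pipeline` can consume."""
    out = Path(out_dir)
    (out / "peaks").mkdir(parents=True, exist_ok=True)
    cfg = config or PipelineConfig(seed=seed)
    spec = synthetic_data.StateScenario(
        n_regions=n_regions,
        timepoints=tuple(cfg.timepoints),
        reference_timepoint=cfg.reference_timepoint,
        noise_sigma=noise_sigma,
        seed=seed,
    )
    res = synthetic_data.generate_state_scenario(spec)

    io_genomics.write_matrix(res.enrichment.raw, out / cfg.enrichment_raw)
    io_genomics.write_table(res.true_states.reset_index(), out / "truth_states.tsv")
    io_genomics.write_table(
        res.true_groups.rename("group").reset_index().rename(columns={"index": "region_id"}),
        out / "truth_groups.tsv",
    )
    with open(out / cfg.regions_bed, "w") as fh:
        for rid, iv in res.regions.items():
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rid}\t0\t.\n")
    for (mark, tp), peaks in res.peaks.items():
        with open(out / "peaks" / f"{mark}_{tp}.bed", "w") as fh:
            for p in peaks:
                iv = p.interval
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.name}\t0\t.\n")

    # one gene per region; TSS just upstream so the region is its promoter
    genes = [
        io_genomics.GeneModel(
            gene_id=rid.replace("region", "gene"),
            chrom=iv.chrom,
            start=max(0, iv.start - 1000),
            end=iv.end + 2000,
            strand="+",
        )
        for rid, iv in res.regions.items()
    ]
    io_genomics.write_gene_table(genes, out / cfg.genes)

    expr, _ = synthetic_data.generate_expression(
        res, rho_target=1.0, seed=seed + 1, mark=cfg.cluster_mark
    )
    io_genomics.write_matrix(expr, out / cfg.expression)

    # planted motif ensembles over the dynamic (non-static) regions
    dynamic = list(res.true_groups.index[res.true_groups != "static"])
    per = max(3, len(dynamic) // 4)
    espec = synthetic_data.make_ensemble_spec(
        n_ensembles=3,
        regions_per_ensemble=per,
        n_background_regions=max(0, len(dynamic) - 3 * per),
        seed=seed + 2,
    )
    matrix, truth_ens = synthetic_data.generate_motif_matrix(espec)
    matrix.index = dynamic[: len(matrix)]
    hits = matrix.stack()
    hits = hits[hits > 0].reset_index()
    hits.columns = ["region_id", "motif_id", "hit"]
    hits["position"] = 0
    hits["strand"] = "+"
    hits["score"] = 1.0
    io_genomics.write_table(
        hits[["region_id", "motif_id", "position", "strand", "score"]],
        out / cfg.motif_hits,
    )

    # synthetic TF-interaction edges: a hub motif per planted ensemble
    edge_rows = []
    for motifs, _, _ in espec.ensembles:
        ids = [f"MOTIF{j:03d}" for j in motifs]
        for other in ids[1:]:
            edge_rows.append({"tf_a": ids[0], "tf_b": other, "weight": 0.9})
    io_genomics.write_table(pd.DataFrame(edge_rows), out / cfg.string_edges)

    cfg2 = dataclasses.replace(cfg, truth_states="truth_states.tsv", truth_groups="truth_groups.tsv")
    cfg2.to_yaml(out / "config.yaml")
    return out


def run_pipeline(
    config: PipelineConfig, input_dir: str | Path, output_dir: str | Path
) -> dict:
    """Run all stages; returns the report dict and writes all outputs.

    Missing inputs fail before any stage runs.  No stage mutates another
    stage's outputs; the stage order is fixed and logged.
    """
    inp, out = Path(input_dir), Path(output_dir)
    required = [
        config.regions_bed, config.enrichment_raw, config.genes,
        config.expression, config.motif_hits,
    ]
    missing = [f for f in required if not (inp / f).exists()]
    if missing:
        raise FileNotFoundError(f"missing input file(s): {missing}")
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    inputs_used = [inp / f for f in required if (inp / f).exists()]
    if (inp / config.string_edges).exists():
        inputs_used.append(inp / config.string_edges)

    # --- regions & enrichment -------------------------------------------
    logger.info("stage 1/8: enrichment")
    regions: dict[str, io_genomics.GenomicInterval] = {}
    with open(inp / config.regions_bed) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            regions[f[3]] = io_genomics.GenomicInterval(f[0], int(f[1]), int(f[2]))
    raw = io_genomics.read_matrix(inp / config.enrichment_raw)
    enrichment = peak_annotation.EnrichmentMatrix.from_raw(
        raw, MARKS, tuple(config.timepoints)
    )
    io_genomics.write_matrix(enrichment.norm, out / "enrichment_norm.tsv")

    # --- annotation ------------------------------------------------------
    logger.info("stage 2/8: annotation")
    genes = io_genomics.read_gene_table(inp / config.genes)
    annotations = peak_annotation.annotate_regions(
        regions, genes, promoter_window=config.promoter_window
    )
    io_genomics.write_matrix(annotations, out / "annotations.tsv")
    marked = peak_annotation.marked_gene_fraction(genes, annotations)

    # --- states & transitions -------------------------------------------
    logger.info("stage 3/8: chromatin states")
    thresholds = state_transitions.compute_thresholds(enrichment)
    states = state_transitions.call_states(enrichment, thresholds)
    io_genomics.write_matrix(states, out / "states.tsv")
    logger.info("stage 4/8: transition groups")
    records = state_transitions.assign_transition_groups(
        states, config.reference_timepoint
    )
    io_genomics.write_matrix(records, out / "transitions.tsv")
    freq = state_transitions.transition_frequency_table(states)
    (out / "transition_frequencies.json").write_text(
        json.dumps({str(c): freq[c].to_dict() for c in freq.columns}, indent=2, sort_keys=True)
    )

    # --- breadth & correlation ------------------------------------------
    logger.info("stage 5/8: breadth and correlation")
    widths = pd.Series({rid: iv.width for rid, iv in regions.items()}).reindex(
        enrichment.region_ids
    )
    breadth = breadth_expression.classify_breadth(widths)
    io_genomics.write_matrix(breadth, out / "breadth.tsv")
    expression = io_genomics.read_matrix(inp / config.expression)
    profile = enrichment.mark_profile(config.cluster_mark)
    profile.columns = [str(c) for c in profile.columns]
    expression.columns = [str(c) for c in expression.columns]
    correlations = breadth_expression.correlate_profiles(
        profile, expression, rho_cut=config.rho_cut, p_cut=config.p_cut
    )
    io_genomics.write_matrix(correlations, out / "correlations.tsv")
    report_breadth = breadth_expression.breadth_expression_report(
        breadth, correlations, expression
    )
    io_genomics.write_matrix(report_breadth, out / "breadth_report.tsv")

    # --- clustering ------------------------------------------------------
    logger.info("stage 6/8: k-means clustering")
    keep = kmeans_clustering.filter_regions_for_clustering(correlations, breadth)
    cluster_input = enrichment.mark_profile(config.cluster_mark).loc[
        enrichment.region_ids.intersection(keep)
    ]
    k_eff = min(config.k, max(1, len(cluster_input)))
    assignment = kmeans_clustering.kmeans_cluster(
        cluster_input, k=k_eff, seed=config.seed
    )
    io_genomics.write_matrix(assignment.labels.to_frame(), out / "clusters.tsv")
    io_genomics.write_matrix(assignment.centroids, out / "cluster_centroids.tsv")

    # --- super-enhancers -------------------------------------------------
    logger.info("stage 7/8: super-enhancer ranking")
    se_signal = enrichment.raw[
        enrichment.column(config.cluster_mark, config.se_timepoint)
    ]
    se_peak_file = inp / config.peaks_dir / f"H3K27ac_{config.se_timepoint}.bed"
    if se_peak_file.exists():
        se_peaks = {}
        with open(se_peak_file) as fh:
            for line in fh:
                f = line.rstrip("\n").split("\t")
                se_peaks[f[3]] = io_genomics.GenomicInterval(f[0], int(f[1]), int(f[2]))
        inputs_used.append(se_peak_file)
    else:  # fall back to all regions
        se_peaks = regions
    stitched = enhancer_ranking.stitch_enhancers(
        se_peaks, signals=se_signal, stitch_distance=config.stitch
    )
    se_table = enhancer_ranking.rank_enhancers(stitched)
    io_genomics.write_matrix(se_table, out / "superenhancers.tsv")

    # --- motif ensembles -------------------------------------------------
    logger.info("stage 8/8: motif ensembles")
    hits = io_genomics.read_table(inp / config.motif_hits)
    if config.ensemble_group == "dynamic":
        selected = records.index[records["group"] != "static"]
    else:
        selected = records.index[records["group"] == config.ensemble_group]
    matrix = motif_ensembles.build_region_motif_matrix(hits)
    matrix = matrix.loc[matrix.index.intersection(selected)]
    ensembles_out: dict = {"n_regions": int(len(matrix))}
    markers = pd.DataFrame()
    if len(matrix) >= 10:
        k_nn = min(config.k_neighbors, len(matrix) - 1)
        partition, markers = motif_ensembles.discover_ensembles(
            matrix,
            n_pcs=config.n_pcs,
            k_neighbors=k_nn,
            resolution=config.resolution,
            seed=config.seed,
            min_pct=config.min_pct,
            logfc_threshold=config.logfc,
        )
        io_genomics.write_matrix(partition.to_frame(), out / "ensemble_partition.tsv")
        io_genomics.write_table(markers, out / "ensemble_markers.tsv")
        ensembles_out["n_clusters"] = int(partition.nunique())
        edges_file = inp / config.string_edges
        if edges_file.exists() and len(markers):
            edges = io_genomics.read_table(edges_file)
            hubs = motif_ensembles.rank_network_hubs(
                edges, markers["motif_id"].unique()
            )
            io_genomics.write_matrix(hubs, out / "hub_ranking.tsv")

    # --- report ----------------------------------------------------------
    report = {
        "n_regions": int(len(enrichment.region_ids)),
        "marked_gene_fraction": marked,
        "state_counts": {
            str(tp): states[tp].value_counts().to_dict() for tp in states.columns
        },
        "transition_counts": records["group"].value_counts().to_dict(),
        "n_broad": int((breadth["breadth_class"] == "broad").sum()),
        "n_positive_correlated": int((correlations["corr_class"] == "positive").sum()),
        "n_clusters": int(assignment.centroids.shape[0]),
        "kmeans_wss": assignment.wss,
        "n_superenhancers": int(se_table["is_super"].sum()),
        "ensembles": ensembles_out,
    }
    truth_states_file = inp / config.truth_states if config.truth_states else None
    if truth_states_file and truth_states_file.exists():
        truth = io_genomics.read_matrix(truth_states_file)
        truth.columns = [int(c) for c in truth.columns]
        report["state_recovery"] = float(
            (states.values == truth.reindex(states.index).values).mean()
        )
        inputs_used.append(truth_states_file)
    truth_groups_file = inp / config.truth_groups if config.truth_groups else None
    if truth_groups_file and truth_groups_file.exists():
        truth_g = io_genomics.read_table(truth_groups_file, index_col=0)["group"]
        report["group_recovery"] = float(
            (records["group"] == truth_g.reindex(records.index)).mean()
        )
        inputs_used.append(truth_groups_file)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))

    manifest = {
        "config": dataclasses.asdict(config),
        "inputs": {str(p.name): _sha256(p) for p in inputs_used},
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
        "stage_order": [
            "enrichment", "annotation", "states", "transitions",
            "breadth_correlation", "clustering", "superenhancers", "ensembles",
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return report
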