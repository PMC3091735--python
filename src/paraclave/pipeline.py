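"""End-to-end orchestration: proteomes in, convergence calls out.

The stages run in a fixed order: paralog calling, paralog-fraction
ranking, COG profiling, per-organism term overrepresentation, the
cross-organism term filter, the species similarity graph, incidence-matrix
biclustering, the strain filter, co-occurrence counting, semantic cluster
scoring, alignment-free distances, and finally the convergence screen
(high term similarity, large phylogenetic distance).  Every output is
written as sorted plain text and the full parameter set is serialized into
a provenance sidecar, so a rerun with the same config and seed is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import (
    biclustering,
    cog_profiles,
    core_model,
    go_enrichment,
    go_semantic_similarity,
    paralog_detection,
    phylo_distance,
    species_graph,
)
from .core_model import AnnotationMap, Proteome, ResultBundle

logger = logging.getLogger("paraclave")

BACKGROUND_KINDS = ("all_paralogs", "all_proteomes", "individual_proteome")


@dataclass
class PipelineConfig:
    """Declarative configuration; defaults match the analysis' standard run."""

    proteome_dir: str = "proteomes"
    table_dir: str = "tables"
    obo_path: str = "go.obo"
    annotations_path: str = "annotations.tsv"
    sixteen_s_path: str = "sixteen_s.fna"
    organisms_path: str = "organisms.tsv"
    singletons_path: str | None = None

    identity_threshold: float = 75.0
    evalue_max: float = 1e-5
    max_hits: int = 1000
    top_n: int = 200
    alpha: float = 0.01
    min_organisms: int = 3
    min_count: int = 10
    min_relative: float = 0.30
    min_rows: int = 2
    min_cols: int = 2
    sim_cut: float = 0.7
    dist_cut: float = 0.1
    background: str = "all_paralogs"
    exclude_species: list[str] = field(default_factory=list)
    compare_backgrounds: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background not in BACKGROUND_KINDS:
            raise ValueError(f"background must be one of {BACKGROUND_KINDS}")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        for name in ("identity_threshold",):
            if not 0 <= getattr(self, name) <= 100:
                raise ValueError(f"{name} must be in [0, 100]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        data = yaml.safe_load(path.read_text()) or {}
        cfg = cls(**data)
        # resolve input paths relative to the config file
        for name in (
            "proteome_dir",
            "table_dir",
            "obo_path",
            "annotations_path",
            "sixteen_s_path",
            "organisms_path",
            "singletons_path",
        ):
            value = getattr(cfg, name)
            if value is not None and not Path(value).is_absolute():
                setattr(cfg, name, str(path.parent / value))
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str) -> None:
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def _load_proteomes(config: PipelineConfig) -> dict[str, Proteome]:
    meta = pd.read_csv(config.organisms_path, sep="\t", dtype=str)
    meta["genome_size"] = meta["genome_size"].astype(int)
    proteomes: dict[str, Proteome] = {}
    for _, row in meta.sort_values("organism_id").iterrows():
        org = row["organism_id"]
        fasta = Path(config.proteome_dir) / f"{org}.faa"
        table = Path(config.table_dir) / f"{org}.tsv"
        records = core_model.read_fasta(fasta)
        cogs = core_model.read_protein_table(table) if table.exists() else {}
        proteins = [
            core_model.Protein(pid, seq, frozenset(cogs.get(pid, set())))
            for pid, seq in records
        ]
        proteomes[org] = Proteome(
            organism_id=org,
            species_label=row.get("species_label", org),
            strain_label=row.get("strain_label", "") or "",
            proteins=proteins,
            genome_size=int(row["genome_size"]),
        )
    if not proteomes:
        raise StageError("load", "no proteomes found")
    return proteomes


def _background_pool(
    kind: str,
    organism: str,
    proteomes: dict[str, Proteome],
    paranomes: dict[str, paralog_detection.Paranome],
) -> go_enrichment.BackgroundModel:
    if kind == "all_paralogs":
        members = frozenset().union(*(p.paralog_ids for p in paranomes.values()))
    elif kind == "all_proteomes":
        members = frozenset(
            p.id for prot in proteomes.values() for p in prot.proteins
        )
    else:
        members = frozenset(p.id for p in proteomes[organism].proteins)
    return go_enrichment.BackgroundModel(kind=kind, member_ids=members)


def _enrich_all(
    kind: str,
    organisms: list[str],
    proteomes: dict[str, Proteome],
    paranomes: dict[str, paralog_detection.Paranome],
    annotations: AnnotationMap,
    alpha: float,
) -> dict[str, list[go_enrichment.EnrichmentRecord]]:
    shared_counts = None
    results: dict[str, list[go_enrichment.EnrichmentRecord]] = {}
    for org in organisms:
        background = _background_pool(kind, org, proteomes, paranomes)
        if kind != "individual_proteome" and shared_counts is None:
            shared_counts = go_enrichment.term_counts(background.member_ids, annotations)
        counts = shared_counts if kind != "individual_proteome" else None
        results[org] = go_enrichment.enrich_organism(
            org,
            set(paranomes[org].paralog_ids),
            background,
            annotations,
            alpha=alpha,
            background_counts=counts,
        )
    return results


def _cluster_chain(
    enriched: dict[str, list[go_enrichment.EnrichmentRecord]],
    config: PipelineConfig,
    strain_map: dict[str, str],
):
    """cross-organism filter -> binarize -> bimax -> strain filter."""
    filtered = go_enrichment.cross_organism_filter(enriched, config.min_organisms)
    term_sets = {org: {r.term for r in recs} for org, recs in filtered.items()}
    matrix, excluded = biclustering.binarize(term_sets, min_terms=2)
    clusters = biclustering.bimax(matrix, config.min_rows, config.min_cols)
    clusters, removed = biclustering.drop_single_species_clusters(clusters, strain_map)
    return filtered, matrix, excluded, clusters, removed


def run_all(config: PipelineConfig, outdir: str | Path) -> ResultBundle:
    """Execute the full analysis and write all stage outputs under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = ResultBundle(provenance={"config": config.to_dict()})

    proteomes = _load_proteomes(config)
    strain_map = {org: p.species_label for org, p in proteomes.items()}
    logger.info("loaded %d proteomes", len(proteomes))

    # --- paralog calling -------------------------------------------------
    paranomes: dict[str, paralog_detection.Paranome] = {}
    try:
        for org in sorted(proteomes):
            hits = paralog_detection.all_vs_all(
                proteomes[org], evalue_max=config.evalue_max, max_hits=config.max_hits
            )
            paranomes[org] = paralog_detection.call_paralogs(
                proteomes[org], hits, config.identity_threshold
            )
    except Exception as exc:  # noqa: BLE001 - halt with stage + organism
        raise StageError("paralogs", f"organism {org}: {exc}") from exc
    paranome_table = pd.DataFrame(
        [
            {
                "organism_id": org,
                "n_proteins": len(proteomes[org]),
                "n_paralogs": len(paranomes[org].paralog_ids),
                "paralog_fraction": paranomes[org].paralog_fraction,
            }
            for org in sorted(paranomes)
        ]
    )
    core_model.write_tsv(paranome_table, outdir / "paranomes.tsv")
    bundle.record("paralogs", paranomes, identity=config.identity_threshold,
                  evalue=config.evalue_max, max_hits=config.max_hits)

    # --- ranking and genome-size trend ----------------------------------
    rank = paralog_detection.paralog_fraction_rank(
        list(paranomes.values()), top_n=config.top_n
    )
    core_model.write_tsv(rank, outdir / "paralog_rank.tsv")
    organisms = sorted(rank["organism_id"])
    trend = paralog_detection.fit_trend(
        [proteomes[o].genome_size / 1e6 for o in organisms],
        [len(paranomes[o].paralog_ids) for o in organisms],
        ids=organisms,
    )
    bundle.record("rank", rank, top_n=config.top_n)
    bundle.record("trend", trend)

    # --- COG profiles ----------------------------------------------------
    cog_map = {
        p.id: set(p.cog_categories)
        for org in organisms
        for p in proteomes[org].proteins
    }
    paralog_ids = [
        pid for org in organisms for pid in sorted(paranomes[org].paralog_ids)
    ]
    paralog_dist = cog_profiles.cog_distribution(paralog_ids, cog_map)
    if config.singletons_path:
        singleton_ids = [
            line.strip()
            for line in Path(config.singletons_path).read_text().splitlines()
            if line.strip()
        ]
    else:
        singleton_ids = [
            p.id
            for org in organisms
            for p in proteomes[org].proteins
            if p.id not in paranomes[org].paralog_ids
        ]
    singleton_dist = cog_profiles.cog_distribution(singleton_ids, cog_map)
    reference_dist = cog_profiles.cog_distribution(sorted(cog_map), cog_map)
    cog_table = cog_profiles.compare_distributions(
        paralog_dist, singleton_dist, reference_dist
    )
    core_model.write_tsv(cog_table, outdir / "cog_profile.tsv")
    bundle.record("cog", cog_table)

    # --- annotations and enrichment -------------------------------------
    dag = core_model.read_obo(config.obo_path)
    direct = core_model.read_annotations(config.annotations_path)
    annotations = go_enrichment.propagate(AnnotationMap(direct=direct), dag)
    kinds = BACKGROUND_KINDS if config.compare_backgrounds else (config.background,)
    enriched_by_model = {
        kind: _enrich_all(kind, organisms, proteomes, paranomes, annotations,
                          config.alpha)
        for kind in kinds
    }
    enriched = enriched_by_model[config.background]
    enr_rows = [
        dataclasses.asdict(r) for org in sorted(enriched) for r in enriched[org]
    ]
    core_model.write_tsv(
        pd.DataFrame(
            enr_rows,
            columns=["organism_id", "term", "k", "n", "K", "N",
                     "p_raw", "p_bonferroni", "m_tests"],
        ),
        outdir / "enrichment.tsv",
    )
    bundle.record("enrichment", enriched, background=config.background,
                  alpha=config.alpha)

    # --- species graph (pre-filter term lists, all categories) ----------
    term_lists = {org: {r.term for r in recs} for org, recs in enriched.items()}
    graph = species_graph.build_graph(
        term_lists, min_count=config.min_count, min_relative=config.min_relative
    )
    core_model.write_edge_list(graph, outdir / "species_graph.tsv")
    summary = species_graph.graph_summary(graph)
    bundle.record("species_graph", summary, min_count=config.min_count,
                  min_relative=config.min_relative)

    # --- biclustering ----------------------------------------------------
    try:
        filtered, matrix, excluded, clusters, removed = _cluster_chain(
            enriched, config, strain_map
        )
    except ValueError as exc:
        raise StageError("biclustering", str(exc)) from exc
    core_model.write_matrix(matrix, outdir / "incidence_matrix.tsv")
    with open(outdir / "biclusters.jsonl", "w") as fh:
        for bc in clusters:
            fh.write(
                '{"rows": [%s], "cols": [%s]}\n'
                % (
                    ", ".join(f'"{r}"' for r in bc.rows),
                    ", ".join(f'"{c}"' for c in bc.cols),
                )
            )
    cooc = biclustering.cooccurrence_counts(
        clusters, exclude_species=config.exclude_species, strain_map=strain_map
    )
    core_model.write_tsv(cooc, outdir / "cooccurrence.tsv")
    bundle.record("biclustering", clusters, min_rows=config.min_rows,
                  min_cols=config.min_cols, unclusterable=excluded,
                  strain_clusters_removed=removed)
    bundle.record("cooccurrence", cooc, exclude_species=config.exclude_species)

    # --- semantic similarity, incl. background-model comparison ---------
    def scores_for(cluster_list) -> list[float]:
        return [
            go_semantic_similarity.cluster_similarity(bc.cols, dag)
            for bc in cluster_list
        ]

    sim_scores = scores_for(clusters)
    scores_by_model = {}
    for kind in kinds:
        if kind == config.background:
            scores_by_model[kind] = sim_scores
        else:
            try:
                _, _, _, model_clusters, _ = _cluster_chain(
                    enriched_by_model[kind], config, strain_map
                )
                scores_by_model[kind] = scores_for(model_clusters)
            except ValueError:
                scores_by_model[kind] = []
    bg_summary, bg_pairwise, best_model = go_semantic_similarity.compare_backgrounds(
        scores_by_model
    )
    core_model.write_tsv(bg_summary, outdir / "background_comparison.tsv")
    bundle.record("semsim", sim_scores)
    bundle.record("background_comparison",
                  {"summary": bg_summary, "pairwise": bg_pairwise, "best": best_model})

    # --- phylogenetic distance and the convergence screen ---------------
    seqs = dict(core_model.read_fasta(config.sixteen_s_path))
    clustered_orgs = sorted({org for bc in clusters for org in bc.rows})
    missing = [o for o in clustered_orgs if o not in seqs]
    if missing:
        logger.warning("no rDNA sequence for %s; dropped from distances", missing)
    usable = {o: seqs[o] for o in clustered_orgs if o in seqs}
    calls: list[phylo_distance.ConvergenceCall] = []
    dmat = None
    if len(usable) >= 2:
        dmat, _ = phylo_distance.distance_matrix(usable)
        core_model.write_matrix(dmat, outdir / "distance_matrix.tsv")
        phylo_distance.write_phylip(dmat, outdir / "distance_matrix.phy")
        cluster_scores = [
            phylo_distance.ClusterScore(
                bicluster=bc,
                go_similarity=sim,
                phylo_distance=phylo_distance.cluster_distance(bc, dmat),
            )
            for bc, sim in zip(clusters, sim_scores)
            if set(bc.rows) <= set(usable)
        ]
        calls = phylo_distance.select_convergent(
            cluster_scores, sim_cut=config.sim_cut, dist_cut=config.dist_cut
        )
    bundle.record("distances", dmat)
    bundle.record("convergence", calls, sim_cut=config.sim_cut,
                  dist_cut=config.dist_cut)

    conv_rows = []
    for call in calls:
        paralogs_in_cluster = [
            pid
            for org in call.bicluster.rows
            for pid in sorted(paranomes[org].paralog_ids)
            if annotations.propagated.get(pid, set()) & set(call.bicluster.cols)
        ]
        if paralogs_in_cluster:
            consensus = cog_profiles.consensus_cog(paralogs_in_cluster, cog_map)
            cog_label, cog_support = consensus.category, consensus.support
        else:
            cog_label, cog_support = "-", 0.0
        conv_rows.append(
            {
                "organisms": ";".join(call.bicluster.rows),
                "terms": ";".join(call.bicluster.cols),
                "go_similarity": round(call.go_similarity, 6),
                "phylo_distance": round(call.phylo_distance, 6),
                "consensus_cog": cog_label,
                "cog_support": round(cog_support, 6),
                "selected": call.selected,
            }
        )
    core_model.write_tsv(
        pd.DataFrame(
            conv_rows,
            columns=["organisms", "terms", "go_similarity", "phylo_distance",
                     "consensus_cog", "cog_support", "selected"],
        ),
        outdir / "convergence_calls.tsv",
    )

    (outdir / "report.txt").write_text(report(bundle))
    bundle.write_provenance(outdir / "provenance.json")
    return bundle


def report(bundle: ResultBundle) -> str:
    """Human-readable run summary mirroring the analysis' headline tables."""
    lines = ["paraclave run report", "=" * 40]
    trend = bundle.stages.get("trend")
    if trend is not None:
        lines.append(
            f"paralog count vs genome size: y = {trend.slope:.2f}x + "
            f"{trend.intercept:.2f} (r = {trend.pearson_r:.3f}, "
            f"{len(trend.outlier_ids)} outliers)"
        )
        if trend.refit is not None:
            lines.append(
                f"  excluding outliers: y = {trend.refit.slope:.2f}x + "
                f"{trend.refit.intercept:.2f} (r = {trend.refit.pearson_r:.3f})"
            )
    cog = bundle.stages.get("cog")
    if cog is not None:
        dominated = cog[cog["dominated"] != ""]
        if len(dominated):
            lines.append("dominated COG categories:")
            for _, row in dominated.iterrows():
                lines.append(
                    f"  {row['category']}: {row['dominated']}-dominated "
                    f"(paralogs {row['paralog_fraction']:.3f}, "
                    f"singletons {row['singleton_fraction']:.3f})"
                )
    sg = bundle.stages.get("species_graph")
    if sg:
        lines.append(
            f"species graph: {sg['n_nodes']} nodes, {sg['n_edges']} edges, "
            f"{sg['n_components']} components"
        )
    clusters = bundle.stages.get("biclustering", [])
    lines.append(f"biclusters: {len(clusters)}")
    bg = bundle.stages.get("background_comparison")
    if bg and len(bg["summary"]):
        lines.append("background-model comparison (mean cluster similarity):")
        for _, row in bg["summary"].iterrows():
            lines.append(f"  {row['model']}: {row['mean']:.3f} (n={row['n']})")
        if bg["best"]:
            lines.append(f"  highest mean: {bg['best']}")
    calls = bundle.stages.get("convergence", [])
    selected = [c for c in calls if c.selected]
    if selected:
        lines.append(f"convergent clusters selected: {len(selected)}")
        for call in selected:
            lines.append(
                f"  organisms: {', '.join(call.bicluster.rows)}\n"
                f"  terms: {', '.join(call.bicluster.cols)}\n"
                f"  similarity {call.go_similarity:.3f}, "
                f"distance {call.phylo_distance:.3f}"
            )
    else:
        lines.append("convergent clusters selected: 0")
    lines.append("-" * 40)
    lines.append("parameters:")
    for key, value in sorted(bundle.provenance.get("config", {}).items()):
        lines.append(f"  {key}: {value}")
    return "\n".join(lines) + "\n"
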