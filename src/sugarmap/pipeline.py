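"""End-to-end orchestration: simulate -> scan -> context -> regulon ->
pathways -> phenotype, with per-stage outputs under one run directory.

Re-running with the same config and seed reproduces byte-identical TSV/JSON
outputs. A stage failure raises :class:`PipelineError` naming the stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from sugarmap import context as ctx
from sugarmap import homology, pathways, phenotype, regulon
from sugarmap.pathways import PathwayMatrix, RoleAssignment
from sugarmap.regulon import Regulon, RegulonCandidate, UpstreamRegion
from sugarmap.simulate import Panel, PanelConfig, simulate_panel

log = logging.getLogger("sugarmap")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 0
    n_genomes: int = 10
    pathway_roles: dict[str, int] = field(default_factory=lambda: {"SynA": 3, "SynB": 3})
    scenario: dict[str, frozenset[int]] = field(default_factory=dict)
    identity_target: float = 0.6
    min_score: float = homology.DEFAULT_MIN_SCORE
    min_identity: float = homology.DEFAULT_MIN_IDENTITY
    max_gap: int = ctx.DEFAULT_MAX_GAP
    motif_length: int = 16
    upstream_window: int = regulon.DEFAULT_WINDOW_UP
    min_other_genomes: int = regulon.DEFAULT_MIN_OTHER_GENOMES
    pseudogene_plan: list[tuple[int, str, str]] = field(default_factory=list)

    @classmethod
    def from_mapping(cls, data: dict, outdir: Path, seed: int | None = None) -> "PipelineConfig":
        scenario = {
            pid: frozenset(idx) for pid, idx in (data.get("scenario") or {}).items()
        }
        return cls(
            outdir=Path(outdir),
            seed=int(data.get("seed", 0)) if seed is None else seed,
            n_genomes=int(data.get("n_genomes", 10)),
            pathway_roles={k: int(v) for k, v in data.get("pathways", {"SynA": 3, "SynB": 3}).items()},
            scenario=scenario,
            identity_target=float(data.get("identity_target", 0.6)),
            min_score=float(data.get("min_score", homology.DEFAULT_MIN_SCORE)),
            min_identity=float(data.get("min_identity", homology.DEFAULT_MIN_IDENTITY)),
            max_gap=int(data.get("max_gap", ctx.DEFAULT_MAX_GAP)),
            motif_length=int(data.get("motif_length", 16)),
            upstream_window=int(data.get("upstream_window", regulon.DEFAULT_WINDOW_UP)),
            min_other_genomes=int(data.get("min_other_genomes", regulon.DEFAULT_MIN_OTHER_GENOMES)),
            pseudogene_plan=[tuple(p) for p in data.get("pseudogenes", [])],
        )

    def panel_config(self) -> PanelConfig:
        return PanelConfig(
            n_genomes=self.n_genomes,
            pathway_roles=dict(self.pathway_roles),
            scenario=dict(self.scenario),
            identity_target=self.identity_target,
            motif_length=self.motif_length,
            upstream_window=self.upstream_window,
            pseudogene_plan=list(self.pseudogene_plan),
            seed=self.seed,
        )


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrapper
    return deco


@_stage("simulate")
def stage_simulate(config: PipelineConfig) -> Panel:
    panel = simulate_panel(config.panel_config())
    panel.write(config.outdir / "panel")
    return panel


@_stage("scan")
def stage_scan(config: PipelineConfig, panel: Panel) -> dict[str, list[homology.SimilarityHit]]:
    queries = panel.family_consensus()
    hits: dict[str, list[homology.SimilarityHit]] = {}
    outdir = config.outdir / "scan"
    outdir.mkdir(parents=True, exist_ok=True)
    for genome in panel.genomes:
        hits[genome.alias] = homology.scan_families(
            genome.proteome(), queries, config.min_score, config.min_identity
        )
        homology.write_hits_tsv(hits[genome.alias], outdir / f"{genome.alias}.hits.tsv")
    return hits


@_stage("context")
def stage_context(config: PipelineConfig, panel: Panel) -> dict[str, list[ctx.OperonCluster]]:
    outdir = config.outdir / "context"
    outdir.mkdir(parents=True, exist_ok=True)
    clusters: dict[str, list[ctx.OperonCluster]] = {}
    for genome in panel.genomes:
        clusters[genome.alias] = ctx.call_clusters(genome, config.max_gap)
        ctx.write_clusters_tsv(clusters[genome.alias], outdir / f"{genome.alias}.clusters.tsv")
    return clusters


def _cluster_lead(cluster: ctx.OperonCluster, genome) -> str:
    """First transcribed gene of a same-strand cluster."""
    ids = list(cluster.gene_ids)
    return ids[0] if cluster.strand != "-" else ids[-1]


@_stage("regulon")
def stage_regulon(
    config: PipelineConfig,
    panel: Panel,
    assignments: dict[str, list[RoleAssignment]],
    clusters: dict[str, list[ctx.OperonCluster]],
) -> dict[str, Regulon]:
    """Per-pathway regulon: discover the motif on operon-lead upstream
    regions, scan with the minimum-training-score threshold, and keep
    candidates conserved in >= min_other_genomes other genomes."""
    outdir = config.outdir / "regulon"
    outdir.mkdir(parents=True, exist_ok=True)
    genomes = {g.alias: g for g in panel.genomes}
    fam_of = {
        (alias, a.gene_id): a.family_id
        for alias, assigned in assignments.items()
        for a in assigned
    }
    family_pathway = {f.family_id: f.pathway_id for f in panel.truth.families.values()}
    # orthology through shared family assignment
    by_family: dict[str, set[tuple[str, str]]] = {}
    for key, fid in fam_of.items():
        by_family.setdefault(fid, set()).add(key)
    orthology = {
        key: members - {key}
        for fid, members in by_family.items()
        for key in members
    }
    regulons: dict[str, Regulon] = {}
    for pid in sorted(config.pathway_roles):
        regulator_fid = f"{pid}_reg"
        with_regulator = sorted(
            alias
            for alias, assigned in assignments.items()
            if any(a.family_id == regulator_fid for a in assigned)
        )
        if len(with_regulator) < 2:
            continue
        # training regions: leads of clusters holding >= 1 gene of the pathway
        lead_regions: list[UpstreamRegion] = []
        all_regions: list[UpstreamRegion] = []
        for alias in with_regulator:
            genome = genomes[alias]
            for cluster in clusters[alias]:
                lead = _cluster_lead(cluster, genome)
                try:
                    # window_down=0: coding starts are themselves conserved
                    # and would otherwise out-compete the regulatory motif
                    region = regulon.extract_upstream(
                        genome, genome.gene(lead), config.upstream_window, 0
                    )
                except regulon.UpstreamError:
                    continue
                all_regions.append(region)
                if any(
                    family_pathway.get(fam_of.get((alias, gid), "")) == pid
                    for gid in cluster.gene_ids
                ):
                    lead_regions.append(region)
        if len(lead_regions) < 2:
            continue
        pwm, training_sites = regulon.discover_motif(
            lead_regions, config.motif_length, seed=config.seed
        )
        threshold = regulon.training_threshold(pwm, training_sites)
        candidates_sites = regulon.scan_regions(pwm, threshold, all_regions)
        cands = [
            RegulonCandidate(s.genome_alias, s.gene_id, fam_of.get((s.genome_alias, s.gene_id)))
            for s in candidates_sites
        ]
        whitelist = frozenset(
            fid for fid, p in family_pathway.items() if p == pid
        )
        retained = regulon.conservation_filter(
            cands, orthology, config.min_other_genomes, whitelist
        )
        reg = Regulon(regulator_family=regulator_fid, threshold=threshold)
        retained_keys = {(c.genome_alias, c.gene_id) for c in retained}
        # membership extends over the retained lead's whole cluster
        for alias in with_regulator:
            members: set[str] = set()
            genome = genomes[alias]
            for cluster in clusters[alias]:
                lead = _cluster_lead(cluster, genome)
                if (alias, lead) in retained_keys:
                    members |= set(cluster.gene_ids)
            if members:
                reg.members[alias] = members
        reg.sites = [
            s for s in candidates_sites if (s.genome_alias, s.gene_id) in retained_keys
        ]
        regulons[pid] = reg
        regulon.write_pwm_tsv(pwm, outdir / f"{pid}.pwm.tsv")
        region_index = {r.gene_id: r for r in all_regions}
        regulon.write_sites_bed(reg.sites, region_index, outdir / f"{pid}.sites.bed")
    return regulons


@_stage("pathways")
def stage_pathways(
    config: PipelineConfig,
    panel: Panel,
    hits: dict[str, list[homology.SimilarityHit]],
) -> tuple[dict[str, list[RoleAssignment]], PathwayMatrix]:
    definitions = panel.pathway_definitions()
    assignments: dict[str, list[RoleAssignment]] = {}
    matrix = PathwayMatrix()
    for genome in panel.genomes:
        assignments[genome.alias] = pathways.assign_roles(hits[genome.alias], genome)
        for definition in definitions.values():
            matrix.calls.append(
                pathways.call_pathway(genome.alias, definition, assignments[genome.alias])
            )
    (config.outdir / "pathways").mkdir(parents=True, exist_ok=True)
    matrix.write_tsv(config.outdir / "pathways" / "status_matrix.tsv")
    return assignments, matrix


@_stage("phenotype")
def stage_phenotype(
    config: PipelineConfig, panel: Panel, matrix: PathwayMatrix
) -> phenotype.ConcordanceReport:
    substrate_map = {pid: pid for pid in config.pathway_roles}
    predicted = phenotype.predict_growth(matrix, substrate_map, panel.aliases)
    observed = {
        (alias, pid): ("p" if panel.truth.pathway_status[alias][pid] == "present" else "n")
        for alias in panel.aliases
        for pid in substrate_map
    }
    report = phenotype.score_concordance(predicted, observed)
    (config.outdir / "phenotype").mkdir(parents=True, exist_ok=True)
    phenotype.write_report_tsv(report, config.outdir / "phenotype" / "concordance.tsv")
    return report


@dataclass
class PipelineResult:
    panel: Panel
    hits: dict[str, list[homology.SimilarityHit]]
    clusters: dict[str, list[ctx.OperonCluster]]
    assignments: dict[str, list[RoleAssignment]]
    matrix: PathwayMatrix
    regulons: dict[str, Regulon]
    report: phenotype.ConcordanceReport
    summary: dict


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.outdir = Path(config.outdir)
    config.outdir.mkdir(parents=True, exist_ok=True)
    panel = stage_simulate(config)
    hits = stage_scan(config, panel)
    clusters = stage_context(config, panel)
    assignments, matrix = stage_pathways(config, panel, hits)
    regulons = stage_regulon(config, panel, assignments, clusters)
    report = stage_phenotype(config, panel, matrix)

    truth = panel.truth
    cells = [
        (alias, pid)
        for alias in panel.aliases
        for pid in sorted(config.pathway_roles)
    ]
    agree = sum(
        1
        for alias, pid in cells
        if matrix.status(alias, pid) == truth.pathway_status[alias][pid]
    )
    summary = {
        "seed": config.seed,
        "n_genomes": config.n_genomes,
        "pathways": sorted(config.pathway_roles),
        "truth_agreement": round(agree / len(cells), 4),
        "n_cells": len(cells),
        "regulons_reconstructed": sorted(regulons),
        "phenotype_counts": report.counts,
    }
    with open(config.outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return PipelineResult(
        panel, hits, clusters, assignments, matrix, regulons, report, summary
    )
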