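"""Genome context: operon-like gene clusters, coupling scores, gap filling."""

from __future__ import annotations

from dataclasses import dataclass

from sugarmap.genome import Gene, Genome, GenomeError
from sugarmap.homology import PhyleticProfile

DEFAULT_MAX_GAP = 200


@dataclass(frozen=True)
class OperonCluster:
    cluster_id: str
    replicon_id: str
    strand: str
    gene_ids: tuple[str, ...]
    span: tuple[int, int]
    max_internal_gap: int

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.gene_ids


def _gap(prev: Gene, nxt: Gene) -> int:
    # overlapping same-strand genes are tolerated: gap treated as 0
    return max(0, nxt.start - prev.end)


def call_clusters(
    genome: Genome,
    max_gap: int = DEFAULT_MAX_GAP,
    require_same_strand: bool = True,
) -> list[OperonCluster]:
    """Partition genes into maximal same-strand runs with gaps <= max_gap.

    Singletons are allowed. On replicons marked circular a run may wrap the
    origin (the first and last clusters merge when they are compatible).
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    clusters: list[OperonCluster] = []
    serial = 0
    for rid in sorted(genome.replicons):
        genes = genome.genes_on(rid)
        for g in genes:
            if g.end > len(genome.replicons[rid]):
                raise GenomeError(f"{g.gene_id}: extends past replicon {rid}")
        runs: list[list[Gene]] = []
        for g in genes:
            if runs and _gap(runs[-1][-1], g) <= max_gap and (
                not require_same_strand or runs[-1][-1].strand == g.strand
            ):
                runs[-1].append(g)
            else:
                runs.append([g])
        if (
            genome.replicons[rid].circular
            and len(runs) > 1
            and (not require_same_strand or runs[0][0].strand == runs[-1][-1].strand)
        ):
            wrap_gap = max(
                0, len(genome.replicons[rid]) - runs[-1][-1].end + runs[0][0].start
            )
            if wrap_gap <= max_gap:
                runs[0] = runs.pop() + runs[0]
        for run in runs:
            gaps = [_gap(a, b) for a, b in zip(run, run[1:])]
            clusters.append(
                OperonCluster(
                    cluster_id=f"{genome.alias}_c{serial}",
                    replicon_id=rid,
                    strand=run[0].strand if require_same_strand else ".",
                    gene_ids=tuple(g.gene_id for g in run),
                    span=(min(g.start for g in run), max(g.end for g in run)),
                    max_internal_gap=max(gaps) if gaps else 0,
                )
            )
            serial += 1
    return clusters


def co_clustering_fraction(
    members_a: dict[str, set[str]],
    members_b: dict[str, set[str]],
    clusters: dict[str, list[OperonCluster]],
) -> float | None:
    """Fraction of co-present genomes in which families A and B share a cluster.

    ``members_*`` map genome alias -> gene ids of that family; ``clusters``
    maps alias -> cluster calls. Returns None when no genome holds both
    families (undefined, deliberately not 0).
    """
    co_present = [
        g for g in clusters if members_a.get(g) and members_b.get(g)
    ]
    if not co_present:
        return None
    shared = 0
    for g in co_present:
        for cluster in clusters[g]:
            ids = set(cluster.gene_ids)
            if ids & members_a[g] and ids & members_b[g]:
                shared += 1
                break
    return shared / len(co_present)


def cooccurrence_score(a: PhyleticProfile, b: PhyleticProfile) -> float | None:
    """Jaccard index of two presence profiles; None when both are empty."""
    if a.genomes != b.genomes:
        raise ValueError("profiles must enumerate the same genomes")
    inter = sum(1 for x, y in zip(a.presence, b.presence) if x and y)
    union = sum(1 for x, y in zip(a.presence, b.presence) if x or y)
    if union == 0:
        return None
    return inter / union


def propose_gap_fillers(
    genome: Genome,
    pathway_gene_ids: set[str],
    assigned_gene_ids: set[str],
    clusters: list[OperonCluster],
    regulon_members: set[str] | None = None,
) -> list[str]:
    """Rank unassigned genes likely to fill missing roles of a pathway.

    Candidates share a cluster and/or regulon with >= 1 gene already assigned
    to the pathway; ranking is (cluster and regulon) > cluster-only >
    regulon-only, ties broken by distance to the nearest pathway gene.
    ``assigned_gene_ids`` are genes with any family assignment (candidates
    must not be among them); returns [] when the genome holds no pathway gene.
    """
    regulon_members = regulon_members or set()
    anchors = pathway_gene_ids & {g.gene_id for g in genome.genes}
    if not anchors:
        return []
    in_cluster: set[str] = set()
    for cluster in clusters:
        ids = set(cluster.gene_ids)
        if ids & anchors:
            in_cluster |= ids
    anchor_genes = [g for g in genome.genes if g.gene_id in anchors]

    def distance(gene: Gene) -> int:
        best = None
        for a in anchor_genes:
            if a.replicon_id != gene.replicon_id:
                continue
            d = max(0, max(a.start, gene.start) - min(a.end, gene.end))
            best = d if best is None else min(best, d)
        return best if best is not None else 10**12

    scored: list[tuple[int, int, str]] = []
    for gene in genome.genes:
        gid = gene.gene_id
        if gid in assigned_gene_ids or gid in anchors:
            continue
        has_cluster = gid in in_cluster
        has_regulon = gid in regulon_members
        if not (has_cluster or has_regulon):
            continue
        rank = 0 if (has_cluster and has_regulon) else (1 if has_cluster else 2)
        scored.append((rank, distance(gene), gid))
    scored.sort()
    return [gid for _, _, gid in scored]


def write_clusters_tsv(clusters: list[OperonCluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\treplicon\tstrand\tgenes\tstart\tend\tmax_gap\n")
        for c in clusters:
            fh.write(
                f"{c.cluster_id}\t{c.replicon_id}\t{c.strand}\t"
                f"{','.join(c.gene_ids)}\t{c.span[0]}\t{c.span[1]}\t{c.max_internal_gap}\n"
            )
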