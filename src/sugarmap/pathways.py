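"""Role assignment, per-genome pathway presence calls, and audits.

A pathway is *present* when every required role is covered by at least one
intact assigned gene, *impaired* when every covering gene of some required
role is a pseudogene (one intact paralog rescues presence), and *absent*
otherwise. Required roles are the transport + enzyme roles of the pathway;
regulators and auxiliary genes inform context but do not gate presence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from sugarmap.context import OperonCluster
from sugarmap.genome import Genome
from sugarmap.homology import SimilarityHit
from sugarmap.registry import PathwayDefinition

STATUS_PRESENT = "present"
STATUS_IMPAIRED = "impaired"
STATUS_ABSENT = "absent"


@dataclass(frozen=True)
class RoleAssignment:
    genome_alias: str
    gene_id: str
    family_id: str
    score: int
    identity: float
    pseudo: bool = False


@dataclass(frozen=True)
class PathwayCall:
    genome_alias: str
    pathway_id: str
    status: str
    missing_roles: frozenset[str] = frozenset()
    disrupted_roles: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.status == STATUS_PRESENT and (self.missing_roles or self.disrupted_roles):
            raise ValueError("present call cannot carry missing/disrupted roles")
        if self.status == STATUS_IMPAIRED and self.missing_roles:
            raise ValueError("impaired call cannot carry missing roles")


def assign_roles(
    hits: list[SimilarityHit], genome: Genome
) -> list[RoleAssignment]:
    """One best family per gene: highest score, ties by identity then
    lexicographic family_id; unassigned genes are omitted."""
    by_gene: dict[str, list[SimilarityHit]] = {}
    for h in hits:
        by_gene.setdefault(h.gene_id, []).append(h)
    pseudo_flags = {g.gene_id: g.pseudo for g in genome.genes}
    assignments: list[RoleAssignment] = []
    for gene_id in sorted(by_gene):
        best = min(by_gene[gene_id], key=lambda h: (-h.score, -h.identity, h.family_id))
        assignments.append(
            RoleAssignment(
                genome_alias=genome.alias,
                gene_id=gene_id,
                family_id=best.family_id,
                score=best.score,
                identity=best.identity,
                pseudo=pseudo_flags.get(gene_id, False),
            )
        )
    return assignments


def call_pathway(
    genome_alias: str,
    definition: PathwayDefinition,
    assignments: list[RoleAssignment],
) -> PathwayCall:
    if not definition.required_roles:
        raise ValueError(f"{definition.pathway_id}: empty required role set")
    missing: set[str] = set()
    disrupted: set[str] = set()
    for role in definition.required_roles:
        covering = [
            a for a in assignments
            if a.genome_alias == genome_alias and a.family_id == role
        ]
        if not covering:
            missing.add(role)
        elif all(a.pseudo for a in covering):
            disrupted.add(role)
    if missing:
        status = STATUS_ABSENT
    elif disrupted:
        status = STATUS_IMPAIRED
    else:
        status = STATUS_PRESENT
    return PathwayCall(
        genome_alias=genome_alias,
        pathway_id=definition.pathway_id,
        status=status,
        missing_roles=frozenset(missing) if status == STATUS_ABSENT else frozenset(),
        disrupted_roles=frozenset(disrupted),
    )


def list_missing_genes(
    calls: list[PathwayCall], definitions: dict[str, PathwayDefinition]
) -> list[tuple[str, str, str]]:
    """(genome, pathway, role) triples for genuine gaps: absent pathways with
    at least one required role found (wholly absent pathways are losses)."""
    triples: list[tuple[str, str, str]] = []
    for call in calls:
        if call.status != STATUS_ABSENT:
            continue
        n_required = len(definitions[call.pathway_id].required_roles)
        if len(call.missing_roles) == n_required:
            continue
        for role in sorted(call.missing_roles):
            triples.append((call.genome_alias, call.pathway_id, role))
    return triples


def list_disconnected_genes(
    assignments: list[RoleAssignment],
    calls: list[PathwayCall],
    family_pathway: dict[str, str],
    clusters: list[OperonCluster],
    regulon_members: dict[str, set[str]] | None = None,
) -> list[str]:
    """Genes assigned to a pathway called absent in their genome that share
    no cluster (and no regulon) with any same-pathway gene."""
    regulon_members = regulon_members or {}
    status = {(c.genome_alias, c.pathway_id): c.status for c in calls}
    out: list[str] = []
    for a in assignments:
        pid = family_pathway.get(a.family_id)
        if pid is None or status.get((a.genome_alias, pid)) != STATUS_ABSENT:
            continue
        mates = {
            b.gene_id
            for b in assignments
            if b.genome_alias == a.genome_alias
            and b.gene_id != a.gene_id
            and family_pathway.get(b.family_id) == pid
        }
        linked = False
        for cluster in clusters:
            if a.gene_id in cluster.gene_ids and mates & set(cluster.gene_ids):
                linked = True
                break
        if not linked:
            members = regulon_members.get(pid, set())
            if a.gene_id in members and mates & members:
                linked = True
        if not linked:
            out.append(a.gene_id)
    return sorted(set(out))


@dataclass
class PathwayMatrix:
    """Genomes x pathways status matrix with TSV emission."""

    calls: list[PathwayCall] = field(default_factory=list)

    def status(self, genome_alias: str, pathway_id: str) -> str:
        for c in self.calls:
            if c.genome_alias == genome_alias and c.pathway_id == pathway_id:
                return c.status
        raise KeyError((genome_alias, pathway_id))

    def write_tsv(self, path) -> None:
        genomes = sorted({c.genome_alias for c in self.calls})
        pathways = sorted({c.pathway_id for c in self.calls})
        code = {STATUS_PRESENT: "P", STATUS_IMPAIRED: "I", STATUS_ABSENT: "A"}
        with open(path, "w") as fh:
            fh.write("genome\t" + "\t".join(pathways) + "\n")
            for g in genomes:
                fh.write(g + "\t" + "\t".join(code[self.status(g, p)] for p in pathways) + "\n")
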