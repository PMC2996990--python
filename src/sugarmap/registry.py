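"""Packaged family/pathway/genome/phenotype fixtures and summary arithmetic.

The fixtures are versioned TSV files under :mod:`sugarmap.data`. Loading
validates closed vocabularies and grid completeness; the summary exposes the
counting identities used elsewhere (total = assigned + unassigned,
peripheral = total - ccm - unassigned).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

ROLE_CLASSES = frozenset(
    {"transport", "regulation", "enzyme", "auxiliary", "upstream", "ccm"}
)
PATHWAY_IDS = frozenset(
    {
        "Nag", "Grt", "Bgl", "Scr", "Mal", "Ara", "Gal", "Gnt", "Aga",
        "Man", "Tre", "Xlt", "Rbs", "Nan", "Alg", "Mtl", "Glc", "CCM",
        "Unassigned",
    }
)
SUBSTRATES = (
    "Glc", "Nag", "Grt", "Bgl", "Scr", "Mal", "Ara", "Gal", "Gnt", "Aga",
    "Tre", "Mtl",
)
PREDICTED_STATES = frozenset({"+", "-"})
OBSERVED_STATES = frozenset({"p", "n", "w", "nd"})

N_STRAINS = 14

#: Size of the original query-family collection the registry extends.
BASE_COLLECTION_SIZE = 480


class RegistryError(ValueError):
    """Fixture fails parsing or vocabulary validation."""


@dataclass(frozen=True)
class FamilyRecord:
    family_id: str
    role_name: str
    role_class: str
    pathway_id: str
    novel: bool
    count_in_registry: int = 1


@dataclass(frozen=True)
class PathwayDefinition:
    pathway_id: str
    required_roles: frozenset[str]
    n_genomes_expected: int | None = None
    n_genes_expected: int | None = None


@dataclass(frozen=True)
class GenomeRecord:
    alias: str
    full_name: str
    total_genes: int
    sugar_genes: int
    sugar_pathways: int


@dataclass(frozen=True)
class PhenotypeCell:
    strain_alias: str
    substrate_id: str
    predicted: str
    observed: str
    flagged_inconsistent: bool = False


@dataclass
class Registry:
    families: dict[str, FamilyRecord] = field(default_factory=dict)
    pathways: dict[str, PathwayDefinition] = field(default_factory=dict)

    def families_of(self, pathway_id: str) -> list[FamilyRecord]:
        return [f for f in self.families.values() if f.pathway_id == pathway_id]

    def glc_definition(self) -> PathwayDefinition:
        """Glucose utilization modeled as permease + glucokinase.

        The pathway table carries no dedicated glucose row; its components
        live inside the maltodextrin/beta-glucoside loci, so the definition
        is synthesized from those families.
        """
        required = frozenset(
            fid for fid in ("fam_glcPMal", "fam_glk2") if fid in self.families
        )
        if not required:
            raise RegistryError("glucose component families missing from registry")
        return PathwayDefinition("Glc", required)


@dataclass(frozen=True)
class EncyclopediaSummary:
    total: int
    assigned: int
    unassigned: int
    ccm: int
    peripheral: int
    novel_total: int
    novel_by_class: dict[str, int]

    def to_json(self) -> str:
        return json.dumps(
            {
                "total": self.total,
                "assigned": self.assigned,
                "unassigned": self.unassigned,
                "ccm": self.ccm,
                "peripheral": self.peripheral,
                "novel_total": self.novel_total,
                "novel_by_class": self.novel_by_class,
            },
            indent=2,
        )


@dataclass
class PhenotypeMatrix:
    cells: dict[tuple[str, str], PhenotypeCell] = field(default_factory=dict)

    @property
    def strains(self) -> list[str]:
        seen: list[str] = []
        for strain, _ in self.cells:
            if strain not in seen:
                seen.append(strain)
        return seen

    @property
    def substrates(self) -> list[str]:
        return list(SUBSTRATES)

    def cell(self, strain: str, substrate: str) -> PhenotypeCell:
        return self.cells[(strain, substrate)]


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------


def _data_path(name: str) -> Path:
    return Path(str(resources.files("sugarmap.data").joinpath(name)))


def _read_tsv(path: Path) -> list[dict[str, str]]:
    with open(path) as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    return list(csv.DictReader(lines, delimiter="\t"))


def load_registry(
    families_path: Path | None = None, pathways_path: Path | None = None
) -> Registry:
    """Load and validate the family registry and pathway definitions.

    With no arguments the packaged fixtures (main-text tables) are used.
    Required roles of each pathway are its transport + enzyme families;
    pathways without any (e.g. central metabolism) require all of their
    families.
    """
    families_path = families_path or _data_path("registry_families.tsv")
    pathways_path = pathways_path or _data_path("pathways.tsv")
    registry = Registry()
    for i, row in enumerate(_read_tsv(families_path), start=1):
        try:
            rec = FamilyRecord(
                family_id=row["family_id"],
                role_name=row["role_name"],
                role_class=row["role_class"],
                pathway_id=row["pathway_id"],
                novel=row["novel"] in ("1", "true", "True"),
                count_in_registry=int(row.get("count", 1)),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise RegistryError(f"{families_path.name} row {i}: malformed ({exc})")
        if rec.role_class not in ROLE_CLASSES:
            raise RegistryError(
                f"{families_path.name} row {i}: unknown role_class {rec.role_class!r}"
            )
        if rec.pathway_id not in PATHWAY_IDS:
            raise RegistryError(
                f"{families_path.name} row {i}: unknown pathway_id {rec.pathway_id!r}"
            )
        if rec.count_in_registry < 1:
            raise RegistryError(f"{families_path.name} row {i}: count < 1")
        if rec.family_id in registry.families:
            raise RegistryError(
                f"{families_path.name} row {i}: duplicate family_id {rec.family_id}"
            )
        registry.families[rec.family_id] = rec

    for i, row in enumerate(_read_tsv(pathways_path), start=1):
        pid = row.get("pathway_id", "")
        if pid not in PATHWAY_IDS:
            raise RegistryError(f"{pathways_path.name} row {i}: unknown pathway_id {pid!r}")
        if pid in registry.pathways:
            raise RegistryError(f"{pathways_path.name} row {i}: duplicate pathway {pid}")
        members = registry.families_of(pid)
        required = frozenset(
            f.family_id for f in members if f.role_class in ("transport", "enzyme")
        ) or frozenset(f.family_id for f in members)
        registry.pathways[pid] = PathwayDefinition(
            pathway_id=pid,
            required_roles=required,
            n_genomes_expected=int(row["n_genomes"]),
            n_genes_expected=int(row["n_genes"]),
        )
    return registry


def summarize_registry(registry: Registry) -> EncyclopediaSummary:
    fams = list(registry.families.values())
    total = len(fams)
    unassigned = sum(1 for f in fams if f.pathway_id == "Unassigned")
    ccm = sum(1 for f in fams if f.role_class == "ccm")
    novel_by_class: dict[str, int] = {}
    for f in fams:
        if f.novel:
            novel_by_class[f.role_class] = novel_by_class.get(f.role_class, 0) + 1
    return EncyclopediaSummary(
        total=total,
        assigned=total - unassigned,
        unassigned=unassigned,
        ccm=ccm,
        peripheral=total - ccm - unassigned,
        novel_total=sum(novel_by_class.values()),
        novel_by_class=novel_by_class,
    )


def load_genome_table(path: Path | None = None) -> dict[str, GenomeRecord]:
    path = path or _data_path("genomes.tsv")
    out: dict[str, GenomeRecord] = {}
    for i, row in enumerate(_read_tsv(path), start=1):
        rec = GenomeRecord(
            alias=row["alias"],
            full_name=row["full_name"],
            total_genes=int(row["total_genes"]),
            sugar_genes=int(row["sugar_genes"]),
            sugar_pathways=int(row["sugar_pathways"]),
        )
        if rec.alias in out:
            raise RegistryError(f"{path.name} row {i}: duplicate alias {rec.alias}")
        if min(rec.total_genes, rec.sugar_genes, rec.sugar_pathways) < 0:
            raise RegistryError(f"{path.name} row {i}: negative count")
        out[rec.alias] = rec
    return out


def load_phenotype_matrix(path: Path | None = None) -> PhenotypeMatrix:
    path = path or _data_path("phenotypes.tsv")
    matrix = PhenotypeMatrix()
    for i, row in enumerate(_read_tsv(path), start=1):
        cell = PhenotypeCell(
            strain_alias=row["strain"],
            substrate_id=row["substrate"],
            predicted=row["predicted"],
            observed=row["observed"],
            flagged_inconsistent=row.get("flag", "0") == "1",
        )
        if cell.substrate_id not in SUBSTRATES:
            raise RegistryError(f"{path.name} row {i}: unknown substrate {cell.substrate_id}")
        if cell.predicted not in PREDICTED_STATES:
            raise RegistryError(f"{path.name} row {i}: bad predicted {cell.predicted!r}")
        if cell.observed not in OBSERVED_STATES:
            raise RegistryError(f"{path.name} row {i}: bad observed {cell.observed!r}")
        key = (cell.strain_alias, cell.substrate_id)
        if key in matrix.cells:
            raise RegistryError(f"{path.name} row {i}: duplicate cell {key}")
        matrix.cells[key] = cell
    strains = matrix.strains
    if len(strains) != N_STRAINS:
        raise RegistryError(f"expected {N_STRAINS} strains, found {len(strains)}")
    for strain in strains:
        for sub in SUBSTRATES:
            if (strain, sub) not in matrix.cells:
                raise RegistryError(f"missing cell ({strain}, {sub})")
    return matrix
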