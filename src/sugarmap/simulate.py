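"""Seeded synthetic genome panels with machine-readable ground truth.

Each panel plants per-pathway homolog families at a controlled percent
identity, arranges pathway genes in compact operons, embeds one regulator
binding site (drawn from a ground-truth PWM) in the upstream window of every
operon lead, distributes pathways mosaically across genomes, and can disrupt
chosen genes by a frameshift or an insertion-element cassette. Outputs are
plain text (FASTA, GFF3, BED, JSON) and byte-identical under a fixed seed.

Intergenic background is i.i.d. uniform nucleotides; substitutions during
homolog generation are drawn proportional to exponentiated BLOSUM62 row
scores so that low-identity homologs stay detectable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

from sugarmap.genome import (
    Gene,
    Genome,
    Replicon,
    reverse_complement,
    translate,
    write_genome,
)
from sugarmap.registry import PathwayDefinition
from sugarmap.regulon import BASES

AA20 = "ACDEFGHIKLMNPQRSTVWY"

PSEUDOGENE_MODES = ("frameshift", "insertion_element")
INSERTION_CASSETTE_LENGTH = 1000


class SimulationError(ValueError):
    """Invalid panel configuration or infeasible packing."""


@dataclass(frozen=True)
class SyntheticFamily:
    family_id: str
    pathway_id: str
    role_class: str
    consensus: str
    regulator: bool = False


@dataclass(frozen=True)
class TruthSite:
    genome_alias: str
    gene_id: str
    start: int  # replicon coordinates, 0-based half-open
    end: int
    strand: str
    word: str
    pathway_id: str


@dataclass
class TruthTable:
    families: dict[str, SyntheticFamily] = field(default_factory=dict)
    gene_families: dict[tuple[str, str], str] = field(default_factory=dict)
    pathway_status: dict[str, dict[str, str]] = field(default_factory=dict)
    sites: list[TruthSite] = field(default_factory=list)
    pwm_counts: dict[str, list[list[float]]] = field(default_factory=dict)

    def members_of(self, family_id: str) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for (alias, gene_id), fid in self.gene_families.items():
            if fid == family_id:
                out.setdefault(alias, set()).add(gene_id)
        return out


@dataclass
class PanelConfig:
    n_genomes: int = 10
    pathway_roles: dict[str, int] = field(default_factory=lambda: {"Syn1": 3})
    scenario: dict[str, frozenset[int]] = field(default_factory=dict)
    identity_target: float = 0.6
    protein_length: int = 120
    motif_length: int = 16
    motif_dominant: float = 0.88
    palindromic: bool = False
    upstream_window: int = 300
    operon_gap: int = 50
    spacer: int = 600
    n_decoys: int = 2
    replicon_length: int | None = None
    pseudogene_plan: list[tuple[int, str, str]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.identity_target <= 1):
            raise SimulationError("identity_target must be in (0, 1]")
        if self.n_genomes < 1:
            raise SimulationError("need >= 1 genome")
        if not self.scenario:
            self.scenario = {
                pid: frozenset(range(self.n_genomes)) for pid in self.pathway_roles
            }
        for pid, idx in self.scenario.items():
            if pid not in self.pathway_roles:
                raise SimulationError(f"scenario pathway {pid} has no role count")
            if idx and (min(idx) < 0 or max(idx) >= self.n_genomes):
                raise SimulationError(f"scenario indices out of range for {pid}")
        if self.spacer < self.upstream_window + self.motif_length + 40:
            raise SimulationError("spacer too small for the upstream window")


@dataclass
class Panel:
    config: PanelConfig
    genomes: list[Genome]
    truth: TruthTable

    @property
    def aliases(self) -> list[str]:
        return [g.alias for g in self.genomes]

    def family_consensus(self) -> dict[str, str]:
        return {fid: f.consensus for fid, f in self.truth.families.items()}

    def pathway_definitions(self) -> dict[str, PathwayDefinition]:
        """Required roles are the non-regulator families of each pathway."""
        out: dict[str, PathwayDefinition] = {}
        for pid in self.config.pathway_roles:
            required = frozenset(
                f.family_id
                for f in self.truth.families.values()
                if f.pathway_id == pid and not f.regulator
            )
            out[pid] = PathwayDefinition(pid, required)
        return out

    def write(self, outdir: Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for genome in self.genomes:
            write_genome(genome, outdir)
        with open(outdir / "sites.bed", "w") as fh:
            for s in self.truth.sites:
                fh.write(
                    f"{s.genome_alias}\t{s.start}\t{s.end}\t{s.gene_id}\t0\t{s.strand}\n"
                )
        payload = {
            "families": {
                fid: {
                    "pathway_id": f.pathway_id,
                    "role_class": f.role_class,
                    "regulator": f.regulator,
                    "consensus": f.consensus,
                }
                for fid, f in self.truth.families.items()
            },
            "gene_families": {
                f"{alias}:{gid}": fid
                for (alias, gid), fid in self.truth.gene_families.items()
            },
            "pathway_status": self.truth.pathway_status,
            "pwm_counts": self.truth.pwm_counts,
        }
        with open(outdir / "truth.json", "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Primitive operations
# ---------------------------------------------------------------------------

_blosum = substitution_matrices.load("BLOSUM62")
_AA_INDEX = {aa: i for i, aa in enumerate(AA20)}
_SUB_PROBS = np.zeros((20, 20))
for _i, _a in enumerate(AA20):
    row = np.array([float(_blosum[_a][_b]) for _b in AA20])
    w = np.exp(row / 2.0)
    w[_i] = 0.0  # substitution must change the residue
    _SUB_PROBS[_i] = w / w.sum()

_CODONS: dict[str, list[str]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    _CODONS.setdefault(_aa, []).append(_codon)
for _aa in _CODONS:
    _CODONS[_aa].sort()


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def mutate_protein(
    consensus: str, identity_target: float, seed: int | np.random.Generator = 0
) -> str:
    """Substitute positions of ``consensus`` down to the target identity.

    The number of substituted positions is ``round(L * (1 - target))``;
    replacement residues are drawn BLOSUM62-proportionally, so realized
    identity equals the rounded target exactly. Deterministic per seed.
    """
    if not consensus:
        raise SimulationError("empty consensus")
    if not (0 < identity_target <= 1):
        raise SimulationError("identity_target must be in (0, 1]")
    rng = _as_rng(seed)
    L = len(consensus)
    n_mut = round(L * (1 - identity_target))
    if n_mut == 0:
        return consensus
    positions = rng.choice(L, size=n_mut, replace=False)
    out = list(consensus)
    for pos in sorted(positions):
        idx = _AA_INDEX[consensus[pos]]
        out[pos] = AA20[rng.choice(20, p=_SUB_PROBS[idx])]
    return "".join(out)


def plant_operon(
    offset: int,
    gene_lengths: list[int],
    gaps: list[int],
    strand: str,
    replicon_length: int,
) -> list[tuple[int, int]]:
    """Coordinates of contiguous same-strand genes separated by given gaps."""
    if len(gaps) < len(gene_lengths) - 1:
        raise SimulationError("need one intergenic gap per adjacent gene pair")
    if any(g < 0 for g in gaps):
        raise SimulationError("gaps must be >= 0")
    if strand not in ("+", "-"):
        raise SimulationError(f"invalid strand {strand!r}")
    coords: list[tuple[int, int]] = []
    cursor = offset
    for i, length in enumerate(gene_lengths):
        if i > 0:
            cursor += gaps[i - 1]
        coords.append((cursor, cursor + length))
        cursor += length
    if cursor > replicon_length:
        raise SimulationError("operon overflows the replicon")
    return coords


def sample_site_word(counts: np.ndarray, rng: np.random.Generator) -> str:
    counts = np.asarray(counts, dtype=float)
    probs = counts / counts.sum(axis=1, keepdims=True)
    return "".join(BASES[rng.choice(4, p=p)] for p in probs)


def plant_sites(
    pwm_counts: np.ndarray,
    windows: list[str],
    seed: int | np.random.Generator = 0,
    palindromic: bool = False,
) -> tuple[list[tuple[int, str, str]], list[str]]:
    """Embed one PWM-sampled site per upstream window.

    Returns ``(records, new_windows)`` where each record is
    (offset, strand, word) with the word in window orientation. The strand is
    '+' unless ``palindromic``, in which case it is drawn at random.
    """
    rng = _as_rng(seed)
    counts = np.asarray(pwm_counts, dtype=float)
    L = counts.shape[0]
    records: list[tuple[int, str, str]] = []
    out_windows: list[str] = []
    for window in windows:
        if len(window) < L:
            raise SimulationError(
                f"window length {len(window)} shorter than motif length {L}"
            )
        word = sample_site_word(counts, rng)
        offset = int(rng.integers(len(window) - L + 1))
        strand = "+" if not palindromic else ("+" if rng.integers(2) == 0 else "-")
        embedded = word if strand == "+" else reverse_complement(word)
        out_windows.append(window[:offset] + embedded + window[offset + L :])
        records.append((offset, strand, word))
    return records, out_windows


def inject_pseudogene(
    genome: Genome, gene_id: str, mode: str, seed: int | np.random.Generator = 0
) -> Genome:
    """Disrupt a gene in place by frameshift or insertion-element cassette.

    A frameshift deletes one nucleotide mid-gene; an insertion element adds a
    1 kb random cassette. The gene's protein is re-translated so it truncates
    or garbles downstream of the lesion, downstream coordinates shift, and
    the pseudo flag is set. Disrupting an already-pseudo gene is an error.
    """
    if mode not in PSEUDOGENE_MODES:
        raise SimulationError(f"unknown pseudogene mode {mode!r}")
    rng = _as_rng(seed)
    gene = genome.gene(gene_id)
    if gene.pseudo:
        raise SimulationError(f"{gene_id} is already a pseudogene")
    rep = genome.replicons[gene.replicon_id]
    lesion = gene.start + gene.length // 2
    if mode == "frameshift":
        rep.sequence = rep.sequence[:lesion] + rep.sequence[lesion + 1 :]
        delta = -1
    else:
        cassette = "".join(BASES[i] for i in rng.integers(0, 4, INSERTION_CASSETTE_LENGTH))
        rep.sequence = rep.sequence[:lesion] + cassette + rep.sequence[lesion:]
        delta = INSERTION_CASSETTE_LENGTH
    for g in genome.genes:
        if g.replicon_id != gene.replicon_id:
            continue
        if g.gene_id == gene_id:
            g.end += delta
            g.pseudo = True
        elif g.start >= lesion:
            g.start += delta
            g.end += delta
    gene.protein = translate(genome.cds_nucleotides(gene))
    return genome


# ---------------------------------------------------------------------------
# Panel assembly
# ---------------------------------------------------------------------------


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(AA20[i] for i in rng.integers(0, 20, length))


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    codons = [
        _CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in protein
    ]
    return "".join(codons) + "TAA"


def _truth_pwm(rng: np.random.Generator, length: int, dominant: float) -> np.ndarray:
    """Integer-count PWM with one dominant base per column."""
    counts = np.zeros((length, 4))
    total = 100
    dom = int(round(dominant * total))
    rest = (total - dom) // 3
    for k in range(length):
        b = int(rng.integers(4))
        counts[k] = rest
        counts[k, b] = total - 3 * rest
    return counts


_ROLE_CYCLE = ("transport", "enzyme", "enzyme", "transport", "enzyme")


def make_families(config: PanelConfig, rng: np.random.Generator) -> dict[str, SyntheticFamily]:
    families: dict[str, SyntheticFamily] = {}
    for pid in sorted(config.pathway_roles):
        reg_id = f"{pid}_reg"
        families[reg_id] = SyntheticFamily(
            reg_id, pid, "regulation", _random_protein(rng, config.protein_length), True
        )
        for i in range(config.pathway_roles[pid]):
            fid = f"{pid}_r{i}"
            families[fid] = SyntheticFamily(
                fid,
                pid,
                _ROLE_CYCLE[i % len(_ROLE_CYCLE)],
                _random_protein(rng, config.protein_length),
            )
    return families


def simulate_panel(config: PanelConfig) -> Panel:
    """Build a genome panel and its truth table from a seeded config."""
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_genomes + 2)
    rng_global = np.random.default_rng(children[0])

    truth = TruthTable()
    truth.families = make_families(config, rng_global)
    pwms = {
        pid: _truth_pwm(rng_global, config.motif_length, config.motif_dominant)
        for pid in sorted(config.pathway_roles)
    }
    truth.pwm_counts = {pid: counts.tolist() for pid, counts in pwms.items()}

    genomes: list[Genome] = []
    for gi in range(config.n_genomes):
        rng = np.random.default_rng(children[gi + 1])
        alias = f"G{gi:02d}"
        rid = f"{alias}_chr"
        plan: list[dict] = []  # gene placements
        site_plan: list[dict] = []
        cursor = 150
        serial = 0

        def place(family: SyntheticFamily | None, start: int, strand: str) -> dict:
            nonlocal serial
            if family is None:
                protein = _random_protein(rng, config.protein_length)
            elif config.identity_target >= 1.0:
                protein = family.consensus
            else:
                protein = mutate_protein(family.consensus, config.identity_target, rng)
            nt = _reverse_translate(protein, rng)
            entry = {
                "gene_id": f"{alias}_{serial:04d}",
                "family": family.family_id if family else None,
                "start": start,
                "end": start + len(nt),
                "strand": strand,
                "protein": protein,
                "nt": nt,
            }
            serial += 1
            plan.append(entry)
            return entry

        truth.pathway_status[alias] = {}
        for p_index, pid in enumerate(sorted(config.pathway_roles)):
            if gi not in config.scenario.get(pid, frozenset()):
                truth.pathway_status[alias][pid] = "absent"
                continue
            truth.pathway_status[alias][pid] = "present"
            reg_fam = truth.families[f"{pid}_reg"]
            reg = place(reg_fam, cursor, "+")
            cursor = reg["end"] + config.spacer
            strand = "+" if p_index % 2 == 0 else "-"
            role_fams = [
                truth.families[f"{pid}_r{i}"] for i in range(config.pathway_roles[pid])
            ]
            if strand == "-":
                role_fams = role_fams[::-1]  # transcribed right-to-left
            operon_entries = []
            for fam in role_fams:
                entry = place(fam, cursor, strand)
                operon_entries.append(entry)
                cursor = entry["end"] + config.operon_gap
            cursor += config.spacer - config.operon_gap
            lead = operon_entries[0] if strand == "+" else operon_entries[-1]
            # one PWM-sampled site in the lead gene's upstream window
            L = config.motif_length
            word = sample_site_word(pwms[pid], rng)
            if strand == "+":
                lo = lead["start"] - config.upstream_window + 20
                hi = lead["start"] - L - 10
                pos = int(rng.integers(lo, hi + 1))
                site_plan.append(
                    {"pos": pos, "seq": word, "strand": "+", "gene": lead["gene_id"], "word": word, "pathway": pid}
                )
            else:
                lo = lead["end"] + 10
                hi = lead["end"] + config.upstream_window - L - 20
                pos = int(rng.integers(lo, hi + 1))
                site_plan.append(
                    {"pos": pos, "seq": reverse_complement(word), "strand": "-", "gene": lead["gene_id"], "word": word, "pathway": pid}
                )

        for d in range(config.n_decoys):
            entry = place(None, cursor, "+" if d % 2 == 0 else "-")
            cursor = entry["end"] + config.spacer

        needed = cursor + 150
        length = config.replicon_length or needed
        if length < needed:
            raise SimulationError(
                f"replicon_length {length} cannot hold {needed} bp of planted content"
            )
        seq = rng.integers(0, 4, length)
        chars = np.frombuffer(BASES.encode(), dtype=np.uint8)
        arr = chars[seq]
        for entry in plan:
            nt = entry["nt"] if entry["strand"] == "+" else reverse_complement(entry["nt"])
            arr[entry["start"] : entry["end"]] = np.frombuffer(nt.encode(), dtype=np.uint8)
        for site in site_plan:
            arr[site["pos"] : site["pos"] + len(site["seq"])] = np.frombuffer(
                site["seq"].encode(), dtype=np.uint8
            )
        genome = Genome(
            alias=alias,
            replicons={rid: Replicon(rid, arr.tobytes().decode())},
            genes=[
                Gene(
                    gene_id=e["gene_id"],
                    replicon_id=rid,
                    start=e["start"],
                    end=e["end"],
                    strand=e["strand"],
                    protein=e["protein"],
                )
                for e in plan
            ],
        )
        genomes.append(genome)
        for e in plan:
            if e["family"] is not None:
                truth.gene_families[(alias, e["gene_id"])] = e["family"]
        for site in site_plan:
            truth.sites.append(
                TruthSite(
                    genome_alias=alias,
                    gene_id=site["gene"],
                    start=site["pos"],
                    end=site["pos"] + len(site["seq"]),
                    strand=site["strand"],
                    word=site["word"],
                    pathway_id=site["pathway"],
                )
            )

    rng_pseudo = np.random.default_rng(children[-1])
    for gi, family_id, mode in config.pseudogene_plan:
        alias = f"G{gi:02d}"
        members = truth.members_of(family_id).get(alias)
        if not members:
            raise SimulationError(f"{family_id} has no member in genome {alias}")
        gene_id = sorted(members)[0]
        target = genomes[gi].gene(gene_id)
        lesion = target.start + target.length // 2
        delta = -1 if mode == "frameshift" else INSERTION_CASSETTE_LENGTH
        inject_pseudogene(genomes[gi], gene_id, mode, rng_pseudo)
        truth.sites = [
            TruthSite(
                s.genome_alias,
                s.gene_id,
                s.start + (delta if s.start >= lesion else 0),
                s.end + (delta if s.start >= lesion else 0),
                s.strand,
                s.word,
                s.pathway_id,
            )
            if s.genome_alias == alias
            else s
            for s in truth.sites
        ]
        fam = truth.families[family_id]
        if not fam.regulator and truth.pathway_status[alias][fam.pathway_id] == "present":
            truth.pathway_status[alias][fam.pathway_id] = "impaired"

    return Panel(config=config, genomes=genomes, truth=truth)
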