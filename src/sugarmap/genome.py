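"""Core genome data model and plain-text genome I/O.

Coordinates are 0-based half-open internally; GFF3 emission converts to the
standard 1-based inclusive convention. Strand is ``'+'`` or ``'-'``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio.Seq import Seq


class GenomeError(ValueError):
    """Malformed genome content (coordinates, strands, sequences)."""


@dataclass
class Gene:
    """A protein-coding gene on a replicon.

    ``protein`` is the translated product actually encoded at the locus; for
    pseudogenes it is truncated/garbled downstream of the lesion.
    """

    gene_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    protein: str = ""
    pseudo: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GenomeError(f"{self.gene_id}: invalid strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise GenomeError(
                f"{self.gene_id}: invalid coordinates [{self.start},{self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Replicon:
    replicon_id: str
    sequence: str
    circular: bool = False

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Genome:
    alias: str
    replicons: dict[str, Replicon] = field(default_factory=dict)
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise GenomeError(f"duplicate gene_id {g.gene_id}")
            seen.add(g.gene_id)

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def genes_on(self, replicon_id: str) -> list[Gene]:
        """Genes on one replicon sorted by (start, end, gene_id)."""
        return sorted(
            (g for g in self.genes if g.replicon_id == replicon_id),
            key=lambda g: (g.start, g.end, g.gene_id),
        )

    def proteome(self) -> dict[str, str]:
        return {g.gene_id: g.protein for g in self.genes if g.protein}

    def cds_nucleotides(self, gene: Gene) -> str:
        """Coding-strand nucleotide sequence of a gene."""
        seq = self.replicons[gene.replicon_id].sequence[gene.start : gene.end]
        if gene.strand == "-":
            seq = reverse_complement(seq)
        return seq


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(nt: str) -> str:
    """Translate codons until the first stop codon (stop not included)."""
    trimmed = nt[: len(nt) - len(nt) % 3]
    if not trimmed:
        return ""
    aa = str(Seq(trimmed).translate())
    stop = aa.find("*")
    return aa if stop < 0 else aa[:stop]


# ---------------------------------------------------------------------------
# Plain-text I/O: FASTA via wrapped writer, GFF3 with a minimal parser.
# ---------------------------------------------------------------------------


def _wrap(seq: str, width: int = 70) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def write_fasta(records: list[tuple[str, str]], path: Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{_wrap(seq)}\n")


def read_fasta(path: Path) -> dict[str, str]:
    out: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        out[name] = "".join(chunks)
    return out


def write_genome(genome: Genome, outdir: Path) -> None:
    """Emit ``<alias>.fna`` (replicons), ``<alias>.faa`` (proteins) and
    ``<alias>.gff`` (gene features, 1-based inclusive, pseudo attribute)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(
        [(r.replicon_id, r.sequence) for r in genome.replicons.values()],
        outdir / f"{genome.alias}.fna",
    )
    write_fasta(
        [(g.gene_id, g.protein) for g in genome.genes if g.protein],
        outdir / f"{genome.alias}.faa",
    )
    with open(outdir / f"{genome.alias}.gff", "w") as fh:
        fh.write("##gff-version 3\n")
        for rid, rep in genome.replicons.items():
            fh.write(f"##sequence-region {rid} 1 {len(rep)}\n")
        for g in genome.genes:
            attrs = f"ID={g.gene_id}"
            if g.pseudo:
                attrs += ";pseudo=true"
            fh.write(
                "\t".join(
                    [
                        g.replicon_id,
                        "sugarmap",
                        "gene",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


_GFF_COLS = 9


def read_genome(alias: str, indir: Path) -> Genome:
    """Parse a genome previously written by :func:`write_genome`."""
    indir = Path(indir)
    replicons = {
        name: Replicon(name, seq) for name, seq in read_fasta(indir / f"{alias}.fna").items()
    }
    proteins = read_fasta(indir / f"{alias}.faa") if (indir / f"{alias}.faa").exists() else {}
    genes: list[Gene] = []
    with open(indir / f"{alias}.gff") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _GFF_COLS:
                raise GenomeError(f"{alias}.gff line {lineno}: expected 9 columns")
            rid, _, ftype, start, end, _, strand, _, attrs = cols
            if ftype != "gene":
                continue
            m = re.search(r"ID=([^;]+)", attrs)
            if not m:
                raise GenomeError(f"{alias}.gff line {lineno}: missing ID attribute")
            gid = m.group(1)
            genes.append(
                Gene(
                    gene_id=gid,
                    replicon_id=rid,
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand,
                    protein=proteins.get(gid, ""),
                    pseudo="pseudo=true" in attrs,
                )
            )
    return Genome(alias=alias, replicons=replicons, genes=genes)


def with_gene(genome: Genome, gene: Gene) -> Genome:
    """Return a copy of ``genome`` with one gene replaced by ``gene``."""
    genes = [gene if g.gene_id == gene.gene_id else g for g in genome.genes]
    return replace(genome, genes=genes)
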