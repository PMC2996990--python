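"""Homology scanning: local alignment, family scans, BBH orthology, profiles.

Local alignment is Smith-Waterman with affine gaps over BLOSUM62, delegated
to :class:`Bio.Align.PairwiseAligner`. A gap of length ``k`` costs
``gap_open + k * gap_extend`` (BLAST convention). An optional shared 4-mer
prefilter skips hopeless pairs during family scans; it is lossless for any
pair whose optimal alignment contains at least one exact 4-letter word and
can be disabled wherever exactness against an oracle is required.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1
DEFAULT_MIN_SCORE = 50
DEFAULT_MIN_IDENTITY = 30.0

_PREFILTER_K = 4


class AlignmentError(ValueError):
    """Invalid alignment input (non-amino-acid residues)."""


@dataclass(frozen=True)
class AlignmentResult:
    score: int
    identity: float  # percent over aligned columns
    aligned_length: int


@dataclass(frozen=True)
class SimilarityHit:
    family_id: str
    gene_id: str
    score: int
    identity: float
    aligned_length: int


@dataclass(frozen=True)
class PhyleticProfile:
    family_id: str
    genomes: tuple[str, ...]
    presence: tuple[bool, ...]

    def __post_init__(self) -> None:
        if len(self.genomes) != len(self.presence):
            raise ValueError("presence vector length must equal genome count")

    @property
    def present_in(self) -> frozenset[str]:
        return frozenset(g for g, p in zip(self.genomes, self.presence) if p)


@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # PairwiseAligner charges open_gap_score for the first gap position, so
    # open = -(gap_open + gap_extend) realizes cost gap_open + k * gap_extend.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _validate(seq: str) -> None:
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise AlignmentError(f"invalid residues {sorted(bad)}")


def local_align(
    a: str,
    b: str,
    matrix: str = DEFAULT_MATRIX,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> AlignmentResult:
    """Optimal local alignment score, percent identity and aligned length."""
    _validate(a)
    _validate(b)
    if not a or not b:
        return AlignmentResult(0, 0.0, 0)
    aligner = _aligner(matrix, gap_open, gap_extend)
    score = int(aligner.score(a, b))
    if score <= 0:
        return AlignmentResult(0, 0.0, 0)
    alignment = next(iter(aligner.align(a, b)))
    matches = 0
    columns = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        columns += a1 - a0
        matches += sum(1 for x, y in zip(a[a0:a1], b[b0:b1]) if x == y)
    identity = 100.0 * matches / columns if columns else 0.0
    return AlignmentResult(score, float(identity), int(columns))


def align_score(
    a: str,
    b: str,
    matrix: str = DEFAULT_MATRIX,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> int:
    """Score-only variant (no traceback), for bulk scans."""
    if not a or not b:
        return 0
    return max(0, int(_aligner(matrix, gap_open, gap_extend).score(a, b)))


def _kmers(seq: str, k: int = _PREFILTER_K) -> frozenset[str]:
    return frozenset(seq[i : i + k] for i in range(len(seq) - k + 1))


def scan_families(
    proteome: dict[str, str],
    families: dict[str, str],
    min_score: float = DEFAULT_MIN_SCORE,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    matrix: str = DEFAULT_MATRIX,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
    prefilter: bool = True,
) -> list[SimilarityHit]:
    """Scan a proteome with one representative sequence per family.

    Returns hits satisfying both thresholds, sorted by
    (family_id, descending score, gene_id).
    """
    if min_score < 0 or min_identity < 0:
        raise ValueError("thresholds must be >= 0")
    gene_kmers = (
        {gid: _kmers(seq) for gid, seq in proteome.items()} if prefilter else {}
    )
    hits: list[SimilarityHit] = []
    for family_id in sorted(families):
        query = families[family_id]
        _validate(query)
        qkmers = _kmers(query) if prefilter else frozenset()
        for gene_id in sorted(proteome):
            target = proteome[gene_id]
            if prefilter and qkmers.isdisjoint(gene_kmers[gene_id]):
                continue
            if align_score(query, target, matrix, gap_open, gap_extend) < min_score:
                continue
            res = local_align(query, target, matrix, gap_open, gap_extend)
            if res.score >= min_score and res.identity >= min_identity:
                hits.append(
                    SimilarityHit(
                        family_id, gene_id, res.score, res.identity, res.aligned_length
                    )
                )
    hits.sort(key=lambda h: (h.family_id, -h.score, h.gene_id))
    return hits


def _best_hits(
    source: dict[str, str],
    target: dict[str, str],
    matrix: str,
    gap_open: int,
    gap_extend: int,
    min_score: float,
    min_identity: float,
) -> dict[str, str]:
    """Best hit in ``target`` for each source protein; ties break by
    (score, identity, lexicographic gene_id) for determinism."""
    best: dict[str, str] = {}
    for sid in sorted(source):
        ranked: list[tuple[int, float, str]] = []
        for tid in sorted(target):
            score = align_score(source[sid], target[tid], matrix, gap_open, gap_extend)
            if score < min_score:
                continue
            res = local_align(source[sid], target[tid], matrix, gap_open, gap_extend)
            if res.identity < min_identity:
                continue
            ranked.append((res.score, res.identity, tid))
        if ranked:
            ranked.sort(key=lambda t: (-t[0], -t[1], t[2]))
            best[sid] = ranked[0][2]
    return best


def bbh_orthologs(
    proteome_a: dict[str, str],
    proteome_b: dict[str, str],
    matrix: str = DEFAULT_MATRIX,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
    min_score: float = DEFAULT_MIN_SCORE,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> set[tuple[str, str]]:
    """Bidirectional best hits between two proteomes.

    Pair (a, b) is included iff b is a's best hit in B and a is b's best hit
    in A (both above thresholds). Symmetric by construction.
    """
    if not proteome_a or not proteome_b:
        return set()
    a2b = _best_hits(proteome_a, proteome_b, matrix, gap_open, gap_extend, min_score, min_identity)
    b2a = _best_hits(proteome_b, proteome_a, matrix, gap_open, gap_extend, min_score, min_identity)
    return {(a, b) for a, b in a2b.items() if b2a.get(b) == a}


def build_phyletic_profile(
    family_id: str,
    hits_by_genome: dict[str, list[SimilarityHit]],
    genomes: list[str] | tuple[str, ...],
) -> PhyleticProfile:
    """Presence vector: true iff the genome has >= 1 hit for the family."""
    presence = tuple(
        any(h.family_id == family_id for h in hits_by_genome.get(g, []))
        for g in genomes
    )
    return PhyleticProfile(family_id, tuple(genomes), presence)


def write_hits_tsv(hits: list[SimilarityHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\tgene_id\tscore\tidentity\taln_len\n")
        for h in hits:
            fh.write(
                f"{h.family_id}\t{h.gene_id}\t{h.score}\t{h.identity:.2f}\t{h.aligned_length}\n"
            )
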