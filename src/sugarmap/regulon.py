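"""Regulon inference: upstream regions, PWM discovery, scanning, filtering.

The motif model is a position weight matrix with per-base pseudocounts:
``weight(b, k) = ln((n(b,k) + c) / ((N + 4c) * bg(b)))`` where ``N`` is the
number of contributing sites and ``c`` the pseudocount. Discovery is a
greedy one-occurrence-per-sequence refinement seeded from random words; the
search threshold is the lowest score observed in the training set, and new
regulon members must have sites conserved in at least two other genomes
unless their family is functionally whitelisted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from sugarmap.genome import Gene, Genome, reverse_complement

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

DEFAULT_WINDOW_UP = 300
DEFAULT_WINDOW_DOWN = 20
DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_MIN_OTHER_GENOMES = 2


class MotifError(ValueError):
    """Invalid motif input (alphabet, lengths, empty training sets)."""


class UpstreamError(ValueError):
    """Upstream window collapsed to zero length."""


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise MotifError(f"non-ACGT character {exc} in sequence")


class PWM:
    """Count-based position weight matrix with log-odds scoring."""

    def __init__(
        self,
        counts: np.ndarray,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        background: np.ndarray | None = None,
        palindromic: bool = False,
    ) -> None:
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise MotifError("counts must have shape (L, 4)")
        if (counts < 0).any():
            raise MotifError("counts must be >= 0")
        if palindromic:
            counts = (counts + counts[::-1, ::-1]) / 2.0
        background = (
            np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
        )
        if background.shape != (4,) or not np.isclose(background.sum(), 1.0):
            raise MotifError("background must be 4 probabilities summing to 1")
        self.counts = counts
        self.pseudocount = float(pseudocount)
        self.background = background
        self.palindromic = palindromic
        colsum = counts.sum(axis=1, keepdims=True)
        self.probabilities = (counts + self.pseudocount) / (colsum + 4 * self.pseudocount)
        with np.errstate(divide="ignore"):
            self.weights = np.log(self.probabilities / background[None, :])

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=1))

    def score(self, word: str) -> float:
        if len(word) != self.length:
            raise MotifError(f"word length {len(word)} != motif length {self.length}")
        idx = encode(word)
        return float(self.weights[np.arange(self.length), idx].sum())

    def scan_scores(self, encoded: np.ndarray) -> np.ndarray:
        """Scores of every length-L window of an encoded sequence."""
        L = self.length
        if len(encoded) < L:
            return np.empty(0)
        windows = np.lib.stride_tricks.sliding_window_view(encoded, L)
        return self.weights[np.arange(L)[None, :], windows].sum(axis=1)

    def reverse_complement(self) -> "PWM":
        return PWM(
            self.counts[::-1, ::-1],
            self.pseudocount,
            self.background[::-1],
            palindromic=False,
        )

    def information_content(self) -> tuple[np.ndarray, float]:
        """Per-column bits (0..2) and their total, from pseudocounted freqs."""
        p = self.probabilities
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log2(p), 0.0)
        per_col = 2.0 + plogp.sum(axis=1)
        return per_col, float(per_col.sum())


@dataclass(frozen=True)
class UpstreamRegion:
    gene_id: str
    genome_alias: str
    sequence: str
    start: int  # replicon coordinates of the extracted window
    end: int

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Site:
    gene_id: str
    genome_alias: str
    offset: int  # within the region, on the region's reading orientation
    strand: str  # relative to the region
    word: str
    score: float


@dataclass
class Regulon:
    regulator_family: str
    threshold: float
    members: dict[str, set[str]] = field(default_factory=dict)  # alias -> genes
    sites: list[Site] = field(default_factory=list)


def extract_upstream(
    genome: Genome,
    gene: Gene,
    window_up: int = DEFAULT_WINDOW_UP,
    window_down: int = DEFAULT_WINDOW_DOWN,
    truncate_at_neighbor: bool = True,
) -> UpstreamRegion:
    """Window around the translation start, read toward the gene.

    For a '+' gene [s, e) the window is [s - window_up, s + window_down)
    clipped to the replicon (and optionally to the nearest upstream
    neighbor); minus-strand genes are mirrored and reverse-complemented.
    """
    rep = genome.replicons[gene.replicon_id]
    others = [
        g
        for g in genome.genes_on(gene.replicon_id)
        if g.gene_id != gene.gene_id
    ]
    if gene.strand == "+":
        lo = max(0, gene.start - window_up)
        hi = min(len(rep), gene.start + window_down)
        if truncate_at_neighbor:
            bounds = [g.end for g in others if g.end <= gene.start]
            if bounds:
                lo = max(lo, min(max(bounds), hi))
        seq = rep.sequence[lo:hi]
    else:
        lo = max(0, gene.end - window_down)
        hi = min(len(rep), gene.end + window_up)
        if truncate_at_neighbor:
            bounds = [g.start for g in others if g.start >= gene.end]
            if bounds:
                hi = min(hi, max(min(bounds), lo))
        seq = reverse_complement(rep.sequence[lo:hi])
    if not seq:
        raise UpstreamError(f"{gene.gene_id}: zero-length upstream window")
    return UpstreamRegion(gene.gene_id, genome.alias, seq, lo, hi)


def build_pwm(
    words: list[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: np.ndarray | None = None,
    palindromic: bool = False,
) -> PWM:
    """Tally aligned equal-length site words into a PWM (>= 2 sites)."""
    if len(words) < 2:
        raise MotifError("need >= 2 sites to build a PWM")
    L = len(words[0])
    if any(len(w) != L for w in words):
        raise MotifError("site words must have equal length")
    counts = np.zeros((L, 4))
    for w in words:
        counts[np.arange(L), encode(w)] += 1
    return PWM(counts, pseudocount, background, palindromic)


def site_score(pwm: PWM, word: str) -> float:
    return pwm.score(word)


def information_content(pwm: PWM) -> tuple[np.ndarray, float]:
    return pwm.information_content()


def _counts_from_words(words: list[str]) -> np.ndarray:
    L = len(words[0])
    counts = np.zeros((L, 4))
    for w in words:
        counts[np.arange(L), encode(w)] += 1
    return counts


def _best_window(
    pwm: PWM, encoded: np.ndarray, raw: str, both_strands: bool
) -> tuple[int, str, str, float]:
    """Best-scoring window of one region; ties leftmost, then '+' strand."""
    plus = pwm.scan_scores(encoded)
    off_p = int(plus.argmax())
    best = (off_p, "+", plus[off_p])
    if both_strands:
        minus = pwm.reverse_complement().scan_scores(encoded)
        off_m = int(minus.argmax())
        if minus[off_m] > best[2]:
            best = (off_m, "-", minus[off_m])
    off, strand, score = best
    word = raw[off : off + pwm.length]
    if strand == "-":
        word = reverse_complement(word)
    return off, strand, word, float(score)


def discover_motif(
    regions: list[UpstreamRegion],
    length: int,
    n_seeds: int | None = None,
    both_strands: bool = True,
    palindromic: bool = False,
    seed: int = 0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: np.ndarray | None = None,
    max_iter: int = 100,
) -> tuple[PWM, list[Site]]:
    """Greedy one-occurrence-per-sequence motif refinement.

    From each seed word: pick the best-scoring window per region (both
    strands if enabled), rebuild the PWM from the chosen words, and repeat
    while total information content increases, up to ``max_iter`` rounds or
    until the site set stabilizes. By default every window of a reference
    region seeds one run (so a run is guaranteed to start on a true site if
    the reference region holds one); ``n_seeds`` switches to that many
    random seeds. The run with the highest total information content wins.
    Deterministic under a fixed seed.
    """
    usable = [r for r in regions if len(r) >= length]
    for r in regions:
        if len(r) < length:
            warnings.warn(
                f"region {r.gene_id} shorter than motif length, excluded",
                stacklevel=2,
            )
    if not usable:
        raise MotifError("all regions shorter than motif length")
    if len(usable) < 2:
        raise MotifError("need >= 2 usable regions for discovery")
    encoded = [encode(r.sequence) for r in usable]
    rng = np.random.default_rng(seed)
    if n_seeds is None:
        ref = max(range(len(usable)), key=lambda i: (len(usable[i]), -i))
        seed_words = [
            usable[ref].sequence[o : o + length]
            for o in range(len(usable[ref]) - length + 1)
        ]
    else:
        seed_words = []
        for _ in range(n_seeds):
            ri = int(rng.integers(len(usable)))
            off = int(rng.integers(len(usable[ri]) - length + 1))
            seed_words.append(usable[ri].sequence[off : off + length])
    best_pwm: PWM | None = None
    best_words: list[tuple[int, str, str, float]] | None = None
    best_ic = -np.inf
    for seed_word in seed_words:
        pwm = PWM(
            _counts_from_words([seed_word]), pseudocount, background, palindromic
        )
        prev_ic = -np.inf
        prev_picks: list[tuple[int, str]] | None = None
        picks: list[tuple[int, str, str, float]] = []
        for _ in range(max_iter):
            picks = [
                _best_window(pwm, enc, reg.sequence, both_strands)
                for enc, reg in zip(encoded, usable)
            ]
            new_pwm = PWM(
                _counts_from_words([p[2] for p in picks]),
                pseudocount,
                background,
                palindromic,
            )
            _, ic = new_pwm.information_content()
            if ic <= prev_ic + 1e-12:
                break
            pwm, prev_ic = new_pwm, ic
            key = [(p[0], p[1]) for p in picks]
            if key == prev_picks:
                break
            prev_picks = key
        if prev_ic > best_ic:
            best_ic, best_pwm, best_words = prev_ic, pwm, picks
    assert best_pwm is not None and best_words is not None
    sites = [
        Site(
            gene_id=reg.gene_id,
            genome_alias=reg.genome_alias,
            offset=off,
            strand=strand,
            word=word,
            score=best_pwm.score(word),
        )
        for reg, (off, strand, word, _) in zip(usable, best_words)
    ]
    return best_pwm, sites


def training_threshold(pwm: PWM, training_sites: list[Site | str]) -> float:
    """Lowest score observed in the training set."""
    if not training_sites:
        raise MotifError("empty training set")
    words = [s if isinstance(s, str) else s.word for s in training_sites]
    return min(pwm.score(w) for w in words)


def _collapse(sites: list[Site], length: int) -> list[Site]:
    """Collapse transitively overlapping hits to the best one per group.

    Ties: best score, then leftmost offset, then '+' strand.
    """
    out: list[Site] = []
    group: list[Site] = []
    group_end = -1
    for s in sorted(sites, key=lambda s: s.offset):
        if group and s.offset >= group_end:
            out.append(
                min(group, key=lambda s: (-s.score, s.offset, 0 if s.strand == "+" else 1))
            )
            group = []
        group.append(s)
        group_end = max(group_end, s.offset + length)
    if group:
        out.append(
            min(group, key=lambda s: (-s.score, s.offset, 0 if s.strand == "+" else 1))
        )
    return out


def scan_regions(
    pwm: PWM,
    threshold: float,
    regions: list[UpstreamRegion],
    both_strands: bool = True,
) -> list[Site]:
    """All windows scoring >= threshold, overlap-collapsed per region."""
    if not np.isfinite(threshold):
        if threshold > 0:  # +inf scans to nothing
            return []
        raise MotifError("threshold must be finite or +inf")
    hits: list[Site] = []
    for region in regions:
        if len(region) < pwm.length:
            continue
        enc = encode(region.sequence)
        found: list[Site] = []
        strands = [("+", pwm)] + ([("-", pwm.reverse_complement())] if both_strands else [])
        for strand, mat in strands:
            scores = mat.scan_scores(enc)
            # epsilon absorbs summation-order rounding between the scan and
            # the canonical per-word score used for the training threshold
            for off in np.flatnonzero(scores >= threshold - 1e-9):
                word = region.sequence[off : off + pwm.length]
                if strand == "-":
                    word = reverse_complement(word)
                found.append(
                    Site(region.gene_id, region.genome_alias, int(off), strand, word, pwm.score(word))
                )
        hits.extend(_collapse(found, pwm.length))
    return hits


@dataclass(frozen=True)
class RegulonCandidate:
    genome_alias: str
    gene_id: str
    family_id: str | None = None


def conservation_filter(
    candidates: list[RegulonCandidate],
    orthology: dict[tuple[str, str], set[tuple[str, str]]],
    min_other_genomes: int = DEFAULT_MIN_OTHER_GENOMES,
    functional_whitelist: frozenset[str] | set[str] = frozenset(),
) -> list[RegulonCandidate]:
    """Keep candidates whose site is conserved in >= min_other_genomes other
    genomes (via orthologs that are themselves candidates), or whose family
    is functionally whitelisted."""
    candidate_keys = {(c.genome_alias, c.gene_id) for c in candidates}
    retained: list[RegulonCandidate] = []
    for cand in candidates:
        if cand.family_id is not None and cand.family_id in functional_whitelist:
            retained.append(cand)
            continue
        orthologs = orthology.get((cand.genome_alias, cand.gene_id), set())
        supporting = {
            genome
            for genome, gene in orthologs
            if genome != cand.genome_alias and (genome, gene) in candidate_keys
        }
        if len(supporting) >= min_other_genomes:
            retained.append(cand)
    return retained


def write_sites_bed(sites: list[Site], regions: dict[str, UpstreamRegion], path) -> None:
    """Emit sites in replicon coordinates as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for s in sites:
            region = regions[s.gene_id]
            start = region.start + s.offset
            fh.write(
                f"{s.genome_alias}\t{start}\t{start + len(s.word)}\t"
                f"{s.gene_id}\t{s.score:.3f}\t{s.strand}\n"
            )


def write_pwm_tsv(pwm: PWM, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# pseudocount={pwm.pseudocount} background={','.join(f'{b:.4f}' for b in pwm.background)} "
            f"palindromic={pwm.palindromic}\n"
        )
        fh.write("pos\tA\tC\tG\tT\n")
        for k, row in enumerate(pwm.counts):
            fh.write(f"{k}\t" + "\t".join(f"{v:.3f}" for v in row) + "\n")
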