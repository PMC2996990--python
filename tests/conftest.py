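"""Shared fixtures and independent oracles.

The oracles deliberately avoid the package's algorithmic paths: the local
alignment oracle enumerates all monotone chains of aligned columns, and the
cluster oracle groups genes by checking every pair through its intermediate
adjacencies.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from sugarmap import regulon
from sugarmap.genome import Gene, Genome, Replicon
from sugarmap.registry import load_phenotype_matrix, load_registry
from sugarmap.simulate import PanelConfig, simulate_panel

_B62 = substitution_matrices.load("BLOSUM62")


def brute_local(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Exhaustive local alignment: max over all monotone chains of aligned
    columns; a gap run of length k between consecutive columns costs
    gap_open + k * gap_extend (each side separately). Floor at 0."""
    best = 0.0
    n, m = len(a), len(b)
    for k in range(1, min(n, m) + 1):
        for ia in combinations(range(n), k):
            for ib in combinations(range(m), k):
                s = 0.0
                for t in range(k):
                    s += _B62[a[ia[t]]][b[ib[t]]]
                for t in range(k - 1):
                    da = ia[t + 1] - ia[t] - 1
                    db = ib[t + 1] - ib[t] - 1
                    if da:
                        s -= gap_open + gap_extend * da
                    if db:
                        s -= gap_open + gap_extend * db
                best = max(best, s)
    return int(best)


def brute_clusters(genes: list[Gene], max_gap: int, same_strand: bool = True):
    """O(n^2) grouping oracle: genes i and j share a cluster iff every
    coordinate-consecutive pair between them satisfies the gap/strand rule."""
    order = sorted(genes, key=lambda g: (g.start, g.end, g.gene_id))

    def adjacent_ok(i: int) -> bool:
        prev, nxt = order[i], order[i + 1]
        if same_strand and prev.strand != nxt.strand:
            return False
        return max(0, nxt.start - prev.end) <= max_gap

    n = len(order)
    same = [[all(adjacent_ok(t) for t in range(i, j)) for j in range(n)] for i in range(n)]
    groups: list[tuple[str, ...]] = []
    used: set[int] = set()
    for i in range(n):
        if i in used:
            continue
        member_idx = [j for j in range(i, n) if same[i][j] or i == j]
        used |= set(member_idx)
        groups.append(tuple(order[j].gene_id for j in member_idx))
    return groups


def toy_genome(
    coords: list[tuple[int, int, str]],
    alias: str = "T",
    length: int | None = None,
    sequence: str | None = None,
) -> Genome:
    length = length or (max(e for _, e, _ in coords) + 100 if coords else 1000)
    seq = sequence or ("A" * length)
    genes = [
        Gene(f"{alias}_g{i}", f"{alias}_chr", s, e, strand)
        for i, (s, e, strand) in enumerate(coords)
    ]
    return Genome(alias=alias, replicons={f"{alias}_chr": Replicon(f"{alias}_chr", seq)}, genes=genes)


def motif_recovery(seed: int) -> tuple[float, float]:
    """Plant-and-recover one 16-site panel; returns (site recall, best
    orientation correlation of truth vs discovered frequency matrices)."""
    cfg = PanelConfig(
        n_genomes=16, pathway_roles={"P": 2}, identity_target=1.0, seed=seed
    )
    panel = simulate_panel(cfg)
    genomes = {g.alias: g for g in panel.genomes}
    truth_sites = {s.genome_alias: s for s in panel.truth.sites}
    regions = {}
    for alias, genome in genomes.items():
        lead = truth_sites[alias].gene_id
        regions[alias] = regulon.extract_upstream(genome, genome.gene(lead), 300, 0)
    pwm, sites = regulon.discover_motif(
        list(regions.values()), cfg.motif_length, seed=seed
    )
    hits = 0
    for s in sites:
        r = regions[s.genome_alias]
        ts = truth_sites[s.genome_alias]
        start = (
            r.start + s.offset
            if ts.strand == "+"
            else r.end - s.offset - len(s.word)
        )
        hits += abs(start - ts.start) <= 1
    recall = hits / len(sites)
    tc = np.asarray(panel.truth.pwm_counts["P"], dtype=float)
    tp = tc / tc.sum(axis=1, keepdims=True)
    dp = pwm.probabilities
    corr = max(
        np.corrcoef(tp.ravel(), dp.ravel())[0, 1],
        np.corrcoef(tp.ravel(), dp[::-1, ::-1].ravel())[0, 1],
    )
    return recall, float(corr)


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def phenotypes():
    return load_phenotype_matrix()


@pytest.fixture(scope="session")
def exact_panel():
    """4 genomes, 2 pathways, identity 1.0 (planted copies are exact)."""
    return simulate_panel(
        PanelConfig(
            n_genomes=4,
            pathway_roles={"P": 2, "Q": 3},
            scenario={"P": frozenset(range(4)), "Q": frozenset({0, 1, 2})},
            identity_target=1.0,
            seed=7,
        )
    )
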