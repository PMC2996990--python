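import hashlib
from pathlib import Path

import numpy as np
import pytest

from sugarmap.genome import read_genome, translate
from sugarmap.simulate import (
    PanelConfig,
    SimulationError,
    inject_pseudogene,
    mutate_protein,
    plant_operon,
    plant_sites,
    simulate_panel,
)


def _identity(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / len(a)


class TestMutateProtein:
    def test_target_one_is_identity(self):
        seq = "MKLVANQWERTYIPASDFGH"
        assert mutate_protein(seq, 1.0, seed=3) == seq

    def test_realized_identity_near_target(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 200))
        mutated = mutate_protein(seq, 0.6, seed=7)
        assert 0.57 <= _identity(seq, mutated) <= 0.63

    def test_empty_consensus_rejected(self):
        with pytest.raises(SimulationError):
            mutate_protein("", 0.5)

    def test_deterministic(self):
        seq = "MKLVANQWERTYIPASDFGH" * 5
        assert mutate_protein(seq, 0.7, seed=11) == mutate_protein(seq, 0.7, seed=11)

    def test_substitutions_change_residue(self):
        seq = "MKLVANQWERTYIPASDFGH" * 10
        mutated = mutate_protein(seq, 0.5, seed=2)
        n_diff = sum(x != y for x, y in zip(seq, mutated))
        assert n_diff == round(len(seq) * 0.5)


class TestPlantOperon:
    def test_three_genes_with_gaps(self):
        coords = plant_operon(1000, [300, 300, 300], [50, 80], "+", 10_000)
        assert coords == [(1000, 1300), (1350, 1650), (1730, 2030)]

    def test_single_gene_consumes_no_gaps(self):
        assert plant_operon(0, [120], [], "+", 500) == [(0, 120)]

    def test_short_gap_list_rejected(self):
        with pytest.raises(SimulationError, match="gap"):
            plant_operon(0, [100, 100, 100], [10], "+", 10_000)

    def test_overflow_rejected(self):
        with pytest.raises(SimulationError, match="overflow"):
            plant_operon(900, [200], [], "+", 1000)


class TestPlantSites:
    def test_deterministic_pwm_plants_consensus(self):
        counts = np.zeros((6, 4))
        counts[:, 2] = 10  # all-G columns: 2 bits each
        records, windows = plant_sites(counts, ["A" * 30, "A" * 30], seed=5)
        for (offset, strand, word), window in zip(records, windows):
            assert word == "GGGGGG"
            assert strand == "+"
            assert window[offset : offset + 6] == "GGGGGG"

    def test_one_site_per_window(self):
        counts = np.ones((4, 4))
        records, windows = plant_sites(counts, ["ACGT" * 10] * 16, seed=0)
        assert len(records) == len(windows) == 16

    def test_window_shorter_than_motif_rejected(self):
        counts = np.ones((18, 4))
        with pytest.raises(SimulationError, match="shorter"):
            plant_sites(counts, ["A" * 15], seed=0)


class TestInjectPseudogene:
    @pytest.fixture()
    def panel(self):
        return simulate_panel(
            PanelConfig(n_genomes=1, pathway_roles={"P": 2}, identity_target=1.0, seed=1)
        )

    def test_frameshift_deletes_one_nucleotide(self, panel):
        genome = panel.genomes[0]
        gene = genome.genes[1]
        before_len, before_prot = gene.length, gene.protein
        inject_pseudogene(genome, gene.gene_id, "frameshift", seed=0)
        assert gene.length == before_len - 1
        assert gene.pseudo
        assert gene.protein != before_prot

    def test_insertion_element_adds_cassette(self, panel):
        genome = panel.genomes[0]
        gene = genome.genes[1]
        before = gene.length
        inject_pseudogene(genome, gene.gene_id, "insertion_element", seed=0)
        assert gene.length == before + 1000
        assert gene.pseudo

    def test_double_disruption_rejected(self, panel):
        genome = panel.genomes[0]
        gid = genome.genes[1].gene_id
        inject_pseudogene(genome, gid, "frameshift", seed=0)
        with pytest.raises(SimulationError, match="already"):
            inject_pseudogene(genome, gid, "insertion_element", seed=0)

    def test_downstream_genes_shift_and_translate(self, panel):
        genome = panel.genomes[0]
        target = genome.genes[1]
        downstream = [g for g in genome.genes if g.start > target.end]
        before = {g.gene_id: (g.start, g.protein) for g in downstream}
        inject_pseudogene(genome, target.gene_id, "frameshift", seed=0)
        for g in downstream:
            start0, prot0 = before[g.gene_id]
            assert g.start == start0 - 1
            # unchanged genes still translate to the same protein
            assert translate(genome.cds_nucleotides(g)) == prot0


class TestSimulatePanel:
    def test_truth_presence_matches_scenario(self, exact_panel):
        scenario = exact_panel.config.scenario
        for pid, present_in in scenario.items():
            aliases = {f"G{i:02d}" for i in present_in}
            from_truth = {
                alias
                for alias, status in (
                    (a, exact_panel.truth.pathway_status[a][pid])
                    for a in exact_panel.aliases
                )
                if status != "absent"
            }
            assert from_truth == aliases

    def test_identity_one_plants_exact_consensus(self, exact_panel):
        consensus = exact_panel.family_consensus()
        for (alias, gene_id), fid in exact_panel.truth.gene_families.items():
            genome = next(g for g in exact_panel.genomes if g.alias == alias)
            assert genome.gene(gene_id).protein == consensus[fid]

    def test_byte_identical_outputs_under_same_seed(self, tmp_path):
        def digest(outdir: Path) -> str:
            h = hashlib.sha256()
            for p in sorted(outdir.rglob("*")):
                if p.is_file():
                    h.update(p.name.encode())
                    h.update(p.read_bytes())
            return h.hexdigest()

        cfg = dict(n_genomes=3, pathway_roles={"P": 2}, seed=42)
        simulate_panel(PanelConfig(**cfg)).write(tmp_path / "a")
        simulate_panel(PanelConfig(**cfg)).write(tmp_path / "b")
        assert digest(tmp_path / "a") == digest(tmp_path / "b")

    def test_gff_fasta_round_trip(self, exact_panel, tmp_path):
        exact_panel.write(tmp_path)
        for genome in exact_panel.genomes:
            parsed = read_genome(genome.alias, tmp_path)
            assert len(parsed.genes) == len(genome.genes)
            for orig, back in zip(genome.genes, parsed.genes):
                assert (back.start, back.end, back.strand) == (
                    orig.start,
                    orig.end,
                    orig.strand,
                )
                assert back.protein == orig.protein
                assert back.pseudo == orig.pseudo

    def test_emitted_sites_match_replicon(self, exact_panel):
        from sugarmap.genome import reverse_complement

        for site in exact_panel.truth.sites:
            genome = next(g for g in exact_panel.genomes if g.alias == site.genome_alias)
            rep = genome.replicons[genome.genes[0].replicon_id]
            segment = rep.sequence[site.start : site.end]
            expected = site.word if site.strand == "+" else reverse_complement(site.word)
            assert segment == expected

    def test_infeasible_packing_rejected(self):
        with pytest.raises(SimulationError, match="replicon_length"):
            simulate_panel(
                PanelConfig(
                    n_genomes=1,
                    pathway_roles={"P": 3},
                    replicon_length=500,
                    seed=0,
                )
            )

    def test_invalid_identity_rejected(self):
        with pytest.raises(SimulationError):
            PanelConfig(identity_target=0.0)

    def test_pseudogene_plan_flips_truth_status(self):
        panel = simulate_panel(
            PanelConfig(
                n_genomes=2,
                pathway_roles={"P": 2},
                identity_target=1.0,
                pseudogene_plan=[(0, "P_r0", "frameshift")],
                seed=3,
            )
        )
        assert panel.truth.pathway_status["G00"]["P"] == "impaired"
        assert panel.truth.pathway_status["G01"]["P"] == "present"
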