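import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import toy_genome
from sugarmap.genome import reverse_complement
from sugarmap.regulon import (
    PWM,
    MotifError,
    RegulonCandidate,
    UpstreamError,
    UpstreamRegion,
    build_pwm,
    conservation_filter,
    discover_motif,
    extract_upstream,
    information_content,
    scan_regions,
    site_score,
    training_threshold,
)

word_st = st.text(alphabet="ACGT", min_size=8, max_size=8)


def region(seq: str, gene_id: str = "g", alias: str = "G") -> UpstreamRegion:
    return UpstreamRegion(gene_id, alias, seq, 0, len(seq))


class TestExtractUpstream:
    def _genome(self, coords, length=3000):
        return toy_genome(coords, length=length, sequence=None)

    def test_plus_strand_window(self):
        genome = self._genome([(1000, 2000, "+")])
        r = extract_upstream(genome, genome.genes[0], 300, 20)
        assert (r.start, r.end) == (700, 1020)
        assert len(r) == 320

    def test_minus_strand_mirrored(self):
        rng = np.random.default_rng(1)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
        genome = toy_genome([(1000, 2000, "-")], length=3000, sequence=seq)
        r = extract_upstream(genome, genome.genes[0], 300, 20)
        assert (r.start, r.end) == (1980, 2300)
        assert r.sequence == reverse_complement(seq[1980:2300])

    def test_clipped_at_replicon_start(self):
        genome = self._genome([(50, 500, "+")])
        r = extract_upstream(genome, genome.genes[0], 300, 20)
        assert (r.start, r.end) == (0, 70)

    def test_truncated_at_neighbor(self):
        genome = self._genome([(0, 900, "+"), (1000, 2000, "+")])
        r = extract_upstream(genome, genome.genes[1], 300, 20)
        assert (r.start, r.end) == (900, 1020)

    def test_zero_length_flagged(self):
        genome = self._genome([(0, 1000, "+"), (1000, 2000, "+")])
        with pytest.raises(UpstreamError):
            extract_upstream(genome, genome.genes[1], 300, 0)


class TestBuildPWM:
    def test_hand_evaluated_weights(self):
        pwm = build_pwm(["ACGT", "ACGA"], pseudocount=0.5)
        # weight(b, k) = ln((n + 0.5) / ((2 + 4*0.5) * 0.25))
        assert pwm.weights[0, 0] == pytest.approx(math.log(2.5 / 1.0))
        assert pwm.weights[0, 1] == pytest.approx(math.log(0.5 / 1.0))
        assert pwm.weights[3, 3] == pytest.approx(math.log(1.5 / 1.0))

    def test_identical_sites_zero_pseudocount(self):
        pwm = build_pwm(["ACGT", "ACGT", "ACGT"], pseudocount=0.0)
        assert np.allclose(pwm.probabilities.max(axis=1), 1.0)
        assert pwm.consensus == "ACGT"

    def test_single_site_rejected(self):
        with pytest.raises(MotifError):
            build_pwm(["ACGT"])

    def test_unequal_lengths_rejected(self):
        with pytest.raises(MotifError):
            build_pwm(["ACGT", "ACG"])


class TestSiteScore:
    def test_hand_evaluated_score(self):
        pwm = build_pwm(["ACGT", "ACGA"], pseudocount=0.5)
        expected = 3 * math.log(2.5) + math.log(1.5)
        assert site_score(pwm, "ACGT") == pytest.approx(expected)

    def test_uniform_pwm_scores_zero(self):
        pwm = PWM(np.ones((5, 4)), pseudocount=0.0)
        for word in ("AAAAA", "ACGTA", "TTTTT"):
            assert site_score(pwm, word) == pytest.approx(0.0)

    def test_invalid_character_rejected(self):
        pwm = build_pwm(["ACGT", "ACGA"])
        with pytest.raises(MotifError):
            site_score(pwm, "ACGN")

    @given(word_st)
    @settings(max_examples=40, deadline=None)
    def test_palindromic_pwm_scores_both_strands_equally(self, word):
        pwm = build_pwm(["ACGTACGT", "AAGTACTT", "ACGTACGT"], palindromic=True)
        assert pwm.score(word) == pytest.approx(pwm.score(reverse_complement(word)))


class TestInformationContent:
    def test_invariant_column(self):
        pwm = PWM(np.array([[2, 0, 0, 0]]), pseudocount=0.0)
        per_col, total = information_content(pwm)
        assert per_col[0] == pytest.approx(2.0)
        assert total == pytest.approx(2.0)

    def test_uniform_column(self):
        pwm = PWM(np.array([[3, 3, 3, 3]]), pseudocount=0.0)
        assert information_content(pwm)[1] == pytest.approx(0.0)

    def test_three_one_split(self):
        pwm = PWM(np.array([[3, 1, 0, 0]]), pseudocount=0.0)
        expected = 2 + 0.75 * math.log2(0.75) + 0.25 * math.log2(0.25)
        assert information_content(pwm)[1] == pytest.approx(expected)

    def test_columns_bounded(self):
        rng = np.random.default_rng(0)
        pwm = PWM(rng.integers(0, 20, (10, 4)).astype(float))
        per_col, _ = information_content(pwm)
        assert np.all(per_col >= 0) and np.all(per_col <= 2)


class TestTrainingThreshold:
    def test_minimum_of_training_scores(self):
        pwm = build_pwm(["ACGT", "ACGA", "ACGT"])
        words = ["ACGT", "ACGA", "AAGT"]
        threshold = training_threshold(pwm, words)
        assert threshold == pytest.approx(min(pwm.score(w) for w in words))
        assert any(pwm.score(w) == pytest.approx(threshold) for w in words)

    def test_single_site_is_its_own_threshold(self):
        pwm = build_pwm(["ACGT", "ACGA"])
        assert training_threshold(pwm, ["ACGA"]) == pytest.approx(pwm.score("ACGA"))

    def test_empty_training_set_rejected(self):
        pwm = build_pwm(["ACGT", "ACGA"])
        with pytest.raises(MotifError):
            training_threshold(pwm, [])


class TestScanRegions:
    def test_training_regions_always_recovered(self):
        rng = np.random.default_rng(4)
        regions = []
        for i in range(6):
            bg = "".join("ACGT"[j] for j in rng.integers(0, 4, 80))
            regions.append(region(bg + "ACGTACGT" + bg, gene_id=f"g{i}"))
        pwm, sites = discover_motif(regions, 8, seed=0)
        threshold = training_threshold(pwm, sites)
        found = {s.gene_id for s in scan_regions(pwm, threshold, regions)}
        assert found >= {f"g{i}" for i in range(6)}

    def test_infinite_threshold_empty(self):
        pwm = build_pwm(["ACGT", "ACGA"])
        assert scan_regions(pwm, np.inf, [region("ACGTACGT")]) == []

    def test_overlap_collapsed_to_best(self):
        pwm = build_pwm(["AAAA", "AAAA", "AAAT"])
        hits = scan_regions(pwm, 0.0, [region("AAAAAA")], both_strands=False)
        assert len(hits) == 1
        assert hits[0].offset == 0  # ties resolve leftmost


class TestDiscoverMotif:
    def test_repeated_word_found_everywhere(self):
        w = "TGACTCAGTA"
        regions = [region(w * 3, gene_id=f"g{i}") for i in range(4)]
        pwm, sites = discover_motif(regions, len(w), both_strands=False, seed=0)
        assert pwm.consensus == w
        assert all(s.word == w for s in sites)

    def test_short_regions_excluded_with_warning(self):
        regions = [region("ACGTACGTAC", gene_id="a"), region("ACG", gene_id="b"),
                   region("ACGTACGTAC", gene_id="c")]
        with pytest.warns(UserWarning, match="shorter"):
            pwm, sites = discover_motif(regions, 8, seed=0)
        assert {s.gene_id for s in sites} == {"a", "c"}

    def test_all_regions_too_short_rejected(self):
        with pytest.raises(MotifError):
            with pytest.warns(UserWarning):
                discover_motif([region("ACG"), region("ACGT")], 8)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(8)
        regions = [
            region("".join("ACGT"[j] for j in rng.integers(0, 4, 60)), gene_id=f"g{i}")
            for i in range(5)
        ]
        a = discover_motif(regions, 8, n_seeds=5, seed=3)
        b = discover_motif(regions, 8, n_seeds=5, seed=3)
        assert np.array_equal(a[0].counts, b[0].counts)
        assert a[1] == b[1]


class TestConservationFilter:
    def _candidates(self):
        return [
            RegulonCandidate("G0", "a0", "famX"),
            RegulonCandidate("G1", "a1", "famX"),
            RegulonCandidate("G2", "a2", "famX"),
            RegulonCandidate("G3", "b3", "famY"),
        ]

    def _orthology(self):
        xs = {("G0", "a0"), ("G1", "a1"), ("G2", "a2")}
        ortho = {k: xs - {k} for k in xs}
        ortho[("G3", "b3")] = set()
        return ortho

    def test_conserved_in_two_other_genomes_retained(self):
        kept = conservation_filter(self._candidates(), self._orthology())
        assert {(c.genome_alias, c.gene_id) for c in kept} == {
            ("G0", "a0"), ("G1", "a1"), ("G2", "a2"),
        }

    def test_unsupported_candidate_dropped_unless_whitelisted(self):
        cands = self._candidates()
        kept = conservation_filter(cands, self._orthology())
        assert all(c.gene_id != "b3" for c in kept)
        kept_wl = conservation_filter(
            cands, self._orthology(), functional_whitelist={"famY"}
        )
        assert any(c.gene_id == "b3" for c in kept_wl)

    def test_empty_candidates(self):
        assert conservation_filter([], {}) == []

    @given(st.integers(0, 6), st.integers(0, 6))
    @settings(max_examples=30, deadline=None)
    def test_raising_requirement_shrinks_result(self, low, extra):
        cands = self._candidates()
        ortho = self._orthology()
        loose = conservation_filter(cands, ortho, min_other_genomes=low)
        strict = conservation_filter(cands, ortho, min_other_genomes=low + extra)
        assert {id(c) for c in strict} <= {id(c) for c in loose}
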