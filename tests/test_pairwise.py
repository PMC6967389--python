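import random

import pytest
from Bio.Align import substitution_matrices

from oracles import (affine_align_score_exhaustive,
                     affine_align_score_oracle)
from speciesgap import pairwise, simgen
from speciesgap.pairwise import (PairwiseParams,
                                 codon_alignment, compare_genomes,
                                 global_nt_align, global_protein_align,
                                 kmer_prescreen, reciprocal_best_hits)
from speciesgap.seqio import GeneRecord, Genome

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def nt_score(x, y):
    return pairwise.NT_MATCH if x == y else pairwise.NT_MISMATCH


def aa_score(x, y):
    return float(BLOSUM62[x, y])


class TestKmerPrescreen:
    def test_identical_genes_share_maximal_kmers(self):
        rng = random.Random(0)
        seq = "".join(rng.choice("ACGT") for _ in range(300))
        a = [GeneRecord.from_nt("x", "A", _make_cds(seq))]
        pairs = kmer_prescreen(a, a, k=11, min_shared=3)
        assert pairs == [(0, 0)]

    def test_random_genes_never_pass(self):
        # 100 seeded trials of unrelated 300-nt gene pairs: none retained
        rng = random.Random(42)
        retained = 0
        for _ in range(100):
            a = [_uniform_gene(rng, "a")]
            b = [_uniform_gene(rng, "b")]
            retained += len(kmer_prescreen(a, b, k=11, min_shared=3))
        assert retained == 0

    def test_shared_kmer_count_is_exact(self):
        # repeat-free sequence has L-k+1 distinct k-mers, all shared with itself
        seq = _make_cds("ACGTACGGATCCTTAGCCAAGGTTCAACGGT"[:30])
        gene = [GeneRecord.from_nt("g", "A", seq)]
        assert kmer_prescreen(gene, gene, k=11, min_shared=len(seq) - 10) \
            == [(0, 0)]
        assert kmer_prescreen(gene, gene, k=11, min_shared=len(seq) - 9) == []

    def test_k_range_validated(self):
        with pytest.raises(ValueError):
            kmer_prescreen([], [], k=7)


def _make_cds(seq):
    """Pad/repair an arbitrary ACGT string into a valid CDS."""
    from speciesgap.seqio import STOP_CODONS
    seq = seq[: len(seq) // 3 * 3]
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    return "".join("AAA" if c in STOP_CODONS else c for c in codons)


def _random_gene(rng, gid, length=300):
    from speciesgap.seqio import SENSE_CODONS
    nt = "".join(rng.choice(SENSE_CODONS) for _ in range(length // 3))
    return GeneRecord.from_nt(gid, gid, nt)


def _uniform_gene(rng, gid, length=300):
    nt = "".join(rng.choice("ACGT") for _ in range(length))
    return GeneRecord.from_nt(gid, gid, _make_cds(nt))


class TestGlobalAlign:
    def test_identical_proteins(self):
        aln = global_protein_align("AA", "AA")
        assert aln.score == 8.0  # 2 x blosum62(A,A)=4
        assert "-" not in aln.seq_a_aligned

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            global_protein_align("A", "")
        with pytest.raises(ValueError):
            global_nt_align("", "ACGT")

    def test_nonstandard_residue_is_an_error(self):
        with pytest.raises(ValueError):
            global_protein_align("AXA", "AAA")
        with pytest.raises(ValueError):
            global_nt_align("ACGN", "ACGT")

    @pytest.mark.parametrize("a, b, identity", [
        ("ACGT", "ACGT", 1.0),
        ("ACGT", "ACGA", 0.75),
    ])
    def test_nt_identity_examples(self, a, b, identity):
        assert global_nt_align(a, b).identity == identity

    def test_terminal_gaps_trimmed_internal_count_as_mismatch(self):
        # b is a with a prefix missing: terminal gap columns are trimmed
        aln = global_nt_align("AAAACCCGGGTTT", "CCCGGGTTT")
        assert aln.identity == 1.0
        assert aln.aligned_length == 9
        assert aln.coverage_b == 1.0
        assert aln.coverage_a == pytest.approx(9 / 13)

    def test_nt_oracle_small_sample(self):
        rng = random.Random(5)
        for _ in range(60):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 8)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 8)))
            expected = affine_align_score_oracle(
                a, b, nt_score, pairwise.NT_GAP_OPEN, pairwise.NT_GAP_EXTEND)
            assert global_nt_align(a, b).score == expected

    def test_protein_oracle_small_sample(self):
        rng = random.Random(6)
        residues = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(60):
            a = "".join(rng.choice(residues) for _ in range(rng.randint(1, 8)))
            b = "".join(rng.choice(residues) for _ in range(rng.randint(1, 8)))
            expected = affine_align_score_oracle(
                a, b, aa_score, pairwise.AA_GAP_OPEN, pairwise.AA_GAP_EXTEND)
            assert global_protein_align(a, b).score == expected

    def test_recursive_oracle_agrees_with_pathwise_enumeration(self):
        # validates the memoized oracle itself on very short sequences
        rng = random.Random(7)
        for _ in range(25):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 4)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 4)))
            assert affine_align_score_oracle(a, b, nt_score, -5, -2) == \
                affine_align_score_exhaustive(a, b, nt_score, -5, -2)


class TestCodonAlignment:
    def test_simple_two_codons(self):
        cols = codon_alignment("MK", "MK", "ATGAAA", "ATGAAG")
        assert cols == [("ATG", "ATG"), ("AAA", "AAG")]

    def test_gap_columns_are_masked(self):
        cols = codon_alignment("MKR", "M-R", "ATGAAACGT", "ATGCGA")
        assert cols == [("ATG", "ATG"), ("CGT", "CGA")]

    def test_identical_cds_gives_identical_columns(self):
        cols = codon_alignment("MKL", "MKL", "ATGAAACTG", "ATGAAACTG")
        assert all(x == y for x, y in cols)

    def test_translation_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            codon_alignment("MK", "MK", "ATGAAA", "ATGCCC")  # MP, not MK


class TestReciprocalBestHits:
    def _aln(self, score, identity=0.9, cov=1.0, length=100):
        return pairwise.PairwiseAlignment(
            seq_a_aligned="", seq_b_aligned="", score=score,
            aligned_length=length, matches=int(identity * length),
            identity=identity, coverage_a=cov, coverage_b=cov,
            len_a=length, len_b=length)

    def test_single_perfect_pair_retained(self):
        assert reciprocal_best_hits({("a1", "b1"): self._aln(100)}) \
            == [("a1", "b1")]

    def test_low_identity_dropped(self):
        scored = {("a1", "b1"): self._aln(100, identity=0.65)}
        assert reciprocal_best_hits(scored) == []

    def test_low_coverage_of_shorter_gene_dropped(self):
        scored = {("a1", "b1"): self._aln(100, cov=0.6)}
        assert reciprocal_best_hits(scored) == []

    def test_non_reciprocal_chain_yields_nothing(self):
        # a1's best is b1, but b1's best is a2; a2's best is b2 etc.
        scored = {("a1", "b1"): self._aln(50),
                  ("a2", "b1"): self._aln(80),
                  ("a2", "b2"): self._aln(90)}
        assert reciprocal_best_hits(scored) == [("a2", "b2")]

    def test_ties_break_lexicographically(self):
        # everything ties at 70: each gene's best partner is the
        # lexicographically smallest, so only (a1, b1) is mutual
        scored = {("a1", "b2"): self._aln(70), ("a1", "b1"): self._aln(70),
                  ("a2", "b1"): self._aln(70), ("a2", "b2"): self._aln(70)}
        assert reciprocal_best_hits(scored) == [("a1", "b1")]


class TestCompareGenomes:
    def test_genome_vs_itself(self):
        genome = simgen.generate_ancestor(20, 300, seed=9, genome_id="self")
        result = compare_genomes(genome, genome)
        assert result.ani == 1.0
        assert result.alignment_fraction == 1.0
        assert result.n_genes_aligned == 20

    def test_symmetry(self, small_pair):
        genome_a, genome_b, _truth, _config = small_pair
        r1 = compare_genomes(genome_a, genome_b)
        r2 = compare_genomes(genome_b, genome_a)
        assert r1.genome_a == r2.genome_a and r1.genome_b == r2.genome_b
        assert r1.ani == r2.ani
        assert r1.alignment_fraction == r2.alignment_fraction
        assert [(a.gene_id_a, a.gene_id_b, a.nt_identity)
                for a in r1.rbh_alignments] == \
               [(a.gene_id_a, a.gene_id_b, a.nt_identity)
                for a in r2.rbh_alignments]

    def test_ani_matches_simulated_truth(self, small_pair, small_pair_result):
        _a, _b, truth, _config = small_pair
        assert small_pair_result.ani == pytest.approx(truth.true_identity,
                                                      abs=0.002)

    def test_disjoint_genomes_flagged_no_alignment(self):
        rng = random.Random(31)
        a = Genome("a", [_random_gene(rng, f"a{i}") for i in range(5)])
        b = Genome("b", [_random_gene(rng, f"b{i}") for i in range(5)])
        result = compare_genomes(a, b)
        assert result.no_alignment
        assert result.ani is None  # undefined, not 0

    def test_ani_decreases_with_divergence(self):
        anis = []
        for idx, div in enumerate([0.02, 0.06, 0.10]):
            config = simgen.PairSimConfig(n_genes=30, divergence=div, seed=17)
            a, b, _ = simgen.simulate_pair(config)
            res = compare_genomes(a, b, PairwiseParams(codon_alignments=False))
            anis.append(res.ani)
        assert anis[0] > anis[1] > anis[2]

    def test_empty_genome_rejected(self):
        genome = simgen.generate_ancestor(2, 300, seed=0)
        with pytest.raises(ValueError):
            compare_genomes(genome, Genome("empty", []))
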