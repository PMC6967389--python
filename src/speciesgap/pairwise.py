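"""Gene-by-gene comparison of two genomes.

The engine mirrors the gene-based ANI workflow used for
metagenome-assembled genomes: a k-mer prescreen proposes candidate gene
pairs, global nucleotide alignments score them, reciprocal best hits
with identity and coverage filters select orthologs, and each retained
ortholog pair is additionally aligned at the protein level and converted
to a codon alignment for downstream dN/dS counting.

Genome-wide ANI is the length-weighted mean nucleotide identity over
RBH gene alignments; the alignment fraction is the share of summed gene
length that aligned, averaged over the two genomes.  The computation is
symmetric by construction: comparing (A, B) and (B, A) yields the same
result object.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import Genome, GeneRecord, translate_cds

_NT_ALPHABET = frozenset("ACGT")
_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

# nucleotide scoring defaults: match +1, mismatch -1, gap open -5, extend -2
NT_MATCH, NT_MISMATCH, NT_GAP_OPEN, NT_GAP_EXTEND = 1, -1, -5, -2
# protein scoring: blosum62, first gap residue -12, each additional -3
AA_GAP_OPEN, AA_GAP_EXTEND = -12, -3


@dataclass(frozen=True)
class PairwiseParams:
    """Tunable parameters of the genome-pair comparison.

    Defaults follow the gene-based ANI convention: candidate pairs must
    share >= ``min_shared`` distinct ``k``-mers, and an RBH pair is
    retained only at >= 70% nucleotide identity with >= 70% of the
    shorter gene covered.
    """

    k: int = 11
    min_shared: int = 3
    min_identity: float = 0.70
    min_coverage: float = 0.70
    codon_alignments: bool = True

    def __post_init__(self) -> None:
        if not 8 <= self.k <= 16:
            raise ValueError(f"k must be in [8, 16], got {self.k}")


def nt_aligner() -> Align.PairwiseAligner:
    """Global nucleotide aligner (affine gaps; open applies to the first
    gap position, extend to each additional one)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = NT_MATCH
    aligner.mismatch_score = NT_MISMATCH
    aligner.open_gap_score = NT_GAP_OPEN
    aligner.extend_gap_score = NT_GAP_EXTEND
    return aligner


def protein_aligner() -> Align.PairwiseAligner:
    """Global blosum62 aligner with -12/-3 affine gaps."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = AA_GAP_OPEN
    aligner.extend_gap_score = AA_GAP_EXTEND
    return aligner


@dataclass
class PairwiseAlignment:
    """A global alignment as two gapped strings plus summary statistics.

    ``aligned_length`` and ``identity`` are computed after trimming
    terminal-gap columns; internal gap columns count as mismatches.
    """

    seq_a_aligned: str
    seq_b_aligned: str
    score: float
    aligned_length: int
    matches: int
    identity: float
    coverage_a: float
    coverage_b: float
    len_a: int = 0
    len_b: int = 0


def _summarize(gapped_a: str, gapped_b: str, score: float,
               len_a: int, len_b: int) -> PairwiseAlignment:
    """Trim terminal-gap columns and compute identity/coverage."""
    n = len(gapped_a)
    start, end = 0, n
    # only columns contiguous with either end are terminal-gap columns
    while start < n and (gapped_a[start] == "-" or gapped_b[start] == "-"):
        start += 1
    while end > start and (gapped_a[end - 1] == "-" or gapped_b[end - 1] == "-"):
        end -= 1
    core_a = gapped_a[start:end]
    core_b = gapped_b[start:end]
    matches = sum(1 for x, y in zip(core_a, core_b) if x == y and x != "-")
    aligned_length = len(core_a)
    identity = matches / aligned_length if aligned_length else 0.0
    cov_a = sum(1 for x in core_a if x != "-") / len_a if len_a else 0.0
    cov_b = sum(1 for y in core_b if y != "-") / len_b if len_b else 0.0
    return PairwiseAlignment(seq_a_aligned=gapped_a, seq_b_aligned=gapped_b,
                             score=score, aligned_length=aligned_length,
                             matches=matches, identity=identity,
                             coverage_a=cov_a, coverage_b=cov_b,
                             len_a=len_a, len_b=len_b)


def _check(seq: str, alphabet: frozenset, kind: str) -> None:
    if not seq:
        raise ValueError(f"empty {kind} sequence")
    bad = set(seq) - alphabet
    if bad:
        raise ValueError(f"non-standard {kind} characters: {sorted(bad)}")


def global_nt_align(nt_a: str, nt_b: str,
                    aligner: Align.PairwiseAligner | None = None) -> PairwiseAlignment:
    """Optimal global nucleotide alignment (+1/-1, gaps -5/-2).

    When the two sequences have equal length and the gapless alignment
    already attains the optimal score, the gapless alignment is returned
    without a traceback (it is then an optimal alignment, and the one a
    match-preferring tie-break selects).
    """
    nt_a, nt_b = nt_a.upper(), nt_b.upper()
    _check(nt_a, _NT_ALPHABET, "nucleotide")
    _check(nt_b, _NT_ALPHABET, "nucleotide")
    if aligner is None:
        aligner = nt_aligner()
    if len(nt_a) == len(nt_b):
        matches = sum(1 for x, y in zip(nt_a, nt_b) if x == y)
        gapless = matches * NT_MATCH + (len(nt_a) - matches) * NT_MISMATCH
        score = aligner.score(nt_a, nt_b)
        if score == gapless:
            return PairwiseAlignment(
                seq_a_aligned=nt_a, seq_b_aligned=nt_b, score=score,
                aligned_length=len(nt_a), matches=matches,
                identity=matches / len(nt_a), coverage_a=1.0, coverage_b=1.0,
                len_a=len(nt_a), len_b=len(nt_b))
    aln = aligner.align(nt_a, nt_b)[0]
    return _summarize(str(aln[0]), str(aln[1]), aln.score, len(nt_a), len(nt_b))


def global_protein_align(aa_a: str, aa_b: str,
                         aligner: Align.PairwiseAligner | None = None
                         ) -> PairwiseAlignment:
    """Optimal global protein alignment (blosum62, gaps -12/-3)."""
    aa_a, aa_b = aa_a.upper(), aa_b.upper()
    _check(aa_a, _AA_ALPHABET, "amino-acid")
    _check(aa_b, _AA_ALPHABET, "amino-acid")
    if aligner is None:
        aligner = protein_aligner()
    aln = aligner.align(aa_a, aa_b)[0]
    return _summarize(str(aln[0]), str(aln[1]), aln.score, len(aa_a), len(aa_b))


def codon_alignment(aa_aligned_a: str, aa_aligned_b: str,
                    nt_a: str, nt_b: str) -> list[tuple[str, str]]:
    """Map a gapped protein alignment back to paired codon columns.

    Columns where either side is a gap are masked out, so the output is a
    gap-free list of (codon_a, codon_b) pairs — one per aligned residue
    pair.  Raises ValueError when the protein alignment is inconsistent
    with the translations of the provided CDS.
    """
    if translate_cds(nt_a) != aa_aligned_a.replace("-", ""):
        raise ValueError("protein alignment does not match translation of nt_a")
    if translate_cds(nt_b) != aa_aligned_b.replace("-", ""):
        raise ValueError("protein alignment does not match translation of nt_b")
    out: list[tuple[str, str]] = []
    ia = ib = 0
    for ra, rb in zip(aa_aligned_a, aa_aligned_b):
        if ra != "-" and rb != "-":
            out.append((nt_a[3 * ia : 3 * ia + 3], nt_b[3 * ib : 3 * ib + 3]))
        if ra != "-":
            ia += 1
        if rb != "-":
            ib += 1
    return out


@dataclass
class GeneAlignment:
    """Alignment of one RBH gene pair between two genomes."""

    gene_id_a: str
    gene_id_b: str
    aligned_length: int
    nt_identity: float
    coverage_a: float
    coverage_b: float
    score: float
    codon_alignment: list[tuple[str, str]] = field(default_factory=list)

    @property
    def is_identical(self) -> bool:
        return self.nt_identity == 1.0


@dataclass
class GenomePairResult:
    """Genome-wide summary of the gene-by-gene comparison of a pair.

    ``ani`` is the length-weighted mean identity over RBH alignments and
    is ``None`` (never 0) when nothing aligned, with ``no_alignment``
    set.  Genome ids are stored in lexicographic order so that the result
    for (A, B) equals the result for (B, A) field-by-field.
    """

    genome_a: str
    genome_b: str
    rbh_alignments: list[GeneAlignment]
    ani: float | None
    alignment_fraction: float | None

    @property
    def n_genes_aligned(self) -> int:
        return len(self.rbh_alignments)

    @property
    def no_alignment(self) -> bool:
        return self.ani is None


def kmer_prescreen(genes_a: list[GeneRecord], genes_b: list[GeneRecord],
                   k: int = 11, min_shared: int = 3) -> list[tuple[int, int]]:
    """Candidate gene pairs sharing at least ``min_shared`` distinct k-mers.

    Returns (index_in_a, index_in_b) pairs.  Exact: a pair is returned iff
    the count of distinct shared k-mers meets the cutoff.
    """
    if not 8 <= k <= 16:
        raise ValueError(f"k must be in [8, 16], got {k}")
    index: dict[str, list[int]] = defaultdict(list)
    for j, gene in enumerate(genes_b):
        seq = gene.nt_seq
        for kmer in {seq[i : i + k] for i in range(len(seq) - k + 1)}:
            index[kmer].append(j)
    out: list[tuple[int, int]] = []
    for i, gene in enumerate(genes_a):
        seq = gene.nt_seq
        shared: dict[int, int] = defaultdict(int)
        for kmer in {seq[p : p + k] for p in range(len(seq) - k + 1)}:
            for j in index.get(kmer, ()):
                shared[j] += 1
        out.extend((i, j) for j, count in sorted(shared.items())
                   if count >= min_shared)
    return out


def _mutual_best(scores: dict[tuple[str, str], float]) -> list[tuple[str, str]]:
    """Mutual-best pairs by score; ties broken toward the
    lexicographically smallest partner id (deterministic)."""
    best_a: dict[str, tuple[float, str]] = {}
    best_b: dict[str, tuple[float, str]] = {}
    for (ga, gb), score in scores.items():
        if ga not in best_a or (-score, gb) < (-best_a[ga][0], best_a[ga][1]):
            best_a[ga] = (score, gb)
        if gb not in best_b or (-score, ga) < (-best_b[gb][0], best_b[gb][1]):
            best_b[gb] = (score, ga)
    return sorted((ga, gb) for ga, (_, gb) in best_a.items()
                  if best_b[gb][1] == ga)


def _passes_filters(aln: PairwiseAlignment, min_identity: float,
                    min_coverage: float) -> bool:
    if aln.identity < min_identity:
        return False
    shorter_cov = aln.coverage_a if aln.len_a <= aln.len_b else aln.coverage_b
    return shorter_cov >= min_coverage


def reciprocal_best_hits(
    scored: dict[tuple[str, str], PairwiseAlignment],
    min_identity: float = 0.70,
    min_coverage: float = 0.70,
) -> list[tuple[str, str]]:
    """Reciprocal best hits among scored candidate pairs, filtered.

    ``scored`` maps (gene_id_a, gene_id_b) to its nucleotide alignment.
    A pair is RBH iff each gene is the other's highest-scoring partner
    (ties broken toward the lexicographically smallest partner id), and
    is retained iff identity >= ``min_identity`` and the alignment covers
    >= ``min_coverage`` of the *shorter* gene.
    """
    mutual = _mutual_best({pair: aln.score for pair, aln in scored.items()})
    return [pair for pair in mutual
            if _passes_filters(scored[pair], min_identity, min_coverage)]


def compare_genomes(genome_a: Genome, genome_b: Genome,
                    params: PairwiseParams | None = None) -> GenomePairResult:
    """Full gene-by-gene comparison of two genomes.

    Pipeline: k-mer prescreen -> global nucleotide alignments -> RBH
    filter (identity/coverage) -> protein + codon alignment per retained
    pair -> genome-wide ANI and alignment fraction.  Symmetric: genomes
    are ordered by id internally, so (A, B) and (B, A) give equal results.
    """
    if params is None:
        params = PairwiseParams()
    if len(genome_a) == 0 or len(genome_b) == 0:
        raise ValueError("cannot compare an empty genome")
    if genome_b.genome_id < genome_a.genome_id:
        genome_a, genome_b = genome_b, genome_a

    candidates = kmer_prescreen(genome_a.genes, genome_b.genes,
                                k=params.k, min_shared=params.min_shared)
    aligner = nt_aligner()
    # phase 1: score-only pass over all candidates (cheap), RBH on scores
    scores: dict[tuple[str, str], float] = {}
    for i, j in candidates:
        ga, gb = genome_a.genes[i], genome_b.genes[j]
        scores[(ga.gene_id, gb.gene_id)] = aligner.score(ga.nt_seq, gb.nt_seq)
    mutual = _mutual_best(scores)

    # phase 2: full alignments for mutual-best pairs only, then filters
    genes_a = {g.gene_id: g for g in genome_a.genes}
    genes_b = {g.gene_id: g for g in genome_b.genes}
    rbh_ids: list[tuple[str, str]] = []
    full: dict[tuple[str, str], PairwiseAlignment] = {}
    for ga_id, gb_id in mutual:
        aln = global_nt_align(genes_a[ga_id].nt_seq, genes_b[gb_id].nt_seq,
                              aligner=aligner)
        if _passes_filters(aln, params.min_identity, params.min_coverage):
            rbh_ids.append((ga_id, gb_id))
            full[(ga_id, gb_id)] = aln

    aa_aligner = protein_aligner() if params.codon_alignments else None
    alignments: list[GeneAlignment] = []
    for ga_id, gb_id in rbh_ids:
        aln = full[(ga_id, gb_id)]
        codons: list[tuple[str, str]] = []
        if params.codon_alignments:
            ga, gb = genes_a[ga_id], genes_b[gb_id]
            paln = global_protein_align(ga.aa_seq, gb.aa_seq, aligner=aa_aligner)
            codons = codon_alignment(paln.seq_a_aligned, paln.seq_b_aligned,
                                     ga.nt_seq, gb.nt_seq)
        alignments.append(GeneAlignment(
            gene_id_a=ga_id, gene_id_b=gb_id,
            aligned_length=aln.aligned_length, nt_identity=aln.identity,
            coverage_a=aln.coverage_a, coverage_b=aln.coverage_b,
            score=aln.score, codon_alignment=codons))

    if not alignments:
        return GenomePairResult(genome_a=genome_a.genome_id,
                                genome_b=genome_b.genome_id,
                                rbh_alignments=[], ani=None,
                                alignment_fraction=None)

    total_aligned = sum(a.aligned_length for a in alignments)
    ani = sum(a.nt_identity * a.aligned_length for a in alignments) / total_aligned
    aligned_a = sum(len(genes_a[a.gene_id_a]) * a.coverage_a for a in alignments)
    aligned_b = sum(len(genes_b[a.gene_id_b]) * a.coverage_b for a in alignments)
    frac = 0.5 * (aligned_a / genome_a.total_gene_length
                  + aligned_b / genome_b.total_gene_length)
    return GenomePairResult(genome_a=genome_a.genome_id,
                            genome_b=genome_b.genome_id,
                            rbh_alignments=alignments, ani=ani,
                            alignment_fraction=min(frac, 1.0))
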