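"""Per-pair evolutionary statistics: Nei-Gojobori dN/dS and the
enriched-identical-genes recombination estimate.

dN/dS is the raw proportion ratio

    dN/dS = (nonsynonymous substitutions / nonsynonymous sites)
          / (synonymous substitutions / synonymous sites)

with sites and substitutions counted codon-by-codon over all
reciprocal-best-hit codon alignments of a genome pair.  No multiple-hit
correction is applied by default; a Jukes-Cantor-corrected variant is
available behind a flag.  At the within/between-species divergences this
package targets (>= 75% identity over a few percent of sites) the
uncorrected proportions are what the estimator is defined on.

The recombination estimate treats each aligned gene as a Bernoulli trial
for being *identical* between the two genomes.  Under clonal divergence
at the genome-wide ANI, a gene whose alignment spans L nucleotides is
identical with probability ANI**L, so identical genes in excess of that
expectation indicate recent homologous recombination / gene transfer:

    hr = (a - e) / i

with a = actual identical genes, e = sum of per-gene chance
probabilities, i = aligned genes passing the length filter.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

from .seqio import CODON_TO_AA, STOP_CODONS
from .pairwise import GenomePairResult

_BASES = "ACGT"


class StopCodonError(ValueError):
    """A stop codon was passed where a sense codon is required."""


@lru_cache(maxsize=None)
def nei_sites(codon: str) -> tuple[float, float]:
    """Nei-Gojobori (synonymous, nonsynonymous) site counts for one codon.

    Each of the three positions contributes a synonymous fraction equal to
    the share of its three possible single-base changes that preserve the
    amino acid; changes producing a stop codon count as nonsynonymous.
    The two counts always sum to 3.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise StopCodonError(f"stop codon {codon}")
    aa = CODON_TO_AA[codon]
    syn = 0.0
    for pos in range(3):
        n_syn = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant not in STOP_CODONS and CODON_TO_AA[mutant] == aa:
                n_syn += 1
        syn += n_syn / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def nei_substitutions(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Nei-Gojobori (synonymous, nonsynonymous) substitution counts
    between two sense codons.

    For multiply-substituted codons the classification is averaged over
    all orderings (pathways) of the differing positions.  Pathways passing
    through a stop codon are excluded; in the degenerate case where every
    pathway hits a stop, all pathways are included with the stop step
    counted as nonsynonymous.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    for c in (codon_a, codon_b):
        if c in STOP_CODONS:
            raise StopCodonError(f"stop codon {c}")
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[float, float, bool]:
        """Classify the steps of one pathway; flags stop passage."""
        syn = nonsyn = 0.0
        hit_stop = False
        current = codon_a
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                hit_stop = True
                nonsyn += 1.0  # only used in the all-stop fallback
            elif current in STOP_CODONS:
                hit_stop = True
                nonsyn += 1.0
            elif CODON_TO_AA[nxt] == CODON_TO_AA[current]:
                syn += 1.0
            else:
                nonsyn += 1.0
            current = nxt
        return syn, nonsyn, hit_stop

    paths = [walk(order) for order in itertools.permutations(diff)]
    valid = [(s, n) for s, n, stopped in paths if not stopped]
    if not valid:
        valid = [(s, n) for s, n, _ in paths]
    syn = sum(s for s, _ in valid) / len(valid)
    nonsyn = sum(n for _, n in valid) / len(valid)
    return syn, nonsyn


@dataclass
class NeiCounts:
    """Accumulated Nei-Gojobori site and substitution counts."""

    syn_sites: float = 0.0
    nonsyn_sites: float = 0.0
    syn_subs: float = 0.0
    nonsyn_subs: float = 0.0

    def add_codon_pair(self, codon_a: str, codon_b: str) -> None:
        """Accumulate one codon-alignment column.

        Sites are the average of the two codons' site counts (so each
        column contributes exactly 3 sites); substitutions are the
        pathway-averaged classification of the differing positions.
        """
        sa, na = nei_sites(codon_a)
        sb, nb = nei_sites(codon_b)
        self.syn_sites += (sa + sb) / 2.0
        self.nonsyn_sites += (na + nb) / 2.0
        ss, ns = nei_substitutions(codon_a, codon_b)
        self.syn_subs += ss
        self.nonsyn_subs += ns

    def __iadd__(self, other: "NeiCounts") -> "NeiCounts":
        self.syn_sites += other.syn_sites
        self.nonsyn_sites += other.nonsyn_sites
        self.syn_subs += other.syn_subs
        self.nonsyn_subs += other.nonsyn_subs
        return self


def dnds_from_counts(counts: NeiCounts, jc_correction: bool = False) -> float | None:
    """dN/dS from accumulated counts; ``None`` when undefined.

    Undefined when there are no synonymous substitutions or no sites of
    either class; undefined values propagate as missing, never as 0 or
    infinity.  ``jc_correction`` applies the Jukes-Cantor multiple-hit
    correction to each proportion before taking the ratio (non-default).
    """
    if counts.syn_subs <= 0 or counts.syn_sites <= 0 or counts.nonsyn_sites <= 0:
        return None
    pn = counts.nonsyn_subs / counts.nonsyn_sites
    ps = counts.syn_subs / counts.syn_sites
    if jc_correction:
        if pn >= 0.75 or ps >= 0.75:
            return None
        pn = -0.75 * math.log(1.0 - 4.0 * pn / 3.0)
        ps = -0.75 * math.log(1.0 - 4.0 * ps / 3.0)
    if ps == 0:
        return None
    return pn / ps


@dataclass
class DnDsResult:
    """Genome-pair dN/dS with all intermediate counts."""

    counts: NeiCounts
    dnds: float | None
    n_genes: int

    @property
    def defined(self) -> bool:
        return self.dnds is not None


def pair_dnds(pair_result: GenomePairResult, jc_correction: bool = False) -> DnDsResult:
    """Genome-wide dN/dS over all RBH codon alignments of a pair.

    Raises ValueError when the pair has no codon alignments.
    """
    alns = [a for a in pair_result.rbh_alignments if a.codon_alignment]
    if not alns:
        raise ValueError(
            f"no codon alignments for pair ({pair_result.genome_a}, "
            f"{pair_result.genome_b})")
    counts = NeiCounts()
    for aln in alns:
        for codon_a, codon_b in aln.codon_alignment:
            counts.add_codon_pair(codon_a, codon_b)
    return DnDsResult(counts=counts,
                      dnds=dnds_from_counts(counts, jc_correction=jc_correction),
                      n_genes=len(alns))


def expected_identical(ani: float, aligned_lengths: list[int]) -> float:
    """Expected count of chance-identical genes: sum over genes of ANI**L.

    ``ani`` is the genome-wide identity as a fraction in (0, 1]; each
    aligned gene of length L is identical by chance with probability
    ANI**L.  (Equivalently the mean per-gene probability multiplied by the
    number of aligned genes.)
    """
    if not 0.0 < ani <= 1.0:
        raise ValueError(f"ani must be in (0, 1], got {ani}")
    return float(sum(ani ** L for L in aligned_lengths))


@dataclass
class RecombinationResult:
    """Enriched-identical-genes estimate for one genome pair.

    ``excluded`` flags pairs with fewer aligned genes than the minimum;
    such pairs carry no hr value (the estimate is too noisy to report).
    """

    a: int
    e: float
    i: int
    hr: float | None
    excluded: bool = False
    excluded_reason: str | None = None


def enriched_identical_genes(pair_result: GenomePairResult,
                             min_aligned_nt: int = 500,
                             min_genes: int = 1000) -> RecombinationResult:
    """hr = (a - e) / i over RBH alignments with >= ``min_aligned_nt`` aligned.

    Pairs with fewer than ``min_genes`` surviving alignments are flagged
    ``excluded`` (a result, not an error).  ``a`` counts alignments at
    100% nucleotide identity over the aligned region (internal gaps
    disqualify identity); ``e`` is :func:`expected_identical` at the
    pair's genome-wide ANI.
    """
    surviving = [aln for aln in pair_result.rbh_alignments
                 if aln.aligned_length >= min_aligned_nt]
    i = len(surviving)
    if i < min_genes:
        return RecombinationResult(
            a=0, e=0.0, i=i, hr=None, excluded=True,
            excluded_reason=f"only {i} aligned genes >= {min_aligned_nt} nt "
                            f"(minimum {min_genes})")
    if pair_result.ani is None:
        return RecombinationResult(a=0, e=0.0, i=i, hr=None, excluded=True,
                                   excluded_reason="no ANI for pair")
    a = sum(1 for aln in surviving if aln.is_identical)
    e = expected_identical(pair_result.ani,
                           [aln.aligned_length for aln in surviving])
    return RecombinationResult(a=a, e=e, i=i, hr=(a - e) / i, excluded=False)


def pair_metrics_row(pair_result: GenomePairResult,
                     min_aligned_nt: int = 500,
                     min_genes: int = 1000) -> dict:
    """One pair-summary TSV row combining ANI, dN/dS and hr fields."""
    row: dict = {
        "genome1": pair_result.genome_a,
        "genome2": pair_result.genome_b,
        "ani": pair_result.ani,
        "alignment_fraction": pair_result.alignment_fraction,
        "n_genes_aligned": pair_result.n_genes_aligned,
        "no_alignment": pair_result.no_alignment,
    }
    if pair_result.no_alignment or not any(
            a.codon_alignment for a in pair_result.rbh_alignments):
        row.update({"dnds": None, "syn_subs": None, "syn_sites": None,
                    "nonsyn_subs": None, "nonsyn_sites": None})
    else:
        dn = pair_dnds(pair_result)
        row.update({"dnds": dn.dnds,
                    "syn_subs": dn.counts.syn_subs,
                    "syn_sites": dn.counts.syn_sites,
                    "nonsyn_subs": dn.counts.nonsyn_subs,
                    "nonsyn_sites": dn.counts.nonsyn_sites})
    rec = enriched_identical_genes(pair_result, min_aligned_nt=min_aligned_nt,
                                   min_genes=min_genes)
    row.update({"a": rec.a, "e": rec.e, "i": rec.i, "hr": rec.hr,
                "excluded_flag": rec.excluded})
    return row
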