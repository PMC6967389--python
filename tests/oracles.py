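"""Independent brute-force oracles used by the test suite.

These deliberately re-derive expected values by enumeration rather than
calling the package's own implementations.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

from Bio.Seq import Seq

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}


def translate1(codon: str) -> str:
    return str(Seq(codon).translate())


def nei_sites_oracle(codon: str) -> tuple[float, float]:
    """Enumerate all 9 single-base changes of a sense codon."""
    aa = translate1(codon)
    syn = 0.0
    for pos, base in itertools.product(range(3), _BASES):
        if base == codon[pos]:
            continue
        mutant = codon[:pos] + base + codon[pos + 1 :]
        if mutant not in _STOPS and translate1(mutant) == aa:
            syn += 1.0 / 3.0
    return syn, 3.0 - syn


def nei_substitutions_oracle(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average syn/nonsyn step classification over all orderings of the
    differing positions, excluding stop-passing pathways (included as a
    fallback, stop steps nonsynonymous, when no pathway avoids stops)."""
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    classified = []
    for order in itertools.permutations(diff):
        current, syn, nonsyn, stopped = codon_a, 0, 0, False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in _STOPS or current in _STOPS:
                stopped = True
                nonsyn += 1
            elif translate1(nxt) == translate1(current):
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        classified.append((syn, nonsyn, stopped))
    ok = [(s, n) for s, n, stopped in classified if not stopped]
    if not ok:
        ok = [(s, n) for s, n, _ in classified]
    return (sum(s for s, _ in ok) / len(ok), sum(n for _, n in ok) / len(ok))


def affine_align_score_oracle(a: str, b: str, score_fn, gap_open: float,
                              gap_extend: float) -> float:
    """Optimal global alignment score by exhaustive recursion over the
    (position, position, gap-state) space.

    ``score_fn(x, y)`` scores one aligned residue pair; the first residue
    of a gap costs ``gap_open``, each subsequent one ``gap_extend``.
    """

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: int) -> float:
        # state: 0 = previous column was a residue pair (or the start),
        #        1 = gap consuming a, 2 = gap consuming b
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            options.append(score_fn(a[i], b[j]) + best(i + 1, j + 1, 0))
        if i < len(a):  # a[i] aligned to a gap in b
            cost = gap_extend if state == 1 else gap_open
            options.append(cost + best(i + 1, j, 1))
        if j < len(b):  # b[j] aligned to a gap in a
            cost = gap_extend if state == 2 else gap_open
            options.append(cost + best(i, j + 1, 2))
        return max(options)

    result = best(0, 0, 0)
    best.cache_clear()
    return result


def affine_align_score_exhaustive(a: str, b: str, score_fn, gap_open: float,
                                  gap_extend: float) -> float:
    """Truly path-by-path enumeration (no memoization); only feasible for
    very short sequences.  Used to validate the recursive oracle itself."""

    def walk(i: int, j: int, state: int) -> list[float]:
        if i == len(a) and j == len(b):
            return [0.0]
        out = []
        if i < len(a) and j < len(b):
            out += [score_fn(a[i], b[j]) + s for s in walk(i + 1, j + 1, 0)]
        if i < len(a):
            cost = gap_extend if state == 1 else gap_open
            out += [cost + s for s in walk(i + 1, j, 1)]
        if j < len(b):
            cost = gap_extend if state == 2 else gap_open
            out += [cost + s for s in walk(i, j + 1, 2)]
        return out

    return max(walk(0, 0, 0))


def hamming_identity(genome_a, genome_b, exclude=()) -> float:
    """Per-site identity of two genomes by direct gene-wise comparison."""
    total = same = 0
    genes_b = {g.gene_id: g for g in genome_b.genes}
    for ga in genome_a.genes:
        if ga.gene_id in exclude:
            continue
        gb = genes_b[ga.gene_id]
        total += len(ga.nt_seq)
        same += sum(1 for x, y in zip(ga.nt_seq, gb.nt_seq) if x == y)
    return same / total


def rescan_thresholds_oracle(identities: dict, labels: dict, grid) -> list:
    """Independent per-threshold re-derivation of (recall, precision, F1)."""
    out = []
    for t in grid:
        tp = fp = fn = 0
        for pair, ident in identities.items():
            same = labels[pair]
            pred = ident >= t
            if pred and same:
                tp += 1
            elif pred and not same:
                fp += 1
            elif not pred and same:
                fn += 1
        recall = tp / (tp + fn) if tp + fn else 0.0
        precision = tp / (tp + fp) if tp + fp else 0.0
        f1 = (2 * recall * precision / (recall + precision)
              if recall + precision else 0.0)
        out.append((recall, precision, f1))
    return out
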