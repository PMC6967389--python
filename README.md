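# speciesgap

Gene-based genome comparison and species-boundary analysis for microbial
genomes, with a ground-truth simulator for validating every statistic.

## The problem

Most bacterial and archaeal diversity is now sampled through
metagenome-assembled genomes (MAGs) rather than isolates, so species
must be delineated from sequence alone.  The standard instrument is
average nucleotide identity (ANI): genome pairs cluster either above
~95% ANI (same species) or below ~90% (different species), with a
depleted "species gap" in between.  This package implements the
analysis toolkit behind that picture for genomes represented as gene
sets (coding sequences):

* **Gene-by-gene ANI** — orthologs are paired by reciprocal best hits
  (RBH) over global nucleotide alignments, filtered at ≥70% identity
  and ≥70% coverage of the shorter gene; genome-wide ANI is the
  length-weighted mean gene identity, and the alignment fraction is the
  share of gene length that aligned.
* **Genome-wide dN/dS** — each RBH pair is aligned as proteins
  (blosum62, gap open −12 / extend −3), back-translated to a codon
  alignment, and counted with the Nei–Gojobori method:

  `dN/dS = (nonsynonymous subs / nonsynonymous sites) / (synonymous subs / synonymous sites)`

* **Recombination via enriched identical genes** — under clonal
  divergence a gene whose alignment spans `L` nucleotides is identical
  by chance with probability `ANI^L`; identical genes in excess of that
  expectation indicate recent homologous recombination:

  `hr = (a − e) / i`

  with `a` actual identical genes, `e = Σ_g ANI^(L_g)` the chance
  expectation, and `i` the aligned genes with ≥500 bp aligned (pairs
  with fewer than 1,000 such genes are excluded by default).
* **Species-threshold scanning** — every identity threshold from 80% to
  100% in 0.1 steps is scored by recall, precision and F1 of the
  pairwise same-species predictions, for whole-genome ANI or for
  single-copy marker genes, plus marker prevalence and
  *recoverability* (assembled marker copies per binned genome).
* **A simulator with exact truth** — genome pairs at controlled
  divergence and synonymous/nonsynonymous acceptance, whole-gene
  transfers, and multi-species populations with a constructed identity
  gap; substitutions are placed at globally distinct sites, so true
  identity, substitution class counts and transferred genes are known
  exactly.

## Worked example

```python
from speciesgap import simgen, pairwise, evometrics

config = simgen.PairSimConfig(n_genes=200, gene_length_mean=300,
                              divergence=0.05, omega=0.3, seed=7)
genome_a, genome_b, truth = simgen.simulate_pair(config)
result = pairwise.compare_genomes(genome_a, genome_b)
print(f"ANI {result.ani:.4f} (truth {truth.true_identity:.4f})")
print(f"dN/dS {evometrics.pair_dnds(result).dnds:.3f} "
      f"(counted truth {truth.true_dnds:.3f})")
```

prints

```
ANI 0.9500 (truth 0.9500)
dN/dS 0.307 (counted truth 0.301)
```

— the gene-based ANI recovers the simulated identity exactly (the
simulator places substitutions at distinct sites, so identity is not
blurred by multiple hits), and the Nei-counted dN/dS sits within a few
percent of the ratio counted from the simulator's substitution log.

The same machinery is driven end-to-end by the numbered scripts under
`analysis/`; for example

```
$ python analysis/04_species_gap.py
optimal species threshold 93.45% ANI, F1 = 1.000; max-F1 plateau
[89.3%, 97.6%] spans the constructed gap (between <= 90%, within >= 97%)
```

and `analysis/02_dnds_selection.py` tabulates dN/dS recovery over
omega ∈ {0.1, 0.3, 1.0} (mean relative error ≤4% at 5% divergence).
Each script writes its tables under `results/`.

There is also a CLI (`speciesgap simulate | compare | metrics |
landscape | scan | markers | pipeline`) exposing the same functions for
shell use; `speciesgap pipeline -o out --seed 1` runs
simulate → compare → scan in one step.

## Layout

```
src/speciesgap/    seqio, simgen, pairwise, evometrics, delineation,
                   markers, cli
analysis/          numbered narrative drivers writing results/
tests/             pytest suite with independent brute-force oracles
docs/methods.md    model, parameter and design notes
```
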