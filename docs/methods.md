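# Methods

## Scope and model

`speciesgap` analyzes microbial genomes represented as sets of in-frame
coding sequences (CDS).  All statistics are pairwise and gene-based: no
whole-contig or fragment-mapping alignment is performed, so results on
genomes with large non-coding or unshared fractions reflect the gene
complement only.

### Gene pairing and ANI

Candidate ortholog pairs between two genomes are proposed by an exact
k-mer prescreen (default k = 11, ≥3 distinct shared k-mers) and scored
with global Needleman–Wunsch alignments (match +1, mismatch −1, gap
open −5, extend −2; "open" is the cost of the *first* gap position,
"extend" of each additional one — conventions differ between tools, so
this is stated explicitly).  A pair is kept when each gene is the
other's highest-scoring partner (reciprocal best hit; score ties broken
toward the lexicographically smallest partner id), its identity over
the aligned region is ≥0.70, and the alignment covers ≥0.70 of the
shorter gene.  "Coverage of the shorter gene" is one of two readings of
the conventional 70/70 RBH filter (the other being the fraction of a
genome's genes participating); it is the permissive, length-robust
choice.

Identity is computed after trimming terminal-gap columns; internal gap
columns count as mismatches (an indel is a difference).  Genome-wide
ANI is the *length-weighted* mean of RBH gene identities — weighting
approximates whole-genome ANI and matches the use of alignment length
in the recombination expectation.  The alignment fraction is the share
of summed gene length that aligned, averaged over the two genomes.  A
pair with no surviving RBH gene has undefined ANI (flagged
`no_alignment`), never ANI 0.  The computation is symmetric by
construction, so reciprocal comparisons need no averaging; an averaging
adapter (`cli.import_external_ani`) exists only for asymmetric external
fragment-mapping ANI tables.

When two genes have equal length and the gapless alignment already
attains the optimal score, the gapless alignment is returned without a
traceback; this is exact (the gapless alignment is then an optimal
alignment, and the one a match-preferring tie-break selects) and makes
large simulated comparisons cheap.  Both aligners are checked against
brute-force enumeration in the test suite.

### dN/dS

Each RBH pair is aligned at the protein level (blosum62, gap open −12,
extend −3), mapped back to a codon alignment with gap columns masked,
and counted with the Nei–Gojobori method: per codon the synonymous site
count is the fraction of the nine single-base changes that preserve the
amino acid (changes to stops count nonsynonymous); per codon pair with
several differences, substitution classes are averaged over all
orderings of the differing positions, excluding pathways through stop
codons (if every pathway hits a stop they are all included, stop steps
nonsynonymous).  Sites for a column are the average of the two codons'
site counts, so each column contributes exactly 3 sites; this
both-codons averaging is the standard convention and one of two
defensible choices (the alternative being one reference codon).

The genome-wide ratio is the raw proportion ratio
`(pN = nonsyn subs / nonsyn sites) / (pS = syn subs / syn sites)` with
**no multiple-hit correction by default**; a Jukes–Cantor-corrected
variant is available behind `jc_correction=True` but is never the
default, because the raw ratio is the quantity the rest of the analysis
is defined on.  When there are no synonymous substitutions (or no sites
of a class) the ratio is undefined and propagates as missing — it is
never coerced to 0 or infinity, and binned medians skip missing values.

### Enriched identical genes (hr)

RBH alignments with ≥500 bp aligned are the trials; pairs with fewer
than 1,000 such genes are flagged excluded rather than scored (the
estimate is too noisy below that).  A gene is *identical* when its
identity over the aligned region is exactly 1.0 (internal gaps
disqualify).  The chance expectation is `e = Σ_g ANI^(L_g)` — the sum
of per-gene probabilities, equivalently the mean per-gene probability
times the gene count; summing is the only length-aware reading when
gene lengths vary.  Then `hr = (a − e)/i ∈ [−e/i, 1]`.  At ANI ≤ 0.95
and L ≥ 500, `e` is astronomically small (0.95^500 ≈ 10⁻¹¹), so any
observed identical gene at moderate divergence is evidence of transfer.

### Threshold scan, landscape, curves

The species scan grid is 80.0–100.0% in 0.1 steps (201 thresholds,
inclusive); a pair is predicted same-species when identity ≥ t (closed
boundary, "at least as similar").  Recall, precision and F1 follow the
standard pairwise definitions with 0/0 scored 0 and flagged.  On gapped
data the maximum-F1 set is an interval; the reported optimum is the
plateau *midpoint* with both bounds reported, so any other tie
convention (low or high edge) is recoverable from the output.
Distance matrices are converted to identities (100 × (1 − d)) so one
scan engine serves genome-wide and marker-gene inputs.  The 95%-ANI
pair-labeling boundary is likewise closed (ANI = 95.0 → same species).

The ANI × alignment-fraction landscape is a Gaussian KDE (bandwidth by
Scott's rule, configurable) on a regular grid.  Per-axis padding is the
larger of three kernel bandwidths and 2 percentage points (capped at
the data range), so the grid resolves the kernel even when an axis
barely varies, as the alignment fraction does for close genomes; an
exactly constant axis is spread by a ±10⁻⁶ deterministic offset to keep
the covariance non-singular.  Binned metric curves use 0.5-pp ANI bins
by default, report the per-bin median with a seeded percentile
bootstrap (1,000 resamples) for the 95% band, and mask bins with fewer
than 3 defined values.  The bootstrap construction is a package choice;
nothing downstream depends on the specific CI method.

### Markers

Marker sets (e.g. ribosomal proteins) enter as per-marker FASTA
(`genome_id|gene_id` headers) or a hits table; HMM searching itself is
out of process, with only a thin hmmsearch `--tblout` parser provided
as an interface.  Multi-copy genomes are represented by their longest
hit (ties by gene id) — the aggregation rule for multi-copy hits is not
standardized anywhere, and "longest" favors complete gene calls.
Benchmarks scan each marker's identity matrix against pair labels
restricted to carrier genomes; with several genome sets the reported
threshold maximizes the *average* F1 across sets.  A marker with fewer
than two carriers, single-class restricted labels, or no identity
variation at all is flagged rather than scored.  Prevalence boundaries
are closed: retained at ≥85% of the reference universe, "present" in a
second (e.g. archaeal) universe at ≥80%.  Recoverability is the plain
quotient assembled gene copies / filtered genomes.

## The simulator

The generator exists to give every statistic an *exactly* recoverable
truth, not to be demographically realistic.

* **Ancestors** are uniform random sense-codon genes; lengths uniform
  within ±20% of the mean, rounded to multiples of 3.
* **Divergence**: `round(divergence × total_sites)` substitutions are
  placed at globally distinct sites (never two hits on one site, in
  either lineage), each assigned to one of the two lineages with equal
  probability.  Realized identity is therefore exactly
  `1 − placed/total_sites` — parameter recovery is an exact test, not
  an asymptotic one.  This caps usable divergence at 0.25 per site,
  which covers the whole within/between-species regime of interest.
* **Selection**: a candidate change is accepted with probability 1 if
  synonymous and `min(1, omega)` if nonsynonymous (for omega > 1 the
  synonymous acceptance is scaled by 1/omega instead); changes creating
  stop codons are rejected and redrawn.  `omega` shapes the process,
  but the recovery target for dN/dS is the **counted** truth — the
  logged substitution classes over Nei site counts of the ancestor —
  because an estimator should be compared to what happened, not to a
  rate parameter.
* **Transfers** overwrite whole genes of lineage B with A's copy,
  mirroring a gene-level identical-gene statistic; there are no
  partial-gene recombination tracts.
* **Populations** are built over one root: each species ancestor
  receives exactly `k = ⌈L(1−between_max)/2⌉` substitutions and each
  genome its own `m_g` substitutions with
  `m_g ∈ [⌈L(1−hi)/2⌉, ⌊L(1−lo)/2⌋]`, all sites globally distinct
  across the entire population.  Every pairwise identity is then an
  exact function of branch counts: within-species pairs land inside
  `[lo, hi]`, between-species pairs at or below `between_max` — the
  identity gap holds by construction, and the truth table of pairwise
  identities is emitted alongside the labels.

Not modeled: indels, rearrangements, gene gain/loss, GC/codon bias,
rate heterogeneity, intra-gene recombination breakpoints, coalescent
structure.  Passing recovery tests therefore demonstrates correctness
of the estimators under substitution-only divergence with known
orthology; they do not validate robustness to fragmented assemblies,
chimeric bins, paralog confusion or alignment ambiguity in real MAGs.

## Problem sizes and numerical choices

Recovery studies run at desk scale, chosen so each estimator operates
in its intended regime: ANI recovery on 100-gene genomes over
divergences 0.01–0.15; dN/dS on 200 × 300-nt genes at 5% divergence
(≈1,500 substitutions per pair, enough for stable proportions); hr on
1,200-gene genomes with a 630-nt mean gene length so that every gene
clears the 500-bp aligned-length filter and the full complement counts
toward `i`; populations of 3 species × 4 genomes × 60 genes for the
threshold scans.  The hr-vs-ANI curve study uses 300-gene genomes with
the aligned-gene minimum scaled to match (the estimator's `min_genes`
is a parameter precisely so the statistic stays defined on smaller
simulated genomes).

Degenerate inputs are contracts, not crashes: empty genomes and
single-class label sets raise; no-alignment pairs and excluded hr pairs
are flagged results; undefined dN/dS is missing data.  All randomness
(simulator, bootstrap) flows from explicit integer seeds, and identical
seeds give byte-identical outputs.

## Known limitations

* ANI and alignment fraction are gene-based; figures built on
  fragment-mapping ANI have a subtly different alignment-fraction axis,
  so landscape comparisons to such tools are qualitative.
* The dN/dS estimator shares the usual Nei–Gojobori small-count
  instability when synonymous substitutions are few; genome-wide sums
  mitigate this but per-gene use would not.
* `hr` detects *whole-gene* homogenization only; partial-gene
  conversion tracts shorter than a gene dilute identity and are missed.
* The k-mer prescreen is exact for its own contract but, at default
  k = 11, passes a small number of spurious candidate pairs on
  codon-structured sequence; these are eliminated by the RBH and
  identity filters and only cost time.
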