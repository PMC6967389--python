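"""Synthetic genome pairs and populations with exact ground truth.

The generative model is deliberately simple so that every downstream
statistic has an exactly recoverable truth:

* An ancestor genome is a set of random sense-codon genes.
* A pair diverges by placing single-base substitutions at *globally
  distinct* sites across both lineages (no site is hit twice by either
  lineage), so every placed substitution is a realized difference and
  the pairwise identity equals ``1 - placed / total_sites`` exactly —
  no back-mutation, no multiple hits.  This restricts the realistic
  divergence range to <= 0.25 per site.
* Selection enters as an acceptance probability: synonymous changes are
  always accepted, nonsynonymous ones with probability ``min(1, omega)``
  (for ``omega > 1`` the synonymous acceptance is scaled by ``1/omega``
  instead).  ``omega`` shapes the substitution process; the recovery
  target for dN/dS estimators is the *counted* truth in the
  :class:`TruthRecord`, not the acceptance parameter itself.
* Horizontal transfer overwrites whole genes of one lineage with the
  other lineage's copy, creating identical genes on a diverged backbone.
* A multi-species population is built over one root ancestor with a
  constructed identity gap: all within-species pairwise identities fall
  in a stated range, all between-species identities below a stated
  maximum, again exactly by the distinct-sites bookkeeping.

Indels, rearrangements, GC bias and intra-gene recombination tracts are
intentionally absent (see the package methods note).
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .seqio import (CODON_TO_AA, SENSE_CODONS, STOP_CODONS, Genome,
                    GeneRecord, write_gene_fasta, write_labels)
from .evometrics import nei_sites

_BASES = "ACGT"


class SimulationError(RuntimeError):
    """The requested divergence could not be realized."""


@dataclass(frozen=True)
class PairSimConfig:
    """Parameters of a simulated genome pair."""

    n_genes: int = 200
    gene_length_mean: int = 300
    divergence: float = 0.05
    omega: float = 0.3
    n_transfers: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.gene_length_mean % 3 != 0 or self.gene_length_mean < 60:
            raise ValueError("gene_length_mean must be a multiple of 3, >= 60")
        if not 0.0 <= self.divergence <= 0.25:
            raise ValueError("divergence must be in [0, 0.25]")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if not 0 <= self.n_transfers <= self.n_genes:
            raise ValueError("n_transfers must be in [0, n_genes]")


@dataclass
class TruthRecord:
    """Exact ground truth for one simulated genome pair.

    ``true_identity`` is the fraction of identical sites over
    non-transferred genes; substitution counts likewise cover
    non-transferred genes (transfers erase the differences they would
    otherwise contribute).  Site counts are Nei-Gojobori counts on the
    ancestor.  ``changes`` logs every accepted substitution.
    """

    total_sites: int
    true_identity: float
    true_syn_subs: int
    true_nonsyn_subs: int
    true_syn_sites: float
    true_nonsyn_sites: float
    transferred_gene_ids: set[str] = field(default_factory=set)
    per_gene: dict[str, dict] = field(default_factory=dict)
    changes: list[dict] = field(default_factory=list)

    @property
    def true_dnds(self) -> float | None:
        """The counted dN/dS truth: substitution proportions over the
        ancestor's Nei site counts (``None`` if no synonymous subs)."""
        if self.true_syn_subs == 0 or self.true_syn_sites == 0:
            return None
        return ((self.true_nonsyn_subs / self.true_nonsyn_sites)
                / (self.true_syn_subs / self.true_syn_sites))

    def to_json(self, path: str | Path, config: PairSimConfig | None = None) -> Path:
        payload = {
            "config": asdict(config) if config is not None else None,
            "total_sites": self.total_sites,
            "true_identity": self.true_identity,
            "true_syn_subs": self.true_syn_subs,
            "true_nonsyn_subs": self.true_nonsyn_subs,
            "true_syn_sites": self.true_syn_sites,
            "true_nonsyn_sites": self.true_nonsyn_sites,
            "true_dnds": self.true_dnds,
            "transferred_gene_ids": sorted(self.transferred_gene_ids),
            "per_gene": self.per_gene,
            "n_changes": len(self.changes),
            "changes": self.changes,
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=1))
        return path


def generate_ancestor(n_genes: int, gene_length_mean: int, seed: int,
                      genome_id: str = "ancestor") -> Genome:
    """Random ancestor genome: uniform sense-codon genes, lengths drawn
    uniformly within +/-20% of the mean (rounded to multiples of 3)."""
    rng = random.Random(seed)
    lo = max(60, int(round(gene_length_mean * 0.8 / 3.0)) * 3)
    hi = int(round(gene_length_mean * 1.2 / 3.0)) * 3
    genes = []
    for g in range(n_genes):
        length = rng.randrange(lo // 3, hi // 3 + 1) * 3
        nt = "".join(rng.choice(SENSE_CODONS) for _ in range(length // 3))
        genes.append(GeneRecord.from_nt(f"g{g:05d}", genome_id, nt))
    return Genome(genome_id=genome_id, genes=genes)


def _ancestor_nei_sites(genome: Genome) -> tuple[float, float]:
    syn = nonsyn = 0.0
    for gene in genome.genes:
        for codon in gene.codons:
            s, n = nei_sites(codon)
            syn += s
            nonsyn += n
    return syn, nonsyn


def _mutate_distinct_sites(seqs: list[list[str]], gene_ids: list[str],
                           n_subs: int, omega: float, rng: random.Random,
                           used: set[tuple[int, int]],
                           n_lineages: int = 1,
                           log: list[dict] | None = None,
                           per_gene: dict[str, dict] | None = None,
                           lineage_names: tuple[str, ...] = ("A", "B"),
                           ) -> None:
    """Place ``n_subs`` accepted substitutions on ``seqs``.

    ``seqs`` holds one or two lineages, each a list of per-gene character
    lists.  Sites are drawn from the global pool excluding ``used`` and
    are marked used on acceptance, so every accepted substitution is a
    realized difference between lineages (and between any two genomes
    sharing the pool).  Changes creating stop codons are rejected and
    redrawn; nonsynonymous changes are accepted with ``min(1, omega)``
    (synonymous with ``1/omega`` when ``omega > 1``).
    """
    if omega > 1:
        p_syn, p_nonsyn = 1.0 / omega, 1.0
    else:
        p_syn, p_nonsyn = 1.0, omega
    sites = [(gi, p) for gi, gene in enumerate(seqs[0])
             for p in range(len(gene)) if (gi, p) not in used]
    rng.shuffle(sites)
    avail = sites
    placed = 0
    attempts = 0
    max_attempts = 200 * max(n_subs, 1) + 10_000
    while placed < n_subs:
        attempts += 1
        if attempts > max_attempts or not avail:
            raise SimulationError(
                f"placed {placed}/{n_subs} substitutions after {attempts} "
                f"attempts; divergence unreachable under the acceptance rules")
        idx = rng.randrange(len(avail))
        gi, pos = avail[idx]
        lineage = rng.randrange(n_lineages)
        gene = seqs[lineage][gi]
        old = gene[pos]
        new = rng.choice([b for b in _BASES if b != old])
        cstart = (pos // 3) * 3
        codon_old = "".join(gene[cstart : cstart + 3])
        codon_new = codon_old[: pos - cstart] + new + codon_old[pos - cstart + 1 :]
        if codon_new in STOP_CODONS:
            continue  # rejected; site stays in the pool
        synonymous = CODON_TO_AA[codon_new] == CODON_TO_AA[codon_old]
        if rng.random() >= (p_syn if synonymous else p_nonsyn):
            continue
        gene[pos] = new
        avail[idx] = avail[-1]
        avail.pop()
        used.add((gi, pos))
        placed += 1
        gid = gene_ids[gi]
        if per_gene is not None:
            rec = per_gene.setdefault(gid, {"syn": 0, "nonsyn": 0, "n_diffs": 0})
            rec["syn" if synonymous else "nonsyn"] += 1
            rec["n_diffs"] += 1
        if log is not None:
            log.append({"lineage": lineage_names[lineage], "gene_id": gid,
                        "site": pos, "from": old, "to": new,
                        "synonymous": synonymous})


def evolve_pair(ancestor: Genome, config: PairSimConfig
                ) -> tuple[Genome, Genome, TruthRecord]:
    """Diverge two lineages from an ancestor to an exact target identity.

    ``round(divergence * total_sites)`` substitutions are placed at
    globally distinct sites, each assigned to lineage A or B with equal
    probability, so the realized per-site difference matches the target
    divergence to within one substitution and
    ``true_identity == 1 - placed / total_sites`` holds exactly.
    """
    rng = random.Random(config.seed)
    seqs_a = [list(g.nt_seq) for g in ancestor.genes]
    seqs_b = [list(g.nt_seq) for g in ancestor.genes]
    gene_ids = [g.gene_id for g in ancestor.genes]
    total_sites = ancestor.total_gene_length
    n_subs = round(config.divergence * total_sites)

    changes: list[dict] = []
    per_gene: dict[str, dict] = {}
    used: set[tuple[int, int]] = set()
    _mutate_distinct_sites([seqs_a, seqs_b], gene_ids, n_subs, config.omega,
                           rng, used, n_lineages=2, log=changes,
                           per_gene=per_gene)

    genome_a = Genome(genome_id=f"{ancestor.genome_id}_A", genes=[
        GeneRecord.from_nt(gid, f"{ancestor.genome_id}_A", "".join(s))
        for gid, s in zip(gene_ids, seqs_a)])
    genome_b = Genome(genome_id=f"{ancestor.genome_id}_B", genes=[
        GeneRecord.from_nt(gid, f"{ancestor.genome_id}_B", "".join(s))
        for gid, s in zip(gene_ids, seqs_b)])

    syn_sites, nonsyn_sites = _ancestor_nei_sites(ancestor)
    truth = TruthRecord(
        total_sites=total_sites,
        true_identity=1.0 - n_subs / total_sites,
        true_syn_subs=sum(c["synonymous"] for c in changes),
        true_nonsyn_subs=sum(not c["synonymous"] for c in changes),
        true_syn_sites=syn_sites,
        true_nonsyn_sites=nonsyn_sites,
        per_gene=per_gene,
        changes=changes,
    )
    if config.n_transfers:
        genome_a, genome_b, truth = apply_transfers(
            genome_a, genome_b, truth, config.n_transfers,
            seed=rng.randrange(2 ** 31))
    return genome_a, genome_b, truth


def apply_transfers(genome_a: Genome, genome_b: Genome, truth: TruthRecord,
                    n_transfers: int, seed: int
                    ) -> tuple[Genome, Genome, TruthRecord]:
    """Overwrite ``n_transfers`` whole genes of B with A's copy.

    Emulates recent gene-scale homologous recombination: transferred
    genes compare at 100% identity while the rest of the genome keeps
    its divergence.  Truth identity and substitution counts are
    recomputed over the non-transferred genes only.
    """
    if not 0 <= n_transfers <= len(genome_b.genes):
        raise ValueError("n_transfers must be in [0, n_genes]")
    rng = random.Random(seed)
    chosen = set(rng.sample([g.gene_id for g in genome_b.genes], n_transfers))
    genes_a = {g.gene_id: g for g in genome_a.genes}
    new_b = [GeneRecord.from_nt(g.gene_id, genome_b.genome_id,
                                genes_a[g.gene_id].nt_seq)
             if g.gene_id in chosen else g
             for g in genome_b.genes]
    genome_b = Genome(genome_id=genome_b.genome_id, genes=new_b)

    transferred = truth.transferred_gene_ids | chosen
    kept_sites = sum(len(g) for g in genome_a.genes
                     if g.gene_id not in transferred)
    kept_changes = [c for c in truth.changes
                    if c["gene_id"] not in transferred]
    n_diffs = len(kept_changes)
    truth = TruthRecord(
        total_sites=truth.total_sites,
        true_identity=(1.0 - n_diffs / kept_sites) if kept_sites else 1.0,
        true_syn_subs=sum(c["synonymous"] for c in kept_changes),
        true_nonsyn_subs=sum(not c["synonymous"] for c in kept_changes),
        true_syn_sites=truth.true_syn_sites,
        true_nonsyn_sites=truth.true_nonsyn_sites,
        transferred_gene_ids=transferred,
        per_gene=truth.per_gene,
        changes=truth.changes,
    )
    return genome_a, genome_b, truth


def simulate_pair(config: PairSimConfig, genome_prefix: str = "sim"
                  ) -> tuple[Genome, Genome, TruthRecord]:
    """Ancestor + divergence + transfers in one deterministic call."""
    ancestor = generate_ancestor(config.n_genes, config.gene_length_mean,
                                 seed=config.seed, genome_id=genome_prefix)
    return evolve_pair(ancestor, config)


@dataclass(frozen=True)
class PopulationSpec:
    """A multi-species population with a constructed identity gap."""

    n_species: int = 3
    genomes_per_species: int = 4
    within_identity_range: tuple[float, float] = (0.97, 0.995)
    between_identity_max: float = 0.90
    n_genes: int = 60
    gene_length_mean: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.within_identity_range
        if not (0.0 < lo < hi <= 1.0):
            raise ValueError("within_identity_range must satisfy 0 < lo < hi <= 1")
        if lo <= self.between_identity_max:
            raise ValueError(
                "no identity gap: within-range low must exceed between max")
        if self.n_species < 1 or self.genomes_per_species < 1:
            raise ValueError("need >= 1 species and >= 1 genome per species")


@dataclass
class PopulationTruth:
    """Ground truth for a simulated population."""

    labels: dict[str, str]
    pair_identity: dict[tuple[str, str], float]
    per_genome_subs: dict[str, int]

    def same_species(self, g1: str, g2: str) -> bool:
        return self.labels[g1] == self.labels[g2]


def generate_population(spec: PopulationSpec
                        ) -> tuple[list[Genome], dict[str, str], PopulationTruth]:
    """Simulate a population with an exact within/between identity gap.

    One root ancestor; each species ancestor receives ``k`` substitutions
    (so species ancestors differ at exactly ``2k`` sites); each genome
    receives its own substitutions on top.  All substitutions across the
    entire population occupy globally distinct sites, so every pairwise
    identity is an exact function of the per-branch substitution counts:
    within-species pairs land inside ``within_identity_range`` and
    between-species pairs at or below ``between_identity_max`` by
    construction.
    """
    rng = random.Random(spec.seed)
    root = generate_ancestor(spec.n_genes, spec.gene_length_mean,
                             seed=rng.randrange(2 ** 31), genome_id="root")
    L = root.total_gene_length
    lo, hi = spec.within_identity_range
    k_between = math.ceil(L * (1.0 - spec.between_identity_max) / 2.0)
    m_lo = math.ceil(L * (1.0 - hi) / 2.0)
    m_hi = math.floor(L * (1.0 - lo) / 2.0)
    if m_lo > m_hi:
        raise ValueError(
            f"within_identity_range too narrow for {L} sites: no integer "
            f"substitution count lands inside it")
    n_genomes = spec.n_species * spec.genomes_per_species
    budget = spec.n_species * k_between + n_genomes * m_hi
    if budget > L:
        raise ValueError(
            f"infeasible spec: up to {budget} distinct substituted sites "
            f"needed but only {L} sites available")

    gene_ids = [g.gene_id for g in root.genes]
    used: set[tuple[int, int]] = set()
    genomes: list[Genome] = []
    labels: dict[str, str] = {}
    branch_sites: dict[str, int] = {}
    species_sites: dict[str, int] = {}

    for si in range(spec.n_species):
        sp_id = f"sp{si:02d}"
        sp_seqs = [list(g.nt_seq) for g in root.genes]
        _mutate_distinct_sites([sp_seqs], gene_ids, k_between, 1.0, rng, used)
        species_sites[sp_id] = k_between
        for gi in range(spec.genomes_per_species):
            genome_id = f"{sp_id}_g{gi:02d}"
            m_g = rng.randint(m_lo, m_hi)
            g_seqs = [list(s) for s in sp_seqs]
            _mutate_distinct_sites([g_seqs], gene_ids, m_g, 1.0, rng, used)
            genomes.append(Genome(genome_id=genome_id, genes=[
                GeneRecord.from_nt(gid, genome_id, "".join(s))
                for gid, s in zip(gene_ids, g_seqs)]))
            labels[genome_id] = sp_id
            branch_sites[genome_id] = m_g

    pair_identity: dict[tuple[str, str], float] = {}
    ids = [g.genome_id for g in genomes]
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            g1, g2 = ids[i], ids[j]
            diffs = branch_sites[g1] + branch_sites[g2]
            if labels[g1] != labels[g2]:
                diffs += species_sites[labels[g1]] + species_sites[labels[g2]]
            pair_identity[(g1, g2)] = 1.0 - diffs / L
    truth = PopulationTruth(labels=labels, pair_identity=pair_identity,
                            per_genome_subs=branch_sites)
    return genomes, labels, truth


def write_pair_outputs(outdir: str | Path, genome_a: Genome, genome_b: Genome,
                       truth: TruthRecord, config: PairSimConfig | None = None
                       ) -> dict[str, Path]:
    """Emit the pair as two gene FASTAs plus a truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    return {
        "fasta_a": write_gene_fasta(genome_a, outdir / f"{genome_a.genome_id}.fna"),
        "fasta_b": write_gene_fasta(genome_b, outdir / f"{genome_b.genome_id}.fna"),
        "truth": truth.to_json(outdir / "truth.json", config=config),
    }


def write_population_outputs(outdir: str | Path, genomes: list[Genome],
                             labels: dict[str, str], truth: PopulationTruth
                             ) -> dict[str, Path]:
    """Emit per-genome gene FASTAs, a labels TSV and a truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for genome in genomes:
        paths[genome.genome_id] = write_gene_fasta(
            genome, outdir / f"{genome.genome_id}.fna")
    paths["labels"] = write_labels(labels, outdir / "labels.tsv")
    truth_payload = {
        "labels": truth.labels,
        "per_genome_subs": truth.per_genome_subs,
        "pair_identity": {f"{a}|{b}": v
                          for (a, b), v in truth.pair_identity.items()},
    }
    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(truth_payload, indent=1))
    paths["truth"] = truth_path
    return paths
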