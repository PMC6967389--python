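"""Single-copy marker-gene benchmarking.

A marker set is the collection of hits of one marker gene (e.g. a
ribosomal protein) across a genome universe.  The module scores each
marker on how well pairwise identities of its sequences reproduce
species labels (optimal threshold and F1 via the shared threshold-scan
engine), on its prevalence across the universe, and on its
*recoverability* from metagenomic assemblies:

    recoverability = assembled marker genes / filtered genomes

so a value above 1 means the marker captures organisms whose genomes
were not recovered by binning.

Upstream HMM searching is out of process: the module ingests per-marker
multi-FASTA (headers ``genome_id|gene_id``) or a hits table, with a thin
adapter for hmmsearch ``--tblout`` output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .delineation import PairLabelMatrix, scan_thresholds, _key
from .pairwise import global_nt_align, nt_aligner


@dataclass(frozen=True)
class MarkerHit:
    genome_id: str
    gene_id: str
    nt_seq: str


@dataclass
class MarkerSet:
    """All hits of one marker across a genome universe (0..n per genome)."""

    marker_name: str
    hits: list[MarkerHit]

    def by_genome(self) -> dict[str, list[MarkerHit]]:
        out: dict[str, list[MarkerHit]] = {}
        for h in self.hits:
            out.setdefault(h.genome_id, []).append(h)
        return out

    def carriers(self) -> list[str]:
        return sorted({h.genome_id for h in self.hits})


def read_marker_fasta(path: str | Path, marker_name: str | None = None
                      ) -> MarkerSet:
    """Read a per-marker multi-FASTA with ``genome_id|gene_id`` headers."""
    path = Path(path)
    if marker_name is None:
        marker_name = path.stem
    hits = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ValueError(
                f"marker FASTA header {rec.id!r} lacks 'genome_id|gene_id'")
        genome_id, gene_id = rec.id.split("|", 1)
        hits.append(MarkerHit(genome_id=genome_id, gene_id=gene_id,
                              nt_seq=str(rec.seq).upper()))
    return MarkerSet(marker_name=marker_name, hits=hits)


def read_hits_table(path: str | Path) -> list[MarkerSet]:
    """Read a hits TSV (genome_id, marker_name, gene_id, sequence)."""
    df = pd.read_csv(Path(path), sep="\t")
    required = {"genome_id", "marker_name", "gene_id", "sequence"}
    if not required <= set(df.columns):
        raise ValueError(f"hits table needs columns {sorted(required)}")
    out = []
    for marker_name, grp in df.groupby("marker_name", sort=True):
        out.append(MarkerSet(marker_name=str(marker_name), hits=[
            MarkerHit(genome_id=str(r.genome_id), gene_id=str(r.gene_id),
                      nt_seq=str(r.sequence).upper())
            for r in grp.itertuples(index=False)]))
    return out


def read_hmmsearch_tblout(path: str | Path) -> pd.DataFrame:
    """Adapter for hmmsearch ``--tblout`` tables: (gene_id, marker_name,
    score) rows.  Sequences must be joined in from gene FASTAs by the
    caller; this parses the search output only."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            continue
        rows.append({"gene_id": fields[0], "marker_name": fields[2],
                     "score": float(fields[5])})
    return pd.DataFrame(rows, columns=["gene_id", "marker_name", "score"])


def select_representatives(marker: MarkerSet,
                           rule: str = "longest") -> dict[str, MarkerHit]:
    """One representative hit per genome.

    ``longest``: the longest sequence, ties broken by lexicographic
    gene id (the only rule currently implemented).
    """
    if rule != "longest":
        raise ValueError(f"unknown one-per-genome rule {rule!r}")
    reps: dict[str, MarkerHit] = {}
    for genome_id, hits in marker.by_genome().items():
        reps[genome_id] = min(hits, key=lambda h: (-len(h.nt_seq), h.gene_id))
    return reps


def marker_identity_matrix(marker: MarkerSet, one_per_genome_rule: str = "longest"
                           ) -> pd.DataFrame:
    """Square percent-identity matrix over carrier genomes.

    Identities come from global nucleotide alignments of one
    representative sequence per genome; genomes lacking the marker are
    absent.  Raises ValueError with fewer than 2 carriers.
    """
    reps = select_representatives(marker, one_per_genome_rule)
    genomes = sorted(reps)
    if len(genomes) < 2:
        raise ValueError(
            f"marker {marker.marker_name}: needs >= 2 carrier genomes")
    aligner = nt_aligner()
    mat = pd.DataFrame(100.0, index=genomes, columns=genomes, dtype=float)
    for g1, g2 in itertools.combinations(genomes, 2):
        aln = global_nt_align(reps[g1].nt_seq, reps[g2].nt_seq, aligner=aligner)
        mat.loc[g1, g2] = mat.loc[g2, g1] = 100.0 * aln.identity
    return mat


def recoverability(n_assembled_genes: int, n_filtered_genomes: int) -> float:
    """Assembled marker-gene copies per binned genome from the same data.

    The number of filtered genomes defines 100% recoverability, so the
    metric is the plain quotient; values above 1 mean the marker was
    assembled more often than genomes were recovered.
    """
    if n_filtered_genomes < 1:
        raise ValueError("n_filtered_genomes must be >= 1")
    if n_assembled_genes < 0:
        raise ValueError("n_assembled_genes must be >= 0")
    return n_assembled_genes / n_filtered_genomes


@dataclass
class RecoverabilityReport:
    marker_name: str
    n_assembled_genes: int
    n_filtered_genomes: int

    @property
    def recoverability(self) -> float:
        return recoverability(self.n_assembled_genes, self.n_filtered_genomes)


def prevalence_filter(markers: Sequence[MarkerSet], genomes: Sequence[str],
                      min_fraction: float = 0.85) -> list[MarkerSet]:
    """Keep markers present in at least ``min_fraction`` of the universe
    (boundary closed: exactly 85% is retained)."""
    if not genomes:
        raise ValueError("empty genome universe")
    universe = set(genomes)
    kept = []
    for m in markers:
        carriers = {g for g in m.carriers() if g in universe}
        if len(carriers) / len(universe) >= min_fraction:
            kept.append(m)
    return kept


def presence_summary(markers: Sequence[MarkerSet], genomes: Sequence[str],
                     min_fraction: float = 0.80) -> dict[str, bool]:
    """Per-marker presence flag in a second universe (e.g. archaeal
    genomes): present iff carried by >= ``min_fraction`` of it."""
    if not genomes:
        raise ValueError("empty genome universe")
    universe = set(genomes)
    return {m.marker_name:
            len({g for g in m.carriers() if g in universe}) / len(universe)
            >= min_fraction
            for m in markers}


@dataclass
class MarkerBenchmarkRow:
    marker_name: str
    optimal_threshold: float | None
    f1: float | None
    n_genomes_with_gene_pct: float
    multiple_copy_pct: float
    flagged: bool = False
    flag_reason: str | None = None
    archaeal_presence: bool | None = None


def _restrict_labels(labels: PairLabelMatrix, genomes: list[str]
                     ) -> PairLabelMatrix:
    keep = [g for g in labels.genomes if g in set(genomes)]
    same = {_key(g1, g2): labels[(g1, g2)]
            for g1, g2 in itertools.combinations(sorted(keep), 2)}
    return PairLabelMatrix(genomes=sorted(keep), same=same,
                           source=labels.source)


def marker_benchmark(markers: Sequence[MarkerSet],
                     label_sets: PairLabelMatrix | Sequence[PairLabelMatrix],
                     genomes: Sequence[str],
                     archaeal_presence: Mapping[str, bool] | None = None,
                     lo: float = 80.0, hi: float = 100.0, step: float = 0.1
                     ) -> list[MarkerBenchmarkRow]:
    """Benchmark markers for species delineation against pair labels.

    For each marker, its identity matrix is scanned against each label
    set (restricted to carrier genomes); with several label sets (e.g.
    several genome collections) the reported threshold maximizes the
    *average* F1 across sets.  Markers with < 2 carriers or single-class
    restricted labels are flagged rather than scored.
    """
    if isinstance(label_sets, PairLabelMatrix):
        label_sets = [label_sets]
    universe = sorted(set(genomes))
    if not universe:
        raise ValueError("empty genome universe")
    rows = []
    for marker in sorted(markers, key=lambda m: m.marker_name):
        by_genome = marker.by_genome()
        carriers = [g for g in universe if g in by_genome]
        presence_pct = 100.0 * len(carriers) / len(universe)
        multi_pct = 100.0 * sum(1 for g in universe
                                if len(by_genome.get(g, [])) >= 2) / len(universe)
        row = MarkerBenchmarkRow(
            marker_name=marker.marker_name, optimal_threshold=None, f1=None,
            n_genomes_with_gene_pct=presence_pct, multiple_copy_pct=multi_pct,
            archaeal_presence=(archaeal_presence or {}).get(marker.marker_name))
        try:
            mat = marker_identity_matrix(marker)
            identities = {
                _key(str(g1), str(g2)): float(mat.loc[g1, g2])
                for g1, g2 in itertools.combinations(mat.index, 2)}
            if len(set(identities.values())) == 1:
                raise ValueError(
                    f"marker {marker.marker_name}: no identity variation "
                    f"among carriers (single-class predictions)")
            f1_sum = None
            n_steps = int(round((hi - lo) / step))
            for labels in label_sets:
                restricted = _restrict_labels(labels, list(mat.index))
                scan = scan_thresholds(identities, restricted,
                                       lo=lo, hi=hi, step=step)
                f1_sum = scan.f1 if f1_sum is None else f1_sum + scan.f1
            mean_f1 = f1_sum / len(label_sets)
            best = mean_f1.max()
            at_best = (mean_f1 == best).nonzero()[0]
            grid = scan.thresholds
            row.optimal_threshold = float(
                (grid[at_best[0]] + grid[at_best[-1]]) / 2.0)
            row.f1 = float(best)
        except ValueError as exc:
            row.flagged = True
            row.flag_reason = str(exc)
        rows.append(row)
    return rows


def benchmark_table(rows: Sequence[MarkerBenchmarkRow],
                    recoverabilities: Mapping[str, float] | None = None
                    ) -> pd.DataFrame:
    """Assemble the benchmark rows into a report table."""
    recs = recoverabilities or {}
    return pd.DataFrame([{
        "marker": r.marker_name,
        "species_ani_threshold_pct": r.optimal_threshold,
        "f1": r.f1,
        "recoverability": recs.get(r.marker_name),
        "genomes_with_gene_pct": r.n_genomes_with_gene_pct,
        "multiple_copy_pct": r.multiple_copy_pct,
        "present_in_archaea": r.archaeal_presence,
        "flagged": r.flagged,
    } for r in rows])
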