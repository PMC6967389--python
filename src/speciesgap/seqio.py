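"""Reading, writing and validation of coding sequences and tabular outputs.

A genome is represented as an ordered collection of validated in-frame
coding sequences (CDS).  Validation enforces the invariants every
downstream computation relies on: length divisible by three, plain
``{A,C,G,T}`` alphabet, and no internal in-frame stop codon.  A start
codon is *not* required (metagenome-derived gene calls are frequently
partial at contig edges).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_STANDARD = CodonTable.unambiguous_dna_by_name["Standard"]

#: sense codon -> single-letter amino acid under the standard genetic code
CODON_TO_AA: Mapping[str, str] = dict(_STANDARD.forward_table)
STOP_CODONS = frozenset(_STANDARD.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

_NT_ALPHABET = frozenset("ACGT")

#: default minimum CDS length (nt); shorter genes carry too little signal
#: for the identity/coverage filters downstream
MIN_GENE_LENGTH = 60


class CdsError(ValueError):
    """A nucleotide sequence is not a valid in-frame coding sequence."""


class EmptyGenomeError(ValueError):
    """A gene FASTA yielded no valid coding sequence."""


def translate_cds(nt_seq: str) -> str:
    """Translate an in-frame CDS under the standard genetic code.

    A single terminal stop codon is allowed and translated to nothing.
    Raises :class:`CdsError` on a bad alphabet, a length that is not a
    multiple of three, or an internal in-frame stop codon.
    """
    seq = nt_seq.upper()
    if not seq:
        raise CdsError("empty sequence")
    if len(seq) % 3 != 0:
        raise CdsError(f"length {len(seq)} is not a multiple of 3")
    bad = set(seq) - _NT_ALPHABET
    if bad:
        raise CdsError(f"non-ACGT characters {sorted(bad)} (ambiguity codes are rejected)")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    aa = []
    for idx, codon in enumerate(codons):
        if codon in STOP_CODONS:
            raise CdsError(f"internal stop codon {codon} at codon position {idx}")
        aa.append(CODON_TO_AA[codon])
    return "".join(aa)


@dataclass(frozen=True)
class GeneRecord:
    """One in-frame coding sequence tied to a genome."""

    gene_id: str
    genome_id: str
    nt_seq: str
    aa_seq: str = field(compare=False)

    @classmethod
    def from_nt(cls, gene_id: str, genome_id: str, nt_seq: str) -> "GeneRecord":
        """Build a record, validating the CDS (raises :class:`CdsError`)."""
        nt_seq = nt_seq.upper()
        return cls(gene_id=gene_id, genome_id=genome_id, nt_seq=nt_seq,
                   aa_seq=translate_cds(nt_seq))

    def __len__(self) -> int:
        return len(self.nt_seq)

    @property
    def codons(self) -> list[str]:
        return [self.nt_seq[i : i + 3] for i in range(0, len(self.nt_seq), 3)]


@dataclass
class Genome:
    """An ordered, uniquely-keyed collection of gene records."""

    genome_id: str
    genes: list[GeneRecord]

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate gene_ids in genome {self.genome_id}: {dupes}")

    @property
    def total_gene_length(self) -> int:
        return sum(len(g) for g in self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


def read_gene_fasta(path: str | Path, genome_id: str | None = None,
                    min_length: int = MIN_GENE_LENGTH) -> Genome:
    """Read a nucleotide gene FASTA into a :class:`Genome`.

    The first whitespace-delimited token of each header is the gene id;
    ``genome_id`` defaults to the filename stem.  Records failing CDS
    validation (frame, alphabet, internal stop) or shorter than
    ``min_length`` nt are dropped with a logged warning.

    Raises OSError if the file is unreadable and :class:`EmptyGenomeError`
    if no record survives validation.
    """
    path = Path(path)
    if genome_id is None:
        genome_id = path.stem
    genes: list[GeneRecord] = []
    n_dropped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        try:
            if len(seq) < min_length:
                raise CdsError(f"length {len(seq)} < minimum {min_length}")
            genes.append(GeneRecord.from_nt(rec.id, genome_id, seq))
        except CdsError as exc:
            n_dropped += 1
            logger.warning("dropping gene %s from %s: %s", rec.id, path.name, exc)
    if n_dropped:
        logger.warning("%s: dropped %d invalid record(s), kept %d", path.name,
                       n_dropped, len(genes))
    if not genes:
        raise EmptyGenomeError(f"no valid coding sequence in {path}")
    return Genome(genome_id=genome_id, genes=genes)


def write_gene_fasta(genome: Genome, path: str | Path) -> Path:
    """Write a genome's genes to a nucleotide FASTA (one record per gene)."""
    path = Path(path)
    records = [SeqRecord(Seq(g.nt_seq), id=g.gene_id, description="")
               for g in genome.genes]
    SeqIO.write(records, str(path), "fasta")
    return path


def check_protein_fasta(genome: Genome, path: str | Path) -> None:
    """Verify that a protein FASTA matches the translations of ``genome``.

    Raises ValueError on any id present in both with a differing sequence.
    """
    by_id = {g.gene_id: g.aa_seq for g in genome.genes}
    for rec in SeqIO.parse(str(Path(path)), "fasta"):
        aa = str(rec.seq).upper().rstrip("*")
        if rec.id in by_id and by_id[rec.id] != aa:
            raise ValueError(
                f"protein record {rec.id} disagrees with CDS translation")


def write_pair_table(rows: Iterable[Mapping], path: str | Path,
                     float_decimals: int = 6) -> Path:
    """Write per-pair metric rows to a TSV (header + one row per pair).

    Rows must carry ``genome1``/``genome2`` keys; each unordered pair may
    appear once (both (A,B) and (B,A) present is an error).  Floats are
    written at ``float_decimals`` decimals, tab-delimited, '.' decimal.
    """
    rows = list(rows)
    seen: set[frozenset] = set()
    for r in rows:
        key = frozenset((r["genome1"], r["genome2"]))
        if key in seen:
            raise ValueError(f"duplicate unordered pair {sorted(key)}")
        seen.add(key)
    if rows:
        df = pd.DataFrame(rows)
    else:
        df = pd.DataFrame(columns=["genome1", "genome2", "ani",
                                   "alignment_fraction", "n_genes_aligned"])
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format=f"%.{float_decimals}f")
    return path


def read_pair_table(path: str | Path) -> pd.DataFrame:
    """Read a pair-summary TSV written by :func:`write_pair_table`."""
    return pd.read_csv(Path(path), sep="\t")


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column (genome_id, species_id) TSV into a dict.

    A header row is accepted (and detected by the names ``genome_id`` /
    ``species_id``) but not required.
    """
    df = pd.read_csv(Path(path), sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("labels table needs two columns: genome_id, species_id")
    if list(df.iloc[0, :2]) == ["genome_id", "species_id"]:
        df = df.iloc[1:]
    dup = df.iloc[:, 0].duplicated()
    if dup.any():
        raise ValueError(f"duplicate genome ids in labels: {sorted(df.iloc[:, 0][dup])}")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_labels(labels: Mapping[str, str], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"genome_id": list(labels), "species_id": [labels[g] for g in labels]}
    ).to_csv(path, sep="\t", index=False)
    return path
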