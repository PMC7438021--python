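"""Genome data model and I/O.

A genome (isolate genome or metagenome-assembled genome, MAG) is represented
as a set of contigs plus an ordered list of protein-coding ORFs with 1-based
inclusive coordinates (GFF3 convention, as emitted by Prokka/Prodigal), a
taxonomy string and CheckM-style quality metrics (completeness %, redundancy %).

ORFs are ranked per contig by ascending start coordinate (``index_on_contig``,
1-based); all gene-neighborhood distances downstream are defined on this rank.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

NUCLEOTIDES = set("ACGTN")

#: metadata table columns
METADATA_COLUMNS = ["genome_id", "taxonomy", "completeness", "redundancy"]


class GenomeModelError(ValueError):
    """Malformed genome input (duplicate ids, out-of-bounds features, ...)."""


@dataclass(frozen=True)
class Contig:
    """One assembled nucleotide sequence."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Orf:
    """One protein-coding gene with 1-based inclusive coordinates."""

    id: str
    contig_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    index_on_contig: int
    protein: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GenomeModelError(f"ORF {self.id}: strand must be '+' or '-'")
        if self.start > self.end or self.start < 1:
            raise GenomeModelError(f"ORF {self.id}: invalid coordinates {self.start}-{self.end}")

    @property
    def nt_length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeRecord:
    """One genome/MAG: contigs, ordered ORFs, taxonomy, quality metrics."""

    id: str
    contigs: dict[str, Contig]
    orfs: list[Orf]
    taxonomy: str = ""
    completeness: float = 100.0
    redundancy: float = 0.0
    _orf_index: dict[str, Orf] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not (0 <= self.completeness <= 100 and 0 <= self.redundancy <= 100):
            raise GenomeModelError(
                f"genome {self.id}: completeness/redundancy must lie in [0, 100]"
            )
        for orf in self.orfs:
            contig = self.contigs.get(orf.contig_id)
            if contig is None:
                raise GenomeModelError(
                    f"genome {self.id}: ORF {orf.id} references unknown contig {orf.contig_id}"
                )
            if orf.end > contig.length:
                raise GenomeModelError(
                    f"genome {self.id}: ORF {orf.id} extends past end of contig "
                    f"{orf.contig_id} ({orf.end} > {contig.length})"
                )
        self._orf_index = {o.id: o for o in self.orfs}
        if len(self._orf_index) != len(self.orfs):
            raise GenomeModelError(f"genome {self.id}: duplicate ORF ids")

    def get_orf(self, orf_id: str) -> Orf:
        try:
            return self._orf_index[orf_id]
        except KeyError:
            raise GenomeModelError(f"genome {self.id}: no ORF {orf_id}") from None

    def orfs_on(self, contig_id: str) -> list[Orf]:
        return [o for o in self.orfs if o.contig_id == contig_id]

    @property
    def phylum(self) -> str:
        return rank_from_taxonomy(self.taxonomy, "p")

    def taxon_rank(self, prefix: str) -> str:
        return rank_from_taxonomy(self.taxonomy, prefix)


@dataclass
class GenomeCollection:
    """A keyed set of genomes."""

    genomes: dict[str, GenomeRecord] = field(default_factory=dict)

    def add(self, genome: GenomeRecord) -> None:
        if genome.id in self.genomes:
            raise GenomeModelError(f"duplicate genome id {genome.id}")
        self.genomes[genome.id] = genome

    def __iter__(self) -> Iterator[GenomeRecord]:
        return iter(self.genomes.values())

    def __len__(self) -> int:
        return len(self.genomes)

    def __getitem__(self, genome_id: str) -> GenomeRecord:
        return self.genomes[genome_id]

    def __contains__(self, genome_id: str) -> bool:
        return genome_id in self.genomes


def rank_from_taxonomy(taxonomy: str, prefix: str) -> str:
    """Extract one rank from a GTDB-style ``d__;p__;c__;...`` lineage string."""
    for token in taxonomy.split(";"):
        token = token.strip()
        if token.startswith(f"{prefix}__"):
            return token[len(prefix) + 2 :]
    return ""


def group_label(
    taxonomy: str,
    class_rank_groups: frozenset[str] = frozenset({"Deltaproteobacteria"}),
) -> str:
    """Taxonomic group of a genome: its phylum, except for groups summarized
    at class rank (by default the Deltaproteobacteria class of Proteobacteria)."""
    cls = rank_from_taxonomy(taxonomy, "c")
    if cls in class_rank_groups:
        return cls
    return rank_from_taxonomy(taxonomy, "p") or "unclassified"


def _clean_sequence(seq: str, record_id: str) -> str:
    """Uppercase a nucleotide sequence, mapping ambiguity codes other than N to N."""
    seq = seq.upper()
    if set(seq) <= NUCLEOTIDES:
        return seq
    bad = sorted(set(seq) - NUCLEOTIDES)
    logger.warning("contig %s: mapping ambiguity characters %s to N", record_id, bad)
    return "".join(c if c in NUCLEOTIDES else "N" for c in seq)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a nucleotide FASTA into (id, sequence) pairs, order preserved.

    Sequences are uppercased; IUPAC ambiguity characters other than N are
    mapped to N with a logged warning. Duplicate ids and empty files error.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise GenomeModelError(f"{path}: duplicate record id {rec.id}")
        seen.add(rec.id)
        records.append((rec.id, _clean_sequence(str(rec.seq), rec.id)))
    if not records:
        raise GenomeModelError(f"{path}: no records")
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    recs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


_BACTERIAL_TABLE = 11


def _translate_cds(contig_seq: str, start: int, end: int, strand: str) -> str:
    nt = contig_seq[start - 1 : end]
    if strand == "-":
        nt = str(Seq(nt).reverse_complement())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # partial codons at contig edges
        protein = str(Seq(nt).translate(table=_BACTERIAL_TABLE))
    return protein.rstrip("*")


def read_genome(
    fasta: str | Path,
    gff: str | Path,
    genome_id: str | None = None,
    taxonomy: str = "",
    completeness: float = 100.0,
    redundancy: float = 0.0,
    protein_fasta: str | Path | None = None,
) -> GenomeRecord:
    """Read one genome from nucleotide FASTA + Prokka-style GFF3.

    CDS features must carry an ``ID`` attribute. Protein translations are
    taken from (in order of preference) a ``translation`` attribute on the
    CDS, a companion protein FASTA keyed by ORF id, or translation of the
    CDS with the bacterial/archaeal code (table 11), trimming terminal stops.
    ORFs are sorted by (contig_id, start, end, id) and ``index_on_contig``
    assigned per contig by ascending start.
    """
    if genome_id is None:
        genome_id = Path(fasta).stem
    contigs = {cid: Contig(cid, seq) for cid, seq in read_fasta(fasta)}

    proteins: dict[str, str] = {}
    if protein_fasta is not None:
        proteins = {rec.id: str(rec.seq).rstrip("*") for rec in SeqIO.parse(str(protein_fasta), "fasta")}

    db = gffutils.create_db(
        str(gff), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    raw: list[tuple[str, int, int, str, str, str]] = []
    for feat in db.features_of_type("CDS"):
        orf_id = feat.attributes.get("ID", [feat.id])[0]
        if feat.seqid not in contigs:
            raise GenomeModelError(
                f"genome {genome_id}: CDS {orf_id} on unknown contig {feat.seqid}"
            )
        contig = contigs[feat.seqid]
        if feat.start < 1 or feat.end > contig.length:
            raise GenomeModelError(
                f"genome {genome_id}: CDS {orf_id} out of bounds on {feat.seqid} "
                f"({feat.start}-{feat.end} vs length {contig.length})"
            )
        translation = feat.attributes.get("translation", [None])[0]
        if translation is None:
            translation = proteins.get(orf_id)
        if translation is None:
            translation = _translate_cds(contig.sequence, feat.start, feat.end, feat.strand)
        if not translation:
            raise GenomeModelError(f"genome {genome_id}: CDS {orf_id} has empty translation")
        raw.append((feat.seqid, feat.start, feat.end, feat.strand, orf_id, translation))

    # rank ORFs per contig by start; ties broken by end then id (deterministic)
    raw.sort(key=lambda r: (r[0], r[1], r[2], r[4]))
    orfs: list[Orf] = []
    rank: dict[str, int] = {}
    for contig_id, start, end, strand, orf_id, translation in raw:
        rank[contig_id] = rank.get(contig_id, 0) + 1
        orfs.append(Orf(orf_id, contig_id, start, end, strand, rank[contig_id], translation))

    return GenomeRecord(
        id=genome_id, contigs=contigs, orfs=orfs, taxonomy=taxonomy,
        completeness=completeness, redundancy=redundancy,
    )


def write_genome(genome: GenomeRecord, fasta: str | Path, gff: str | Path) -> None:
    """Write a genome back to FASTA + GFF3 with embedded translations."""
    write_fasta(fasta, [(c.id, c.sequence) for c in genome.contigs.values()])
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig in genome.contigs.values():
            fh.write(f"##sequence-region {contig.id} 1 {contig.length}\n")
        for orf in genome.orfs:
            attrs = f"ID={orf.id};translation={orf.protein}"
            fh.write(
                f"{orf.contig_id}\thgcscan\tCDS\t{orf.start}\t{orf.end}\t.\t"
                f"{orf.strand}\t0\t{attrs}\n"
            )


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the genome metadata table (genome_id, taxonomy, completeness, redundancy)."""
    meta = pd.read_csv(path, sep="\t")
    missing = set(METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise GenomeModelError(f"{path}: metadata table missing columns {sorted(missing)}")
    if meta["genome_id"].duplicated().any():
        dup = meta.loc[meta["genome_id"].duplicated(), "genome_id"].iloc[0]
        raise GenomeModelError(f"{path}: duplicate genome id {dup}")
    return meta


def write_metadata(path: str | Path, meta: pd.DataFrame) -> None:
    meta.to_csv(path, sep="\t", index=False, columns=METADATA_COLUMNS)


def read_collection(genome_dir: str | Path, metadata: str | Path | pd.DataFrame) -> GenomeCollection:
    """Read every genome named in a metadata table from ``<dir>/<id>.fna`` + ``<dir>/<id>.gff``."""
    genome_dir = Path(genome_dir)
    meta = metadata if isinstance(metadata, pd.DataFrame) else read_metadata(metadata)
    collection = GenomeCollection()
    for row in meta.itertuples(index=False):
        genome = read_genome(
            genome_dir / f"{row.genome_id}.fna",
            genome_dir / f"{row.genome_id}.gff",
            genome_id=row.genome_id,
            taxonomy=row.taxonomy,
            completeness=float(row.completeness),
            redundancy=float(row.redundancy),
        )
        collection.add(genome)
    return collection


def filter_by_quality(
    collection: GenomeCollection,
    min_completeness: float = 50.0,
    max_redundancy: float = 10.0,
) -> GenomeCollection:
    """Retain genomes with completeness > min AND redundancy < max (strict, MIMAG-style).

    Non-destructive: returns a new collection sharing the genome records.
    """
    kept = GenomeCollection()
    for genome in collection:
        if genome.completeness > min_completeness and genome.redundancy < max_redundancy:
            kept.genomes[genome.id] = genome
    logger.info(
        "quality filter (>%s%% complete, <%s%% redundant): kept %d of %d genomes",
        min_completeness, max_redundancy, len(kept), len(collection),
    )
    return kept
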