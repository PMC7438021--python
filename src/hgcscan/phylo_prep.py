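"""Concatenated-marker supermatrix preparation for phylogenetics.

Assembles per-marker amino-acid alignments (e.g. the rp16 set of 16 ribosomal
proteins, or HgcA+HgcB for the protein tree) into a partitioned supermatrix:
genomes must carry at least 12 of the 16 ribosomal markers to be included;
genomes missing a marker receive all-gap blocks; columns are masked by a gap-
fraction threshold (default 0.5) with a minimum kept-block size (default 5).

Alignment itself (MAFFT/MUSCLE) and tree inference (RAxML/FastTree) are
external; this module only implements the completeness, concatenation and
masking contracts and writes aligned FASTA plus a partition file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Default ribosomal marker names for the rp16 concatenated species tree.
#: Configurable; this particular selection of large/small-subunit ribosomal
#: proteins is conventional for concatenated prokaryotic phylogenies but is
#: not canonical — supply your own list to match an existing marker database.
RP16_MARKERS = (
    "rpL2", "rpL3", "rpL4", "rpL5", "rpL6", "rpL14", "rpL15", "rpL16",
    "rpL18", "rpL22", "rpL24", "rpS3", "rpS8", "rpS10", "rpS17", "rpS19",
)


class SupermatrixError(ValueError):
    """Inconsistent alignment inputs or empty result."""


@dataclass
class MarkerAlignment:
    """One per-marker alignment: genome id -> aligned amino-acid row."""

    marker: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        widths = {len(r) for r in self.rows.values()}
        if len(widths) > 1:
            raise SupermatrixError(f"alignment {self.marker}: unequal row widths {sorted(widths)}")

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0


@dataclass
class Supermatrix:
    """Concatenated alignment with a 1-based inclusive partition table."""

    rows: dict[str, str]
    partitions: list[tuple[str, int, int]]  # (marker, start col, end col)

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0


def filter_marker_completeness(
    per_genome_markers: Mapping[str, Iterable[str]],
    min_markers: int = 12,
) -> set[str]:
    """Genomes carrying at least ``min_markers`` of the marker set (default 12 of 16)."""
    return {g for g, markers in per_genome_markers.items() if len(set(markers)) >= min_markers}


def concatenate(alignments: Sequence[MarkerAlignment], genomes: Iterable[str]) -> Supermatrix:
    """Concatenate marker alignments over a genome set, gap-filling missing markers."""
    genomes = sorted(set(genomes))
    if not alignments:
        raise SupermatrixError("no alignments to concatenate")
    for g in genomes:
        if not any(g in a.rows for a in alignments):
            raise SupermatrixError(f"genome {g} present in no alignment")
    rows = {g: [] for g in genomes}
    partitions: list[tuple[str, int, int]] = []
    col = 1
    for aln in alignments:
        width = aln.width
        if width == 0:
            raise SupermatrixError(f"alignment {aln.marker} is empty")
        for g in genomes:
            rows[g].append(aln.rows.get(g, "-" * width))
        partitions.append((aln.marker, col, col + width - 1))
        col += width
    return Supermatrix({g: "".join(parts) for g, parts in rows.items()}, partitions)


def mask_columns(
    matrix: Supermatrix,
    max_gap_fraction: float = 0.5,
    min_block_size: int = 5,
) -> Supermatrix:
    """Drop columns whose gap fraction exceeds the threshold, then kept runs
    shorter than the minimum block size; partitions are remapped.

    This is a deliberately simple mask (gap fraction + block size) with
    defaults 0.5/5; externally masked alignments can be supplied instead when
    entropy-based trimming is wanted.
    """
    if not 0 <= max_gap_fraction <= 1:
        raise SupermatrixError("max_gap_fraction must lie in [0, 1]")
    genomes = list(matrix.rows)
    n = len(genomes)
    width = matrix.width
    keep = []
    for j in range(width):
        gaps = sum(matrix.rows[g][j] == "-" for g in genomes)
        keep.append(gaps / n <= max_gap_fraction)
    # drop kept runs shorter than the block size
    j = 0
    while j < width:
        if keep[j]:
            k = j
            while k < width and keep[k]:
                k += 1
            if k - j < min_block_size:
                for t in range(j, k):
                    keep[t] = False
            j = k
        else:
            j += 1
    kept_cols = [j for j in range(width) if keep[j]]
    if not kept_cols:
        raise SupermatrixError("empty matrix after masking")
    new_rows = {g: "".join(matrix.rows[g][j] for j in kept_cols) for g in genomes}
    # remap partitions to the surviving columns
    new_partitions: list[tuple[str, int, int]] = []
    pos = 0
    for marker, start, end in matrix.partitions:
        n_kept = sum(1 for j in kept_cols if start - 1 <= j <= end - 1)
        if n_kept:
            new_partitions.append((marker, pos + 1, pos + n_kept))
            pos += n_kept
    logger.info(
        "masking (gap fraction > %s dropped, blocks < %d dropped): %d -> %d columns",
        max_gap_fraction, min_block_size, width, len(kept_cols),
    )
    return Supermatrix(new_rows, new_partitions)


def read_alignment_fasta(path: str | Path, marker: str | None = None) -> MarkerAlignment:
    rows = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not rows:
        raise SupermatrixError(f"{path}: no records")
    return MarkerAlignment(marker or Path(path).stem, rows)


def write_supermatrix_fasta(path: str | Path, matrix: Supermatrix) -> None:
    with open(path, "w") as fh:
        for genome in sorted(matrix.rows):
            fh.write(f">{genome}\n{matrix.rows[genome]}\n")


def write_partition_file(path: str | Path, matrix: Supermatrix) -> None:
    """Write ``marker = start-end`` lines usable by common tree-inference tools."""
    with open(path, "w") as fh:
        for marker, start, end in matrix.partitions:
            fh.write(f"{marker} = {start}-{end}\n")
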