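"""Mismatch-tolerant in-silico PCR with IUPAC-degenerate primers.

Scans genome contigs for primer-pair binding sites: a forward-primer match on
one strand and the reverse primer binding the opposite strand downstream
(i.e. its reverse complement on the same strand), with per-primer mismatch
counts up to a configured maximum and a product-length cap. Both template
orientations are scanned; coordinates are always reported on the plus strand.

A template N (assembly gap / unknown base) matches only a primer N — this is
conservative and avoids calling amplification across gaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_model import Contig, GenomeCollection, group_label
from .motif_synteny import MethylatorCall

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_BASES = "ACGTN"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


class PcrError(ValueError):
    """Invalid primer or scan parameters."""


@dataclass(frozen=True)
class Primer:
    """A named IUPAC-degenerate primer, written 5'->3'."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise PcrError(f"primer {self.name}: empty sequence")
        bad = set(self.sequence.upper()) - set(IUPAC)
        if bad:
            raise PcrError(f"primer {self.name}: invalid IUPAC characters {sorted(bad)}")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AmpliconHit:
    """One predicted PCR product (all coordinates 1-based inclusive, plus strand)."""

    genome_id: str
    contig_id: str
    fwd_start: int
    fwd_end: int
    rev_start: int
    rev_end: int
    product_length: int
    fwd_mismatches: int
    rev_mismatches: int
    orientation: str  # 'plus': fwd primer on + strand; 'minus': fwd primer on - strand


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_match(primer_char: str, base: str) -> bool:
    """True iff the template base satisfies the degenerate primer character.

    Template N matches only primer N.
    """
    try:
        expansion = IUPAC[primer_char]
    except KeyError:
        raise PcrError(f"invalid IUPAC code {primer_char!r}") from None
    if base == "N":
        return primer_char == "N"
    if base not in "ACGT":
        raise PcrError(f"invalid template base {base!r}")
    return base in expansion


def count_mismatches(primer: Primer, window: str) -> int:
    """Positions of the window failing the primer's degenerate match."""
    if len(window) != len(primer):
        raise PcrError(
            f"window length {len(window)} != primer length {len(primer)}"
        )
    return sum(not iupac_match(p, b) for p, b in zip(primer.sequence, window))


def _match_table(primer_seq: str) -> np.ndarray:
    """(primer_len, 5) boolean table: does primer position k accept base b."""
    table = np.zeros((len(primer_seq), len(_BASES)), dtype=bool)
    for k, p in enumerate(primer_seq):
        for b in IUPAC[p]:
            table[k, _BASE_INDEX[b]] = True
        if p == "N":
            table[k, _BASE_INDEX["N"]] = True  # template N matches only primer N
    return table


def _encode(seq: str) -> np.ndarray:
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lookup = np.full(128, _BASE_INDEX["N"], dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        lookup[ord(b)] = i
    return lookup[codes]


def _mismatch_profile(seq_codes: np.ndarray, primer_seq: str) -> np.ndarray:
    """Mismatch count of the primer at every plus-strand start (0-based)."""
    m, n = len(primer_seq), len(seq_codes)
    if n < m:
        return np.zeros(0, dtype=np.int32)
    table = _match_table(primer_seq)
    counts = np.zeros(n - m + 1, dtype=np.int32)
    for k in range(m):
        counts += ~table[k][seq_codes[k : n - m + 1 + k]]
    return counts


def scan_amplicons(
    contig: Contig,
    fwd: Primer,
    rev: Primer,
    max_mismatches: int = 2,
    max_product: int = 10_000,
    genome_id: str = "",
    require_3prime_match: bool = False,
) -> list[AmpliconHit]:
    """All predicted products of a primer pair on one contig.

    A product requires a forward-primer site and, downstream on the same
    strand, the reverse complement of the reverse primer, each with at most
    ``max_mismatches`` mismatches, spanning at most ``max_product`` bp. Both
    orientations are scanned; overlapping/nested products are all reported.
    ``require_3prime_match`` additionally forces each primer's 3'-terminal
    base to match exactly.
    """
    if max_mismatches < 0:
        raise PcrError("max_mismatches must be >= 0")
    if max_product <= len(fwd) + len(rev):
        raise PcrError("max_product must exceed the summed primer lengths")

    seq_codes = _encode(contig.sequence)
    hits: list[AmpliconHit] = []

    # orientation 'plus': fwd on + strand, revcomp(rev) downstream
    # orientation 'minus': rev on + strand, revcomp(fwd) downstream
    layouts = (
        ("plus", fwd.sequence, reverse_complement(rev.sequence), True),
        ("minus", rev.sequence, reverse_complement(fwd.sequence), False),
    )
    for orientation, left_seq, right_seq, left_is_fwd in layouts:
        left_mm = _mismatch_profile(seq_codes, left_seq)
        right_mm = _mismatch_profile(seq_codes, right_seq)
        left_pos = np.nonzero(left_mm <= max_mismatches)[0]
        right_pos = np.nonzero(right_mm <= max_mismatches)[0]
        if left_pos.size == 0 or right_pos.size == 0:
            continue
        for i in left_pos:
            j_min = i + len(left_seq)  # primers must not overlap
            j_max = i + max_product - len(right_seq)  # inclusive start bound
            lo = np.searchsorted(right_pos, j_min, side="left")
            hi = np.searchsorted(right_pos, j_max, side="right")
            for j in right_pos[lo:hi]:
                left_span = (int(i) + 1, int(i) + len(left_seq))
                right_span = (int(j) + 1, int(j) + len(right_seq))
                if left_is_fwd:
                    f_span, r_span = left_span, right_span
                    f_mm, r_mm = int(left_mm[i]), int(right_mm[j])
                else:
                    f_span, r_span = right_span, left_span
                    f_mm, r_mm = int(right_mm[j]), int(left_mm[i])
                if require_3prime_match:
                    if not _three_prime_ok(contig.sequence, fwd, f_span, orientation == "plus"):
                        continue
                    if not _three_prime_ok(contig.sequence, rev, r_span, orientation != "plus"):
                        continue
                hits.append(
                    AmpliconHit(
                        genome_id=genome_id,
                        contig_id=contig.id,
                        fwd_start=f_span[0], fwd_end=f_span[1],
                        rev_start=r_span[0], rev_end=r_span[1],
                        product_length=right_span[1] - left_span[0] + 1,
                        fwd_mismatches=f_mm, rev_mismatches=r_mm,
                        orientation=orientation,
                    )
                )
    hits.sort(key=lambda h: (h.contig_id, min(h.fwd_start, h.rev_start), h.orientation))
    return hits


def _three_prime_ok(sequence: str, primer: Primer, span: tuple[int, int], plus: bool) -> bool:
    """Exact match of the primer's 3'-terminal base within its matched span."""
    start, end = span
    window = sequence[start - 1 : end]
    if plus:
        return iupac_match(primer.sequence[-1], window[-1])
    return iupac_match(primer.sequence[-1], reverse_complement(window)[-1])


def scan_collection(
    collection: GenomeCollection,
    fwd: Primer,
    rev: Primer,
    max_mismatches: int = 2,
    max_product: int = 10_000,
    require_3prime_match: bool = False,
) -> list[AmpliconHit]:
    hits: list[AmpliconHit] = []
    for genome in collection:
        for contig in genome.contigs.values():
            hits.extend(
                scan_amplicons(
                    contig, fwd, rev, max_mismatches, max_product,
                    genome_id=genome.id, require_3prime_match=require_3prime_match,
                )
            )
    return hits


def crosstab_amplification(
    hits_by_setting: Mapping[int, Sequence[AmpliconHit]],
    collection: GenomeCollection,
    calls: Sequence[MethylatorCall],
) -> pd.DataFrame:
    """Per-phylum amplification summary across mismatch settings.

    For each phylum present in the collection: the number of hgcA+ genomes
    (from the methylator calls), the number of genomes amplified at each
    mismatch setting, and the number whose amplified span overlaps a called
    hgcA ORF (on-target by coordinate overlap).
    """
    phylum_of = {g.id: group_label(g.taxonomy) for g in collection}
    calls_by_genome: dict[str, list[MethylatorCall]] = {}
    for call in calls:
        calls_by_genome.setdefault(call.genome_id, []).append(call)

    phyla = sorted(set(phylum_of.values()))
    rows = []
    for phylum in phyla:
        members = [g for g in collection if phylum_of[g.id] == phylum]
        row: dict[str, object] = {
            "phylum": phylum,
            "n_genomes": len(members),
            "n_hgcA_genomes": sum(g.id in calls_by_genome for g in members),
        }
        for setting in sorted(hits_by_setting):
            hits = [h for h in hits_by_setting[setting] if phylum_of.get(h.genome_id) == phylum]
            amplified = {h.genome_id for h in hits}
            on_target = set()
            for h in hits:
                genome = collection[h.genome_id]
                span_lo = min(h.fwd_start, h.rev_start)
                span_hi = max(h.fwd_end, h.rev_end)
                for call in calls_by_genome.get(h.genome_id, []):
                    orf = genome.get_orf(call.hgcA_orf)
                    if orf.contig_id == h.contig_id and orf.start <= span_hi and orf.end >= span_lo:
                        on_target.add(h.genome_id)
                        break
            row[f"n_amplified_mm{setting}"] = len(amplified)
            row[f"n_on_target_mm{setting}"] = len(on_target)
        rows.append(row)
    return pd.DataFrame(rows)


PRIMER_CONFIG_COLUMNS = ["name", "fwd_seq", "rev_seq", "target_group"]


def read_primer_config(path: str | Path) -> pd.DataFrame:
    """Read the primer-pair config table (name, fwd_seq, rev_seq, target_group)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(PRIMER_CONFIG_COLUMNS) - set(df.columns)
    if missing:
        raise PcrError(f"{path}: primer config missing columns {sorted(missing)}")
    return df


def write_amplicon_table(path: str | Path, hits: Sequence[AmpliconHit]) -> None:
    pd.DataFrame([vars(h) for h in hits]).to_csv(path, sep="\t", index=False)


def write_amplicon_bed(path: str | Path, hits: Sequence[AmpliconHit]) -> None:
    """Amplicon spans as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for h in hits:
            lo = min(h.fwd_start, h.rev_start) - 1
            hi = max(h.fwd_end, h.rev_end)
            strand = "+" if h.orientation == "plus" else "-"
            fh.write(f"{h.contig_id}\t{lo}\t{hi}\t{h.genome_id}\t.\t{strand}\n")
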