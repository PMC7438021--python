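"""Conserved-motif validation and gene-neighborhood (synteny) rules.

A genome is called a putative mercury methylator when it carries an hgcA hit
that passes the score/E-value rule AND contains the conserved cap-helix domain
G(I/V)NVWCAAGK. A confident hgcB partner must pass its score rule, contain the
ferredoxin-binding motif CXXCXXXC, sit on the same contig as hgcA, and lie
within five ORFs downstream of hgcA in hgcA's transcriptional direction. A
putative ArsR-like transcriptional regulator may sit immediately upstream of
the hgcAB locus or one to two genes further upstream.

Distances are strand-relative ORF-rank differences: intervening genes are
allowed (some experimentally verified methylators have genes between hgcA and
hgcB), and reversing a contig leaves all distances invariant.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genome_model import GenomeCollection, GenomeRecord, Orf
from .marker_search import DEFAULT_RULES, MarkerHit, ThresholdRule, filter_hits

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class MotifError(ValueError):
    """Malformed motif pattern."""


@dataclass(frozen=True)
class Motif:
    """Degenerate protein motif: residues, X (any), and alternation ``(I/V)``.

    Every expansion has the same fixed length (one residue per element).
    """

    pattern: str

    def elements(self) -> list[str]:
        """Split the pattern into per-position residue sets."""
        out: list[str] = []
        i, pat = 0, self.pattern
        while i < len(pat):
            c = pat[i]
            if c == "(":
                j = pat.find(")", i)
                if j < 0:
                    raise MotifError(f"{pat}: unclosed '('")
                choices = pat[i + 1 : j].split("/")
                if not choices or any(len(x) != 1 or x not in AMINO_ACIDS for x in choices):
                    raise MotifError(f"{pat}: bad alternation '{pat[i:j+1]}'")
                out.append("".join(choices))
                i = j + 1
            elif c == "X":
                out.append(AMINO_ACIDS)
                i += 1
            elif c in AMINO_ACIDS:
                out.append(c)
                i += 1
            else:
                raise MotifError(f"{pat}: invalid character {c!r}")
        if not out:
            raise MotifError("empty motif")
        return out

    def __len__(self) -> int:
        return len(self.elements())

    def n_expansions(self) -> int:
        n = 1
        for el in self.elements():
            n *= len(el)
        return n

    def expansions(self) -> Iterable[str]:
        """All fixed-length words the motif matches (may be large for many X)."""
        for word in itertools.product(*self.elements()):
            yield "".join(word)

    def to_regex(self) -> re.Pattern[str]:
        parts = []
        for el in self.elements():
            parts.append("." if el == AMINO_ACIDS else (el if len(el) == 1 else f"[{el}]"))
        return re.compile("".join(parts))


#: Conserved HgcA cap-helix domain.
CAP_HELIX = Motif("G(I/V)NVWCAAGK")
#: Conserved HgcB 2[4Fe-4S] ferredoxin-binding motif.
FERREDOXIN = Motif("CXXCXXXC")


def match_motif(protein: str, motif: Motif) -> list[int]:
    """1-based start positions of all (possibly overlapping) motif matches."""
    if not protein:
        raise MotifError("empty protein")
    rx = motif.to_regex()
    # lookahead so overlapping occurrences are all reported
    overlap = re.compile(f"(?=({rx.pattern}))")
    return [m.start() + 1 for m in overlap.finditer(protein)]


def validate_hgcA(protein: str, motif: Motif = CAP_HELIX) -> bool:
    """True iff the cap-helix domain occurs at least once."""
    return bool(match_motif(protein, motif))


def validate_hgcB(protein: str, motif: Motif = FERREDOXIN) -> bool:
    """True iff the ferredoxin-binding motif occurs at least once."""
    return bool(match_motif(protein, motif))


def downstream_distance(genome: GenomeRecord, a: Orf, b: Orf) -> int | None:
    """ORF-rank distance from a to b in a's transcriptional downstream direction.

    None if on different contigs. Positive when b lies downstream of a
    (relative to a's strand); callers treat non-positive values as
    "not downstream".
    """
    for orf in (a, b):
        if orf.id not in genome._orf_index:
            raise ValueError(f"ORF {orf.id} not in genome {genome.id}")
    if a.contig_id != b.contig_id:
        return None
    diff = b.index_on_contig - a.index_on_contig
    return diff if a.strand == "+" else -diff


def upstream_distance(genome: GenomeRecord, a: Orf, b: Orf) -> int | None:
    """Strand-relative rank distance, positive when b lies upstream of a."""
    d = downstream_distance(genome, a, b)
    return None if d is None else -d


def _pick_candidate(
    genome: GenomeRecord,
    hgcA: Orf,
    hits: Sequence[MarkerHit],
    distance_fn,
    max_distance: int,
    require_same_strand: bool = False,
) -> tuple[str | None, int | None]:
    """Nearest candidate within [1, max_distance]; ties by score then orf id."""
    candidates: list[tuple[int, float, str]] = []
    for hit in hits:
        if hit.genome_id != genome.id or hit.orf_id not in genome._orf_index:
            continue
        orf = genome.get_orf(hit.orf_id)
        if require_same_strand and orf.strand != hgcA.strand:
            continue
        d = distance_fn(genome, hgcA, orf)
        if d is not None and 1 <= d <= max_distance:
            candidates.append((d, -hit.score, hit.orf_id))
    if not candidates:
        return None, None
    d, _, orf_id = min(candidates)
    return orf_id, d


def pair_hgcB(
    genome: GenomeRecord,
    hgcA: Orf,
    hgcB_hits: Sequence[MarkerHit],
    max_orfs_downstream: int = 5,
    require_same_strand: bool = False,
) -> tuple[str | None, int | None]:
    """Confident hgcB partner: same contig, within 5 ORFs downstream of hgcA.

    ``hgcB_hits`` must already be threshold- and motif-filtered. Returns the
    nearest candidate (ties: highest score, then lexicographic ORF id).
    """
    return _pick_candidate(
        genome, hgcA, hgcB_hits, downstream_distance, max_orfs_downstream,
        require_same_strand,
    )


def find_regulator(
    genome: GenomeRecord,
    hgcA: Orf,
    reg_hits: Sequence[MarkerHit],
    max_genes_upstream: int = 3,
) -> tuple[str | None, int | None]:
    """Putative regulator immediately upstream of hgcAB or 1-2 genes upstream.

    Upstream rank distance 1 is the adjacent gene; the default window of 3
    admits up to two intervening genes. ``reg_hits`` must be pre-filtered.
    """
    return _pick_candidate(genome, hgcA, reg_hits, upstream_distance, max_genes_upstream)


@dataclass(frozen=True)
class MethylatorCall:
    """Per-genome verdict for one validated hgcA locus."""

    genome_id: str
    hgcA_orf: str
    hgcA_motif_ok: bool
    hgcB_orf: str | None = None
    hgcB_distance: int | None = None
    hgcB_same_contig: bool = False
    regulator_orf: str | None = None
    regulator_distance: int | None = None


def call_methylators(
    collection: GenomeCollection,
    hits_by_marker: Mapping[str, Sequence[MarkerHit]],
    rules: Mapping[str, ThresholdRule] = DEFAULT_RULES,
    max_orfs_downstream: int = 5,
    max_genes_upstream: int = 3,
    require_same_strand: bool = False,
) -> list[MethylatorCall]:
    """Emit one call per genome per validated hgcA ORF.

    hgcA hits must pass the score/E-value rule AND carry the cap-helix domain;
    genomes with no validated hgcA are absent from the output. hgcB and
    regulator evidence is attached per the synteny rules.
    """
    hgcA_pass = filter_hits(list(hits_by_marker.get("hgcA", [])), rules["hgcA"])
    hgcB_pass = filter_hits(list(hits_by_marker.get("hgcB", [])), rules["hgcB"])
    reg_pass = filter_hits(list(hits_by_marker.get("regulator", [])), rules["regulator"])

    calls: list[MethylatorCall] = []
    for genome in collection:
        gid = genome.id
        my_hgcA = [h for h in hgcA_pass if h.genome_id == gid and h.orf_id in genome._orf_index]
        # motif-validate hgcB candidates once per genome
        my_hgcB = [
            h for h in hgcB_pass
            if h.genome_id == gid
            and h.orf_id in genome._orf_index
            and validate_hgcB(genome.get_orf(h.orf_id).protein)
        ]
        my_reg = [h for h in reg_pass if h.genome_id == gid and h.orf_id in genome._orf_index]
        for hit in sorted(my_hgcA, key=lambda h: h.orf_id):
            hgcA_orf = genome.get_orf(hit.orf_id)
            if not validate_hgcA(hgcA_orf.protein):
                logger.info("%s/%s: hgcA hit lacks the cap-helix domain, removed", gid, hit.orf_id)
                continue
            hgcB_orf, hgcB_dist = pair_hgcB(
                genome, hgcA_orf, my_hgcB, max_orfs_downstream, require_same_strand
            )
            reg_orf, reg_dist = find_regulator(genome, hgcA_orf, my_reg, max_genes_upstream)
            calls.append(
                MethylatorCall(
                    genome_id=gid,
                    hgcA_orf=hgcA_orf.id,
                    hgcA_motif_ok=True,
                    hgcB_orf=hgcB_orf,
                    hgcB_distance=hgcB_dist,
                    hgcB_same_contig=hgcB_orf is not None,
                    regulator_orf=reg_orf,
                    regulator_distance=reg_dist,
                )
            )
    logger.info(
        "called %d putative methylator loci in %d genomes (%d with confident hgcB, %d with regulator)",
        len(calls), len({c.genome_id for c in calls}),
        sum(c.hgcB_orf is not None for c in calls),
        sum(c.regulator_orf is not None for c in calls),
    )
    return calls


CALL_COLUMNS = [
    "genome_id", "hgcA_orf", "hgcA_motif_ok", "hgcB_orf", "hgcB_distance",
    "hgcB_same_contig", "regulator_orf", "regulator_distance",
]


def calls_to_frame(calls: Sequence[MethylatorCall]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in calls], columns=CALL_COLUMNS)


def write_calls(path: str | Path, calls: Sequence[MethylatorCall]) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> list[MethylatorCall]:
    df = pd.read_csv(path, sep="\t")

    def _opt(v):
        return None if pd.isna(v) else v

    return [
        MethylatorCall(
            genome_id=str(r.genome_id),
            hgcA_orf=str(r.hgcA_orf),
            hgcA_motif_ok=bool(r.hgcA_motif_ok),
            hgcB_orf=_opt(r.hgcB_orf),
            hgcB_distance=None if pd.isna(r.hgcB_distance) else int(r.hgcB_distance),
            hgcB_same_contig=bool(r.hgcB_same_contig),
            regulator_orf=_opt(r.regulator_orf),
            regulator_distance=None if pd.isna(r.regulator_distance) else int(r.regulator_distance),
        )
        for r in df.itertuples(index=False)
    ]


def extract_neighborhood(
    genome: GenomeRecord, center: Orf, window: int
) -> list[tuple[str, int, int, str, str]]:
    """ORFs within ``window`` rank positions of ``center`` on its contig.

    Returned in coordinate order as (orf_id, start, end, strand, contig_id)
    tuples, truncated at contig edges.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    neighbors = [
        o for o in genome.orfs_on(center.contig_id)
        if abs(o.index_on_contig - center.index_on_contig) <= window
    ]
    neighbors.sort(key=lambda o: o.start)
    return [(o.id, o.start, o.end, o.strand, o.contig_id) for o in neighbors]


def write_neighborhood_bed(
    path: str | Path, rows: Sequence[tuple[str, int, int, str, str]]
) -> None:
    """Write a neighborhood as a BED-like table (0-based half-open starts)."""
    with open(path, "w") as fh:
        for orf_id, start, end, strand, contig_id in rows:
            fh.write(f"{contig_id}\t{start - 1}\t{end}\t{orf_id}\t.\t{strand}\n")
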