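"""Profile-search hit tables: parsing, score/E-value filtering, and a naive scorer.

Profile HMM searches (hmmsearch against HgcA/HgcB/regulator/ribosomal/metabolic
profiles) run upstream of this package; their tabular output is the input here.
Hits are filtered by marker-specific rules: for hgcA a joint E-value <= 1e-50
and bit score >= 300 cutoff, for hgcB an exclusive bit score > 70 cutoff, and
for the putative upstream regulator E-value <= 1e-10.

``naive_profile_score`` is a dependency-free position-specific scorer (best
ungapped placement of a per-column log-odds table) used as an in-repo stand-in
for external profile searches in offline tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

HIT_TABLE_COLUMNS = ["genome_id", "orf_id", "marker", "evalue", "score"]


class HitTableError(ValueError):
    """Malformed hit-table input."""


@dataclass(frozen=True)
class MarkerHit:
    """One profile-search hit (full-sequence E-value and bit score)."""

    genome_id: str
    orf_id: str
    marker: str
    evalue: float
    score: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise HitTableError(f"hit {self.orf_id}/{self.marker}: negative E-value")


@dataclass(frozen=True)
class ThresholdRule:
    """Score/E-value acceptance rule for one marker.

    ``min_score_exclusive`` selects strict score comparison (score > min_score),
    used for the hgcB "greater than 70" rule; the default is inclusive.
    """

    marker: str
    max_evalue: float | None = None
    min_score: float | None = None
    min_score_exclusive: bool = False

    def __post_init__(self) -> None:
        if self.max_evalue is None and self.min_score is None:
            raise HitTableError(f"rule for {self.marker}: no threshold set")

    def accepts(self, hit: MarkerHit) -> bool:
        if self.max_evalue is not None and not hit.evalue <= self.max_evalue:
            return False
        if self.min_score is not None:
            if self.min_score_exclusive:
                return hit.score > self.min_score
            return hit.score >= self.min_score
        return True


#: Default per-marker rules.
DEFAULT_RULES: dict[str, ThresholdRule] = {
    "hgcA": ThresholdRule("hgcA", max_evalue=1e-50, min_score=300.0),
    "hgcB": ThresholdRule("hgcB", min_score=70.0, min_score_exclusive=True),
    "regulator": ThresholdRule("regulator", max_evalue=1e-10),
}


def _dedup_best(hits: Iterable[MarkerHit]) -> list[MarkerHit]:
    """Collapse duplicate (genome, orf, marker) rows, keeping the best score."""
    best: dict[tuple[str, str, str], MarkerHit] = {}
    order: list[tuple[str, str, str]] = []
    for hit in hits:
        key = (hit.genome_id, hit.orf_id, hit.marker)
        if key not in best:
            best[key] = hit
            order.append(key)
        elif hit.score > best[key].score:
            best[key] = hit
    return [best[k] for k in order]


def parse_hit_table(
    path: str | Path,
    marker: str | None = None,
    genome_id: str | None = None,
) -> list[MarkerHit]:
    """Parse hmmsearch ``--tblout`` output into MarkerHits.

    Columns used: target name (ORF id, col 1), query name (marker, col 3),
    full-sequence E-value (col 5) and full-sequence bit score (col 6).
    ``marker`` overrides the query name; ``genome_id`` sets the genome for all
    rows (default: the ORF id's prefix before its last underscore, the Prokka
    locus-tag convention). Duplicate (orf, marker) rows keep the best score.
    """
    hits: list[MarkerHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise HitTableError(f"{path}:{lineno}: expected >=6 fields, got {len(fields)}")
            orf_id, query = fields[0], fields[2]
            try:
                evalue, score = float(fields[4]), float(fields[5])
            except ValueError as exc:
                raise HitTableError(f"{path}:{lineno}: malformed numeric field ({exc})") from None
            gid = genome_id if genome_id is not None else orf_id.rsplit("_", 1)[0]
            hits.append(MarkerHit(gid, orf_id, marker or query, evalue, score))
    return _dedup_best(hits)


def read_hit_table(path: str | Path) -> list[MarkerHit]:
    """Read the package's own delimited hit-table dialect (with header)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(HIT_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise HitTableError(f"{path}: missing columns {sorted(missing)}")
    hits = [
        MarkerHit(str(r.genome_id), str(r.orf_id), str(r.marker), float(r.evalue), float(r.score))
        for r in df.itertuples(index=False)
    ]
    return _dedup_best(hits)


def write_hit_table(path: str | Path, hits: Sequence[MarkerHit]) -> None:
    df = pd.DataFrame(
        [(h.genome_id, h.orf_id, h.marker, h.evalue, h.score) for h in hits],
        columns=HIT_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def filter_hits(hits: Sequence[MarkerHit], rule: ThresholdRule) -> list[MarkerHit]:
    """Retain hits passing the rule, order preserved.

    Monotone (tightening thresholds never adds hits) and idempotent.
    """
    kept = [h for h in hits if rule.accepts(h)]
    if len(kept) != len(hits):
        logger.info(
            "marker %s: %d of %d hits pass (max_evalue=%s, min_score=%s%s)",
            rule.marker, len(kept), len(hits), rule.max_evalue, rule.min_score,
            " exclusive" if rule.min_score_exclusive else "",
        )
    return kept


def hits_by_genome(hits: Iterable[MarkerHit]) -> dict[str, list[MarkerHit]]:
    out: dict[str, list[MarkerHit]] = {}
    for hit in hits:
        out.setdefault(hit.genome_id, []).append(hit)
    return out


def naive_profile_score(protein: str, profile: Sequence[Mapping[str, float]]) -> float:
    """Best ungapped placement score of a per-column residue log-odds table.

    Returns max over placements of the sum of column log-odds. The sequence
    must be at least as long as the profile.
    """
    m = len(profile)
    if m == 0:
        raise ValueError("empty profile")
    n = len(protein)
    if n < m:
        raise ValueError(f"sequence length {n} shorter than profile length {m}")
    best = None
    for i in range(n - m + 1):
        total = 0.0
        for k, column in enumerate(profile):
            total += column[protein[i + k]]
        if best is None or total > best:
            best = total
    assert best is not None
    return best
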