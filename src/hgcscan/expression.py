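"""Metatranscriptome TPM normalization and phylum-level expression summaries.

ORF-level read counts (from pseudo-alignment against the predicted ORFs of the
putative-methylator genomes) are normalized per sample to transcripts per
million (TPM): per sample, rate_i = count_i / length_i and
TPM_i = 1e6 * rate_i / sum_j rate_j, so each nonzero sample column sums to one
million. Samples with no mapped reads yield all-zero columns rather than
errors (sites with no detectable transcripts).

Summaries mirror genome-resolved metatranscriptome practice: per-phylum summed
marker (hgcA/hgcB/regulator) TPM per sample with a per-sample grand total;
per-phylum genome-averaged whole-genome TPM; and per-genome comparison of hgcA
expression against the rpoB housekeeping gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .marker_search import MarkerHit
from .motif_synteny import MethylatorCall

logger = logging.getLogger(__name__)


class ExpressionError(ValueError):
    """Malformed count input or missing ORFs."""


@dataclass
class CountMatrix:
    """ORF x sample raw counts with per-ORF genome ids and nucleotide lengths."""

    counts: pd.DataFrame  # index orf_id, columns sample ids, non-negative
    genome_of: pd.Series  # orf_id -> genome_id
    length_bp: pd.Series  # orf_id -> nt length

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ExpressionError("negative counts")
        if not self.length_bp.index.equals(self.counts.index):
            self.length_bp = self.length_bp.reindex(self.counts.index)
        if not self.genome_of.index.equals(self.counts.index):
            self.genome_of = self.genome_of.reindex(self.counts.index)
        if self.length_bp.isna().any() or (self.length_bp <= 0).any():
            raise ExpressionError("every ORF needs a positive length")
        if self.genome_of.isna().any():
            raise ExpressionError("every ORF needs a genome id")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class TpmMatrix:
    """TPM-normalized twin of a CountMatrix (same shape and annotations)."""

    tpm: pd.DataFrame
    genome_of: pd.Series
    length_bp: pd.Series

    @property
    def samples(self) -> list[str]:
        return list(self.tpm.columns)


def tpm_normalize(counts: CountMatrix) -> TpmMatrix:
    """Transcripts-per-million normalization, one normalization per sample
    across the union of all ORFs; all-zero columns stay all-zero."""
    # lengths enter only through their ratios, so a uniform unit change
    # (bp vs kb) cancels exactly, not just to rounding
    relative_length = counts.length_bp / counts.length_bp.min()
    rates = counts.counts.div(relative_length, axis=0)
    totals = rates.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpm = rates.div(totals, axis=1) * 1e6
    tpm = tpm.where(np.isfinite(tpm), 0.0)
    zero_cols = totals[totals == 0].index.tolist()
    if zero_cols:
        logger.info("samples with no mapped reads (all-zero TPM): %s", zero_cols)
    return TpmMatrix(tpm, counts.genome_of, counts.length_bp)


def _marker_orfs(calls: Sequence[MethylatorCall], marker: str) -> dict[str, str]:
    """orf_id -> genome_id for one marker of the methylator calls."""
    attr = {"hgcA": "hgcA_orf", "hgcB": "hgcB_orf", "regulator": "regulator_orf"}[marker]
    out: dict[str, str] = {}
    for call in calls:
        orf = getattr(call, attr)
        if orf is not None:
            out[orf] = call.genome_id
    return out


def marker_expression_by_group(
    tpm: TpmMatrix,
    calls: Sequence[MethylatorCall],
    marker: str,
    taxonomy: Mapping[str, str],
) -> pd.DataFrame:
    """Per-phylum summed marker TPM per sample, plus a per-sample grand total row.

    ``taxonomy`` maps genome_id -> group (phylum) label. Every called marker
    ORF must be present in the matrix.
    """
    orf_to_genome = _marker_orfs(calls, marker)
    missing = [o for o in orf_to_genome if o not in tpm.tpm.index]
    if missing:
        raise ExpressionError(f"called {marker} ORFs missing from the count matrix: {missing}")
    groups = sorted({taxonomy[g] for g in orf_to_genome.values()})
    table = pd.DataFrame(0.0, index=groups, columns=tpm.samples)
    for orf, genome in orf_to_genome.items():
        table.loc[taxonomy[genome]] += tpm.tpm.loc[orf]
    table.loc["total"] = table.sum(axis=0)
    return table


def genome_average_by_group(
    tpm: TpmMatrix,
    taxonomy: Mapping[str, str],
) -> pd.DataFrame:
    """Average whole-genome expression per phylum: sum of TPM over all ORFs of
    all genomes in the phylum, divided by the number of genomes in the phylum."""
    genome_ids = pd.unique(tpm.genome_of)
    group_of_genome = {g: taxonomy[g] for g in genome_ids}
    group_of_orf = tpm.genome_of.map(group_of_genome)
    sums = tpm.tpm.groupby(group_of_orf).sum()
    n_genomes = pd.Series(group_of_genome).value_counts()
    return sums.div(n_genomes.reindex(sums.index), axis=0).sort_index()


def compare_to_housekeeping(
    tpm: TpmMatrix,
    calls: Sequence[MethylatorCall],
    rpoB_hits: Sequence[MarkerHit],
) -> pd.DataFrame:
    """Long-format (genome, sample, hgcA_tpm, rpoB_tpm) pairs.

    hgcA TPM per genome is summed over its called hgcA ORFs. The best-scoring
    rpoB hit per genome is used; genomes lacking a confident rpoB are excluded
    and flagged in the ``rpoB_found`` column of the returned table.
    """
    best_rpoB: dict[str, MarkerHit] = {}
    for hit in rpoB_hits:
        if hit.orf_id in tpm.tpm.index:
            cur = best_rpoB.get(hit.genome_id)
            if cur is None or hit.score > cur.score:
                best_rpoB[hit.genome_id] = hit
    hgcA_by_genome: dict[str, list[str]] = {}
    for call in calls:
        hgcA_by_genome.setdefault(call.genome_id, []).append(call.hgcA_orf)

    rows = []
    for genome, hgcA_orfs in sorted(hgcA_by_genome.items()):
        rpoB = best_rpoB.get(genome)
        if rpoB is None:
            logger.info("genome %s: no confident rpoB, excluded from comparison", genome)
            for sample in tpm.samples:
                rows.append({"genome_id": genome, "sample": sample, "rpoB_found": False,
                             "hgcA_tpm": np.nan, "rpoB_tpm": np.nan})
            continue
        hgcA_tpm = tpm.tpm.loc[[o for o in hgcA_orfs if o in tpm.tpm.index]].sum(axis=0)
        rpoB_tpm = tpm.tpm.loc[rpoB.orf_id]
        for sample in tpm.samples:
            rows.append({
                "genome_id": genome, "sample": sample, "rpoB_found": True,
                "hgcA_tpm": float(hgcA_tpm[sample]), "rpoB_tpm": float(rpoB_tpm[sample]),
            })
    return pd.DataFrame(rows, columns=["genome_id", "sample", "rpoB_found", "hgcA_tpm", "rpoB_tpm"])


def read_counts(path: str | Path) -> CountMatrix:
    """Read the delimited count matrix (orf_id, genome_id, length_bp, <samples...>)."""
    df = pd.read_csv(path, sep="\t")
    required = ["orf_id", "genome_id", "length_bp"]
    missing = set(required) - set(df.columns)
    if missing:
        raise ExpressionError(f"{path}: count matrix missing columns {sorted(missing)}")
    samples = [c for c in df.columns if c not in required]
    if not samples:
        raise ExpressionError(f"{path}: no sample columns")
    df = df.set_index("orf_id")
    return CountMatrix(
        counts=df[samples].astype(float),
        genome_of=df["genome_id"].astype(str),
        length_bp=df["length_bp"].astype(float),
    )


def write_counts(path: str | Path, counts: CountMatrix) -> None:
    out = pd.concat(
        [counts.genome_of.rename("genome_id"), counts.length_bp.rename("length_bp"),
         counts.counts], axis=1,
    )
    out.index.name = "orf_id"
    out.to_csv(path, sep="\t")


def plot_expression_heatmap(
    table: pd.DataFrame, path: str | Path, scale_break: float = 100.0, vmax: float = 165.0
) -> None:
    """Render a group x sample TPM table as a heatmap with a continuous scale
    up to ``scale_break`` and a compressed band above it (low-range contrast)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.colors as mcolors
    import matplotlib.pyplot as plt

    body = table.drop(index="total", errors="ignore")
    norm = mcolors.TwoSlopeNorm(vmin=0.0, vcenter=scale_break, vmax=max(vmax, scale_break + 1))
    fig, ax = plt.subplots(figsize=(1 + 0.5 * body.shape[1], 1 + 0.4 * body.shape[0]))
    im = ax.imshow(np.minimum(body.values, vmax), cmap="magma", norm=norm, aspect="auto")
    ax.set_xticks(range(body.shape[1]), body.columns, rotation=90)
    ax.set_yticks(range(body.shape[0]), body.index)
    fig.colorbar(im, ax=ax, label="TPM")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
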