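"""Genome x metabolic-marker presence/absence matrices and guild summaries.

Broad metabolic capabilities (sulfur, nitrogen and carbon cycling, metal
resistance) are screened across putative methylators as marker presence/
absence, then summarized per taxonomic group as the percentage of genomes
carrying each marker. Multi-subunit complexes (nif, nar, nir, nor, nos) are
reported as the arithmetic mean of their per-subunit group percentages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .genome_model import GenomeCollection, group_label
from .marker_search import MarkerHit, ThresholdRule

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MarkerSet:
    """A named marker or subunit complex appearing as one row of the summary."""

    name: str
    members: tuple[str, ...]
    averaged: bool = False

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"marker set {self.name}: no members")


@dataclass
class PresenceMatrix:
    """Boolean genome x marker matrix."""

    data: pd.DataFrame  # index: genome ids, columns: marker ids, dtype bool

    @property
    def genomes(self) -> list[str]:
        return list(self.data.index)

    @property
    def markers(self) -> list[str]:
        return list(self.data.columns)


def build_presence_matrix(
    collection: GenomeCollection,
    hits: Sequence[MarkerHit],
    rules: Mapping[str, ThresholdRule],
) -> PresenceMatrix:
    """Cell (genome, marker) is true iff >= 1 hit passes that marker's rule."""
    genome_ids = sorted(collection.genomes)
    markers = sorted(rules)
    data = pd.DataFrame(False, index=genome_ids, columns=markers)
    for hit in hits:
        if hit.genome_id not in collection:
            raise ValueError(f"hit references unknown genome {hit.genome_id}")
        if hit.marker not in rules:
            raise ValueError(f"no threshold rule for marker {hit.marker}")
        if rules[hit.marker].accepts(hit):
            data.loc[hit.genome_id, hit.marker] = True
    return PresenceMatrix(data)


def summarize_groups(
    matrix: PresenceMatrix,
    collection: GenomeCollection,
    sets: Sequence[MarkerSet],
    min_group_size: int = 5,
    min_completeness: float = 90.0,
    max_redundancy: float = 10.0,
    class_rank_groups: frozenset[str] = frozenset({"Deltaproteobacteria"}),
) -> pd.DataFrame:
    """Long-format (group, marker_set, percent) table.

    Genomes are filtered to completeness > min and redundancy < max (strict);
    groups with more than ``min_group_size`` genomes (strict) are retained.
    Unaveraged sets report 100 x carriers / group size; averaged sets report
    the arithmetic mean of the per-subunit percentages.
    """
    eligible = [
        g for g in collection
        if g.id in matrix.data.index
        and g.completeness > min_completeness
        and g.redundancy < max_redundancy
    ]
    by_group: dict[str, list[str]] = {}
    for g in eligible:
        by_group.setdefault(group_label(g.taxonomy, class_rank_groups), []).append(g.id)
    groups = {k: v for k, v in sorted(by_group.items()) if len(v) > min_group_size}
    logger.info(
        "guild summary: %d of %d genomes pass quality, %d groups with > %d genomes",
        len(eligible), len(collection), len(groups), min_group_size,
    )

    rows = []
    for group, members in groups.items():
        sub = matrix.data.loc[members]
        for mset in sets:
            missing = [m for m in mset.members if m not in sub.columns]
            if missing:
                raise ValueError(f"marker set {mset.name}: markers {missing} absent from matrix")
            if mset.averaged:
                # per-subunit group percentages, then their arithmetic mean
                percent = float((100.0 * sub[list(mset.members)].mean(axis=0)).mean())
            else:
                # single markers; multi-member unaveraged sets count any member
                present = sub[list(mset.members)].any(axis=1)
                percent = float(100.0 * present.mean())
            rows.append({"group": group, "marker_set": mset.name,
                         "n_genomes": len(members), "percent": percent})
    return pd.DataFrame(rows, columns=["group", "marker_set", "n_genomes", "percent"])


MARKER_CONFIG_COLUMNS = ["marker_id", "set_name", "averaged", "min_score_or_evalue"]


def read_marker_config(path: str | Path) -> tuple[list[MarkerSet], dict[str, ThresholdRule]]:
    """Read the marker config table into marker sets and per-marker rules.

    ``min_score_or_evalue`` is interpreted as a curated bit-score cutoff when
    >= 1 and as an E-value cutoff when < 1; blank falls back to E <= 1e-10.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(MARKER_CONFIG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: marker config missing columns {sorted(missing)}")
    rules: dict[str, ThresholdRule] = {}
    members: dict[str, list[str]] = {}
    averaged: dict[str, bool] = {}
    for r in df.itertuples(index=False):
        marker = str(r.marker_id)
        cutoff = r.min_score_or_evalue
        if pd.isna(cutoff):
            rules[marker] = ThresholdRule(marker, max_evalue=1e-10)
        elif float(cutoff) >= 1:
            rules[marker] = ThresholdRule(marker, min_score=float(cutoff))
        else:
            rules[marker] = ThresholdRule(marker, max_evalue=float(cutoff))
        set_name = str(r.set_name)
        members.setdefault(set_name, []).append(marker)
        averaged[set_name] = bool(r.averaged)
    sets = [MarkerSet(name, tuple(m), averaged[name]) for name, m in members.items()]
    return sets, rules


def plot_guild_heatmap(summary: pd.DataFrame, path: str | Path) -> None:
    """Render the group x marker-set percentage table as a heatmap."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    wide = summary.pivot(index="group", columns="marker_set", values="percent")
    fig, ax = plt.subplots(figsize=(1 + 0.6 * wide.shape[1], 1 + 0.4 * wide.shape[0]))
    im = ax.imshow(wide.values, cmap="viridis", vmin=0, vmax=100, aspect="auto")
    ax.set_xticks(range(wide.shape[1]), wide.columns, rotation=90)
    ax.set_yticks(range(wide.shape[0]), wide.index)
    fig.colorbar(im, ax=ax, label="% of genomes in group")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
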