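"""Seeded synthetic genome collections with known ground truth.

Generates everything the pipeline consumes — genome FASTA+GFF3, metadata,
profile-search hit tables, primer constructs and metatranscriptome count
matrices — with a truth table recording every planted element, so each stage
is testable offline. All randomness flows from a single integer seed; fixed
(config, seed) reruns are byte-identical.

Planted genome classes:

* ``true``        — hgcA with the cap-helix domain, hgcB within 5 ORFs
                    downstream on the same contig, a regulator 1-3 genes
                    upstream, and hit scores comfortably past the cutoffs.
* ``no_motif``    — an hgcA-like hit whose protein lacks the cap-helix domain.
* ``off_contig``  — valid hgcA but its hgcB partner sits on another contig.
* ``far_hgcb``    — valid hgcA but hgcB six ORFs downstream (past the rule).
* ``low_score``   — motif-bearing hgcA whose hit straddles the score/E-value
                    boundary on the rejecting side.

Background ORFs are random codon sequences whose proteins are rejected if they
contain either conserved motif, so planted loci are the only motif carriers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .expression import CountMatrix, write_counts
from .genome_model import Contig, GenomeCollection, GenomeRecord, Orf, write_genome, write_metadata
from .insilico_pcr import IUPAC, reverse_complement
from .marker_search import MarkerHit, write_hit_table
from .motif_synteny import AMINO_ACIDS, CAP_HELIX, FERREDOXIN, match_motif

#: Cap-helix variant with the alternation position broken (L is not I/V).
BROKEN_CAP_HELIX = "GLNVWCAAGK"

_CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in CodonTable.unambiguous_dna_by_id[11].forward_table.items():
    _CODONS_BY_AA.setdefault(aa, []).append(codon)
for codons in _CODONS_BY_AA.values():
    codons.sort()

DEFAULT_LINEAGES = (
    "d__Bacteria;p__Proteobacteria;c__Deltaproteobacteria;o__;f__;g__;s__",
    "d__Bacteria;p__Firmicutes;c__Clostridia;o__;f__;g__;s__",
    "d__Bacteria;p__Bacteroidetes;c__vadinHA17;o__;f__;g__;s__",
    "d__Bacteria;p__Actinobacteria;c__Coriobacteriia;o__OPB41;f__;g__;s__",
    "d__Bacteria;p__Verrucomicrobia;c__Opitutae;o__;f__;g__;s__",
)

DEFAULT_SAMPLES = (
    "palsa_shallow", "bog_medium", "bog_deep", "fen_shallow", "fen_medium", "fen_deep",
)
_SITE_EFFECT = {"palsa": 0.0, "bog": 1.0, "fen": 2.0}
_DEPTH_EFFECT = {"shallow": 0.5, "medium": 1.0, "deep": 1.5}

DEFAULT_METABOLIC_PRESENCE = {
    "dsrA": 0.5, "dsrB": 0.5, "sat": 0.3, "nifD": 0.4, "nifH": 0.4, "nifK": 0.4,
}


class SyntheticConfigError(ValueError):
    """Infeasible generator configuration."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic collection."""

    n_true: int = 10
    n_no_motif: int = 10
    n_off_contig: int = 10
    n_far_hgcb: int = 10
    n_low_score: int = 10
    lineages: tuple[str, ...] = DEFAULT_LINEAGES
    contigs_per_genome: int = 2
    orfs_per_contig: int = 12
    orf_length_aa: int = 100
    intergenic_bp: tuple[int, int] = (20, 60)
    true_hgcb_max_offset: int = 5      # true loci plant hgcB at offsets 1..this
    far_hgcb_offset: int = 6           # just past the five-ORF rule
    completeness_range: tuple[float, float] = (80.0, 99.0)
    redundancy_range: tuple[float, float] = (0.0, 9.0)
    # in-silico PCR plants
    primer_fwd: str | None = None
    primer_rev: str | None = None
    primer_target_phylum: str | None = None
    primer_mismatches: tuple[int, int] = (0, 0)
    primer_inner_bp: int = 120
    n_off_target_plants: int = 0
    # expression
    metabolic_presence: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_METABOLIC_PRESENCE)
    )

    @property
    def n_genomes(self) -> int:
        return (self.n_true + self.n_no_motif + self.n_off_contig
                + self.n_far_hgcb + self.n_low_score)


TRUTH_COLUMNS = [
    "genome_id", "klass", "taxonomy", "phylum", "expression_multiplier",
    "hgcA_orf", "hgcA_has_motif", "hgcA_contig",
    "hgcB_orf", "hgcB_offset", "hgcB_contig", "hgcB_expected_pairing",
    "regulator_orf", "regulator_offset",
    "primer_planted", "primer_fwd_mm", "primer_rev_mm",
    "primer_contig", "primer_start", "primer_end", "primer_on_target",
]

_AA_ARRAY = np.array(list(AMINO_ACIDS))


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA_ARRAY, size=length))


def _background_protein(rng: np.random.Generator, length: int) -> str:
    """Random protein guaranteed to carry neither conserved motif."""
    while True:
        protein = _random_protein(rng, length)
        if not match_motif(protein, CAP_HELIX) and not match_motif(protein, FERREDOXIN):
            return protein


def _embed(rng: np.random.Generator, protein: str, word: str) -> str:
    pos = int(rng.integers(1, len(protein) - len(word)))
    return protein[:pos] + word + protein[pos + len(word):]


def _hgcA_protein(rng: np.random.Generator, length: int, with_motif: bool) -> str:
    word = ("G" + ("IV"[rng.integers(2)]) + "NVWCAAGK") if with_motif else BROKEN_CAP_HELIX
    return _embed(rng, _background_protein(rng, length), word)


def _hgcB_protein(rng: np.random.Generator, length: int) -> str:
    xs = _random_protein(rng, 5)
    word = f"C{xs[0]}{xs[1]}C{xs[2]}{xs[3]}{xs[4]}C"
    return _embed(rng, _background_protein(rng, length), word)


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    nt = "".join(_CODONS_BY_AA[aa][rng.integers(len(_CODONS_BY_AA[aa]))] for aa in protein)
    return nt + "TAA"


def _primer_word(rng: np.random.Generator, primer_seq: str, mismatches: int) -> str:
    """A binding-site word matching the primer with exactly k mismatches."""
    word = [IUPAC[p][rng.integers(len(IUPAC[p]))] for p in primer_seq]
    mutable = [i for i, p in enumerate(primer_seq) if len(IUPAC[p]) < 4]
    if mismatches > len(mutable):
        raise SyntheticConfigError(
            f"cannot plant {mismatches} mismatches into primer {primer_seq} "
            f"({len(mutable)} non-degenerate positions)"
        )
    for i in rng.choice(len(mutable), size=mismatches, replace=False):
        pos = mutable[int(i)]
        off = [b for b in "ACGT" if b not in IUPAC[primer_seq[pos]]]
        word[pos] = off[rng.integers(len(off))]
    return "".join(word)


def generate_collection(
    config: GeneratorConfig,
    seed: int,
    outdir: str | Path | None = None,
) -> tuple[GenomeCollection, pd.DataFrame]:
    """Generate a genome collection plus its truth table.

    When ``outdir`` is given, writes ``genomes/<id>.fna`` + ``.gff``,
    ``metadata.tsv`` and ``truth.tsv`` under it.
    """
    n = config.orfs_per_contig
    max_down = max(config.far_hgcb_offset, config.true_hgcb_max_offset)
    max_up = 3
    if config.contigs_per_genome < 2 or n < max_down + max_up + 2:
        raise SyntheticConfigError(
            f"need >=2 contigs and >= {max_down + max_up + 2} ORFs per contig "
            f"to place all planted loci (got {config.contigs_per_genome}, {n})"
        )
    rng = np.random.default_rng(seed)
    classes = (
        ["true"] * config.n_true
        + ["no_motif"] * config.n_no_motif
        + ["off_contig"] * config.n_off_contig
        + ["far_hgcb"] * config.n_far_hgcb
        + ["low_score"] * config.n_low_score
    )
    collection = GenomeCollection()
    truth_rows: list[dict] = []
    off_target_budget = config.n_off_target_plants

    for gi, klass in enumerate(classes):
        gid = f"G{gi:03d}"
        lineage = config.lineages[gi % len(config.lineages)]
        phylum = _phylum_of(lineage)

        strand = "+" if rng.integers(2) else "-"
        if strand == "+":
            hgcA_rank = int(rng.integers(1 + max_up, n - max_down + 1))
        else:
            hgcA_rank = int(rng.integers(1 + max_down, n - max_up + 1))
        sign = 1 if strand == "+" else -1

        if klass in ("true", "low_score"):
            offset = int(rng.integers(1, config.true_hgcb_max_offset + 1))
        elif klass == "far_hgcb":
            offset = config.far_hgcb_offset
        else:
            offset = int(rng.integers(1, config.true_hgcb_max_offset + 1))
        reg_offset = int(rng.integers(1, max_up + 1)) if klass == "true" else None

        # per-contig plan: rank -> (role, protein)
        plans: list[dict[int, tuple[str, str]]] = [dict() for _ in range(config.contigs_per_genome)]
        hgcA_protein = _hgcA_protein(rng, config.orf_length_aa, with_motif=klass != "no_motif")
        plans[0][hgcA_rank] = ("hgcA", hgcA_protein)
        hgcB_protein = _hgcB_protein(rng, config.orf_length_aa)
        if klass == "off_contig":
            hgcB_contig, hgcB_rank = 1, int(rng.integers(2, n))
        else:
            hgcB_contig, hgcB_rank = 0, hgcA_rank + sign * offset
        plans[hgcB_contig][hgcB_rank] = ("hgcB", hgcB_protein)
        if reg_offset is not None:
            plans[0][hgcA_rank - sign * reg_offset] = ("regulator", _background_protein(rng, config.orf_length_aa))

        contigs: dict[str, Contig] = {}
        orfs: list[Orf] = []
        roles: dict[str, str] = {}  # role -> orf id
        serial = 0
        for ci in range(config.contigs_per_genome):
            contig_id = f"{gid}.c{ci}"
            parts: list[str] = []
            pos = 0
            lo, hi = config.intergenic_bp
            for rank in range(1, n + 1):
                spacer = _random_nt(rng, int(rng.integers(lo, hi)))
                parts.append(spacer)
                pos += len(spacer)
                role, protein = plans[ci].get(rank, (None, None))
                if protein is None:
                    protein = _background_protein(rng, config.orf_length_aa)
                orf_strand = strand if role else ("+" if rng.integers(2) else "-")
                coding = _reverse_translate(rng, protein)
                nt = coding if orf_strand == "+" else reverse_complement(coding)
                serial += 1
                orf_id = f"{gid}_{serial:05d}"
                orfs.append(Orf(orf_id, contig_id, pos + 1, pos + len(nt), orf_strand, rank, protein))
                if role:
                    roles[role] = orf_id
                parts.append(nt)
                pos += len(nt)
            parts.append(_random_nt(rng, int(rng.integers(lo, hi))))
            contigs[contig_id] = Contig(contig_id, "".join(parts))

        # primer constructs overwrite template DNA (coding consistency is not
        # emulated for planted binding sites; translations live in the GFF)
        primer = {"planted": False, "fwd_mm": None, "rev_mm": None,
                  "contig": None, "start": None, "end": None, "on_target": None}
        if config.primer_fwd and config.primer_rev:
            hgcA_orf = next(o for o in orfs if o.id == roles["hgcA"])
            on_target = (
                config.primer_target_phylum is not None
                and phylum == config.primer_target_phylum
                and klass != "no_motif"
            )
            off_target = not on_target and off_target_budget > 0
            if on_target or off_target:
                fwd_mm, rev_mm = config.primer_mismatches
                word_f = _primer_word(rng, config.primer_fwd.upper(), fwd_mm)
                word_r = _primer_word(rng, config.primer_rev.upper(), rev_mm)
                construct = word_f + _random_nt(rng, config.primer_inner_bp) + reverse_complement(word_r)
                if on_target:
                    target_contig, plant_at = hgcA_orf.contig_id, hgcA_orf.start + 4
                    if len(construct) > hgcA_orf.nt_length - 8:
                        raise SyntheticConfigError("primer construct does not fit inside the hgcA ORF")
                else:
                    off_target_budget -= 1
                    target_contig = f"{gid}.c1"
                    plant_at = 30
                seq = contigs[target_contig].sequence
                end = plant_at - 1 + len(construct)
                contigs[target_contig] = Contig(
                    target_contig, seq[: plant_at - 1] + construct + seq[end:]
                )
                primer = {"planted": True, "fwd_mm": fwd_mm, "rev_mm": rev_mm,
                          "contig": target_contig, "start": plant_at, "end": end,
                          "on_target": on_target}

        completeness = float(np.round(rng.uniform(*config.completeness_range), 2))
        redundancy = float(np.round(rng.uniform(*config.redundancy_range), 2))
        collection.add(GenomeRecord(gid, contigs, orfs, lineage, completeness, redundancy))
        truth_rows.append({
            "genome_id": gid, "klass": klass, "taxonomy": lineage, "phylum": phylum,
            "expression_multiplier": None,  # filled below
            "hgcA_orf": roles["hgcA"], "hgcA_has_motif": klass != "no_motif",
            "hgcA_contig": f"{gid}.c0",
            "hgcB_orf": roles.get("hgcB"), "hgcB_offset": offset,
            "hgcB_contig": f"{gid}.c{hgcB_contig}",
            "hgcB_expected_pairing": klass == "true",
            "regulator_orf": roles.get("regulator"), "regulator_offset": reg_offset,
            "primer_planted": primer["planted"], "primer_fwd_mm": primer["fwd_mm"],
            "primer_rev_mm": primer["rev_mm"], "primer_contig": primer["contig"],
            "primer_start": primer["start"], "primer_end": primer["end"],
            "primer_on_target": primer["on_target"],
        })

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    # planted per-phylum expression multipliers: 10x steps following lineage order
    phyla_order = [_phylum_of(l) for l in config.lineages]
    mult = {p: 10.0 ** (len(phyla_order) - 1 - i) for i, p in enumerate(phyla_order)}
    truth["expression_multiplier"] = truth["phylum"].map(mult)

    if outdir is not None:
        outdir = Path(outdir)
        (outdir / "genomes").mkdir(parents=True, exist_ok=True)
        meta_rows = []
        for genome in collection:
            write_genome(genome, outdir / "genomes" / f"{genome.id}.fna",
                         outdir / "genomes" / f"{genome.id}.gff")
            meta_rows.append((genome.id, genome.taxonomy, genome.completeness, genome.redundancy))
        write_metadata(outdir / "metadata.tsv", pd.DataFrame(
            meta_rows, columns=["genome_id", "taxonomy", "completeness", "redundancy"]))
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return collection, truth


_NT_ARRAY = np.array(list("ACGT"))


def _random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_NT_ARRAY, size=length))


def _phylum_of(lineage: str) -> str:
    for token in lineage.split(";"):
        token = token.strip()
        if token.startswith("c__Deltaproteobacteria"):
            return "Deltaproteobacteria"
        if token.startswith("p__"):
            phylum = token[3:]
    return phylum


def generate_hit_tables(
    collection: GenomeCollection,
    truth: pd.DataFrame,
    seed: int,
    outdir: str | Path | None = None,
    metabolic_presence: Mapping[str, float] = DEFAULT_METABOLIC_PRESENCE,
    metabolic_min_score: float = 50.0,
) -> dict[str, list[MarkerHit]]:
    """Emulated profile-search hits against the planted truth.

    True loci score comfortably past the cutoffs (hgcA score ~U(310,400),
    E <= 1e-55); the low-score class straddles the 300 / 1e-50 boundary on the
    rejecting side. hgcB, regulator, rpoB and metabolic markers are generated
    against their own thresholds. Writes ``hits_<marker>.tsv`` when ``outdir``
    is set.
    """
    rng = np.random.default_rng(seed)
    hits: dict[str, list[MarkerHit]] = {"hgcA": [], "hgcB": [], "regulator": [], "rpoB": []}

    for row in truth.itertuples(index=False):
        gid = row.genome_id
        if row.klass == "low_score":
            # rejecting side of the joint rule: fail score or E-value (or both)
            which = rng.integers(3)
            score = float(rng.uniform(150, 295)) if which in (0, 2) else float(rng.uniform(310, 400))
            evalue = 10.0 ** -rng.uniform(30, 48) if which in (1, 2) else 10.0 ** -rng.uniform(55, 80)
            hits["hgcA"].append(MarkerHit(gid, row.hgcA_orf, "hgcA", evalue, score))
        else:
            hits["hgcA"].append(MarkerHit(
                gid, row.hgcA_orf, "hgcA",
                10.0 ** -rng.uniform(55, 80), float(rng.uniform(310, 400))))
        if row.hgcB_orf is not None and not pd.isna(row.hgcB_orf):
            hits["hgcB"].append(MarkerHit(
                gid, row.hgcB_orf, "hgcB",
                10.0 ** -rng.uniform(20, 60), float(rng.uniform(80, 150))))
        if row.regulator_orf is not None and not pd.isna(row.regulator_orf):
            hits["regulator"].append(MarkerHit(
                gid, row.regulator_orf, "regulator",
                10.0 ** -rng.uniform(15, 40), float(rng.uniform(60, 200))))

    planted = set(truth["hgcA_orf"]) | set(truth["hgcB_orf"].dropna()) | set(
        truth["regulator_orf"].dropna())
    for genome in collection:
        background = [o for o in genome.orfs if o.id not in planted]
        rpoB_orf = background[-1]
        hits["rpoB"].append(MarkerHit(
            genome.id, rpoB_orf.id, "rpoB",
            10.0 ** -rng.uniform(60, 120), float(rng.uniform(400, 600))))
        for marker, prob in metabolic_presence.items():
            if rng.random() < prob:
                orf = background[int(rng.integers(len(background) - 1))]
                hits.setdefault(marker, []).append(MarkerHit(
                    genome.id, orf.id, marker,
                    10.0 ** -rng.uniform(20, 60),
                    float(rng.uniform(metabolic_min_score + 10, metabolic_min_score + 100))))
            else:
                hits.setdefault(marker, [])

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for marker, marker_hits in sorted(hits.items()):
            write_hit_table(outdir / f"hits_{marker}.tsv", marker_hits)
    return hits


def generate_counts(
    collection: GenomeCollection,
    truth: pd.DataFrame,
    seed: int,
    n_samples: int = 6,
    sample_labels: Sequence[str] = DEFAULT_SAMPLES,
    dispersion: float = 0.5,
    base_mean: float = 5.0,
    outdir: str | Path | None = None,
) -> CountMatrix:
    """Overdispersed (negative-binomial) counts with planted phylum and
    site/depth structure.

    count ~ NB(mean = base x phylum_multiplier x site_effect x depth_effect,
    dispersion d: variance = mu + d mu^2). Palsa samples get site effect 0,
    emulating sites with no detectable transcripts. Writes ``counts.tsv``
    when ``outdir`` is set.
    """
    if n_samples < 1:
        raise SyntheticConfigError("n_samples must be >= 1")
    samples = list(sample_labels)[:n_samples]
    if len(samples) < n_samples:
        samples += [f"sample_{i}" for i in range(len(samples), n_samples)]
    rng = np.random.default_rng(seed)
    mult = dict(zip(truth["genome_id"], truth["expression_multiplier"]))

    orf_ids, genome_of, lengths, mus = [], [], [], []
    for genome in collection:
        m = mult.get(genome.id, 1.0)
        for orf in genome.orfs:
            orf_ids.append(orf.id)
            genome_of.append(genome.id)
            lengths.append(orf.nt_length)
            base = rng.lognormal(mean=np.log(base_mean), sigma=1.0)
            mus.append(base * m)
    mus = np.asarray(mus)

    columns = {}
    for sample in samples:
        site, depth = sample.split("_", 1)
        effect = _SITE_EFFECT.get(site, 1.0) * _DEPTH_EFFECT.get(depth, 1.0)
        mu = mus * effect
        if dispersion > 0:
            size = 1.0 / dispersion
            with np.errstate(divide="ignore", invalid="ignore"):
                p = size / (size + mu)
            draws = np.where(mu > 0, rng.negative_binomial(size, np.where(mu > 0, p, 1.0)), 0)
        else:
            draws = rng.poisson(mu)
        columns[sample] = draws.astype(float)

    counts = CountMatrix(
        counts=pd.DataFrame(columns, index=pd.Index(orf_ids, name="orf_id")),
        genome_of=pd.Series(genome_of, index=orf_ids, name="genome_id"),
        length_bp=pd.Series(lengths, index=orf_ids, dtype=float, name="length_bp"),
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_counts(outdir / "counts.tsv", counts)
    return counts
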