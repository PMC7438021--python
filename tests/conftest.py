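import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hgcscan.genome_model import Contig, GenomeCollection, GenomeRecord, Orf

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_genome(
    genome_id: str = "G1",
    n_orfs: int = 10,
    strands: list[str] | None = None,
    contig_id: str = "c1",
    taxonomy: str = "d__Bacteria;p__TestPhylum;c__;o__;f__;g__;s__",
    orf_bp: int = 30,
    spacer_bp: int = 10,
    proteins: dict[int, str] | None = None,
    completeness: float = 95.0,
    redundancy: float = 2.0,
) -> GenomeRecord:
    """One-contig genome with evenly spaced ORFs, rank i at slot i (1-based)."""
    rng = np.random.default_rng(hash(genome_id) % 2**31)
    length = n_orfs * (orf_bp + spacer_bp) + spacer_bp
    seq = "".join(rng.choice(list("ACGT"), size=length))
    orfs = []
    for i in range(1, n_orfs + 1):
        start = spacer_bp + (i - 1) * (orf_bp + spacer_bp) + 1
        strand = strands[i - 1] if strands else "+"
        protein = (proteins or {}).get(i, "M" + "A" * 9)
        orfs.append(Orf(f"{genome_id}_{i:05d}", contig_id, start, start + orf_bp - 1,
                        strand, i, protein))
    return GenomeRecord(genome_id, {contig_id: Contig(contig_id, seq)}, orfs,
                        taxonomy, completeness, redundancy)


@pytest.fixture
def ten_orf_genome() -> GenomeRecord:
    return make_genome()


@pytest.fixture
def small_synthetic():
    """A small planted collection shared by several test modules."""
    from hgcscan.synthetic import GeneratorConfig, generate_collection, generate_hit_tables

    config = GeneratorConfig(n_true=3, n_no_motif=2, n_off_contig=2, n_far_hgcb=2, n_low_score=2)
    collection, truth = generate_collection(config, seed=11)
    hits = generate_hit_tables(collection, truth, seed=12)
    return collection, truth, hits


def as_collection(*genomes: GenomeRecord) -> GenomeCollection:
    collection = GenomeCollection()
    for g in genomes:
        collection.add(g)
    return collection
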