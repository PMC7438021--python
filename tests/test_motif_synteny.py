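import numpy as np
import pytest

from hgcscan.genome_model import Contig, GenomeRecord, Orf
from hgcscan.marker_search import MarkerHit
from hgcscan.motif_synteny import (
    CAP_HELIX,
    FERREDOXIN,
    Motif,
    MotifError,
    call_methylators,
    downstream_distance,
    extract_neighborhood,
    find_regulator,
    match_motif,
    pair_hgcB,
    upstream_distance,
    validate_hgcA,
)

from _oracles import oracle_motif_positions
from conftest import as_collection, make_genome


class TestMatchMotif:
    @pytest.mark.parametrize(
        "protein,motif,expected",
        [
            ("MGGINVWCAAGKA", CAP_HELIX, [3]),
            ("CAACAAAC", FERREDOXIN, [1]),
            ("GLNVWCAAGK", CAP_HELIX, []),  # L is not in the I/V alternation
            ("GVNVWCAAGKXXGINVWCAAGK", CAP_HELIX, [1, 13]),
        ],
    )
    def test_conserved_domain_examples(self, protein, motif, expected):
        protein = protein.replace("X", "A")
        assert match_motif(protein, motif) == expected

    def test_overlapping_occurrences_all_reported(self):
        # CXXCXXXC occurrences can share cysteines
        protein = "CAACAACCAAC"
        assert match_motif(protein, FERREDOXIN) == [1, 4]

    @pytest.mark.parametrize("pattern", ["G(I/V", "G(I/J)K", "g", "", "A(/)B"])
    def test_malformed_patterns_error(self, pattern):
        with pytest.raises(MotifError):
            Motif(pattern).elements()

    def test_truncated_motif_does_not_validate(self):
        assert not validate_hgcA("AAGINVWCAAG")
        assert validate_hgcA("AAGINVWCAAGKAA")

    def test_equals_full_expansion_oracle_on_random_motifs(self):
        rng = np.random.default_rng(0)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(25):
            motif = _random_motif(rng)
            protein = "".join(rng.choice(aas, size=120))
            # guarantee one planted occurrence
            word = next(iter(motif.expansions()))
            pos = int(rng.integers(0, len(protein) - len(word)))
            protein = protein[:pos] + word + protein[pos + len(word):]
            assert match_motif(protein, motif) == oracle_motif_positions(
                protein, motif.elements()
            )


def _random_motif(rng, max_expansions=64):
    aas = "ACDEFGHIKLMNPQRSTVWY"
    while True:
        parts, expansions = [], 1
        for _ in range(int(rng.integers(4, 9))):
            kind = rng.random()
            if kind < 0.75:
                parts.append(aas[rng.integers(20)])
            elif kind < 0.95:
                pair = rng.choice(list(aas), size=int(rng.integers(2, 4)), replace=False)
                parts.append("(" + "/".join(pair) + ")")
                expansions *= len(pair)
            else:
                parts.append("X")
                expansions *= 20
        if expansions <= max_expansions:
            return Motif("".join(parts))


def seventeen_orf_genome(hgcA_strand: str, hgcA_rank: int = 9):
    return make_genome("G1", n_orfs=17, strands=[hgcA_strand] * 17), hgcA_rank


class TestDistances:
    def test_plus_strand_adjacency(self, ten_orf_genome):
        g = ten_orf_genome
        assert downstream_distance(g, g.orfs[4], g.orfs[5]) == 1

    def test_minus_strand_downstream_runs_leftward(self):
        g = make_genome(strands=["-"] * 10)
        assert downstream_distance(g, g.orfs[4], g.orfs[2]) == 2
        assert upstream_distance(g, g.orfs[4], g.orfs[6]) == 2

    def test_different_contigs_is_none(self, ten_orf_genome):
        g = ten_orf_genome
        other = Orf("x", "c2", 1, 30, "+", 1, "MA")
        g2 = GenomeRecord(
            "G2",
            {**g.contigs, "c2": Contig("c2", "A" * 100)},
            [*g.orfs, other],
            g.taxonomy, g.completeness, g.redundancy,
        )
        assert downstream_distance(g2, g2.orfs[0], other) is None

    def test_unknown_orf_errors(self, ten_orf_genome):
        stray = Orf("stray", "c1", 1, 3, "+", 1, "M")
        with pytest.raises(ValueError, match="stray"):
            downstream_distance(ten_orf_genome, ten_orf_genome.orfs[0], stray)

    def test_contig_reversal_leaves_distances_invariant(self):
        """Strand-relative distances are unchanged by flipping the whole contig."""
        g = make_genome(strands=["+", "-", "+", "+", "-", "+", "-", "+", "+", "-"])
        n = len(g.orfs)
        flipped_orfs = []
        length = g.contigs["c1"].length
        for o in reversed(g.orfs):
            flipped_orfs.append(
                Orf(o.id, "c1", length - o.end + 1, length - o.start + 1,
                    "-" if o.strand == "+" else "+", n - o.index_on_contig + 1, o.protein)
            )
        flipped_orfs.sort(key=lambda o: o.index_on_contig)
        gf = GenomeRecord("Gf", {"c1": Contig("c1", g.contigs["c1"].sequence)},
                          flipped_orfs, g.taxonomy)
        for a, b in [(0, 5), (7, 2), (3, 3)]:
            assert downstream_distance(g, g.orfs[a], g.orfs[b]) == downstream_distance(
                gf, gf.get_orf(g.orfs[a].id), gf.get_orf(g.orfs[b].id)
            )


class TestSyntenyRules:
    """pair_hgcB / find_regulator vs exhaustive placement enumeration."""

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_hgcb_rule_over_all_offsets(self, strand):
        genome, rank = seventeen_orf_genome(strand)
        hgcA = genome.orfs[rank - 1]
        sign = 1 if strand == "+" else -1
        for offset in range(-8, 9):
            candidate_rank = rank + sign * offset
            if not 1 <= candidate_rank <= 17 or offset == 0:
                continue
            candidate = genome.orfs[candidate_rank - 1]
            hits = [MarkerHit("G1", candidate.id, "hgcB", 1e-30, 100.0)]
            orf_id, dist = pair_hgcB(genome, hgcA, hits)
            if 1 <= offset <= 5:
                assert (orf_id, dist) == (candidate.id, offset)
            else:
                assert orf_id is None and dist is None

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_regulator_rule_over_all_offsets(self, strand):
        genome, rank = seventeen_orf_genome(strand)
        hgcA = genome.orfs[rank - 1]
        sign = 1 if strand == "+" else -1
        for offset in range(-8, 9):
            candidate_rank = rank - sign * offset  # positive = upstream
            if not 1 <= candidate_rank <= 17 or offset == 0:
                continue
            candidate = genome.orfs[candidate_rank - 1]
            hits = [MarkerHit("G1", candidate.id, "regulator", 1e-20, 50.0)]
            orf_id, dist = find_regulator(genome, hgcA, hits)
            if 1 <= offset <= 3:
                assert (orf_id, dist) == (candidate.id, offset)
            else:
                assert orf_id is None

    def test_nearest_candidate_wins_then_score_then_id(self):
        genome, rank = seventeen_orf_genome("+")
        hgcA = genome.orfs[rank - 1]
        at = lambda off: genome.orfs[rank - 1 + off]
        hits = [
            MarkerHit("G1", at(4).id, "hgcB", 1e-30, 200.0),
            MarkerHit("G1", at(2).id, "hgcB", 1e-30, 90.0),
        ]
        assert pair_hgcB(genome, hgcA, hits)[1] == 2

    def test_same_strand_requirement_is_optional(self):
        genome = make_genome(strands=["+", "-", "+", "+", "+", "+", "+", "+", "+", "+"])
        hgcA = genome.orfs[0]
        hits = [MarkerHit("G1", genome.orfs[1].id, "hgcB", 1e-30, 100.0)]
        assert pair_hgcB(genome, hgcA, hits)[0] is not None
        assert pair_hgcB(genome, hgcA, hits, require_same_strand=True)[0] is None


class TestCallMethylators:
    def test_recovers_planted_truth_classes(self, small_synthetic):
        collection, truth, hits = small_synthetic
        calls = call_methylators(collection, hits)
        klass = dict(zip(truth.genome_id, truth.klass))
        called = {c.genome_id: c for c in calls}
        for row in truth.itertuples(index=False):
            if row.klass in ("no_motif", "low_score"):
                assert row.genome_id not in called
            else:
                call = called[row.genome_id]
                assert call.hgcA_orf == row.hgcA_orf
                if row.klass == "true":
                    assert call.hgcB_orf == row.hgcB_orf
                    assert call.hgcB_distance == row.hgcB_offset
                    assert call.regulator_orf == row.regulator_orf
                    assert call.regulator_distance == row.regulator_offset
                else:  # off-contig or distance-6 hgcB: call without hgcB evidence
                    assert call.hgcB_orf is None
        assert len(calls) == sum(1 for k in klass.values() if k in ("true", "off_contig", "far_hgcb"))

    def test_motif_failure_yields_no_call(self):
        genome = make_genome(proteins={3: "AAGLNVWCAAGKAA"})  # broken cap helix
        hits = {"hgcA": [MarkerHit("G1", genome.orfs[2].id, "hgcA", 1e-60, 350.0)]}
        assert call_methylators(as_collection(genome), hits) == []

    def test_no_hits_no_calls(self, ten_orf_genome):
        assert call_methylators(as_collection(ten_orf_genome), {}) == []


class TestNeighborhood:
    def test_window_zero_is_center_only(self, ten_orf_genome):
        g = ten_orf_genome
        rows = extract_neighborhood(g, g.orfs[3], 0)
        assert [r[0] for r in rows] == [g.orfs[3].id]

    def test_window_two_spans_five_orfs(self, ten_orf_genome):
        g = ten_orf_genome
        rows = extract_neighborhood(g, g.orfs[3], 2)
        assert [r[0] for r in rows] == [o.id for o in g.orfs[1:6]]

    def test_contig_edge_truncates_without_error(self, ten_orf_genome):
        g = ten_orf_genome
        rows = extract_neighborhood(g, g.orfs[0], 5)
        assert [r[0] for r in rows] == [o.id for o in g.orfs[:6]]

    def test_negative_window_errors(self, ten_orf_genome):
        with pytest.raises(ValueError):
            extract_neighborhood(ten_orf_genome, ten_orf_genome.orfs[0], -1)
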