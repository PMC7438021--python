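import numpy as np
import pytest

from hgcscan.genome_model import Contig
from hgcscan.insilico_pcr import (
    AmpliconHit,
    PcrError,
    Primer,
    count_mismatches,
    crosstab_amplification,
    iupac_match,
    reverse_complement,
    scan_amplicons,
)
from hgcscan.motif_synteny import call_methylators
from hgcscan.synthetic import GeneratorConfig, generate_collection, generate_hit_tables

from _oracles import oracle_scan

FWD = Primer("fwd", "GGNRTNAAYGTNTGG")
REV = Primer("rev", "TGYGCNGCNGGNAAR")


def _hit_key(h: AmpliconHit):
    return (h.fwd_start, h.fwd_end, h.rev_start, h.rev_end, h.product_length,
            h.fwd_mismatches, h.rev_mismatches, h.orientation)


def random_contig(rng, length, cid="c"):
    return Contig(cid, "".join(rng.choice(list("ACGT"), size=length)))


class TestIupacSemantics:
    @pytest.mark.parametrize(
        "code,base,expected",
        [("R", "A", True), ("R", "G", True), ("R", "C", False),
         ("N", "T", True), ("A", "N", False), ("N", "N", True), ("Y", "T", True)],
    )
    def test_degenerate_codes(self, code, base, expected):
        assert iupac_match(code, base) is expected

    def test_invalid_code_errors(self):
        with pytest.raises(PcrError):
            iupac_match("Z", "A")

    @pytest.mark.parametrize(
        "primer,window,expected",
        [("ATG", "ATG", 0), ("ATG", "ATC", 1), ("GGNGG", "GGAGC", 1),
         ("RYN", "GTT", 0), ("AAA", "NNN", 3)],
    )
    def test_count_mismatches(self, primer, window, expected):
        assert count_mismatches(Primer("p", primer), window) == expected

    def test_window_length_mismatch_errors(self):
        with pytest.raises(PcrError):
            count_mismatches(Primer("p", "ATG"), "ATGC")


class TestPlantedConstructs:
    def test_exact_construct_yields_single_hit_with_expected_product(self):
        rng = np.random.default_rng(1)
        inner = "".join(rng.choice(list("ACGT"), size=200))
        fwd_site = FWD.sequence.replace("N", "A").replace("R", "A").replace("Y", "C")
        rev_site = REV.sequence.replace("N", "A").replace("R", "A").replace("Y", "C")
        seq = "TTTT" + fwd_site + inner + reverse_complement(rev_site) + "TTTT"
        hits = scan_amplicons(Contig("c", seq), FWD, REV, max_mismatches=0)
        assert len(hits) == 1
        (hit,) = hits
        assert hit.product_length == len(FWD) + 200 + len(REV)
        assert hit.orientation == "plus"
        assert (hit.fwd_mismatches, hit.rev_mismatches) == (0, 0)

    def test_three_substitutions_exceed_two_mismatch_setting(self):
        fwd_site = FWD.sequence.replace("N", "A").replace("R", "A").replace("Y", "C")
        rev_site = REV.sequence.replace("N", "A").replace("R", "A").replace("Y", "C")
        # GG..TGG fixed positions: break three of them
        broken = "CC" + fwd_site[2:-3] + "ACC"
        seq = "TT" + broken + "A" * 100 + reverse_complement(rev_site) + "TT"
        assert scan_amplicons(Contig("c", seq), FWD, REV, max_mismatches=2) == []

    def test_product_length_cap(self):
        fwd_site = "ACGTACGTACGT"
        rev_site = "TTGGCCAATTGG"
        seq = fwd_site + "A" * 500 + reverse_complement(rev_site)
        fwd, rev = Primer("f", fwd_site), Primer("r", rev_site)
        assert scan_amplicons(Contig("c", seq), fwd, rev, 0, max_product=100) == []
        assert len(scan_amplicons(Contig("c", seq), fwd, rev, 0, max_product=1000)) == 1

    def test_template_n_blocks_amplification(self):
        fwd_site = "ACGTACGTACGT"
        rev_site = "TTGGCCAATTGG"
        seq = fwd_site[:-1] + "N" + "A" * 50 + reverse_complement(rev_site)
        fwd, rev = Primer("f", fwd_site), Primer("r", rev_site)
        assert scan_amplicons(Contig("c", seq), fwd, rev, 0) == []
        assert len(scan_amplicons(Contig("c", seq), fwd, rev, 1)) == 1


class TestOracleEquivalence:
    def test_equals_exhaustive_scan_on_random_contigs(self):
        rng = np.random.default_rng(7)
        for trial in range(20):
            contig = random_contig(rng, int(rng.integers(150, 500)))
            fwd = Primer("f", _random_primer(rng))
            rev = Primer("r", _random_primer(rng))
            for mm in (0, 1, 2):
                got = {_hit_key(h) for h in scan_amplicons(contig, fwd, rev, mm, 400)}
                want = oracle_scan(contig.sequence, fwd.sequence, rev.sequence, mm, 400)
                assert got == want, f"trial {trial}, mm {mm}"

    def test_mismatch_monotonicity(self):
        rng = np.random.default_rng(9)
        contig = random_contig(rng, 800)
        fwd = Primer("f", _random_primer(rng, 10))
        rev = Primer("r", _random_primer(rng, 10))
        tiers = [
            {_hit_key(h) for h in scan_amplicons(contig, fwd, rev, mm, 700)}
            for mm in (0, 1, 2, 3)
        ]
        # at higher allowances mismatch counts are recorded identically,
        # so hit keys nest
        assert tiers[0] <= tiers[1] <= tiers[2] <= tiers[3]

    def test_reverse_complement_invariance(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            contig = random_contig(rng, 400)
            fwd = Primer("f", _random_primer(rng))
            rev = Primer("r", _random_primer(rng))
            hits = scan_amplicons(contig, fwd, rev, 2, 350)
            flipped = Contig("c", reverse_complement(contig.sequence))
            mirrored = scan_amplicons(flipped, fwd, rev, 2, 350)
            n = contig.length

            def mirror(h):
                return (n - h.fwd_end + 1, n - h.fwd_start + 1,
                        n - h.rev_end + 1, n - h.rev_start + 1,
                        h.product_length, h.fwd_mismatches, h.rev_mismatches,
                        "minus" if h.orientation == "plus" else "plus")

            assert {mirror(h) for h in hits} == {_hit_key(h) for h in mirrored}


def _random_primer(rng, length=14):
    codes = list("ACGT") * 5 + list("RYSWKMN")
    return "".join(rng.choice(codes, size=length))


class TestCrosstab:
    @pytest.fixture(scope="class")
    @staticmethod
    def planted():
        config = GeneratorConfig(
            n_true=4, n_no_motif=0, n_off_contig=0, n_far_hgcb=0, n_low_score=0,
            lineages=(
                "d__Bacteria;p__Proteobacteria;c__Deltaproteobacteria;o__;f__;g__;s__",
                "d__Bacteria;p__Firmicutes;c__Clostridia;o__;f__;g__;s__",
            ),
            primer_fwd=FWD.sequence, primer_rev=REV.sequence,
            primer_target_phylum="Deltaproteobacteria",
            n_off_target_plants=1,
        )
        collection, truth = generate_collection(config, seed=21)
        hits_by_marker = generate_hit_tables(collection, truth, seed=22)
        calls = call_methylators(collection, hits_by_marker)
        from hgcscan.insilico_pcr import scan_collection

        amplicons = {mm: scan_collection(collection, FWD, REV, mm) for mm in (0, 2)}
        return collection, truth, calls, amplicons

    def test_amplification_confined_to_planted_genomes(self, planted):
        collection, truth, calls, amplicons = planted
        planted_ids = set(truth.loc[truth.primer_planted, "genome_id"])
        assert {h.genome_id for h in amplicons[0]} == planted_ids

    def test_crosstab_counts_and_on_target_flags(self, planted):
        collection, truth, calls, amplicons = planted
        table = crosstab_amplification(amplicons, collection, calls).set_index("phylum")
        n_delta_planted = int(truth[(truth.phylum == "Deltaproteobacteria")
                                    & truth.primer_planted].shape[0])
        assert table.loc["Deltaproteobacteria", "n_amplified_mm0"] == n_delta_planted
        assert table.loc["Deltaproteobacteria", "n_on_target_mm0"] == n_delta_planted
        # the off-target plant amplifies but does not overlap the hgcA ORF
        assert table.loc["Firmicutes", "n_amplified_mm0"] == 1
        assert table.loc["Firmicutes", "n_on_target_mm0"] == 0

    def test_no_hits_gives_zero_rows_for_every_phylum(self, planted):
        collection, truth, calls, _ = planted
        table = crosstab_amplification({0: []}, collection, calls)
        assert set(table["phylum"]) == {"Deltaproteobacteria", "Firmicutes"}
        assert (table["n_amplified_mm0"] == 0).all()
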