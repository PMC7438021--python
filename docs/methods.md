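# Methods

## Screening model

A genome is called a putative mercury methylator when it carries an HgcA
profile hit passing a joint cutoff — full-sequence E-value ≤ 10⁻⁵⁰ **and**
full-sequence bit score ≥ 300, both inclusive — whose protein contains the
conserved cap-helix domain `G(I/V)NVWCAAGK` at least once. These are
deliberately stringent settings chosen so that surviving hits essentially
always carry the domain; relaxing them is a config change
(`thresholds.hgcA_max_evalue`, `thresholds.hgcA_min_score`).

A confident HgcB partner additionally requires:

- bit score strictly greater than 70 (the rule is worded as "greater than",
  so exactly 70.0 is rejected);
- the ferredoxin-binding motif `CXXCXXXC` in the protein;
- residence on the same contig as HgcA; and
- a strand-relative ORF-rank distance of 1–5 downstream of HgcA. Intervening
  genes are allowed — some experimentally verified methylators have genes
  between *hgcA* and *hgcB* — and "downstream" is defined in *hgcA*'s
  transcriptional direction, so reversing a contig changes nothing. A stricter
  same-strand requirement is available (`require_same_strand`, default off)
  but not applied by default, since strand agreement of the pair is not part
  of the rule set.

The putative ArsR-like transcriptional regulator is accepted at E ≤ 10⁻¹⁰ if
it lies immediately upstream of the *hgcAB* locus or one to two genes further
upstream; we read that as upstream rank distance ∈ {1, 2, 3} (adjacent, or up
to two intervening genes). The narrower reading {1, 2} is one config knob away
(`max_genes_upstream`). When several candidates qualify, the nearest wins,
with ties broken by score and then ORF id, deterministically.

Genomes may carry several validated HgcA ORFs; each yields its own call.
Fused HgcAB-like single ORFs are not specially detected — the same-contig /
downstream rules deliberately prefer false negatives over false positives,
and a fused gene simply yields a call without separate *hgcB* evidence.

ORF rank (`index_on_contig`) is assigned per contig by ascending start
coordinate regardless of strand, ties broken by end coordinate then id.
Annotation order in the GFF is ignored; coordinate rank is reproducible across
re-sorted files.

## Quality and grouping conventions

MAG quality gates are strict on both sides: completeness > threshold and
redundancy < threshold (so 50.0% completeness fails a ">50%" gate). The
identification stage defaults to >50/<10 (medium-quality MAG convention); the
guild profiler defaults to >90/<10 and drops taxonomic groups with five or
fewer genomes. Groups are phyla, except Deltaproteobacteria, which is
summarized at class rank (no other Proteobacteria carry the locus in practice);
the class-rank override set is configurable.

## In-silico PCR

Primers are IUPAC-degenerate 5'→3' words. A predicted product is a
forward-primer site and, downstream on the same strand, the reverse complement
of the reverse primer, each with at most the configured number of mismatches
(per primer, not summed — the commercial tools' semantics are not published,
and per-primer is the conservative reading), product span ≤ 10 kb by default.
Both template orientations are scanned and coordinates are always reported on
the plus strand. Template `N` (assembly gaps) matches only primer `N`, so
amplification is never called across gaps. All overlapping/nested products are
reported; no shortest-product collapsing. 3'-terminal anchoring (common in PCR
simulators) is off by default because the mismatch setting is a plain count;
`require_3prime_match=True` enables it. The scanner is vectorized over
template positions; tests compare it against an exhaustive all-positions/
all-strands brute-force oracle on contigs up to 5 kb.

## Guild profiling

Presence is an OR over threshold-passing hits per genome and marker. Group
summaries are percentages of genomes in the group carrying the marker.
Multi-subunit complexes (nif, nar, nir, nor, nos) are reported as the
arithmetic mean of their per-subunit group percentages; with fixed group
membership this equals averaging per-genome subunit indicators first, but the
per-subunit-percentage formulation is the one implemented. Metabolic marker
cutoffs come from the marker config (a value ≥ 1 is a curated bit-score
cutoff, < 1 an E-value cutoff, blank falls back to E ≤ 10⁻¹⁰). `hgcA` can be
included in the matrix like any other marker, making its 100% column an
internal consistency check on methylator-only collections.

## Supermatrix preparation

Per-marker amino-acid alignments are concatenated over the union of genomes;
a genome missing a marker receives an all-gap block, and a partition table
(`marker = start-end`) is emitted for tree software. Genomes must carry at
least 12 of the 16 ribosomal markers to enter the species-tree matrix. The
shipped rp16 name list is a conventional large/small-subunit ribosomal protein
selection and explicitly configurable — it is not canonical. Column masking is
a deliberately simple, fully specified stand-in for entropy-based trimmers:
drop columns with gap fraction > 0.5, then drop surviving runs shorter than
5 columns (both parameters exposed). Externally masked alignments can be
supplied when BLOSUM/entropy-based trimming is required; the masking contract
here is chosen for reproducibility, not equivalence.

## Expression summaries

Counts are ORF-level (pseudo-alignment output); TPM is computed per sample
over the union of all ORFs in the matrix (one normalization per sample, not
per genome). Lengths are annotated nucleotide lengths; no effective-length
correction is applied because the counts are gene-level, not fragment-level.
Internally lengths enter only as ratios to the minimum length, so a uniform
unit change (bp vs kb) leaves TPM bitwise identical. Samples with zero library
mass yield all-zero columns, not errors — sites with no detectable transcripts
are an expected outcome, not a failure. Phylum marker expression is the sum of
TPM over called marker ORFs in the phylum, with a per-sample grand total row;
genome-average expression is the phylum's total TPM divided by its genome
count. For the housekeeping comparison the best-scoring rpoB hit per genome is
used; genomes without one are flagged and excluded from pairs.

## Synthetic data generator

The generator emulates the study conditions end to end: 50 genomes by default
— 10 true methylators and 10 of each decoy class (broken cap-helix,
off-contig hgcB, hgcB six ORFs downstream, sub-threshold hgcA scores) — spread
across five lineages, two contigs of twelve ORFs per genome, ~100-aa ORFs as
random codon sequences (bacterial code, random synonymous codons) separated by
20–60 bp spacers. Background proteins are rejection-sampled so they contain
neither conserved motif; planted loci are therefore the only motif carriers.
True hgcB offsets are drawn from 1–5; regulators from 1–3 upstream. Hit scores
are drawn comfortably on the correct side of each cutoff (true hgcA
~U(310,400) with E ≤ 10⁻⁵⁵; the low-score class straddles the 300/10⁻⁵⁰
boundary on the rejecting side). Primer binding sites with controlled
mismatch counts overwrite template DNA inside the hgcA ORF (on-target) or on
the second contig (off-target); coding consistency is not maintained for
planted sites — translations live in the GFF — which is acceptable because the
generator does not model coding constraints at all. Counts are negative
binomial (variance μ + dμ², dispersion d = 0.5 by default, a typical
overdispersion level for metatranscriptome counts) with mean
base × phylum-multiplier × site-effect × depth-effect; phylum multipliers are
10× steps following lineage order, and palsa-labelled samples get site effect
0 to emulate no-detection sites. All randomness flows from one integer seed;
fixed (config, seed) reruns are byte-identical.

What passing tests on these data do **not** show: robustness to real profile
search score distributions, fragmented assemblies (planted loci never straddle
contig ends except by design), codon bias, strain heterogeneity, or
pseudo-alignment ambiguity. The generator validates the decision rules and
bookkeeping, not upstream inference.

## Problem sizes and numerical choices

The test suite exercises the planted-truth screen over 20 seeds × 50 genomes,
threshold monotonicity over 1,000 randomized hit tables, motif-oracle
equivalence over 10,000 random proteins × 52 motifs, PCR-oracle equivalence
over 500 random contigs (most 150–600 bp, ten at 5 kb) at mismatch settings
0–2, TPM conservation over 100 random matrices (column sums within 10⁻⁶
relative of 10⁶; group totals within 10⁻⁹), rank recovery over 100 seeds
(≥95% required), and masking agreement over 100 random alignment sets. The
full-expansion motif oracle is used for motifs with ≤ 64 expansions; the
ferredoxin motif (20⁵ expansions) is checked against a position-wise
brute-force scan instead. `scripts/acceptance.py` recomputes the same
quantities at comparable sizes in well under a minute of CPU each.
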