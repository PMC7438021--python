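# hgcscan

Genome-resolved screening for putative mercury-methylating microorganisms.

Methylmercury, a bioaccumulative neurotoxin, is produced by anaerobic bacteria
and archaea carrying the *hgcAB* gene pair: *hgcA* encodes a corrinoid-dependent
putative methyltransferase and *hgcB* a 2[4Fe-4S] ferredoxin. Because the locus
has spread by horizontal transfer, methylation potential cannot be read off
16S/ribosomal phylogeny — it has to be established genome by genome. `hgcscan`
implements the screening pipeline used for that purpose on collections of
isolate genomes and metagenome-assembled genomes (MAGs):

- **Marker filtering** — profile-HMM hit tables (hmmsearch `--tblout` or a
  simple TSV dialect) filtered by the screening rules: HgcA requires
  E ≤ 10⁻⁵⁰ **and** bit score ≥ 300; HgcB requires score > 70; the putative
  ArsR-like regulator requires E ≤ 10⁻¹⁰.
- **Motif validation** — HgcA hits must contain the conserved cap-helix domain
  `G(I/V)NVWCAAGK`; HgcB hits must contain the ferredoxin-binding motif
  `CXXCXXXC`.
- **Synteny rules** — a confident *hgcB* must lie on the same contig, within
  five ORFs downstream of *hgcA* (strand-relative rank distance, intervening
  genes allowed); the regulator immediately upstream or 1–2 genes further.
- **In-silico PCR** — mismatch-tolerant scanning of IUPAC-degenerate primer
  pairs (e.g. broad-range and clade-specific *hgcA* qPCR primers) across
  contigs, with per-phylum amplification/on-target cross-tabulation.
- **Guild profiling** — genome × metabolic-marker presence/absence matrices
  (sulfur, nitrogen, carbon cycling, metal resistance) summarized as per-group
  percentages, averaging multi-subunit complexes (*nif*, *nar*, *nir*, *nor*,
  *nos*).
- **Phylogenetic prep** — concatenated ribosomal-protein (rp16) supermatrices
  with a 12-of-16 completeness rule, gap/block column masking and partition
  files; alignment and tree inference stay external (MAFFT/MUSCLE, RAxML).
- **Expression** — TPM normalization of ORF-level metatranscriptome counts
  (per sample, TPMᵢ = 10⁶ · (cᵢ/ℓᵢ) / Σⱼ(cⱼ/ℓⱼ)), per-phylum *hgcA/hgcB*
  totals, per-phylum genome-averaged expression, and *hgcA*-vs-*rpoB*
  housekeeping comparisons.
- **Synthetic data** — a seeded generator of genome collections with planted
  true loci and decoy classes (broken cap-helix, off-contig *hgcB*,
  *hgcB* six ORFs away, sub-threshold scores), primer constructs with
  controlled mismatches, and negative-binomial count matrices with planted
  phylum/depth structure — so the whole pipeline is testable offline.

## Worked example

Simulate a 50-genome collection (10 true methylators, 10 of each decoy class
across five lineages), then identify methylators, test a broad-range primer
pair and summarize expression:

```bash
cat > config.yaml <<'EOF'
seed: 7
paths:
  genome_dir: sim/genomes
  metadata: sim/metadata.tsv
  hits_dir: sim/hits
  counts: sim/counts.tsv
  calls: out_identify/methylator_calls.tsv
  primers: primers.tsv
simulate:
  primer_fwd: GGNRTNAAYGTNTGGTGYGC
  primer_rev: TGYGCNGCNGGNAARATGAA
  primer_target_phylum: Deltaproteobacteria
  n_off_target_plants: 2
EOF
printf 'name\tfwd_seq\trev_seq\ttarget_group\nbroadA\tGGNRTNAAYGTNTGGTGYGC\tTGYGCNGCNGGNAARATGAA\tDeltaproteobacteria\n' > primers.tsv

hgcscan simulate -c config.yaml -o sim
hgcscan identify -c config.yaml -o out_identify
hgcscan pcr      -c config.yaml -o out_pcr
hgcscan express  -c config.yaml -o out_express
```

which prints:

```
simulated 50 genomes into sim
30 methylator loci in 30 genomes (10 with confident hgcB, 10 with regulator)
scanned 1 primer pairs at settings [0, 2]
normalized 1200 ORFs x 6 samples
```

30 genomes are called: the 10 true methylators (each with hgcB and regulator
evidence) plus the off-contig and distance-6 decoys, which carry a valid
motif-bearing *hgcA* but — correctly — no confident *hgcB*. The broken-motif
and sub-threshold decoys are rejected outright. The primer cross-tab
(`out_pcr/amplification_crosstab.tsv`) shows the planted specificity — the
Deltaproteobacteria-targeted pair amplifies 8 Deltaproteobacteria genomes
(6 overlapping the called *hgcA* ORF) and picks up the two planted off-target
sites in other phyla:

```
primer_pair  phylum               n_genomes  n_hgcA_genomes  n_amplified_mm0  n_on_target_mm0 ...
broadA       Actinobacteria       10         6               0                0
broadA       Bacteroidetes        10         6               1                0
broadA       Deltaproteobacteria  10         6               8                6
broadA       Firmicutes           10         6               1                0
broadA       Verrucomicrobia      10         6               0                0
```

`out_express/hgcA_expression_by_group.tsv` holds per-phylum summed *hgcA* TPM
per sample plus a per-sample grand total; palsa-like samples with no planted
transcription come out as all-zero columns rather than errors.

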