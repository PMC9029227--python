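# sexmir

A small-RNA analysis pipeline for finding **sex-biased microRNAs in
dioecious plant flowers**, built as a reusable, fully tested Python package.
It covers the complete path from raw small-RNA sequencing reads to candidate
sex-determination miRNAs:

1. **Read filtering** — six ordered rules (quality, 3'/5' adapters, null
   inserts, poly(A), minimum length) turn raw reads into *clean tags* with
   exact per-category accounting.
2. **Tag annotation** — removal of rRNA/scRNA/snoRNA/snRNA/tRNA fragments
   (ungapped identity > 97%), mRNA degradation fragments (gene-body
   overlap), and repeat-derived tags; exact matching against a mature miRNA
   reference identifies known miRNAs.
3. **Novel miRNA discovery** — exact genome mapping, hairpin-precursor
   excision, minimum-free-energy folding under a documented stacking energy
   model, and eleven precursor criteria (length bounds, copy number ≤ 20,
   precursor MFE ≤ −18 kcal/mol, miRNA/miRNA* spacing 16–300 nt, bulge ≤ 4,
   asymmetry ≤ 4, 20 nt flanks).
4. **Expression analysis** — TPM normalization
   (`TPM = count / total clean tags × 10⁶`) and exact count-based
   differential expression between pooled conditions using the
   Audic–Claverie statistic

   ```
   p(y|x) = (N₂/N₁)ʸ · (x+y)! / (x!·y!) · (1 + N₂/N₁)^-(x+y+1)
   ```

   with lower/upper tail sums C and D and two-sided p = min(1, 2·min(C, D)).
   A miRNA is differentially expressed at fold change ≥ 2 and p < 0.05.
5. **Sex-bias classification** — a miRNA is *sex-biased* when it is DE with
   a consistent direction in all three female/male flower stage pairs
   (FNS/M03, FNB/M05, FYS/M10), and *sex-specific* when additionally silent
   (TPM < 1) in every sample of the other sex. miRNAs are also assigned to
   chromosomes so candidates on the sex chromosome (chr4) can be singled out.
6. **Target prediction** — plant-style ungapped duplex scanning with six
   rules (≤ 4 mismatches with G:U = 0.5, no runs > 2, positional seed
   constraints, duplex MFE ≥ 74% of the perfect-complement MFE), followed by
   antagonistic pairing of sex-biased miRNAs with oppositely biased target
   genes.

Because deposited sequencing data cannot ship with a package, a first-class
**synthetic-data module** generates a complete miniature study — genome with
planted compliant hairpins and single-violation decoys, ncRNA references,
gene models, repeats, transcriptome with planted target sites, and
per-sample FASTQ reads with known contaminant categories and sex-dependent
fold changes — together with a machine-readable truth file, so every stage
has an exact oracle.

## Worked example

Write a small study configuration and run the whole pipeline:

```yaml
# small.yaml
seed: 3
chromosomes: [[chr1, 30000], [chr2, 30000], [chr3, 30000], [chr4, 30000]]
n_planted_hairpins: 10
n_decoy_loci: 10
n_known: 4
depth: 5000
category_counts: {low_quality: 100, adapter3_null: 80, adapter5_contaminant: 50,
                  insert_null: 50, polyA: 100, shorter_than_min: 200}
ncrna_fragment_reads: 300
degradation_fragment_reads: 200
repeat_fragment_reads: 100
expression_model: {n_female_biased: 2, n_male_biased: 2,
                   n_female_specific: 1, n_male_specific: 1}
error_rate: 0.0
n_transcripts: 20
```

```bash
sexmir run --config small.yaml --out demo
```

prints

```json
{
  "antagonistic_pairs": 6,
  "clean_reads": 79560,
  "de_counts": {"FNB/M05": 6, "FNS/M03": 6, "FYS/M10": 6},
  "known_mirnas": 4,
  "novel_mirnas": 6,
  "raw_reads": 90000,
  "rejected_loci": 13,
  "samples": 18,
  "sex_biased": 6,
  "sex_chromosome_de_FNS_M03": 3,
  "sex_specific": 2,
  "target_sites": 9,
  "unique_tags": 116
}
```

Reading the numbers: 18 samples of 5,000 reads each were simulated; 79,560
of 90,000 reads survive filtering (the 580 planted contaminants per sample
are removed, category by category). All 4 known and all 6 novel planted
miRNAs are recovered while the 10 decoy loci are rejected with named
criterion violations. The 6 planted sex-biased miRNAs (2 female-biased,
2 male-biased, 1 female-specific, 1 male-specific) are exactly the 6 DE
calls in each stage pair, 3 of them reside on the sex chromosome in the
FNS/M03 comparison, and each pairs antagonistically with its planted
opposite-bias target gene — 6 miRNA–target pairs. Result tables are under
`demo/results/` (filter report, counts, TPM, per-pair DE, sex-bias calls,
chromosome residency, target sites, pairs).

`sexmir simulate` writes just the synthetic study (FASTA/GFF3/BED/FASTQ and
`truth.json`); `sexmir filter` cleans a single FASTQ into collapsed tags.
The per-stage operations (annotation, discovery, quantification, DE,
classification, target scanning) are the library API — see
`sexmir.annotation`, `sexmir.discovery`, `sexmir.expression`,
`sexmir.targets`.

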