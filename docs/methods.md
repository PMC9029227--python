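# Methods

This note documents the models, rules and numerical conventions the
package implements, the design choices made where several readings were
possible, and what the synthetic data does and does not establish.

## Read filtering

Raw single-end small-RNA reads pass a fixed cascade; each removed read is
attributed to the **first** rule it trips:

1. *low quality* — more than `max_low_quality_bases` (default 1) bases at
   Phred ≤ 20, or any `N`;
2. *3' adapter null* — the 3' adapter is located by the earliest occurrence
   of its first 8 nt allowing one mismatch, scanning from read position 0;
   no hit means no insert boundary and the read is dropped;
3. *5' adapter contaminant* — the full 5' adapter contained verbatim in the
   trimmed insert;
4. *insert null* — the 3' adapter starts at position 0 (adapters ligated
   back to back);
5. *poly(A)* — insert A fraction strictly greater than 0.70;
6. *short* — insert below 18 nt.

The adapter seed is searched from position 0 (not from the minimum insert
length): an adapter at position 0 is the definition of an empty insert, and
inserts of 1–17 nt can only be recognized as "short" if the adapter may be
found inside the first 18 bases. An optional `max_insert_length` exists but
defaults to off, because the report has no category for over-long inserts
and a default cap would break the exact conservation identity
`input reads = Σ removal categories + clean reads`, which filtering
guarantees and the tests assert. "Re-filtering removes nothing" holds in
the sense that every surviving insert, re-adapted and re-submitted,
classifies as clean again.

Two implementations exist on purpose: a vectorized batch filter (the
pipeline path) and a scalar single-read classifier used by the read
generator; a property test drives random reads through both and requires
identical partitions.

## Tag annotation

Precedence is fixed: `ncRNA > degradation > repeat > known miRNA >
unannotated`; every tag receives exactly one label, so label counts
partition the tag set. ncRNA matching is an ungapped end-to-end alignment
of the tag against reference windows with identity strictly above 0.97; for
tags of ≤ 33 nt this permits zero mismatches, so it reduces to exact
substring search (the general mismatch path exists for longer queries).
GenBank-style and Rfam-style references are supplied as one merged
reference set per class; classes are tried in the order rRNA, scRNA,
snoRNA, snRNA, tRNA. Degradation requires ≥ 1 bp overlap of any exact
genomic locus with a gene body (exons and introns both lie inside the gene
span) on either strand. A multi-locus tag is labelled *repeat* only when
**all** its loci fall in repeat intervals — one genic copy keeps a tag
eligible for discovery. Known-miRNA matching is zero-mismatch anchored
containment with the tag length within ±2 nt of the reference, which admits
exactly-contained length isomiRs and nothing else.

## Energy model and folding

The package uses one simplified stacking model everywhere (precursor
folding, duplex energies, target MFE ratios): G:C −3.0, A:U −2.0, G:U −1.0
kcal/mol **as stacking contributions** — a pair earns its table value when
the pair immediately inside it is also formed, and the isolated value
−1.0 kcal/mol otherwise (so a helix of k pairs scores the sum of its k−1
outer stack terms plus −1.0 for the innermost pair). Hairpin loops must
span ≥ 3 nt; there are no loop, terminal or dangling penalties. Folding is
an exact dynamic programme over this model (three tables: paired,
unconstrained, pair-excluded), with deterministic traceback preferring
pairs with smaller 5' indices. A full thermodynamic (Turner-parameter)
folder is deliberately out of scope: the simple model keeps the hairpin
criteria meaningful, is exhaustively testable (the tests enumerate *all*
nested structures of short random RNAs and require energy equality), and
makes the −18 kcal/mol precursor threshold a documented, configurable
convention of this model rather than an opaque import. Model symmetry: the
minimum energy is invariant under sequence reversal (G:U maps to U:G);
reverse-complement invariance holds only without wobbles, since a G:U pair
reverse-complements to the unpairable A:C.

"Maximal free energy 18 kcal/mol" is read as a stability bound: the
precursor MFE must be ≤ −18 kcal/mol (stable hairpins have negative
energies).

## Hairpin criteria and precursor evaluation

For each genome locus of an unannotated tag, excision windows grow through
a ladder (96, 192, then `max_star_space + tag + flank` nt) on either side;
each window is folded and the miRNA\* is located from the pair table as the
span of the mature's pairing partners, shifted 2 nt toward its 3' end for
the canonical 2 nt 3' overhang. Eleven criteria are scored: mature length
18–25 nt, star length 20–23 nt (the "reference sequence length" bounds are
applied to the recovered star), genomic copy number ≤ 20, precursor MFE ≤
−18 kcal/mol (refolded over the arm span plus 20 nt flanks), mature/star
spacing 16–300 nt, longest unpaired run in the duplex ≤ 4 nt on either
strand, duplex asymmetry ≤ 4 nt, and availability of the 20 nt flanks.
Unpaired mature bases count toward bulge and asymmetry over the whole
mature (only the canonical 2 nt 3' overhang may dangle): without this, a
mature paired at only a few bases could present a tiny, clean "duplex" and
pass. Asymmetry is the **sum over the duplex's internal loops of the
difference between their mature-side and star-side lengths** (plus mature
edge overhangs), not the global difference of unpaired totals: a clean
duplex with symmetric loops scores 0 either way, but a mature scattering
a handful of incidental pairs across a random window accumulates
asymmetric loops and fails — under the global-difference reading such
regions can balance out and slip through all eleven criteria, with the
precursor energy carried by structure unrelated to the hairpin. The
per-loop sum also matches how stem-loop evaluation tools of this family
penalize duplex distortion. The first ladder step that yields a fully compliant
candidate wins (best energy among its candidates); otherwise the rejection
with the fewest violated criteria (earliest window on ties) is reported, so
a rejection names every violated criterion.

Tags whose accepted precursors overlap on the genome are merged into one
hairpin regardless of strand — a perfect hairpin is an inverted repeat, so
the same locus is legitimately recovered from both strands — with the most
abundant tag as mature and counts aggregated over distinct member tags.
Novel ids (`novel-m{N}-{5p|3p}`) are assigned in genome order; both arms,
when both are expressed, keep distinct ids.

## Exact count test and differential expression

The Audic–Claverie statistic conditions one observed count on the other:
`p(y|x) = (N₂/N₁)ʸ (x+y)!/(x!y!) (1+N₂/N₁)^−(x+y+1)`. Both tails are
accumulated by direct summation of log-gamma terms — the upper tail
truncated once its geometric remainder is negligible — so small tail masses
retain full relative precision (no `1 − Σ` cancellation). The two-sided
p-value is `min(1, 2·min(C, D))`.

**Conditioning convention.** Conditioning always on `x` makes the verdict
depend on which group is listed first (the two tails are not symmetric
under swapping the conditioned side). The package therefore conditions on
the side with the larger count (ties: larger library, then condition 1) and
maps the tails back to the caller's orientation; the p-value is then
*exactly* invariant under exchanging the two conditions, which is the
behaviour a two-group comparison should have. The tests verify both the
symmetry and agreement with brute-force summation of the printed formula
under this convention.

Replicates are pooled by summation before testing (the statistic is defined
for one count per condition; pooling matches its original usage);
per-replicate dispersion modelling is out of scope. Fold change is computed
on pooled TPM; when either group is zero, a pseudo-TPM of 0.01 is added to
both groups only, keeping infinite-fold (sex-specific) cases callable.
Significance is |log₂ FC| ≥ 1 and p < 0.05, with no multiple-testing
correction by default (a hook exists in the thresholds). The test is
anti-conservative under overdispersion; with pure Poisson nulls its type-I
error sits near the nominal level (measured ≈ 0.045–0.051 at 10,000 nulls).

Sex-biased = significantly DE with the same direction in **all three**
stage pairs (the Venn intersection); sex-specific additionally requires
TPM < 1 (default `presence_threshold`) in every sample of the other sex —
the threshold is a package convention, since "specific expression" has no
standard numeric definition. The 2^−ΔΔCt helper implements
ΔCt = Ct_target − Ct_reference per condition, ΔΔCt = ΔCt_treated −
ΔCt_control.

## Target rules

Sites are ungapped antiparallel duplexes: miRNA position 1 (5' end) faces
the window's 3'-most base. G:U wobbles contribute 0.5 to the scored rules
(total ≤ 4.0; positions 1–12 ≤ 2.5) but are **not** mismatches for the
adjacency and forbidden-position rules (no run > 2 anywhere; no adjacent
pair within 2–12; none at 10–11): weighting by 0.5 is defined for mismatch
*counts*, and treating wobbles as hard mismatches at 10–11 would reject
canonical plant sites. `strict_wobble` switches to the harsher reading.
The MFE ratio is |duplex energy| / |perfect-complement energy| under the
shared stacking model, threshold 0.74. Gapped duplexes (target bulges) are
out of scope — the rules are positional over a fixed-length duplex.
Antagonistic pairing keeps exactly female-biased/-specific miRNA →
male-biased gene and vice versa, with gene bias supplied externally.

## Synthetic data: what it emulates

The default configuration mirrors the study design the package targets:
2 sexes × 3 flower stages × 3 replicates (FNS/FNB/FYS vs M03/M05/M10), a
designated sex chromosome (chr4) hosting a configurable share of hairpins,
50 compliant hairpins (12 entering the known-miRNA reference) plus 200
decoys, and 200,000 reads per sample of which ~4% are planted contaminants
(roughly the contaminant fraction real runs of this kind report) and 8,000
are ncRNA/degradation/repeat fragments. Expression is gamma-Poisson:
gamma baselines per miRNA, a gamma replicate multiplier (variance 0.05),
multinomial allocation so per-sample totals are exact; 22 miRNAs carry
4-fold sex bias (8 female-, 8 male-biased, 3 + 3 sex-specific with zero
expression in the other sex). Errors are substitution-only at 0.001/base;
error reads are constrained to remain clean under the filters and not to
map exactly anywhere on the genome — the behaviour real substitution errors
have with overwhelming probability — so mapped tag sets stay exactly the
planted ones. Depth, rates and panel sizes are configurable; the defaults
were chosen once as a desk-scale rendition of the study design.

Every planted construct is verified at generation time with the same
evaluator the pipeline runs (compliant hairpins must pass all eleven
criteria; each decoy must fail, naming its designed criterion) and
re-sampled until it does. Decoy classes: no stable hairpin, spacing
> 300 nt, bulge > 4 nt (a 5×5 internal loop, so asymmetry stays 0),
asymmetry > 4 nt (two 4 nt star-side bulges), and precursor energy above
threshold. The energy decoys are built G-free with C-only flanks so only
their seven isolated A:U pairs can form, bounding the MFE above −18 by
construction. Contaminant reads are constructed—and verified—to trip
exactly one filter rule each.

**What passing does not show.** The generator draws contaminants and
fragments from the same distributions the filters test, reads have uniform
high quality, no indels, no adapter truncation, no isomiR/length
heterogeneity beyond exact matures, and hairpin decoys violate one
criterion cleanly rather than ambiguously. Perfect recall and exact
accounting on this data demonstrate correctness of the implemented rules,
not performance on real libraries with correlated errors, partial adapters
or borderline hairpins.

## Numerical and determinism conventions

All coordinates are 0-based half-open internally; GFF3 output is 1-based
inclusive, BED 0-based half-open. FASTA is wrapped at 70 columns. All
randomness flows from a single integer seed through separated
`SeedSequence` streams (genome, baselines, one per sample); iteration
orders are sorted or design-ordered, never over unordered sets. Two runs of
the full pipeline at the same configuration are byte-identical, which the
acceptance suite asserts. Problem sizes in the test suite (exact-test grid
x, y ≤ 100; folding oracle at ≤ 14 nt; 10,000-null calibration; the
50 + 200 discovery benchmark; full pipeline at 18 × 200k reads) are the
package's chosen desk-scale study conditions.

## Known limitations

- The energy model is intentionally minimal; absolute kcal/mol values are
  not comparable with Turner-model folders, and the −18 kcal/mol bound is
  calibrated to this model.
- Known-miRNA matching does not quantify isomiRs separately; variants
  collapse onto their reference id.
- The exact test on pooled counts ignores biological replicate variance;
  with strong overdispersion its p-values are optimistic.
- Target scanning is ungapped; bulged target sites are invisible.
- BLAST/Rfam covariance search, RepeatMasker and patmatch internals are
  replaced by the documented identity/interval/duplex rules operating on
  user-supplied references.
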