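"""End-to-end pipeline: simulate -> filter -> annotate -> discover ->
quantify -> differential expression -> sex-bias calls -> targets.

`run_pipeline` drives every stage on a synthetic study configuration and
writes all result tables under an output directory with deterministic
content, so two runs with the same configuration are byte-identical.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path

import pandas as pd

from . import io as sio
from .annotation import ReferenceSet, annotate_tags
from .discovery import build_genome_index, map_tags, call_novel, assign_chromosome
from .expression import (
    CountMatrix, STAGE_PAIRS, tpm_normalize, call_de, classify_sex_bias,
    filter_sex_chromosome,
)
from .read_processing import filter_reads, report_frame
from .synthetic_data import (
    SyntheticSpec, generate_genome, generate_reads, write_truth,
)
from .targets import TargetRuleParams, scan_targets, pair_sex_biased

__all__ = ["simulate", "run_pipeline"]


def simulate(spec: SyntheticSpec, out_dir: str | Path) -> Path:
    """Generate the full synthetic study (references, reads, truth) on disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, gff, repeats, refs, truth = generate_genome(spec)

    sio.write_fasta(genome, out / "genome.fa")
    sio.write_gff3(gff, out / "genes.gff3")
    sio.write_bed(repeats, out / "repeats.bed")
    for cls in sorted(refs["ncrna"]):
        sio.write_fasta(refs["ncrna"][cls], out / f"ncrna_{cls}.fa")
    sio.write_fasta(refs["mature_mirnas"], out / "mature_mirnas.fa")
    sio.write_fasta(refs["transcripts"], out / "transcripts.fa")
    pd.Series(refs["gene_bias"], name="bias").rename_axis("gene").to_csv(
        out / "gene_bias.tsv", sep="\t")

    reads_dir = out / "reads"
    reads_dir.mkdir(exist_ok=True)
    generate_reads(spec, truth, reads_dir, genome=genome)
    write_truth(truth, out / "truth.json")
    return out


def run_pipeline(spec: SyntheticSpec, out_dir: str | Path) -> dict:
    """Run every stage on a synthetic study; returns a summary dictionary."""
    out = Path(out_dir)
    sim_dir = out / "sim"
    res_dir = out / "results"
    res_dir.mkdir(parents=True, exist_ok=True)
    simulate(spec, sim_dir)

    genome = sio.read_fasta(sim_dir / "genome.fa")
    gene_models = sio.read_gff3_genes(sim_dir / "genes.gff3")
    repeats = sio.read_bed(sim_dir / "repeats.bed")
    mature_ref = sio.read_fasta(sim_dir / "mature_mirnas.fa")
    transcripts = sio.read_fasta(sim_dir / "transcripts.fa")
    gene_bias = pd.read_csv(sim_dir / "gene_bias.tsv", sep="\t",
                            index_col=0)["bias"].to_dict()
    ncrna = {}
    for cls in ("rRNA", "scRNA", "snoRNA", "snRNA", "tRNA"):
        p = sim_dir / f"ncrna_{cls}.fa"
        if p.exists():
            ncrna[cls] = sio.read_fasta(p)

    samples = [s for s, _ in spec.samples]
    fp = spec.filter_params()

    # --- filter and collapse ------------------------------------------------
    reports = {}
    per_sample_counts: dict[str, Counter] = {}
    for sample in samples:
        reads = sio.iter_fastq(sim_dir / "reads" / f"{sample}.fastq")
        inserts, report = filter_reads(reads, fp)
        reports[sample] = report
        per_sample_counts[sample] = Counter(inserts)
    rep_df = report_frame(reports)
    rep_df.to_csv(res_dir / "filter_report.tsv", sep="\t")

    tag_counts: dict[str, dict[str, int]] = {}
    for sample in samples:
        for seq, c in per_sample_counts[sample].items():
            tag_counts.setdefault(seq, {})[sample] = c

    # --- annotate -------------------------------------------------------------
    refs = ReferenceSet(ncrna=ncrna, mature_mirnas=mature_ref, genome=genome,
                        gene_models=gene_models, repeats=repeats)
    index = build_genome_index(genome)
    loci = map_tags(sorted(tag_counts), genome, index=index)
    annotations, known_counts = annotate_tags(tag_counts, refs, loci)

    label_totals = Counter(a.label.split(":")[0] for a in annotations.values())
    pd.Series(dict(sorted(label_totals.items())), name="tags").rename_axis(
        "label").to_csv(res_dir / "annotation_summary.tsv", sep="\t")

    # --- novel discovery --------------------------------------------------------
    unann = {t: tag_counts[t] for t, a in annotations.items()
             if a.label == "unannotated"}
    novel, rejections = call_novel(unann, genome, spec.mireap,
                                   loci={t: loci[t] for t in unann}, index=index)
    sio.write_fasta({nm.id: nm.candidate.mature for nm in novel},
                    res_dir / "novel_mature.fa")
    sio.write_gff3(
        [(nm.candidate.precursor_locus.chromosome, "sexmir", "miRNA_primary_transcript",
          nm.candidate.precursor_locus.start, nm.candidate.precursor_locus.end,
          nm.candidate.precursor_locus.strand, f"ID={nm.id}") for nm in novel],
        res_dir / "novel_precursors.gff3")

    # --- count matrix -------------------------------------------------------------
    rows = {}
    for mid in sorted(known_counts):
        rows[mid] = known_counts[mid]
    for nm in novel:
        rows[nm.id] = nm.candidate.counts
    counts = pd.DataFrame(
        [[rows[m].get(s, 0) for s in samples] for m in rows],
        index=list(rows), columns=samples, dtype=int)
    totals = {s: int(reports[s].clean_reads) for s in samples}
    groups = {f"{g}-{r}": g for g, _x, n in spec.sample_design for r in range(1, n + 1)}
    cm = CountMatrix(counts=counts, totals=totals, groups=groups)
    counts.to_csv(res_dir / "counts.tsv", sep="\t")
    tpm = tpm_normalize(cm)
    tpm.round(4).to_csv(res_dir / "tpm.tsv", sep="\t")

    # --- DE + sex-bias classification ----------------------------------------------
    de_tables = {}
    for pair in STAGE_PAIRS:
        de = call_de(cm, pair[0], pair[1])
        de_tables[pair] = de
        de.to_csv(res_dir / f"de_{pair[0]}_vs_{pair[1]}.tsv", sep="\t")
    calls = classify_sex_bias(de_tables, tpm, groups)
    calls_df = pd.DataFrame(
        [(c.mirna, c.label) for c in calls], columns=["mirna", "label"]
    ).set_index("mirna")
    calls_df.to_csv(res_dir / "sex_bias.tsv", sep="\t")

    # --- chromosome residency --------------------------------------------------------
    known_seqs = {mid: mature_ref[mid] for mid in mature_ref}
    chrom_of, _multi = assign_chromosome(novel, known_seqs, genome, index=index)
    pd.Series(dict(sorted(chrom_of.items())), name="chromosome").rename_axis(
        "mirna").to_csv(res_dir / "chromosomes.tsv", sep="\t")
    sex_de = filter_sex_chromosome(de_tables[STAGE_PAIRS[0]][
        de_tables[STAGE_PAIRS[0]]["significant"]], chrom_of, spec.sex_chromosome,
        known_chromosomes=set(genome))
    sex_de.to_csv(res_dir / "sex_chromosome_de_FNS_M03.tsv", sep="\t")

    # --- target prediction --------------------------------------------------------------
    biased = [c for c in calls if c.label != "none"]
    mirna_seq = {}
    for c in biased:
        if c.mirna in mature_ref:
            mirna_seq[c.mirna] = mature_ref[c.mirna]
        else:
            for nm in novel:
                if nm.id == c.mirna:
                    mirna_seq[c.mirna] = nm.candidate.mature
    sites = []
    rp = TargetRuleParams()
    for mid in sorted(mirna_seq):
        for tid in sorted(transcripts):
            sites.extend(scan_targets(mid, mirna_seq[mid], tid, transcripts[tid], rp))
    pairs = pair_sex_biased(sites, calls, gene_bias)
    site_rows = [(s.mirna_id, s.transcript_id, s.position,
                  s.alignment.mismatch_score, round(s.alignment.mfe_ratio, 4))
                 for s in sites]
    pd.DataFrame(site_rows, columns=["mirna", "gene", "position", "score", "mfe_ratio"]
                 ).to_csv(res_dir / "target_sites.tsv", sep="\t", index=False)
    pd.DataFrame([(p.mirna_id, p.mirna_label, p.gene_id, p.gene_label, len(p.sites))
                  for p in pairs],
                 columns=["mirna", "mirna_bias", "gene", "gene_bias", "n_sites"]
                 ).to_csv(res_dir / "antagonistic_pairs.tsv", sep="\t", index=False)

    summary = {
        "samples": len(samples),
        "clean_reads": int(rep_df["clean_reads"].sum()),
        "raw_reads": int(rep_df["raw_reads"].sum()),
        "unique_tags": len(tag_counts),
        "known_mirnas": int(len(known_counts)),
        "novel_mirnas": len(novel),
        "rejected_loci": len(rejections),
        "de_counts": {f"{a}/{b}": int(de_tables[(a, b)]["significant"].sum())
                      for a, b in STAGE_PAIRS},
        "sex_biased": sum(1 for c in calls if c.label != "none"),
        "sex_specific": sum(1 for c in calls if c.label.endswith("specific")),
        "target_sites": len(sites),
        "antagonistic_pairs": len(pairs),
        "sex_chromosome_de_FNS_M03": int(len(sex_de)),
    }
    return summary
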