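"""Pre-classification of clean tags before miRNA discovery.

Each tag receives exactly one label, with fixed precedence:

``ncRNA:<class>`` > ``degradation`` > ``repeat`` > ``known_mirna:<id>`` >
``unannotated``

* ncRNA: ungapped end-to-end alignment of the tag against any reference of
  the class with identity strictly above ``min_identity`` (default 0.97 —
  for tags up to 33 nt this permits zero mismatches, so matching reduces to
  exact substring search). Classes are tried in the conventional listing
  order rRNA, scRNA, snoRNA, snRNA, tRNA.
* degradation: any exact genomic locus of the tag overlaps a gene body
  (exon or intron) by at least 1 bp on either strand.
* repeat: every exact genomic locus of the tag falls inside a repeat
  interval (a single non-repeat locus keeps the tag eligible).
* known miRNA: zero-mismatch anchored containment against a mature miRNA
  reference, with the tag length within +/-2 nt of the reference length
  (length-variant isomiRs are accepted only when contained exactly).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .discovery import GenomeLocus

__all__ = [
    "ReferenceSet",
    "TagAnnotation",
    "classify_ncrna",
    "remove_degradation",
    "mask_repeats",
    "match_known",
    "annotate_tags",
]

logger = logging.getLogger(__name__)

NCRNA_CLASS_ORDER = ("rRNA", "scRNA", "snoRNA", "snRNA", "tRNA")


@dataclass
class ReferenceSet:
    """Reference sequences and annotations used for tag classification."""

    ncrna: dict[str, dict[str, str]] = field(default_factory=dict)
    mature_mirnas: dict[str, str] = field(default_factory=dict)
    genome: dict[str, str] = field(default_factory=dict)
    gene_models: list[tuple] = field(default_factory=list)  # (chrom, start, end, strand, gid)
    repeats: list[tuple] = field(default_factory=list)      # (chrom, start, end)


@dataclass
class TagAnnotation:
    tag: str
    label: str
    evidence: str = ""


def _substring_index(refs: dict[str, str], lengths: set[int]) -> dict[str, str]:
    """Map every reference substring of the given lengths to its source id."""
    idx: dict[str, str] = {}
    for rid in sorted(refs):
        seq = refs[rid].upper().replace("U", "T")
        for L in sorted(lengths):
            for p in range(len(seq) - L + 1):
                idx.setdefault(seq[p:p + L], rid)
    return idx


def _ungapped_best_identity(tag: str, ref: str) -> tuple[float, str | None]:
    """Best end-to-end ungapped identity of ``tag`` against windows of ``ref``."""
    L = len(tag)
    best, best_pos = -1.0, None
    for p in range(len(ref) - L + 1):
        window = ref[p:p + L]
        matches = sum(a == b for a, b in zip(tag, window))
        ident = matches / L
        if ident > best:
            best, best_pos = ident, p
    return best, best_pos


def classify_ncrna(
    tags: list[str],
    refs: ReferenceSet,
    min_identity: float = 0.97,
) -> dict[str, TagAnnotation]:
    """Label tags matching structural/housekeeping ncRNA references.

    A tag is ``ncRNA:<class>`` when it aligns end-to-end (ungapped) to a
    reference of the class with identity strictly greater than
    ``min_identity``; ties across classes follow :data:`NCRNA_CLASS_ORDER`.
    """
    out: dict[str, TagAnnotation] = {}
    lengths = {len(t) for t in tags}
    classes = [c for c in NCRNA_CLASS_ORDER if c in refs.ncrna] + sorted(
        set(refs.ncrna) - set(NCRNA_CLASS_ORDER))
    for cls in classes:
        seqs = refs.ncrna[cls]
        if not seqs:
            logger.warning("ncRNA class %s has no reference sequences; skipped", cls)
            continue
        # mismatch budget per tag length under strict-inequality identity
        budgets = {L: math.ceil(L * (1.0 - min_identity)) - 1 for L in lengths}
        exact_only = all(b <= 0 for b in budgets.values())
        if exact_only:
            idx = _substring_index(seqs, lengths)
            for tag in tags:
                if tag in out:
                    continue
                rid = idx.get(tag.upper().replace("U", "T"))
                if rid is not None:
                    out[tag] = TagAnnotation(tag, f"ncRNA:{cls}",
                                             f"{rid} identity=1.000")
        else:
            for tag in tags:
                if tag in out:
                    continue
                for rid in sorted(seqs):
                    ident, _ = _ungapped_best_identity(
                        tag.upper().replace("U", "T"),
                        seqs[rid].upper().replace("U", "T"))
                    if ident > min_identity:
                        out[tag] = TagAnnotation(tag, f"ncRNA:{cls}",
                                                 f"{rid} identity={ident:.3f}")
                        break
    return out


def _build_trees(intervals: list[tuple]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        chrom, start, end = iv[0], int(iv[1]), int(iv[2])
        if end > start:
            trees.setdefault(chrom, IntervalTree()).addi(start, end, iv)
    return trees


def remove_degradation(
    tags: list[str],
    loci: dict[str, list[GenomeLocus]],
    gene_models: list[tuple],
) -> dict[str, TagAnnotation]:
    """Label tags overlapping gene bodies as mRNA degradation fragments.

    ``gene_models`` rows are ``(chrom, start, end, strand, gene_id)`` gene
    spans (0-based half-open); exons and introns are both inside the span.
    Overlap of >= 1 bp at any exact locus, on either strand, triggers the
    label.
    """
    trees = _build_trees([(g[0], g[1], g[2], g[3], g[4]) for g in gene_models])
    out: dict[str, TagAnnotation] = {}
    for tag in tags:
        for locus in loci.get(tag, []):
            tree = trees.get(locus.chromosome)
            if tree is None:
                continue
            hits = tree.overlap(locus.start, locus.end)
            if hits:
                gid = sorted(h.data[4] for h in hits)[0]
                out[tag] = TagAnnotation(
                    tag, "degradation",
                    f"{gid}@{locus.chromosome}:{locus.start}-{locus.end}")
                break
    return out


def mask_repeats(
    tags: list[str],
    loci: dict[str, list[GenomeLocus]],
    repeats: list[tuple],
) -> dict[str, TagAnnotation]:
    """Label tags whose *every* exact locus overlaps a repeat interval."""
    trees = _build_trees(repeats)
    out: dict[str, TagAnnotation] = {}
    for tag in tags:
        tl = loci.get(tag, [])
        if not tl:
            continue
        if all(trees.get(l.chromosome) is not None
               and trees[l.chromosome].overlap(l.start, l.end)
               for l in tl):
            l0 = tl[0]
            out[tag] = TagAnnotation(
                tag, "repeat", f"{l0.chromosome}:{l0.start}-{l0.end}")
    return out


def match_known(
    tags: list[str],
    mature_mirnas: dict[str, str],
    tag_counts: dict[str, dict[str, int]] | None = None,
    max_length_diff: int = 2,
) -> tuple[dict[str, TagAnnotation], dict[str, dict[str, int]]]:
    """Match tags to a mature miRNA reference with zero mismatches.

    A tag hits a reference when one sequence contains the other exactly and
    their lengths differ by at most ``max_length_diff``.  Returns the tag
    annotations and a per-reference aggregated count table.  The reference
    may be a mapping or an iterable of (id, sequence) pairs; duplicate ids
    raise an error listing them.
    """
    if not isinstance(mature_mirnas, dict):
        pairs = list(mature_mirnas)
        ids = [i for i, _ in pairs]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate mature miRNA ids: {dupes}")
        mature_mirnas = dict(pairs)
    refs = {rid: mature_mirnas[rid].upper().replace("U", "T")
            for rid in sorted(mature_mirnas)}
    # index reference substrings of the permitted lengths for O(1) lookup
    sub_idx: dict[str, str] = {}
    for rid, seq in refs.items():
        for L in range(max(1, len(seq) - max_length_diff), len(seq) + 1):
            for p in range(len(seq) - L + 1):
                sub_idx.setdefault(seq[p:p + L], rid)

    out: dict[str, TagAnnotation] = {}
    counts: dict[str, dict[str, int]] = {}
    for tag in tags:
        t = tag.upper().replace("U", "T")
        rid = sub_idx.get(t)
        if rid is None:
            # tag longer than the reference: reference contained in tag
            for cand, seq in refs.items():
                if 0 < len(t) - len(seq) <= max_length_diff and seq in t:
                    rid = cand
                    break
        if rid is None:
            continue
        out[tag] = TagAnnotation(tag, f"known_mirna:{rid}", rid)
        if tag_counts is not None:
            agg = counts.setdefault(rid, {})
            for sample, c in tag_counts.get(tag, {}).items():
                agg[sample] = agg.get(sample, 0) + c
    return out, counts


def annotate_tags(
    tag_counts: dict[str, dict[str, int]],
    refs: ReferenceSet,
    loci: dict[str, list[GenomeLocus]],
    min_identity: float = 0.97,
) -> tuple[dict[str, TagAnnotation], dict[str, dict[str, int]]]:
    """Assign every tag exactly one label under the fixed precedence.

    Returns (annotations, known-miRNA per-sample count table).  Tags not
    captured by any rule are labelled ``unannotated``.
    """
    tags = sorted(tag_counts)
    ann: dict[str, TagAnnotation] = {}

    for tag, a in classify_ncrna(tags, refs, min_identity).items():
        ann[tag] = a
    remaining = [t for t in tags if t not in ann]

    for tag, a in remove_degradation(remaining, loci, refs.gene_models).items():
        ann[tag] = a
    remaining = [t for t in remaining if t not in ann]

    for tag, a in mask_repeats(remaining, loci, refs.repeats).items():
        ann[tag] = a
    remaining = [t for t in remaining if t not in ann]

    known_ann, known_counts = match_known(remaining, refs.mature_mirnas, tag_counts)
    ann.update(known_ann)

    for tag in tags:
        if tag not in ann:
            ann[tag] = TagAnnotation(tag, "unannotated")
    return ann, known_counts
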