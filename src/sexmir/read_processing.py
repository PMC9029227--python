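"""Raw small-RNA read filtering and tag collapsing.

Turns raw single-end small-RNA reads into adapter-trimmed *clean tags* while
accounting every removed read to exactly one category, in the fixed rule
order used throughout the pipeline:

1. low quality: more than ``max_low_quality_bases`` bases at or below the
   quality threshold, or any unknown base (N);
2. no 3' adapter;
3. 5' adapter sequence contained in the insert;
4. insert null (3' adapter starts at read position 0);
5. poly(A) insert (A fraction strictly above ``polyA_fraction``);
6. insert shorter than ``min_insert_length``.

The 3' adapter is located by the earliest occurrence of its first 8 nt
allowing one mismatch, scanning from read position 0; the 5' adapter is
detected by exact containment of its full sequence in the trimmed insert.
Surviving inserts are collapsed into unique tags with per-sample counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FilterParams",
    "FilterReport",
    "CleanTag",
    "filter_reads",
    "collapse_tags",
    "tags_to_frame",
    "report_frame",
]

_SEED_LEN = 8
_SEED_MISMATCHES = 1

#: report categories in attribution order (after the high-quality gate)
CATEGORIES = (
    "adapter3_null",
    "adapter5_contaminant",
    "insert_null",
    "polyA",
    "shorter_than_min",
)


@dataclass(frozen=True)
class FilterParams:
    adapter3: str
    adapter5: str
    max_low_quality_bases: int = 1
    low_quality_phred: int = 20
    polyA_fraction: float = 0.70
    min_insert_length: int = 18
    max_insert_length: int | None = None   # off by default

    def __post_init__(self) -> None:
        if not self.adapter3 or not self.adapter5:
            raise ValueError("adapter sequences must be non-empty")
        if len(self.adapter3) < _SEED_LEN:
            raise ValueError(f"3' adapter shorter than seed length {_SEED_LEN}")
        if not 0.0 < self.polyA_fraction < 1.0:
            raise ValueError("polyA_fraction must be in (0, 1)")
        if self.min_insert_length < 1:
            raise ValueError("min_insert_length must be >= 1")


@dataclass
class FilterReport:
    """Per-sample read accounting (column layout mirrors a run summary table)."""

    raw_reads: int = 0
    high_quality: int = 0
    adapter3_null: int = 0
    insert_null: int = 0
    adapter5_contaminant: int = 0
    shorter_than_min: int = 0
    polyA: int = 0
    clean_reads: int = 0

    def check(self) -> None:
        removed = (self.adapter3_null + self.insert_null
                   + self.adapter5_contaminant + self.shorter_than_min
                   + self.polyA)
        if self.high_quality != removed + self.clean_reads:
            raise AssertionError("filter report does not balance")


@dataclass
class CleanTag:
    """A unique insert sequence with per-sample read counts."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


class MalformedReadError(ValueError):
    pass


def _as_matrix(strings: list[str], pad: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Pack variable-length ASCII strings into a padded uint8 matrix."""
    n = len(strings)
    lengths = np.fromiter((len(s) for s in strings), dtype=np.int64, count=n)
    width = int(lengths.max()) if n else 0
    mat = np.zeros((n, width), dtype=np.uint8)
    joined = "".join(strings).encode("ascii")
    flat = np.frombuffer(joined, dtype=np.uint8)
    starts = np.concatenate(([0], np.cumsum(lengths)))
    for i in range(n):
        mat[i, : lengths[i]] = flat[starts[i]:starts[i + 1]]
    return mat, lengths


def _find_adapter3(mat: np.ndarray, lengths: np.ndarray, adapter3: str) -> np.ndarray:
    """Earliest seed hit (first 8 nt, <=1 mismatch) per read; -1 if absent."""
    n, width = mat.shape
    seed = np.frombuffer(adapter3[:_SEED_LEN].encode("ascii"), dtype=np.uint8)
    pos = np.full(n, -1, dtype=np.int64)
    unfound = np.ones(n, dtype=bool)
    for off in range(0, width - _SEED_LEN + 1):
        window = mat[:, off:off + _SEED_LEN]
        mism = (window != seed[None, :]).sum(axis=1)
        fits = lengths >= off + _SEED_LEN
        hit = unfound & fits & (mism <= _SEED_MISMATCHES)
        pos[hit] = off
        unfound &= ~hit
        if not unfound.any():
            break
    return pos


def classify_read(seq: str, qual: str, params: FilterParams) -> tuple[str, str]:
    """Classify a single read; returns (category, trimmed insert).

    Categories: ``low_quality``, ``adapter3_null``, ``adapter5_contaminant``,
    ``insert_null``, ``polyA``, ``shorter_than_min`` or ``clean``.  This is a
    scalar mirror of :func:`filter_reads` used where reads are handled one at
    a time; the two paths are property-tested against each other.
    """
    seq = seq.upper()
    if len(seq) != len(qual):
        raise MalformedReadError("sequence/quality length mismatch")
    low = sum(1 for q in qual if ord(q) - 33 <= params.low_quality_phred)
    if low > params.max_low_quality_bases or "N" in seq:
        return "low_quality", ""
    seed = params.adapter3[:_SEED_LEN]
    pos3 = -1
    for off in range(0, len(seq) - _SEED_LEN + 1):
        mism = sum(1 for a, b in zip(seq[off:off + _SEED_LEN], seed) if a != b)
        if mism <= _SEED_MISMATCHES:
            pos3 = off
            break
    if pos3 < 0:
        return "adapter3_null", ""
    insert = seq[:pos3]
    if params.adapter5 in insert:
        return "adapter5_contaminant", ""
    if not insert:
        return "insert_null", ""
    if insert.count("A") / len(insert) > params.polyA_fraction:
        return "polyA", ""
    if len(insert) < params.min_insert_length:
        return "shorter_than_min", ""
    if params.max_insert_length is not None and len(insert) > params.max_insert_length:
        return "shorter_than_min", ""
    return "clean", insert


def filter_reads(
    reads,
    params: FilterParams,
) -> tuple[list[str], FilterReport]:
    """Apply the six filter rules to a stream of reads.

    Parameters
    ----------
    reads:
        Iterable of ``(read_id, sequence, quality_string)`` triples
        (Phred+33 quality) or Biopython ``SeqRecord`` objects with
        ``letter_annotations["phred_quality"]``.

    Returns
    -------
    (inserts, report):
        ``inserts`` are the adapter-trimmed sequences of surviving reads, in
        input order; ``report`` accounts every input read.
    """
    ids: list[str] = []
    seqs: list[str] = []
    quals: list[str] = []
    for rec in reads:
        if hasattr(rec, "letter_annotations"):  # SeqRecord
            rid = rec.id
            seq = str(rec.seq)
            q = "".join(chr(p + 33) for p in rec.letter_annotations["phred_quality"])
        else:
            rid, seq, q = rec
        if len(seq) != len(q):
            raise MalformedReadError(
                f"read {rid}: sequence length {len(seq)} != quality length {len(q)}")
        ids.append(rid)
        seqs.append(seq.upper())
        quals.append(q)

    report = FilterReport(raw_reads=len(seqs))
    if not seqs:
        return [], report

    mat, lengths = _as_matrix(seqs)
    qmat, _ = _as_matrix(quals)

    # rule 1: quality gate (padding is 0 and never counts as low quality
    # because positions beyond the read length are masked)
    width = mat.shape[1]
    valid = np.arange(width)[None, :] < lengths[:, None]
    low = valid & (qmat <= params.low_quality_phred + 33)
    has_n = (valid & (mat == ord("N"))).any(axis=1)
    hq = (low.sum(axis=1) <= params.max_low_quality_bases) & ~has_n
    report.high_quality = int(hq.sum())

    # rule 2: locate the 3' adapter
    pos3 = _find_adapter3(mat, lengths, params.adapter3)
    a3_null = hq & (pos3 < 0)
    report.adapter3_null = int(a3_null.sum())
    alive = hq & ~a3_null
    insert_len = np.where(pos3 >= 0, pos3, 0)

    # rule 3: full 5' adapter contained in the insert
    a5 = np.frombuffer(params.adapter5.encode("ascii"), dtype=np.uint8)
    la5 = len(a5)
    has5 = np.zeros(len(seqs), dtype=bool)
    for off in range(0, width - la5 + 1):
        fits = insert_len >= off + la5
        if not fits.any():
            continue
        match = (mat[:, off:off + la5] == a5[None, :]).all(axis=1)
        has5 |= fits & match
    a5_hit = alive & has5
    report.adapter5_contaminant = int(a5_hit.sum())
    alive &= ~a5_hit

    # rule 4: insert null
    inull = alive & (insert_len == 0)
    report.insert_null = int(inull.sum())
    alive &= ~inull

    # rule 5: poly(A) insert
    cum_a = np.cumsum(np.concatenate(
        [np.zeros((len(seqs), 1), dtype=np.int64), (mat == ord("A")).astype(np.int64)],
        axis=1), axis=1)
    a_count = cum_a[np.arange(len(seqs)), insert_len]
    with np.errstate(invalid="ignore", divide="ignore"):
        a_frac = np.where(insert_len > 0, a_count / np.maximum(insert_len, 1), 0.0)
    polya = alive & (a_frac > params.polyA_fraction)
    report.polyA = int(polya.sum())
    alive &= ~polya

    # rule 6: short inserts (and over-long ones when a cap is configured)
    short = alive & (insert_len < params.min_insert_length)
    if params.max_insert_length is not None:
        short |= alive & (insert_len > params.max_insert_length)
    report.shorter_than_min = int(short.sum())
    alive &= ~short

    report.clean_reads = int(alive.sum())
    report.check()

    idx = np.nonzero(alive)[0]
    inserts = [seqs[i][: insert_len[i]] for i in idx]
    return inserts, report


def collapse_tags(inserts_per_sample: dict[str, list[str]]) -> list[CleanTag]:
    """Collapse identical inserts into unique tags with per-sample counts.

    Tags are ordered by descending total count, then lexicographically.
    """
    counts: dict[str, Counter] = {}
    for sample in sorted(inserts_per_sample):
        for seq, c in Counter(inserts_per_sample[sample]).items():
            counts.setdefault(seq, Counter())[sample] = c
    tags = [CleanTag(sequence=s, counts=dict(c)) for s, c in counts.items()]
    tags.sort(key=lambda t: (-t.total, t.sequence))
    return tags


def tags_to_frame(tags: list[CleanTag], samples: list[str]) -> pd.DataFrame:
    """Tag count matrix (rows = tag sequences, columns = samples)."""
    data = np.zeros((len(tags), len(samples)), dtype=np.int64)
    col = {s: j for j, s in enumerate(samples)}
    for i, t in enumerate(tags):
        for s, c in t.counts.items():
            data[i, col[s]] = c
    return pd.DataFrame(data, index=[t.sequence for t in tags], columns=samples)


def report_frame(reports: dict[str, FilterReport]) -> pd.DataFrame:
    """Stack per-sample filter reports into a summary table."""
    rows = {}
    for sample in sorted(reports):
        r = reports[sample]
        rows[sample] = {
            "raw_reads": r.raw_reads,
            "high_quality": r.high_quality,
            "adapter3_null": r.adapter3_null,
            "insert_null": r.insert_null,
            "adapter5_contaminant": r.adapter5_contaminant,
            "shorter_than_min": r.shorter_than_min,
            "polyA": r.polyA,
            "clean_reads": r.clean_reads,
        }
    return pd.DataFrame.from_dict(rows, orient="index")
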