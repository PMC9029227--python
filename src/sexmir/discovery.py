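"""Novel miRNA discovery from unannotated small-RNA tags.

Implements the hairpin-based discovery stage of the pipeline: exact genome
mapping of tags, excision of candidate precursor windows around each locus,
minimum-free-energy folding under a simplified stacking energy model, location
of the miRNA* (passenger) arm from the pair table, and evaluation of the
eleven precursor criteria (length bounds, copy number, precursor energy,
mature/star spacing, bulge, asymmetry, flanks).

Energy model
------------
Base pairs are G:C, A:U and the G:U wobble.  A pair contributes its
*stacking* energy when the pair immediately inside it (i+1, j-1) is also
formed; the innermost pair of every helix, and any lone pair, contributes the
isolated-pair energy instead.  Defaults (kcal/mol): G:C -3.0, A:U -2.0,
G:U -1.0, isolated -1.0.  Hairpin loops must span at least 3 unpaired bases;
there are no loop or dangling-end penalties.  The same table drives both
:func:`fold_rna` and :func:`duplex_energy`, so precursor stability and
miRNA/target duplex stability are judged on one scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "MireapParams",
    "FoldResult",
    "GenomeLocus",
    "HairpinCandidate",
    "NovelMirna",
    "CRITERIA",
    "fold_rna",
    "duplex_energy",
    "perfect_duplex_energy",
    "map_tags",
    "build_genome_index",
    "excise_and_evaluate",
    "call_novel",
    "assign_chromosome",
    "encode_rna",
    "revcomp",
]

# ---------------------------------------------------------------------------
# Alphabet and energy table
# ---------------------------------------------------------------------------

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}
_RNA = "ACGU"
_COMP = str.maketrans("ACGUT", "UGCAA")
_DNA_COMP = str.maketrans("ACGTN", "TGCAN")

# stacking energies by encoded pair; 0.0 marks an unpairable combination
_STACK = np.zeros((4, 4), dtype=np.float64)
_STACK[2, 1] = _STACK[1, 2] = -3.0   # G:C
_STACK[0, 3] = _STACK[3, 0] = -2.0   # A:U
_STACK[2, 3] = _STACK[3, 2] = -1.0   # G:U wobble
_ISOLATED = -1.0
_MIN_LOOP = 3


def encode_rna(seq: str) -> np.ndarray:
    """Encode an RNA/DNA string as int8 codes (A=0, C=1, G=2, U/T=3)."""
    out = np.empty(len(seq), dtype=np.int8)
    for i, ch in enumerate(seq.upper()):
        code = _CODE.get(ch)
        if code is None:
            raise ValueError(f"invalid RNA base {ch!r} at position {i}")
        out[i] = code
    return out


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N preserved)."""
    return seq.upper().translate(_DNA_COMP)[::-1]


def _rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


# ---------------------------------------------------------------------------
# Parameters and result containers
# ---------------------------------------------------------------------------

#: names of the eleven precursor criteria, in the order they are reported
CRITERIA = (
    "mature_len_min",      # mature length >= 18 nt
    "mature_len_max",      # mature length <= 25 nt
    "star_len_min",        # miRNA* length >= 20 nt
    "star_len_max",        # miRNA* length <= 23 nt
    "copy_number",         # <= 20 exact genomic loci
    "precursor_energy",    # precursor MFE <= -18 kcal/mol
    "star_space_max",      # mature/star gap <= 300 nt
    "star_space_min",      # mature/star gap >= 16 nt
    "bulge",               # longest unpaired run in the duplex <= 4 nt
    "asymmetry",           # sum of per-loop side differences <= 4 nt
    "flank",               # 20 nt flanks fit inside the chromosome
)


@dataclass(frozen=True)
class MireapParams:
    """Bounds for hairpin-precursor acceptance (Mireap-style defaults)."""

    min_mirna_len: int = 18
    max_mirna_len: int = 25
    min_ref_len: int = 20        # miRNA* length lower bound
    max_ref_len: int = 23        # miRNA* length upper bound
    max_copy_number: int = 20
    max_precursor_energy: float = -18.0   # MFE must be <= this (kcal/mol)
    max_star_space: int = 300
    min_star_space: int = 16
    max_bulge: int = 4
    max_asymmetry: int = 4
    flank_len: int = 20

    def __post_init__(self) -> None:
        if self.min_mirna_len > self.max_mirna_len:
            raise ValueError("min_mirna_len > max_mirna_len")
        if self.min_ref_len > self.max_ref_len:
            raise ValueError("min_ref_len > max_ref_len")
        if self.min_star_space > self.max_star_space:
            raise ValueError("min_star_space > max_star_space")
        for name in ("max_copy_number", "max_bulge", "max_asymmetry", "flank_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class FoldResult:
    """Minimum-energy secondary structure of a single RNA sequence."""

    structure: str                 # dot-bracket string
    energy: float                  # kcal/mol, <= 0
    pair_table: np.ndarray         # pair_table[i] = j if (i,j) paired else -1

    def pairs(self) -> list[tuple[int, int]]:
        return [(i, int(j)) for i, j in enumerate(self.pair_table) if j > i]


@dataclass(frozen=True)
class GenomeLocus:
    """0-based half-open genomic interval with strand."""

    chromosome: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty locus {self.chromosome}:{self.start}-{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class HairpinCandidate:
    """An excised precursor with fold, arms and per-criterion verdicts."""

    locus: GenomeLocus                 # mature locus on the genome
    precursor_locus: GenomeLocus       # precursor span on the genome
    precursor: str                     # precursor RNA sequence (5'->3')
    fold: FoldResult
    mature: str
    mature_offset: int                 # offset of mature within precursor
    arm: str                           # "5p" or "3p"
    star: str
    star_offset: int
    criteria: dict[str, bool]
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def compliant(self) -> bool:
        return all(self.criteria.values())

    @property
    def violated(self) -> list[str]:
        return [k for k in CRITERIA if not self.criteria[k]]


@dataclass
class NovelMirna:
    """An accepted novel miRNA (one mature product of a hairpin)."""

    id: str
    candidate: HairpinCandidate
    chromosome: str


# ---------------------------------------------------------------------------
# Folding dynamic programme
# ---------------------------------------------------------------------------

@njit(cache=True)
def _fold_dp(seq, stack, isolated, min_loop):  # pragma: no cover - numba
    n = seq.shape[0]
    INF = 1e30
    V = np.full((n, n), INF)    # min energy of [i..j] with (i,j) paired
    W = np.zeros((n, n))        # min energy of [i..j]
    WX = np.zeros((n, n))       # min energy of [i..j] with (i,j) not paired

    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            # WX: j unpaired, or j paired with some k > i
            best_x = W[i, j - 1]
            for k in range(i + 1, j - min_loop):
                if V[k, j] < INF:
                    cand = W[i, k - 1] + V[k, j]
                    if cand < best_x:
                        best_x = cand
            WX[i, j] = best_x
            # V: (i,j) paired if allowed
            e = stack[seq[i], seq[j]]
            if e < 0.0:
                inner = isolated + (WX[i + 1, j - 1] if j - 1 - (i + 1) > min_loop else 0.0)
                if j - 1 - (i + 1) > min_loop and V[i + 1, j - 1] < INF:
                    st = e + V[i + 1, j - 1]
                    if st < inner:
                        inner = st
                V[i, j] = inner
            # W
            W[i, j] = best_x if V[i, j] >= best_x else V[i, j]
    return V, W, WX


def _traceback(seq: np.ndarray, V: np.ndarray, W: np.ndarray, WX: np.ndarray) -> np.ndarray:
    """Deterministic traceback of the fold DP (prefers smaller i, then j)."""
    n = len(seq)
    pt = np.full(n, -1, dtype=np.int64)
    eps = 1e-9
    stack: list[tuple[int, int, str]] = [(0, n - 1, "W")]
    while stack:
        i, j, mode = stack.pop()
        if j - i <= _MIN_LOOP:
            continue
        if mode == "V":
            pt[i], pt[j] = j, i
            e = _STACK[seq[i], seq[j]]
            if (
                j - 1 - (i + 1) > _MIN_LOOP
                and V[i + 1, j - 1] < 1e29
                and abs(V[i, j] - (e + V[i + 1, j - 1])) < eps
            ):
                stack.append((i + 1, j - 1, "V"))
            else:
                stack.append((i + 1, j - 1, "WX"))
            continue
        # W or WX: pairing (i,j) is allowed only in W mode
        if mode == "W" and V[i, j] < W[i, j] - eps:
            stack.append((i, j, "V"))
            continue
        ref = W[i, j] if mode == "W" else WX[i, j]
        if mode == "W" and abs(V[i, j] - ref) < eps:
            stack.append((i, j, "V"))
            continue
        if abs(W[i, j - 1] - ref) < eps:
            stack.append((i, j - 1, "W"))
            continue
        for k in range(i + 1, j - _MIN_LOOP):
            if V[k, j] < 1e29 and abs((W[i, k - 1] + V[k, j]) - ref) < eps:
                stack.append((i, k - 1, "W"))
                stack.append((k, j, "V"))
                break
    return pt


def fold_rna(sequence: str) -> FoldResult:
    """Fold an RNA sequence to its minimum-energy nested structure.

    Dynamic programme over the package's stacking energy model; ties are
    broken deterministically (pairs with smaller 5' index are preferred).

    Parameters
    ----------
    sequence:
        RNA string over A/C/G/U (T accepted as U); length >= 10.
    """
    seq = _rna(sequence)
    if len(seq) < 10:
        raise ValueError(f"sequence too short to fold ({len(seq)} nt < 10)")
    enc = encode_rna(seq)
    V, W, WX = _fold_dp(enc, _STACK, _ISOLATED, _MIN_LOOP)
    energy = float(W[0, len(seq) - 1])
    pt = _traceback(enc, V, W, WX)
    chars = ["."] * len(seq)
    for i, j in enumerate(pt):
        if j > i:
            chars[i] = "("
            chars[int(j)] = ")"
    return FoldResult(structure="".join(chars), energy=energy, pair_table=pt)


def structure_energy(seq: str, pairs: set[tuple[int, int]]) -> float:
    """Energy of an explicit structure (used by tests as well as internally).

    A pair (i, j) contributes its stacking energy when (i+1, j-1) is also in
    ``pairs``, the isolated-pair energy otherwise.
    """
    enc = encode_rna(_rna(seq))
    total = 0.0
    for i, j in pairs:
        e = _STACK[enc[i], enc[j]]
        if e == 0.0:
            raise ValueError(f"positions {i},{j} cannot pair")
        total += e if (i + 1, j - 1) in pairs else _ISOLATED
    return total


# ---------------------------------------------------------------------------
# Duplex energy (shared with target prediction)
# ---------------------------------------------------------------------------

def duplex_energy(seq_a: str, seq_b: str, paired: np.ndarray | list[bool]) -> float:
    """Energy of an ungapped antiparallel duplex.

    ``seq_a`` and ``seq_b`` are both given 5'->3'; position k of ``seq_a``
    faces position L-1-k of ``seq_b``.  ``paired[k]`` says whether that face
    is a base pair.  Paired positions contribute under the same stacking
    model as :func:`fold_rna` (a pair stacks when the next position toward
    the 3' end of ``seq_a`` is also paired); unpaired positions contribute 0.
    """
    a = encode_rna(_rna(seq_a))
    b = encode_rna(_rna(seq_b))
    if len(a) != len(b):
        raise ValueError(f"ungapped duplex requires equal lengths ({len(a)} vs {len(b)})")
    mask = np.asarray(paired, dtype=bool)
    if mask.shape[0] != len(a):
        raise ValueError("pairing mask length mismatch")
    total = 0.0
    L = len(a)
    for k in range(L):
        if not mask[k]:
            continue
        e = _STACK[a[k], b[L - 1 - k]]
        if e == 0.0:
            raise ValueError(f"position {k} marked paired but bases cannot pair")
        total += e if (k + 1 < L and mask[k + 1]) else _ISOLATED
    return total


def perfect_duplex_energy(seq: str) -> float:
    """Energy of ``seq`` bound to its exact Watson-Crick complement."""
    s = _rna(seq)
    comp = s.translate(_COMP)[::-1]
    return duplex_energy(s, comp, np.ones(len(s), dtype=bool))


# ---------------------------------------------------------------------------
# Genome mapping
# ---------------------------------------------------------------------------

_INDEX_K = 18


def build_genome_index(genome: dict[str, str], k: int = _INDEX_K) -> dict:
    """Hash every forward k-mer of the genome to its (chrom, pos) list."""
    index: dict[str, list[tuple[str, int]]] = {}
    for chrom in sorted(genome):
        seq = genome[chrom].upper()
        for pos in range(len(seq) - k + 1):
            kmer = seq[pos:pos + k]
            index.setdefault(kmer, []).append((chrom, pos))
    return index


def map_tags(
    tags: list[str],
    genome: dict[str, str],
    max_copy_number: int | None = None,
    index: dict | None = None,
) -> dict[str, list[GenomeLocus]]:
    """Exact full-length mapping of tags to both genome strands.

    Minus-strand hits are loci whose forward-strand sequence is the reverse
    complement of the tag.  When ``max_copy_number`` is given, tags with more
    loci are still reported (callers flag/exclude them).
    """
    if index is None:
        index = build_genome_index(genome)
    out: dict[str, list[GenomeLocus]] = {}
    for tag in tags:
        hits: list[GenomeLocus] = []
        seen: set[tuple[str, int, str]] = set()
        for strand, query in (("+", tag.upper().replace("U", "T")),
                              ("-", revcomp(tag.upper().replace("U", "T")))):
            if len(query) < _INDEX_K:
                continue
            for chrom, pos in index.get(query[:_INDEX_K], ()):
                if genome[chrom][pos:pos + len(query)].upper() == query:
                    key = (chrom, pos, strand)
                    if key not in seen:
                        seen.add(key)
                        hits.append(GenomeLocus(chrom, pos, pos + len(query), strand))
        hits.sort(key=lambda l: (l.chromosome, l.start, l.strand))
        out[tag] = hits
    return out


# ---------------------------------------------------------------------------
# Precursor excision and criteria evaluation
# ---------------------------------------------------------------------------

def _window_sequence(genome: dict[str, str], locus: GenomeLocus,
                     up: int, down: int) -> tuple[str, int, int]:
    """Excise [start-up, end+down) on the locus strand.

    Returns (RNA sequence 5'->3' on the tag strand, mature offset in that
    sequence, genomic start of the window).
    """
    chrom_seq = genome[locus.chromosome]
    if locus.end > len(chrom_seq) or locus.start < 0:
        raise ValueError(
            f"locus out of bounds on {locus.chromosome}: {locus.start}-{locus.end}")
    if locus.strand == "+":
        g0 = max(0, locus.start - up)
        g1 = min(len(chrom_seq), locus.end + down)
        seq = chrom_seq[g0:g1]
        offset = locus.start - g0
    else:
        g0 = max(0, locus.start - down)
        g1 = min(len(chrom_seq), locus.end + up)
        seq = revcomp(chrom_seq[g0:g1])
        offset = g1 - locus.end
    return _rna(seq), offset, g0


def _duplex_geometry(pt: np.ndarray, m0: int, m1: int) -> dict | None:
    """Locate the miRNA* and measure duplex geometry from a pair table.

    ``[m0, m1)`` is the mature span in fold coordinates.  Returns None when
    no mature base pairs outside itself.

    Bulge = longest unpaired run inside the duplex on either strand
    (mature edges count, except the canonical 2 nt 3' overhang).
    Asymmetry = sum over the duplex's internal loops of the difference
    between their mature-side and star-side lengths; a clean duplex with
    symmetric internal loops scores 0, while scattered incidental pairing
    against a random region accumulates asymmetric loops and fails.
    """
    down = [(i, int(pt[i])) for i in range(m0, m1) if pt[i] >= m1]
    up = [(i, int(pt[i])) for i in range(m0, m1) if 0 <= pt[i] < m0]
    if not down and not up:
        return None
    # the arm hosting most mature partners is the star side
    duplex = down if len(down) >= len(up) else up
    upstream = duplex is up
    partners = [p for _i, p in duplex]
    lo, hi = min(partners), max(partners)
    if upstream:
        s0, s1 = lo - 2, hi - 1
        gap = m0 - hi - 1
    else:
        s0, s1 = lo + 2, hi + 3
        gap = lo - m1
    n = len(pt)
    s0 = max(0, min(s0, n))
    s1 = max(0, min(s1, n))

    runs: list[int] = []
    asym = 0
    # mature edge overhangs (3' overhang of 2 nt is canonical and free)
    first_i, last_i = duplex[0][0], duplex[-1][0]
    lead = first_i - m0
    trail = (m1 - 2) - 1 - last_i
    if lead > 0:
        runs.append(lead)
        asym += lead
    if trail > 0:
        runs.append(trail)
        asym += trail
    # internal loops between consecutive duplex pairs
    # partners descend as mature positions ascend (non-crossing), on
    # either arm
    for (i, p), (i2, p2) in zip(duplex, duplex[1:]):
        a = i2 - i - 1                      # unpaired on the mature side
        b = p - p2 - 1                      # unpaired on the star side
        if a > 0:
            runs.append(a)
        if b > 0:
            runs.append(b)
        asym += abs(a - b)
    return {
        "star_span": (s0, s1),
        "gap": gap,
        "bulge": max(runs, default=0),
        "asymmetry": asym,
        "upstream": upstream,
    }


def _evaluate_window(
    tag: str,
    locus: GenomeLocus,
    genome: dict[str, str],
    params: MireapParams,
    up: int,
    down: int,
    n_loci: int,
) -> HairpinCandidate:
    """Fold one excision window and score the eleven criteria."""
    window, m_off, _ = _window_sequence(genome, locus, up, down)
    fold = fold_rna(window)
    L = len(tag)
    geom = _duplex_geometry(fold.pair_table, m_off, m_off + L)

    crit: dict[str, bool] = {name: True for name in CRITERIA}
    crit["mature_len_min"] = L >= params.min_mirna_len
    crit["mature_len_max"] = L <= params.max_mirna_len
    crit["copy_number"] = n_loci <= params.max_copy_number

    if geom is None:
        star_seq, s_rel = "", m_off + L
        crit["star_len_min"] = False
        crit["precursor_energy"] = False
        prec_seq, prec_off, prec_fold = window, m_off, fold
        p_g0 = None
    else:
        s0, s1 = geom["star_span"]
        star_seq = window[s0:s1]
        star_len = s1 - s0
        crit["star_len_min"] = star_len >= params.min_ref_len
        crit["star_len_max"] = star_len <= params.max_ref_len
        crit["star_space_max"] = geom["gap"] <= params.max_star_space
        crit["star_space_min"] = geom["gap"] >= params.min_star_space
        crit["bulge"] = geom["bulge"] <= params.max_bulge
        crit["asymmetry"] = geom["asymmetry"] <= params.max_asymmetry

        # re-excise the precursor (arm span + flanks) and refold for the
        # final energy and reported structure
        lo = min(m_off, s0)
        hi = max(m_off + L, s1)
        p0 = lo - params.flank_len
        p1 = hi + params.flank_len
        crit["flank"] = p0 >= 0 and p1 <= len(window)
        p0c, p1c = max(0, p0), min(len(window), p1)
        prec_seq = window[p0c:p1c]
        prec_off = m_off - p0c
        s_rel = s0 - p0c
        if len(prec_seq) >= 10:
            prec_fold = fold_rna(prec_seq)
            crit["precursor_energy"] = prec_fold.energy <= params.max_precursor_energy
        else:
            prec_fold = fold
            crit["precursor_energy"] = False
        # genomic span of the precursor
        if locus.strand == "+":
            g0 = locus.start - (m_off - p0c)
            p_g0 = (g0, g0 + len(prec_seq))
        else:
            g1 = locus.end + (m_off - p0c)
            p_g0 = (g1 - len(prec_seq), g1)

    if p_g0 is None:
        if locus.strand == "+":
            g0 = locus.start - m_off
            p_g0 = (g0, g0 + len(window))
        else:
            g1 = locus.end + m_off
            p_g0 = (g1 - len(window), g1)

    arm = "5p" if (geom is None or not geom["upstream"]) else "3p"
    return HairpinCandidate(
        locus=locus,
        precursor_locus=GenomeLocus(locus.chromosome, max(0, p_g0[0]),
                                    p_g0[1], locus.strand),
        precursor=prec_seq,
        fold=prec_fold,
        mature=_rna(tag),
        mature_offset=prec_off,
        arm=arm,
        star=star_seq,
        star_offset=s_rel,
        criteria=crit,
    )


# excision ladder: windows grow until a compliant hairpin is found; the
# first step is large enough for a compact hairpin (loop <= ~50 nt) plus
# the star and the 20 nt flank
_LADDER = (96, 192, None)


def excise_and_evaluate(
    tag: str,
    locus: GenomeLocus,
    genome: dict[str, str],
    params: MireapParams = MireapParams(),
    n_loci: int = 1,
) -> HairpinCandidate:
    """Excise precursor windows around ``locus`` and evaluate the criteria.

    Windows extend upstream or downstream of the tag by an increasing ladder
    of extents, up to ``max_star_space + len(tag) + flank_len``; the first
    ladder step that yields a compliant candidate wins (best energy among
    compliant candidates of that step).  When no window is compliant the
    rejection with the fewest violated criteria (largest window preferred on
    ties) is returned, so the verdict names every violated criterion.
    """
    if not (params.min_mirna_len <= len(tag) <= params.max_mirna_len):
        # still evaluated so the length criteria are reported
        pass
    full_ext = params.max_star_space + len(tag) + params.flank_len
    flank = params.flank_len
    best_reject: HairpinCandidate | None = None
    for ext in _LADDER:
        e = full_ext if ext is None else min(ext, full_ext)
        compliant: list[HairpinCandidate] = []
        for up, down in ((flank, e), (e, flank)):
            cand = _evaluate_window(tag, locus, genome, params, up, down, n_loci)
            if cand.compliant:
                compliant.append(cand)
            else:
                if best_reject is None or len(cand.violated) < len(best_reject.violated):
                    best_reject = cand
        if compliant:
            compliant.sort(key=lambda c: (c.fold.energy, c.arm))
            return compliant[0]
        if ext is None and e == full_ext:
            break
    assert best_reject is not None
    return best_reject


# ---------------------------------------------------------------------------
# Novel miRNA calling
# ---------------------------------------------------------------------------

def call_novel(
    tag_counts: dict[str, dict[str, int]],
    genome: dict[str, str],
    params: MireapParams = MireapParams(),
    loci: dict[str, list[GenomeLocus]] | None = None,
    index: dict | None = None,
) -> tuple[list[NovelMirna], list[tuple[str, GenomeLocus, list[str]]]]:
    """Identify novel miRNAs among unannotated tags.

    Parameters
    ----------
    tag_counts:
        Mapping tag sequence -> {sample: read count}.
    loci:
        Optional precomputed tag loci (from :func:`map_tags`).

    Returns
    -------
    (novel, rejections):
        ``novel`` holds one entry per accepted hairpin product with
        deterministic ids in genome order; ``rejections`` lists
        (tag, locus, violated criteria) for every evaluated, rejected locus.
    """
    tags = sorted(tag_counts)
    if loci is None:
        loci = map_tags(tags, genome, index=index)

    accepted: list[tuple[str, HairpinCandidate]] = []
    rejections: list[tuple[str, GenomeLocus, list[str]]] = []
    for tag in tags:
        tl = loci.get(tag, [])
        if not tl:
            continue
        if not (params.min_mirna_len <= len(tag) <= params.max_mirna_len):
            continue
        if len(tl) > params.max_copy_number:
            for locus in tl:
                rejections.append((tag, locus, ["copy_number"]))
            continue
        for locus in tl:
            cand = excise_and_evaluate(tag, locus, genome, params, n_loci=len(tl))
            if cand.compliant:
                accepted.append((tag, cand))
            else:
                rejections.append((tag, locus, cand.violated))

    # merge tags whose precursors overlap (either strand: a perfect hairpin
    # is an inverted repeat, so the same locus is recovered from both
    # strands); the most abundant tag provides the mature/candidate and
    # counts are aggregated over the distinct member tags
    def total(tag: str) -> int:
        return sum(tag_counts[tag].values())

    accepted.sort(key=lambda tc: (
        tc[1].precursor_locus.chromosome,
        tc[1].precursor_locus.start,
        tc[1].precursor_locus.strand,
        tc[0],
    ))
    clusters: list[list[tuple[str, HairpinCandidate]]] = []
    for tag, cand in accepted:
        placed = False
        for cluster in clusters:
            ref = cluster[0][1].precursor_locus
            pl = cand.precursor_locus
            if (ref.chromosome == pl.chromosome
                    and pl.start < ref.end and ref.start < pl.end):
                cluster.append((tag, cand))
                placed = True
                break
        if not placed:
            clusters.append([(tag, cand)])

    novel: list[NovelMirna] = []
    chrom_order = {c: i for i, c in enumerate(sorted(genome))}
    clusters.sort(key=lambda cl: (
        chrom_order[cl[0][1].precursor_locus.chromosome],
        cl[0][1].precursor_locus.start,
        cl[0][1].precursor_locus.strand,
    ))
    for n, cluster in enumerate(clusters, start=1):
        cluster.sort(key=lambda tc: (-total(tc[0]), tc[0]))
        mature_tag, cand = cluster[0]
        counts: dict[str, int] = {}
        for tag in sorted({t for t, _ in cluster}):
            for sample, c in tag_counts[tag].items():
                counts[sample] = counts.get(sample, 0) + c
        cand.counts = counts
        novel.append(NovelMirna(
            id=f"novel-m{n}-{cand.arm}",
            candidate=cand,
            chromosome=cand.precursor_locus.chromosome,
        ))
    return novel, rejections


def assign_chromosome(
    novel: list[NovelMirna],
    known_sequences: dict[str, str],
    genome: dict[str, str],
    index: dict | None = None,
) -> tuple[dict[str, str], dict[str, list[str]]]:
    """Assign each miRNA to a chromosome (or 'unplaced').

    Novel miRNAs take their precursor's chromosome; known miRNAs take the
    chromosome of the exact genomic match of their mature sequence.  Returns
    (assignment, multi) where ``multi`` lists all chromosomes for miRNAs with
    exact matches on several chromosomes.
    """
    assignment: dict[str, str] = {}
    multi: dict[str, list[str]] = {}
    for nm in novel:
        assignment[nm.id] = nm.chromosome
    if known_sequences:
        loci = map_tags(sorted(known_sequences.values()), genome, index=index)
        for mid in sorted(known_sequences):
            hits = loci.get(known_sequences[mid], [])
            chroms = sorted({h.chromosome for h in hits})
            if not chroms:
                assignment[mid] = "unplaced"
            else:
                assignment[mid] = chroms[0]
                if len(chroms) > 1:
                    multi[mid] = chroms
    return assignment, multi
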