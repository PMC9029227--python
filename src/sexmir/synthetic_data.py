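"""Synthetic small-RNA study generator with exact ground truth.

Builds a miniature dioecious-plant flower study end to end: a multi-
chromosome genome with planted miRNA hairpins (compliant ones and decoys
that each violate a known precursor criterion), gene models, repeat
intervals, ncRNA references, a transcriptome with planted miRNA target
sites, and per-sample FASTQ reads whose exact composition — contaminant
categories, ncRNA/degradation/repeat fragments, and per-miRNA read counts
with sex-dependent fold changes — is recorded in a machine-readable truth
object.  Every planted construct is verified at generation time with the
same evaluation code the pipeline runs, so downstream stages have exact
oracles.

The default configuration emulates the study design this package was built
around: 18 samples (three female flower stages FNS/FNB/FYS and three male
stages M03/M05/M10, three replicates each), a designated sex chromosome
(chr4), 50 compliant hairpins plus 200 single-violation decoys, and a small
panel of sex-biased and sex-specific miRNAs with 4-fold expression
differences.  Reads carry a 3' adapter and substitution-only errors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .discovery import (
    GenomeLocus,
    MireapParams,
    excise_and_evaluate,
    revcomp,
)
from .read_processing import FilterParams, classify_read
from .targets import TargetRuleParams, build_alignment, apply_rules, scan_targets

__all__ = [
    "ExpressionModel",
    "SyntheticSpec",
    "PlantedHairpin",
    "PlantedSite",
    "PlantedTruth",
    "SizingError",
    "generate_genome",
    "generate_reads",
    "write_truth",
    "load_truth",
]

DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"
DEFAULT_ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"

#: (group label, sex) in study order
GROUPS = (("FNS", "F"), ("FNB", "F"), ("FYS", "F"),
          ("M03", "M"), ("M05", "M"), ("M10", "M"))

DECOY_CLASSES = ("no_hairpin", "spacing", "bulge", "asymmetry", "energy")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SizingError(ValueError):
    """A chromosome is too short to host the requested planted loci."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ExpressionModel:
    """Baseline abundances and sex-dependent fold changes.

    Baselines are gamma-distributed relative weights; per-replicate means
    get a gamma multiplier of mean 1 and variance ``dispersion``
    (gamma-Poisson overdispersion), and read counts per sample are a
    multinomial draw so totals are exact.
    """

    baseline_shape: float = 1.2
    baseline_scale: float = 100.0
    dispersion: float = 0.05
    fold_change: float = 4.0
    n_female_biased: int = 8
    n_male_biased: int = 8
    n_female_specific: int = 3
    n_male_specific: int = 3


@dataclass
class SyntheticSpec:
    """Full configuration of a synthetic study."""

    seed: int = 42
    chromosomes: tuple = (("chr1", 40000), ("chr2", 40000), ("chr3", 40000),
                          ("chr4", 40000), ("chr5", 40000), ("chr6", 40000))
    sex_chromosome: str = "chr4"
    n_planted_hairpins: int = 50
    n_decoy_loci: int = 200
    n_known: int = 12
    sex_chromosome_fraction: float = 0.25
    ncrna_classes: dict = field(default_factory=lambda: {
        "rRNA": (3, (120, 300)), "scRNA": (2, (80, 150)),
        "snoRNA": (3, (70, 160)), "snRNA": (3, (80, 200)),
        "tRNA": (4, (70, 90)),
    })
    sample_design: tuple = tuple((g, s, 3) for g, s in GROUPS)
    depth: int = 200_000
    category_counts: dict = field(default_factory=lambda: {
        "low_quality": 2000, "adapter3_null": 1500, "adapter5_contaminant": 600,
        "insert_null": 500, "polyA": 1000, "shorter_than_min": 2400,
    })
    ncrna_fragment_reads: int = 4000
    degradation_fragment_reads: int = 3000
    repeat_fragment_reads: int = 1000
    expression_model: ExpressionModel = field(default_factory=ExpressionModel)
    error_rate: float = 0.001
    adapter3: str = DEFAULT_ADAPTER3
    adapter5: str = DEFAULT_ADAPTER5
    n_genes_per_chromosome: int = 2
    n_repeats_per_chromosome: int = 2
    n_transcripts: int = 40
    mireap: MireapParams = field(default_factory=MireapParams)

    def validate(self) -> None:
        names = [c[0] for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        if self.sex_chromosome not in names:
            raise ValueError(f"sex chromosome {self.sex_chromosome!r} not in chromosomes")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        if self.expression_model.fold_change <= 0:
            raise ValueError("fold_change must be > 0")
        overhead = (sum(self.category_counts.values()) + self.ncrna_fragment_reads
                    + self.degradation_fragment_reads + self.repeat_fragment_reads)
        if self.depth < overhead:
            raise ValueError(
                f"depth {self.depth} below contaminant+fragment reads {overhead}")
        em = self.expression_model
        n_biased = (em.n_female_biased + em.n_male_biased
                    + em.n_female_specific + em.n_male_specific)
        if n_biased > self.n_planted_hairpins:
            raise ValueError("more sex-biased miRNAs requested than planted hairpins")
        if self.n_known > self.n_planted_hairpins:
            raise ValueError("n_known exceeds n_planted_hairpins")

    @property
    def samples(self) -> list[tuple[str, str]]:
        """[(sample name, sex)] in design order."""
        out = []
        for group, sex, nrep in self.sample_design:
            for r in range(1, nrep + 1):
                out.append((f"{group}-{r}", sex))
        return out

    def filter_params(self) -> FilterParams:
        return FilterParams(adapter3=self.adapter3, adapter5=self.adapter5)


# ---------------------------------------------------------------------------
# Truth containers
# ---------------------------------------------------------------------------

@dataclass
class PlantedHairpin:
    id: str
    cls: str                    # "compliant" or "decoy:<class>"
    chromosome: str
    start: int                  # mature locus, 0-based half-open
    end: int
    strand: str
    precursor: str
    mature: str                 # DNA, tag strand
    star: str
    arm: str
    compliant: bool
    violated: list[str] = field(default_factory=list)
    known: bool = False
    bias: str = "none"
    fold: float = 1.0


@dataclass
class PlantedSite:
    transcript_id: str
    position: int               # 1-based site start on the transcript
    mirna_id: str
    label: str                  # "pass", a failing rule name, or "same_sex"


@dataclass
class PlantedTruth:
    hairpins: list[PlantedHairpin] = field(default_factory=list)
    samples: list[str] = field(default_factory=list)
    mirna_counts: dict = field(default_factory=dict)      # sample -> {hairpin id: reads}
    category_counts: dict = field(default_factory=dict)   # sample -> {category: reads}
    fragment_counts: dict = field(default_factory=dict)   # sample -> {pool: reads}
    fragment_pools: dict = field(default_factory=dict)    # pool -> [sequences]
    target_sites: list[PlantedSite] = field(default_factory=list)
    gene_bias: dict = field(default_factory=dict)         # transcript -> bias label

    def hairpin_by_id(self, hid: str) -> PlantedHairpin:
        for h in self.hairpins:
            if h.id == hid:
                return h
        raise KeyError(hid)


# ---------------------------------------------------------------------------
# Random sequence helpers
# ---------------------------------------------------------------------------

def _rand_dna(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode()


def _read_ok(insert: str, fp: FilterParams) -> bool:
    """Would a clean read with this insert survive the filters intact?"""
    read = insert + fp.adapter3
    cat, trimmed = classify_read(read, "I" * len(read), fp)
    return cat == "clean" and trimmed == insert


def _rand_mature(rng: np.random.Generator, length: int, fp: FilterParams,
                 taken: set[str]) -> str:
    """A mature miRNA sequence that yields clean reads and is unambiguous."""
    for _ in range(500):
        seq = _rand_dna(rng, length)
        if seq.count("A") > 0.55 * length:
            continue
        if seq.count("G") + seq.count("C") < 0.3 * length:
            continue
        if seq in taken:
            continue
        if _read_ok(seq, fp):
            return seq
    raise RuntimeError("could not draw a usable mature sequence")


# ---------------------------------------------------------------------------
# Hairpin element builders
# ---------------------------------------------------------------------------
# Each builder returns (element sequence, mature offset within element,
# expected violated criterion or None).  Elements embed their own 20 nt
# flanks so the precursor excised downstream is fully under our control.

_FLANK = 20


def _build_compliant(rng, fp, taken):
    L = int(rng.integers(20, 24))
    mature = _rand_mature(rng, L, fp, taken)
    loop = _rand_dna(rng, int(rng.integers(16, 49)))
    elem = _rand_dna(rng, _FLANK) + mature + loop + revcomp(mature) + _rand_dna(rng, _FLANK)
    return elem, mature, _FLANK, None


def _build_spacing(rng, fp, taken):
    L = int(rng.integers(20, 23))
    mature = _rand_mature(rng, L, fp, taken)
    loop = _rand_dna(rng, int(rng.integers(305, 316)))
    elem = _rand_dna(rng, _FLANK) + mature + loop + revcomp(mature) + _rand_dna(rng, _FLANK)
    return elem, mature, _FLANK, "star_space_max"


def _build_bulge(rng, fp, taken):
    # 18-pair stem interrupted by an internal 5x5 loop: bulge run = 5 on
    # both arms, asymmetry 0
    core = _rand_dna(rng, 18)
    rc = revcomp(core)
    bulge_m = "".join(rng.choice(list("CA"), size=5))
    bulge_s = "".join(rng.choice(list("CA"), size=5))
    mature = core[:9] + bulge_m + core[9:]
    if not _read_ok(mature, fp) or mature in taken:
        raise _Retry
    loop = _rand_dna(rng, int(rng.integers(16, 31)))
    star = rc[:9] + bulge_s + rc[9:]
    elem = _rand_dna(rng, _FLANK) + mature + loop + star + _rand_dna(rng, _FLANK)
    return elem, mature, _FLANK, "bulge"


def _build_asymmetry(rng, fp, taken):
    # mature fully paired, star carrying two 4 nt bulges: per-run bulge <= 4
    # but 8 unpaired star-side bases against 0 on the mature side
    mature = _rand_mature(rng, 20, fp, taken)
    rc = revcomp(mature)
    b1 = "".join(rng.choice(list("CA"), size=4))
    b2 = "".join(rng.choice(list("CA"), size=4))
    star = rc[:7] + b1 + rc[7:14] + b2 + rc[14:]
    loop = _rand_dna(rng, int(rng.integers(16, 31)))
    elem = _rand_dna(rng, _FLANK) + mature + loop + star + _rand_dna(rng, _FLANK)
    return elem, mature, _FLANK, "asymmetry"


def _build_energy(rng, fp, taken):
    # G-free arms: only the 7 planted A:T pairs can form, all isolated, so
    # the precursor MFE is bounded above -18 kcal/mol by construction
    for _ in range(200):
        gaps = rng.integers(2, 5, size=6)
        length = 7 + int(gaps.sum())
        if not 20 <= length <= 23:
            continue
        mature = "A" + "".join("C" * int(g) + "A" for g in gaps)
        if mature in taken or not _read_ok(mature, fp):
            continue
        star = "".join("T" if c == "A" else "C" for c in mature)[::-1]
        # the long 3' C-flank keeps the whole first excision window free of
        # G so no pairing beyond the designed isolated A:U pairs can form
        elem = "C" * _FLANK + mature + "C" * 18 + star + "C" * 60
        return elem, mature, _FLANK, "precursor_energy"
    raise _Retry


def _build_no_hairpin(rng, fp, taken):
    mature = _rand_mature(rng, int(rng.integers(20, 24)), fp, taken)
    elem = _rand_dna(rng, _FLANK) + mature + _rand_dna(rng, 40)
    return elem, mature, _FLANK, None


class _Retry(Exception):
    pass


_BUILDERS = {
    "compliant": _build_compliant,
    "spacing": _build_spacing,
    "bulge": _build_bulge,
    "asymmetry": _build_asymmetry,
    "energy": _build_energy,
    "no_hairpin": _build_no_hairpin,
}

# reserved slot length per element class (upper bound on element size)
_SLOT = {
    "compliant": 140, "spacing": 420, "bulge": 120,
    "asymmetry": 120, "energy": 150, "no_hairpin": 90,
}
_GAP = 420   # minimum spacing between planted elements


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

def generate_genome(spec: SyntheticSpec):
    """Build the genome, references and truth for a synthetic study.

    Returns ``(genome, gff_features, repeats, references, truth)`` where
    ``genome`` is {chromosome: sequence}, ``gff_features`` are 0-based
    feature tuples for :func:`sexmir.io.write_gff3`, ``repeats`` are BED
    intervals, and ``references`` bundles ncRNA classes, the mature-miRNA
    reference, the transcriptome and the per-gene bias table.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    fp = spec.filter_params()

    chrom_names = [c[0] for c in spec.chromosomes]
    chrom_len = dict(spec.chromosomes)

    # --- plan hairpin placement -------------------------------------------
    classes = ["compliant"] * spec.n_planted_hairpins
    for i in range(spec.n_decoy_loci):
        classes.append("decoy:" + DECOY_CLASSES[i % len(DECOY_CLASSES)])

    n_sex = int(round(spec.sex_chromosome_fraction * spec.n_planted_hairpins))
    others = [c for c in chrom_names if c != spec.sex_chromosome]
    chrom_of: list[str] = []
    for i, cls in enumerate(classes):
        if cls == "compliant" and i < n_sex:
            chrom_of.append(spec.sex_chromosome)
        else:
            chrom_of.append((others + [spec.sex_chromosome])[i % len(chrom_names)])

    # --- allocate coordinates ---------------------------------------------
    cursor = {c: 600 for c in chrom_names}
    placements: list[tuple[str, str, int]] = []   # (class, chrom, position)
    for cls, chrom in zip(classes, chrom_of):
        slot = _SLOT[cls.split(":")[-1]]
        placements.append((cls, chrom, cursor[chrom]))
        cursor[chrom] += slot + _GAP

    gene_slots: list[tuple[str, int]] = []
    for chrom in chrom_names:
        for _ in range(spec.n_genes_per_chromosome):
            gene_slots.append((chrom, cursor[chrom]))
            cursor[chrom] += 1400 + _GAP
    repeat_slots: list[tuple[str, int]] = []
    for chrom in chrom_names:
        for _ in range(spec.n_repeats_per_chromosome):
            repeat_slots.append((chrom, cursor[chrom]))
            cursor[chrom] += 1000 + _GAP

    for chrom in chrom_names:
        if cursor[chrom] + 600 > chrom_len[chrom]:
            raise SizingError(
                f"chromosome {chrom} too short ({chrom_len[chrom]} bp) for the "
                f"requested loci (needs >= {cursor[chrom] + 600} bp)")

    # --- random background -------------------------------------------------
    chrom_bytes = {
        c: bytearray(bytes(_BASES[rng.integers(0, 4, size=chrom_len[c])]))
        for c in chrom_names
    }

    # --- stamp and verify hairpins -----------------------------------------
    truth = PlantedTruth()
    taken: set[str] = set()
    n_compliant = 0
    for idx, (cls, chrom, pos) in enumerate(placements):
        short = cls.split(":")[-1]
        builder = _BUILDERS[short]
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        cand = None
        for _attempt in range(300):
            try:
                elem, mature, m_off, expected = builder(rng, fp, taken)
            except _Retry:
                continue
            stamped = elem if strand == "+" else revcomp(elem)
            chrom_bytes[chrom][pos:pos + len(elem)] = stamped.encode()
            genome_view = {chrom: chrom_bytes[chrom].decode()}
            if strand == "+":
                locus = GenomeLocus(chrom, pos + m_off, pos + m_off + len(mature), "+")
            else:
                locus = GenomeLocus(chrom, pos + len(elem) - m_off - len(mature),
                                    pos + len(elem) - m_off, "-")
            cand = excise_and_evaluate(mature, locus, genome_view, spec.mireap)
            ok = (cand.compliant if short == "compliant" else
                  (not cand.compliant
                   and (expected is None or expected in cand.violated)))
            if ok and short != "compliant":
                # a full revcomp(mature) star creates a mirror locus on the
                # other strand; a decoy must stay non-compliant there too
                star_off = elem.find(revcomp(mature), m_off + len(mature))
                if star_off >= 0:
                    Lm = len(mature)
                    if strand == "+":
                        mirror = GenomeLocus(chrom, pos + star_off,
                                             pos + star_off + Lm, "-")
                    else:
                        mirror = GenomeLocus(chrom, pos + len(elem) - star_off - Lm,
                                             pos + len(elem) - star_off, "+")
                    mcand = excise_and_evaluate(mature, mirror, genome_view,
                                                spec.mireap)
                    ok = not mcand.compliant
            if ok and mature not in taken:
                taken.add(mature)
                break
            cand = None
        if cand is None:
            raise RuntimeError(f"failed to plant {cls} element at {chrom}:{pos}")

        if short == "compliant":
            n_compliant += 1
            hid = f"hp{n_compliant:03d}"
        else:
            hid = f"decoy{idx:03d}-{short}"
        truth.hairpins.append(PlantedHairpin(
            id=hid, cls=cls, chromosome=chrom,
            start=locus.start, end=locus.end, strand=strand,
            precursor=cand.precursor, mature=mature, star=cand.star,
            arm=cand.arm, compliant=cand.compliant,
            violated=list(cand.violated),
        ))

    genome = {c: chrom_bytes[c].decode() for c in chrom_names}

    # --- gene models and repeats -------------------------------------------
    gff: list[tuple] = []
    gene_models: list[tuple] = []
    exons_by_gene: dict[str, list[tuple[str, int, int]]] = {}
    for gi, (chrom, pos) in enumerate(gene_slots, start=1):
        gid = f"gene{gi:03d}"
        strand = "+" if gi % 2 else "-"
        n_ex = int(rng.integers(2, 5))
        exon_lens = rng.integers(150, 401, size=n_ex)
        intron_lens = rng.integers(80, 201, size=max(0, n_ex - 1))
        cur = pos
        exons = []
        for e in range(n_ex):
            exons.append((chrom, cur, cur + int(exon_lens[e])))
            cur += int(exon_lens[e])
            if e < n_ex - 1:
                cur += int(intron_lens[e])
        g_start, g_end = exons[0][1], exons[-1][2]
        gff.append((chrom, "sexmir", "gene", g_start, g_end, strand, f"ID={gid}"))
        for k, (c, s, e) in enumerate(exons, start=1):
            gff.append((c, "sexmir", "exon", s, e, strand, f"Parent={gid};ID={gid}.e{k}"))
        gene_models.append((chrom, g_start, g_end, strand, gid))
        exons_by_gene[gid] = exons

    repeats: list[tuple] = []
    for ri, (chrom, pos) in enumerate(repeat_slots, start=1):
        length = int(rng.integers(500, 901))
        repeats.append((chrom, pos, pos + length, f"rep{ri:03d}"))

    # --- ncRNA references ----------------------------------------------------
    ncrna: dict[str, dict[str, str]] = {}
    for cls_name in sorted(spec.ncrna_classes):
        n, (lo, hi) = spec.ncrna_classes[cls_name]
        ncrna[cls_name] = {
            f"{cls_name}-{k + 1}": _rand_dna(rng, int(rng.integers(lo, hi + 1)))
            for k in range(n)
        }

    # --- bias assignment and known/novel split ------------------------------
    compliant = [h for h in truth.hairpins if h.compliant]
    em = spec.expression_model
    order = rng.permutation(len(compliant))
    labels = (["female-specific"] * em.n_female_specific
              + ["male-specific"] * em.n_male_specific
              + ["female-biased"] * em.n_female_biased
              + ["male-biased"] * em.n_male_biased)
    for slot_i, lab in enumerate(labels):
        h = compliant[order[slot_i]]
        h.bias = lab
        h.fold = em.fold_change if lab != "none" else 1.0
    for h in compliant[:spec.n_known]:
        h.known = True

    mature_ref = {f"spo-miR{200 + i}": h.mature
                  for i, h in enumerate(compliant) if h.known}

    # --- fragment pools -------------------------------------------------------
    sub_index: dict[str, str] = {}   # ncRNA substring -> class, for cross-checks
    for cls_name in sorted(ncrna):
        for seq in ncrna[cls_name].values():
            for Lf in range(18, 31):
                for p in range(len(seq) - Lf + 1):
                    sub_index.setdefault(seq[p:p + Lf], cls_name)

    def _draw_fragment(source: str, forbidden_classes: set[str] | None) -> str:
        for _ in range(500):
            Lf = int(rng.integers(18, 31))
            if len(source) < Lf:
                continue
            p = int(rng.integers(0, len(source) - Lf + 1))
            frag = source[p:p + Lf]
            if frag in taken:
                continue
            cls_hit = sub_index.get(frag)
            if forbidden_classes is not None and cls_hit is not None:
                continue
            if _read_ok(frag, fp):
                return frag
        raise RuntimeError("fragment sampling failed")

    pools: dict[str, list[str]] = {}
    for cls_name in sorted(ncrna):
        pool = []
        refs = list(ncrna[cls_name].values())
        for _ in range(12):
            src = refs[int(rng.integers(0, len(refs)))]
            for _ in range(200):
                frag = _draw_fragment(src, None)
                if sub_index.get(frag) == cls_name:
                    break
            pool.append(frag)
        pools[f"ncRNA:{cls_name}"] = pool
    deg_pool = []
    gids = sorted(exons_by_gene)
    for _ in range(24):
        gid = gids[int(rng.integers(0, len(gids)))]
        chrom, s, e = exons_by_gene[gid][int(rng.integers(0, len(exons_by_gene[gid])))]
        deg_pool.append(_draw_fragment(genome[chrom][s:e], set(ncrna)))
    pools["degradation"] = deg_pool
    rep_pool = []
    for _ in range(12):
        chrom, s, e, _name = repeats[int(rng.integers(0, len(repeats)))]
        rep_pool.append(_draw_fragment(genome[chrom][s:e], set(ncrna)))
    pools["repeat"] = rep_pool
    truth.fragment_pools = pools

    # --- transcriptome with planted target sites -----------------------------
    transcripts, gene_bias, sites = _build_transcriptome(spec, rng, compliant)
    truth.target_sites = sites
    truth.gene_bias = gene_bias
    truth.samples = [s for s, _ in spec.samples]

    references = {
        "ncrna": ncrna,
        "mature_mirnas": mature_ref,
        "transcripts": transcripts,
        "gene_bias": gene_bias,
        "gene_models": gene_models,
    }
    return genome, gff, repeats, references, truth


# ---------------------------------------------------------------------------
# Transcriptome with planted sites
# ---------------------------------------------------------------------------

def _rna_of(dna: str) -> str:
    return dna.upper().replace("T", "U")


def _site_for(mature_dna: str) -> str:
    """Transcript (DNA) window that is the perfect target of the miRNA."""
    return revcomp(mature_dna)


def _mutate_site(rng, mature: str, rule: str) -> tuple[str, str] | None:
    """Build a site variant designed to fail one rule; returns (site, rule)."""
    m = _rna_of(mature)
    L = len(m)
    site = list(_site_for(mature))

    def face(pos1: int) -> int:
        # transcript index facing miRNA position pos1 (1-based)
        return L - pos1

    def set_mismatch(pos1: int) -> None:
        mb = m[pos1 - 1]
        comp = {"A": "T", "U": "A", "G": "C", "C": "G"}[mb]
        options = [b for b in "ACGT" if b != comp
                   and (mb, {"A": "U", "C": "G", "G": "C", "T": "A"}[b]) not in
                   {("G", "U"), ("U", "G")}]
        # avoid wobble: G:U means site T under miRNA G, or site G under miRNA U
        if mb == "G":
            options = [b for b in options if b != "T"]
        if mb == "U":
            options = [b for b in options if b != "G"]
        site[face(pos1)] = options[int(rng.integers(0, len(options)))]

    def set_wobble(pos1: int) -> bool:
        mb = m[pos1 - 1]
        if mb == "G":
            site[face(pos1)] = "T"
            return True
        if mb == "U":
            site[face(pos1)] = "G"
            return True
        return False

    if rule == "rule4_positions_10_11":
        set_mismatch(10)
    elif rule == "rule2_adjacent_run":
        for p in (15, 16, 17):
            set_mismatch(p)
    elif rule == "rule3_adjacent_2_12":
        set_mismatch(6)
        set_mismatch(7)
    elif rule == "rule5_score_1_12":
        for p in (2, 4, 6):
            set_mismatch(p)
    elif rule == "rule1_total_score":
        wobblable = [p for p in range(1, L + 1) if m[p - 1] in "GU"]
        front = [p for p in wobblable if p <= 12][:5]
        back = [p for p in wobblable if p > 12]
        chosen = front + back
        if len(chosen) < 9:
            return None
        for p in chosen[:9]:
            set_wobble(p)
    elif rule == "rule6_mfe_ratio":
        # wobbles erode the duplex energy without creating hard mismatches;
        # add them (G positions first: larger energy loss) until the ratio
        # drops below threshold, keeping <= 8 total and <= 5 in 1-12
        # isolated mismatches beyond position 12 first (largest energy loss
        # per unit of mismatch score, and they cannot trip rules 2-5), then
        # wobbles; stop as soon as the ratio criterion fails
        weight = {"G": 3, "C": 3, "A": 2, "U": 2}
        mm_cand = sorted((p for p in range(13, L + 1)),
                         key=lambda p: (-weight[m[p - 1]], p))
        mm_chosen: list[int] = []
        for p in mm_cand:
            if all(abs(p - q) > 1 for q in mm_chosen):
                mm_chosen.append(p)
        score = 0.0
        done = False
        for p in mm_chosen:
            if score + 1.0 > 4.0:
                break
            set_mismatch(p)
            score += 1.0
            if build_alignment(m, _rna_of("".join(site))).mfe_ratio < 0.74:
                done = True
                break
        if not done:
            wob = ([p for p in range(13, L + 1) if m[p - 1] in "GU"
                    and p not in mm_chosen[:int(score)]]
                   + [p for p in range(1, 13) if m[p - 1] in "GU"])
            front_used = 0
            for p in wob:
                if score + 0.5 > 4.0 or (p <= 12 and front_used >= 5):
                    continue
                if site[L - p] != _site_for(mature)[L - p]:
                    continue   # already altered
                set_wobble(p)
                score += 0.5
                front_used += p <= 12
                if build_alignment(m, _rna_of("".join(site))).mfe_ratio < 0.74:
                    done = True
                    break
        if not done:
            return None
    else:
        raise ValueError(rule)
    return "".join(site), rule


def _build_transcriptome(spec: SyntheticSpec, rng, compliant: list[PlantedHairpin]):
    biased = [h for h in compliant if h.bias != "none"]
    transcripts: dict[str, str] = {}
    gene_bias: dict[str, str] = {}
    sites: list[PlantedSite] = []
    rules = ("rule1_total_score", "rule2_adjacent_run", "rule3_adjacent_2_12",
             "rule4_positions_10_11", "rule5_score_1_12", "rule6_mfe_ratio")
    rp = TargetRuleParams()

    def opposite(bias: str) -> str:
        return "male-biased" if bias.startswith("female") else "female-biased"

    def same(bias: str) -> str:
        return "female-biased" if bias.startswith("female") else "male-biased"

    def plant(tid: str, mirna: PlantedHairpin, site: str, label: str) -> None:
        for _ in range(100):
            length = int(rng.integers(800, 1501))
            pos = int(rng.integers(50, length - len(site) - 50))
            tx = _rand_dna(rng, pos) + site + _rand_dna(rng, length - pos - len(site))
            found = scan_targets("q", _rna_of(mirna.mature), tid, tx, rp)
            expected = {pos + 1} if label == "pass" or label == "same_sex" else set()
            if {s.position for s in found} == expected:
                transcripts[tid] = tx
                sites.append(PlantedSite(tid, pos + 1, mirna.id, label))
                return
        raise RuntimeError(f"could not plant target site for {mirna.id}")

    ti = 0
    for h in biased:
        ti += 1
        tid = f"tx{ti:03d}"
        gene_bias[tid] = opposite(h.bias)
        plant(tid, h, _site_for(h.mature), "pass")

    # rule-violating sites, cycling over biased miRNAs
    for rule in rules if biased else ():
        planted = False
        for h in biased:
            made = _mutate_site(rng, h.mature, rule)
            if made is None:
                continue
            site, _ = made
            flags = apply_rules(build_alignment(_rna_of(h.mature), _rna_of(site)), rp)
            if flags[rule]:
                continue   # construction did not break the intended rule
            ti += 1
            tid = f"tx{ti:03d}"
            gene_bias[tid] = opposite(h.bias)
            plant(tid, h, site, rule)
            planted = True
            break
        if not planted:
            raise RuntimeError(f"could not construct a {rule}-violating site")

    # same-direction bias: perfect site but non-antagonistic pair
    for h in biased[:3]:
        ti += 1
        tid = f"tx{ti:03d}"
        gene_bias[tid] = same(h.bias)
        plant(tid, h, _site_for(h.mature), "same_sex")

    while ti < spec.n_transcripts:
        ti += 1
        tid = f"tx{ti:03d}"
        gene_bias[tid] = "none"
        transcripts[tid] = _rand_dna(rng, int(rng.integers(600, 1201)))
    return transcripts, gene_bias, sites


# ---------------------------------------------------------------------------
# Read generation
# ---------------------------------------------------------------------------

def generate_reads(
    spec: SyntheticSpec,
    truth: PlantedTruth,
    out_dir: str | Path | None = None,
    genome: dict[str, str] | None = None,
):
    """Generate per-sample FASTQ reads and record exact counts in truth.

    When ``out_dir`` is given, writes ``<sample>.fastq`` files and returns
    the updated truth; otherwise returns ``(truth, reads_per_sample)`` with
    reads held in memory (intended for small configurations).  When
    ``genome`` is supplied, error-mutated reads are additionally required
    not to map exactly anywhere on it (matching the behaviour of real
    substitution errors), so genome-mapped tag sets stay exactly the
    planted ones.
    """
    spec.validate()
    fp = spec.filter_params()
    em = spec.expression_model
    master = np.random.SeedSequence([spec.seed, 1])
    sample_seeds = master.spawn(len(spec.samples))

    entities = truth.hairpins   # every planted mature can produce reads
    baseline_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    baselines = baseline_rng.gamma(em.baseline_shape, em.baseline_scale,
                                   size=len(entities)) + 5.0

    def rate(h: PlantedHairpin, sex: str) -> float:
        if h.bias == "none":
            return 1.0
        if h.bias == "female-specific":
            return h.fold if sex == "F" else 0.0
        if h.bias == "male-specific":
            return h.fold if sex == "M" else 0.0
        if h.bias == "female-biased":
            return h.fold if sex == "F" else 1.0
        return h.fold if sex == "M" else 1.0

    n_overhead = (sum(spec.category_counts.values()) + spec.ncrna_fragment_reads
                  + spec.degradation_fragment_reads + spec.repeat_fragment_reads)
    n_mirna_reads = spec.depth - n_overhead

    mature_set = {h.mature for h in entities}
    genome_index = None
    if genome is not None and spec.error_rate > 0:
        from .discovery import build_genome_index
        genome_index = (genome, build_genome_index(genome))
    in_memory: dict[str, list] = {}

    for (sample, sex), seed in zip(spec.samples, sample_seeds):
        rng = np.random.default_rng(seed)
        reads: list[tuple[str, str, str]] = []

        # contaminants, each constructed (and verified) to trip one rule
        for category in sorted(spec.category_counts):
            n = spec.category_counts[category]
            for _ in range(n):
                reads.append(_contaminant_read(rng, category, fp))
        truth.category_counts[sample] = dict(spec.category_counts)

        # fragments
        frag_counts: dict[str, int] = {}
        ncls = sorted(truth.fragment_pools)
        nc_classes = [p for p in ncls if p.startswith("ncRNA:")]
        per_class = spec.ncrna_fragment_reads // len(nc_classes)
        rest = spec.ncrna_fragment_reads - per_class * len(nc_classes)
        for j, pool_name in enumerate(nc_classes):
            cnt = per_class + (1 if j < rest else 0)
            frag_counts[pool_name] = cnt
            _emit_fragments(rng, reads, truth.fragment_pools[pool_name], cnt, fp)
        frag_counts["degradation"] = spec.degradation_fragment_reads
        _emit_fragments(rng, reads, truth.fragment_pools["degradation"],
                        spec.degradation_fragment_reads, fp)
        frag_counts["repeat"] = spec.repeat_fragment_reads
        _emit_fragments(rng, reads, truth.fragment_pools["repeat"],
                        spec.repeat_fragment_reads, fp)
        truth.fragment_counts[sample] = frag_counts

        # miRNA reads: gamma-Poisson weights, multinomial totals
        lam = np.array([baselines[i] * rate(h, sex)
                        for i, h in enumerate(entities)])
        if em.dispersion > 0:
            noise = rng.gamma(1.0 / em.dispersion, em.dispersion, size=len(entities))
            lam = lam * noise
        lam_sum = lam.sum()
        counts = rng.multinomial(n_mirna_reads, lam / lam_sum)
        truth.mirna_counts[sample] = {
            h.id: int(c) for h, c in zip(entities, counts) if c > 0
        }
        _emit_mirna_reads(rng, reads, entities, counts, spec, fp, mature_set,
                          genome_index)

        # deterministic shuffle, then neutral read ids
        perm = rng.permutation(len(reads))
        reads = [reads[i] for i in perm]
        reads = [(f"{sample}.{i + 1}", seq, qual)
                 for i, (_rid, seq, qual) in enumerate(reads)]
        if out_dir is not None:
            from .io import write_fastq
            write_fastq(reads, Path(out_dir) / f"{sample}.fastq")
        else:
            in_memory[sample] = reads

    if out_dir is None:
        return truth, in_memory
    return truth


def _contaminant_read(rng, category: str, fp: FilterParams) -> tuple[str, str, str]:
    """One read guaranteed (verified) to land in the given filter category."""
    for _ in range(500):
        if category == "low_quality":
            insert = _rand_dna(rng, int(rng.integers(19, 27)))
            seq = insert + fp.adapter3
            qual = list("I" * len(seq))
            k = int(rng.integers(2, 4))
            pos = rng.choice(len(seq), size=k, replace=False)
            for p in pos:
                qual[p] = "#"
            qual = "".join(qual)
        elif category == "adapter3_null":
            seq = _rand_dna(rng, 40)
            qual = "I" * len(seq)
        elif category == "adapter5_contaminant":
            insert = fp.adapter5 + _rand_dna(rng, int(rng.integers(1, 5)))
            seq = insert + fp.adapter3
            qual = "I" * len(seq)
        elif category == "insert_null":
            seq = fp.adapter3 + _rand_dna(rng, int(rng.integers(12, 20)))
            qual = "I" * len(seq)
        elif category == "polyA":
            L = int(rng.integers(20, 25))
            n_other = int(rng.integers(0, max(1, int(0.2 * L))))
            chars = ["A"] * (L - n_other) + list(
                rng.choice(list("CGT"), size=n_other))
            insert = "".join(chars)
            seq = insert + fp.adapter3
            qual = "I" * len(seq)
        elif category == "shorter_than_min":
            L = int(rng.integers(8, fp.min_insert_length))
            insert = _rand_dna(rng, L)
            seq = insert + fp.adapter3
            qual = "I" * len(seq)
        else:
            raise ValueError(f"unknown category {category}")
        got, _ = classify_read(seq, qual, fp)
        if got == category:
            return ("x", seq, qual)
    raise RuntimeError(f"could not construct a {category} read")


def _emit_fragments(rng, reads, pool: list[str], count: int, fp: FilterParams) -> None:
    picks = rng.integers(0, len(pool), size=count)
    for i in picks:
        insert = pool[int(i)]
        seq = insert + fp.adapter3
        reads.append(("x", seq, "I" * len(seq)))


def _maps_exactly(seq: str, genome_index) -> bool:
    genome, index = genome_index
    for query in (seq, revcomp(seq)):
        for chrom, pos in index.get(query[:18], ()):
            if genome[chrom][pos:pos + len(query)] == query:
                return True
    return False


def _emit_mirna_reads(rng, reads, entities, counts, spec: SyntheticSpec,
                      fp: FilterParams, mature_set: set[str],
                      genome_index=None) -> None:
    err = spec.error_rate
    for h, c in zip(entities, counts):
        c = int(c)
        if c == 0:
            continue
        L = len(h.mature)
        base_read = h.mature + fp.adapter3
        qual = "I" * len(base_read)
        if err <= 0:
            reads.extend([("x", base_read, qual)] * c)
            continue
        n_mut = int(rng.binomial(c, 1.0 - (1.0 - err) ** L))
        reads.extend([("x", base_read, qual)] * (c - n_mut))
        for _ in range(n_mut):
            for _try in range(100):
                k = 1 + int(rng.binomial(L - 1, err))   # at least one substitution
                pos = rng.choice(L, size=min(k, L), replace=False)
                s = list(h.mature)
                for p in pos:
                    choices = [b for b in "ACGT" if b != s[p]]
                    s[p] = choices[int(rng.integers(0, 3))]
                mutated = "".join(s)
                if mutated in mature_set:
                    continue
                if genome_index is not None and _maps_exactly(mutated, genome_index):
                    continue
                if _read_ok(mutated, fp):
                    reads.append(("x", mutated + fp.adapter3, qual))
                    break
            else:
                reads.append(("x", base_read, qual))


# ---------------------------------------------------------------------------
# Truth round trip
# ---------------------------------------------------------------------------

def write_truth(truth: PlantedTruth, path: str | Path) -> None:
    """Serialize the truth object as pretty-printed JSON."""
    payload = {
        "hairpins": [asdict(h) for h in truth.hairpins],
        "samples": truth.samples,
        "mirna_counts": truth.mirna_counts,
        "category_counts": truth.category_counts,
        "fragment_counts": truth.fragment_counts,
        "fragment_pools": truth.fragment_pools,
        "target_sites": [asdict(s) for s in truth.target_sites],
        "gene_bias": truth.gene_bias,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_truth(path: str | Path) -> PlantedTruth:
    """Load a truth file written by :func:`write_truth`."""
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(
                f"truth parse error in {path} at line {exc.lineno}: {exc.msg}"
            ) from exc
    return PlantedTruth(
        hairpins=[PlantedHairpin(**h) for h in payload["hairpins"]],
        samples=payload["samples"],
        mirna_counts=payload["mirna_counts"],
        category_counts=payload["category_counts"],
        fragment_counts=payload["fragment_counts"],
        fragment_pools=payload["fragment_pools"],
        target_sites=[PlantedSite(**s) for s in payload["target_sites"]],
        gene_bias=payload["gene_bias"],
    )
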