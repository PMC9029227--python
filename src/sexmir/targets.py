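"""Rule-based plant miRNA target prediction and antagonistic pairing.

A candidate site is an ungapped antiparallel duplex between a miRNA and a
window of a transcript: miRNA position 1 (5' end) faces the 3'-most base of
the window.  Each position is a Watson-Crick pair, a G:U wobble, or a
mismatch.  The six acceptance rules (positions numbered from the miRNA
5' end):

1. total mismatch score <= 4.0, where a wobble counts 0.5;
2. no run of more than 2 adjacent mismatches anywhere;
3. no 2 adjacent mismatches within positions 2-12;
4. no mismatch at positions 10-11;
5. mismatch score within positions 1-12 <= 2.5;
6. duplex MFE >= 74% of the MFE of the miRNA bound to its perfect
   complement (energies from the shared stacking model).

Wobbles contribute to the scored rules (1, 5) but by default do not count
as mismatches for the adjacency/positional rules (2, 3, 4); ``strict_wobble``
treats them as mismatches everywhere.

Antagonistic pairing keeps exactly the (miRNA, gene) pairs where a
female-biased miRNA targets a male-biased gene or vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np

from .discovery import duplex_energy, perfect_duplex_energy
from .expression import SexBiasCall

__all__ = [
    "TargetRuleParams",
    "DuplexAlignment",
    "TargetSite",
    "MirnaTargetPair",
    "build_alignment",
    "apply_rules",
    "scan_targets",
    "pair_sex_biased",
]

logger = logging.getLogger(__name__)

WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "U"), ("U", "G")}

RULE_NAMES = ("rule1_total_score", "rule2_adjacent_run", "rule3_adjacent_2_12",
              "rule4_positions_10_11", "rule5_score_1_12", "rule6_mfe_ratio")


@dataclass(frozen=True)
class TargetRuleParams:
    max_mismatches: float = 4.0
    max_adjacent_mismatches: int = 2
    no_adjacent_mismatch_region: tuple[int, int] = (2, 12)   # 1-based inclusive
    no_mismatch_region: tuple[int, int] = (10, 11)
    max_mismatches_1_12: float = 2.5
    min_mfe_ratio: float = 0.74
    strict_wobble: bool = False


@dataclass
class DuplexAlignment:
    """Ungapped miRNA/target-site duplex with per-position states."""

    mirna: str                      # 5'->3'
    site: str                       # transcript window, 5'->3'
    states: list[str]               # per miRNA position: "pair"|"wobble"|"mismatch"
    mismatch_score: float
    energy: float
    perfect_energy: float

    @property
    def mfe_ratio(self) -> float:
        if self.perfect_energy == 0.0:
            return 0.0
        return abs(self.energy) / abs(self.perfect_energy)


@dataclass
class TargetSite:
    mirna_id: str
    transcript_id: str
    position: int                   # 1-based start of the site on the transcript
    alignment: DuplexAlignment
    rule_flags: dict[str, bool]

    @property
    def verdict(self) -> bool:
        return all(self.rule_flags.values())


@dataclass
class MirnaTargetPair:
    mirna_id: str
    mirna_label: str
    gene_id: str
    gene_label: str
    sites: list[TargetSite] = field(default_factory=list)


def _rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def build_alignment(mirna: str, site: str) -> DuplexAlignment:
    """Classify every position of the duplex and compute its energies.

    miRNA position k (1-based from the 5' end) faces site base L-k (0-based),
    i.e. the site is read 3'->5' against the miRNA.
    """
    m = _rna(mirna)
    s = _rna(site)
    if len(m) != len(s):
        raise ValueError("miRNA and site must have equal length (ungapped duplex)")
    L = len(m)
    states: list[str] = []
    for k in range(L):
        duo = (m[k], s[L - 1 - k])
        if duo in WC:
            states.append("pair")
        elif duo in WOBBLE:
            states.append("wobble")
        else:
            states.append("mismatch")
    score = sum(1.0 if st == "mismatch" else (0.5 if st == "wobble" else 0.0)
                for st in states)
    paired = np.array([st != "mismatch" for st in states], dtype=bool)
    energy = duplex_energy(m, s, paired)
    return DuplexAlignment(
        mirna=m, site=s, states=states, mismatch_score=score,
        energy=energy, perfect_energy=perfect_duplex_energy(m))


def apply_rules(
    aln: DuplexAlignment,
    params: TargetRuleParams = TargetRuleParams(),
) -> dict[str, bool]:
    """Evaluate the six positional/energetic rules on an alignment."""
    states = aln.states
    L = len(states)
    hard = [st == "mismatch" or (params.strict_wobble and st == "wobble")
            for st in states]

    flags: dict[str, bool] = {}
    flags["rule1_total_score"] = aln.mismatch_score <= params.max_mismatches

    # rule 2: longest run of adjacent hard mismatches
    run = best = 0
    for h in hard:
        run = run + 1 if h else 0
        best = max(best, run)
    flags["rule2_adjacent_run"] = best <= params.max_adjacent_mismatches

    # rule 3: both members of the adjacent pair must lie inside the region
    lo, hi = params.no_adjacent_mismatch_region
    flags["rule3_adjacent_2_12"] = not any(
        hard[q - 1] and hard[q]                      # 1-based positions q, q+1
        for q in range(lo, min(hi - 1, L - 1) + 1))

    nlo, nhi = params.no_mismatch_region
    flags["rule4_positions_10_11"] = not any(
        hard[k - 1] for k in range(nlo, min(nhi, L) + 1))

    score_1_12 = sum(
        1.0 if states[k] == "mismatch" else (0.5 if states[k] == "wobble" else 0.0)
        for k in range(0, min(12, L)))
    flags["rule5_score_1_12"] = score_1_12 <= params.max_mismatches_1_12

    flags["rule6_mfe_ratio"] = aln.mfe_ratio >= params.min_mfe_ratio
    return flags


def scan_targets(
    mirna_id: str,
    mirna_seq: str,
    transcript_id: str,
    transcript_seq: str,
    params: TargetRuleParams = TargetRuleParams(),
    all_sites: bool = False,
) -> list[TargetSite]:
    """Slide the miRNA along a transcript and report passing target sites.

    Returns sites at every window whose duplex satisfies all six rules
    (or every window when ``all_sites`` is set), with 1-based positions.
    A transcript shorter than the miRNA yields an empty list.
    """
    m = _rna(mirna_seq)
    t = _rna(transcript_seq)
    L, n = len(m), len(t)
    if n < L:
        return []
    sites: list[TargetSite] = []
    for start in range(0, n - L + 1):
        aln = build_alignment(m, t[start:start + L])
        flags = apply_rules(aln, params)
        if all_sites or all(flags.values()):
            sites.append(TargetSite(
                mirna_id=mirna_id,
                transcript_id=transcript_id,
                position=start + 1,
                alignment=aln,
                rule_flags=flags,
            ))
    return sites


def pair_sex_biased(
    sites: list[TargetSite],
    mirna_calls: list[SexBiasCall],
    gene_bias: dict[str, str],
) -> list[MirnaTargetPair]:
    """Keep miRNA/target pairs with antagonistic sex bias.

    A pair survives when a female-biased (or female-specific) miRNA targets
    a male-biased gene, or a male-biased/-specific miRNA targets a
    female-biased gene.  Sites referencing genes absent from ``gene_bias``
    are skipped with a warning.  Output is ordered by (miRNA id, gene id).
    """
    mirna_label = {c.mirna: c.label for c in mirna_calls}

    def sex_of(label: str) -> str | None:
        if label.startswith("female"):
            return "F"
        if label.startswith("male"):
            return "M"
        return None

    pairs: dict[tuple[str, str], MirnaTargetPair] = {}
    for site in sites:
        if site.transcript_id not in gene_bias:
            logger.warning("site references unknown gene %s; skipped",
                           site.transcript_id)
            continue
        ml = mirna_label.get(site.mirna_id, "none")
        gl = gene_bias[site.transcript_id]
        ms, gs = sex_of(ml), sex_of(gl)
        if ms is None or gs is None or ms == gs:
            continue
        key = (site.mirna_id, site.transcript_id)
        if key not in pairs:
            pairs[key] = MirnaTargetPair(
                mirna_id=site.mirna_id, mirna_label=ml,
                gene_id=site.transcript_id, gene_label=gl)
        pairs[key].sites.append(site)
    return [pairs[k] for k in sorted(pairs)]
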