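"""miRNA expression quantification and differential expression.

Quantification is tags-per-million (TPM): ``count / total clean tags * 1e6``
per sample.  Differential expression between two conditions uses the exact
count-comparison test of Audic & Claverie: given a count ``x`` observed in a
library of ``N1`` clean tags, the probability of observing ``y`` in a
library of ``N2`` tags is

    p(y|x) = (N2/N1)^y * (x+y)! / (x! y!) * (1 + N2/N1)^-(x+y+1)

The lower tail C = sum_{v<=y} p(v|x) and the upper tail D = sum_{v>=y}
p(v|x) are combined into a two-sided p-value min(1, 2*min(C, D)).

Conditioning convention: the distribution is conditioned on the side with
the larger count (ties broken by the larger library, then by condition 1)
and the tails are mapped back to the caller's orientation.  With that
convention the p-value is exactly invariant under swapping the two
conditions, which a two-group comparison should be; conditioning always on
``x`` would make the verdict depend on group order.

Replicates are pooled by summation before testing (the statistic is defined
for one count per condition).  A comparison is significant when
|log2 fold change| >= 1 and p < 0.05 (both configurable); the fold change is
computed on pooled TPM with a pseudo-TPM of 0.01 added to both groups only
when either group is zero, so sex-specific miRNAs remain callable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "CountMatrix",
    "ACTestResult",
    "SexBiasCall",
    "tpm_normalize",
    "ac_test",
    "call_de",
    "classify_sex_bias",
    "filter_sex_chromosome",
    "ddct",
    "STAGE_PAIRS",
]

#: the three female/male flower stage pairs compared throughout
STAGE_PAIRS = (("FNS", "M03"), ("FNB", "M05"), ("FYS", "M10"))

FEMALE_GROUPS = ("FNS", "FNB", "FYS")
MALE_GROUPS = ("M03", "M05", "M10")


@dataclass
class CountMatrix:
    """Read counts per miRNA and sample, with library sizes and design.

    ``counts``: DataFrame, rows = miRNA ids, columns = sample names.
    ``totals``: total clean tags per sample (the TPM denominator).
    ``groups``: sample -> group label (FNS/FNB/FYS/M03/M05/M10).
    """

    counts: pd.DataFrame
    totals: dict[str, int]
    groups: dict[str, str]

    def __post_init__(self) -> None:
        for s in self.counts.columns:
            if s not in self.totals:
                raise ValueError(f"sample {s} missing from totals")
            if s not in self.groups:
                raise ValueError(f"sample {s} missing from groups")
            if self.totals[s] < int(self.counts[s].sum()):
                raise ValueError(f"sample {s}: total clean tags below column sum")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    def sex_of(self, sample: str) -> str:
        return "F" if self.groups[sample] in FEMALE_GROUPS else "M"

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.groups[s] == group]


def tpm_normalize(cm: CountMatrix) -> pd.DataFrame:
    """Tags-per-million normalization: count / total clean tags * 1e6."""
    tpm = cm.counts.astype(float).copy()
    for s in tpm.columns:
        n = cm.totals[s]
        if n <= 0:
            raise ValueError(f"sample {s} has zero total clean tags")
        tpm[s] = tpm[s] / n * 1e6
    return tpm


# ---------------------------------------------------------------------------
# Exact count test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ACTestResult:
    x: int
    y: int
    N1: float
    N2: float
    C: float            # lower-tail mass of y given the conditioning side
    D: float            # upper-tail mass
    p: float            # two-sided p-value
    fold_change: float  # (y/N2) / (x/N1), may be inf/nan at zero counts


def _tail_sums(cond: int, obs: int, ratio: float) -> tuple[float, float]:
    """C = sum_{v<=obs} p(v|cond), D = sum_{v>=obs} p(v|cond).

    Both tails are accumulated by direct summation (log-space terms), the
    upper tail truncated adaptively once its geometric remainder is
    negligible, so small tail masses keep full relative precision.
    """
    log_r = math.log(ratio)
    log_1r = math.log1p(ratio)

    def block(lo: int, hi: int) -> np.ndarray:
        v = np.arange(lo, hi, dtype=np.float64)
        logp = (v * log_r - (cond + v + 1.0) * log_1r
                + gammaln(cond + v + 1.0) - gammaln(cond + 1.0) - gammaln(v + 1.0))
        return np.exp(logp)

    lower = float(block(0, obs + 1).sum()) if obs >= 0 else 0.0

    # upper tail from obs upward; term ratio -> ratio/(1+ratio) < 1
    upper = 0.0
    lo = obs
    chunk = max(64, 2 * (cond + obs + 2))
    while True:
        terms = block(lo, lo + chunk)
        upper += float(terms.sum())
        last = float(terms[-1])
        v_next = lo + chunk
        # the term ratio decreases in v; once below 1 a geometric bound on
        # the remainder is valid
        rho = ratio * (cond + v_next + 1.0) / ((v_next + 1.0) * (1.0 + ratio))
        if last == 0.0:
            break
        if rho < 1.0 and last * rho / (1.0 - rho) <= 1e-16 * max(upper, 1e-300):
            break
        lo += chunk
    return lower, upper


def ac_test(x: int, y: int, N1: float, N2: float) -> ACTestResult:
    """Exact comparison of one count per condition (Audic-Claverie).

    ``x`` is the count in condition 1 (library size ``N1``), ``y`` the count
    in condition 2 (``N2``).  See the module docstring for the tail and
    conditioning conventions.
    """
    for name, v in (("x", x), ("y", y)):
        if not float(v).is_integer() or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    if N1 <= 0 or N2 <= 0:
        raise ValueError("library sizes must be positive")
    x, y = int(x), int(y)

    # condition on the larger count (tie: larger library, then condition 1)
    if (y, N2) > (x, N1):
        lower, upper = _tail_sums(cond=y, obs=x, ratio=N1 / N2)
        # small x <=> large y: the lower tail of x maps to the upper tail of y
        C, D = upper, lower
    else:
        lower, upper = _tail_sums(cond=x, obs=y, ratio=N2 / N1)
        C, D = lower, upper

    p = min(1.0, 2.0 * min(C, D))
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = (y / N2) / (x / N1) if x > 0 else (math.inf if y > 0 else math.nan)
    return ACTestResult(x=x, y=y, N1=N1, N2=N2, C=C, D=D, p=p, fold_change=fc)


# ---------------------------------------------------------------------------
# Differential expression calling
# ---------------------------------------------------------------------------

PSEUDO_TPM = 0.01


def call_de(
    cm: CountMatrix,
    group_a: str,
    group_b: str,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Differential expression between two groups on pooled counts.

    Returns a table indexed by miRNA id with columns
    ``x, y, N1, N2, C, D, p, log2fc, significant, direction`` where
    direction is "up_in_b" / "up_in_a" / "none".  ``x`` pools ``group_a``.
    """
    samples_a = cm.samples_in_group(group_a)
    samples_b = cm.samples_in_group(group_b)
    if not samples_a or not samples_b:
        raise ValueError(f"empty group in comparison {group_a} vs {group_b}")
    N1 = float(sum(cm.totals[s] for s in samples_a))
    N2 = float(sum(cm.totals[s] for s in samples_b))
    xs = cm.counts[samples_a].sum(axis=1).astype(int)
    ys = cm.counts[samples_b].sum(axis=1).astype(int)

    rows = []
    log2_thr = math.log2(fc_threshold)
    for mid in cm.counts.index:
        x, y = int(xs[mid]), int(ys[mid])
        r = ac_test(x, y, N1, N2)
        tpm_a = x / N1 * 1e6
        tpm_b = y / N2 * 1e6
        if tpm_a == 0.0 or tpm_b == 0.0:
            tpm_a += PSEUDO_TPM
            tpm_b += PSEUDO_TPM
        log2fc = math.log2(tpm_b / tpm_a)
        sig = abs(log2fc) >= log2_thr and r.p < p_threshold
        direction = "none"
        if sig:
            direction = "up_in_b" if log2fc > 0 else "up_in_a"
        rows.append((x, y, N1, N2, r.C, r.D, r.p, log2fc, sig, direction))
    return pd.DataFrame(
        rows,
        index=cm.counts.index,
        columns=["x", "y", "N1", "N2", "C", "D", "p", "log2fc",
                 "significant", "direction"],
    )


# ---------------------------------------------------------------------------
# Sex-bias classification
# ---------------------------------------------------------------------------

@dataclass
class SexBiasCall:
    mirna: str
    label: str                       # female-/male-biased, -specific, or none
    verdicts: dict[str, str] = field(default_factory=dict)  # pair -> direction


def classify_sex_bias(
    de_tables: dict[tuple[str, str], pd.DataFrame],
    tpm: pd.DataFrame,
    groups: dict[str, str],
    presence_threshold: float = 1.0,
) -> list[SexBiasCall]:
    """Classify miRNAs as sex-biased/-specific across the three stage pairs.

    A miRNA is sex-biased when it is significantly DE *in all three*
    female/male stage comparisons with a consistent direction, and
    sex-specific when additionally its TPM stays below
    ``presence_threshold`` in every sample of the other sex.  ``de_tables``
    must be keyed by exactly the pairs (FNS,M03), (FNB,M05), (FYS,M10) with
    the female group as condition 1 (``x``).
    """
    missing = [p for p in STAGE_PAIRS if p not in de_tables]
    if missing:
        raise ValueError(f"missing stage-pair DE tables: {missing}")

    female_samples = [s for s in tpm.columns if groups[s] in FEMALE_GROUPS]
    male_samples = [s for s in tpm.columns if groups[s] in MALE_GROUPS]

    calls: list[SexBiasCall] = []
    for mid in de_tables[STAGE_PAIRS[0]].index:
        verdicts: dict[str, str] = {}
        for pair in STAGE_PAIRS:
            row = de_tables[pair].loc[mid]
            if not row["significant"]:
                verdicts["/".join(pair)] = "none"
            elif row["direction"] == "up_in_b":
                verdicts["/".join(pair)] = "male-higher"
            else:
                verdicts["/".join(pair)] = "female-higher"
        dirs = set(verdicts.values())
        if dirs == {"male-higher"}:
            label = "male-biased"
            other = female_samples
        elif dirs == {"female-higher"}:
            label = "female-biased"
            other = male_samples
        else:
            calls.append(SexBiasCall(mid, "none", verdicts))
            continue
        if mid in tpm.index and other and (tpm.loc[mid, other] < presence_threshold).all():
            label = label.replace("biased", "specific")
        calls.append(SexBiasCall(mid, label, verdicts))
    return calls


def filter_sex_chromosome(
    table: pd.DataFrame,
    chromosome_of: dict[str, str],
    sex_chromosome: str,
    known_chromosomes: set[str] | None = None,
) -> pd.DataFrame:
    """Subset a DE (or call) table to miRNAs residing on the sex chromosome."""
    if known_chromosomes is not None and sex_chromosome not in known_chromosomes:
        raise ValueError(f"unknown chromosome {sex_chromosome!r}")
    keep = [mid for mid in table.index
            if chromosome_of.get(mid) == sex_chromosome]
    return table.loc[keep]


# ---------------------------------------------------------------------------
# qRT-PCR helper
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DdCtInput:
    ct_target_treated: float
    ct_reference_treated: float
    ct_target_control: float
    ct_reference_control: float

    def __post_init__(self) -> None:
        for f in (self.ct_target_treated, self.ct_reference_treated,
                  self.ct_target_control, self.ct_reference_control):
            if f is None or not math.isfinite(f) or f <= 0:
                raise ValueError("all Ct values must be positive and finite")


def ddct(inp: DdCtInput) -> float:
    """Relative expression by the 2^-ddCt method."""
    d_treated = inp.ct_target_treated - inp.ct_reference_treated
    d_control = inp.ct_target_control - inp.ct_reference_control
    return 2.0 ** -(d_treated - d_control)
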