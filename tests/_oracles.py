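"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the implementation's code paths: structures are
enumerated recursively, tail sums use the printed term recurrence, and
target windows are evaluated with direct per-position logic.
"""

from __future__ import annotations

COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}
PAIR_E = {("G", "C"): -3.0, ("C", "G"): -3.0,
          ("A", "U"): -2.0, ("U", "A"): -2.0,
          ("G", "U"): -1.0, ("U", "G"): -1.0}
ISOLATED = -1.0
MIN_LOOP = 3


def enumerate_structures(seq: str):
    """Yield every non-pseudoknotted pair set of an RNA (min loop 3)."""
    n = len(seq)

    def pairable(i, j):
        return (seq[i], seq[j]) in PAIR_E and j - i - 1 >= MIN_LOOP

    def gen(i, j):
        if j - i < MIN_LOOP + 1:
            yield frozenset()
            return
        for s in gen(i, j - 1):
            yield s
        for k in range(i, j - MIN_LOOP):
            if pairable(k, j):
                left = list(gen(i, k - 1)) if k > i else [frozenset()]
                for s2 in gen(k + 1, j - 1):
                    base = s2 | {(k, j)}
                    for s1 in left:
                        yield s1 | base

    yield from gen(0, n - 1)


def structure_energy(seq: str, pairs) -> float:
    """Energy of an explicit structure: stack term when (i+1, j-1) paired."""
    pairs = set(pairs)
    total = 0.0
    for i, j in pairs:
        e = PAIR_E[(seq[i], seq[j])]
        total += e if (i + 1, j - 1) in pairs else ISOLATED
    return total


def min_energy_enumerated(seq: str) -> float:
    best = 0.0
    for s in enumerate_structures(seq):
        e = structure_energy(seq, s)
        if e < best:
            best = e
    return best


def ac_brute(x: int, y: int, N1: float, N2: float):
    """Tails of the exact count test by direct summation of the printed
    term recurrence, under the same conditioning convention as the
    implementation (condition on the larger count; tie -> larger library)."""
    if (y, N2) > (x, N1):
        cond, obs, ratio, swap = y, x, N1 / N2, True
    else:
        cond, obs, ratio, swap = x, y, N2 / N1, False
    t = (1.0 + ratio) ** -(cond + 1)       # p(0|cond)
    lower = 0.0
    tv = t
    for v in range(obs):
        lower += tv
        tv = tv * ratio * (cond + v + 1) / ((v + 1) * (1.0 + ratio))
    lower += tv                            # includes the observed point
    upper = tv
    v = obs
    while True:
        tv = tv * ratio * (cond + v + 1) / ((v + 1) * (1.0 + ratio))
        upper += tv
        v += 1
        if v > cond + obs + 10 and tv < 1e-30 * (upper + 1e-300):
            break
    C, D = (upper, lower) if swap else (lower, upper)
    return C, D, min(1.0, 2.0 * min(C, D))


def window_verdict(mirna: str, site: str, params) -> tuple[bool, dict]:
    """Direct re-implementation of the six target rules for one window."""
    L = len(mirna)
    m = mirna.upper().replace("T", "U")
    s = site.upper().replace("T", "U")
    states = []
    for k in range(L):
        a, b = m[k], s[L - 1 - k]
        if COMP.get(a) == b:
            states.append("pair")
        elif (a, b) in (("G", "U"), ("U", "G")):
            states.append("wobble")
        else:
            states.append("mismatch")

    def sc(st):
        return 1.0 if st == "mismatch" else (0.5 if st == "wobble" else 0.0)

    score = sum(sc(st) for st in states)
    hard = [st == "mismatch" for st in states]

    run = best = 0
    for h in hard:
        run = run + 1 if h else 0
        best = max(best, run)

    adj_2_12 = any(hard[q - 1] and hard[q] for q in range(2, min(11, L - 1) + 1))
    mm_10_11 = any(hard[k] for k in (9, 10) if k < L)
    score_1_12 = sum(sc(states[k]) for k in range(min(12, L)))

    energy = 0.0
    for k in range(L):
        if states[k] == "mismatch":
            continue
        e = PAIR_E[(m[k], s[L - 1 - k])]
        nxt = k + 1 < L and states[k + 1] != "mismatch"
        energy += e if nxt else ISOLATED
    perfect = 0.0
    for k in range(L):
        e = PAIR_E[(m[k], COMP[m[k]])]
        perfect += e if k + 1 < L else ISOLATED
    ratio = abs(energy) / abs(perfect) if perfect else 0.0

    flags = {
        "rule1_total_score": score <= params.max_mismatches,
        "rule2_adjacent_run": best <= params.max_adjacent_mismatches,
        "rule3_adjacent_2_12": not adj_2_12,
        "rule4_positions_10_11": not mm_10_11,
        "rule5_score_1_12": score_1_12 <= params.max_mismatches_1_12,
        "rule6_mfe_ratio": ratio >= params.min_mfe_ratio,
    }
    return all(flags.values()), flags
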