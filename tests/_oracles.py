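"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected result by a method structurally
different from the implementation it checks (enumeration, exhaustive
search, or a third-party routine), so agreement is evidence rather than
tautology.
"""

from __future__ import annotations

import itertools


# ---------------------------------------------------------------- ACMG

def acmg_oracle(codes: frozenset[str]) -> str:
    """Rule-by-rule transcription of the criteria-combining table.

    Checks every listed combination explicitly instead of counting into
    shared boolean algebra.
    """
    pvs = [c for c in codes if c == "PVS1"]
    ps = [c for c in codes if c.startswith("PS")]
    pm = [c for c in codes if c.startswith("PM")]
    pp = [c for c in codes if c.startswith("PP")]
    ba = [c for c in codes if c == "BA1"]
    bs = [c for c in codes if c.startswith("BS")]
    bp = [c for c in codes if c.startswith("BP")]

    pathogenic_rules = [
        len(pvs) >= 1 and len(ps) >= 1,
        len(pvs) >= 1 and len(pm) >= 2,
        len(pvs) >= 1 and len(pm) == 1 and len(pp) == 1,
        len(pvs) >= 1 and len(pp) >= 2,
        len(ps) >= 2,
        len(ps) == 1 and len(pm) >= 3,
        len(ps) == 1 and len(pm) == 2 and len(pp) >= 2,
        len(ps) == 1 and len(pm) == 1 and len(pp) >= 4,
    ]
    likely_pathogenic_rules = [
        len(pvs) == 1 and len(pm) == 1,
        len(ps) == 1 and 1 <= len(pm) <= 2,
        len(ps) == 1 and len(pp) >= 2,
        len(pm) >= 3,
        len(pm) == 2 and len(pp) >= 2,
        len(pm) == 1 and len(pp) >= 4,
    ]
    benign_rules = [len(ba) >= 1, len(bs) >= 2]
    likely_benign_rules = [len(bs) == 1 and len(bp) == 1, len(bp) >= 2]

    # contradictory evidence (codes on both sides) defaults to VUS
    if (pvs or ps or pm or pp) and (ba or bs or bp):
        return "VUS"

    pathogenic = any(pathogenic_rules)
    likely = any(likely_pathogenic_rules)
    benign = any(benign_rules)
    likely_benign = any(likely_benign_rules)

    if pathogenic:
        return "P"
    if likely:
        return "LP"
    if benign:
        return "B"
    if likely_benign:
        return "LB"
    return "VUS"


def all_code_subsets(codes, max_size):
    for k in range(max_size + 1):
        yield from itertools.combinations(codes, k)


# ------------------------------------------------------- indel left shift

def normalize_oracle(pos: int, ref: str, alt: str, seq: str):
    """Exhaustive-search normal form of an allele pair.

    Enumerates every (position, ref, alt) representation in a window that
    reproduces the same edited sequence, then picks the shortest, leftmost
    one with non-empty alleles — the parsimonious left-aligned form.
    """
    edited = seq[:pos - 1] + alt + seq[pos - 1 + len(ref):]
    n, m = len(seq), len(edited)
    best = None
    for p in range(max(1, pos - 40), min(n, pos + 40) + 1):
        for lr in range(0, 41):
            if p - 1 + lr > n:
                break
            r = seq[p - 1:p - 1 + lr]
            suffix_len = n - (p - 1 + lr)
            la = m - (p - 1) - suffix_len
            if la < 0:
                continue
            a = edited[p - 1:p - 1 + la]
            if seq[:p - 1] + a + seq[p - 1 + lr:] != edited:
                continue
            if not r or not a or r == a:
                continue
            cand = (len(r) + len(a), p, r, a)
            if best is None or cand[:2] < best[:2]:
                best = cand
    assert best is not None
    return best[1], best[2], best[3]


# ------------------------------------------------------------ phase logic

def phase_oracle(father_gt, mother_gt, father_gt2, mother_gt2):
    """Enumerate parental transmissions for a double-het child.

    Returns (kind, segregation) by listing every transmissible haplotype
    pair and asking which phases are possible.
    """
    if father_gt is None and mother_gt is None and \
            father_gt2 is None and mother_gt2 is None:
        return "compound_het", "untested"

    def alleles(gt):
        return {None: (0, 1), 0: (0,), 1: (0, 1), 2: (1,)}[gt]

    phases = set()
    for f1 in alleles(father_gt):
        for f2 in alleles(father_gt2):
            for m1 in alleles(mother_gt):
                for m2 in alleles(mother_gt2):
                    if f1 + m1 == 1 and f2 + m2 == 1:
                        phases.add(("trans" if f1 != f2 else "cis"))
    if not phases:
        return "compound_het", "inconsistent"
    if phases == {"trans"}:
        return "compound_het", "consistent"
    if phases == {"cis"}:
        return "single_het", "consistent"
    return "compound_het", "untested"
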