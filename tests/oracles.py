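"""Independent brute-force oracles used to cross-check the production code.

Each oracle re-implements an operation from first principles (exhaustive
enumeration, naive recursion, textbook formulas) without importing the
production implementation of the step it checks. They are deliberately
slow and simple.
"""

from __future__ import annotations

import math
from functools import lru_cache
from itertools import permutations, product

# ---------------------------------------------------------------------------
# NG86 Ka/Ks by explicit enumeration
# ---------------------------------------------------------------------------

_BASES = "ACGT"
_CODON_TABLE = {}  # built from Biopython to stay independent of the package
from Bio.Data.CodonTable import unambiguous_dna_by_id as _tables

_fwd = _tables[1].forward_table
for _b1, _b2, _b3 in product(_BASES, repeat=3):
    _c = _b1 + _b2 + _b3
    _CODON_TABLE[_c] = _fwd.get(_c, "*")
_STOPS = {c for c, a in _CODON_TABLE.items() if a == "*"}


def codon_sites(codon: str) -> tuple[float, float]:
    """Synonymous / non-synonymous site counts; mutations to stop codons
    count as non-synonymous."""
    syn = 0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            if _CODON_TABLE[mut] == _CODON_TABLE[codon]:
                syn += 1
    return syn / 3.0, 3.0 - syn / 3.0


def codon_pair_differences(a: str, b: str) -> tuple[float, float]:
    """Equal-weight average of (syn, nonsyn) steps over minimal pathways,
    skipping pathways through stops unless all are blocked."""
    positions = [i for i in range(3) if a[i] != b[i]]
    if not positions:
        return 0.0, 0.0
    clean, blocked = [], []
    for order in permutations(positions):
        current = a
        sd = nd = 0
        hit_stop = False
        for pos in order:
            nxt = current[:pos] + b[pos] + current[pos + 1 :]
            if nxt in _STOPS:
                hit_stop = True
            if _CODON_TABLE[nxt] == _CODON_TABLE[current]:
                sd += 1
            else:
                nd += 1
            current = nxt
        (blocked if hit_stop else clean).append((sd, nd))
    pool = clean or blocked
    return (
        sum(x for x, _ in pool) / len(pool),
        sum(y for _, y in pool) / len(pool),
    )


def ng86_oracle(codons_a, codons_b):
    """(ka, ks) or None for a saturated distance; codon columns with a
    gap, N, or stop are skipped."""
    S = N = sd = nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        if "-" in ca or "-" in cb or "N" in ca or "N" in cb:
            continue
        if ca in _STOPS or cb in _STOPS:
            continue
        sa, na = codon_sites(ca)
        sb, nb = codon_sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        s, n = codon_pair_differences(ca, cb)
        sd += s
        nd += n
    def jc(p):
        if p >= 0.75:
            return None
        return -0.75 * math.log(1 - 4 * p / 3) or 0.0
    return jc(nd / N), jc(sd / S)


# ---------------------------------------------------------------------------
# Gotoh global alignment by naive memoized recursion
# ---------------------------------------------------------------------------


def gotoh_oracle(a: str, b: str, score, gap_open: float, gap_extend: float):
    """Optimal global alignment with affine gaps; ties broken by state
    preference M > X > Y (X = gap in b). Returns (aln_a, aln_b, score)."""
    NEG = float("-inf")

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: int) -> float:
        # value of the best alignment of a[:i], b[:j] ending in `state`
        if i == 0 and j == 0:
            return 0.0 if state == 0 else NEG
        if state == 0:  # match/mismatch consuming a[i-1], b[j-1]
            if i == 0 or j == 0:
                return NEG
            prev = max(best(i - 1, j - 1, s) for s in range(3))
            return prev + score(a[i - 1], b[j - 1])
        if state == 1:  # a[i-1] aligned to gap
            if i == 0:
                return NEG
            return max(
                best(i - 1, j, 0) - gap_open,
                best(i - 1, j, 1) - gap_extend,
                best(i - 1, j, 2) - gap_open,
            )
        if j == 0:
            return NEG
        return max(
            best(i, j - 1, 0) - gap_open,
            best(i, j - 1, 1) - gap_open,
            best(i, j - 1, 2) - gap_extend,
        )

    i, j = len(a), len(b)
    finals = [best(i, j, s) for s in range(3)]
    state = finals.index(max(finals))
    total = finals[state]
    out_a, out_b = [], []
    tol = 1e-9
    while i > 0 or j > 0:
        if state == 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            prev = best(i, j, 0) - score(a[i - 1], b[j - 1])
            i, j = i - 1, j - 1
            costs = [0.0, 0.0, 0.0]
        elif state == 1:
            out_a.append(a[i - 1])
            out_b.append("-")
            prev = best(i, j, 1)
            i -= 1
            costs = [gap_open, gap_extend, gap_open]
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            prev = best(i, j, 2)
            j -= 1
            costs = [gap_open, gap_open, gap_extend]
        for s in range(3):
            if abs(best(i, j, s) - costs[s] - prev) < tol:
                state = s
                break
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    best.cache_clear()
    return "".join(reversed(out_a)), "".join(reversed(out_b)), total


# ---------------------------------------------------------------------------
# Motif scanning by exhaustive expansion enumeration
# ---------------------------------------------------------------------------


def prosite_scan_oracle(seq: str, positions) -> list[tuple[int, int]]:
    """All (start, end) 1-based hits of a PROSITE-style position-spec list.

    Per start, run lengths are enumerated in leftmost-non-greedy
    (lexicographic) order and the first satisfying combination is reported
    — the same documented semantics as the production scanner, and the
    shortest total expansion for patterns (like the thaumatin signature)
    whose enumeration order gives nondecreasing totals.
    """
    runs = [i for i, p in enumerate(positions) if p.kind == "run"]
    hits = []
    for start in range(len(seq)):
        found_end = None
        for lengths in product(
            *[range(positions[r].min_len, positions[r].max_len + 1) for r in runs]
        ):
            run_len = dict(zip(runs, lengths))
            pos = start
            ok = True
            for i, spec in enumerate(positions):
                if spec.kind == "run":
                    pos += run_len[i]
                    if pos > len(seq):
                        ok = False
                        break
                    continue
                if pos >= len(seq):
                    ok = False
                    break
                ch = seq[pos]
                if spec.kind == "fixed" and ch != spec.residues:
                    ok = False
                    break
                if spec.kind == "set" and ch not in spec.residues:
                    ok = False
                    break
                pos += 1
            if ok:
                found_end = pos
                break
        if found_end is not None:
            hits.append((start + 1, found_end))
    return hits


_IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "W": {"A", "T"}, "S": {"C", "G"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T", "N"},
}


def iupac_scan_oracle(seq: str, pattern: str) -> list[int]:
    """1-based start positions where the IUPAC pattern matches, by direct
    sliding-window set membership."""
    hits = []
    for start in range(len(seq) - len(pattern) + 1):
        if all(seq[start + k] in _IUPAC_SETS[p] for k, p in enumerate(pattern)):
            hits.append(start + 1)
    return hits


# ---------------------------------------------------------------------------
# Small statistics oracles
# ---------------------------------------------------------------------------

#: Average residue masses typed independently from a standard reference.
RESIDUE_MASS_ORACLE = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}


def mw_oracle_kda(seq: str) -> float:
    return (sum(RESIDUE_MASS_ORACLE[c] for c in seq) + 18.0153) / 1000.0


def two_sample_t_oracle(x, y):
    """Equal-variance two-sample t statistic and two-tailed p (textbook
    pooled formula + scipy's t survival function)."""
    from scipy.stats import t as tdist

    nx, ny = len(x), len(y)
    mx = sum(x) / nx
    my = sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
    tstat = (mx - my) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    p = 2 * tdist.sf(abs(tstat), nx + ny - 2)
    return tstat, p
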