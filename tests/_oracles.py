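"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected result from first principles (exhaustive
enumeration, a hand-written codon table, simple scans) without touching the
implementation under test.
"""

from __future__ import annotations

from itertools import combinations

# --- translation -----------------------------------------------------------

_BASES = "TCAG"
_AMINO = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE = {
    a + b + c: _AMINO[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


def translate_oracle(nt: str, frame: int) -> str:
    """Codon-by-codon translation with an explicit codon table."""
    out = []
    i = frame
    while i + 3 <= len(nt):
        out.append(CODON_TABLE[nt[i : i + 3]])
        i += 3
    return "".join(out)


# --- amino-acid distance ---------------------------------------------------


def aa_distance_oracle(a: str, b: str) -> int:
    """Exhaustive enumeration over all global alignments (small strings only).

    Scores match +1 / mismatch -1 / gap -2; among score-optimal alignments the
    minimum count of substituted plus inserted/deleted positions is returned.
    Equal lengths short-circuit to positional comparison, as defined.
    """
    if not a or not b:
        return len(a) + len(b)
    if len(a) == len(b):
        return sum(1 for x, y in zip(a, b) if x != y)

    results: list[tuple[int, int]] = []

    def rec(i: int, j: int, score: int, dist: int):
        if i == len(a) and j == len(b):
            results.append((score, dist))
            return
        if i < len(a) and j < len(b):
            if a[i] == b[j]:
                rec(i + 1, j + 1, score + 1, dist)
            else:
                rec(i + 1, j + 1, score - 1, dist + 1)
        if i < len(a):
            rec(i + 1, j, score - 2, dist + 1)
        if j < len(b):
            rec(i, j + 1, score - 2, dist + 1)

    rec(0, 0, 0, 0)
    best = max(s for s, _ in results)
    return min(d for s, d in results if s == best)


# --- paired-end overlap ----------------------------------------------------

_COMP = str.maketrans("ACGT", "TGCA")


def merge_oracle(
    fwd_seq: str, rev_seq: str, min_overlap: int = 10, max_mismatch_frac: float = 0.25
):
    """All-offsets overlap scan. Returns (overlap_len, merged_len) or None."""
    rseq = rev_seq.translate(_COMP)[::-1]
    best = None  # (matches, overlap)
    for o in range(min_overlap, min(len(fwd_seq), len(rseq)) + 1):
        mm = sum(1 for x, y in zip(fwd_seq[len(fwd_seq) - o :], rseq[:o]) if x != y)
        if mm / o > max_mismatch_frac:
            continue
        if best is None or (o - mm, o) > best:
            best = (o - mm, o)
    if best is None:
        return None
    o = best[1]
    return o, len(fwd_seq) + len(rseq) - o


# --- chimera breakpoints ---------------------------------------------------


def chimera_oracle(seq: str, parents: list[str]) -> bool:
    """Direct breakpoint scan: seq == p1[:k] + p2[k:] for distinct parents."""
    n = len(seq)
    for k in range(1, n):
        for p1 in parents:
            if len(p1) < k or p1[:k] != seq[:k]:
                continue
            for p2 in parents:
                if p1 != p2 and len(p2) == n and p2[k:] == seq[k:]:
                    return True
    return False


# --- haplotype pools -------------------------------------------------------


def explains(pool, allele_set) -> bool:
    subs = [h for h in pool if h <= allele_set]
    return any(h1 | h2 == allele_set for i, h1 in enumerate(subs) for h2 in subs[i:])


def exhaustive_minimal_pools(sets: dict, max_k: int = 5):
    """All minimal-size haplotype pools explaining every animal as a union of
    at most two pool members.

    Candidate haplotypes are the animal sets closed (one round) under pairwise
    difference and intersection — every set recoverable by co-segregation
    reasoning lies in this universe for the cohorts exercised in the tests.
    Returns (k_min, list of pools as frozensets-of-frozensets) or (None, []).
    """
    base = {frozenset(s) for s in sets.values() if s}
    universe = set(base)
    for s in base:
        for t in base:
            for u in (s - t, s & t):
                if u:
                    universe.add(u)
    universe = sorted(universe, key=lambda x: (len(x), tuple(sorted(x))))
    targets = [frozenset(s) for s in sets.values() if s]
    for k in range(1, max_k + 1):
        found = [
            frozenset(c)
            for c in combinations(universe, k)
            if all(explains(c, s) for s in targets)
        ]
        if found:
            return k, found
    return None, []
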