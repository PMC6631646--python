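"""Independent brute-force oracles used by the test suite.

Every oracle here recomputes a quantity by the most direct method available
(exhaustive enumeration, regex engines, frozen lookup tables) without
touching the implementation's code paths.
"""

from __future__ import annotations

from collections import Counter

STOPS = {"UAA", "UAG", "UGA"}
PAIRS = {("G", "C"), ("C", "G"), ("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")}
PAIR_SCORES = {
    ("G", "C"): 3, ("C", "G"): 3, ("A", "U"): 2, ("U", "A"): 2,
    ("G", "U"): 1, ("U", "G"): 1,
}


def orf_oracle(seq: str, min_aa: int, starts=("AUG",)) -> list[tuple[int, int]]:
    """Maximal start-to-stop ORFs as (start, end) 1-based inclusive.

    Enumerates every start-codon occurrence, scans to the next in-frame
    stop, then keeps only the 5'-most start per (frame, stop).
    """
    n = len(seq)
    candidates = []
    for p in range(n - 2):
        if seq[p : p + 3] not in starts:
            continue
        q = p
        while q + 3 <= n and seq[q : q + 3] not in STOPS:
            q += 3
        if q + 3 <= n:  # stop found
            candidates.append((p + 1, q + 3))
    best: dict[tuple[int, int], int] = {}
    for start, end in candidates:
        key = (start % 3, end)
        if key not in best or start < best[key]:
            best[key] = start
    orfs = sorted(
        (s, e)
        for (_, e), s in best.items()
        if (e - s + 1) // 3 - 1 >= min_aa
    )
    return orfs


def slippery_mismatch_oracle(heptamer: str) -> int:
    """Distance to X XXY YYZ via majority counting (not min-over-instantiations)."""
    c1 = 3 - Counter(heptamer[0:3]).most_common(1)[0][1]
    c2 = 3 - Counter(heptamer[3:6]).most_common(1)[0][1]
    return c1 + c2


def stem_oracle(seq: str, lo: int, hi: int, min_pairs: int, max_loop=None):
    """All maximal perfect helices as (arm5_start, arm5_end, arm3_start,
    arm3_end, pairs, score), 1-based, within [lo, hi] 1-based inclusive.

    Explicitly enumerates every (i, j, k) helix, checks maximality against
    outward extension and inward extension, then removes shifted registers
    contained in a longer helix.
    """
    l0, h0 = lo - 1, hi - 1
    helices = []
    for i in range(l0, h0 + 1):
        for j in range(i + 1, h0 + 1):
            for k in range(1, (j - i) // 2 + 2):
                if i + k - 1 >= j - k + 1:
                    break
                if any((seq[i + t], seq[j - t]) not in PAIRS for t in range(k)):
                    break
                # outward extension possible?
                if i - 1 >= l0 and j + 1 <= h0 and (seq[i - 1], seq[j + 1]) in PAIRS:
                    continue
                # inward extension possible?
                if i + k < j - k and (seq[i + k], seq[j - k]) in PAIRS:
                    continue
                loop_len = (j - k) - (i + k) + 1
                if k < min_pairs or (max_loop is not None and loop_len > max_loop):
                    continue
                score = sum(PAIR_SCORES[(seq[i + t], seq[j - t])] for t in range(k))
                helices.append((i + 1, i + k, j - k + 2, j + 1, k, score))
    kept = []
    for h in helices:
        contained = any(
            t[4] > h[4]
            and t[0] <= h[0] and h[1] <= t[1]
            and t[2] <= h[2] and h[3] <= t[3]
            for t in helices
        )
        if not contained:
            kept.append(h)
    return sorted(set(kept))


def pseudoknot_pairs_oracle(stems, max_span=None, min_score=0.0):
    """All ordered crossing stem pairs from a stem_oracle list.

    Returns tuples of the two stems' arm coordinates plus combined score.
    """
    out = []
    for s1 in stems:
        a5s, a5e, a3s, a3e, _, sc1 = s1
        loop = (a5e + 1, a3s - 1)
        if loop[0] > loop[1]:
            continue
        for s2 in stems:
            if s2 == s1:
                continue
            b5s, b5e, b3s, b3e, _, sc2 = s2
            if not (loop[0] <= b5s and b5e <= loop[1] and b3s > a3e):
                continue
            span = b3e - a5s + 1
            if max_span is not None and span > max_span:
                continue
            score = sc1 + sc2
            if score < min_score:
                continue
            out.append((s1[:4], s2[:4], score))
    return sorted(out)


def agp_oracle(protein: str, window: int, threshold: float):
    """Merged AGP-rich regions via a covered-position mask (1-based)."""
    n = len(protein)
    covered = [False] * (n + 1)
    for s in range(1, n - window + 2):
        frac = sum(c in "AGP" for c in protein[s - 1 : s - 1 + window]) / window
        if frac >= threshold:
            for p in range(s, s + window):
                covered[p] = True
    regions = []
    p = 1
    while p <= n:
        if covered[p]:
            q = p
            while q + 1 <= n and covered[q + 1]:
                q += 1
            frac = sum(c in "AGP" for c in protein[p - 1 : q]) / (q - p + 1)
            regions.append((p, q, frac))
            p = q + 1
        else:
            p += 1
    return regions


#: Frozen Expasy-style average residue masses for the summation oracle.
RESIDUE_AVG = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}


def mass_oracle(protein: str) -> float:
    """Counter-based residue-mass summation + one water."""
    counts = Counter(protein)
    return 18.0153 + sum(RESIDUE_AVG[aa] * k for aa, k in counts.items())
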