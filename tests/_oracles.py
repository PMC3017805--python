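"""Independent brute-force oracles used only by the test suite.

Each oracle is written against the definition of the quantity, not
against the package implementation: exhaustive Smith–Waterman for local
alignment scores, substring enumeration for exact runs, exhaustive
(start, period, extension) scanning for SSRs, full ATG..stop enumeration
for ORFs, recursive pathway enumeration for NG86 counting, and
Needleman–Wunsch for global peptide alignment scores.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from Bio.Seq import Seq

# --- exhaustive local alignment (Gotoh affine), same scoring convention
# as the package default: match +1, mismatch -2, first gap column -7,
# each further gap column -2.  N never matches.

MATCH, MISMATCH, GAP_OPEN_TOTAL, GAP_EXTEND = 1.0, -2.0, 7.0, 2.0


@njit(cache=True)
def _sw_score(a: np.ndarray, b: np.ndarray) -> float:
    n, m = len(a), len(b)
    NEG = -1e18
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if a[i - 1] == b[j - 1] and a[i - 1] != 78:  # ord('N')
                s = MATCH
            else:
                s = MISMATCH
            E[i, j] = max(H[i, j - 1] - GAP_OPEN_TOTAL,
                          E[i, j - 1] - GAP_EXTEND)
            F[i, j] = max(H[i - 1, j] - GAP_OPEN_TOTAL,
                          F[i - 1, j] - GAP_EXTEND)
            h = max(0.0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
            H[i, j] = h
            if h > best:
                best = h
    return best


def sw_score(a: str, b: str) -> float:
    return _sw_score(np.frombuffer(a.encode(), dtype=np.uint8),
                     np.frombuffer(b.encode(), dtype=np.uint8))


# --- brute-force longest shared exact substring

def brute_longest_run(a: str, b: str) -> int:
    best = 0
    for i in range(len(a)):
        for j in range(len(b)):
            k = 0
            while (i + k < len(a) and j + k < len(b)
                   and a[i + k] == b[j + k] and a[i + k] != "N"):
                k += 1
            best = max(best, k)
    return best


# --- brute-force SSR scan: every (start, period) tested for maximal
# perfect extension

def brute_ssrs(seq: str, thresholds: dict[int, int]) -> set[tuple]:
    found = set()
    n = len(seq)
    for period, min_count in thresholds.items():
        for start in range(n):
            unit = seq[start:start + period]
            if len(unit) < period or "N" in unit:
                continue
            # primitive unit only
            if any(len(unit) % p == 0 and unit == unit[:p] * (len(unit) // p)
                   for p in range(1, period)):
                continue
            # maximal: the periodicity must not extend leftward (a one-base
            # extension re-anchors the same run at an earlier phase)
            if start >= 1 and seq[start - 1] == seq[start + period - 1]:
                continue
            count = 1
            while seq[start + count * period:
                      start + (count + 1) * period] == unit:
                count += 1
            if count >= min_count:
                found.add((start, start + count * period, period, count))
    return found


# --- exhaustive longest-ORF enumeration over 3 forward frames

def brute_longest_orf(seq: str) -> tuple[int, int, bool] | None:
    stops = {"TAA", "TAG", "TGA"}
    spans = []
    for s in range(len(seq) - 2):
        if seq[s:s + 3] != "ATG":
            continue
        e = s
        partial = True
        while e + 3 <= len(seq):
            if seq[e:e + 3] in stops and e > s:
                partial = False
                break
            e += 3
        end = e + 3 if not partial else s + ((len(seq) - s) // 3) * 3
        if end > s:
            spans.append((s, end, partial))
    if not spans:
        return None
    return min(spans, key=lambda t: (-(t[1] - t[0]), t[0]))


# --- independent NG86 counting written from the definition

_TABLE = {}
for _b1 in "ACGT":
    for _b2 in "ACGT":
        for _b3 in "ACGT":
            _c = _b1 + _b2 + _b3
            _TABLE[_c] = str(Seq(_c).translate())


def ng86_sites(codon: str) -> float:
    aa = _TABLE[codon]
    syn = 0.0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if _TABLE[alt] != "*" and _TABLE[alt] == aa:
                syn += 1 / 3
    return syn


def ng86_differences(ca: str, cb: str) -> tuple[float, float]:
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return 0.0, 0.0

    def paths(cur, remaining):
        if not remaining:
            yield []
            return
        for i, pos in enumerate(remaining):
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            step_syn = (_TABLE[nxt] != "*" and _TABLE[cur] != "*"
                        and _TABLE[cur] == _TABLE[nxt])
            crosses = _TABLE[nxt] == "*"
            for rest in paths(nxt, remaining[:i] + remaining[i + 1:]):
                yield [(step_syn, crosses)] + rest

    all_paths = list(paths(ca, diff))
    clean = [p for p in all_paths if not any(c for _, c in p)]
    use = clean if clean else all_paths
    sd = sum(sum(1 for s, _ in p if s) for p in use) / len(use)
    nd = sum(sum(1 for s, _ in p if not s) for p in use) / len(use)
    return sd, nd


def ng86(pairs: list[tuple[str, str]]) -> dict[str, float]:
    import math

    S = sum((ng86_sites(a) + ng86_sites(b)) / 2 for a, b in pairs)
    N = 3 * len(pairs) - S
    sd = nd = 0.0
    for a, b in pairs:
        d_s, d_n = ng86_differences(a, b)
        sd += d_s
        nd += d_n
    ps, pn = sd / S, nd / N

    def jc(p):
        return None if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)

    return {"S": S, "N": N, "Sd": sd, "Nd": nd, "ps": ps, "pn": pn,
            "ks": jc(ps), "ka": jc(pn)}


# --- global peptide alignment score (Needleman-Wunsch, BLOSUM62; the
# first column of a gap costs -11 and each further column -1)

def nw_peptide_score(a: str, b: str) -> float:
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    NEG = float("-inf")
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    for j in range(1, m + 1):
        E[0][j] = -11.0 - (j - 1) * 1.0
        H[0][j] = E[0][j]
    for i in range(1, n + 1):
        F[i][0] = -11.0 - (i - 1) * 1.0
        H[i][0] = F[i][0]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = blosum[a[i - 1], b[j - 1]]
            E[i][j] = max(H[i][j - 1] - 11.0, E[i][j - 1] - 1.0)
            F[i][j] = max(H[i - 1][j] - 11.0, F[i - 1][j] - 1.0)
            H[i][j] = max(H[i - 1][j - 1] + s, E[i][j], F[i][j])
    return H[n][m]
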