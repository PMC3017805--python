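"""Pairwise alignment engine shared by every identity-threshold rule.

Two modes are provided:

* ``local`` — exact affine-gap Smith–Waterman local alignment, computed by
  :class:`Bio.Align.PairwiseAligner` (C implementation).  k-mer seeding is
  used only as a *candidate prefilter* (see :func:`kmer_candidate_pairs`);
  the alignment itself is exact DP, so the reported score equals the
  exhaustive-DP optimum by construction.
* ``ungapped`` — the best-scoring gap-free diagonal segment (per-diagonal
  maximum-subarray scan), standing in for an ungapped BLASTN search.

Scoring defaults are BLASTN-like: match +1, mismatch −2, gap open −5 with a
−2 per-column extension (so the first gap column costs −7).  ``N`` never
matches anything, including ``N``: identities are counted conservatively.
The identity denominator is *all* alignment columns, gap columns included.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import reverse_complement

__all__ = [
    "PairwiseAlignment",
    "Scoring",
    "align",
    "longest_exact_run",
    "kmer_candidate_pairs",
    "shared_diagonals",
    "revcomp",
]


def revcomp(seq: str) -> str:
    return str(reverse_complement(seq))


@dataclass(frozen=True)
class Scoring:
    match: float = 1
    mismatch: float = -2
    gap_open: float = -5  # charged once per gap run, on top of the extension
    gap_extend: float = -2


DEFAULT_SCORING = Scoring()

# Long-gap-tolerant scoring for isoform-pair comparison, where a retained
# intron of a couple hundred nt must be bridged by a single local alignment.
LONG_GAP_SCORING = Scoring(gap_open=-10, gap_extend=-0.5)


@dataclass(frozen=True)
class PairwiseAlignment:
    """A local (or ungapped) alignment of *query* against *subject*.

    ``ops`` is one character per alignment column: ``M`` match, ``X``
    mismatch, ``I`` gap in subject (query base unmatched), ``D`` gap in
    query.  Subject coordinates are always on the original subject strand;
    for ``orientation == "reverse-complement"`` the ops string reads along
    the query and the reverse complement of the subject.
    """

    query_id: str
    subject_id: str
    query_interval: tuple[int, int]
    subject_interval: tuple[int, int]
    orientation: str  # "forward" | "reverse-complement"
    columns: int
    matches: int
    mismatches: int
    gap_columns: int
    score: float
    ops: str

    def __post_init__(self) -> None:
        if self.matches + self.mismatches + self.gap_columns != self.columns:
            raise ValueError("column counts inconsistent")
        if not 0 <= self.identity <= 1:
            raise ValueError("identity out of range")

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0

    @property
    def query_coverage_length(self) -> int:
        return self.query_interval[1] - self.query_interval[0]


def _make_aligner(scoring: Scoring) -> Align.PairwiseAligner:
    mat = substitution_matrices.Array("ACGTN", dims=2)
    for x in "ACGTN":
        for y in "ACGTN":
            if x == y and x != "N":
                mat[x, y] = scoring.match
            else:
                mat[x, y] = scoring.mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = scoring.gap_open + scoring.gap_extend
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def _ops_from_alignment(aln, a: str, b: str) -> tuple[str, int, int, int]:
    """Column-by-column ops string from a Biopython alignment object."""
    qa, sa = aln.aligned
    ops: list[str] = []
    matches = mismatches = gaps = 0
    prev_q = prev_s = None
    for (qs, qe), (ss, se) in zip(qa, sa):
        if prev_q is not None:
            gq = qs - prev_q
            gs = ss - prev_s
            ops.append("I" * gq + "D" * gs)
            gaps += gq + gs
        for x, y in zip(a[qs:qe], b[ss:se]):
            if x == y and x != "N":
                ops.append("M")
                matches += 1
            else:
                ops.append("X")
                mismatches += 1
        prev_q, prev_s = qe, se
    return "".join(ops), matches, mismatches, gaps


def _align_forward(
    a: str, b: str, scoring: Scoring, query_id: str, subject_id: str,
    orientation: str, b_original_len: int,
) -> PairwiseAlignment | None:
    aligner = _make_aligner(scoring)
    try:
        aln = aligner.align(a, b)[0]
    except (IndexError, ValueError):
        return None
    if aln.score <= 0:
        return None
    qa, sa = aln.aligned
    if len(qa) == 0:
        return None
    ops, matches, mismatches, gaps = _ops_from_alignment(aln, a, b)
    q_iv = (int(qa[0][0]), int(qa[-1][1]))
    s_lo, s_hi = int(sa[0][0]), int(sa[-1][1])
    if orientation == "reverse-complement":
        s_iv = (b_original_len - s_hi, b_original_len - s_lo)
    else:
        s_iv = (s_lo, s_hi)
    return PairwiseAlignment(
        query_id=query_id, subject_id=subject_id,
        query_interval=q_iv, subject_interval=s_iv,
        orientation=orientation,
        columns=len(ops), matches=matches, mismatches=mismatches,
        gap_columns=gaps, score=float(aln.score), ops=ops,
    )


def _best_ungapped(
    a: str, b: str, scoring: Scoring, diagonals: Iterable[int] | None = None
) -> tuple[float, int, int, int, int, int] | None:
    """Best gap-free segment: (score, qs, qe, ss, matches, mismatches).

    ``diagonals`` optionally restricts the scan to diagonals k = qpos - spos.
    """
    A = np.frombuffer(a.encode(), dtype=np.uint8)
    B = np.frombuffer(b.encode(), dtype=np.uint8)
    n_char = ord("N")
    diag_iter = (
        sorted(set(diagonals)) if diagonals is not None
        else range(-(len(b) - 1), len(a))
    )
    best = None
    for k in diag_iter:
        qs0 = max(0, k)
        ss0 = qs0 - k
        L = min(len(a) - qs0, len(b) - ss0)
        if L <= 0:
            continue
        av = A[qs0 : qs0 + L]
        bv = B[ss0 : ss0 + L]
        eq = (av == bv) & (av != n_char)
        s = np.where(eq, scoring.match, scoring.mismatch)
        prefix = np.concatenate(([0], np.cumsum(s)))
        minpref = np.minimum.accumulate(prefix[:-1])
        vals = prefix[1:] - minpref
        j = int(np.argmax(vals))
        score = float(vals[j])
        if score <= 0:
            continue
        start = int(np.argmin(prefix[: j + 1]))
        m = int(eq[start : j + 1].sum())
        mm = (j + 1 - start) - m
        cand = (score, qs0 + start, qs0 + j + 1, ss0 + start, m, mm)
        if best is None or cand[0] > best[0]:
            best = cand
    return best


def align(
    a: str,
    b: str,
    mode: str = "local",
    strand: str = "both",
    query_id: str = "query",
    subject_id: str = "subject",
    scoring: Scoring = DEFAULT_SCORING,
) -> PairwiseAlignment | None:
    """Best pairwise alignment of ``a`` (query) vs ``b`` (subject).

    With ``strand="both"`` the reverse complement of the subject is also
    searched and the higher-scoring orientation returned (forward wins
    ties).  Returns ``None`` when no positive-scoring alignment exists.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if mode not in ("local", "ungapped"):
        raise ValueError(f"unknown mode {mode!r}")
    if strand not in ("both", "forward"):
        raise ValueError(f"unknown strand {strand!r}")

    candidates: list[PairwiseAlignment] = []
    targets = [("forward", b)]
    if strand == "both":
        targets.append(("reverse-complement", revcomp(b)))
    for orientation, bseq in targets:
        if mode == "local":
            hit = _align_forward(a, bseq, scoring, query_id, subject_id,
                                 orientation, len(b))
        else:
            seg = _best_ungapped(a, bseq, scoring)
            if seg is None:
                hit = None
            else:
                score, qs, qe, ss, m, mm = seg
                L = qe - qs
                s_lo, s_hi = ss, ss + L
                if orientation == "reverse-complement":
                    s_iv = (len(b) - s_hi, len(b) - s_lo)
                else:
                    s_iv = (s_lo, s_hi)
                ops = "".join(
                    "M" if (x == y and x != "N") else "X"
                    for x, y in zip(a[qs:qe], bseq[ss:ss + L])
                )
                hit = PairwiseAlignment(
                    query_id=query_id, subject_id=subject_id,
                    query_interval=(qs, qe), subject_interval=s_iv,
                    orientation=orientation, columns=L, matches=m,
                    mismatches=mm, gap_columns=0, score=score, ops=ops,
                )
        if hit is not None:
            candidates.append(hit)
    if not candidates:
        return None
    # forward listed first, so ties resolve to forward
    return max(candidates, key=lambda h: h.score)


def longest_exact_run(a: str, b: str) -> int:
    """Length of the longest contiguous block shared exactly by a and b."""
    if not a or not b:
        return 0
    A = np.frombuffer(a.encode(), dtype=np.uint8)
    B = np.frombuffer(b.encode(), dtype=np.uint8)
    n_char = ord("N")
    prev = np.zeros(len(B) + 1, dtype=np.int32)
    best = 0
    for x in A:
        eq = (B == x) & (B != n_char)
        cur = np.zeros_like(prev)
        cur[1:] = np.where(eq, prev[:-1] + 1, 0)
        m = int(cur.max())
        if m > best:
            best = m
        prev = cur
    return best


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def kmer_candidate_pairs(
    seqs: Sequence[str], k: int = 14, both_strands: bool = False
) -> set[tuple[int, int]]:
    """Indices (i < j) of sequence pairs sharing at least one exact k-mer.

    A seeding prefilter: only these pairs are worth aligning.  With
    ``both_strands`` a pair also qualifies when a k-mer of one sequence
    occurs in the reverse complement of the other.
    """
    index: dict[str, list[int]] = defaultdict(list)
    for i, s in enumerate(seqs):
        for km in _kmers(s, k):
            index[km].append(i)
    pairs: set[tuple[int, int]] = set()
    for ids in index.values():
        if len(ids) < 2:
            continue
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                pairs.add((ids[ai], ids[bi]))
    if both_strands:
        for i, s in enumerate(seqs):
            rc_kmers = _kmers(revcomp(s), k)
            for km in rc_kmers:
                for j in index.get(km, ()):
                    if j != i:
                        pairs.add((min(i, j), max(i, j)))
    return pairs


def shared_diagonals(a: str, b: str, k: int = 12) -> set[int]:
    """Diagonals (qpos - spos) on which a and b share an exact k-mer."""
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(b) - k + 1):
        index[b[i : i + k]].append(i)
    diags: set[int] = set()
    for i in range(len(a) - k + 1):
        for j in index.get(a[i : i + k], ()):
            diags.add(i - j)
    return diags
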