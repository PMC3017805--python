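"""cis-natural-antisense transcript (NAT) pair detection.

A NAT pair is two distinct transcripts whose sequences overlap in
reverse-complement orientation over at least 50 nt with fewer than 2
mismatches (read strictly: at most 1), gap-free.  The longest qualifying
window per pair is reported, so each pair carries a single overlap length.
Candidate pairs are prefiltered with shared 25-mers against the reverse
complement — any >=50 nt window with <=1 mismatch necessarily contains an
exact 25-mer, so the prefilter is lossless.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from . import alignment_core as ac
from .orf_composition import ORFAnnotation
from .sequence_io import TranscriptRecord

MIN_OVERLAP = 50
MAX_MISMATCHES = 1  # "< 2 mismatches"
_SEED_K = 25  # lossless for the 50 nt / <=1 mismatch rule


@dataclass(frozen=True)
class NATPair:
    sense_id: str
    antisense_id: str
    overlap_length: int
    mismatches: int
    sense_interval: tuple[int, int]
    antisense_interval: tuple[int, int]

    def __post_init__(self) -> None:
        if self.sense_id == self.antisense_id:
            raise ValueError("a transcript cannot be its own antisense")
        if self.overlap_length < MIN_OVERLAP:
            raise ValueError("overlap below the 50 nt minimum")
        if self.mismatches > MAX_MISMATCHES:
            raise ValueError("too many mismatches for a NAT pair")


def _best_window(a: str, b_rc: str, diagonals: set[int],
                 max_mm: int) -> tuple[int, int, int, int] | None:
    """Longest window with <= max_mm mismatches on the given diagonals of
    a vs b_rc: returns (length, mismatches, a_start, brc_start)."""
    best: tuple[int, int, int, int] | None = None
    for k in sorted(diagonals):
        qs0 = max(0, k)
        ss0 = qs0 - k
        L = min(len(a) - qs0, len(b_rc) - ss0)
        if L <= 0:
            continue
        mism = [i for i in range(L)
                if a[qs0 + i] != b_rc[ss0 + i] or a[qs0 + i] == "N"]
        # sweep over mismatch positions: longest stretch with <= max_mm
        bounds = [-1] + mism + [L] * (max_mm + 1)
        for wi in range(len(mism) + 1):
            lo = bounds[wi] + 1
            hi = min(bounds[wi + max_mm + 1], L)  # exclusive
            length = hi - lo
            if length <= 0:
                continue
            mm_in = sum(1 for m in mism if lo <= m < hi)
            if best is None or length > best[0]:
                best = (length, mm_in, qs0 + lo, ss0 + lo)
    return best


def detect_nats(
    transcripts: Sequence[TranscriptRecord],
    min_overlap: int = MIN_OVERLAP,
    max_mismatches: int = MAX_MISMATCHES,
) -> list[NATPair]:
    """All unordered transcript pairs with a gap-free reverse-complement
    overlap of >= ``min_overlap`` columns and <= ``max_mismatches``
    mismatches; each pair reported once, with its longest overlap."""
    seqs = [t.seq for t in transcripts]
    pairs = ac.kmer_candidate_pairs(seqs, k=_SEED_K, both_strands=True)
    out: list[NATPair] = []
    for i, j in sorted(pairs):
        a = seqs[i]
        b_rc = ac.revcomp(seqs[j])
        diags = ac.shared_diagonals(a, b_rc, k=_SEED_K)
        if not diags:
            continue
        # widen each seeded diagonal: one mismatch cannot shift the frame,
        # so seeded diagonals are exactly the qualifying ones
        best = _best_window(a, b_rc, diags, max_mismatches)
        if best is None:
            continue
        length, mm, a_start, brc_start = best
        if length < min_overlap:
            continue
        len_b = len(seqs[j])
        b_iv = (len_b - (brc_start + length), len_b - brc_start)
        out.append(NATPair(
            sense_id=transcripts[i].id,
            antisense_id=transcripts[j].id,
            overlap_length=length,
            mismatches=mm,
            sense_interval=(a_start, a_start + length),
            antisense_interval=b_iv,
        ))
    return out


def _orf_class(ann: ORFAnnotation | None) -> str:
    if ann is None:
        return "none"
    if ann.aa_length > 100:
        return ">100aa"
    if ann.aa_length >= 30:
        return "30-100aa"
    return "none"


def nat_summary(
    pairs: Sequence[NATPair], annotations: Mapping[str, ORFAnnotation]
) -> pd.DataFrame:
    """Cross-tab of NAT pairs by the ORF classes of their two members
    (>100 aa / 30-100 aa / none; unordered)."""
    classes = [">100aa", "30-100aa", "none"]
    table = pd.DataFrame(0, index=classes, columns=classes)
    for p in pairs:
        ca = _orf_class(annotations.get(p.sense_id))
        cb = _orf_class(annotations.get(p.antisense_id))
        hi, lo = sorted([ca, cb], key=classes.index)
        table.loc[hi, lo] += 1
    return table


def pairs_to_frame(pairs: Sequence[NATPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "sense_id": p.sense_id,
            "antisense_id": p.antisense_id,
            "overlap_length": p.overlap_length,
            "mismatches": p.mismatches,
            "sense_start": p.sense_interval[0],
            "sense_end": p.sense_interval[1],
            "antisense_start": p.antisense_interval[0],
            "antisense_end": p.antisense_interval[1],
        } for p in pairs]
    )
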