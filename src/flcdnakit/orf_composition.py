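"""Longest-ORF annotation, regional GC content and codon usage.

FL-cDNAs are directionally cloned, so the ORF search scans the three
*forward* frames only (a stated deviation from both-strand ORF finders).
The longest ATG-initiated ORF is taken as the transcript's coding region;
ORFs that run off the 3' end without an in-frame stop are kept and flagged
``partial`` (FL-cDNA sets contain 3'-truncated clones).

GC is summarized per region (whole transcript, 5'UTR, ORF, 3'UTR) and per
codon position (GC1/GC2/GC3, ORF codons only, stop codon included).  All
means are per-sequence means averaged over sequences.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .sequence_io import TranscriptRecord

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset(standard_dna_table.stop_codons)  # TAA TAG TGA

_CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in STOP_CODONS:
    _CODON_TO_AA[_stop] = "*"

SENSE_CODONS = tuple(sorted(standard_dna_table.forward_table))  # 61 codons
ALL_CODONS = tuple(sorted(_CODON_TO_AA))  # 64


def translate_cds(cds: str) -> str:
    """Translate a CDS, trailing stop (if any) stripped."""
    aa = str(Seq(cds).translate())
    return aa[:-1] if aa.endswith("*") else aa


@dataclass(frozen=True)
class ORFAnnotation:
    transcript_id: str
    orf_interval: tuple[int, int]  # includes the stop codon when present
    frame: int
    aa_length: int
    partial: bool  # no in-frame stop before the transcript end
    utr5_interval: tuple[int, int]
    utr3_interval: tuple[int, int]

    def __post_init__(self) -> None:
        s, e = self.orf_interval
        if (e - s) % 3:
            raise ValueError("ORF length must be a multiple of 3")
        if self.utr5_interval[1] != s or self.utr3_interval[0] != e:
            raise ValueError("UTR/ORF intervals must tile the transcript")


def find_longest_orf(
    seq: str, transcript_id: str = "transcript"
) -> ORFAnnotation | None:
    """Longest ATG..stop ORF over the three forward frames.

    Ties are broken in favour of the 5'-most start.  An ORF reaching the
    transcript end without a stop is allowed and flagged partial.  Returns
    None when no ATG-initiated ORF exists.
    """
    if len(seq) < 3:
        return None
    best: tuple[int, int, bool] | None = None  # (start, end, partial)
    for frame in range(3):
        start: int | None = None
        i = frame
        while i + 3 <= len(seq):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in STOP_CODONS:
                cand = (start, i + 3, False)
                if best is None or _orf_better(cand, best):
                    best = cand
                start = None
            i += 3
        if start is not None:
            end = start + ((len(seq) - start) // 3) * 3
            if end > start:
                cand = (start, end, True)
                if best is None or _orf_better(cand, best):
                    best = cand
    if best is None:
        return None
    s, e, partial = best
    n_codons = (e - s) // 3
    aa_length = n_codons if partial else n_codons - 1  # stop not an aa
    return ORFAnnotation(
        transcript_id=transcript_id,
        orf_interval=(s, e),
        frame=s % 3,
        aa_length=aa_length,
        partial=partial,
        utr5_interval=(0, s),
        utr3_interval=(e, len(seq)),
    )


def _orf_better(cand: tuple[int, int, bool], best: tuple[int, int, bool]) -> bool:
    len_c = cand[1] - cand[0]
    len_b = best[1] - best[0]
    if len_c != len_b:
        return len_c > len_b
    return cand[0] < best[0]  # tie: 5'-most start


def annotate_orfs(
    transcripts: Sequence[TranscriptRecord],
) -> dict[str, ORFAnnotation]:
    """Longest-ORF annotation per transcript; transcripts without an ORF
    are absent from the result."""
    out: dict[str, ORFAnnotation] = {}
    for rec in transcripts:
        ann = find_longest_orf(rec.seq, rec.id)
        if ann is not None:
            out[rec.id] = ann
    return out


def orf_size_filter(
    annotations: Mapping[str, ORFAnnotation], min_aa: int = 100
) -> dict[str, ORFAnnotation]:
    """Keep annotations with aa_length strictly greater than ``min_aa``."""
    return {k: v for k, v in annotations.items() if v.aa_length > min_aa}


def _gc(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


@dataclass(frozen=True)
class CompositionSummary:
    n_sequences: int
    gc_overall: float
    gc_utr5: float | None
    gc_utr3: float | None
    gc_orf: float
    gc1: float
    gc2: float
    gc3: float
    codon_usage: pd.DataFrame  # codon, aa, count, freq, rscu

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{
                "n_sequences": self.n_sequences,
                "gc_overall": self.gc_overall,
                "gc_utr5": self.gc_utr5,
                "gc_utr3": self.gc_utr3,
                "gc_orf": self.gc_orf,
                "gc1": self.gc1,
                "gc2": self.gc2,
                "gc3": self.gc3,
            }]
        )


def composition_summary(
    transcripts: Sequence[TranscriptRecord],
    annotations: Mapping[str, ORFAnnotation],
) -> CompositionSummary:
    """GC by region and codon position plus the codon-usage table.

    Only transcripts present in ``annotations`` are summarized.  A missing
    region (e.g. an empty 5'UTR) is excluded from that region's mean.
    """
    by_id = {t.id: t for t in transcripts}
    gc_all: list[float] = []
    gc5: list[float] = []
    gc3utr: list[float] = []
    gco: list[float] = []
    gc_pos: list[tuple[float, float, float]] = []
    codon_counts: Counter[str] = Counter()
    n = 0
    for tid, ann in annotations.items():
        rec = by_id.get(tid)
        if rec is None:
            continue
        n += 1
        seq = rec.seq
        s, e = ann.orf_interval
        orf = seq[s:e]
        gc_all.append(_gc(seq))
        gco.append(_gc(orf))
        u5 = seq[ann.utr5_interval[0] : ann.utr5_interval[1]]
        u3 = seq[ann.utr3_interval[0] : ann.utr3_interval[1]]
        if u5:
            gc5.append(_gc(u5))
        if u3:
            gc3utr.append(_gc(u3))
        codons = [orf[i : i + 3] for i in range(0, len(orf), 3)]
        p1 = "".join(c[0] for c in codons)
        p2 = "".join(c[1] for c in codons)
        p3 = "".join(c[2] for c in codons)
        gc_pos.append((_gc(p1), _gc(p2), _gc(p3)))
        codon_counts.update(codons)
    if n == 0:
        raise ValueError("no annotated transcripts to summarize")
    if not gc5:
        logger.info("composition_summary: no transcript has a 5'UTR")
    if not gc3utr:
        logger.info("composition_summary: no transcript has a 3'UTR")

    usage = codon_usage_table(codon_counts)
    mean = lambda xs: sum(xs) / len(xs)
    return CompositionSummary(
        n_sequences=n,
        gc_overall=mean(gc_all),
        gc_utr5=mean(gc5) if gc5 else None,
        gc_utr3=mean(gc3utr) if gc3utr else None,
        gc_orf=mean(gco),
        gc1=mean([g[0] for g in gc_pos]),
        gc2=mean([g[1] for g in gc_pos]),
        gc3=mean([g[2] for g in gc_pos]),
        codon_usage=usage,
    )


def codon_usage_table(codon_counts: Mapping[str, int]) -> pd.DataFrame:
    """Per-codon counts, within-family frequency and relative synonymous
    codon usage (RSCU).  Families are the synonymous codons of one amino
    acid (stops form their own family)."""
    families: dict[str, list[str]] = {}
    for codon in ALL_CODONS:
        families.setdefault(_CODON_TO_AA[codon], []).append(codon)
    rows = []
    for aa, codons in sorted(families.items()):
        fam_total = sum(codon_counts.get(c, 0) for c in codons)
        k = len(codons)
        for c in codons:
            cnt = codon_counts.get(c, 0)
            freq = cnt / fam_total if fam_total else 0.0
            rscu = cnt * k / fam_total if fam_total else 0.0
            rows.append(
                {"codon": c, "aa": aa, "count": cnt, "freq": freq, "rscu": rscu}
            )
    return pd.DataFrame(rows)
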