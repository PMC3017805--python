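"""Simple-sequence-repeat (microsatellite) detection and localization.

Perfect, maximal tandem repeats of 1–6 nt motifs are reported when they
meet period-specific minimum repeat counts (MISA-style defaults: mono >=10,
di >=6, tri through hexa >=5).  Motifs are canonicalized to their
lexicographically minimal rotation; an optional flag additionally folds a
motif with its reverse complement (e.g. pooling CCG with CGG).  Hits are
localized to 5'UTR / ORF / 3'UTR by the midpoint of the hit interval, with
a signed distance from the first base of the start codon.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .alignment_core import revcomp
from .orf_composition import ORFAnnotation
from .sequence_io import TranscriptRecord

DEFAULT_THRESHOLDS: dict[int, int] = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}


@dataclass(frozen=True)
class SSRHit:
    transcript_id: str
    motif: str  # canonical (minimal-rotation) form
    period: int
    repeat_count: int
    interval: tuple[int, int]
    region: str = "unannotated"  # 5'UTR | ORF | 3'UTR | unannotated
    distance_to_start_codon: int | None = None  # midpoint - ATG, nt

    def __post_init__(self) -> None:
        s, e = self.interval
        if e - s != self.period * self.repeat_count:
            raise ValueError("interval length != period * repeat_count")


def canonical_motif(motif: str, fold_revcomp: bool = False) -> str:
    """Lexicographically minimal rotation; optionally also fold with the
    minimal rotation of the reverse complement."""
    rotations = [motif[i:] + motif[:i] for i in range(len(motif))]
    best = min(rotations)
    if fold_revcomp:
        rc = revcomp(motif)
        best = min(best, canonical_motif(rc))
    return best


def _is_primitive(motif: str) -> bool:
    """True unless the motif is itself a repetition of a shorter motif."""
    n = len(motif)
    for p in range(1, n):
        if n % p == 0 and motif == motif[:p] * (n // p):
            return False
    return True


def detect_ssrs(
    seq: str,
    transcript_id: str = "transcript",
    thresholds: Mapping[int, int] = DEFAULT_THRESHOLDS,
    fold_revcomp: bool = False,
) -> list[SSRHit]:
    """All maximal perfect repeats meeting the thresholds.

    Overlapping repeats of different periods are each reported; within one
    period a maximal run is reported once, anchored at its leftmost start.
    ``N`` bases never participate in a repeat.
    """
    hits: list[SSRHit] = []
    n = len(seq)
    for period, min_count in sorted(thresholds.items()):
        i = 0
        while i + period * min_count <= n:
            unit = seq[i : i + period]
            if "N" in unit or not _is_primitive(unit):
                i += 1
                continue
            # extend the run of this unit starting at i
            j = i + period
            while j + period <= n and seq[j : j + period] == unit:
                j += period
            count = (j - i) // period
            if count >= min_count:
                # maximality: do not report if the same run extends leftward
                if i >= period and seq[i - period : i] == unit:
                    i += 1
                    continue
                hits.append(
                    SSRHit(
                        transcript_id=transcript_id,
                        motif=canonical_motif(unit, fold_revcomp),
                        period=period,
                        repeat_count=count,
                        interval=(i, i + period * count),
                    )
                )
                i = i + period * count  # jump past the reported run
            else:
                i += 1
    hits.sort(key=lambda h: (h.interval[0], h.period))
    return hits


def localize_ssrs(
    hits: Sequence[SSRHit], annotations: Mapping[str, ORFAnnotation]
) -> list[SSRHit]:
    """Assign each hit a region by interval midpoint and a signed distance
    (nt) from the first base of the start codon (negative = upstream)."""
    out: list[SSRHit] = []
    for hit in hits:
        ann = annotations.get(hit.transcript_id)
        if ann is None:
            out.append(replace(hit, region="unannotated",
                               distance_to_start_codon=None))
            continue
        mid = (hit.interval[0] + hit.interval[1]) // 2
        orf_s, orf_e = ann.orf_interval
        if mid < orf_s:
            region = "5'UTR"
        elif mid < orf_e:
            region = "ORF"
        else:
            region = "3'UTR"
        out.append(replace(hit, region=region,
                           distance_to_start_codon=mid - orf_s))
    return out


def ssr_spectrum(
    hits: Sequence[SSRHit],
    transcripts: Sequence[TranscriptRecord],
    bin_width: int = 30,
    upstream_window: int = 150,
) -> dict[str, object]:
    """Summary tables: per-period counts, per-canonical-motif counts,
    fraction of transcripts with >=1 SSR, and a positional histogram in
    fixed bins of ``bin_width`` nt starting ``upstream_window`` nt upstream
    of the start codon."""
    per_period = Counter(h.period for h in hits)
    per_motif = Counter(h.motif for h in hits)
    with_ssr = {h.transcript_id for h in hits}
    frac = (
        sum(1 for t in transcripts if t.id in with_ssr) / len(transcripts)
        if transcripts else 0.0
    )
    pos_bins: Counter[int] = Counter()
    for h in hits:
        d = h.distance_to_start_codon
        if d is None or d < -upstream_window:
            continue
        pos_bins[((d + upstream_window) // bin_width) * bin_width
                 - upstream_window] += 1
    period_df = pd.DataFrame(
        sorted(per_period.items()), columns=["period", "count"]
    )
    motif_df = pd.DataFrame(
        sorted(per_motif.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["motif", "count"],
    )
    pos_df = pd.DataFrame(
        sorted(pos_bins.items()), columns=["bin_start", "count"]
    )
    return {
        "per_period": period_df,
        "per_motif": motif_df,
        "fraction_with_ssr": frac,
        "positional_histogram": pos_df,
    }


def hits_to_frame(hits: Iterable[SSRHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "transcript_id": h.transcript_id,
            "motif": h.motif,
            "period": h.period,
            "repeat_count": h.repeat_count,
            "start": h.interval[0],
            "end": h.interval[1],
            "region": h.region,
            "distance_to_start_codon": h.distance_to_start_codon,
        } for h in hits]
    )
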