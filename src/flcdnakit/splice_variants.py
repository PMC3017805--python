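"""Genome-free detection and classification of alternative-splicing pairs.

Without a genome, two isoforms of one gene can only be compared as mature
transcripts: splicing differences surface as indel blocks (or terminal
overlap geometry) inside an otherwise near-identical pairwise alignment.
A candidate isoform pair must show >99% identity over at least 100 aligned
columns once AS-sized gap blocks (>= 30 nt, the minimum accepted intron)
are excised; smaller indels are treated as sequencing artifacts.

Each AS-sized block is tested against the GT-AG rule, sliding the gap
register across equal flanking bases to resolve alignment-ambiguous gap
placement before rejecting.  The six event types are operationalized as:

* ``IntronR`` — a single retained block beginning GT and ending AG
  (GC..AG accepted as the minor class only when GT-AG fails);
* ``AltP``   — both transcripts retain a GT/GC..AG block, at different
  positions (an intron retained at an alternative position);
* ``AltD``   — block carries the donor dinucleotide only (starts GT,
  never ends AG at any register);
* ``AltA``   — block carries the acceptor only (ends AG, never starts
  GT/GC);
* ``ExonS``  — an internal block with no splice dinucleotides at any
  register (a cassette exon, whose introns are invisible in mRNA);
* ``ExonO``  — no internal block at all: a dovetail terminal overlap
  between two single-exon-style transcripts.

The ExonO/AltP geometries are this package's explicit operational
definitions, not a published standard; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean, median
from typing import Mapping, Sequence

from . import alignment_core as ac
from .clustering import Cluster
from .sequence_io import TranscriptRecord

AS_TYPES = ("IntronR", "AltP", "ExonO", "ExonS", "AltA", "AltD")

MIN_INTRON = 30
MIN_FLANK_COLUMNS = 100
MIN_FLANK_IDENTITY = 0.99
MIN_OVERHANG = 30  # nt of unshared sequence required for ExonO dovetails
TERMINUS_SLACK = 20


@dataclass(frozen=True)
class ASEvent:
    transcript_a: str
    transcript_b: str
    as_type: str
    boundary: str | None  # "GT-AG" | "GC-AG" | None
    block_carrier: str | None  # id of the transcript holding the block
    block_interval: tuple[int, int] | None
    inferred_intron_length: int | None

    def __post_init__(self) -> None:
        if self.as_type not in AS_TYPES:
            raise ValueError(f"unknown AS type {self.as_type!r}")


@dataclass(frozen=True)
class CandidatePair:
    id_a: str
    id_b: str
    alignment: ac.PairwiseAlignment


@dataclass(frozen=True)
class _Block:
    carrier: str  # transcript id
    interval: tuple[int, int]  # on the carrier
    length: int
    status: str  # "GT-AG" | "GC-AG" | "donor" | "acceptor" | "none"


def _slide_registers(t: str, p: int, L: int) -> range:
    """Registers r such that shifting the block [p, p+L) by r within its
    transcript leaves the implied alignment unchanged (equal flanking
    bases on the appropriate side)."""
    right = 0
    while p + L + right < len(t) and t[p + right] == t[p + L + right]:
        right += 1
    left = 0
    while p - left - 1 >= 0 and t[p - left - 1] == t[p + L - left - 1]:
        left += 1
    return range(-left, right + 1)


def _block_status(t: str, p: int, L: int) -> tuple[str, int]:
    """GT-AG classification of a retained block, over all slid registers.

    Preference order: GT..AG, then GC..AG, then donor-only (GT start),
    then acceptor-only (AG end), then none.  Within one status the
    register closest to the aligned placement wins.
    """
    registers = sorted(_slide_registers(t, p, L), key=lambda r: (abs(r), r))
    found = {"GT-AG": None, "GC-AG": None, "donor": None, "acceptor": None}
    for r in registers:
        s2 = t[p + r : p + r + 2]
        e2 = t[p + L + r - 2 : p + L + r]
        if s2 == "GT" and e2 == "AG" and found["GT-AG"] is None:
            found["GT-AG"] = r
        elif s2 == "GC" and e2 == "AG" and found["GC-AG"] is None:
            found["GC-AG"] = r
        if s2 == "GT" and found["donor"] is None:
            found["donor"] = r
        if e2 == "AG" and found["acceptor"] is None:
            found["acceptor"] = r
    for status in ("GT-AG", "GC-AG", "donor", "acceptor"):
        if found[status] is not None:
            return status, found[status]
    return "none", 0


def _parse_blocks(
    aln: ac.PairwiseAlignment, seq_a: str, seq_b: str,
    id_a: str, id_b: str, min_intron: int,
) -> tuple[list[_Block], int, int]:
    """AS-sized gap blocks plus flank statistics (columns, matches) of the
    alignment with those blocks excised."""
    qpos = aln.query_interval[0]
    spos = aln.subject_interval[0]
    blocks: list[_Block] = []
    flank_cols = flank_matches = 0
    i = 0
    ops = aln.ops
    while i < len(ops):
        op = ops[i]
        j = i
        while j < len(ops) and ops[j] == op:
            j += 1
        run = j - i
        if op == "I":  # block present in A only
            if run >= min_intron:
                status, r = _block_status(seq_a, qpos, run)
                iv = (qpos + r, qpos + run + r)
                blocks.append(_Block(id_a, iv, run, status))
            else:
                flank_cols += run
            qpos += run
        elif op == "D":  # block present in B only
            if run >= min_intron:
                status, r = _block_status(seq_b, spos, run)
                iv = (spos + r, spos + run + r)
                blocks.append(_Block(id_b, iv, run, status))
            else:
                flank_cols += run
            spos += run
        else:
            flank_cols += run
            flank_matches += ops[i:j].count("M")
            qpos += run
            spos += run
        i = j
    return blocks, flank_cols, flank_matches


def _is_dovetail(
    aln: ac.PairwiseAlignment, len_a: int, len_b: int,
    min_overhang: int = MIN_OVERHANG, slack: int = TERMINUS_SLACK,
) -> bool:
    """True when the aligned region joins the 3' end of one transcript to
    the 5' end of the other, each with a substantial unshared remainder."""
    qs, qe = aln.query_interval
    ss, se = aln.subject_interval
    a_head, a_tail = qs, len_a - qe
    b_head, b_tail = ss, len_b - se
    fwd = (a_tail <= slack and b_head <= slack
           and a_head >= min_overhang and b_tail >= min_overhang)
    rev = (b_tail <= slack and a_head <= slack
           and b_head >= min_overhang and a_tail >= min_overhang)
    return fwd or rev


def candidate_as_pairs(
    clusters: Sequence[Cluster],
    transcripts: Sequence[TranscriptRecord],
    min_intron: int = MIN_INTRON,
    min_flank_columns: int = MIN_FLANK_COLUMNS,
    min_flank_identity: float = MIN_FLANK_IDENTITY,
) -> list[CandidatePair]:
    """Within-cluster transcript pairs that look like isoform pairs.

    Singletons contribute nothing.  A pair qualifies when its flanking
    alignment (AS-sized gaps excised) spans >= 100 columns at >99%
    identity and the alignment shows either an AS-sized gap or a dovetail
    terminal-overlap geometry.
    """
    by_id = {t.id: t for t in transcripts}
    out: list[CandidatePair] = []
    for cl in clusters:
        members = [m for m in cl.member_ids if m in by_id]
        for x in range(len(members)):
            for y in range(x + 1, len(members)):
                id_a, id_b = members[x], members[y]
                seq_a, seq_b = by_id[id_a].seq, by_id[id_b].seq
                aln = ac.align(seq_a, seq_b, mode="local", strand="forward",
                               query_id=id_a, subject_id=id_b,
                               scoring=ac.LONG_GAP_SCORING)
                if aln is None:
                    continue
                blocks, fc, fm = _parse_blocks(
                    aln, seq_a, seq_b, id_a, id_b, min_intron)
                if fc < min_flank_columns or fm / fc <= min_flank_identity:
                    continue
                if blocks or _is_dovetail(aln, len(seq_a), len(seq_b)):
                    out.append(CandidatePair(id_a, id_b, aln))
    return out


def classify_as_event(
    pair: CandidatePair,
    transcripts: Sequence[TranscriptRecord] | Mapping[str, TranscriptRecord],
    min_intron: int = MIN_INTRON,
) -> list[ASEvent]:
    """Classify one candidate pair; an empty list means rejected.

    A pair with several AS-sized blocks can emit several events (isoform
    groups may show more than one AS pattern at once).
    """
    by_id = (transcripts if isinstance(transcripts, Mapping)
             else {t.id: t for t in transcripts})
    seq_a = by_id[pair.id_a].seq
    seq_b = by_id[pair.id_b].seq
    aln = pair.alignment
    blocks, _, _ = _parse_blocks(aln, seq_a, seq_b,
                                 pair.id_a, pair.id_b, min_intron)
    events: list[ASEvent] = []

    if not blocks:
        if _is_dovetail(aln, len(seq_a), len(seq_b)):
            events.append(ASEvent(pair.id_a, pair.id_b, "ExonO",
                                  None, None, None, None))
        return events

    intron_blocks = [b for b in blocks if b.status in ("GT-AG", "GC-AG")]
    carriers = {b.carrier for b in intron_blocks}
    if len(carriers) == 2:
        # GT..AG blocks retained on both sides: intron at alternative position
        first = intron_blocks[0]
        events.append(ASEvent(pair.id_a, pair.id_b, "AltP",
                              first.status, first.carrier, first.interval,
                              first.length))
        remaining = [b for b in blocks if b not in intron_blocks]
    else:
        remaining = list(blocks)

    for b in remaining:
        if b.status in ("GT-AG", "GC-AG"):
            events.append(ASEvent(pair.id_a, pair.id_b, "IntronR",
                                  b.status, b.carrier, b.interval, b.length))
        elif b.status == "donor":
            events.append(ASEvent(pair.id_a, pair.id_b, "AltD",
                                  None, b.carrier, b.interval, None))
        elif b.status == "acceptor":
            events.append(ASEvent(pair.id_a, pair.id_b, "AltA",
                                  None, b.carrier, b.interval, None))
        else:
            events.append(ASEvent(pair.id_a, pair.id_b, "ExonS",
                                  None, b.carrier, b.interval, None))
    return events


def classify_all(
    pairs: Sequence[CandidatePair],
    transcripts: Sequence[TranscriptRecord],
    min_intron: int = MIN_INTRON,
) -> list[ASEvent]:
    by_id = {t.id: t for t in transcripts}
    events: list[ASEvent] = []
    for pair in pairs:
        events.extend(classify_as_event(pair, by_id, min_intron))
    return events


def intron_size_summary(events: Sequence[ASEvent]) -> dict[str, float]:
    """Mean/median retained-intron length over IntronR events."""
    lengths = [e.inferred_intron_length for e in events
               if e.as_type == "IntronR" and e.inferred_intron_length]
    if not lengths:
        raise ValueError("no IntronR events with an inferred intron length")
    return {
        "n": len(lengths),
        "mean": float(mean(lengths)),
        "median": float(median(lengths)),
    }


def type_counts(events: Sequence[ASEvent]) -> dict[str, int]:
    counts = {t: 0 for t in AS_TYPES}
    for e in events:
        counts[e.as_type] += 1
    return counts
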