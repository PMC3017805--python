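"""Synthetic FL-cDNA / EST collections with machine-readable ground truth.

The generator emulates the statistical structure of a grass full-length
cDNA project: GC-rich transcripts of mean length ~1,092 nt with
ATG-initiated ORFs (> 100 aa), GC3 near 0.692, AT-poorer 5'UTRs than
3'UTRs, microsatellites planted by region, alternative-splicing isoform
pairs with GT-AG (minor class GC-AG) introns of mean ~218 nt,
cis-antisense partners overlapping 73–960 nt (mean 467), duplicated
paralogs at chosen Ks, and 5'-anchored single-pass EST reads whose
per-gene depth follows a truncated negative binomial of mean 8.

Everything is driven by one :class:`numpy.random.Generator`; identical
config + seed reproduces identical records byte for byte.  Every planted
AS / NAT / SSR / duplication event appears exactly once in the returned
truth table, and base sequences are scrubbed so that no *unplanted* event
passes the detection thresholds — the generator output is a closed world
for precision/recall closure tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import ssr_profiler
from .divergence_dating import mutate_to_ks
from .orf_composition import STOP_CODONS, _CODON_TO_AA, find_longest_orf
from .phylogeny import TreeNode
from .sequence_io import TranscriptRecord
from .splice_variants import _block_status, _slide_registers

AS_TYPES = ("IntronR", "AltP", "ExonO", "ExonS", "AltA", "AltD")

# AS-type frequencies proportional to a typical FL-cDNA survey's counts
# (the pooled GT-AG classes split 120/18 between IntronR and AltP; 288
# typed events across the AS-positive groups).
DEFAULT_AS_PROBS = {
    "IntronR": 120 / 288, "AltP": 18 / 288, "ExonO": 92 / 288,
    "ExonS": 29 / 288, "AltA": 15 / 288, "AltD": 14 / 288,
}

_SENSE_CODONS = sorted(c for c in _CODON_TO_AA if c not in STOP_CODONS)
_GC_ENDING = [c for c in _SENSE_CODONS if c[2] in "GC"]
_AT_ENDING = [c for c in _SENSE_CODONS if c[2] in "AT"]

_SSR_MOTIFS = {
    1: ["A", "T", "G", "C"],
    2: ["AG", "AT", "AC", "CG"],
    3: ["CCG", "AGG", "AGC", "ACG"],
}
# tri-nucleotide motifs safe inside an ORF (in-frame, never a stop)
_ORF_SSR_MOTIFS = ["GCG", "CCG", "AGG", "AGC"]


@dataclass
class SimulationConfig:
    """Study-condition defaults for the synthetic transcriptome."""

    n_genes: int = 200
    mean_transcript_length: int = 1092
    sd_transcript_length: int = 220
    min_transcript_length: int = 550
    orf_min_aa: int = 100
    gc3_target: float = 0.692
    gc_utr5: float = 0.568
    gc_utr3: float = 0.423
    intron_mean_length: float = 218.0
    intron_sd_length: float = 60.0
    intron_min_length: int = 60
    gc_ag_fraction: float = 6 / 138  # minor splice class frequency
    as_fraction: float = 304 / 10608
    as_type_probabilities: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AS_PROBS))
    ssr_probability: float = 0.24
    ssr_region_probabilities: dict[str, float] = field(
        default_factory=lambda: {"5'UTR": 0.35, "ORF": 0.35, "3'UTR": 0.30})
    nat_fraction: float = 25 / 10608
    nat_overlap_range: tuple[int, int] = (73, 960)
    nat_overlap_mean: float = 467.0
    nat_overlap_sd: float = 150.0
    duplication_fraction: float = 0.0
    duplication_ks: float = 0.195
    duplication_ka_ks: float = 0.2
    est_depth_mean: float = 8.0
    est_depth_nb_r: float = 0.35
    est_length_mean: float = 550.0
    est_length_sd: float = 80.0
    est_min_length: int = 100
    est_error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        probs = self.as_type_probabilities
        if set(probs) - set(AS_TYPES):
            raise ValueError(f"unknown AS types {set(probs) - set(AS_TYPES)}")
        if any(not 0 <= p <= 1 for p in probs.values()):
            raise ValueError("AS-type probabilities must lie in [0, 1]")
        if probs and abs(sum(probs.values()) - 1) > 1e-9:
            raise ValueError("AS-type probabilities must sum to 1")
        for p in (self.as_fraction, self.ssr_probability, self.nat_fraction,
                  self.duplication_fraction, self.gc3_target, self.gc_utr5,
                  self.gc_utr3, self.est_error_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities/fractions must lie in [0, 1]")
        min_orf_nt = 3 * (self.orf_min_aa + 2)
        if min_orf_nt + 60 > self.min_transcript_length:
            raise ValueError(
                "min_transcript_length cannot accommodate an ORF longer "
                f"than {self.orf_min_aa} aa plus UTRs"
            )


@dataclass(frozen=True)
class GeneModel:
    """A simulated locus; the mature transcript is the exon concatenation."""

    gene_id: str
    scaffold: str
    exons: tuple[tuple[int, int], ...]
    cds_interval: tuple[int, int]  # on the mature transcript
    gc_targets: dict[str, float]
    truth: dict[str, object]

    def __post_init__(self) -> None:
        prev_end = None
        for s, e in self.exons:
            if s >= e:
                raise ValueError("empty exon")
            if prev_end is not None:
                if s < prev_end:
                    raise ValueError("exons must be sorted, non-overlapping")
                intron = self.scaffold[prev_end:s]
                donor_ok = intron.startswith("GT") or (
                    self.truth.get("gc_ag") and intron.startswith("GC"))
                if not (donor_ok and intron.endswith("AG")):
                    raise ValueError("intron violates the GT-AG rule")
            prev_end = e

    @property
    def mature_transcript(self) -> str:
        return "".join(self.scaffold[s:e] for s, e in self.exons)


@dataclass(frozen=True)
class SimulatedTranscriptome:
    genes: tuple[GeneModel, ...]
    transcripts: tuple[TranscriptRecord, ...]  # primary + derived records
    primary_ids: tuple[str, ...]
    truth: pd.DataFrame
    orf_truth: dict[str, tuple[int, int]]  # planted ORF interval per primary


# ---------------------------------------------------------------------------
# low-level sequence builders

def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _random_orf(rng: np.random.Generator, n_codons: int, gc3: float) -> str:
    """ATG + sense codons with third-base class Bernoulli(gc3) + stop."""
    body = []
    for _ in range(n_codons):
        pool = _GC_ENDING if rng.random() < gc3 else _AT_ENDING
        body.append(pool[int(rng.integers(len(pool)))])
    stop = ("TAA", "TGA", "TAG")[int(rng.integers(3))]
    return "ATG" + "".join(body) + stop


def _point_mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        alts = [b for b in "ACGT" if b != out[i]]
        out[i] = alts[int(rng.integers(3))]
    return "".join(out)


def _has_unplanted_ssr(seq: str) -> bool:
    return bool(ssr_profiler.detect_ssrs(seq))


def _clean_dna(rng: np.random.Generator, n: int, gc: float,
               forbid_atg: bool = False, max_tries: int = 200) -> str:
    """Random DNA free of detection-threshold SSRs (and optionally ATG)."""
    for _ in range(max_tries):
        seq = _random_dna(rng, n, gc)
        if forbid_atg and "ATG" in seq:
            continue
        if not _has_unplanted_ssr(seq):
            return seq
    raise RuntimeError("could not build a clean random segment")


def _clean_orf(rng: np.random.Generator, n_codons: int, gc3: float,
               max_tries: int = 200) -> str:
    for _ in range(max_tries):
        seq = _random_orf(rng, n_codons, gc3)
        if not _has_unplanted_ssr(seq):
            return seq
    raise RuntimeError("could not build a clean ORF")


# ---------------------------------------------------------------------------
# AS block builders (each validated against the classifier's geometry)

def _status_of_block(iso: str, p: int, L: int) -> str:
    return _block_status(iso, p, L)[0]


def _make_block(rng: np.random.Generator, kind: str, length: int,
                gc: float = 0.45) -> str:
    """Interior of a retained block for the requested AS geometry."""
    inner = _clean_dna(rng, max(length - 4, 1), gc)
    if kind in ("GT-AG", "GC-AG"):
        donor = "GT" if kind == "GT-AG" else "GC"
        return donor + inner[: length - 4] + "AG"
    if kind == "donor":
        return "GT" + inner[: length - 2]
    if kind == "acceptor":
        return inner[: length - 2] + "AG"
    return inner[:length] if len(inner) >= length else inner + _clean_dna(
        rng, length - len(inner), gc)


_EXPECTED_STATUS = {"GT-AG": "GT-AG", "GC-AG": "GC-AG", "donor": "donor",
                    "acceptor": "acceptor", "exon": "none"}


def _insert_block(rng: np.random.Generator, base: str, kind: str,
                  length: int, max_tries: int = 200,
                  region: tuple[int, int] | None = None) -> tuple[str, int]:
    """Insert a block of the given splice geometry into ``base`` such that
    the classifier, after register sliding, sees exactly that geometry.
    Returns (isoform sequence, insertion position)."""
    lo, hi = region if region else (200, len(base) - 200)
    if hi <= lo:
        raise ValueError("transcript too short for an internal AS block")
    want = _EXPECTED_STATUS[kind]
    for _ in range(max_tries):
        p = int(rng.integers(lo, hi))
        block = _make_block(rng, kind, length)
        iso = base[:p] + block + base[p:]
        if _status_of_block(iso, p, len(block)) == want:
            # scan the whole isoform so junction-spanning repeats are caught
            if not _has_unplanted_ssr(iso):
                return iso, p
    raise RuntimeError(f"could not place a clean {kind} block")


# ---------------------------------------------------------------------------
# the transcriptome simulator

def _build_primary(rng: np.random.Generator, cfg: SimulationConfig,
                   max_tries: int = 50) -> tuple[str, tuple[int, int]]:
    """One scrubbed primary transcript whose longest ORF equals the plant."""
    for _ in range(max_tries):
        total = int(rng.normal(cfg.mean_transcript_length,
                               cfg.sd_transcript_length))
        total = max(total, cfg.min_transcript_length)
        utr5 = max(30, int(round(total * 0.12)))
        utr3 = max(30, int(round(total * 0.25)))
        orf_nt = total - utr5 - utr3
        orf_nt -= orf_nt % 3
        min_orf = 3 * (cfg.orf_min_aa + 2)
        if orf_nt < min_orf:
            orf_nt = min_orf
        n_codons = orf_nt // 3 - 2  # minus ATG and stop
        u5 = _clean_dna(rng, utr5, cfg.gc_utr5, forbid_atg=True)
        orf = _clean_orf(rng, n_codons, cfg.gc3_target)
        u3 = _clean_dna(rng, utr3, cfg.gc_utr3)
        seq = u5 + orf + u3
        ann = find_longest_orf(seq)
        planted = (utr5, utr5 + len(orf))
        if ann is not None and ann.orf_interval == planted:
            return seq, planted
    raise RuntimeError("could not build a primary transcript")


def simulate_transcriptome(config: SimulationConfig) -> SimulatedTranscriptome:
    """Generate gene models, transcript records and the truth table.

    Roles (AS isoform, NAT partner, duplication) are assigned to disjoint
    gene subsets so that every planted event is attributable to exactly
    one truth row; SSRs are planted only in genes without another role.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    genes: list[GeneModel] = []
    transcripts: list[TranscriptRecord] = []
    primary_ids: list[str] = []
    truth_rows: list[dict[str, object]] = []
    orf_truth: dict[str, tuple[int, int]] = {}

    as_types = sorted(cfg.as_type_probabilities)
    as_p = [cfg.as_type_probabilities[t] for t in as_types]

    for g in range(cfg.n_genes):
        gid = f"g{g:05d}"
        seq, cds = _build_primary(rng, cfg)

        u = rng.random()
        role = "plain"
        if u < cfg.as_fraction and as_types:
            role = "as"
        elif u < cfg.as_fraction + cfg.nat_fraction:
            role = "nat"
        elif u < (cfg.as_fraction + cfg.nat_fraction
                  + cfg.duplication_fraction):
            role = "dup"

        intron_scaffold: tuple[str, tuple[tuple[int, int], ...]] | None = None
        gene_truth: dict[str, object] = {"role": role}

        if role == "as":
            as_type = as_types[int(rng.choice(len(as_types), p=as_p))]
            iso_id = f"{gid}.as"
            gc_ag = (as_type in ("IntronR", "AltP")
                     and rng.random() < cfg.gc_ag_fraction)
            boundary_kind = "GC-AG" if gc_ag else "GT-AG"
            gene_truth["gc_ag"] = gc_ag
            if as_type == "IntronR":
                L = _intron_length(rng, cfg)
                iso, p = _insert_block(rng, seq, boundary_kind, L)
                intron_scaffold = (iso, ((0, p), (p + L, len(iso))))
                truth_rows.append(_as_row(gid, gid, iso_id, as_type, p, L))
                transcripts_extra = [(iso_id, iso)]
            elif as_type == "AltP":
                L = _intron_length(rng, cfg)
                iso_a, p = _insert_block(rng, seq, boundary_kind, L,
                                         region=(200, len(seq) // 2))
                iso_b, q = _insert_block(rng, seq, boundary_kind, L,
                                         region=(len(seq) // 2 + 60,
                                                 len(seq) - 200))
                seq = iso_a  # the primary carries one placement
                ann = find_longest_orf(seq)
                cds = ann.orf_interval if ann else _shift_interval(cds, p, L)
                truth_rows.append(_as_row(gid, gid, iso_id, as_type, q, L))
                transcripts_extra = [(iso_id, iso_b)]
            elif as_type in ("AltD", "AltA"):
                kind = "donor" if as_type == "AltD" else "acceptor"
                L = max(40, int(rng.normal(120, 40)))
                iso, p = _insert_block(rng, seq, kind, L)
                truth_rows.append(_as_row(gid, gid, iso_id, as_type, p, L))
                transcripts_extra = [(iso_id, iso)]
            elif as_type == "ExonS":
                L = max(cfg.intron_min_length, int(rng.normal(150, 40)))
                iso, p = _insert_block(rng, seq, "exon", L)
                truth_rows.append(_as_row(gid, gid, iso_id, as_type, p, L))
                transcripts_extra = [(iso_id, iso)]
            else:  # ExonO: dovetail partner sharing the 3' end of the gene
                for _ in range(50):
                    o = int(rng.integers(150, max(151, len(seq) - 200)))
                    tail = _clean_dna(rng, int(rng.integers(200, 400)), 0.45)
                    iso = seq[-o:] + tail
                    if not _has_unplanted_ssr(iso):
                        break
                truth_rows.append(_as_row(gid, gid, iso_id, as_type,
                                          len(seq) - o, o))
                transcripts_extra = [(iso_id, iso)]
            gene_truth["as_isoform"] = {"id": iso_id, "type": as_type}
        elif role == "nat":
            nat_id = f"{gid}.nat"
            o = _nat_overlap(rng, cfg, len(seq))
            i0 = int(rng.integers(0, len(seq) - o + 1))
            window_rc = _revcomp(seq[i0:i0 + o])
            for _ in range(50):
                pad1 = _clean_dna(rng, int(rng.integers(100, 300)), 0.45)
                pad2 = _clean_dna(rng, int(rng.integers(100, 300)), 0.45)
                partner = pad1 + window_rc + pad2
                if not _has_unplanted_ssr(partner):
                    break
            truth_rows.append({
                "event_type": "NAT", "gene_id": gid, "id_a": gid,
                "id_b": nat_id, "subtype": "", "start": i0, "end": i0 + o,
                "length": o, "motif": "", "value": 0.0,
            })
            gene_truth["nat_partner_id"] = nat_id
            transcripts_extra = [(nat_id, partner)]
        elif role == "dup":
            dup_id = f"{gid}.dup"
            dup_seq = _duplicate_gene(rng, seq, cds, cfg)
            truth_rows.append({
                "event_type": "DUP", "gene_id": gid, "id_a": gid,
                "id_b": dup_id, "subtype": "", "start": -1, "end": -1,
                "length": len(dup_seq), "motif": "",
                "value": cfg.duplication_ks,
            })
            gene_truth["duplicate_of"] = gid
            gene_truth["target_ks"] = cfg.duplication_ks
            transcripts_extra = [(dup_id, dup_seq)]
        else:
            transcripts_extra = []
            if rng.random() < cfg.ssr_probability:
                seq, cds, row = _plant_ssr(rng, cfg, gid, seq, cds)
                if row is not None:
                    truth_rows.append(row)
                    gene_truth["ssr"] = {
                        "motif": row["motif"], "region": row["subtype"]}

        if intron_scaffold is not None:
            scaffold, exons = intron_scaffold
        else:
            scaffold, exons = seq, ((0, len(seq)),)

        genes.append(GeneModel(
            gene_id=gid, scaffold=scaffold, exons=exons, cds_interval=cds,
            gc_targets={"5'UTR": cfg.gc_utr5, "ORF3": cfg.gc3_target,
                        "3'UTR": cfg.gc_utr3},
            truth=gene_truth,
        ))
        transcripts.append(TranscriptRecord(gid, seq, f"simulated gene {gid}"))
        primary_ids.append(gid)
        orf_truth[gid] = cds
        for xid, xseq in transcripts_extra:
            transcripts.append(TranscriptRecord(xid, xseq,
                                                f"derived from {gid}"))

    truth = pd.DataFrame(
        truth_rows,
        columns=["event_type", "gene_id", "id_a", "id_b", "subtype",
                 "start", "end", "length", "motif", "value"],
    )
    return SimulatedTranscriptome(
        genes=tuple(genes), transcripts=tuple(transcripts),
        primary_ids=tuple(primary_ids), truth=truth, orf_truth=orf_truth,
    )


def _revcomp(seq: str) -> str:
    from .alignment_core import revcomp
    return revcomp(seq)


def _shift_interval(iv: tuple[int, int], p: int, L: int) -> tuple[int, int]:
    s, e = iv
    if p <= s:
        return (s + L, e + L)
    if p < e:
        return (s, e + L)
    return iv


def _intron_length(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    L = int(rng.normal(cfg.intron_mean_length, cfg.intron_sd_length))
    return max(cfg.intron_min_length, L)


def _nat_overlap(rng: np.random.Generator, cfg: SimulationConfig,
                 seq_len: int) -> int:
    lo, hi = cfg.nat_overlap_range
    hi = min(hi, seq_len)
    for _ in range(100):
        o = int(rng.normal(cfg.nat_overlap_mean, cfg.nat_overlap_sd))
        if lo <= o <= hi:
            return o
    return min(max(int(cfg.nat_overlap_mean), lo), hi)


def _as_row(gid: str, id_a: str, id_b: str, as_type: str,
            start: int, length: int) -> dict[str, object]:
    return {
        "event_type": "AS", "gene_id": gid, "id_a": id_a, "id_b": id_b,
        "subtype": as_type, "start": start, "end": start + length,
        "length": length, "motif": "", "value": float("nan"),
    }


def _duplicate_gene(rng: np.random.Generator, seq: str,
                    cds: tuple[int, int], cfg: SimulationConfig) -> str:
    s, e = cds
    new_cds = mutate_to_ks(seq[s:e], cfg.duplication_ks, rng,
                           ka_ks=cfg.duplication_ka_ks)
    # UTRs drift at roughly the synonymous rate
    utr_rate = 0.75 * (1 - math.exp(-4 * cfg.duplication_ks / 3)) * 0.9
    u5 = _point_mutate(rng, seq[:s], utr_rate)
    u3 = _point_mutate(rng, seq[e:], utr_rate)
    return u5 + new_cds + u3


def _plant_ssr(
    rng: np.random.Generator, cfg: SimulationConfig, gid: str,
    seq: str, cds: tuple[int, int], max_tries: int = 100,
) -> tuple[str, tuple[int, int], dict[str, object] | None]:
    regions = sorted(cfg.ssr_region_probabilities)
    probs = [cfg.ssr_region_probabilities[r] for r in regions]
    total = sum(probs)
    probs = [p / total for p in probs]
    region = regions[int(rng.choice(len(regions), p=probs))]
    s, e = cds
    for _ in range(max_tries):
        if region == "ORF":
            period = 3
            motif = _ORF_SSR_MOTIFS[int(rng.integers(len(_ORF_SSR_MOTIFS)))]
            count = int(ssr_profiler.DEFAULT_THRESHOLDS[3]
                        + rng.integers(0, 4))
            # in-frame, inside the ORF body, away from start/stop codons
            n_codons = (e - s) // 3
            pos_codon = int(rng.integers(2, n_codons - 2 - count))
            pos = s + 3 * pos_codon
        else:
            period = int(rng.choice([1, 2, 3], p=[0.35, 0.3, 0.35]))
            motifs = _SSR_MOTIFS[period]
            motif = motifs[int(rng.integers(len(motifs)))]
            count = int(ssr_profiler.DEFAULT_THRESHOLDS[period]
                        + rng.integers(0, 4))
            if region == "5'UTR":
                if s < 8:
                    return seq, cds, None
                pos = int(rng.integers(2, max(3, s - 2)))
            else:
                if len(seq) - e < 8:
                    return seq, cds, None
                pos = int(rng.integers(e + 2, len(seq) - 2))
        repeat = motif * count
        new_seq = seq[:pos] + repeat + seq[pos:]
        new_cds = _shift_interval(cds, pos, len(repeat))
        hits = ssr_profiler.detect_ssrs(new_seq)
        canonical = ssr_profiler.canonical_motif(motif)
        expected = [h for h in hits
                    if h.interval == (pos, pos + len(repeat))
                    and h.motif == canonical and h.repeat_count == count]
        ann = find_longest_orf(new_seq)
        if (len(hits) == 1 and expected and ann is not None
                and ann.orf_interval == new_cds):
            row = {
                "event_type": "SSR", "gene_id": gid, "id_a": gid,
                "id_b": "", "subtype": region, "start": pos,
                "end": pos + len(repeat), "length": period,
                "motif": canonical, "value": float(count),
            }
            return new_seq, new_cds, row
    return seq, cds, None


# ---------------------------------------------------------------------------
# EST simulation

def _nb_raw_mean(target_mean: float, r: float) -> float:
    """Raw NB mean whose zero-truncated mean equals ``target_mean``."""
    lo, hi = 1e-6, target_mean
    for _ in range(80):
        mid = (lo + hi) / 2
        p0 = (r / (r + mid)) ** r
        if mid / (1 - p0) < target_mean:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def simulate_ests(
    transcripts: Sequence[TranscriptRecord],
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
) -> list[TranscriptRecord]:
    """Directional 5'-anchored single-pass reads.

    Per-transcript depth is a zero-truncated negative binomial whose mean
    equals ``est_depth_mean``; read lengths are normal(est_length_mean,
    est_length_sd) truncated to [est_min_length, transcript length];
    substitution errors occur at ``est_error_rate`` per base.
    """
    if not transcripts:
        raise ValueError("transcripts must be non-empty")
    cfg = config
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(cfg.seed + 1 if rng is None else rng)
    m0 = _nb_raw_mean(cfg.est_depth_mean, cfg.est_depth_nb_r)
    p_nb = cfg.est_depth_nb_r / (cfg.est_depth_nb_r + m0)
    reads: list[TranscriptRecord] = []
    for t in transcripts:
        depth = 0
        while depth == 0:
            depth = int(rng.negative_binomial(cfg.est_depth_nb_r, p_nb))
        for k in range(depth):
            start = 0 if rng.random() < 0.8 else int(
                rng.integers(1, max(2, min(40, len(t.seq) // 10))))
            length = int(rng.normal(cfg.est_length_mean, cfg.est_length_sd))
            length = min(max(length, cfg.est_min_length), len(t.seq) - start)
            raw = t.seq[start:start + length]
            read = _point_mutate(rng, raw, cfg.est_error_rate)
            reads.append(TranscriptRecord(
                f"{t.id}.e{k:03d}", read,
                description=f"EST from {t.id} at {start}",
                source_hint=t.id,
            ))
    return reads


def simulate_ests_fixed_depth(
    transcripts: Sequence[TranscriptRecord],
    depth: int,
    config: SimulationConfig,
    rng: np.random.Generator | int | None = None,
) -> list[TranscriptRecord]:
    """Exactly ``depth`` reads per transcript (constant depth law)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed + 1 if rng is None else rng)
    cfg = config
    reads: list[TranscriptRecord] = []
    for t in transcripts:
        for k in range(depth):
            start = 0 if rng.random() < 0.8 else int(
                rng.integers(1, max(2, min(40, len(t.seq) // 10))))
            length = int(rng.normal(cfg.est_length_mean, cfg.est_length_sd))
            length = min(max(length, cfg.est_min_length), len(t.seq) - start)
            read = _point_mutate(rng, t.seq[start:start + length],
                                 cfg.est_error_rate)
            reads.append(TranscriptRecord(f"{t.id}.e{k:03d}", read,
                                          source_hint=t.id))
    return reads


# ---------------------------------------------------------------------------
# duplication clusters (EST haplotype dating closure)

def simulate_duplication_clusters(
    n_clusters: int,
    target_ks: float,
    config: SimulationConfig | None = None,
    depth_per_haplotype: int = 4,
    est_error_rate: float = 0.005,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[TranscriptRecord], dict[str, tuple[int, int]],
           list[TranscriptRecord]]:
    """EST clusters containing two haplotypes diverged at ``target_ks``.

    Reads are full-length (they must span the coding region for the
    dating rule); errors are substitutions at ``est_error_rate``.
    Returns (FL-cDNA references, ORF truth intervals, EST reads).
    """
    cfg = config or SimulationConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(cfg.seed + 2 if rng is None else rng)
    fl: list[TranscriptRecord] = []
    orf_truth: dict[str, tuple[int, int]] = {}
    ests: list[TranscriptRecord] = []
    for c in range(n_clusters):
        gid = f"dc{c:04d}"
        seq, cds = _build_primary(rng, cfg)
        s, e = cds
        hap_b = (seq[:s]
                 + mutate_to_ks(seq[s:e], target_ks, rng, ka_ks=0.1)
                 + seq[e:])
        fl.append(TranscriptRecord(gid, seq))
        orf_truth[gid] = cds
        for h, hap in (("a", seq), ("b", hap_b)):
            for k in range(depth_per_haplotype):
                read = _point_mutate(rng, hap, est_error_rate)
                ests.append(TranscriptRecord(f"{gid}.{h}{k}", read,
                                             source_hint=gid))
    return fl, orf_truth, ests


# ---------------------------------------------------------------------------
# cross-species homolog / ortholog sets

def simulate_homolog_sets(
    n_genes: int,
    species: Sequence[str] = ("rice", "wheat", "barley", "brachypodium"),
    shared_fraction: float = 0.4,
    anchor_only_fraction: float = 0.2,
    ortholog_ks: float = 0.3,
    ortholog_ka_ks: float = 0.2,
    utr_divergence: float = 0.10,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[TranscriptRecord], dict[str, list[TranscriptRecord]],
           dict[str, str]]:
    """Query transcripts plus per-species databases with known categories.

    Genes are "shared" (an ortholog in every species), "anchor_only"
    (ortholog only in the first species) or "unique" (no ortholog
    anywhere).  Returns (queries, species databases, truth category per
    query id).
    """
    cfg = config or SimulationConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(cfg.seed + 3 if rng is None else rng)
    anchor = species[0]
    queries: list[TranscriptRecord] = []
    dbs: dict[str, list[TranscriptRecord]] = {sp: [] for sp in species}
    categories: dict[str, str] = {}
    for g in range(n_genes):
        gid = f"q{g:04d}"
        seq, cds = _build_primary(rng, cfg)
        queries.append(TranscriptRecord(gid, seq))
        u = rng.random()
        if u < shared_fraction:
            cat = "shared"
            targets = list(species)
        elif u < shared_fraction + anchor_only_fraction:
            cat = "anchor_only"
            targets = [anchor]
        else:
            cat = "unique"
            targets = []
        categories[gid] = cat
        s, e = cds
        for sp in targets:
            hom_cds = mutate_to_ks(seq[s:e], ortholog_ks, rng,
                                   ka_ks=ortholog_ka_ks)
            u5 = _point_mutate(rng, seq[:s], utr_divergence)
            u3 = _point_mutate(rng, seq[e:], utr_divergence)
            dbs[sp].append(TranscriptRecord(f"{sp}_{gid}", u5 + hom_cds + u3))
    return queries, dbs, categories


# ---------------------------------------------------------------------------
# sequence evolution on a tree (phylogeny closure)

def simulate_jc_alignment(
    tree: TreeNode,
    n_columns: int,
    rng: np.random.Generator | int | None = None,
) -> dict[str, str]:
    """Evolve an alignment on ``tree`` under Jukes–Cantor: each branch of
    length t substitutes each site with probability (3/4)(1 − e^(−4t/3))."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    bases = np.array(list("ACGT"))
    root_seq = rng.integers(0, 4, size=n_columns)
    out: dict[str, str] = {}

    def walk(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            p = 0.75 * (1 - math.exp(-4 * child.length / 3))
            child_seq = seq.copy()
            hit = rng.random(n_columns) < p
            shift = rng.integers(1, 4, size=int(hit.sum()))
            child_seq[hit] = (child_seq[hit] + shift) % 4
            if child.is_leaf:
                out[child.name] = "".join(bases[child_seq])
            else:
                walk(child, child_seq)

    walk(tree, root_seq)
    return out
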