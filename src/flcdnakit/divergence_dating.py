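"""Codon-aware Ka/Ks estimation and Ks-based duplication dating.

The estimator is Nei–Gojobori (1986) counting with Jukes–Cantor multiple-
hit correction:

* synonymous site count of a codon = sum over its three positions of the
  fraction of the three possible base changes that preserve the amino
  acid (changes creating a stop codon count as nonsynonymous); S is the
  average of the two sequences' totals and N = 3·codons − S;
* observed differences in multi-hit codons are averaged with equal weight
  over the minimal mutational pathways, pathways crossing a stop codon
  excluded (all pathways used if every one crosses a stop);
* d = −(3/4)·ln(1 − (4/3)·p) applied to ps = Sd/S and pn = Nd/N, with
  p ≥ 0.75 flagged as saturated (Ks/Ka undefined).

Divergence/duplication times follow the molecular clock T = Ks / (2r)
with the grass synonymous rate r = 6.5e-9 substitutions per synonymous
site per year as the default.

The EST-cluster duplication analysis rebuilds the paleoduplication dating
procedure: ESTs are assigned to their best-matching FL-cDNA by ungapped
alignment, stacked into a reference-anchored alignment, polymorphic
columns supported by fewer than 2 reads are masked as sequencing error,
reads are grouped into haplotypes over the retained polymorphic columns,
and two-haplotype clusters whose reads span the entire predicted coding
region are dated via the Ks between haplotype consensus CDSs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from . import alignment_core as ac
from .orf_composition import ORFAnnotation, STOP_CODONS, _CODON_TO_AA, translate_cds
from .sequence_io import TranscriptRecord

GRASS_SYNONYMOUS_RATE = 6.5e-9  # substitutions / synonymous site / year

_BASES = "ACGT"


class SaturationError(ValueError):
    """Synonymous divergence beyond the Jukes–Cantor correctable range."""


@dataclass(frozen=True)
class DivergenceEstimate:
    id_a: str
    id_b: str
    codons_used: int
    S: float
    N: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    ks: float | None  # None when saturated
    ka: float | None

    @property
    def ratio(self) -> float | None:
        if self.ks is None or self.ka is None or self.ks == 0:
            return None
        return self.ka / self.ks

    @property
    def saturated(self) -> bool:
        return self.ks is None or self.ka is None


def _syn_fraction(codon: str) -> float:
    """Synonymous sites of one codon (0..3)."""
    aa = _CODON_TO_AA[codon]
    total = 0.0
    for pos in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt not in STOP_CODONS and _CODON_TO_AA[alt] == aa:
                syn += 1
        total += syn / 3
    return total


def _pathway_counts(ca: str, cb: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons,
    averaged over stop-free minimal mutational pathways."""
    diff_pos = [i for i in range(3) if ca[i] != cb[i]]
    nd = len(diff_pos)
    if nd == 0:
        return 0.0, 0.0
    if nd == 1:
        p = diff_pos[0]
        alt = cb
        same_aa = _CODON_TO_AA[ca] == _CODON_TO_AA[alt]
        return (1.0, 0.0) if same_aa else (0.0, 1.0)
    valid: list[tuple[int, int]] = []
    all_paths: list[tuple[int, int]] = []
    for order in permutations(diff_pos):
        cur = ca
        sd = nd_ = 0
        crosses_stop = False
        for p in order:
            nxt = cur[:p] + cb[p] + cur[p + 1:]
            if nxt in STOP_CODONS:
                crosses_stop = True
            if (nxt not in STOP_CODONS and cur not in STOP_CODONS
                    and _CODON_TO_AA[cur] == _CODON_TO_AA[nxt]):
                sd += 1
            else:
                nd_ += 1
            cur = nxt
        all_paths.append((sd, nd_))
        if not crosses_stop:
            valid.append((sd, nd_))
    paths = valid if valid else all_paths
    sd = sum(p[0] for p in paths) / len(paths)
    nd_ = sum(p[1] for p in paths) / len(paths)
    return sd, nd_


def _peptide_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def codon_align(cds_a: str, cds_b: str) -> list[tuple[str, str]]:
    """Peptide-guided codon alignment of two CDSs.

    Both inputs must be ATG-initiated, a multiple of 3, and free of
    internal stop codons (a trailing stop is allowed and excluded).
    Returns aligned codon pairs; gap columns and codons containing N are
    dropped.
    """
    for name, cds in (("first", cds_a), ("second", cds_b)):
        if len(cds) < 3 or len(cds) % 3:
            raise ValueError(f"{name} CDS length must be a positive multiple of 3")
        if not cds.startswith("ATG"):
            raise ValueError(f"{name} CDS must start with ATG")
        codons = [cds[i:i + 3] for i in range(0, len(cds) - 3, 3)]
        if any(c in STOP_CODONS for c in codons):
            raise ValueError(f"{name} CDS contains an internal stop codon")
    pep_a = translate_cds(cds_a)
    pep_b = translate_cds(cds_b)
    aln = _peptide_aligner().align(pep_a, pep_b)[0]
    qa, sa = aln.aligned
    pairs: list[tuple[str, str]] = []
    for (qs, qe), (ss, se) in zip(qa, sa):
        for off in range(qe - qs):
            ca = cds_a[3 * (qs + off): 3 * (qs + off) + 3]
            cb = cds_b[3 * (ss + off): 3 * (ss + off) + 3]
            if "N" in ca or "N" in cb:
                continue
            pairs.append((ca, cb))
    return pairs


def jukes_cantor(p: float) -> float | None:
    """JC69 distance; None beyond the correctable range (p >= 0.75)."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        return None
    if p == 0:
        return 0.0
    return -0.75 * math.log(1 - (4.0 / 3.0) * p)


def estimate_ka_ks(
    codon_pairs: Sequence[tuple[str, str]],
    id_a: str = "a",
    id_b: str = "b",
) -> DivergenceEstimate:
    """NG86 Ka/Ks from aligned codon pairs (>= 10 comparable codons)."""
    if len(codon_pairs) < 10:
        raise ValueError("need at least 10 comparable codons")
    s_a = s_b = 0.0
    sd = nd = 0.0
    for ca, cb in codon_pairs:
        s_a += _syn_fraction(ca)
        s_b += _syn_fraction(cb)
        d_s, d_n = _pathway_counts(ca, cb)
        sd += d_s
        nd += d_n
    n_codons = len(codon_pairs)
    S = (s_a + s_b) / 2
    N = 3 * n_codons - S
    ps = sd / S if S else 0.0
    pn = nd / N if N else 0.0
    return DivergenceEstimate(
        id_a=id_a, id_b=id_b, codons_used=n_codons,
        S=S, N=N, Sd=sd, Nd=nd, ps=ps, pn=pn,
        ks=jukes_cantor(ps), ka=jukes_cantor(pn),
    )


def kaks_pair(cds_a: str, cds_b: str, id_a: str = "a",
              id_b: str = "b") -> DivergenceEstimate:
    """Convenience: codon-align two CDSs and estimate Ka/Ks."""
    return estimate_ka_ks(codon_align(cds_a, cds_b), id_a, id_b)


def date_divergence(ks: float | None,
                    r: float = GRASS_SYNONYMOUS_RATE) -> float | None:
    """Molecular-clock age in years, T = Ks / (2r); None when Ks is
    undefined (saturated)."""
    if ks is None:
        return None
    if ks < 0 or r <= 0:
        raise ValueError("require Ks >= 0 and r > 0")
    return ks / (2 * r)


def ks_window_filter(
    estimates: Sequence[DivergenceEstimate], max_ks: float = 0.75
) -> dict[str, object]:
    """Pairs with Ks strictly below ``max_ks`` (likely orthologous range),
    plus the count under positive selection (Ka/Ks > 1) and the Ka/Ks
    occupancy of the low-ratio bins."""
    kept = [e for e in estimates if e.ks is not None and e.ks < max_ks]
    ratios = [e.ratio for e in kept if e.ratio is not None]
    bins = {
        "0.0-0.1": sum(1 for x in ratios if x < 0.1),
        "0.1-0.2": sum(1 for x in ratios if 0.1 <= x < 0.2),
        "0.2-0.3": sum(1 for x in ratios if 0.2 <= x < 0.3),
    }
    return {
        "kept": kept,
        "n_kept": len(kept),
        "n_ratio_gt1": sum(1 for x in ratios if x > 1.0),
        "ratio_bins": bins,
    }


# ---------------------------------------------------------------------------
# sequence mutation toward a target Ks (generator support)

def _syn_neighbours(codon: str) -> list[tuple[int, str]]:
    aa = _CODON_TO_AA[codon]
    out = []
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt not in STOP_CODONS and _CODON_TO_AA[alt] == aa:
                out.append((pos, b))
    return out


def _nonsyn_neighbours(codon: str) -> list[tuple[int, str]]:
    aa = _CODON_TO_AA[codon]
    out = []
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt not in STOP_CODONS and _CODON_TO_AA[alt] != aa:
                out.append((pos, b))
    return out


def mutate_to_ks(
    cds: str,
    target_ks: float,
    rng: np.random.Generator | int | None = None,
    ka_ks: float = 0.0,
) -> str:
    """Mutate a CDS so that NG86 Ks(input, output) ~= ``target_ks``.

    Substitutions are single-base codon-aware changes restricted to
    synonymous moves (matching the NG86 counting assumptions, so recovery
    is unbiased); with ``ka_ks`` > 0, nonsynonymous moves are added until
    Ka reaches ka_ks * target_ks.  The measured Ks is re-evaluated after
    every accepted move and mutation stops at the first value >= target.
    """
    if target_ks < 0:
        raise ValueError("target_Ks must be >= 0")
    ps_needed = 0.75 * (1 - math.exp(-4 * target_ks / 3))
    if ps_needed >= 0.749:
        raise SaturationError(
            f"target Ks {target_ks} implies ps {ps_needed:.3f}, beyond the "
            "Jukes-Cantor saturation limit (ps >= 0.749)"
        )
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if target_ks == 0 and ka_ks == 0:
        return cds
    has_stop = cds[-3:] in STOP_CODONS
    body = cds[:-3] if has_stop else cds
    codons = [body[i:i + 3] for i in range(0, len(body), 3)]
    original_pairs_ref = codons[:]

    def measured() -> DivergenceEstimate:
        return estimate_ka_ks(list(zip(original_pairs_ref, codons)))

    max_steps = 40 * len(codons)
    for phase, want in (("syn", target_ks), ("nonsyn", ka_ks * target_ks)):
        if want <= 0:
            continue
        steps = 0
        while steps < max_steps:
            est = measured()
            value = est.ks if phase == "syn" else est.ka
            if value is None:
                raise SaturationError("mutation drove divergence to saturation")
            if value >= want:
                break
            idx = int(rng.integers(len(codons)))
            nbrs = (_syn_neighbours(codons[idx]) if phase == "syn"
                    else _nonsyn_neighbours(codons[idx]))
            steps += 1
            if not nbrs:
                continue
            pos, b = nbrs[int(rng.integers(len(nbrs)))]
            codons[idx] = codons[idx][:pos] + b + codons[idx][pos + 1:]
        else:
            raise SaturationError(
                f"could not reach target ({phase}) within {max_steps} moves"
            )
    out = "".join(codons)
    return out + cds[-3:] if has_stop else out


# ---------------------------------------------------------------------------
# EST-cluster duplication analysis

@dataclass(frozen=True)
class DuplicationCluster:
    fl_cdna_id: str
    member_est_ids: tuple[str, ...]
    n_polymorphic_sites: int
    haplotype_count: int
    ks: float | None  # only for 2-haplotype clusters
    t_years: float | None
    excluded_reason: str | None = None


def _assign_ests(
    fl_cdnas: Sequence[TranscriptRecord],
    ests: Sequence[TranscriptRecord],
    seed_k: int = 14,
) -> dict[str, list[int]]:
    """Best-scoring ungapped assignment of each EST to one FL-cDNA."""
    from collections import defaultdict

    index: dict[str, list[int]] = defaultdict(list)
    for fi, fl in enumerate(fl_cdnas):
        for i in range(len(fl.seq) - seed_k + 1):
            index[fl.seq[i:i + seed_k]].append(fi)
    groups: dict[str, list[int]] = {fl.id: [] for fl in fl_cdnas}
    for ei, est in enumerate(ests):
        cand = set()
        for i in range(len(est.seq) - seed_k + 1):
            cand.update(index.get(est.seq[i:i + seed_k], ()))
        best_fi, best_score = None, 0.0
        for fi in sorted(cand):
            diags = ac.shared_diagonals(est.seq, fl_cdnas[fi].seq, k=seed_k)
            seg = ac._best_ungapped(est.seq, fl_cdnas[fi].seq,
                                    ac.DEFAULT_SCORING, diags)
            if seg is not None and seg[0] > best_score:
                best_fi, best_score = fi, seg[0]
        if best_fi is not None:
            groups[fl_cdnas[best_fi].id].append(ei)
    return groups


def duplication_analysis(
    fl_cdnas: Sequence[TranscriptRecord],
    annotations: Mapping[str, ORFAnnotation],
    ests: Sequence[TranscriptRecord],
    r: float = GRASS_SYNONYMOUS_RATE,
    min_cluster: int = 6,
    min_support: int = 2,
    bin_width_my: float = 5.0,
    max_my: float = 50.0,
) -> tuple[list[DuplicationCluster], pd.DataFrame]:
    """Date within-cluster haplotype divergence from redundant ESTs.

    Returns the per-cluster records (excluded clusters carry a reason) and
    a histogram of T in ``bin_width_my``-My bins over [0, ``max_my``).
    """
    groups = _assign_ests(fl_cdnas, ests)
    by_id = {f.id: f for f in fl_cdnas}
    clusters: list[DuplicationCluster] = []
    times: list[float] = []
    for fl_id, est_idx in groups.items():
        if len(est_idx) < min_cluster:
            continue
        members = [ests[i] for i in est_idx]
        ref = by_id[fl_id].seq
        ann = annotations.get(fl_id)
        cluster = _analyse_cluster(fl_id, ref, ann, members, r,
                                   min_support)
        clusters.append(cluster)
        if cluster.t_years is not None:
            times.append(cluster.t_years / 1e6)
    edges = np.arange(0, max_my + bin_width_my, bin_width_my)
    counts, _ = np.histogram(times, bins=edges)
    hist = pd.DataFrame({"bin_start_my": edges[:-1], "count": counts})
    return clusters, hist


def _analyse_cluster(
    fl_id: str,
    ref: str,
    ann: ORFAnnotation | None,
    members: Sequence[TranscriptRecord],
    r: float,
    min_support: int,
) -> DuplicationCluster:
    ids = tuple(m.id for m in members)
    if ann is None:
        return DuplicationCluster(fl_id, ids, 0, 0, None, None,
                                  "no ORF annotation on reference")
    # reference-anchored stacking via best ungapped placement
    placements: list[tuple[int, str]] = []  # (ref offset, read seq)
    for m in members:
        diags = ac.shared_diagonals(m.seq, ref, k=12)
        seg = ac._best_ungapped(m.seq, ref, ac.DEFAULT_SCORING, diags)
        if seg is None:
            continue
        _, qs, qe, ss, _, _ = seg
        placements.append((ss - qs, m.seq))
    if len(placements) < len(members):
        ids = tuple(ids)  # unplaced reads silently dropped from the stack
    n = len(ref)
    # allele matrix: rows reads, cols reference positions, "." = no cover
    rows = []
    for off, seq in placements:
        row = ["."] * n
        for i, base in enumerate(seq):
            pos = off + i
            if 0 <= pos < n:
                row[pos] = base
        rows.append(row)
    arr = np.array(rows) if rows else np.empty((0, n), dtype="<U1")
    retained_cols: list[int] = []
    for col in range(n):
        column = arr[:, col] if len(arr) else np.array([])
        bases, counts = np.unique(column[column != "."], return_counts=True)
        if len(bases) >= 2 and np.sort(counts)[-2] >= min_support:
            # keep only alleles supported by >= min_support reads
            supported = bases[counts >= min_support]
            if len(supported) >= 2:
                retained_cols.append(col)
    orf_s, orf_e = ann.orf_interval
    covered = np.zeros(n, dtype=bool)
    for off, seq in placements:
        lo, hi = max(0, off), min(n, off + len(seq))
        covered[lo:hi] = True
    if not covered[orf_s:orf_e].all():
        return DuplicationCluster(fl_id, ids, len(retained_cols), 0, None,
                                  None, "coding region not covered")
    # haplotype grouping over retained polymorphic columns.  Reads are
    # joined by single linkage on Hamming distance across the retained
    # columns (distance < half the column count): haplotypes differ at
    # most retained sites, while residual shared sequencing errors that
    # survived the >=2-support rule perturb only a few.
    if not retained_cols:
        return DuplicationCluster(fl_id, ids, 0, 1, None, None, None)
    vectors: list[tuple[int, tuple[str, ...]]] = []
    for ri in range(len(placements)):
        alleles = tuple(arr[ri, c] for c in retained_cols)
        if "." in alleles:
            continue  # read does not cover all retained sites
        vectors.append((ri, alleles))
    threshold = max(1, (len(retained_cols) + 1) // 2)
    parent = list(range(len(vectors)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(vectors)):
        for j in range(i + 1, len(vectors)):
            d = sum(a != b for a, b in zip(vectors[i][1], vectors[j][1]))
            if d < threshold:
                parent[max(find(i), find(j))] = min(find(i), find(j))
    groups: dict[int, list[int]] = {}
    for i, (ri, _) in enumerate(vectors):
        groups.setdefault(find(i), []).append(ri)
    # drop haplotypes below the support threshold (sequencing-error reads)
    haplo_reads = {root: rs for root, rs in groups.items()
                   if len(rs) >= min_support}
    k = len(haplo_reads)
    if k != 2:
        return DuplicationCluster(fl_id, ids, len(retained_cols), k, None,
                                  None, None if k else "no complete reads")
    consensi = []
    for rs in haplo_reads.values():
        cons = list(ref)
        for col in range(orf_s, orf_e):
            column = arr[rs, col]
            column = column[column != "."]
            if len(column):
                bases, counts = np.unique(column, return_counts=True)
                cons[col] = bases[np.argmax(counts)]
        consensi.append("".join(cons))
    cds_pair = [c[orf_s:orf_e] for c in consensi]
    try:
        est = kaks_pair(cds_pair[0], cds_pair[1], fl_id + "/h1", fl_id + "/h2")
    except ValueError as exc:
        return DuplicationCluster(fl_id, ids, len(retained_cols), 2, None,
                                  None, f"Ks estimation failed: {exc}")
    t = date_divergence(est.ks, r)
    return DuplicationCluster(fl_id, ids, len(retained_cols), 2, est.ks, t)
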