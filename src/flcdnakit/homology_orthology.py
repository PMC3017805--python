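"""Cross-species homolog recognition and one-to-one ortholog selection.

Homolog thresholds:

* nucleotide level — local alignment identity > 75% covering > 50% of the
  query FL-cDNA;
* protein level — the query's annotated ORF translation aligned to the
  subject's (re-)predicted peptide at > 60% identity over >= 50 aligned
  amino acids.

Ortholog picking mirrors a stringent reciprocal-best procedure: take the
three best-scoring subjects, re-predict each subject's ORF, align the
predicted peptides to the query peptide, keep the single highest-identity
subject, and accept it only if the reciprocal search from that subject
returns the query.  Ties at any step yield no call (conservative).
E-value ranking is replaced throughout by alignment-score ranking, which
is deterministic and independent of database size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from . import alignment_core as ac
from .orf_composition import ORFAnnotation, annotate_orfs, find_longest_orf, translate_cds
from .sequence_io import TranscriptRecord

logger = logging.getLogger(__name__)

NT_MIN_IDENTITY = 0.75
NT_MIN_COVERAGE = 0.5
AA_MIN_IDENTITY = 0.60
AA_MIN_LENGTH = 50


@dataclass(frozen=True)
class HomologHit:
    query_id: str
    subject_id: str
    subject_species: str
    level: str  # "nucleotide" | "protein"
    identity: float
    coverage_of_query: float
    score: float


def _protein_local(a: str, b: str) -> ac.PairwiseAlignment | None:
    """Local peptide alignment with a flat +1/−1 scheme; the identity
    thresholds here operate far above the twilight zone where a scoring
    matrix would matter."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    try:
        aln = aligner.align(a, b)[0]
    except (IndexError, ValueError):
        return None
    qa, sa = aln.aligned
    if len(qa) == 0:
        return None
    ops, matches, mismatches, gaps = ac._ops_from_alignment(aln, a, b)
    return ac.PairwiseAlignment(
        query_id="q", subject_id="s",
        query_interval=(int(qa[0][0]), int(qa[-1][1])),
        subject_interval=(int(sa[0][0]), int(sa[-1][1])),
        orientation="forward", columns=len(ops), matches=matches,
        mismatches=mismatches, gap_columns=gaps,
        score=float(aln.score), ops=ops,
    )


def find_homologs(
    queries: Sequence[TranscriptRecord],
    subject_db: Sequence[TranscriptRecord],
    species: str,
    level: str = "nucleotide",
    annotations: Mapping[str, ORFAnnotation] | None = None,
    seed_k: int = 11,
) -> list[HomologHit]:
    """All subjects passing the level-specific homology threshold, per
    query, ranked by alignment score (descending)."""
    if level not in ("nucleotide", "protein"):
        raise ValueError(f"unknown level {level!r}")
    hits: list[HomologHit] = []
    if level == "protein" and annotations is None:
        annotations = annotate_orfs(queries)
    subject_peptides: dict[str, str] = {}
    if level == "protein":
        for s in subject_db:
            ann = find_longest_orf(s.seq, s.id)
            if ann is not None:
                lo, hi = ann.orf_interval
                subject_peptides[s.id] = translate_cds(s.seq[lo:hi])
    all_seqs = [q.seq for q in queries] + [s.seq for s in subject_db]
    nq = len(queries)
    cand = ac.kmer_candidate_pairs(all_seqs, k=seed_k)
    adj: dict[int, set[int]] = {}
    for i, j in cand:
        if i < nq <= j:
            adj.setdefault(i, set()).add(j - nq)
    for qi, q in enumerate(queries):
        for sj in sorted(adj.get(qi, ())):
            s = subject_db[sj]
            if level == "nucleotide":
                aln = ac.align(q.seq, s.seq, mode="local", strand="forward",
                               query_id=q.id, subject_id=s.id)
                if aln is None:
                    continue
                coverage = aln.query_coverage_length / len(q.seq)
                if aln.identity > NT_MIN_IDENTITY and coverage > NT_MIN_COVERAGE:
                    hits.append(HomologHit(q.id, s.id, species, level,
                                           aln.identity, coverage, aln.score))
            else:
                ann = annotations.get(q.id) if annotations else None
                if ann is None:
                    logger.info("find_homologs: query %s lacks an ORF; "
                                "skipped at protein level", q.id)
                    continue
                lo, hi = ann.orf_interval
                pep_q = translate_cds(q.seq[lo:hi])
                pep_s = subject_peptides.get(s.id)
                if not pep_q or not pep_s:
                    continue
                aln = _protein_local(pep_q, pep_s)
                if aln is None or aln.columns < AA_MIN_LENGTH:
                    continue
                if aln.identity > AA_MIN_IDENTITY:
                    coverage = aln.query_coverage_length / len(pep_q)
                    hits.append(HomologHit(q.id, s.id, species, level,
                                           aln.identity, coverage, aln.score))
    hits.sort(key=lambda h: (h.query_id, -h.score, h.subject_id))
    return hits


def _best_protein_partner(
    query: TranscriptRecord,
    target_db: Sequence[TranscriptRecord],
    species: str,
    top_n: int = 3,
) -> str | None:
    """One direction of the ortholog search: top-``top_n`` subjects by
    nucleotide alignment score, peptides re-predicted and aligned, unique
    best identity returned (None on tie or no hit)."""
    hits = find_homologs([query], target_db, species, level="nucleotide")
    top = hits[:top_n]
    if not top:
        return None
    q_ann = find_longest_orf(query.seq, query.id)
    if q_ann is None:
        return None
    lo, hi = q_ann.orf_interval
    pep_q = translate_cds(query.seq[lo:hi])
    by_id = {s.id: s for s in target_db}
    scored: list[tuple[float, str]] = []
    for hit in top:
        subj = by_id[hit.subject_id]
        s_ann = find_longest_orf(subj.seq, subj.id)  # re-predict the ORF
        if s_ann is None:
            continue
        slo, shi = s_ann.orf_interval
        pep_s = translate_cds(subj.seq[slo:shi])
        if not pep_s:
            continue
        aln = _protein_local(pep_q, pep_s)
        if aln is None or aln.columns == 0:
            continue
        scored.append((aln.identity, subj.id))
    if not scored:
        return None
    scored.sort(key=lambda t: (-t[0], t[1]))
    if len(scored) > 1 and scored[0][0] == scored[1][0]:
        logger.info("ortholog pick for %s: identity tie, no call", query.id)
        return None
    return scored[0][1]


def pick_ortholog(
    query: TranscriptRecord,
    species_db: Sequence[TranscriptRecord],
    species: str,
    query_species_db: Sequence[TranscriptRecord] | None = None,
    top_n: int = 3,
) -> str | None:
    """One-to-one ortholog of ``query`` in ``species_db``, or None.

    When ``query_species_db`` is given the reciprocal search is enforced:
    the candidate's own best partner in the query's species must be the
    query itself.
    """
    candidate = _best_protein_partner(query, species_db, species, top_n)
    if candidate is None:
        return None
    if query_species_db is not None:
        by_id = {s.id: s for s in species_db}
        back = _best_protein_partner(by_id[candidate], query_species_db,
                                     "query-species", top_n)
        if back != query.id:
            logger.info("ortholog pick %s->%s: reciprocal search returned "
                        "%s, no call", query.id, candidate, back)
            return None
    return candidate


def ortholog_groups(
    queries: Sequence[TranscriptRecord],
    species_dbs: Mapping[str, Sequence[TranscriptRecord]],
    query_species: str = "query",
) -> pd.DataFrame:
    """One row per query with a one-to-one ortholog in *every* species."""
    rows = []
    for q in queries:
        row = {query_species: q.id}
        complete = True
        for species, db in species_dbs.items():
            partner = pick_ortholog(q, db, species, query_species_db=queries)
            if partner is None:
                complete = False
                break
            row[species] = partner
        if complete:
            rows.append(row)
    return pd.DataFrame(rows, columns=[query_species, *species_dbs])


def partition_shared_unique(
    queries: Sequence[TranscriptRecord],
    anchor_db: Sequence[TranscriptRecord],
    other_dbs: Mapping[str, Sequence[TranscriptRecord]],
    anchor_species: str = "rice",
) -> dict[str, object]:
    """Four-way partition of the query set by homology pattern.

    Categories: hit in the anchor species AND in all others; anchor only
    (not all others); no anchor hit but hits in all others; no anchor hit
    and not all others (includes query-unique genes).  Exhaustive and
    mutually exclusive by construction.
    """
    anchor_hits = {h.query_id for h in
                   find_homologs(queries, anchor_db, anchor_species)}
    others_hit: dict[str, set[str]] = {}
    for species, db in other_dbs.items():
        others_hit[species] = {h.query_id for h in
                               find_homologs(queries, db, species)}
    all_others = (set.intersection(*others_hit.values())
                  if others_hit else set())
    counts = {"anchor_and_all_others": 0, "anchor_not_all_others": 0,
              "no_anchor_all_others": 0, "no_anchor_not_all_others": 0}
    assignment: dict[str, str] = {}
    for q in queries:
        in_anchor = q.id in anchor_hits
        in_all = q.id in all_others
        if in_anchor and in_all:
            cat = "anchor_and_all_others"
        elif in_anchor:
            cat = "anchor_not_all_others"
        elif in_all:
            cat = "no_anchor_all_others"
        else:
            cat = "no_anchor_not_all_others"
        counts[cat] += 1
        assignment[q.id] = cat
    n = len(queries)
    fractions = {k: v / n if n else 0.0 for k, v in counts.items()}
    return {"counts": counts, "fractions": fractions,
            "assignment": assignment}


def hits_to_frame(hits: Sequence[HomologHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "query_id": h.query_id, "subject_id": h.subject_id,
            "species": h.subject_species, "level": h.level,
            "identity": h.identity, "coverage_of_query": h.coverage_of_query,
            "score": h.score,
        } for h in hits]
    )
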