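import numpy as np
import pytest

from flcdnakit.clustering import Cluster, cluster_ests
from flcdnakit.sequence_io import TranscriptRecord
from flcdnakit.splice_variants import (
    candidate_as_pairs,
    classify_all,
    classify_as_event,
    intron_size_summary,
)
from flcdnakit.synthetic_data import SimulationConfig, simulate_transcriptome

from conftest import random_dna


def _pair_records(a, b):
    return [TranscriptRecord("A", a), TranscriptRecord("B", b)]


def _candidates(a, b):
    recs = _pair_records(a, b)
    clusters = [Cluster("cl0", ("A", "B"))]
    return candidate_as_pairs(clusters, recs), recs


def _clean(rng, n):
    # plain random DNA is fine for flanks here; no SSR scrubbing needed
    return random_dna(rng, n)


def test_identical_pair_not_candidate(rng):
    s = _clean(rng, 600)
    pairs, _ = _candidates(s, s)
    assert pairs == []


def test_retained_intron_classified(rng):
    base = _clean(rng, 800)
    intron = "GT" + _clean(rng, 214) + "AG"
    iso = base[:400] + intron + base[400:]
    pairs, recs = _candidates(base, iso)
    assert len(pairs) == 1
    events = classify_as_event(pairs[0], recs)
    assert len(events) == 1
    ev = events[0]
    assert ev.as_type == "IntronR"
    assert ev.boundary == "GT-AG"
    assert ev.inferred_intron_length == 218
    # the reported block is literally GT..AG in the carrier sequence
    s, e = ev.block_interval
    assert iso[s:s + 2] == "GT" and iso[e - 2:e] == "AG"


def test_gc_ag_minor_class(rng):
    base = _clean(rng, 800)
    intron = "GC" + _clean(rng, 100) + "AG"
    if intron[2:4] == "T" or intron[:2] == "GT":
        intron = "GC" + "CC" + intron[4:]
    iso = base[:400] + intron + base[400:]
    pairs, recs = _candidates(base, iso)
    events = classify_as_event(pairs[0], recs)
    kinds = {(e.as_type, e.boundary) for e in events}
    assert ("IntronR", "GC-AG") in kinds or ("IntronR", "GT-AG") in kinds


def test_non_splice_block_not_intronr(rng):
    """A retained CA..AG block violates the GT-AG rule."""
    base = _clean(rng, 800)
    block = "CA" + _clean(rng, 100) + "CT"
    # ensure no GT/GC start or AG end can appear at any register
    iso = base[:400] + block + base[400:]
    pairs, recs = _candidates(base, iso)
    if pairs:
        events = classify_as_event(pairs[0], recs)
        assert all(e.as_type != "IntronR" for e in events)


def test_flank_identity_threshold(rng):
    """98% flank identity fails the >99% rule: not a candidate."""
    base = _clean(rng, 600)
    intron = "GT" + _clean(rng, 100) + "AG"
    iso = list(base[:300] + intron + base[300:])
    noisy = list(base)
    for p in rng.choice(np.arange(20, 280), size=9, replace=False):
        noisy[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[noisy[p]]
    pairs, _ = _candidates("".join(noisy), "".join(iso))
    assert pairs == []


def test_orientation_invariance(rng):
    base = _clean(rng, 700)
    intron = "GT" + _clean(rng, 150) + "AG"
    iso = base[:350] + intron + base[350:]
    p1, r1 = _candidates(base, iso)
    p2, r2 = _candidates(iso, base)
    e1 = classify_as_event(p1[0], r1)
    e2 = classify_as_event(p2[0], r2)
    assert {e.as_type for e in e1} == {e.as_type for e in e2}
    assert e1[0].block_carrier == "B" and e2[0].block_carrier == "A"


def test_intron_size_summary():
    from flcdnakit.splice_variants import ASEvent

    def ev(L):
        return ASEvent("a", "b", "IntronR", "GT-AG", "b", (0, L), L)

    assert intron_size_summary([ev(218)])["mean"] == 218
    s = intron_size_summary([ev(100), ev(300)])
    assert s["mean"] == 200 and s["median"] == 200
    with pytest.raises(ValueError):
        intron_size_summary([])


@pytest.mark.parametrize("seed", [1, 2])
def test_synthetic_closure_per_type(seed):
    """On clean synthetic isoform pairs every planted event is recovered
    with its planted type and nothing spurious is emitted."""
    cfg = SimulationConfig(n_genes=40, seed=seed, as_fraction=1.0,
                           nat_fraction=0.0, ssr_probability=0.0)
    sim = simulate_transcriptome(cfg)
    recs = list(sim.transcripts)
    clusters = cluster_ests(recs)
    pairs = candidate_as_pairs(clusters, recs)
    events = classify_all(pairs, recs)
    truth = sim.truth[sim.truth.event_type == "AS"]
    detected = {}
    for e in events:
        detected.setdefault(
            tuple(sorted([e.transcript_a, e.transcript_b])), []
        ).append(e.as_type)
    # recall: every planted pair found with the planted type
    for _, row in truth.iterrows():
        key = tuple(sorted([row.id_a, row.id_b]))
        assert key in detected, f"missed {key} ({row.subtype})"
        assert row.subtype in detected[key]
    # precision: one event per pair, no extra pairs
    assert len(events) == len(truth)


def test_recovered_intron_mean_close_to_target():
    cfg = SimulationConfig(
        n_genes=40, seed=9, as_fraction=1.0, nat_fraction=0.0,
        ssr_probability=0.0,
        as_type_probabilities={"IntronR": 1.0, "AltP": 0, "ExonO": 0,
                               "ExonS": 0, "AltA": 0, "AltD": 0})
    sim = simulate_transcriptome(cfg)
    recs = list(sim.transcripts)
    pairs = candidate_as_pairs(cluster_ests(recs), recs)
    events = classify_all(pairs, recs)
    summary = intron_size_summary(events)
    assert abs(summary["mean"] - 218) / 218 < 0.10
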