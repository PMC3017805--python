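import numpy as np
import pytest

from flcdnakit.orf_composition import annotate_orfs
from flcdnakit.splice_variants import _block_status
from flcdnakit.synthetic_data import (
    SimulationConfig,
    simulate_ests,
    simulate_ests_fixed_depth,
    simulate_transcriptome,
)


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(n_genes=0)
    with pytest.raises(ValueError, match="sum to 1"):
        SimulationConfig(as_type_probabilities={"IntronR": 0.5})
    with pytest.raises(ValueError):
        SimulationConfig(gc3_target=1.5)
    with pytest.raises(ValueError, match="accommodate"):
        SimulationConfig(min_transcript_length=200)


def test_seed_determinism_byte_identical():
    cfg = SimulationConfig(n_genes=20, seed=1, as_fraction=0.3,
                           nat_fraction=0.1, ssr_probability=0.3)
    a = simulate_transcriptome(cfg)
    b = simulate_transcriptome(cfg)
    assert [(t.id, t.seq) for t in a.transcripts] == \
        [(t.id, t.seq) for t in b.transcripts]
    assert a.truth.equals(b.truth)
    ra = simulate_ests(list(a.transcripts), cfg)
    rb = simulate_ests(list(b.transcripts), cfg)
    assert [(r.id, r.seq) for r in ra] == [(r.id, r.seq) for r in rb]


def test_forced_intronr_pair_obeys_gt_ag():
    cfg = SimulationConfig(
        n_genes=1, seed=7, as_fraction=1.0, gc_ag_fraction=0.0,
        as_type_probabilities={"IntronR": 1.0, "AltP": 0, "ExonO": 0,
                               "ExonS": 0, "AltA": 0, "AltD": 0})
    sim = simulate_transcriptome(cfg)
    assert len(sim.transcripts) == 2
    truth = sim.truth[sim.truth.event_type == "AS"].iloc[0]
    assert truth.subtype == "IntronR"
    iso = [t for t in sim.transcripts if t.id == truth.id_b][0]
    retained = iso.seq[truth.start:truth.end]
    assert retained.startswith("GT") and retained.endswith("AG")


def test_every_intron_obeys_boundary_invariant():
    cfg = SimulationConfig(n_genes=60, seed=3, as_fraction=1.0,
                           nat_fraction=0.0, ssr_probability=0.0)
    sim = simulate_transcriptome(cfg)
    for gene in sim.genes:
        prev_end = None
        for s, e in gene.exons:
            if prev_end is not None:
                intron = gene.scaffold[prev_end:s]
                assert intron[:2] in ("GT", "GC")
                assert intron.endswith("AG")
            prev_end = e
    # every planted GT-AG/GC-AG block classifies as an intron
    by_id = {t.id: t for t in sim.transcripts}
    for _, row in sim.truth.iterrows():
        if row.subtype in ("IntronR", "AltP"):
            carrier = by_id[row.id_b if row.subtype != "AltP" else row.id_b]
            status, _ = _block_status(carrier.seq, row.start,
                                      row.end - row.start)
            assert status in ("GT-AG", "GC-AG")


def test_truth_table_completeness():
    """Every derived transcript corresponds to exactly one truth row."""
    cfg = SimulationConfig(n_genes=50, seed=5, as_fraction=0.4,
                           nat_fraction=0.2, duplication_fraction=0.2,
                           ssr_probability=0.5)
    sim = simulate_transcriptome(cfg)
    derived = {t.id for t in sim.transcripts
               if t.id not in set(sim.primary_ids)}
    referenced = set(sim.truth.id_b) - {""}
    assert derived == referenced
    assert not sim.truth.duplicated(subset=["id_a", "id_b", "start"]).any()


def test_gc3_target_recovered():
    cfg = SimulationConfig(n_genes=150, seed=3, as_fraction=0.0,
                           nat_fraction=0.0, ssr_probability=0.0)
    sim = simulate_transcriptome(cfg)
    gc3 = []
    for t in sim.transcripts:
        s, e = sim.orf_truth[t.id]
        third = t.seq[s + 2:e:3]
        gc3.append((third.count("G") + third.count("C")) / len(third))
    assert abs(np.mean(gc3) - 0.692) < 0.02


def test_mean_length_near_target():
    cfg = SimulationConfig(n_genes=150, seed=8, as_fraction=0.0,
                           nat_fraction=0.0, ssr_probability=0.0)
    sim = simulate_transcriptome(cfg)
    lengths = [len(t.seq) for t in sim.transcripts]
    assert abs(np.mean(lengths) - cfg.mean_transcript_length) < 60


def test_error_free_reads_are_substrings():
    cfg = SimulationConfig(n_genes=5, seed=2, est_error_rate=0.0,
                           as_fraction=0, nat_fraction=0, ssr_probability=0)
    sim = simulate_transcriptome(cfg)
    by_id = {t.id: t for t in sim.transcripts}
    reads = simulate_ests(list(sim.transcripts), cfg)
    for r in reads:
        src = by_id[r.source_hint]
        assert r.seq in src.seq
        assert src.seq.index(r.seq) <= 40  # 5'-anchored


def test_fixed_depth_law():
    cfg = SimulationConfig(n_genes=5, seed=2, as_fraction=0,
                           nat_fraction=0, ssr_probability=0)
    sim = simulate_transcriptome(cfg)
    reads = simulate_ests_fixed_depth(list(sim.transcripts), 6, cfg)
    from collections import Counter
    per_source = Counter(r.source_hint for r in reads)
    assert set(per_source.values()) == {6}


def test_depth_mean_near_target():
    cfg = SimulationConfig(n_genes=300, seed=11, as_fraction=0,
                           nat_fraction=0, ssr_probability=0,
                           min_transcript_length=550,
                           mean_transcript_length=700,
                           sd_transcript_length=50)
    sim = simulate_transcriptome(cfg)
    reads = simulate_ests(list(sim.transcripts), cfg)
    from collections import Counter
    sizes = list(Counter(r.source_hint for r in reads).values())
    assert abs(np.mean(sizes) - cfg.est_depth_mean) <= 1.0


def test_read_length_bounds():
    cfg = SimulationConfig(n_genes=10, seed=6, as_fraction=0,
                           nat_fraction=0, ssr_probability=0)
    sim = simulate_transcriptome(cfg)
    by_id = {t.id: t for t in sim.transcripts}
    for r in simulate_ests(list(sim.transcripts), cfg):
        assert cfg.est_min_length <= len(r.seq) <= len(by_id[r.source_hint].seq)


def test_primary_orf_truth_matches_annotation():
    cfg = SimulationConfig(n_genes=30, seed=9, as_fraction=0.0,
                           nat_fraction=0.0, ssr_probability=0.5)
    sim = simulate_transcriptome(cfg)
    anns = annotate_orfs(list(sim.transcripts))
    for tid, iv in sim.orf_truth.items():
        assert anns[tid].orf_interval == iv
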