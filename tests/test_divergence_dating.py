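import numpy as np
import pytest

from flcdnakit.divergence_dating import (
    GRASS_SYNONYMOUS_RATE,
    SaturationError,
    codon_align,
    date_divergence,
    duplication_analysis,
    estimate_ka_ks,
    jukes_cantor,
    kaks_pair,
    ks_window_filter,
    mutate_to_ks,
)
from flcdnakit.orf_composition import find_longest_orf
from flcdnakit.sequence_io import TranscriptRecord
from flcdnakit.synthetic_data import (
    SimulationConfig,
    _random_orf,
    simulate_duplication_clusters,
)

from _oracles import ng86, nw_peptide_score


def _codons(cds):
    return [cds[i:i + 3] for i in range(0, len(cds), 3)]


def _pad(pairs, n=12):
    """Pad a short codon-pair list with identical GGG codons to reach the
    minimum comparable-codon count without adding differences or
    synonymous-site-free codons that would change the hand count."""
    return pairs + [("GGG", "GGG")] * (n - len(pairs))


def test_identical_sequences_zero_divergence():
    pairs = [(c, c) for c in _codons("ATGAAACCCTTTGGGCTGCGTACGATCGAG")]
    est = estimate_ka_ks(pairs)
    assert est.Sd == est.Nd == 0
    assert est.ks == 0 and est.ka == 0


def test_hand_counted_single_synonymous_difference():
    """ATG AAA CCC TTT vs ATG AAG CCC TTT: S = 5/3, Sd = 1, Nd = 0."""
    pairs = list(zip(_codons("ATGAAACCCTTT"), _codons("ATGAAGCCCTTT")))
    # hand count on the raw 4 codons (below the estimator's minimum, so
    # check the counting through the padded form: GGG adds 1 syn site)
    est = estimate_ka_ks(_pad(pairs))
    assert est.Sd == 1 and est.Nd == 0
    assert est.S == pytest.approx(5 / 3 + 8 * 1.0)  # GGG has 1 syn site
    assert est.ka == 0
    assert est.ps == pytest.approx(1 / (5 / 3 + 8))


def test_hand_counted_nonsynonymous_difference():
    # AAA (Lys) -> GAA (Glu): one nonsynonymous difference
    pairs = _pad(list(zip(_codons("ATGAAA"), _codons("ATGGAA"))))
    est = estimate_ka_ks(pairs)
    assert est.Sd == 0 and est.Nd == 1


def test_two_hit_codon_pathway_average():
    # TTT (Phe) vs TTA+GTT? use TTT vs GTA: differs at pos 1 and 3
    # pathways: TTT->GTT(Val,N)->GTA(Val,S)  and  TTT->TTA(Leu,N)->GTA(Val,N)
    # average: Sd = 0.5, Nd = 1.5
    pairs = _pad(list(zip(_codons("ATGTTT"), _codons("ATGGTA"))))
    est = estimate_ka_ks(pairs)
    assert est.Sd == pytest.approx(0.5)
    assert est.Nd == pytest.approx(1.5)


@pytest.mark.parametrize("seed", range(5))
def test_estimator_matches_independent_oracle(seed):
    rng = np.random.default_rng(seed)
    cds = _random_orf(rng, 40, 0.6)
    other = mutate_to_ks(cds, 0.25, rng, ka_ks=0.4)
    pairs = list(zip(_codons(cds[:-3]), _codons(other[:-3])))
    est = estimate_ka_ks(pairs)
    oracle = ng86(pairs)
    assert est.S == pytest.approx(oracle["S"])
    assert est.Sd == pytest.approx(oracle["Sd"])
    assert est.Nd == pytest.approx(oracle["Nd"])
    assert est.ks == pytest.approx(oracle["ks"])
    assert est.ka == pytest.approx(oracle["ka"])


def test_estimator_matches_biopython_ng86():
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

    rng = np.random.default_rng(99)
    cds = _random_orf(rng, 80, 0.65)
    other = mutate_to_ks(cds, 0.3, rng, ka_ks=0.2)
    pairs = list(zip(_codons(cds[:-3]), _codons(other[:-3])))
    est = estimate_ka_ks(pairs)
    dn, ds = cal_dn_ds(CodonSeq(cds[:-3]), CodonSeq(other[:-3]),
                       method="NG86")
    assert est.ka == pytest.approx(dn, abs=1e-9)
    assert est.ks == pytest.approx(ds, abs=1e-9)


def test_symmetry(rng):
    cds = _random_orf(rng, 50, 0.6)
    other = mutate_to_ks(cds, 0.2, np.random.default_rng(1), ka_ks=0.3)
    ab = kaks_pair(cds, other)
    ba = kaks_pair(other, cds)
    assert ab.ks == pytest.approx(ba.ks)
    assert ab.ka == pytest.approx(ba.ka)


def test_codon_align_gap_excluded(rng):
    cds = _random_orf(rng, 40, 0.6)
    # delete one interior full codon from the second sequence
    other = cds[:30] + cds[33:]
    pairs = codon_align(cds, other)
    assert len(pairs) == 41 - 1  # ATG + 40 codons, stop stripped, one gap


def test_codon_align_rejects_internal_stop():
    with pytest.raises(ValueError, match="internal stop"):
        codon_align("ATGTAAAAATAG", "ATGAAAAAATAG")


def test_codon_align_matches_global_peptide_oracle(rng):
    for _ in range(8):
        n = int(rng.integers(12, 30))
        a = _random_orf(rng, n, 0.5)
        b = mutate_to_ks(a, 0.1, rng, ka_ks=0.5)
        if rng.random() < 0.5:  # add an indel of one codon
            cut = 3 * int(rng.integers(2, n - 2))
            b = b[:cut] + b[cut + 3:]
        from flcdnakit.divergence_dating import _peptide_aligner
        from flcdnakit.orf_composition import translate_cds

        pa, pb = translate_cds(a), translate_cds(b)
        got = _peptide_aligner().align(pa, pb)[0].score
        assert got == pytest.approx(nw_peptide_score(pa, pb))


def test_jukes_cantor_values():
    assert jukes_cantor(0.0) == 0.0
    assert jukes_cantor(0.10) == pytest.approx(0.10732, abs=1e-5)
    assert jukes_cantor(0.75) is None


def test_mutate_to_ks_zero_is_identity(rng):
    cds = _random_orf(rng, 40, 0.6)
    assert mutate_to_ks(cds, 0.0, rng) == cds


def test_mutate_to_ks_saturation_rejected(rng):
    cds = _random_orf(rng, 40, 0.6)
    with pytest.raises(SaturationError):
        mutate_to_ks(cds, 5.0, rng)


@pytest.mark.parametrize("target", [0.1, 0.3])
def test_mutate_to_ks_recovery(target):
    cds = _random_orf(np.random.default_rng(0), 331, 0.65)  # 999 nt
    measured = [kaks_pair(cds, mutate_to_ks(cds, target,
                                            np.random.default_rng(i))).ks
                for i in range(15)]
    assert abs(np.median(measured) - target) / target < 0.10


def test_clock_arithmetic():
    assert date_divergence(0.0) == 0.0
    assert date_divergence(0.195) == pytest.approx(1.5e7)
    assert date_divergence(0.368) == pytest.approx(2.83e7, rel=0.01)
    assert date_divergence(None) is None
    assert date_divergence(0.13, 6.5e-9) == pytest.approx(1e7)


def test_ks_window_filter_strict_bound():
    def _fake(ks, ka):
        from flcdnakit.divergence_dating import DivergenceEstimate
        return DivergenceEstimate("a", "b", 100, 75.0, 225.0, 1, 1,
                                  0.01, 0.004, ks, ka)

    res = ks_window_filter([_fake(0.75, 0.0), _fake(0.74, 0.0),
                            _fake(0.2, 0.3)])
    assert res["n_kept"] == 2
    assert res["n_ratio_gt1"] == 1  # 0.3/0.2 = 1.5
    assert res["ratio_bins"]["0.0-0.1"] == 1  # the ka=0 pair


def test_duplication_cluster_dating():
    cfg = SimulationConfig(n_genes=1, seed=0)
    fl, orf_truth, ests = simulate_duplication_clusters(
        5, target_ks=0.13, config=cfg, rng=1)
    anns = {r.id: find_longest_orf(r.seq, r.id) for r in fl}
    clusters, hist = duplication_analysis(fl, anns, ests)
    dated = [c for c in clusters if c.t_years is not None]
    assert len(dated) >= 4
    for c in dated:
        assert c.haplotype_count == 2
        assert abs(c.t_years - 1e7) / 1e7 < 0.35
    assert hist["count"].sum() == len(dated)


def test_identical_ests_one_haplotype(rng):
    cfg = SimulationConfig(n_genes=1, seed=4)
    from flcdnakit.synthetic_data import _build_primary
    seq, cds = _build_primary(np.random.default_rng(2), cfg)
    fl = [TranscriptRecord("g", seq)]
    anns = {"g": find_longest_orf(seq, "g")}
    ests = [TranscriptRecord(f"e{i}", seq) for i in range(6)]
    clusters, _ = duplication_analysis(fl, anns, ests)
    assert clusters[0].haplotype_count == 1
    assert clusters[0].t_years is None


def test_singleton_error_masked(rng):
    """A polymorphism supported by one read is sequencing error: masked."""
    cfg = SimulationConfig(n_genes=1, seed=4)
    from flcdnakit.synthetic_data import _build_primary
    seq, _ = _build_primary(np.random.default_rng(3), cfg)
    fl = [TranscriptRecord("g", seq)]
    anns = {"g": find_longest_orf(seq, "g")}
    bad = list(seq)
    bad[50] = {"A": "C", "C": "G", "G": "T", "T": "A"}[bad[50]]
    ests = [TranscriptRecord(f"e{i}", seq) for i in range(5)]
    ests.append(TranscriptRecord("e5", "".join(bad)))
    clusters, _ = duplication_analysis(fl, anns, ests)
    assert clusters[0].n_polymorphic_sites == 0
    assert clusters[0].haplotype_count == 1
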