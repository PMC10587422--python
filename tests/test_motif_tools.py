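"""Motif pipeline checks: run finding against a run-length oracle, candidate
scoring against an exhaustive matched-filter oracle, PFM construction against
binomial sampling error, MEME round-trips, and the distribution analyses
against constructions with known answers."""

import numpy as np
import pytest

from circseg.dataprep import BindingInterval, LabeledWindow, one_hot_encode
from circseg.motif_tools import (
    MotifCandidate,
    PFM,
    PredictedRegion,
    PositionalHistogram,
    build_pfm,
    find_regions,
    first_layer_activations,
    kmer_flank_analysis,
    motif_distribution,
    read_meme,
    score_candidates,
    sponge_overlap,
    write_meme,
)
from circseg.synthdata import MotifModel


class FakeModel:
    """Model stub exposing handcrafted first-layer weights."""

    def __init__(self, weights):
        self.first_conv_weights = np.asarray(weights, dtype=float)


def one_hot_kernel(s, n_filters=1, which=0):
    """(k, 4, F) weights where filter ``which`` is the one-hot of ``s``."""
    W = np.zeros((len(s), 4, n_filters))
    for i, b in enumerate(s):
        W[i, "ACGU".index(b), which] = 1.0
    return W


class TestFindRegions:
    def test_run_length_oracle(self):
        regs = find_regions(np.array([0, 1, 1, 1, 0, 1]), min_run=2)
        assert [(r.start, r.end) for r in regs] == [(1, 4)]

    def test_all_zeros(self):
        assert find_regions(np.zeros(20, dtype=int)) == []

    def test_all_ones(self):
        regs = find_regions(np.ones(30, dtype=int), min_run=5)
        assert [(r.start, r.end) for r in regs] == [(0, 30)]

    def test_multiple_runs_in_order(self):
        labels = np.array([1, 1, 0, 1, 1, 1, 0, 0, 1, 1])
        regs = find_regions(labels, min_run=2)
        assert [(r.start, r.end) for r in regs] == [(0, 2), (3, 6), (8, 10)]


class TestScoreCandidates:
    def test_matched_filter_recovers_planted_string(self):
        # dot-product is maximized by the identical substring
        seq = "AAAAAUGUGUAAAAAAAAAA"
        model = FakeModel(one_hot_kernel("UGUGU"))
        regs = find_regions(np.array([0] * 3 + [1] * 12 + [0] * 5), min_run=5)
        cands = score_candidates(model, seq, regs)
        assert len(cands) == 1
        assert cands[0].subsequence == "UGUGU"
        assert cands[0].position == 5

    def test_exhaustive_dot_product_oracle(self, rng):
        seq = "".join(rng.choice(list("ACGU"), 40))
        W = rng.normal(size=(6, 4, 3))
        model = FakeModel(W)
        regs = [PredictedRegion("w", 0, 40)]
        cands = score_candidates(model, seq, regs)
        oh = one_hot_encode(seq)
        best = max(
            float((oh[p : p + 6] * W[:, :, f]).sum())
            for p in range(40 - 6 + 1)
            for f in range(3)
        )
        assert cands[0].score == pytest.approx(best)

    def test_leftmost_tie_break(self):
        seq = "UGUGUAAUGUGUAAAAAAAA"  # two identical exact matches
        model = FakeModel(one_hot_kernel("UGUGU"))
        regs = find_regions(np.ones(20, dtype=int), min_run=5)
        cands = score_candidates(model, seq, regs)
        assert cands[0].position == 0

    def test_short_region_extended(self):
        seq = "AAAAAUGUGUAAAAAAAAAA"
        model = FakeModel(one_hot_kernel("UGUGU"))
        # region of 3 < kernel 5: extended symmetrically, still finds motif
        regs = find_regions(np.array([0] * 6 + [1] * 3 + [0] * 11), min_run=2)
        cands = score_candidates(model, seq, regs)
        assert len(cands) == 1
        assert cands[0].subsequence == "UGUGU"

    def test_no_regions_empty(self):
        model = FakeModel(one_hot_kernel("UGUGU"))
        assert score_candidates(model, "ACGU" * 5, []) == []


def make_candidate(s, pos=45, f=0, window_length=101, center=None):
    return MotifCandidate(
        window_id="w", subsequence=s, position=pos, filter_index=f, score=1.0,
        region_center=center if center is not None else pos + len(s) / 2,
        window_length=window_length,
    )


class TestBuildPfm:
    def test_unanimous_columns(self):
        cands = [make_candidate("ACG", pos=49, window_length=101) for _ in range(3)]
        pfms = build_pfm(cands, min_support=2)
        assert len(pfms) == 1
        np.testing.assert_allclose(
            pfms[0].matrix,
            np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1], [0, 0, 0]]),
        )

    def test_fractional_column(self):
        cands = [make_candidate("AA", pos=49), make_candidate("AC", pos=49)]
        pfms = build_pfm(cands, min_support=2)
        np.testing.assert_allclose(pfms[0].matrix[:, 1], [0.5, 0.5, 0, 0])

    def test_min_support_drops_small_groups(self):
        cands = [make_candidate("ACG", f=0)] * 5 + [make_candidate("CGA", f=1)] * 2
        pfms = build_pfm(cands, min_support=3)
        assert len(pfms) == 1 and pfms[0].name.endswith("_0")

    def test_sampled_pwm_within_3se(self, rng):
        pwm = MotifModel.from_consensus("UGCAUGGUAA", strength=0.8)
        n = 100
        cands = [make_candidate(pwm.sample(rng), pos=45) for _ in range(n)]
        pfms = build_pfm(cands, min_support=10)
        se = np.sqrt(0.8 * 0.2 / n)
        dev = np.abs(pfms[0].matrix - pwm.pwm.T).max()
        # the max runs over 40 cells, so the per-cell 3*SE band is exceeded
        # ~10% of the time by multiplicity; 4*SE keeps that below 0.5%
        assert dev <= 4 * max(se, np.sqrt(0.25 * 0.75 / n)) + 1e-9

    def test_columns_sum_to_one(self, rng):
        cands = [make_candidate("".join(rng.choice(list("ACGU"), 8)), pos=46)
                 for _ in range(20)]
        for pfm in build_pfm(cands, min_support=1):
            np.testing.assert_allclose(pfm.matrix.sum(axis=0), 1.0, atol=1e-9)

    def test_recentring_corrects_constant_register_shift(self):
        # all candidates sit one base right of the window-centred start 45;
        # context lets build_pfm shift them back
        cands = [
            MotifCandidate(
                window_id=f"w{i}", subsequence="GCAUGGUAAC", position=46,
                filter_index=0, score=1.0, region_center=50.5, window_length=101,
                context="AAUGCAUGGUAACAA", context_start=43,
            )
            for i in range(12)
        ]
        pfms = build_pfm(cands, min_support=5)
        assert pfms[0].consensus == "UGCAUGGUAA"

    def test_empty_input(self):
        assert build_pfm([]) == []


class TestMemeFormat:
    def test_single_motif_block(self, tmp_path, rng):
        mat = rng.dirichlet(np.ones(4), size=10).T
        pfm = PFM(name="m1", matrix=mat, n_sites=33)
        path = tmp_path / "motifs.meme"
        write_meme([pfm], path)
        text = path.read_text()
        assert text.startswith("MEME version 4")
        assert "ALPHABET= ACGU" in text
        assert "letter-probability matrix: alength= 4 w= 10 nsites= 33" in text

    def test_zero_pfms_header_only(self, tmp_path):
        path = tmp_path / "empty.meme"
        write_meme([], path)
        assert "MEME version 4" in path.read_text()
        assert read_meme(path) == []

    def test_roundtrip_frequencies(self, tmp_path, rng):
        mats = [rng.dirichlet(np.ones(4), size=8).T for _ in range(3)]
        pfms = [PFM(name=f"m{i}", matrix=m, n_sites=10 + i) for i, m in enumerate(mats)]
        path = tmp_path / "rt.meme"
        write_meme(pfms, path)
        back = read_meme(path)
        assert [p.name for p in back] == ["m0", "m1", "m2"]
        for orig, rt in zip(pfms, back):
            np.testing.assert_allclose(rt.matrix, orig.matrix, atol=1e-6)
            assert rt.n_sites == orig.n_sites


class TestMotifDistribution:
    def test_mode_at_planted_position(self):
        windows = ["A" * 45 + "UGUGU" + "A" * 51 for _ in range(10)]
        hist = motif_distribution(windows, "UGUGU")
        assert hist.counts.argmax() == 45
        assert hist.counts[45] == 10

    def test_absent_pattern_zero(self):
        hist = motif_distribution(["A" * 101], "CGCGC")
        assert hist.total == 0

    def test_total_bounded(self, rng):
        windows = ["".join(rng.choice(list("ACGU"), 101)) for _ in range(5)]
        hist = motif_distribution(windows, "AC")
        assert hist.total <= 5 * (101 - 2 + 1)

    def test_pwm_log_odds_scan_finds_consensus(self):
        m = MotifModel.from_consensus("UGCAUGGUAA", strength=0.9)
        windows = ["C" * 40 + "UGCAUGGUAA" + "C" * 51]
        hist = motif_distribution(windows, m)
        assert hist.counts.argmax() == 40


class TestSpongeOverlap:
    def test_all_mass_inside(self):
        hist = PositionalHistogram(20, np.array([0] * 5 + [3] * 5 + [0] * 10))
        rep = sponge_overlap(hist, [(5, 10)])
        assert rep.fraction == 1.0

    def test_all_mass_outside(self):
        hist = PositionalHistogram(20, np.array([2] * 5 + [0] * 15))
        rep = sponge_overlap(hist, [(10, 20)])
        assert rep.fraction == 0.0

    def test_uniform_mass_proportional(self):
        hist = PositionalHistogram(100, np.ones(100, dtype=int))
        rep = sponge_overlap(hist, [(0, 30)])
        assert rep.fraction == pytest.approx(0.3)

    def test_main_interval_holds_half_mass(self):
        counts = np.zeros(50, dtype=int)
        counts[20:25] = 10
        counts[40] = 1
        rep = sponge_overlap(PositionalHistogram(50, counts), [(0, 50)])
        s, e = rep.main_interval
        assert counts[s:e].sum() >= 0.5 * counts.sum()
        assert 20 <= s and e <= 25  # the tight mass concentration wins

    def test_empty_histogram_flagged(self):
        rep = sponge_overlap(PositionalHistogram(10, np.zeros(10, dtype=int)), [(0, 5)])
        assert rep.empty and rep.fraction is None


class TestKmerFlankAnalysis:
    def test_sliding_window_arithmetic(self):
        stats = kmer_flank_analysis(["A" * 101], k=12, count_threshold=1)
        assert len(stats) == 1
        assert stats[0].kmer == "A" * 12
        assert stats[0].total == 101 - 12 + 1

    def test_kmer_accounting(self, rng):
        windows = ["".join(rng.choice(list("ACGU"), 60)) for _ in range(4)]
        stats = kmer_flank_analysis(windows, k=12, count_threshold=1)
        assert sum(s.total for s in stats) == 4 * (60 - 12 + 1)

    def test_left_flank_classification(self, rng):
        # a 12-mer planted only in the first 50 positions of 201-nt records
        motif = "UGUGUGUGUGUG"
        windows = []
        for _ in range(20):
            bg = "".join(rng.choice(list("AC"), 201))
            p = int(rng.integers(0, 38))
            windows.append(bg[:p] + motif + bg[p + 12:])
        stats = kmer_flank_analysis(windows, k=12, count_threshold=10)
        by_kmer = {s.kmer: s for s in stats}
        assert by_kmer[motif].distribution_type == "left-flank"

    def test_binding_region_classification(self, rng):
        motif = "UGUGUGUGUGUG"
        windows = []
        for _ in range(20):
            bg = "".join(rng.choice(list("AC"), 201))
            p = int(rng.integers(80, 110))
            windows.append(bg[:p] + motif + bg[p + 12:])
        stats = kmer_flank_analysis(windows, k=12, count_threshold=10)
        by_kmer = {s.kmer: s for s in stats}
        assert by_kmer[motif].distribution_type == "binding-region"

    def test_threshold_filters(self, rng):
        windows = ["".join(rng.choice(list("ACGU"), 101)) for _ in range(3)]
        stats = kmer_flank_analysis(windows, k=12, count_threshold=50)
        assert stats == [] or all(s.total >= 50 for s in stats)

    def test_k_longer_than_window_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            kmer_flank_analysis(["ACGU"], k=12)
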