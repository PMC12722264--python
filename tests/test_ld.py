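"""Linkage disequilibrium machinery: r2, EM, scan, bins, pruning."""

import numpy as np
import pandas as pd
import pytest

from bovpop.genotype_io import MISSING
from bovpop.ld import (
    assign_decay_bin,
    bin_ld_decay,
    decay_bin_edges,
    em_haplotype_freqs,
    genotype_r2,
    ld_scan,
    prune_r2,
    prune_vif,
)
from tests.conftest import make_dataset


class TestGenotypeR2:
    def test_identical_vectors(self):
        x = np.array([0, 1, 2, 1, 0], dtype=np.uint8)
        assert genotype_r2(x, x) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert genotype_r2(
            np.array([0, 0, 2, 2], dtype=np.uint8), np.array([0, 2, 0, 2], dtype=np.uint8)
        ) == pytest.approx(0.0)

    def test_matches_corrcoef_oracle(self, rng):
        for _ in range(10):
            x = rng.integers(0, 3, 40).astype(np.uint8)
            y = rng.integers(0, 3, 40).astype(np.uint8)
            if x.std() == 0 or y.std() == 0:
                continue
            assert genotype_r2(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2)

    def test_symmetric_and_flip_behavior(self, rng):
        x = rng.integers(0, 3, 30).astype(np.uint8)
        y = rng.integers(0, 3, 30).astype(np.uint8)
        assert genotype_r2(x, y) == pytest.approx(genotype_r2(y, x))
        assert genotype_r2((2 - x).astype(np.uint8), y) == pytest.approx(genotype_r2(x, y))

    def test_zero_variance_undefined(self):
        assert np.isnan(genotype_r2(np.zeros(5, np.uint8), np.array([0, 1, 2, 1, 0], np.uint8)))

    def test_complete_case_over_missing(self):
        x = np.array([0, 2, MISSING, 1], dtype=np.uint8)
        y = np.array([0, 2, 1, 1], dtype=np.uint8)
        assert genotype_r2(x, y) == pytest.approx(np.corrcoef([0, 2, 1], [0, 2, 1])[0, 1] ** 2)


class TestEMHaplotypes:
    def test_two_homozygote_classes_give_full_coupling(self):
        # equal numbers of AABB and aabb: fAB = fab = 0.5, D = 0.25, D' = 1
        x = np.array([2, 2, 0, 0], dtype=np.uint8)
        y = np.array([2, 2, 0, 0], dtype=np.uint8)
        out = em_haplotype_freqs(x, y)
        assert out["fAB"] == pytest.approx(0.5, abs=1e-9)
        assert out["fab"] == pytest.approx(0.5, abs=1e-9)
        assert out["D"] == pytest.approx(0.25, abs=1e-9)
        assert out["Dprime"] == pytest.approx(1.0, abs=1e-8)

    def test_independent_loci_have_small_d(self, rng):
        x = rng.binomial(2, 0.5, 2000).astype(np.uint8)
        y = rng.binomial(2, 0.5, 2000).astype(np.uint8)
        assert abs(em_haplotype_freqs(x, y)["D"]) < 0.02

    def test_no_double_heterozygotes_equals_direct_counting(self):
        x = np.array([2, 2, 1, 0, 0, 1], dtype=np.uint8)
        y = np.array([2, 1, 0, 0, 1, 2], dtype=np.uint8)
        out = em_haplotype_freqs(x, y)
        # haplotypes countable by hand: each individual contributes 2
        # AB: (2,2)->2, (2,1)->1, (1,2)->1 ; Ab: (2,1)->1,(1,0)->1,(2,0)->0...
        want_AB = (2 + 1 + 1) / 12
        want_Ab = (1 + 1) / 12
        want_aB = (1 + 1) / 12
        want_ab = (2 + 1 + 1) / 12
        assert out["fAB"] == pytest.approx(want_AB, abs=1e-9)
        assert out["fAb"] == pytest.approx(want_Ab, abs=1e-9)
        assert out["faB"] == pytest.approx(want_aB, abs=1e-9)
        assert out["fab"] == pytest.approx(want_ab, abs=1e-9)

    def test_marginal_consistency(self, rng):
        for _ in range(10):
            x = rng.integers(0, 3, 60).astype(np.uint8)
            y = rng.integers(0, 3, 60).astype(np.uint8)
            out = em_haplotype_freqs(x, y)
            total = out["fAB"] + out["fAb"] + out["faB"] + out["fab"]
            assert total == pytest.approx(1.0, abs=1e-8)
            assert out["fAB"] + out["fAb"] == pytest.approx(x.mean() / 2, abs=1e-8)
            assert out["fAB"] + out["faB"] == pytest.approx(y.mean() / 2, abs=1e-8)


class TestScan:
    def test_three_markers_three_pairs(self, rng):
        calls = rng.integers(0, 3, size=(20, 3)).astype(np.uint8)
        ds = make_dataset(calls, positions=[10_000, 500_000, 900_000])
        pairs = ld_scan(ds)
        assert len(pairs) == 3

    def test_cross_chromosome_pairs_excluded(self, rng):
        calls = rng.integers(0, 3, size=(20, 2)).astype(np.uint8)
        ds = make_dataset(calls, chromosome=["1", "2"], positions=[100, 200])
        assert len(ld_scan(ds)) == 0

    def test_pair_count_matches_bruteforce(self, rng):
        m = 30
        pos = np.sort(rng.choice(3_000_000, m, replace=False)) + 1
        calls = rng.integers(0, 3, size=(25, m)).astype(np.uint8)
        ds = make_dataset(calls, positions=pos.tolist())
        pairs = ld_scan(ds, max_distance_bp=1_000_000, with_d=False)
        want = 0
        for i in range(m):
            for j in range(i + 1, m):
                if pos[j] - pos[i] <= 1_000_000 and np.std(calls[:, i]) > 0 and np.std(calls[:, j]) > 0:
                    want += 1
        assert len(pairs) == want


class TestDecayBins:
    def test_examples(self):
        assert assign_decay_bin(np.array([15_000]))[0] == 0  # [10,20) kb
        edges = decay_bin_edges()
        b = assign_decay_bin(np.array([250_000]))[0]
        assert (edges[b], edges[b + 1]) == (200_000, 300_000)

    def test_partition_has_no_gaps_or_overlaps_at_boundaries(self):
        edges = decay_bin_edges()
        probe = np.concatenate([edges - 1, edges, edges + 1])
        probe = probe[(probe >= 10_000) & (probe <= 1_000_000)]
        idx = assign_decay_bin(probe)
        assert (idx >= 0).all()
        # each distance falls in exactly the bin whose bounds bracket it
        for d, b in zip(probe, idx):
            lo, hi = edges[b], edges[b + 1]
            assert lo <= d < hi or (d == 1_000_000 and hi == 1_000_000)

    def test_out_of_range_distances_unbinned(self):
        idx = assign_decay_bin(np.array([9_999, 1_000_001]))
        assert (idx == -1).all()

    def test_underfilled_bin_flagged(self, rng):
        pairs = pd.DataFrame(
            {"distance_bp": [15_000] * 49, "r2": rng.random(49)}
        )
        table = bin_ld_decay(pairs, min_pairs=50)
        row = table.iloc[0]
        assert row["n_pairs"] == 49 and not row["reliable"]


class TestPruning:
    def test_independent_markers_all_kept(self, rng):
        calls = rng.binomial(2, 0.5, size=(200, 12)).astype(np.uint8)
        ds = make_dataset(calls)
        assert len(prune_r2(ds)) == 12
        assert len(prune_vif(ds)) == 12

    def test_duplicate_marker_pruned_once(self, rng):
        base = rng.binomial(2, 0.5, size=(50, 1)).astype(np.uint8)
        calls = np.hstack([base, base, rng.binomial(2, 0.5, (50, 3)).astype(np.uint8)])
        ds = make_dataset(calls)
        kept = prune_r2(ds)
        assert ("m1" in kept) != ("m2" in kept)
        kept_v = prune_vif(ds)
        assert ("m1" in kept_v) != ("m2" in kept_v)

    def test_r2_property_holds_on_recheck(self, rng):
        # correlated block structure to force removals
        z = rng.binomial(2, 0.5, size=(80, 5)).astype(np.uint8)
        noisy = [z[:, [j // 4]].ravel() for j in range(20)]
        calls = np.array(noisy).T.astype(np.uint8)
        flip = rng.random(calls.shape) < 0.05
        calls[flip] = rng.integers(0, 3, flip.sum())
        ds = make_dataset(calls)
        kept = prune_r2(ds, r2_max=0.8)
        loc = [list(ds.markers["marker_id"]).index(k) for k in kept]
        sub = calls[:, loc].astype(float)
        for a in range(len(loc)):
            for b in range(a + 1, len(loc)):
                if abs(loc[a] - loc[b]) < 50:
                    r = np.corrcoef(sub[:, a], sub[:, b])[0, 1]
                    assert r * r <= 0.8 + 1e-9

    def test_vif_property_holds_on_recheck(self, rng):
        z = rng.binomial(2, 0.5, size=(100, 4)).astype(float)
        # build 10 markers as noisy combinations: high mutual VIF
        mix = rng.normal(size=(4, 10))
        latent = z @ mix + rng.normal(scale=0.6, size=(100, 10))
        calls = np.clip(np.round(latent - latent.mean(0) + 1), 0, 2).astype(np.uint8)
        ds = make_dataset(calls)
        kept = prune_vif(ds, vif_max=2.0)
        loc = [list(ds.markers["marker_id"]).index(k) for k in kept]
        sub = calls[:, loc].astype(float)
        if len(loc) >= 2:
            R = np.corrcoef(sub.T)
            vif = np.diag(np.linalg.inv(R + 1e-10 * np.eye(len(loc))))
            assert vif.max() <= 2.0 + 1e-6
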