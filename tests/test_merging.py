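"""Pooling, inverse-variance merging, R-factors, CC1/2 and sigAno."""

import math
from collections import defaultdict

import numpy as np
import pytest

from isomerge.merging import (
    cc_half,
    merge_intensities,
    pool,
    r_factors,
    sig_ano,
    statistics,
)
from isomerge.symmetry import CrystalCell, decode_keys, unique_reflections

from conftest import make_dataset


class TestPool:
    def test_pool_size_is_sum_of_members(self):
        a = make_dataset("a", [[h, 0, 0] for h in range(1, 11)], np.arange(10.0) + 1)
        b = make_dataset("b", [[h, 0, 0] for h in range(1, 11)], np.arange(10.0) + 2)
        p = pool(["a", "b"], [a, b])
        assert len(p) == 20

    def test_duplicate_member_rejected(self):
        a = make_dataset("a", [[1, 0, 0]], [1.0])
        with pytest.raises(ValueError, match="distinct"):
            pool(["a", "a"], [a])

    def test_unknown_member_rejected(self):
        a = make_dataset("a", [[1, 0, 0]], [1.0])
        with pytest.raises(KeyError, match="nope"):
            pool(["nope"], [a])

    def test_synthetic_cluster_counting(self, small_run):
        datasets, _, _ = small_run
        members = [ds.id for ds in datasets[:5]]
        p = pool(members, datasets)
        assert len(p) == sum(len(ds) for ds in datasets[:5])


class TestMergeIntensities:
    def test_single_observation(self):
        a = make_dataset("a", [[1, 0, 0]], [100.0], [10.0])
        merged = merge_intensities(pool(["a"], [a]))
        assert len(merged) == 1
        assert merged[0].i_mean == pytest.approx(100.0)
        assert merged[0].sigma == pytest.approx(10.0)
        assert merged[0].multiplicity == 1

    def test_equal_weight_mean(self):
        a = make_dataset("a", [[1, 0, 0], [1, 0, 0]], [100.0, 200.0], [10.0, 10.0])
        merged = merge_intensities(pool(["a"], [a]))
        assert merged[0].i_mean == pytest.approx(150.0)
        assert merged[0].sigma == pytest.approx(10 / math.sqrt(2))
        assert merged[0].multiplicity == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_accumulation(self, seed):
        rng = np.random.default_rng(seed)
        n = 200
        hkl = rng.integers(1, 5, size=(n, 3))
        hkl[np.all(hkl == 0, axis=1)] = [1, 1, 1]
        intensity = rng.lognormal(3, 1, n)
        sigma = rng.uniform(0.5, 3.0, n)
        ds = make_dataset("a", hkl, intensity, sigma)
        merged = merge_intensities(pool(["a"], [ds]))
        # brute-force per-key accumulation in plain dicts (P1: key = +/- hkl)
        groups = defaultdict(list)
        for (h, k, l), i, s in zip(hkl, intensity, sigma):
            key = max((h, k, l), (-h, -k, -l))
            groups[key].append((i, s))
        assert len(merged) == len(groups)
        by_key = {m.key.hkl: m for m in merged}
        for key, obs in groups.items():
            w = np.array([1 / s**2 for _, s in obs])
            i = np.array([i for i, _ in obs])
            m = by_key[key]
            assert m.i_mean == pytest.approx(float((w * i).sum() / w.sum()))
            assert m.sigma == pytest.approx(float(math.sqrt(1 / w.sum())))
            assert m.multiplicity == len(obs)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        n = 50
        hkl = rng.integers(1, 4, size=(n, 3))
        intensity = rng.lognormal(3, 1, n)
        sigma = rng.uniform(0.5, 2, n)
        perm = rng.permutation(n)
        a = make_dataset("a", hkl, intensity, sigma)
        b = make_dataset("b", hkl[perm], intensity[perm], sigma[perm])
        ma = merge_intensities(pool(["a"], [a]))
        mb = merge_intensities(pool(["b"], [b]))
        for x, y in zip(ma, mb):
            assert x.key == y.key
            assert x.i_mean == pytest.approx(y.i_mean)
            assert x.sigma == pytest.approx(y.sigma)

    def test_anomalous_separates_friedel_mates(self):
        a = make_dataset(
            "a", [[1, 2, 3], [-1, -2, -3]], [120.0, 100.0], [3.0, 4.0]
        )
        merged = merge_intensities(pool(["a"], [a], anomalous=True))
        assert len(merged) == 1
        m = merged[0]
        assert m.n_plus == 1 and m.n_minus == 1
        assert {m.i_plus, m.i_minus} == {120.0, 100.0}


class TestRFactors:
    def test_identical_observations_give_zero(self):
        a = make_dataset("a", [[1, 0, 0]] * 4, [50.0] * 4, [1.0] * 4)
        rm, rme, rp = r_factors(pool(["a"], [a]))
        assert rm == rme == rp == 0.0

    def test_hand_computed_doublet(self):
        a = make_dataset("a", [[1, 0, 0], [1, 0, 0]], [90.0, 110.0], [1.0, 1.0])
        rm, rme, rp = r_factors(pool(["a"], [a]))
        assert rm == pytest.approx(0.1)
        assert rme == pytest.approx(0.1 * math.sqrt(2))
        assert rp == pytest.approx(0.1)

    def test_all_singletons_undefined(self):
        a = make_dataset("a", [[1, 0, 0], [2, 0, 0]], [1.0, 2.0])
        assert r_factors(pool(["a"], [a])) == (None, None, None)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_and_ordering(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = 300
        hkl = rng.integers(1, 6, size=(n, 3))
        intensity = rng.lognormal(3, 0.5, n)
        ds = make_dataset("a", hkl, intensity)
        rm, rme, rp = r_factors(pool(["a"], [ds]))
        groups = defaultdict(list)
        for (h, k, l), i in zip(hkl, intensity):
            groups[max((h, k, l), (-h, -k, -l))].append(i)
        num_m = num_me = num_p = den = 0.0
        for obs in groups.values():
            if len(obs) < 2:
                continue
            obs = np.array(obs)
            dev = np.abs(obs - obs.mean()).sum()
            num_m += dev
            num_me += dev * math.sqrt(len(obs) / (len(obs) - 1))
            num_p += dev * math.sqrt(1 / (len(obs) - 1))
            den += obs.sum()
        assert rm == pytest.approx(num_m / den)
        assert rme == pytest.approx(num_me / den)
        assert rp == pytest.approx(num_p / den)
        assert rp <= rme

    def test_doublet_pool_identities(self):
        # with every group of size 2: r_meas = sqrt(2) r_merge, r_pim = r_merge
        rng = np.random.default_rng(4)
        base = np.stack([np.arange(1, 41), np.full(40, 2), np.full(40, 3)], axis=1)
        hkl = np.repeat(base, 2, axis=0)
        intensity = rng.lognormal(3, 0.4, 80)
        ds = make_dataset("a", hkl, intensity, cell=CrystalCell(100, 10, 10))
        p = pool(["a"], [ds])
        _, counts = np.unique(p.group_codes(), return_counts=True)
        assert set(counts.tolist()) == {2}
        rm, rme, rp = r_factors(p)
        assert rme == pytest.approx(rm * math.sqrt(2))
        assert rp == pytest.approx(rm)


class TestCcHalf:
    def test_noise_free_pool_gives_one(self):
        rng = np.random.default_rng(1)
        base = np.stack([np.arange(1, 51), np.full(50, 1), np.full(50, 2)], axis=1)
        hkl = np.repeat(base, 3, axis=0)
        truth = np.repeat(rng.lognormal(3, 1, 50), 3)
        ds = make_dataset("a", hkl, truth, cell=CrystalCell(120, 10, 10))
        assert cc_half(pool(["a"], [ds]), seed=0) == pytest.approx(1.0)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        hkl = np.repeat(rng.integers(1, 8, size=(60, 3)), 4, axis=0)
        vals = np.repeat(rng.lognormal(3, 1, 60), 4) + rng.normal(0, 5, 240)
        ds = make_dataset("a", hkl, vals)
        p = pool(["a"], [ds])
        assert cc_half(p, seed=7) == cc_half(p, seed=7)
        # different seeds may differ, but stay in [-1, 1]
        assert -1 <= cc_half(p, seed=8) <= 1

    def test_too_few_groups_undefined(self):
        a = make_dataset("a", [[1, 0, 0], [2, 0, 0]], [1.0, 2.0])
        assert cc_half(pool(["a"], [a]), seed=0) is None

    def test_matches_analytic_expectation(self):
        # doublet groups around true values: E[CC1/2] = var_sig/(var_sig + var_noise)
        rng = np.random.default_rng(12)
        n_groups = 4000
        sig_true = 50.0
        sig_noise = 30.0
        truth = rng.normal(500, sig_true, n_groups)
        hkl = np.repeat(np.stack([np.arange(1, n_groups + 1) % 7 + 1,
                                  np.arange(n_groups) % 11 + 1,
                                  np.arange(n_groups) + 1], axis=1), 2, axis=0)
        vals = np.repeat(truth, 2) + rng.normal(0, sig_noise, 2 * n_groups)
        cell = CrystalCell(500, 500, 5000)
        ds = make_dataset("a", hkl, vals, cell=cell)
        expected = sig_true**2 / (sig_true**2 + sig_noise**2)
        got = cc_half(pool(["a"], [ds]), seed=3)
        assert got == pytest.approx(expected, abs=0.03)


class TestSigAno:
    def test_equal_mates_give_zero(self):
        a = make_dataset("a", [[1, 2, 3], [-1, -2, -3]], [100.0, 100.0], [3.0, 4.0])
        merged = merge_intensities(pool(["a"], [a], anomalous=True))
        assert sig_ano(merged) == pytest.approx(0.0)

    def test_three_four_five(self):
        a = make_dataset("a", [[1, 2, 3], [-1, -2, -3]], [120.0, 100.0], [3.0, 4.0])
        merged = merge_intensities(pool(["a"], [a], anomalous=True))
        assert sig_ano(merged) == pytest.approx(4.0)

    def test_no_eligible_keys_undefined(self):
        a = make_dataset("a", [[1, 2, 3]], [120.0], [3.0])
        merged = merge_intensities(pool(["a"], [a], anomalous=True))
        assert sig_ano(merged) is None

    def test_null_signal_concentrates_at_half_normal_mean(self):
        # |I+ - I-|/sqrt(s+^2+s-^2) ~ |N(0,1)| under no anomalous signal
        rng = np.random.default_rng(5)
        n = 10_000
        hkl = np.stack(
            [rng.integers(1, 30, n), rng.integers(1, 30, n), np.arange(1, n + 1)], axis=1
        )
        sigma = 10.0
        truth = rng.lognormal(6, 0.3, n)
        iplus = truth + rng.normal(0, sigma, n)
        iminus = truth + rng.normal(0, sigma, n)
        cell = CrystalCell(100, 100, 20000)
        ds = make_dataset(
            "a",
            np.concatenate([hkl, -hkl]),
            np.concatenate([iplus, iminus]),
            np.full(2 * n, sigma),
            cell=cell,
        )
        merged = merge_intensities(pool(["a"], [ds], anomalous=True))
        assert sig_ano(merged) == pytest.approx(math.sqrt(2 / math.pi), abs=0.02)


class TestStatistics:
    def test_complete_noise_free_dataset_fully_complete(self, p1):
        cell = CrystalCell(10, 10, 10)
        codes, _ = unique_reflections(cell, p1, 4.0)
        hkl, _ = decode_keys(codes)
        ds = make_dataset("a", hkl, np.arange(len(hkl)) + 1.0, cell=cell)
        st = statistics(pool(["a"], [ds]), d_min=4.0, n_shells=4)
        assert st.overall.completeness == pytest.approx(1.0)
        for shell in st.shells:
            assert shell.completeness == pytest.approx(1.0)

    def test_shells_partition_unique_counts(self, small_run):
        datasets, _, _ = small_run
        p = pool([ds.id for ds in datasets[:8]], datasets)
        st = statistics(p, n_shells=6, seed=2)
        assert sum(s.n_unique for s in st.shells) == st.overall.n_unique
        assert sum(s.n_total for s in st.shells) == st.overall.n_total
        assert st.overall.n_unique <= st.overall.n_total
        if st.overall.r_pim is not None:
            assert st.overall.r_pim <= st.overall.r_meas

    def test_pure_cluster_beats_indiscriminate_merge(self, small_run):
        datasets, labels, _ = small_run
        pure = [ds.id for ds, lab in zip(datasets, labels) if lab == 0]
        everything = [ds.id for ds in datasets]
        st_pure = statistics(pool(pure, datasets), n_shells=4, seed=0)
        st_all = statistics(pool(everything, datasets), n_shells=4, seed=0)
        assert st_pure.overall.cc_half > st_all.overall.cc_half
        assert st_pure.overall.r_meas < st_all.overall.r_meas

    def test_json_report_is_machine_readable(self, small_run):
        import json

        datasets, _, _ = small_run
        st = statistics(pool([datasets[0].id, datasets[1].id], datasets), n_shells=3)
        payload = json.loads(st.to_json())
        assert payload["overall"]["n_total"] == st.overall.n_total
        assert len(payload["shells"]) == 3
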