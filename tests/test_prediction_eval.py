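"""Metrics, repeated-split evaluation, AUC/DeLong machinery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import vfdecomp as vd
from vfdecomp.longitudinal import aa_decomposer, fcm_decomposer


def auc_pair_counting(scores, labels):
    """Exhaustive Mann-Whitney pair counting (ties 1/2): brute-force oracle."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestMetrics:
    def test_mse_hand_cases(self):
        assert vd.mse([1, 2, 3], [1, 2, 3]) == 0.0
        assert vd.mse([1, 2, 3], [1, 1, 1]) == pytest.approx(5 / 3)

    def test_mse_homogeneity(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=20)
        x = y + rng.normal(size=20)
        assert vd.mse(y, y + 3 * (x - y)) == pytest.approx(9 * vd.mse(y, x))

    def test_pcc_extremes_and_hand_case(self):
        x = np.array([1.0, 2.0, 3.0])
        assert vd.pcc(x, x) == pytest.approx(1.0)
        assert vd.pcc(x, -x) == pytest.approx(-1.0)
        assert vd.pcc([2, 4, 5], [1, 2, 3]) == pytest.approx(0.98198051, abs=1e-6)

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=40)
    def test_formulas_match_direct_sums(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=15)
        x = y + rng.normal(size=15)
        assert vd.mse(y, x) == pytest.approx(np.sum((y - x) ** 2) / 15, abs=1e-12)
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert vd.pcc(y, x) == pytest.approx(num / den, abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            vd.mse([1, 2], [1])
        with pytest.raises(ValueError):
            vd.pcc([1, 1, 1], [1, 2, 3])


class TestBuildInstances:
    def test_row_counts_and_shared_labels(self, bank_atset, small_longitudinal):
        series, _ = small_longitudinal
        cohort = [vd.drop_learning_tests(s, 2) for s in series]
        Xa, ya, ia = vd.build_instances(cohort, aa_decomposer(bank_atset))
        Xf, yf, _ = vd.build_instances(cohort, fcm_decomposer(bank_atset))
        n_tests = sum(len(s) for s in cohort)
        assert len(ya) == n_tests - len(cohort)  # one row per non-baseline visit
        np.testing.assert_array_equal(ya, yf)
        assert Xa.shape == Xf.shape == (len(ya), 16)
        assert not np.allclose(Xa, Xf)

    def test_linear_label_map_gives_near_zero_mse(self, bank, bank_atset):
        # labels an exact linear map of the features: a flexible regressor
        # on a few thousand instances should transmit the signal with high
        # fidelity for both feature sets
        cfg = vd.SimulationConfig(n_patients=150, visits_per_eye=7, seed=41)
        series, _ = vd.simulate_longitudinal(bank, cfg)
        cohort = [vd.drop_learning_tests(s, 2) for s in series]
        Xf, _, _ = vd.build_instances(cohort, fcm_decomposer(bank_atset))
        beta = np.arange(16, dtype=float)
        y = Xf @ beta
        ea, ef, p = vd.repeated_eval((Xf, y), (Xf, y), "knn", repeats=3, seed=0)
        assert ef.mse_mean < 0.2 * float(np.var(y))
        assert ef.pcc_mean > 0.9

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            vd.build_instances([], lambda X: X)


class TestRepeatedEval:
    def test_identical_tables_p_one(self, bank_atset, small_longitudinal):
        series, _ = small_longitudinal
        cohort = [vd.drop_learning_tests(s, 2) for s in series[:20]]
        Xf, y, _ = vd.build_instances(cohort, fcm_decomposer(bank_atset))
        ea, ef, p = vd.repeated_eval((Xf, y), (Xf, y), "knn", repeats=5, seed=1)
        np.testing.assert_array_equal(ea.mse_values, ef.mse_values)
        assert p["mse"] == 1.0 and p["pcc"] == 1.0

    def test_same_seed_bit_identical(self, bank_atset, small_longitudinal):
        series, _ = small_longitudinal
        cohort = [vd.drop_learning_tests(s, 2) for s in series[:20]]
        Xa, y, _ = vd.build_instances(cohort, aa_decomposer(bank_atset))
        Xf, _, _ = vd.build_instances(cohort, fcm_decomposer(bank_atset))
        r1 = vd.repeated_eval((Xa, y), (Xf, y), "knn", repeats=4, seed=3)
        r2 = vd.repeated_eval((Xa, y), (Xf, y), "knn", repeats=4, seed=3)
        np.testing.assert_array_equal(r1[0].mse_values, r2[0].mse_values)
        np.testing.assert_array_equal(r1[1].pcc_values, r2[1].pcc_values)

    def test_mismatched_labels_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError):
            vd.repeated_eval((X, np.zeros(10)), (X, np.ones(10)), "knn", repeats=2)

    def test_too_few_repeats_rejected(self):
        X = np.zeros((10, 2))
        y = np.zeros(10)
        with pytest.raises(ValueError):
            vd.repeated_eval((X, y), (X, y), "knn", repeats=1)


class TestRocAuc:
    def test_perfect_separation(self):
        r = vd.roc_auc([3, 4, 5, 1, 2], [1, 1, 1, 0, 0])
        assert r.auc == 1.0

    def test_all_ties_half(self):
        r = vd.roc_auc([2, 2, 2, 2], [1, 1, 0, 0])
        assert r.auc == 0.5

    def test_worked_example(self):
        # pairs: (.9,.6)+ (.9,.1)+ (.4,.6)- (.4,.1)+ -> 3/4
        r = vd.roc_auc([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0])
        assert r.auc == pytest.approx(0.75)
        assert r.ci_low <= r.auc <= r.ci_high

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=60)
    def test_equals_pair_counting_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        labels = np.zeros(n, dtype=int)
        labels[: int(rng.integers(1, n))] = 1
        rng.shuffle(labels)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = np.round(rng.normal(size=n), 1)  # coarse grid forces ties
        r = vd.roc_auc(scores, labels)
        assert r.auc == pytest.approx(auc_pair_counting(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            vd.roc_auc([1, 2, 3], [1, 1, 1])


class TestDelong:
    def test_identical_scores_p_one(self):
        s = [0.2, 0.8, 0.4, 0.9, 0.1, 0.7]
        y = [0, 1, 0, 1, 0, 1]
        assert vd.delong_compare(s, s, y) == 1.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        a = rng.normal(size=40)
        b = rng.normal(size=40)
        p1 = vd.delong_compare(a, b, y)
        p2 = vd.delong_compare(np.exp(a), b, y)  # strictly monotone transform
        assert p1 == pytest.approx(p2, abs=1e-12)
        assert vd.roc_auc(a, y).auc == vd.roc_auc(np.exp(a), y).auc

    def test_agrees_with_bootstrap(self):
        # paired correlated scores with a modest true AUC difference
        rng = np.random.default_rng(7)
        n = 60
        y = np.array([1] * 30 + [0] * 30)
        latent = y * 1.0 + rng.normal(size=n)
        a = latent + rng.normal(scale=0.6, size=n)
        b = 0.6 * latent + rng.normal(scale=1.0, size=n)
        p_delong = vd.delong_compare(a, b, y)

        auc_a = vd.roc_auc(a, y).auc
        auc_b = vd.roc_auc(b, y).auc
        diffs = []
        pos_idx = np.where(y == 1)[0]
        neg_idx = np.where(y == 0)[0]
        for _ in range(10_000):
            idx = np.concatenate([
                rng.choice(pos_idx, len(pos_idx)), rng.choice(neg_idx, len(neg_idx))
            ])
            diffs.append(
                auc_pair_counting(a[idx], y[idx]) - auc_pair_counting(b[idx], y[idx])
            )
        se = np.std(diffs, ddof=1)
        p_boot = 2 * stats.norm.sf(abs(auc_a - auc_b) / se)
        assert p_delong == pytest.approx(p_boot, abs=0.02)


class TestProgressionAucTable:
    @pytest.fixture(scope="class")
    def strong_cohort(self, bank):
        cfg = vd.SimulationConfig(
            n_patients=40, visits_per_eye=7, progression_fraction=0.4,
            progression_target_at=12, progression_rate=0.1, noise_sd_db=1.0,
            seed=31,
        )
        series, truth = vd.simulate_longitudinal(bank, cfg)
        return [vd.drop_learning_tests(s, 2) for s in series], truth

    def test_shape_and_cells(self, strong_cohort, bank_atset):
        cohort, _ = strong_cohort
        table = vd.progression_auc_table(cohort[:30], bank_atset)
        assert len(table) == 16 * 3
        assert {"auc_aa", "auc_fcm", "p_delong"} <= set(table.columns)

    def test_defect_at_slope_fcm_discriminates(self, strong_cohort, bank_atset):
        cohort, truth = strong_cohort
        dec = fcm_decomposer(bank_atset)
        scores, labels = [], []
        for s, prog in zip(cohort, truth.progressing):
            fits = vd.coefficient_slopes(s, dec)
            scores.append(fits[12].slope)  # weight gain on the defect AT
            labels.append(int(prog))
        assert vd.roc_auc(scores, labels).auc > 0.9

    def test_label_permutation_near_half(self, strong_cohort, bank_atset):
        cohort, truth = strong_cohort
        dec = fcm_decomposer(bank_atset)
        scores = [vd.coefficient_slopes(s, dec)[12].slope for s in cohort]
        rng = np.random.default_rng(0)
        perm = rng.permutation(np.array(truth.progressing, dtype=int))
        if perm.min() == perm.max():
            perm[0] = 1 - perm[0]
        assert abs(vd.roc_auc(scores, perm).auc - 0.5) < 0.2

    def test_single_class_criterion_gives_nan_not_error(self, bank, bank_atset):
        cfg = vd.SimulationConfig(
            n_patients=4, visits_per_eye=5, progression_fraction=0.0,
            noise_sd_db=0.2, seed=33,
        )
        series, _ = vd.simulate_longitudinal(bank, cfg)
        cohort = [vd.drop_learning_tests(s, 2) for s in series]
        table = vd.progression_auc_table(cohort, bank_atset)
        assert len(table) == 16 * 3
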