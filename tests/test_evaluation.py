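"""Histogram baselines, DeLong AUC inference, chi-square checks."""

import numpy as np
import pytest
from scipy import stats

from conftest import make_random_lesion
from oracles import auc_oracle, chi2_oracle
from plaqueomics.evaluation import (auc_delong, chi_square_balance,
                                    compare_delong, low_attenuation_area,
                                    mean_hu, univariate_logistic_baseline)
from plaqueomics.firstorder import compute_firstorder
from plaqueomics.io import VoxelLesion


def _lesion(values, coords=None, spacing=(0.4, 0.4, 0.6)):
    values = np.asarray(values)
    if coords is None:
        coords = np.column_stack([np.arange(len(values)),
                                  np.zeros(len(values), dtype=int),
                                  np.zeros(len(values), dtype=int)])
    return VoxelLesion(values=values, coords=np.asarray(coords),
                       spacing_mm=spacing)


class TestHistogramBaselines:
    def test_low_attenuation_area_single_layer(self):
        values = [20] * 10 + [90] * 10
        assert low_attenuation_area(_lesion(values)) == pytest.approx(1.6)

    def test_all_above_threshold_is_zero(self):
        assert low_attenuation_area(_lesion([30, 40, 100])) == 0.0

    def test_threshold_is_strict(self):
        # a voxel at exactly 30 HU is not low attenuation
        assert low_attenuation_area(_lesion([30])) == 0.0
        assert low_attenuation_area(_lesion([29])) == pytest.approx(0.16)

    def test_multilayer_slab_uses_mean_per_layer_area(self):
        coords = [[i, 0, z] for z in range(3) for i in range(4)]
        values = [20] * 12
        assert low_attenuation_area(_lesion(values, coords)) == pytest.approx(
            12 * 0.16 / 3)

    def test_mean_hu(self):
        assert mean_hu(_lesion([0, 10, 20])) == 10.0
        assert mean_hu(_lesion([50] * 9)) == 50.0

    def test_mean_hu_equals_firstorder_mean(self, rng):
        lesion = make_random_lesion(rng)
        assert mean_hu(lesion) == compute_firstorder(lesion)["fo_mean"]


class TestAucDeLong:
    def test_four_point_example(self):
        roc = auc_delong([0.2, 0.8, 0.6, 0.4], [0, 1, 0, 1])
        assert roc.auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        roc = auc_delong([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert roc.auc == 1.0
        assert roc.variance == 0.0
        assert roc.ci == (1.0, 1.0)

    def test_matches_pair_counting_on_100_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 60))
            labels = np.concatenate([[0, 1], rng.integers(0, 2, size=n - 2)])
            scores = np.round(rng.normal(size=n), 1)  # induce ties
            roc = auc_delong(scores, labels)
            assert roc.auc == pytest.approx(auc_oracle(scores, labels),
                                            abs=1e-10)

    def test_invariant_under_monotone_transform(self, rng):
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        scores = rng.normal(size=50)
        a = auc_delong(scores, labels)
        b = auc_delong(np.exp(3 * scores), labels)
        assert b.auc == pytest.approx(a.auc, abs=1e-12)
        assert b.variance == pytest.approx(a.variance, abs=1e-12)

    def test_one_class_raises(self):
        with pytest.raises(ValueError):
            auc_delong([0.1, 0.2], [1, 1])

    def test_ci_contains_auc_within_unit_interval(self, rng):
        for _ in range(20):
            labels = np.concatenate([[0, 1], rng.integers(0, 2, size=30)])
            scores = rng.normal(size=32)
            roc = auc_delong(scores, labels)
            assert 0.0 <= roc.ci[0] <= roc.auc <= roc.ci[1] <= 1.0

    def test_variance_close_to_bootstrap(self, rng):
        """DeLong variance within 20% of a 2000-replicate bootstrap at n=200."""
        n = 200
        labels = np.array([0, 1] * (n // 2))
        scores = rng.normal(size=n) + 0.8 * labels
        roc = auc_delong(scores, labels)
        boot = []
        for _ in range(2000):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(labels[idx])) < 2:
                continue
            boot.append(auc_delong(scores[idx], labels[idx]).auc)
        boot_var = np.var(boot, ddof=1)
        assert roc.variance == pytest.approx(boot_var, rel=0.2)


class TestCompareDeLong:
    def test_shifted_scores_are_rank_identical_hence_degenerate(self, rng):
        labels = np.array([0, 1] * 20)
        scores = rng.normal(size=40)
        cmp = compare_delong(auc_delong(scores, labels),
                             auc_delong(scores + 5.0, labels))
        assert cmp.auc_difference == pytest.approx(0.0)
        assert cmp.degenerate

    def test_z_sign_flips_on_swap(self, rng):
        labels = np.array([0, 1] * 30)
        a = auc_delong(rng.normal(size=60) + labels, labels)
        b = auc_delong(rng.normal(size=60) + 0.2 * labels, labels)
        fwd = compare_delong(a, b)
        rev = compare_delong(b, a)
        assert fwd.z == pytest.approx(-rev.z)
        assert fwd.p_value == pytest.approx(rev.p_value)
        assert np.sign(fwd.z) == np.sign(fwd.auc_difference)

    def test_mismatched_labels_rejected(self, rng):
        a = auc_delong(rng.normal(size=10), [0, 1] * 5)
        b = auc_delong(rng.normal(size=10), [1, 0] * 5)
        with pytest.raises(ValueError):
            compare_delong(a, b)

    def test_type_one_error_rate_sanity(self, rng):
        """Small null simulation; the full 2000-replicate check runs in the
        acceptance suite."""
        rejections = 0
        n_sim = 300
        for _ in range(n_sim):
            labels = np.array([0, 1] * 30)
            a = auc_delong(rng.normal(size=60), labels)
            b = auc_delong(rng.normal(size=60), labels)
            cmp = compare_delong(a, b)
            rejections += cmp.p_value < 0.05
        assert 0.02 <= rejections / n_sim <= 0.09


class TestLogisticBaseline:
    def test_label_valued_predictor_gives_auc_one(self):
        y_tr = np.array([0, 1] * 20)
        y_val = np.array([0, 1] * 10)
        roc = univariate_logistic_baseline(y_tr.astype(float), y_tr,
                                           y_val.astype(float), y_val)
        assert roc.auc == 1.0

    def test_validation_auc_equals_raw_predictor_auc(self, rng):
        """Logistic scoring is monotone in a single predictor."""
        x_tr = rng.normal(size=80)
        y_tr = (x_tr + rng.normal(size=80) > 0).astype(int)
        x_val = rng.normal(size=40)
        y_val = (x_val + rng.normal(size=40) > 0).astype(int)
        roc = univariate_logistic_baseline(x_tr, y_tr, x_val, y_val)
        assert roc.auc == pytest.approx(auc_oracle(x_val, y_val), abs=1e-10)

    def test_uninformative_categories_near_half(self, rng):
        aucs = []
        for rep in range(30):
            r = np.random.default_rng(rep)
            x_tr = r.integers(0, 3, size=120)
            y_tr = r.integers(0, 2, size=120)
            x_val = r.integers(0, 3, size=120)
            y_val = r.integers(0, 2, size=120)
            roc = univariate_logistic_baseline(x_tr, y_tr, x_val, y_val,
                                               categorical=True)
            aucs.append(roc.auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.06)


class TestChiSquare:
    def test_balanced_table_statistic_zero(self):
        stat, p = chi_square_balance([[10, 10], [10, 10]])
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_diagonal_table_hand_value(self):
        stat, _ = chi_square_balance([[20, 0], [0, 20]])
        assert stat == pytest.approx(40.0)

    def test_matches_textbook_formula_on_random_tables(self, rng):
        for _ in range(100):
            table = rng.integers(1, 50, size=(int(rng.integers(2, 4)),
                                              int(rng.integers(2, 4))))
            stat, p = chi_square_balance(table)
            assert stat == pytest.approx(chi2_oracle(table), abs=1e-10)
            df = (table.shape[0] - 1) * (table.shape[1] - 1)
            assert p == pytest.approx(stats.chi2.sf(stat, df), abs=1e-12)

    def test_zero_margin_dropped_with_warning(self):
        with pytest.warns(UserWarning):
            stat, _ = chi_square_balance([[10, 5], [0, 0], [3, 8]])
        assert np.isfinite(stat)
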