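"""Agreement metrics, volume statistics, ICC and the cluster-number sweep."""

import numpy as np
import pytest

import infarctseg as iseg
from infarctseg.evaluation import (
    ConfusionCounts,
    cohen_kappa,
    confusion,
    delta_vol,
    icc_volumes,
    predictive_metrics,
    similarity_index,
    sweep_cluster_number,
)

from conftest import make_mask
from _oracles import dice_from_sets, icc21_mean_squares


def random_mask_pair(rng, shape=(6, 6, 3)):
    a = rng.uniform(size=shape) > 0.7
    b = rng.uniform(size=shape) > 0.7
    return a, b


class TestConfusion:
    def test_identical_masks(self):
        rng = np.random.default_rng(0)
        a, _ = random_mask_pair(rng)
        mask = make_mask(np.ones(a.shape, dtype=np.uint8))
        c = confusion(a, a, mask)
        assert c.fp == c.fn == 0
        assert c.tp == a.sum()

    def test_empty_auto(self):
        ref = np.zeros((4, 4, 2), dtype=bool)
        ref[0, 0, 0] = ref[1, 1, 1] = True
        mask = make_mask(np.ones(ref.shape, dtype=np.uint8))
        c = confusion(np.zeros_like(ref), ref, mask)
        assert (c.tp, c.fn) == (0, 2)

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 1), dtype=bool)
        r = np.zeros_like(a)
        a[:2, 0, 0] = True
        r[2:, 0, 0] = True
        mask = make_mask(np.ones(a.shape, dtype=np.uint8))
        c = confusion(a, r, mask)
        assert (c.tp, c.fp, c.fn) == (0, 2, 2)

    def test_counts_only_inside_mask(self):
        a = np.ones((4, 4, 1), dtype=bool)
        mask_data = np.zeros(a.shape, dtype=np.uint8)
        mask_data[:2] = 1
        c = confusion(a, a, make_mask(mask_data))
        assert c.total == 8

    def test_shape_mismatch_rejected(self):
        mask = make_mask(np.ones((4, 4, 1), dtype=np.uint8))
        with pytest.raises(ValueError, match="shape"):
            confusion(np.zeros((4, 4, 1), bool), np.zeros((4, 4, 2), bool), mask)


class TestSimilarityIndex:
    @pytest.mark.parametrize(
        "c, expected",
        [(ConfusionCounts(3, 90, 1, 1), 0.75),
         (ConfusionCounts(10, 90, 0, 0), 1.0),
         (ConfusionCounts(0, 90, 3, 2), 0.0)],
    )
    def test_formula(self, c, expected):
        assert similarity_index(c) == pytest.approx(expected)

    def test_undefined_when_both_masks_empty(self):
        assert np.isnan(similarity_index(ConfusionCounts(0, 10, 0, 0)))

    def test_equals_independent_dice_on_random_pairs(self):
        rng = np.random.default_rng(1)
        mask = make_mask(np.ones((6, 6, 3), dtype=np.uint8))
        for _ in range(50):
            a, b = random_mask_pair(rng)
            si = similarity_index(confusion(a, b, mask))
            oracle = dice_from_sets(np.argwhere(a), np.argwhere(b))
            if np.isnan(oracle):
                assert np.isnan(si)
            else:
                assert si == pytest.approx(oracle, abs=0)


class TestKappa:
    def test_identical_masks_kappa_one(self):
        assert cohen_kappa(ConfusionCounts(5, 95, 0, 0)) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        """tp=40, fp=10, fn=10, tn=40: p_o = 0.8, p_e = 0.5, kappa = 0.6."""
        assert cohen_kappa(ConfusionCounts(40, 40, 10, 10)) == pytest.approx(0.6)

    def test_matches_sklearn_on_random_tables(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.uniform(size=400) > 0.8
            b = rng.uniform(size=400) > 0.8
            c = ConfusionCounts(
                tp=int((a & b).sum()), tn=int((~a & ~b).sum()),
                fp=int((a & ~b).sum()), fn=int((~a & b).sum()),
            )
            assert cohen_kappa(c) == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)

    def test_kappa_near_zero_for_independent_masks(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(size=200_000) > 0.5
        b = rng.uniform(size=200_000) > 0.5
        c = ConfusionCounts(
            tp=int((a & b).sum()), tn=int((~a & ~b).sum()),
            fp=int((a & ~b).sum()), fn=int((~a & b).sum()),
        )
        assert abs(cohen_kappa(c)) < 0.01


class TestPredictiveMetrics:
    def test_sensitivity(self):
        sen, _, _, _ = predictive_metrics(ConfusionCounts(88, 0, 0, 12))
        assert sen == pytest.approx(0.88)

    def test_perfect_ppv_when_no_false_positives(self):
        _, _, ppv, _ = predictive_metrics(ConfusionCounts(5, 10, 0, 3))
        assert ppv == 1.0

    def test_empty_auto_gives_nan_ppv(self):
        _, _, ppv, _ = predictive_metrics(ConfusionCounts(0, 10, 0, 3))
        assert np.isnan(ppv)


class TestDeltaVol:
    def test_printed_convention_reproduces_published_rows(self):
        assert round(100 * delta_vol(46.828, 54.497), 1) == 16.4
        assert round(100 * delta_vol(482.939, 429.534), 1) == -11.1

    def test_equal_volumes_zero(self):
        assert delta_vol(2.0, 2.0) == 0.0

    def test_alternative_sign_convention(self):
        assert delta_vol(2.0, 1.0, printed_convention=False) == pytest.approx(0.5)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            delta_vol(0.0, 1.0)


class TestICC:
    def test_identical_columns_icc_one(self):
        v = [1.0, 2.0, 5.0, 9.0]
        assert icc_volumes(v, v) == pytest.approx(1.0)

    def test_constant_offset_penalized(self):
        """absolute agreement: a large systematic offset drives the ICC well
        below the perfect Pearson correlation of the two columns."""
        ref = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert icc_volumes(ref, ref + 10.0) < 0.5

    def test_matches_mean_squares_oracle(self):
        ref = [0.399, 2.141, 46.828, 482.939]
        auto = [0.381, 3.232, 54.497, 429.534]
        assert icc_volumes(ref, auto) == pytest.approx(
            icc21_mean_squares(ref, auto), abs=1e-9
        )

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            icc_volumes([1.0, 2.0], [1.0, 2.0])


class TestCohortTable:
    def test_cohort_loads_with_22_patients(self):
        df = iseg.load_reference_cohort()
        assert len(df) == 22
        assert df["si_pct"].between(0, 100).all()

    def test_volume_icc_high_as_published(self):
        """the published volume agreement: ICC ~0.99 over the cohort."""
        df = iseg.load_reference_cohort()
        assert icc_volumes(df["vol_semi_ml"], df["vol_auto_ml"]) > 0.98


class TestSweep:
    def test_single_k_returns_single_pair(self, normalized_triple, default_bundle):
        dwi, _, mask = normalized_triple
        curve = sweep_cluster_number(
            dwi, mask, default_bundle.truth, [25], iseg.PipelineConfig(seed=1)
        )
        assert len(curve) == 1
        k, si = curve[0]
        assert k == 25
        assert 0.0 <= si <= 1.0

    def test_reference_matching_label_scores_unity(self, normalized_triple, default_bundle):
        """when the reference equals the infarct blob, the overlapping label
        reproduces it and the sweep SI reaches ~1 at an adequate K."""
        dwi, _, mask = normalized_triple
        curve = sweep_cluster_number(
            dwi, mask, default_bundle.truth, [50], iseg.PipelineConfig(seed=1)
        )
        assert curve[0][1] >= 0.95

    def test_empty_reference_rejected(self, normalized_triple):
        dwi, _, mask = normalized_triple
        with pytest.raises(ValueError, match="reference"):
            sweep_cluster_number(dwi, mask, np.zeros(dwi.shape, bool), [10])
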