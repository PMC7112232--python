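import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ssikit import ise
from ssikit.ise import (
    ConfusionCounts,
    DescriptorRange,
    Filter,
    ISEConfig,
    ISEModel,
    best_range_per_descriptor,
    build_model,
    build_range_pool,
    eliminate_ranges,
    enumerate_subranges,
    evaluate_filter,
    filter_space_size,
    load_model,
    mbi_score,
    mcc,
    model_to_json,
    roc_auc,
    run_ise_fold,
    sample_filters,
    save_model,
    score_molecules,
    score_table,
    stratified_folds,
)
from ssikit.synthdata import PlantedDescriptorSpec, gen_descriptor_dataset


class TestEnumerateSubranges:
    def test_matches_brute_force_at_small_n(self):
        for n in (2, 3, 5, 8):
            brute = [(i, j) for i in range(n) for j in range(n) if i < j]
            assert sorted(enumerate_subranges(n)) == sorted(brute)

    def test_count_formula(self):
        assert len(enumerate_subranges(2)) == 1
        assert len(enumerate_subranges(5)) == 10
        assert len(enumerate_subranges(100)) == 4950

    def test_rejects_degenerate_grid(self):
        with pytest.raises(ValueError):
            enumerate_subranges(1)


class TestMCC:
    def test_perfect_and_inverted(self):
        assert mcc(ConfusionCounts(tp=10, fp=0, tn=100, fn=0)) == 1.0
        assert mcc(ConfusionCounts(tp=0, fp=10, tn=0, fn=100)) == -1.0

    def test_hand_computed_value(self):
        assert mcc(ConfusionCounts(tp=3, fp=1, tn=5, fn=1)) == pytest.approx(14 / 24)

    def test_zero_denominator_convention(self):
        assert mcc(ConfusionCounts(tp=5, fp=5, tn=0, fn=0)) == 0.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            mcc(ConfusionCounts(tp=0, fp=0, tn=0, fn=0))

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    def test_bounded(self, tp, fp, tn, fn):
        if tp + fp + tn + fn == 0:
            return
        assert -1.0 <= mcc(ConfusionCounts(tp, fp, tn, fn)) <= 1.0


class TestEvaluateFilter:
    def _six_molecule_case(self):
        # 2 actives in range, 1 active out; 1 inactive in, 2 inactives out
        data = pd.DataFrame({"x": [0.5, 0.6, 0.9, 0.55, 0.05, 0.95]})
        labels = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        return data, labels, [DescriptorRange("x", 0.4, 0.7)]

    def test_hand_constructed_counts(self):
        data, labels, ranges = self._six_molecule_case()
        counts, m = evaluate_filter(ranges, data, labels)
        assert (counts.tp, counts.fn, counts.fp, counts.tn) == (2, 1, 1, 2)
        assert m == pytest.approx((4 - 1) / math.sqrt(3 * 3 * 3 * 3))

    def test_perfect_filter(self):
        data = pd.DataFrame({"x": [0.5, 0.6, 0.1, 0.9]})
        labels = np.array([1, 1, 0, 0], dtype=bool)
        counts, m = evaluate_filter([DescriptorRange("x", 0.4, 0.7)], data, labels)
        assert m == 1.0

    def test_whole_space_filter_is_uninformative(self):
        data = pd.DataFrame({"x": np.linspace(0, 1, 20)})
        labels = np.arange(20) < 3
        counts, m = evaluate_filter([DescriptorRange("x", 0.0, 1.0)], data, labels)
        assert counts.tp == 3 and counts.fp == 17 and m == 0.0

    def test_missing_column_rejected(self):
        data = pd.DataFrame({"x": [1.0, 2.0]})
        with pytest.raises(KeyError):
            evaluate_filter([DescriptorRange("y", 0, 1)], data, np.array([True, False]))


class TestBestRange:
    def test_perfectly_separated_classes(self, rng):
        values = np.concatenate([rng.uniform(0.4, 0.6, 50), rng.uniform(0.8, 1.0, 50)])
        labels = np.arange(100) < 50
        (lo, hi), m = best_range_per_descriptor(values, labels)
        assert m == 1.0
        assert lo <= values[labels].min() and values[labels].max() <= hi < values[~labels].min()

    def test_recovers_planted_interval_at_large_n(self, rng):
        values = np.concatenate([rng.uniform(0.4, 0.6, 1000), rng.uniform(0, 1, 1000)])
        labels = np.arange(2000) < 1000
        (lo, hi), _ = best_range_per_descriptor(values, labels)
        jaccard = (min(hi, 0.6) - max(lo, 0.4)) / (max(hi, 0.6) - min(lo, 0.4))
        assert jaccard >= 0.8

    def test_uninformative_labels_give_small_mcc(self, rng):
        values = rng.uniform(0, 1, 500)
        labels = rng.random(500) < 0.5
        _, m = best_range_per_descriptor(values, labels)
        assert abs(m) < 0.2

    def test_constant_descriptor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            best_range_per_descriptor(np.ones(10), np.arange(10) < 5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            best_range_per_descriptor(np.linspace(0, 1, 10), np.ones(10, dtype=bool))

    def test_zero_slack_is_the_literal_argmax(self, rng):
        values = np.concatenate([rng.uniform(0.3, 0.5, 30), rng.uniform(0, 1, 600)])
        labels = np.arange(630) < 30
        (lo, hi), m = best_range_per_descriptor(values, labels, slack_scale=0.0)
        # oracle: exhaustive scan over every grid window
        edges = np.linspace(values.min(), values.max(), 101)
        best = -2.0
        for i, j in itertools.combinations(range(101), 2):
            inside = (values >= edges[i]) & (values <= edges[j])
            counts = ConfusionCounts(
                tp=int((inside & labels).sum()), fp=int((inside & ~labels).sum()),
                tn=int((~inside & ~labels).sum()), fn=int((~inside & labels).sum()),
            )
            best = max(best, mcc(counts))
        assert m == pytest.approx(best, abs=1e-12)


class TestSampleFilters:
    def test_deterministic_under_seed(self):
        a = sample_filters(20, (4, 5), 500, np.random.default_rng(7))
        b = sample_filters(20, (4, 5), 500, np.random.default_rng(7))
        assert a == b

    def test_structure(self):
        for combo in sample_filters(20, (4, 5), 1000, np.random.default_rng(0)):
            assert len(combo) in (4, 5)
            assert len(set(combo)) == len(combo)
            assert combo == tuple(sorted(combo))

    def test_pool_too_small(self):
        with pytest.raises(ValueError):
            sample_filters(3, (4, 5), 10, np.random.default_rng(0))

    def test_descriptor_frequency_is_uniform(self):
        from scipy.stats import chisquare

        combos = sample_filters(20, (4, 5), 100_000, np.random.default_rng(3))
        counts = np.zeros(20)
        for combo in combos:
            for j in combo:
                counts[j] += 1
        _, p = chisquare(counts)
        assert p > 0.001


class TestEliminateRanges:
    def _pool(self, n):
        return [DescriptorRange(f"d{i}", 0.0, 1.0) for i in range(n)]

    def test_worst_biased_range_eliminated(self):
        # 200 filters, decile = 20.  Range 0: 60 appearances (expected 6 per
        # decile), all 20 worst-decile slots and none of the best decile ->
        # 20 > 2*6 and 0 < 0.5*6 -> eliminated.  Range 1: everything else,
        # owns the best decile -> kept.
        cfg = ISEConfig()
        sample = []
        for k in range(200):
            combo = (0,) if (k < 20 or 100 <= k < 140) else (1,)
            sample.append((combo, float(k)))
        keep, log = eliminate_ranges(sample, self._pool(2), cfg)
        assert 0 not in keep and 1 in keep

    def test_uniformly_spread_range_kept(self):
        cfg = ISEConfig()
        sample = [((k % 2,), float(k)) for k in range(400)]
        keep, log = eliminate_ranges(sample, self._pool(2), cfg)
        assert keep == [0, 1]

    def test_best_only_range_kept(self):
        cfg = ISEConfig()
        sample = [((0,), float(k)) for k in range(100)]
        sample += [((1,), float(100 + k)) for k in range(100)]  # range 1 owns the top
        keep, _ = eliminate_ranges(sample, self._pool(2), cfg)
        assert 1 in keep

    def test_direct_rule_arithmetic(self):
        cfg = ISEConfig()
        # 1000 filters; range 0 appears 100x total: 40 in worst decile, 0 in best
        sample = []
        idx = 0
        for k in range(1000):
            if k < 40 or (400 <= k < 460):
                combo = (0,)
            elif k >= 900:
                combo = (2,)
            else:
                combo = (1,)
            sample.append((combo, float(k)))
        keep, log = eliminate_ranges(sample, self._pool(3), cfg)
        # expected for range 0 = 100 * 0.1 = 10; worst 40 > 2*10; best 0 < 0.5*10
        assert 0 not in keep
        assert log and log[0]["descriptor"] == "d0"

    def test_insufficient_evidence_skips(self):
        cfg = ISEConfig()
        sample = [((0,), float(k)) for k in range(20)]
        keep, log = eliminate_ranges(sample, self._pool(1), cfg)
        assert keep == [0] and "skipped" in log[0]


class TestRunIseFold:
    def _toy(self, n_desc=6, seed=0):
        spec = PlantedDescriptorSpec(
            n_actives=25, n_inactives=600, n_signal_descriptors=3,
            n_noise_descriptors=n_desc - 3, seed=seed,
        )
        table, truth = gen_descriptor_dataset(spec)
        return table.drop(columns=["label"]), table["label"].to_numpy(dtype=bool), truth

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_top_mcc_equals_brute_force_oracle(self, seed):
        """Exhaustive-regime search must equal independent brute-force enumeration."""
        feat, labels, _ = self._toy(seed=seed)
        cfg = ISEConfig(max_filters=50)
        ensemble = run_ise_fold(feat, labels, cfg, np.random.default_rng(seed))
        pool = build_range_pool(feat, labels, cfg)
        best = -2.0
        for size in cfg.filter_sizes:
            for combo in itertools.combinations(pool, size):
                _, m = evaluate_filter(list(combo), feat, labels)
                best = max(best, m)
        assert ensemble[0].mcc == pytest.approx(best, abs=1e-12)

    def test_planted_descriptors_recovered(self):
        spec = PlantedDescriptorSpec(seed=2)
        table, truth = gen_descriptor_dataset(spec)
        feat = table.drop(columns=["label"])
        labels = table["label"].to_numpy(dtype=bool)
        ensemble = run_ise_fold(feat, labels, ISEConfig(), np.random.default_rng(2))
        overlap = set(ensemble[0].descriptors) & set(truth["signal_descriptors"])
        assert len(overlap) >= 2

    def test_empty_active_class_rejected(self):
        feat = pd.DataFrame(np.random.default_rng(0).uniform(size=(50, 6)))
        feat.columns = [f"d{i}" for i in range(6)]
        with pytest.raises(ValueError, match="actives"):
            run_ise_fold(feat, np.zeros(50, dtype=bool), ISEConfig(), np.random.default_rng(0))

    def test_elimination_path_converges_and_recovers(self):
        """With >10^6 combinations the stochastic elimination loop must engage."""
        spec = PlantedDescriptorSpec(n_noise_descriptors=56, seed=1)  # C(60,4)+C(60,5) > 1e6
        table, truth = gen_descriptor_dataset(spec)
        feat = table.drop(columns=["label"])
        labels = table["label"].to_numpy(dtype=bool)
        cfg = ISEConfig(sample_size=20_000, max_filters=200)
        assert filter_space_size(60, cfg.filter_sizes) >= cfg.exhaustive_threshold
        ensemble = run_ise_fold(feat, labels, cfg, np.random.default_rng(1))
        overlap = set(ensemble[0].descriptors) & set(truth["signal_descriptors"])
        assert len(overlap) >= 2

    def test_fraction_keep_mode_restricts_to_near_top(self):
        feat, labels, _ = self._toy()
        cfg = ISEConfig(keep_mode="fraction", mcc_fraction=0.8)
        ensemble = run_ise_fold(feat, labels, cfg, np.random.default_rng(0))
        top = ensemble[0].mcc
        assert all(f.mcc >= 0.8 * top for f in ensemble)
        cap_cfg = ISEConfig()
        cap_ensemble = run_ise_fold(feat, labels, cap_cfg, np.random.default_rng(0))
        assert len(cap_ensemble) >= len(ensemble)

    def test_stored_mcc_consistent_with_counts(self):
        feat, labels, _ = self._toy()
        ensemble = run_ise_fold(feat, labels, ISEConfig(max_filters=100), np.random.default_rng(0))
        for f in ensemble:
            assert f.mcc == pytest.approx(mcc(f.counts), abs=1e-12)


class TestBuildModel:
    def test_every_molecule_scored_once(self, planted_small):
        table, _ = planted_small
        model, held = build_model(table, table["label"].to_numpy(), ISEConfig(max_filters=100), seed=0)
        assert not held["mbi"].isna().any()
        assert set(held["fold"]) == set(range(5))
        # stratified: every fold holds out some actives
        assert (held.groupby("fold")["label"].sum() > 0).all()

    def test_planted_signal_gives_high_held_out_auc(self, planted_default):
        table, _ = planted_default
        model, held = build_model(table, table["label"].to_numpy(), seed=5)
        auc = roc_auc(held["mbi"].to_numpy(), held["label"].to_numpy().astype(bool))
        assert auc >= 0.95

    def test_permuted_labels_give_null_auc(self):
        spec = PlantedDescriptorSpec(n_actives=15, n_inactives=2985, seed=3)
        table, _ = gen_descriptor_dataset(spec)
        rng = np.random.default_rng(3)
        labels = rng.permutation(table["label"].to_numpy())
        model, held = build_model(table, labels, ISEConfig(max_filters=100), seed=3)
        auc = roc_auc(held["mbi"].to_numpy(), held["label"].to_numpy().astype(bool))
        assert 0.4 <= auc <= 0.6

    def test_too_few_actives_rejected(self):
        feat = pd.DataFrame(np.random.default_rng(0).uniform(size=(100, 6)),
                            columns=[f"d{i}" for i in range(6)])
        labels = np.zeros(100, dtype=int)
        labels[:3] = 1
        with pytest.raises(ValueError, match="actives"):
            build_model(feat, labels, seed=0)

    def test_seed_determinism_byte_identical(self, planted_small, tmp_path):
        table, _ = planted_small
        cfg = ISEConfig(max_filters=100)
        model1, held1 = build_model(table, table["label"].to_numpy(), cfg, seed=9)
        model2, held2 = build_model(table, table["label"].to_numpy(), cfg, seed=9)
        assert model_to_json(model1) == model_to_json(model2)
        assert held1.to_csv() == held2.to_csv()

    def test_serialization_roundtrip(self, planted_small, tmp_path):
        table, _ = planted_small
        model, _ = build_model(table, table["label"].to_numpy(), ISEConfig(max_filters=50), seed=1)
        path = tmp_path / "model.json"
        save_model(model, path)
        assert model_to_json(load_model(path)) == model_to_json(model)


class TestStratifiedFolds:
    def test_partition_is_stratified(self, rng):
        labels = np.zeros(1030, dtype=bool)
        labels[:30] = True
        fold = stratified_folds(labels, 5, rng)
        for f in range(5):
            assert labels[fold == f].sum() == 6
        counts = np.bincount(fold)
        assert counts.max() - counts.min() <= 1 + 1  # round-robin remainder


class TestMBIScore:
    def _filter(self, ranges, eff, ineff):
        counts = ConfusionCounts(tp=1, fp=1, tn=1, fn=1)
        return Filter(ranges=tuple(ranges), counts=counts, mcc=0.0,
                      efficiency=eff, inefficiency=ineff)

    def _model(self, filters):
        return ISEModel(filters=filters, descriptor_names=["x", "y"],
                        config=ISEConfig(), seed=0)

    def test_single_passing_filter(self):
        model = self._model([self._filter([DescriptorRange("x", 0, 1)], 0.8, 0.9)])
        assert mbi_score({"x": 0.5}, model)["mbi"] == pytest.approx(0.8)

    def test_pass_one_fail_one(self):
        model = self._model([
            self._filter([DescriptorRange("x", 0, 1)], 0.8, 0.5),
            self._filter([DescriptorRange("y", 0, 0.2)], 0.7, 0.9),
        ])
        out = mbi_score({"x": 0.5, "y": 0.9}, model)
        assert out["mbi"] == pytest.approx((0.8 - 0.9) / 2)
        assert out["passes"] == [True, False]

    def test_failing_everything_hits_lower_bound(self):
        model = self._model([
            self._filter([DescriptorRange("x", 0, 0.1)], 0.9, 1.0),
            self._filter([DescriptorRange("y", 0, 0.1)], 0.9, 1.0),
        ])
        assert mbi_score({"x": 0.5, "y": 0.5}, model)["mbi"] == -1.0

    def test_proportion_mode_bounds_on_real_model(self, planted_small, rng):
        table, _ = planted_small
        model, _ = build_model(table, table["label"].to_numpy(), ISEConfig(max_filters=100), seed=2)
        probe = pd.DataFrame(rng.uniform(-1, 2, size=(200, table.shape[1] - 1)),
                             columns=[c for c in table.columns if c != "label"])
        scores = score_molecules(model, probe)
        assert scores["mbi"].between(-1.0, 1.0).all()

    def test_missing_descriptor_rejected(self, planted_small):
        table, _ = planted_small
        model, _ = build_model(table, table["label"].to_numpy(), ISEConfig(max_filters=50), seed=2)
        with pytest.raises(KeyError):
            score_molecules(model, pd.DataFrame({"sig_1": [0.5]}))


class TestScoreTable:
    def test_perfect_and_reversed_separation(self):
        labels = np.array([1, 1, 0, 0], dtype=bool)
        _, auc = score_table(np.array([0.9, 0.8, 0.2, 0.1]), labels, [0.5])
        assert auc == 1.0
        _, auc = score_table(np.array([0.1, 0.2, 0.8, 0.9]), labels, [0.5])
        assert auc == 0.0

    def test_hand_ranked_case(self):
        scores = np.array([0.9, 0.8, 0.7, 0.1])
        labels = np.array([1, 0, 1, 0], dtype=bool)
        table, auc = score_table(scores, labels, [0.85])
        assert auc == pytest.approx(0.75)
        assert table.loc[0, "tp"] == 1 and table.loc[0, "fp"] == 0

    def test_cutoffs_are_strict(self):
        table, _ = score_table(np.array([0.85, 0.9]), np.array([True, False]), [0.85])
        assert table.loc[0, "tp"] == 0 and table.loc[0, "fp"] == 1

    def test_single_class_auc_undefined(self):
        with pytest.raises(ValueError, match="single-class"):
            score_table(np.array([0.1, 0.2]), np.array([True, True]), [0.0])

    def test_auc_matches_sklearn_oracle(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = np.round(rng.normal(size=500), 1)  # coarse values force ties
        labels = rng.random(500) < 0.1
        assert roc_auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


class TestFilterSpaceSize:
    def test_against_math_comb(self):
        assert filter_space_size(180, [5]) == math.comb(180, 5)
        assert filter_space_size(30, (4, 5)) == math.comb(30, 4) + math.comb(30, 5)
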