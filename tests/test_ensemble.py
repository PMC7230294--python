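from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pairedpls.ensemble import (
    EnsembleConfig,
    EnsembleError,
    aggregate_medians,
    class_breakdown,
    count_combinations,
    make_outer_split,
    run_ensemble,
    select_discriminant,
    stride_indices,
    unrank_combination,
    _BMRecord,
)
from pairedpls.panel import PairedDataset, SampleKey
from conftest import make_small_dataset


class TestCombinatorics:
    def test_thirty_choose_twenty(self):
        assert count_combinations(30, 20) == 30_045_015

    def test_choose_zero(self):
        for n in (0, 1, 17):
            assert count_combinations(n, 0) == 1

    def test_six_choose_three_by_enumeration(self):
        assert count_combinations(6, 3) == len(list(combinations(range(6), 3))) == 20

    def test_invalid_arguments(self):
        with pytest.raises(EnsembleError):
            count_combinations(3, 5)
        with pytest.raises(EnsembleError):
            count_combinations(-1, 0)

    @pytest.mark.parametrize("n,k", [(6, 3), (8, 4), (8, 1), (7, 7), (5, 0)])
    def test_unranking_reproduces_lexicographic_enumeration(self, n, k):
        expected = [list(c) for c in combinations(range(n), k)]
        got = [unrank_combination(r, n, k) for r in range(count_combinations(n, k))]
        assert got == expected

    def test_unrank_bounds(self):
        assert unrank_combination(0, 30, 20) == list(range(20))
        assert unrank_combination(count_combinations(30, 20) - 1, 30, 20) == list(range(10, 30))
        with pytest.raises(EnsembleError, match="out of range"):
            unrank_combination(count_combinations(6, 3), 6, 3)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.integers(1, 9), st.data())
    def test_unranking_is_monotone_and_valid(self, n, data):
        k = data.draw(st.integers(0, n))
        total = count_combinations(n, k)
        r = data.draw(st.integers(0, total - 1))
        subset = unrank_combination(r, n, k)
        assert sorted(set(subset)) == subset and len(subset) == k
        if r + 1 < total:
            assert subset < unrank_combination(r + 1, n, k)  # lexicographic order


class TestStride:
    def test_paper_shaped_sampling(self):
        ranks = stride_indices(30_045_015, 1287)
        assert len(ranks) == 23_345
        assert ranks[0] == 0 and ranks[-1] == 1287 * 23_344

    def test_stride_one_yields_all(self):
        assert stride_indices(10, 1) == list(range(10))

    def test_stride_beyond_total(self):
        assert stride_indices(10, 100, offset=3) == [3]

    def test_offset_beyond_total_is_empty(self):
        assert stride_indices(10, 2, offset=10) == []


class TestOuterSplit:
    @pytest.mark.parametrize("n_pairs,expected", [(40, (30, 10)), (39, (30, 9))])
    def test_study_arm_sizes(self, n_pairs, expected):
        pairs = [f"P{i}" for i in range(n_pairs)]
        split = make_outer_split(pairs, seed=0)
        assert (len(split.trainval_pairs), len(split.test_pairs)) == expected
        assert set(split.trainval_pairs) | set(split.test_pairs) == set(pairs)
        assert not set(split.trainval_pairs) & set(split.test_pairs)

    def test_seed_determinism(self):
        pairs = [f"P{i}" for i in range(40)]
        assert make_outer_split(pairs, seed=5) == make_outer_split(pairs, seed=5)
        other = make_outer_split(pairs, seed=6)
        assert other != make_outer_split(pairs, seed=5)
        assert len(other.trainval_pairs) == 30

    def test_too_few_pairs(self):
        with pytest.raises(EnsembleError, match="at least 8"):
            make_outer_split(["a"] * 7, seed=0)


def _small_run(small_panel, effects, seed=0, **cfg_kwargs):
    ds, truth = make_small_dataset(
        small_panel, n_pairs=12, effects=effects, seed=seed
    )
    cfg = EnsembleConfig(
        inner_train_size=6, target_n_models=150, seed=seed + 50, **cfg_kwargs
    )
    return run_ensemble(ds, cfg), truth, ds


class TestRunEnsemble:
    def test_deterministic_end_to_end(self, small_panel):
        r1, _, _ = _small_run(small_panel, [("Ala", 0.9)])
        r2, _, _ = _small_run(small_panel, [("Ala", 0.9)])
        pd.testing.assert_frame_equal(r1.models, r2.models)
        pd.testing.assert_series_equal(r1.median_vip, r2.median_vip)
        pd.testing.assert_frame_equal(r1.median_coords, r2.median_coords)

    def test_single_model_degenerate_ensemble(self, small_panel):
        ds, _ = make_small_dataset(small_panel, n_pairs=12,
                                   effects=[("Ala", 1.0)], seed=1)
        total = count_combinations(9, 6)
        res = run_ensemble(ds, EnsembleConfig(inner_train_size=6, stride=total,
                                              seed=3))
        assert res.n_models == 1
        row = res.models.iloc[0]
        assert res.median_val_auroc == row["val_auroc"]
        assert res.median_val_p == row["val_p"]
        if row["is_bm"]:
            assert res.median_test_auroc == row["test_auroc"]

    def test_no_pair_split_across_sets(self, small_panel):
        res, _, ds = _small_run(small_panel, [("Ala", 0.9)])
        assert not set(res.split.trainval_pairs) & set(res.split.test_pairs)
        tv_patients = {s.patient_id for s in res.trainval_samples}
        assert tv_patients == set(res.split.trainval_pairs)
        # both states of every trainval patient present in the coordinates
        states = {}
        for s in res.trainval_samples:
            states.setdefault(s.patient_id, set()).add(s.state)
        assert all(v == {"IC", "OC"} for v in states.values())

    def test_strong_effects_pass_criterion(self, strong_run):
        res = strong_run["result"]
        assert res.n_bm > 0
        assert res.median_test_auroc >= 0.8
        assert res.passed

    def test_monotone_effect_size(self, small_panel):
        """Doubling every planted log-fold effect never decreases the median
        test AUROC (checked over 3 seeds)."""
        effects = [("Ala", 0.35), ("C2", -0.3), ("Gly", 0.3)]
        doubled = [(m, 2 * e) for m, e in effects]
        for seed in range(3):
            base, _, _ = _small_run(small_panel, effects, seed=seed,
                                    bm_threshold=0.8)
            strong, _, _ = _small_run(small_panel, doubled, seed=seed,
                                      bm_threshold=0.8)
            if np.isnan(base.median_test_auroc):
                continue  # no BMs at the weaker effect: trivially not worse
            assert strong.median_test_auroc >= base.median_test_auroc - 1e-12

    def test_label_permutation_destroys_test_performance(self, small_panel):
        """Swapping each pair's IC/OC labels at random removes the class
        signal: median test AUROC falls into the chance band."""
        ds, _ = make_small_dataset(small_panel, n_pairs=16,
                                   effects=[("Ala", 1.2), ("Gly", 1.0)], seed=2)
        rng = np.random.default_rng(9)
        flip = {p: rng.random() < 0.5 for p in ds.patients}
        samples = [
            SampleKey(s.patient_id,
                      {"IC": "OC", "OC": "IC"}[s.state] if flip[s.patient_id] else s.state,
                      s.matrix)
            for s in ds.samples
        ]
        permuted = PairedDataset(samples, list(ds.metabolites), ds.values.copy(),
                                 ds.flags.copy())
        res = run_ensemble(permuted, EnsembleConfig(inner_train_size=8,
                                                    target_n_models=200,
                                                    bm_threshold=0.7, seed=4))
        assert 0.3 <= res.median_test_auroc <= 0.7

    def test_zero_bm_result_is_explicit(self, small_panel, caplog):
        ds, _ = make_small_dataset(small_panel, n_pairs=16, effects=[], seed=5)
        with caplog.at_level("WARNING", logger="pairedpls"):
            res = run_ensemble(ds, EnsembleConfig(inner_train_size=6,
                                                  target_n_models=50,
                                                  bm_threshold=1.0, seed=6))
        assert res.n_bm == 0  # null data, 6v6 validation, threshold 1.0
        assert not res.passed
        assert np.isnan(res.median_test_auroc)
        assert res.median_vip.isna().all()
        assert any("zero_best_models" in r.message for r in caplog.records)


class TestAggregation:
    def _record(self, rank, loadings, vip, coords, oriented=None):
        return _BMRecord(
            rank=rank,
            x_loadings=np.asarray(loadings, float),
            oriented_loading=np.asarray(
                oriented if oriented is not None else loadings, float
            )[:, 0],
            vip=np.asarray(vip, float),
            coords=np.asarray(coords, float),
        )

    def test_single_bm_is_identity(self):
        bm = self._record(0, [[0.5, 0.1], [0.2, -0.3]], [1.2, 0.6],
                          [[1.0, 2.0], [-1.0, 0.5]])
        mv, ml, coords = aggregate_medians([bm], ["a", "b"])
        np.testing.assert_allclose(mv, bm.vip)
        np.testing.assert_allclose(coords, bm.coords)

    def test_sign_flipped_models_align(self):
        L = np.array([[0.5, 0.1], [0.2, -0.3]])
        C = np.array([[1.0, 2.0], [-1.0, 0.5]])
        a = self._record(0, L, [1.0, 1.0], C, oriented=L)
        b = self._record(1, -L, [1.0, 1.0], -C, oriented=L)  # exact sign flip
        _, ml, coords = aggregate_medians([a, b], ["a", "b"])
        np.testing.assert_allclose(coords, C)
        np.testing.assert_allclose(ml, L[:, 0])

    def test_hand_median_vip(self):
        recs = [
            self._record(i, [[0.1, 0.1]], [v], [[0.0, 0.0]])
            for i, v in enumerate([0.5, 1.0, 1.5])
        ]
        mv, _, _ = aggregate_medians(recs, ["m"])
        assert mv["m"] == pytest.approx(1.0)

    def test_empty_bm_set_rejected(self):
        with pytest.raises(EnsembleError, match="empty"):
            aggregate_medians([], ["m"])


class TestSelection:
    def test_threshold_crossing(self, kit_panel, strong_run):
        res = strong_run["result"]
        sel = select_discriminant(res, kit_panel, vip_threshold=1.0)
        assert (sel["median_vip"] >= 1.0).all()
        assert list(sel["median_vip"]) == sorted(sel["median_vip"], reverse=True)
        assert set(sel["direction"]) <= {"increased", "decreased"}
        assert sum(class_breakdown(sel).values()) == len(sel)

    def test_all_below_threshold_gives_empty_table(self, kit_panel, strong_run):
        res = strong_run["result"]
        sel = select_discriminant(res, kit_panel, vip_threshold=1e9)
        assert sel.empty

    def test_ground_truth_recovery(self, strong_run, kit_panel):
        res = strong_run["result"]
        truth = strong_run["truth"]
        sel = set(select_discriminant(res, kit_panel)["metabolite_id"])
        planted = truth.discriminant_set & set(res.metabolites)
        nulls = set(res.metabolites) - truth.discriminant_set
        assert len(sel & planted) / len(planted) >= 0.8
        assert len(sel & nulls) / len(nulls) <= 0.1

    def test_direction_sign_consistent_with_planted_effects(self, strong_run, kit_panel):
        res = strong_run["result"]
        truth = strong_run["truth"]
        sel = select_discriminant(res, kit_panel)
        directions = dict(zip(sel["metabolite_id"], sel["direction"]))
        hits = misses = 0
        for m, eff in truth.effects.items():
            if m in directions:
                expected = "increased" if eff > 0 else "decreased"
                hits += directions[m] == expected
                misses += directions[m] != expected
        assert hits > 0 and misses == 0
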