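"""Binned likelihood model, LOO-CV, resampling and stability scores."""

import numpy as np
import pandas as pd
import pytest

import recurra as r
from recurra.classifier import INDETERMINATE, patient_distance_pools
from recurra.ordination import Ordination


class TestBinnedModel:
    def test_hand_counted_separated_classes(self):
        model = r.fit_binned_model([0.12, 0.15], [0.31, 0.35, 0.38])
        assert model.n_bins == 4
        assert model.p_recurrence[1] == pytest.approx(0.0)   # [0.1, 0.2)
        assert model.p_recurrence[3] == pytest.approx(1.0)   # [0.3, 0.4)
        assert np.isnan(model.p_recurrence[0])
        assert np.isnan(model.p_recurrence[2])

    def test_identical_distributions_give_half_everywhere(self):
        vals = [0.05, 0.15, 0.15, 0.25]
        model = r.fit_binned_model(vals, vals)
        defined = ~np.isnan(model.p_recurrence)
        assert np.allclose(model.p_recurrence[defined], 0.5)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        model = r.fit_binned_model(rng.random(40), rng.random(25) * 1.4)
        defined = ~np.isnan(model.p_recurrence)
        p_rem = 1.0 - model.p_recurrence[defined]
        assert np.allclose(model.p_recurrence[defined] + p_rem, 1.0)
        freq = model.freq_remission + model.freq_recurrence
        norm = model.freq_recurrence / np.where(freq > 0, freq, 1)
        assert np.allclose(model.p_recurrence[defined], norm[defined])

    def test_class_swap_complements_probabilities(self):
        rng = np.random.default_rng(1)
        a, b = rng.random(30), rng.random(50) * 0.8 + 0.1
        m1 = r.fit_binned_model(a, b)
        m2 = r.fit_binned_model(b, a)
        d = ~np.isnan(m1.p_recurrence)
        assert np.array_equal(d, ~np.isnan(m2.p_recurrence))
        assert np.allclose(m1.p_recurrence[d], 1.0 - m2.p_recurrence[d])

    def test_class_normalization_removes_imbalance(self):
        # same shape, 10x count imbalance: normalized model stays at 0.5
        rem = [0.15] * 10
        rec = [0.15] * 100
        assert r.fit_binned_model(rem, rec).p_recurrence[1] == pytest.approx(0.5)
        raw = r.fit_binned_model(rem, rec, class_normalized=False)
        assert raw.p_recurrence[1] == pytest.approx(100 / 110)

    def test_ceiling_and_overflow_binning(self):
        model = r.fit_binned_model([0.05], [0.35])
        assert model.edges[-1] == pytest.approx(0.4)
        assert model.bin_of(0.99) == model.n_bins - 1

    @pytest.mark.parametrize("bad", [([], [0.1]), ([0.1], []), ([-0.1], [0.1])])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            r.fit_binned_model(*bad)

    def test_nonpositive_bin_width_rejected(self):
        with pytest.raises(ValueError):
            r.fit_binned_model([0.1], [0.2], bin_width=0.0)


class TestPredict:
    @pytest.fixture
    def model(self):
        return r.fit_binned_model([0.12, 0.15], [0.31, 0.35, 0.38])

    def test_all_distances_in_pure_bins(self, model):
        pred = r.predict_recurrence(model, [0.33, 0.39])
        assert pred.probability == pytest.approx(1.0)
        assert pred.predicted == "recurrence"

    def test_balanced_bins_yield_indeterminate(self):
        model = r.fit_binned_model([0.1] * 8 + [0.3] * 2, [0.1] * 2 + [0.3] * 8)
        # bins have P=0.2 and P=0.8; their mean is exactly 0.5
        pred = r.predict_recurrence(model, [0.1, 0.3])
        assert pred.probability == pytest.approx(0.5)
        assert pred.predicted == INDETERMINATE

    def test_undefined_bin_contributes_prior(self, model):
        pred = r.predict_recurrence(model, [0.25])  # empty bin in training
        assert pred.probability == pytest.approx(0.5)

    def test_order_invariance(self, model):
        d = [0.12, 0.33, 0.38, 0.05]
        p1 = r.predict_recurrence(model, d).probability
        p2 = r.predict_recurrence(model, d[::-1]).probability
        assert p1 == pytest.approx(p2)

    def test_negative_distance_rejected(self, model):
        with pytest.raises(ValueError):
            r.predict_recurrence(model, [-0.1])


class TestLoocv:
    def test_separable_classes_fully_recovered(self):
        pools = {
            "rem1": [0.05, 0.1], "rem2": [0.08, 0.12], "rem3": [0.11],
            "rec1": [0.45, 0.5], "rec2": [0.41], "rec3": [0.55, 0.48],
        }
        labels = {p: ("remission" if p.startswith("rem") else "recurrence") for p in pools}
        preds, summary = r.loocv(pools, labels)
        assert summary["accuracy"] == 1.0
        assert summary["n_patients"] == len(preds) == 6
        assert all(p.winning_probability == pytest.approx(1.0) for p in preds)

    def test_holdout_never_in_training(self, monkeypatch):
        """Instrumented fit: training pools never contain held-out values."""
        pools = {
            "a": [0.111], "b": [0.222], "c": [0.333],
            "d": [0.444], "e": [0.555], "f": [0.666],
        }
        labels = dict(zip(pools, ["remission"] * 3 + ["recurrence"] * 3))
        seen = []
        import recurra.classifier as mod
        orig = mod.fit_binned_model

        def spy(rem, rec, **kw):
            seen.append(set(np.concatenate([rem, rec]).tolist()))
            return orig(rem, rec, **kw)

        monkeypatch.setattr(mod, "fit_binned_model", spy)
        r.loocv(pools, labels)
        assert len(seen) == 6
        for (held, vals), train in zip(pools.items(), seen):
            assert vals[0] not in train

    def test_empty_class_fold_is_error(self):
        pools = {"a": [0.1], "b": [0.2], "c": [0.5]}
        labels = {"a": "remission", "b": "recurrence", "c": "recurrence"}
        with pytest.raises(ValueError, match="holding out 'a'"):
            r.loocv(pools, labels)

    def test_shuffled_labels_break_recovery(self):
        """Label permutation on separable data drives accuracy to chance."""
        rng = np.random.default_rng(0)
        accs = []
        for s in range(60):
            pools = {}
            labels = {}
            names = [f"p{k}" for k in range(6)]
            truths = ["remission"] * 3 + ["recurrence"] * 3
            for name, lab in zip(names, truths):
                loc = 0.1 if lab == "remission" else 0.5
                pools[name] = rng.normal(loc, 0.02, size=4).clip(0)
            shuffled = rng.permutation(truths)
            labels = dict(zip(names, shuffled))
            _, summary = r.loocv(pools, labels)
            accs.append(summary["accuracy"])
        assert 0.3 <= np.mean(accs) <= 0.7


class TestSingleBiopsyResampling:
    def _null_matrix(self, n_biopsies=18, n_ctrl=24, seed=0):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n_biopsies + n_ctrl, 4))
        from scipy.spatial.distance import pdist, squareform

        ids = [f"b{i}" for i in range(n_biopsies)] + [f"c{i}" for i in range(n_ctrl)]
        return r.DistanceMatrix(ids, squareform(pdist(pts))), ids

    def _patients(self, n_biopsies=18):
        pats = {f"p{k}": [f"b{3 * k + j}" for j in range(3)] for k in range(6)}
        labels = {f"p{k}": ("remission" if k < 3 else "recurrence") for k in range(6)}
        return pats, labels

    def test_reps_one_is_binary(self):
        D, ids = self._null_matrix()
        pats, labels = self._patients()
        ctrl = [s for s in ids if s.startswith("c")]
        out = r.single_biopsy_resampling(D, pats, labels, ctrl, reps=1, seed=5)
        assert out["fraction_significant"] in (0.0, 1.0)

    def test_deterministic_per_seed(self):
        D, ids = self._null_matrix()
        pats, labels = self._patients()
        ctrl = [s for s in ids if s.startswith("c")]
        a = r.single_biopsy_resampling(D, pats, labels, ctrl, reps=500, seed=9)
        b = r.single_biopsy_resampling(D, pats, labels, ctrl, reps=500, seed=9)
        assert a["fraction_significant"] == b["fraction_significant"]

    def test_strong_separation_always_significant(self):
        rng = np.random.default_rng(1)
        pts = np.vstack(
            [
                rng.normal(0, 0.01, size=(9, 2)),        # remission biopsies
                rng.normal([8, 0], 0.01, size=(9, 2)),   # recurrence biopsies
                rng.normal([0, 4], 0.01, size=(24, 2)),  # controls
            ]
        )
        from scipy.spatial.distance import pdist, squareform

        ids = [f"b{i}" for i in range(18)] + [f"c{i}" for i in range(24)]
        D = r.DistanceMatrix(ids, squareform(pdist(pts)))
        pats, labels = self._patients()
        ctrl = [s for s in ids if s.startswith("c")]
        out = r.single_biopsy_resampling(D, pats, labels, ctrl, reps=300, seed=3)
        assert out["fraction_significant"] >= 0.99

    def test_too_few_patients_is_error(self):
        D, ids = self._null_matrix()
        pats = {"p0": ["b0"], "p1": ["b1"], "p2": ["b2"]}
        labels = {"p0": "remission", "p1": "recurrence", "p2": "recurrence"}
        with pytest.raises(ValueError, match="2 patients"):
            r.single_biopsy_resampling(D, pats, labels, ["c0", "c1", "c2"], reps=10)


class TestCombinationTests:
    def _coords(self, counts, seed=0, sep=0.0):
        rng = np.random.default_rng(seed)
        out = {}
        labels = {}
        for k, c in enumerate(counts):
            lab = "remission" if k < len(counts) // 2 else "recurrence"
            shift = 0.0 if lab == "remission" else sep
            out[f"p{k}"] = rng.normal(shift, 1.0, size=(c, 3))
            labels[f"p{k}"] = lab
        return out, labels

    def test_printed_combination_count(self):
        coords, labels = self._coords([3, 3, 3, 3, 3, 2])
        res = r.combination_tests(coords, np.zeros(3), labels)
        assert res["n_combinations"] == 486
        assert len(res["p_values"]) == 486

    def test_all_singletons_one_combination(self):
        coords, labels = self._coords([1, 1, 1, 1])
        res = r.combination_tests(coords, np.zeros(3), labels)
        assert res["n_combinations"] == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_count_equals_product_of_counts(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(1, 5, size=6).tolist()
        coords, labels = self._coords(counts, seed=seed)
        res = r.combination_tests(coords, np.zeros(3), labels)
        assert res["n_combinations"] == int(np.prod(counts))

    def test_exhaustive_matches_monte_carlo_limit(self):
        """Random re-draws of combinations converge to the exhaustive fraction."""
        coords, labels = self._coords([3, 3, 3, 3, 3, 2], seed=2, sep=2.0)
        res = r.combination_tests(coords, np.zeros(3), labels)
        rng = np.random.default_rng(0)
        pats = list(coords)
        reps = 50000
        picks = np.column_stack(
            [rng.integers(0, len(coords[p]), size=reps) for p in pats]
        )
        dists = np.column_stack(
            [
                np.linalg.norm(coords[p], axis=1)[picks[:, j]]
                for j, p in enumerate(pats)
            ]
        )
        from recurra.classifier import _welch_p_rows

        rem = [j for j, p in enumerate(pats) if labels[p] == "remission"]
        rec = [j for j, p in enumerate(pats) if labels[p] == "recurrence"]
        mc = float((_welch_p_rows(dists[:, rem], dists[:, rec]) < 0.05).mean())
        assert abs(mc - res["fraction_significant"]) < 0.02

    def test_dimension_mismatch_is_error(self):
        coords, labels = self._coords([2, 2, 2, 2])
        with pytest.raises(ValueError, match="mismatch"):
            r.combination_tests(coords, np.zeros(5), labels)


class TestStability:
    def test_identical_timepoints_score_zero(self):
        ids = ["s1", "s2"]
        coords = np.array([[1.0, 1.0], [1.0, 1.0]])
        ordn = Ordination(ids, coords, np.array([1.0]), np.array([1.0]), 0.0)
        meta = r.SampleMetadata(pd.DataFrame(
            {
                "sample_id": ids, "patient_id": ["p1", "p1"],
                "cohort": ["crohns"] * 2, "procedure": ["surgery", "colonoscopy"],
                "timepoint": [1, 2], "site": ["ileum"] * 2, "inflamed": [False] * 2,
            }
        ))
        st = r.stability_through_time(meta, ordn=ordn)
        assert st["p1"] == pytest.approx(0.0)

    def test_single_biopsy_per_timepoint_is_plain_distance(self):
        ids = ["s1", "s2"]
        coords = np.array([[0.0, 0.0], [3.0, 4.0]])
        ordn = Ordination(ids, coords, np.array([1.0]), np.array([1.0]), 0.0)
        meta = r.SampleMetadata(pd.DataFrame(
            {
                "sample_id": ids, "patient_id": ["p1", "p1"],
                "cohort": ["crohns"] * 2, "procedure": ["surgery", "colonoscopy"],
                "timepoint": [1, 2], "site": ["ileum"] * 2, "inflamed": [False] * 2,
            }
        ))
        st = r.stability_through_time(meta, ordn=ordn)
        assert st["p1"] == pytest.approx(5.0)

    def test_missing_timepoint_skipped(self, small_cohort):
        _, tree, table, meta = small_cohort
        D = r.unifrac_matrix(tree, table)
        ordn = r.pcoa(D)
        st = r.stability_through_time(meta, ordn=ordn)
        # controls only have one timepoint, so only Crohn's patients scored
        assert set(st) == {p for p, o in meta.outcomes().items() if o != "unknown"}

    def test_within_surgery_mode_mean_pairwise(self, small_cohort):
        _, tree, table, meta = small_cohort
        D = r.unifrac_matrix(tree, table)
        st = r.stability_through_time(meta, D=D, mode="within-surgery")
        pat = next(iter(st))
        ids = meta.select(patient_id=pat, timepoint=1)["sample_id"].tolist()
        want = D.submatrix(ids).condensed().mean()
        assert st[pat] == pytest.approx(want)


class TestPools:
    def test_pool_variants_shapes(self, small_cohort):
        _, tree, table, meta = small_cohort
        D = r.unifrac_matrix(tree, table)
        n_surg_ctrl = len(meta.select(cohort="control", procedure="surgery"))
        n_ctrl = len(meta.select(cohort="control"))
        pools_s, labels = patient_distance_pools(D, meta, pool="surgical-controls")
        pools_a, _ = patient_distance_pools(D, meta, pool="all-controls")
        pools_t, _ = patient_distance_pools(D, meta, pool="through-time")
        assert set(labels.values()) == {"remission", "recurrence"}
        for p in pools_s:
            assert len(pools_s[p]) == 3 * n_surg_ctrl
            assert len(pools_a[p]) == 3 * n_ctrl
            assert len(pools_t[p]) == 9  # 3 surgical x 3 post-op biopsies
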