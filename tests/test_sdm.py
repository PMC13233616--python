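import itertools

import numpy as np
import pandas as pd
import pytest

import divprior as dp
from divprior import sdm, synthetic as syn


class TestScreenPredictors:
    def test_duplicate_layer_dropped(self, rng):
        x = rng.normal(size=100)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=100)})
        retained, dropped = sdm.screen_predictors(df, 0.85)
        assert len(retained) == 2
        assert len(set(retained) & {"a", "b"}) == 1

    def test_uncorrelated_identity(self, rng):
        df = pd.DataFrame(rng.normal(size=(500, 4)), columns=list("abcd"))
        retained, dropped = sdm.screen_predictors(df, 0.85)
        assert retained == list("abcd") and dropped == []

    def test_constant_dropped_first(self, rng):
        df = pd.DataFrame({"k": np.ones(50), "a": rng.normal(size=50)})
        retained, dropped = sdm.screen_predictors(df, 0.85)
        assert dropped == ["k"]

    def test_matches_exhaustive_policy_check(self, rng):
        """4-predictor fixture with a known correlation graph: the retained
        set must be feasible (all |r| <= bound) and reproduce the stated
        drop policy step by step."""
        n = 4000
        z = rng.normal(size=n)
        df = pd.DataFrame(
            {
                "a": z + 0.05 * rng.normal(size=n),
                "b": z + 0.05 * rng.normal(size=n),
                "c": rng.normal(size=n),
                "d": rng.normal(size=n),
            }
        )
        retained, dropped = sdm.screen_predictors(df, 0.85)
        corr = df[retained].corr().abs().values
        np.fill_diagonal(corr, 0)
        assert corr.max() <= 0.85
        # brute force: some subset obeying the bound must equal the result,
        # and the policy (drop larger mean |r| from the worst pair) fixes it
        feasible = []
        for k in range(1, 5):
            for combo in itertools.combinations(df.columns, k):
                c = df[list(combo)].corr().abs().values
                np.fill_diagonal(c, 0)
                if c.size == 1 or c.max() <= 0.85:
                    feasible.append(set(combo))
        assert set(retained) in feasible
        full = df.corr().abs()
        worst_pair = ("a", "b")  # only pair above the bound
        means = {p: full.loc[p].drop(p).mean() for p in worst_pair}
        victim = max(worst_pair, key=lambda p: (means[p], p))
        assert set(retained) == set(df.columns) - {victim}


class TestPseudoAbsences:
    def test_full_available_set(self):
        domain = np.arange(20)
        sets = sdm.sample_pseudo_absences(domain, 15, set(range(5)), n_sets=1,
                                          seed=3)
        assert np.array_equal(sets[0], np.arange(5, 20))

    def test_disjoint_from_presences(self):
        domain = np.arange(100)
        presences = set(range(0, 100, 3))
        sets = sdm.sample_pseudo_absences(domain, 30, presences, n_sets=2, seed=1)
        for s in sets:
            assert presences.isdisjoint(int(c) for c in s)

    def test_determinism_and_set_independence(self):
        domain = np.arange(200)
        a = sdm.sample_pseudo_absences(domain, 50, set(), n_sets=2, seed=9)
        b = sdm.sample_pseudo_absences(domain, 50, set(), n_sets=2, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
        assert not np.array_equal(a[0], a[1])

    def test_insufficient_cells_rejected(self):
        with pytest.raises(ValueError, match="available"):
            sdm.sample_pseudo_absences(np.arange(10), 8, set(range(5)), seed=0)


class TestSplit:
    def test_seventy_thirty(self):
        pts = pd.DataFrame({"cell": np.arange(20),
                            "label": [1] * 10 + [0] * 10})
        train, test = sdm.split_train_test(pts, 0.7, seed=2)
        assert (train["label"] == 1).sum() == 7
        assert (test["label"] == 1).sum() == 3

    def test_partition(self):
        pts = pd.DataFrame({"cell": np.arange(30), "label": [1] * 12 + [0] * 18})
        train, test = sdm.split_train_test(pts, 0.7, seed=5)
        assert len(train) + len(test) == 30
        assert set(train.index).isdisjoint(test.index)

    def test_determinism(self):
        pts = pd.DataFrame({"cell": np.arange(30), "label": [1] * 12 + [0] * 18})
        a, _ = sdm.split_train_test(pts, 0.7, seed=5)
        b, _ = sdm.split_train_test(pts, 0.7, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_degenerate_class_rejected(self):
        pts = pd.DataFrame({"cell": [1, 2, 3], "label": [1, 1, 0]})
        with pytest.raises(ValueError):
            sdm.split_train_test(pts, 0.7, seed=0)


class TestEvaluate:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.7, 0.2, 0.1])
        labels = np.array([1, 1, 1, 0, 0])
        st = sdm.evaluate_predictions(scores, labels)
        assert st.auc == 1.0
        assert st.tss == pytest.approx(1.0)

    def test_confusion_matrix_arithmetic(self):
        sens, spec, tss = sdm.stats_from_confusion(tp=40, fn=10, tn=45, fp=5)
        assert sens == pytest.approx(0.8)
        assert spec == pytest.approx(0.9)
        assert tss == pytest.approx(0.7)

    def test_tss_identity_holds(self, rng):
        scores = rng.random(200)
        labels = rng.integers(0, 2, 200)
        st = sdm.evaluate_predictions(scores, labels)
        assert st.tss == pytest.approx(st.sensitivity + st.specificity - 1)

    def test_null_auc_near_half(self):
        rng = np.random.default_rng(7)
        scores = rng.random(10_000)
        labels = rng.integers(0, 2, 10_000)
        st = sdm.evaluate_predictions(scores, labels)
        assert abs(st.auc - 0.5) <= 0.02

    def test_auc_invariant_under_monotone_transform(self, rng):
        scores = rng.random(300)
        labels = rng.integers(0, 2, 300)
        a = sdm.evaluate_predictions(scores, labels).auc
        b = sdm.evaluate_predictions(np.exp(3 * scores), labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_smallest_maximizing_threshold(self):
        scores = np.array([0.2, 0.2, 0.8, 0.8])
        labels = np.array([0, 0, 1, 1])
        st = sdm.evaluate_predictions(scores, labels)
        assert st.tss_max_threshold == pytest.approx(0.8)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            sdm.evaluate_predictions([0.5, 0.4], [1, 1])


class TestEnsemble:
    def _stats(self, tss, auc=0.9):
        return sdm.EvalStats(0.9, tss + 0.1, tss, auc, 0.5)

    def test_single_passing_model(self):
        maps = [np.array([0.1, 0.9]), np.array([0.5, 0.5])]
        stats = [self._stats(0.8), self._stats(0.2)]
        ens, passing = sdm.tss_weighted_ensemble(maps, stats)
        np.testing.assert_allclose(ens, maps[0], rtol=1e-12)
        assert passing == [0]

    def test_equal_tss_is_mean(self):
        maps = [np.zeros(4), np.ones(4)]
        stats = [self._stats(0.6), self._stats(0.6)]
        ens, _ = sdm.tss_weighted_ensemble(maps, stats)
        np.testing.assert_allclose(ens, 0.5)

    def test_weighted_mean_arithmetic(self):
        maps = [np.full(3, 0.2), np.full(3, 0.8)]
        stats = [self._stats(0.5), self._stats(0.75)]
        ens, _ = sdm.tss_weighted_ensemble(maps, stats)
        np.testing.assert_allclose(ens, (0.5 * 0.2 + 0.75 * 0.8) / 1.25)
        np.testing.assert_allclose(ens, 0.56)

    def test_bounded_by_members(self, rng):
        maps = [rng.random(50) for _ in range(4)]
        stats = [self._stats(t) for t in (0.5, 0.6, 0.7, 0.8)]
        ens, _ = sdm.tss_weighted_ensemble(maps, stats)
        lo = np.min(maps, axis=0)
        hi = np.max(maps, axis=0)
        assert (ens >= lo - 1e-12).all() and (ens <= hi + 1e-12).all()

    def test_none_passing_raises(self):
        with pytest.raises(sdm.NoPassingModelError):
            sdm.tss_weighted_ensemble([np.ones(2)], [self._stats(0.1)])


class TestBinarizeStack:
    def test_threshold_zero_all_presence(self):
        m = np.array([0.0, 0.3, 1.0])
        assert sdm.binarize(m, 0.0).tolist() == [1, 1, 1]

    def test_threshold_above_max_all_absence(self):
        m = np.array([0.0, 0.3, 0.9])
        assert sdm.binarize(m, 1.0).tolist() == [0, 0, 0]

    def test_idempotent_at_half(self):
        b = np.array([0, 1, 1, 0], dtype=np.int8)
        np.testing.assert_array_equal(sdm.binarize(b.astype(float), 0.5), b)

    def test_stack_single_species(self):
        cells = np.arange(4)
        b = np.array([1, 0, 1, 0])
        s = sdm.stack_richness({"a": b}, cells)
        np.testing.assert_array_equal(s.values, b)

    def test_disjoint_ranges(self):
        cells = np.arange(6)
        maps = {f"s{i}": np.eye(6, dtype=int)[i] for i in range(3)}
        s = sdm.stack_richness(maps, cells)
        assert s.values.max() == 1
        assert s.values.sum() == 3

    def test_matches_accumulation_oracle(self, rng):
        cells = np.arange(40)
        maps = {f"s{i}": (rng.random(40) < 0.3).astype(int) for i in range(12)}
        s = sdm.stack_richness(maps, cells)
        brute = [sum(maps[sp][j] for sp in maps) for j in range(40)]
        np.testing.assert_array_equal(s.values, brute)

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sdm.stack_richness({"a": np.ones(3), "b": np.ones(4)}, np.arange(3))


class TestChangeAssessment:
    def test_twenty_percent_growth(self):
        cur = {"a": np.array([1] * 10 + [0] * 5)}
        fut = {"a": np.array([1] * 12 + [0] * 3)}
        ca = sdm.change_assessment(cur, fut)
        assert ca.pct_change["a"] == pytest.approx(20.0)
        assert ca.species_class["a"] == "increase"

    def test_identical_maps_unchanged(self):
        m = {"a": np.array([1, 0, 1])}
        ca = sdm.change_assessment(m, {"a": m["a"].copy()})
        assert ca.pct_change["a"] == 0.0
        assert ca.species_class["a"] == "unchanged"
        np.testing.assert_array_equal(ca.delta_sr, 0)

    def test_three_species_fixture(self):
        cur = {
            "grow": np.array([1, 0, 0, 0]),
            "shrink": np.array([1, 1, 1, 0]),
            "static": np.array([0, 1, 0, 0]),
        }
        fut = {
            "grow": np.array([1, 1, 0, 0]),
            "shrink": np.array([1, 0, 0, 0]),
            "static": np.array([0, 1, 0, 0]),
        }
        ca = sdm.change_assessment(cur, fut)
        assert ca.class_fractions == {
            "increase": pytest.approx(1 / 3),
            "decrease": pytest.approx(1 / 3),
            "unchanged": pytest.approx(1 / 3),
        }

    def test_new_range_handling(self):
        ca = sdm.change_assessment(
            {"a": np.zeros(3, int)}, {"a": np.array([1, 0, 0])}
        )
        assert ca.species_class["a"] == "increase"
        assert np.isinf(ca.pct_change["a"])


class TestEnvelopeLearner:
    def test_inside_all_windows(self):
        X = pd.DataFrame({"p": np.linspace(0, 1, 20), "q": np.linspace(5, 9, 20)})
        y = np.ones(20, int)
        lrn = sdm.EnvelopeLearner(percentile=0).fit(X, y)
        mid = pd.DataFrame({"p": [0.5], "q": [7.0]})
        assert lrn.predict(mid)[0] == 1.0

    def test_outside_all_windows(self):
        X = pd.DataFrame({"p": np.linspace(0, 1, 20), "q": np.linspace(5, 9, 20)})
        lrn = sdm.EnvelopeLearner(percentile=0).fit(X, np.ones(20, int))
        far = pd.DataFrame({"p": [99.0], "q": [-50.0]})
        assert lrn.predict(far)[0] == 0.0

    def test_too_few_presences(self):
        X = pd.DataFrame({"p": [1.0, 2.0]})
        with pytest.raises(ValueError):
            sdm.EnvelopeLearner().fit(X, np.ones(2, int))

    def test_registry(self):
        assert isinstance(sdm.get_learner("envelope"), sdm.EnvelopeLearner)
        with pytest.raises(KeyError):
            sdm.get_learner("maxent")


def _envelope_world(seed=4):
    """Flat world with 3 independent predictors and 10 envelope species."""
    g = syn.make_landscape(30, 25, 50, 0.0, seed=seed)
    clim = syn.simulate_climate(
        g, ["p1", "p2", "p3"], seed=seed, engineer_collinear_pair=False,
        gradient_strength=1.0, noise_sigma=0.5, smooth=0.0,
    )
    cur = syn.predictors_as_frame(clim, g, "current")
    rng = np.random.default_rng(seed)
    species = {}
    for i in range(10):
        mask = np.ones(len(cur), dtype=bool)
        for col in cur.columns:
            lo_q = rng.uniform(0.05, 0.35)
            hi_q = lo_q + rng.uniform(0.35, 0.6)
            lo, hi = cur[col].quantile([lo_q, min(hi_q, 0.98)])
            mask &= (cur[col] >= lo) & (cur[col] <= hi)
        if mask.sum() < 30:  # ensure a usable range
            mask = cur["p1"] >= cur["p1"].quantile(0.5)
        species[f"sp{i}"] = cur.index.to_numpy()[mask]
    return g, cur, species


class TestEnvelopeRecovery:
    def test_single_species_range_recovery(self):
        """Max-TSS binarization recovers >= 90% of true-range cells."""
        g, cur, species = _envelope_world()
        sp, cells = next(iter(species.items()))
        res = sdm.run_species_sdm(
            sp, cells, {"current": cur}, n_runs=2, seed=3,
            learner_kwargs={"envelope": {"percentile": 0.0}},
        )
        pos = {int(c): i for i, c in enumerate(cur.index)}
        hit = sum(res.binary["current"][pos[int(c)]] for c in cells)
        assert hit / len(cells) >= 0.9

    def test_end_to_end_stacked_richness_mae(self):
        """10 noiseless envelope species: stacked SR recovered with
        per-cell MAE <= 1."""
        g, cur, species = _envelope_world()
        true_maps = {}
        pred_maps = {}
        rng = np.random.default_rng(11)
        for sp, cells in species.items():
            true = np.zeros(len(cur), dtype=int)
            pos = {int(c): i for i, c in enumerate(cur.index)}
            for c in cells:
                true[pos[int(c)]] = 1
            true_maps[sp] = true
            n_pres = min(200, len(cells))
            presences = rng.choice(cells, size=n_pres, replace=False)
            res = sdm.run_species_sdm(
                sp, presences, {"current": cur}, n_runs=2,
                seed=int(rng.integers(2**31 - 1)),
                learner_kwargs={"envelope": {"percentile": 0.0}},
            )
            pred_maps[sp] = res.binary["current"]
        true_sr = sdm.stack_richness(true_maps, cur.index.to_numpy()).values
        pred_sr = sdm.stack_richness(pred_maps, cur.index.to_numpy()).values
        mae = np.abs(true_sr - pred_sr).mean()
        assert mae <= 1.0
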