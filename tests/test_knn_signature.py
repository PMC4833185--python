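"""KNN-LOOCV outcome prediction: median t-statistic, folds, stability, selection."""

import numpy as np
import pandas as pd
import pytest

from wt1sig import (
    KnnConfig,
    SimulationConfig,
    ValidationError,
    knn_loocv,
    knn_predict,
    outcome_labels,
    rank_features,
    select_optimal_signature,
    simulate_series,
    stable_features,
    tstat_median,
)
from wt1sig.knn_signature import ADVERSE, FAVOURABLE, FoldRecord

from conftest import make_expr


def naive_knn_loocv(values, labels, k, n_features):
    """Brute-force oracle: plain loops, explicit median-t selection and voting."""
    n = values.shape[1]
    preds = []
    for i in range(n):
        train_idx = [j for j in range(n) if j != i]
        # median-t feature selection on the training fold
        stats = []
        for g in range(values.shape[0]):
            x = [values[g, j] for j in train_idx if labels[j] == ADVERSE]
            y = [values[g, j] for j in train_idx if labels[j] == FAVOURABLE]
            num = np.median(x) - np.median(y)
            den = np.sqrt(
                np.var(x, ddof=1) / len(x) + np.var(y, ddof=1) / len(y)
            )
            stats.append(abs(num / den) if den > 0 else (0.0 if num == 0 else 1e12))
        order = sorted(range(values.shape[0]), key=lambda g: (-stats[g], f"g{g}"))
        feats = order[:n_features]
        # z-score on training statistics
        mu = {g: np.mean([values[g, j] for j in train_idx]) for g in feats}
        sd = {g: np.std([values[g, j] for j in train_idx], ddof=1) or 1.0 for g in feats}
        dists = []
        for j in train_idx:
            d = sum(
                ((values[g, j] - mu[g]) / sd[g] - (values[g, i] - mu[g]) / sd[g]) ** 2
                for g in feats
            )
            dists.append((np.sqrt(d), j))
        dists.sort(key=lambda t: t[0])
        votes = [labels[j] for _, j in dists[:k]]
        n_adv = votes.count(ADVERSE)
        preds.append(ADVERSE if n_adv > len(votes) / 2 else FAVOURABLE)
    return preds


class TestTstatMedian:
    def test_equal_vectors(self):
        assert tstat_median([1, 2, 3], [1, 2, 3]) == 0.0

    def test_median_semantics_overrides_means(self):
        # medians agree although the means differ by 10/3
        assert tstat_median([0, 0, 10], [0, 0, 0]) == 0.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x, y = rng.normal(size=8), rng.normal(1, 2, size=5)
            assert tstat_median(x, y) == pytest.approx(-tstat_median(y, x))

    def test_hand_formula(self):
        x, y = [1.0, 2.0, 6.0], [0.0, 1.0, 2.0, 3.0]
        expected = (2.0 - 1.5) / np.sqrt(
            np.var(x, ddof=1) / 3 + np.var(y, ddof=1) / 4
        )
        assert tstat_median(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_caps(self):
        t = tstat_median([5.0, 5.0], [1.0, 1.0])
        assert t > 1e9

    def test_short_input_rejected(self):
        with pytest.raises(ValidationError):
            tstat_median([1.0], [1.0, 2.0])


class TestRankFeatures:
    def _labels(self, expr, adverse_idx):
        lab = [ADVERSE if i in adverse_idx else FAVOURABLE
               for i in range(len(expr.sample_ids))]
        return pd.Series(lab, index=expr.sample_ids)

    def test_recovers_planted_probes(self):
        hits = []
        for seed in range(3):
            cfg = SimulationConfig(
                n_samples=300, n_probes=300, n_signal_probes=25, seed=70 + seed
            )
            expr, clin, truth = simulate_series(cfg)
            ranked = rank_features(expr, outcome_labels(clin))
            top = set(ranked[:20])
            hits.append(len(top & set(truth.signal_probe_ids)) / 20)
        assert float(np.mean(hits)) >= 0.8

    def test_permuted_labels_give_chance_overlap(self):
        cfg = SimulationConfig(n_samples=300, n_probes=300, n_signal_probes=25, seed=73)
        expr, clin, truth = simulate_series(cfg)
        labels = outcome_labels(clin)
        rng = np.random.default_rng(1)
        perm = pd.Series(
            rng.permutation(labels.to_numpy()), index=labels.index
        )
        ranked = rank_features(expr, perm)
        k = len(truth.signal_probe_ids)
        overlap = len(set(ranked[:k]) & set(truth.signal_probe_ids)) / k
        # chance level is k / n_probes ~= 0.083
        assert overlap < 0.35

    def test_invariant_to_sample_order_and_constant_probes(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(12, 20))
        expr = make_expr(vals)
        labels = self._labels(expr, set(range(10)))
        base = rank_features(expr, labels)
        perm = rng.permutation(20)
        shuffled = make_expr(vals[:, perm],
                             samples=[expr.sample_ids[i] for i in perm])
        assert rank_features(shuffled, labels) == base
        padded = make_expr(
            np.vstack([vals, np.full((1, 20), 3.0)]),
            probes=expr.probe_ids + ["zz_const"],
        )
        assert rank_features(padded, labels)[:-1] == base

    def test_single_class_rejected(self):
        expr = make_expr(np.random.default_rng(0).normal(size=(3, 6)))
        labels = self._labels(expr, set(range(6)))
        with pytest.raises(ValidationError):
            rank_features(expr, labels)


class TestKnnLoocv:
    def test_hand_separable_example(self):
        expr = make_expr([[0.0, 0.1, 10.0, 10.1]])
        labels = pd.Series(
            [FAVOURABLE, FAVOURABLE, ADVERSE, ADVERSE], index=expr.sample_ids
        )
        cfg = KnnConfig(k_neighbours=1, n_features_grid=(2,))
        records = knn_loocv(expr, labels, cfg, n_features=1)
        assert all(r.predicted == r.true for r in records)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 21))
        p = int(rng.integers(2, 6))
        vals = rng.normal(size=(p, n))
        lab = np.array([ADVERSE] * (n // 2) + [FAVOURABLE] * (n - n // 2))
        rng.shuffle(lab)
        if len(set(lab)) < 2:
            lab[0] = ADVERSE
            lab[1] = FAVOURABLE
        expr = make_expr(vals)
        labels = pd.Series(lab, index=expr.sample_ids)
        cfg = KnnConfig(k_neighbours=3, n_features_grid=(2,))
        m = min(3, p)
        got = [r.predicted for r in knn_loocv(expr, labels, cfg, n_features=m)]
        want = naive_knn_loocv(vals, lab, k=3, n_features=m)
        assert got == want

    def test_agrees_with_sklearn_on_tie_free_data(self):
        from sklearn.neighbors import KNeighborsClassifier

        rng = np.random.default_rng(8)
        train = rng.normal(size=(4, 30))
        test = rng.normal(size=(4, 7))
        lab = np.array([ADVERSE] * 15 + [FAVOURABLE] * 15)
        cfg = KnnConfig(k_neighbours=3)
        mine = knn_predict(train, lab, test, cfg)
        mu = train.mean(axis=1, keepdims=True)
        sd = train.std(axis=1, ddof=1, keepdims=True)
        clf = KNeighborsClassifier(n_neighbors=3)
        clf.fit(((train - mu) / sd).T, lab)
        theirs = clf.predict(((test - mu) / sd).T)
        assert mine == list(theirs)

    def test_null_accuracy_near_majority_fraction(self):
        accs, majs = [], []
        for seed in range(5):
            cfg = SimulationConfig(
                n_samples=100, n_probes=60, n_signal_probes=5, seed=80 + seed,
                signal_loading_scale=0.0, driver_loading=0.0, hazard_coeff=0.0,
            )
            expr, clin, _ = simulate_series(cfg)
            labels = outcome_labels(clin)
            recs = knn_loocv(expr, labels, KnnConfig(), n_features=10)
            accs.append(np.mean([r.predicted == r.true for r in recs]))
            majs.append(labels.value_counts(normalize=True).max())
        assert abs(float(np.mean(accs)) - float(np.mean(majs))) < 0.10

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            KnnConfig(k_neighbours=2).validate()  # even k with majority vote
        with pytest.raises(ValidationError):
            KnnConfig(stability_threshold=0.0).validate()
        with pytest.raises(ValidationError):
            KnnConfig(distance="cosine").validate()


class TestStableFeatures:
    def _folds(self, lists):
        return [
            FoldRecord(held_out=f"s{i}", features=fl, predicted=ADVERSE, true=ADVERSE)
            for i, fl in enumerate(lists)
        ]

    def test_always_selected_is_kept(self):
        folds = self._folds([["a", "b"]] * 10)
        assert stable_features(folds, 0.9) == ["a", "b"]

    def test_eight_of_ten_is_dropped_at_ninety(self):
        lists = [["a", "b"]] * 8 + [["a"]] * 2
        assert stable_features(self._folds(lists), 0.9) == ["a"]

    def test_threshold_monotone(self):
        rng = np.random.default_rng(3)
        pool = [f"g{i}" for i in range(12)]
        lists = [list(rng.choice(pool, size=6, replace=False)) for _ in range(10)]
        strict = set(stable_features(self._folds(lists), 1.0))
        loose = set(stable_features(self._folds(lists), 0.9))
        assert strict <= loose

    def test_ordering_frequency_then_rank(self):
        lists = [["a", "b"], ["b", "a"], ["b", "c"]]
        # b in 3/3 folds, a in 2/3, c in 1/3
        out = stable_features(self._folds(lists), threshold=0.6)
        assert out == ["b", "a"]

    def test_empty_folds_rejected(self):
        with pytest.raises(ValidationError):
            stable_features([], 0.9)


class TestSelectOptimalSignature:
    def test_planted_recovery_and_report(self):
        cfg = SimulationConfig(n_samples=150, n_probes=200, n_signal_probes=25, seed=31)
        expr, clin, truth = simulate_series(cfg)
        # restrict to a plausible high-driver universe: signal + some nulls
        universe = list(truth.signal_probe_ids) + [
            p for p in expr.probe_ids if p not in set(truth.signal_probe_ids)
        ][:25]
        sub = expr.subset_probes(universe)
        knn = KnnConfig(n_features_grid=tuple(range(10, 41, 5)))
        sig, report = select_optimal_signature(sub, outcome_labels(clin), clin, knn)
        assert sig is not None
        frac_planted = len(set(sig.probes) & set(truth.signal_probe_ids)) / len(sig.probes)
        assert frac_planted >= 0.6
        assert set(report.index) == set(knn.n_features_grid)
        assert report["selected"].sum() == 1
        best = report[report["selected"]].iloc[0]
        assert best["logrank_p_efs"] < 0.01

    def test_requires_endpoints(self):
        rng = np.random.default_rng(0)
        expr = make_expr(rng.normal(size=(10, 20)))
        labels = pd.Series(
            [ADVERSE] * 10 + [FAVOURABLE] * 10, index=expr.sample_ids
        )
        clin_df = pd.DataFrame(
            {"rfs_time": np.ones(20), "rfs_event": np.zeros(20, int)},
            index=pd.Index(expr.sample_ids, name="sample_id"),
        )
        from wt1sig import ClinicalTable

        clin = ClinicalTable(clin_df)
        with pytest.raises(ValidationError, match="endpoint"):
            select_optimal_signature(expr, labels, clin, KnnConfig(n_features_grid=(5,)))
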