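"""Drug-wise CV, Spearman and ROC metrics against brute-force oracles."""

import warnings

import numpy as np
import pytest

from toxmark import (
    ExpressionMatrix,
    SymptomDataset,
    cross_validate,
    make_drug_folds,
    roc_auc,
    spearman,
)
from toxmark.errors import ConfigError, UndefinedMetricError


def oracle_spearman(a, b):
    """Rank-then-Pearson with hand-computed midranks."""

    def midrank(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    ra, rb = midrank(a), midrank(b)
    ra -= ra.mean()
    rb -= rb.mean()
    return float((ra @ rb) / np.sqrt((ra @ ra) * (rb @ rb)))


def oracle_auc(pred, occ):
    """Exhaustive concordant-pair counting with half credit for ties."""
    pos = pred[occ]
    neg = pred[~occ]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestFoldPlan:
    def test_even_drug_split(self, small_dataset):
        plan = make_drug_folds(small_dataset, k=4, seed=0)
        counts = np.bincount(list(plan.fold_of_drug.values()), minlength=4)
        assert counts.max() - counts.min() <= 1

    def test_twenty_drugs_ten_folds(self):
        ds = _toy_dataset(n_drugs=20, per_drug=3)
        plan = make_drug_folds(ds, k=10, seed=1)
        counts = np.bincount(list(plan.fold_of_drug.values()), minlength=10)
        assert np.all(counts == 2)

    def test_samples_inherit_drug_fold(self, small_dataset):
        plan = make_drug_folds(small_dataset, k=3, seed=2)
        fold = plan.fold_of_samples(small_dataset.drug_of)
        for d in set(small_dataset.drug_of):
            assert len(set(fold[small_dataset.drug_of == d])) == 1

    def test_deterministic(self, small_dataset):
        p1 = make_drug_folds(small_dataset, k=4, seed=5)
        p2 = make_drug_folds(small_dataset, k=4, seed=5)
        assert p1.fold_of_drug == p2.fold_of_drug

    def test_too_few_drugs(self, small_dataset):
        with pytest.raises(ConfigError):
            make_drug_folds(small_dataset, k=100, seed=0)


class TestSpearman:
    def test_monotone_identity(self):
        assert spearman([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)

    def test_reversal(self):
        assert spearman([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_ties_match_oracle(self):
        a = np.array([0, 0, 1, 2], float)
        b = np.array([0.1, 0.2, 0.9, 1.5])
        assert abs(spearman(a, b) - oracle_spearman(a, b)) < 1e-12

    def test_random_tied_fixtures_match_oracle(self, rng):
        for _ in range(20):
            a = rng.integers(0, 4, size=12).astype(float)
            b = np.round(rng.standard_normal(12), 1)
            if np.all(a == a[0]) or np.all(b == b[0]):
                continue
            assert abs(spearman(a, b) - oracle_spearman(a, b)) < 1e-12

    def test_constant_actual_undefined(self):
        with pytest.raises(UndefinedMetricError):
            spearman([1, 1, 1], [1, 2, 3])

    def test_invariant_under_monotone_transform(self, rng):
        a = rng.integers(0, 5, 30).astype(float)
        b = rng.standard_normal(30)
        assert spearman(a, b) == pytest.approx(spearman(a, np.exp(b)), abs=1e-12)


class TestRocAuc:
    def test_perfect_separation(self):
        occ = np.array([True] * 3 + [False] * 4)
        pred = np.array([3.0, 2.5, 2.0, 1.0, 0.5, 0.2, 0.0])
        _, auc = roc_auc(pred, occ)
        assert auc == 1.0

    def test_all_equal_predictions(self):
        occ = np.array([True, False, True, False])
        _, auc = roc_auc(np.ones(4), occ)
        assert auc == pytest.approx(0.5)

    def test_eight_sample_fixture_matches_pair_counting(self, rng):
        for _ in range(25):
            occ = np.array([True] * 3 + [False] * 5)
            pred = np.round(rng.standard_normal(8), 1)  # force some ties
            _, auc = roc_auc(pred, occ)
            assert auc == pytest.approx(oracle_auc(pred, occ), abs=1e-12)

    def test_complement_property(self, rng):
        occ = rng.random(20) < 0.4
        occ[0], occ[1] = True, False
        pred = rng.standard_normal(20)  # continuous, tie-free
        _, a1 = roc_auc(pred, occ)
        _, a2 = roc_auc(-pred, occ)
        assert a1 + a2 == pytest.approx(1.0, abs=1e-12)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc(np.array([1.0, 2.0]), np.array([True, True]))

    def test_threshold_semantics_ge(self):
        # threshold sweep uses prediction >= threshold as "positive"
        occ = np.array([True, True, False, False])
        pred = np.array([2.0, 1.0, 1.0, 0.0])
        points, auc = roc_auc(pred, occ)
        assert auc == pytest.approx(oracle_auc(pred, occ), abs=1e-12)
        at_1 = points[np.isclose(points[:, 2], 1.0)]
        assert at_1.shape[0] == 1
        # at threshold 1.0: both cases called (TPR 1), one control (FPR .5)
        assert at_1[0, 0] == pytest.approx(0.5)
        assert at_1[0, 1] == pytest.approx(1.0)


def _toy_dataset(n_drugs=12, per_drug=6, n_genes=40, seed=0):
    rng = np.random.default_rng(seed)
    n = n_drugs * per_drug
    drug_of = np.repeat([f"d{i}" for i in range(n_drugs)], per_drug).astype(object)
    sev = np.zeros(n, dtype=int)
    for i in range(0, n_drugs, 2):  # every other drug toxic
        sl = slice(i * per_drug, (i + 1) * per_drug)
        sev[sl] = np.minimum(np.arange(per_drug), 4)
    X = rng.standard_normal((n_genes, n))
    X[:5] += sev * 0.9  # informative genes
    ids = [f"s{i}" for i in range(n)]
    return SymptomDataset(
        X=ExpressionMatrix([f"g{i:03d}" for i in range(n_genes)], ids, X),
        severity=sev,
        occurrence=sev >= 1,
        drug_of=drug_of,
        symptom="necrosis",
    )


@pytest.fixture(scope="module")
def cv_result():
    ds = _toy_dataset()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return ds, cross_validate(
            ds, method="anova", m=8, k=4, n_models=4,
            rf_params={"n_trees": 5}, seed=3,
        )


class TestCrossValidate:
    def test_selection_never_sees_held_out_drugs(self):
        ds = _toy_dataset()
        plan_seen: list[tuple[int, set]] = []

        def hook(fold, ids):
            plan_seen.append((fold, set(ids)))

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            res = cross_validate(ds, method="anova", m=8, k=4, n_models=2,
                                 seed=1, selection_hook=hook)
        fold_of = res.fold_plan.fold_of_samples(ds.drug_of)
        ids = np.array(ds.sample_ids, dtype=object)
        for fold, seen in plan_seen:
            held_out = set(ids[fold_of == fold])
            assert not seen & held_out

    def test_train_test_drugs_disjoint(self, cv_result):
        ds, res = cv_result
        fold_of = res.fold_plan.fold_of_samples(ds.drug_of)
        for fold in range(res.fold_plan.k):
            train_drugs = set(ds.drug_of[fold_of != fold])
            test_drugs = set(ds.drug_of[fold_of == fold])
            assert not train_drugs & test_drugs

    def test_every_sample_predicted_once(self, cv_result):
        _, res = cv_result
        assert np.all(np.isfinite(res.predictions["predicted"]))

    def test_signal_detected(self, cv_result):
        _, res = cv_result
        assert res.pooled_scc > 0.3
        assert res.auc > 0.7

    def test_deterministic(self):
        ds = _toy_dataset()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            r1 = cross_validate(ds, method="ttest", m=8, k=4, n_models=3, seed=11)
            r2 = cross_validate(ds, method="ttest", m=8, k=4, n_models=3, seed=11)
        assert r1.pooled_scc == r2.pooled_scc
        np.testing.assert_array_equal(
            r1.predictions["predicted"], r2.predictions["predicted"]
        )

    def test_caseless_fold_recorded_undefined(self):
        # concentrate all cases in two drugs so some folds have no cases
        ds = _toy_dataset(n_drugs=8, per_drug=6)
        sev = np.zeros(ds.n_samples, dtype=int)
        sev[:18] = np.tile([0, 1, 2, 3, 4, 4], 3)  # cases live in 3 of 8 drugs
        ds = SymptomDataset(X=ds.X, severity=sev, occurrence=sev >= 1,
                            drug_of=ds.drug_of, symptom="necrosis")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            with pytest.warns(UserWarning, match="SCC undefined"):
                res = cross_validate(ds, method="ttest", m=4, k=4, n_models=2, seed=0)
        assert any(np.isnan(s) for s in res.fold_scc)
        assert np.isfinite(res.mean_fold_scc)

    def test_per_fold_normalization_mode_runs(self):
        ds = _toy_dataset()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            res = cross_validate(ds, method="anova", m=8, k=4, n_models=2,
                                 normalize="per-fold", seed=2)
        assert np.isfinite(res.pooled_scc)
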