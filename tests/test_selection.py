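"""Marker ranking: statistic oracles, tie rules, panel invariants."""

import numpy as np
import pytest
from scipy import stats

from toxmark import SymptomDataset, zscore_genes
from toxmark.errors import DegenerateLabelsError
from toxmark.selection import (
    MarkerSet,
    anova_f,
    select_markers,
    select_markers_anova,
    select_markers_slda,
    select_markers_ttest,
    welch_t,
)
from toxmark.slda import SldaModel, fit_slda


def oracle_anova(groups):
    """Textbook one-way ANOVA from sums of squares."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    dfb, dfw = len(groups) - 1, len(allv) - len(groups)
    F = (ssb / dfb) / (ssw / dfw)
    return F, stats.f.sf(F, dfb, dfw)


def oracle_welch(a, b):
    """Closed-form Welch t with Satterthwaite df."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t, 2 * stats.t.sf(abs(t), df)


class TestAnova:
    def test_matches_sums_of_squares_oracle(self, rng):
        labels = np.array([0] * 5 + [1] * 4 + [2] * 6)
        X = rng.standard_normal((15, 7))
        F, p = anova_f(X, labels)
        for g in range(7):
            groups = [X[labels == k, g] for k in (0, 1, 2)]
            Fo, po = oracle_anova(groups)
            assert abs(F[g] - Fo) < 1e-10
            assert abs(p[g] - po) < 1e-10

    def test_zero_within_variance_ranks_first(self):
        labels = np.array([0, 0, 1, 1])
        X = np.array([[0.0, 1.2], [0.0, 0.7], [1.0, 0.9], [1.0, 1.5]])
        F, p = anova_f(X, labels)
        assert np.isinf(F[0]) and p[0] == 0.0
        ms = select_markers_anova(X, labels, 2, ["gA", "gB"])
        assert ms.genes[0] == "gA"

    def test_identical_group_means_f_zero(self):
        labels = np.array([0, 0, 1, 1])
        X = np.array([[1.0], [3.0], [3.0], [1.0]])
        F, p = anova_f(X, labels)
        assert F[0] == 0.0 and p[0] == 1.0

    def test_small_groups_excluded(self, rng):
        # grade 2 has one member: dropped from the grouping, so the F
        # equals a two-group ANOVA on grades 0 and 1 alone
        labels = np.array([0, 0, 0, 1, 1, 1, 2])
        X = rng.standard_normal((7, 3))
        F, p = anova_f(X, labels)
        for g in range(3):
            Fo, po = oracle_anova([X[labels == 0, g], X[labels == 1, g]])
            assert abs(F[g] - Fo) < 1e-10 and abs(p[g] - po) < 1e-10

    def test_too_few_groups_degenerate(self, rng):
        with pytest.raises(DegenerateLabelsError):
            anova_f(rng.standard_normal((4, 2)), np.array([0, 0, 0, 1]))


class TestTtest:
    def test_matches_welch_oracle(self, rng):
        occ = np.array([True] * 6 + [False] * 9)
        X = rng.standard_normal((15, 5)) + occ[:, None] * 0.5
        t, p = welch_t(X, occ)
        for g in range(5):
            to, po = oracle_welch(X[occ, g], X[~occ, g])
            assert abs(t[g] - to) < 1e-10
            assert abs(p[g] - po) < 1e-10

    def test_equal_means_t_zero(self):
        occ = np.array([True, True, False, False])
        X = np.array([[1.0], [2.0], [2.0], [1.0]])
        t, p = welch_t(X, occ)
        assert t[0] == 0.0 and p[0] == 1.0

    def test_label_swap_symmetry(self, rng):
        occ = np.array([True] * 5 + [False] * 7)
        X = rng.standard_normal((12, 4))
        t1, p1 = welch_t(X, occ)
        t2, p2 = welch_t(X, ~occ)
        np.testing.assert_allclose(np.abs(t1), np.abs(t2), atol=1e-12)
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_pooled_variant_matches_scipy(self, rng):
        occ = np.array([True] * 5 + [False] * 7)
        X = rng.standard_normal((12, 3))
        t, p = welch_t(X, occ, variant="pooled")
        ref = stats.ttest_ind(X[occ], X[~occ], axis=0, equal_var=True)
        np.testing.assert_allclose(t, ref.statistic, atol=1e-12)

    def test_tiny_group_degenerate(self, rng):
        with pytest.raises(DegenerateLabelsError):
            welch_t(rng.standard_normal((3, 2)), np.array([True, False, False]))


class TestSldaSelection:
    def test_joint_signal_pair_chosen(self):
        # a two-gene discriminant toy: genes 2 and 3 carry the class
        # signal with opposite signs, genes 1 and 4 are noise
        rng = np.random.default_rng(9)
        y = np.repeat([0, 1, 2], 30)
        g2 = y * 1.5 + rng.standard_normal(90) * 0.4
        g3 = -y * 1.5 + rng.standard_normal(90) * 0.4
        X = np.column_stack([rng.standard_normal(90), g2, g3,
                             rng.standard_normal(90)])
        X = (X - X.mean(0)) / X.std(0)
        model = fit_slda(X, y, m=2, lam2=1e-3)
        ms = select_markers_slda(model, 2, gene_ids=["gene1", "gene2", "gene3", "gene4"])
        assert set(ms.genes) == {"gene2", "gene3"}

    def test_fewer_nonzero_than_m(self):
        model = SldaModel(
            directions=np.array([[0.5], [0.0], [-0.2], [0.0], [0.1], [0.0], [0.3]]),
            scores=np.array([[1.0], [-1.0]]),
            class_levels=[0, 1],
            lam2=0.0,
            m=7,
            direction_r2=np.array([1.0]),
        )
        ms = select_markers_slda(model, 32, gene_ids=[f"g{i}" for i in range(7)])
        assert len(ms) == 4  # only the non-zero loadings

    def test_tied_loadings_order_by_gene_id(self):
        model = SldaModel(
            directions=np.array([[0.5], [-0.5], [0.2]]),
            scores=np.array([[1.0], [-1.0]]),
            class_levels=[0, 1],
            lam2=0.0,
            m=3,
            direction_r2=np.array([1.0]),
        )
        ms = select_markers_slda(model, 2, gene_ids=["zz", "aa", "mm"])
        assert ms.genes == ["aa", "zz"]


class TestPanelInvariants:
    @pytest.mark.parametrize("m", [2, 4, 8, 16, 32, 64, 128, 256])
    @pytest.mark.parametrize("method", ["slda", "anova", "ttest"])
    def test_size_and_score_monotonicity(self, small_dataset, method, m):
        ds = small_dataset
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            Xz = zscore_genes(ds.X)
        ms = select_markers(
            Xz.values.T, ds.severity, ds.occurrence, Xz.gene_ids, method=method, m=m
        )
        assert len(ms) <= min(m, ds.X.n_genes)
        if method == "ttest":
            # p-ordering is the ranking rule; |t| is monotone only per-df
            _, p = welch_t(Xz.values.T, ds.occurrence)
            idx = {g: i for i, g in enumerate(Xz.gene_ids)}
            pr = [p[idx[g]] for g in ms.genes]
            assert np.all(np.diff(pr) >= -1e-15)
        else:
            assert np.all(np.diff(ms.scores) <= 1e-12)


class TestWeakPairRecovery:
    def test_joint_selection_beats_univariate_on_pair(self):
        """The correlated weak pair (each member individually weak, the
        pair jointly strong) is recovered by sparse LDA at a higher rate
        than by the per-gene ANOVA screen across 20 replicates."""
        import warnings

        from toxmark import build_dataset, simulate_cohort, zscore_genes
        from toxmark.simulate import SYMPTOM, weak_pair_scenario

        hits = {"slda": 0, "anova": 0}
        for seed in range(1, 21):
            expr, samples, truth = simulate_cohort(weak_pair_scenario(seed))
            ds = build_dataset(expr, samples, SYMPTOM)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                Xz = zscore_genes(ds.X)
            for meth in hits:
                mk = select_markers(
                    Xz.values.T, ds.severity, ds.occurrence, Xz.gene_ids,
                    method=meth, m=16,
                )
                if set(truth.weak_pair) <= set(mk.genes):
                    hits[meth] += 1
        assert hits["slda"] > hits["anova"], hits
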