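"""Rank and select candidate marker genes per symptom.

Three screens are offered, differing in what label information they use:

* ``slda``  — sparse discriminant loadings over severity groups (joint,
  multivariate; genes compete and cooperate within each direction);
* ``anova`` — per-gene one-way F across severity groups (univariate,
  severity-aware);
* ``ttest`` — per-gene two-sample t between occurrence groups
  (univariate, occurrence-only; severity grades are collapsed to
  present/absent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateLabelsError, ValidationError
from .slda import SldaModel, fit_slda

__all__ = [
    "MarkerSet",
    "select_markers_slda",
    "select_markers_anova",
    "select_markers_ttest",
    "anova_f",
    "welch_t",
]

METHODS = ("slda", "anova", "ttest")


@dataclass
class MarkerSet:
    """Ranked marker genes for one symptom and one selection method.

    ``scores`` carries the method's own statistic (max |loading| for
    slda, F for anova, |t| for ttest), aligned with ``genes`` from
    strongest to weakest.
    """

    symptom: str
    method: str
    genes: list[str]
    scores: np.ndarray
    m: int

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(f"unknown selection method {self.method!r}")
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != len(self.scores):
            raise ValidationError("genes and scores must be aligned")
        if len(self.genes) > self.m:
            raise ValidationError("marker set larger than requested size m")

    def __len__(self) -> int:
        return len(self.genes)


def _rank(gene_ids, primary, secondary=None):
    """Order gene indices by ``primary`` ascending, ties by gene id.

    ``secondary`` (descending) breaks primary ties before the id rule;
    used to keep score columns monotone when the primary is a p-value.
    """
    keys = list(range(len(gene_ids)))
    if secondary is None:
        keys.sort(key=lambda i: (primary[i], gene_ids[i]))
    else:
        keys.sort(key=lambda i: (primary[i], -secondary[i], gene_ids[i]))
    return keys


def select_markers_slda(
    model: SldaModel,
    m: int,
    gene_ids: list[str] | None = None,
    symptom: str = "",
) -> MarkerSet:
    """Markers = genes with non-zero discriminant weight, ranked by the
    largest absolute loading across directions, truncated to ``m``.

    Loadings from different directions come from separate regressions
    whose coefficient scales are not comparable, so each direction is
    weighted by its canonical fit quality R^2 before the per-gene max
    is taken; trailing directions that fit mostly noise are thereby
    discounted rather than allowed to outrank weak true loadings.
    """
    ids = gene_ids if gene_ids is not None else model.gene_ids
    if ids is None:
        raise ValidationError("gene ids required (set model.gene_ids or pass gene_ids)")
    if model.directions.shape[0] != len(ids):
        raise ValidationError("gene ids do not match the model's feature dimension")
    if model.q:
        weights = (
            model.direction_r2
            if len(model.direction_r2) == model.q
            else np.ones(model.q)
        )
        loading = np.max(np.abs(model.directions) * weights, axis=1)
    else:
        loading = np.zeros(len(ids))
    nz = np.flatnonzero(loading > 0)
    order = sorted(nz, key=lambda i: (-loading[i], ids[i]))[:m]
    return MarkerSet(
        symptom=symptom,
        method="slda",
        genes=[ids[i] for i in order],
        scores=loading[list(order)],
        m=m,
    )


def anova_f(X: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised one-way ANOVA per gene (column of ``X``).

    Groups with fewer than 2 members are excluded. Zero within-group
    variance with non-zero between-group variance yields ``F = inf``,
    ``p = 0`` (maximally discriminative); zero between-group variance
    yields ``F = 0``, ``p = 1``.
    """
    labels = np.asarray(labels)
    levels = [lv for lv in np.unique(labels) if np.sum(labels == lv) >= 2]
    if len(levels) < 2:
        raise DegenerateLabelsError(
            "need >= 2 severity groups with >= 2 members each for ANOVA"
        )
    keep = np.isin(labels, levels)
    Xk, lk = X[keep], labels[keep]
    n, K = Xk.shape[0], len(levels)
    grand = Xk.mean(axis=0)
    ssb = np.zeros(X.shape[1])
    ssw = np.zeros(X.shape[1])
    for lv in levels:
        grp = Xk[lk == lv]
        mu = grp.mean(axis=0)
        ssb += len(grp) * (mu - grand) ** 2
        ssw += ((grp - mu) ** 2).sum(axis=0)
    dfb, dfw = K - 1, n - K
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / dfb) / (ssw / dfw)
    F = np.where(ssw == 0, np.where(ssb > 0, np.inf, 0.0), F)
    p = np.where(np.isinf(F), 0.0, stats.f.sf(np.where(np.isinf(F), 1.0, F), dfb, dfw))
    p = np.where(F == 0, 1.0, p)
    return F, p


def select_markers_anova(
    X: np.ndarray,
    labels: np.ndarray,
    m: int,
    gene_ids: list[str],
    symptom: str = "",
) -> MarkerSet:
    """Top ``m`` genes by ascending one-way ANOVA p-value over severity
    groups (ties by F, then gene id)."""
    F, p = anova_f(X, labels)
    order = _rank(gene_ids, p, secondary=F)[: min(m, len(gene_ids))]
    return MarkerSet(
        symptom=symptom,
        method="anova",
        genes=[gene_ids[i] for i in order],
        scores=F[order],
        m=m,
    )


def welch_t(
    X: np.ndarray, occurrence: np.ndarray, variant: str = "welch"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene two-sample t between occurrence groups.

    ``variant='welch'`` (default) uses the unequal-variance statistic
    with Satterthwaite degrees of freedom; ``'pooled'`` the classical
    equal-variance form.
    """
    occurrence = np.asarray(occurrence, dtype=bool)
    a, b = X[occurrence], X[~occurrence]
    if len(a) < 2 or len(b) < 2:
        raise DegenerateLabelsError(
            "both occurrence groups need >= 2 members for the t-test"
        )
    res = stats.ttest_ind(a, b, axis=0, equal_var=(variant == "pooled"))
    t = np.nan_to_num(res.statistic, nan=0.0)
    p = np.nan_to_num(res.pvalue, nan=1.0)
    return t, p


def select_markers_ttest(
    X: np.ndarray,
    occurrence: np.ndarray,
    m: int,
    gene_ids: list[str],
    symptom: str = "",
    variant: str = "welch",
) -> MarkerSet:
    """Top ``m`` genes by ascending two-sample-t p-value between
    occurrence groups (ties by |t|, then gene id)."""
    t, p = welch_t(X, occurrence, variant=variant)
    order = _rank(gene_ids, p, secondary=np.abs(t))[: min(m, len(gene_ids))]
    return MarkerSet(
        symptom=symptom,
        method="ttest",
        genes=[gene_ids[i] for i in order],
        scores=np.abs(t[order]),
        m=m,
    )


def select_markers(
    X: np.ndarray,
    severity: np.ndarray,
    occurrence: np.ndarray,
    gene_ids: list[str],
    method: str,
    m: int,
    symptom: str = "",
    lam2: float = 1e-3,
    ttest_variant: str = "welch",
    slda_max_iter: int = 20,
    slda_tol: float = 1e-4,
) -> MarkerSet:
    """Dispatch to one of the three selection methods.

    ``X`` is samples × genes, already standardised. The sparse-LDA
    tolerance here is the screening default: the selected support
    stabilises long before the coefficients do, so a loose tolerance
    changes rankings only in ties.
    """
    if method == "slda":
        model = fit_slda(
            X, severity, m=m, lam2=lam2, max_iter=slda_max_iter, tol=slda_tol
        )
        return select_markers_slda(model, m, gene_ids=gene_ids, symptom=symptom)
    if method == "anova":
        return select_markers_anova(X, severity, m, gene_ids, symptom=symptom)
    if method == "ttest":
        return select_markers_ttest(
            X, occurrence, m, gene_ids, symptom=symptom, variant=ttest_variant
        )
    raise ValidationError(f"unknown selection method {method!r}")
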