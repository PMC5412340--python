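"""Drug-wise cross-validated evaluation of marker panels.

Folds partition *drugs*, not samples: every sample of a compound shares
its fold, so a held-out fold contains only compounds the selection and
the model have never seen. Marker selection is repeated inside each
training split — selecting markers on the full cohort and then
cross-validating the regressor alone would leak compound identity
through the marker panel.

Two read-outs:

* Spearman's correlation (SCC) between actual and predicted severity,
  per fold and pooled over the concatenated out-of-fold predictions
  (pooled is primary);
* occurrence ROC/AUC, obtained by sweeping a decision threshold over
  the predicted severity (sample called positive when prediction >=
  threshold); the trapezoidal AUC equals the Mann–Whitney statistic
  with ties credited 1/2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

from .dataio import ExpressionMatrix
from .errors import ConfigError, UndefinedMetricError, ValidationError
from .preprocess import SymptomDataset, zscore_genes, zscore_with_stats
from .selection import METHODS, MarkerSet, select_markers
from .severity_model import predict_severity, train_balanced_ensemble

__all__ = [
    "FoldPlan",
    "EvaluationResult",
    "make_drug_folds",
    "cross_validate",
    "spearman",
    "roc_auc",
]


@dataclass
class FoldPlan:
    """Assignment of every drug to exactly one of k folds."""

    k: int
    fold_of_drug: dict
    seed: int

    def __post_init__(self) -> None:
        sizes = np.bincount(list(self.fold_of_drug.values()), minlength=self.k)
        if sizes.max() - sizes.min() > 1:
            raise ValidationError("fold sizes differ by more than one drug")

    def fold_of_samples(self, drug_of: np.ndarray) -> np.ndarray:
        return np.array([self.fold_of_drug[d] for d in drug_of], dtype=int)


def make_drug_folds(ds: SymptomDataset, k: int, seed: int) -> FoldPlan:
    """Shuffle drugs with ``seed`` and deal them round-robin to k folds."""
    drugs = sorted(set(ds.drug_of))
    if len(drugs) < k:
        raise ConfigError(f"{len(drugs)} drugs cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    order = [drugs[i] for i in rng.permutation(len(drugs))]
    return FoldPlan(k=k, fold_of_drug={d: i % k for i, d in enumerate(order)}, seed=seed)


def spearman(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Spearman correlation: Pearson correlation of average-fractional
    ranks (standard midrank tie handling)."""
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape or actual.ndim != 1:
        raise ValidationError("inputs must be equal-length vectors")
    if len(actual) < 3:
        raise ValidationError("need at least 3 observations for a rank correlation")
    if np.all(actual == actual[0]):
        raise UndefinedMetricError("Spearman undefined: actual severities are constant")
    ra = stats.rankdata(actual)
    rp = stats.rankdata(predicted)
    if np.all(rp == rp[0]):
        raise UndefinedMetricError("Spearman undefined: predictions are constant")
    return float(np.corrcoef(ra, rp)[0, 1])


def roc_auc(
    predicted: np.ndarray, occurrence: np.ndarray
) -> tuple[np.ndarray, float]:
    """Threshold-swept ROC over the distinct predicted values.

    Returns (points, auc) where points is an array of rows
    (fpr, tpr, threshold); a sample is called positive when its
    prediction is >= the threshold.
    """
    occurrence = np.asarray(occurrence, dtype=bool)
    predicted = np.asarray(predicted, dtype=float)
    if occurrence.all() or not occurrence.any():
        raise UndefinedMetricError("ROC undefined: only one occurrence class present")
    fpr, tpr, thr = roc_curve(occurrence, predicted, drop_intermediate=False)
    points = np.column_stack([fpr, tpr, thr])
    return points, float(_trapezoid_auc(fpr, tpr))


@dataclass
class EvaluationResult:
    """Cross-validated metrics for one (symptom, method, m) setting."""

    symptom: str
    method: str
    m: int
    fold_scc: list[float]
    pooled_scc: float
    roc_points: np.ndarray
    auc: float
    predictions: pd.DataFrame  # sample_id, drug_id, fold, actual, predicted
    fold_plan: FoldPlan
    selection_sample_ids: list[list[str]] = field(default_factory=list)
    fold_markers: list[MarkerSet] = field(default_factory=list)

    @property
    def mean_fold_scc(self) -> float:
        vals = [s for s in self.fold_scc if np.isfinite(s)]
        return float(np.mean(vals)) if vals else float("nan")

    def metrics_dict(self) -> dict:
        return {
            "symptom": self.symptom,
            "method": self.method,
            "m": self.m,
            "pooled_scc": self.pooled_scc,
            "mean_fold_scc": self.mean_fold_scc,
            "fold_scc": list(self.fold_scc),
            "auc": self.auc,
            "k": self.fold_plan.k,
        }


def cross_validate(
    ds: SymptomDataset,
    method: str = "slda",
    m: int = 32,
    k: int = 10,
    n_models: int = 100,
    rf_params: dict | None = None,
    lam2: float = 1e-3,
    ttest_variant: str = "welch",
    normalize: str = "global",
    seed: int = 0,
    selection_hook: Callable[[int, list[str]], None] | None = None,
) -> EvaluationResult:
    """Drug-unit k-fold CV with in-fold marker selection.

    ``normalize='global'`` z-scores genes once over all samples of
    ``ds`` (matching a pipeline that standardises the cohort before
    modelling, at the cost of a mild train/test statistic leak);
    ``'per-fold'`` standardises with training-fold statistics only.

    ``selection_hook(fold, sample_ids)`` is invoked with exactly the
    sample ids visible to marker selection in each fold; tests use it to
    assert that held-out samples are never touched.
    """
    if method not in METHODS:
        raise ConfigError(f"unknown method {method!r}")
    if normalize not in ("global", "per-fold"):
        raise ConfigError(f"unknown normalization mode {normalize!r}")
    rng = np.random.default_rng(seed)
    plan = make_drug_folds(ds, k, seed=int(rng.integers(2**31 - 1)))
    fold_of = plan.fold_of_samples(ds.drug_of)
    ids = np.array(ds.sample_ids, dtype=object)

    if normalize == "global":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            Xz_full = zscore_genes(ds.X).values  # genes x samples
    fold_scc: list[float] = []
    all_pred = np.full(ds.n_samples, np.nan)
    selection_ids: list[list[str]] = []
    fold_markers: list[MarkerSet] = []

    for fold in range(k):
        test_mask = fold_of == fold
        train_mask = ~test_mask
        assert not set(ds.drug_of[train_mask]) & set(ds.drug_of[test_mask])
        if normalize == "global":
            Xtr = Xz_full[:, train_mask]
            Xte = Xz_full[:, test_mask]
        else:
            Xtr, mu, sd = zscore_with_stats(ds.X.values[:, train_mask])
            Xte = (ds.X.values[:, test_mask] - mu) / sd
        train_ids = list(ids[train_mask])
        if selection_hook is not None:
            selection_hook(fold, train_ids)
        selection_ids.append(train_ids)

        markers = select_markers(
            Xtr.T,
            ds.severity[train_mask],
            ds.occurrence[train_mask],
            ds.X.gene_ids,
            method=method,
            m=m,
            symptom=ds.symptom,
            lam2=lam2,
            ttest_variant=ttest_variant,
        )
        fold_markers.append(markers)
        train_ds = SymptomDataset(
            X=ExpressionMatrix(list(ds.X.gene_ids), train_ids, Xtr),
            severity=ds.severity[train_mask],
            occurrence=ds.occurrence[train_mask],
            drug_of=ds.drug_of[train_mask],
            symptom=ds.symptom,
        )
        model = train_balanced_ensemble(
            train_ds,
            markers,
            n_models=n_models,
            rf_params=rf_params,
            seed=int(rng.integers(2**31 - 1)),
        )
        test_X = ExpressionMatrix(list(ds.X.gene_ids), list(ids[test_mask]), Xte)
        pred = predict_severity(model, test_X)
        all_pred[test_mask] = pred
        try:
            fold_scc.append(spearman(ds.severity[test_mask], pred))
        except (UndefinedMetricError, ValidationError) as exc:
            warnings.warn(
                f"fold {fold}: SCC undefined ({exc}); excluded from per-fold mean",
                UserWarning,
                stacklevel=2,
            )
            fold_scc.append(float("nan"))

    pooled_scc = spearman(ds.severity, all_pred)
    roc_points, auc_value = roc_auc(all_pred, ds.occurrence)
    predictions = pd.DataFrame(
        {
            "sample_id": ids,
            "drug_id": ds.drug_of,
            "fold": fold_of,
            "actual": ds.severity,
            "predicted": all_pred,
        }
    )
    return EvaluationResult(
        symptom=ds.symptom,
        method=method,
        m=m,
        fold_scc=fold_scc,
        pooled_scc=pooled_scc,
        roc_points=roc_points,
        auc=auc_value,
        predictions=predictions,
        fold_plan=plan,
        selection_sample_ids=selection_ids,
        fold_markers=fold_markers,
    )
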