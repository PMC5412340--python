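"""Model/Results facade over the marker-selection + ensemble pipeline.

``SeverityMarkerModel`` is constructed from data (a per-symptom dataset,
or raw dataframes via :meth:`from_dataframes`), holds the analysis
settings, and ``fit()`` returns a :class:`SeverityMarkerResults` object
carrying the selected marker panel, the trained balanced ensemble,
in-sample diagnostics and a ``summary()`` table. Cross-validated
evaluation re-runs the whole pipeline per fold and hangs off the model
object as :meth:`cross_validate`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import ExpressionMatrix, SampleTable
from .errors import ConfigError
from .evaluation import EvaluationResult, cross_validate, roc_auc, spearman
from .preprocess import SymptomDataset, build_dataset, zscore_genes
from .selection import METHODS, MarkerSet, select_markers
from .severity_model import (
    DEFAULT_RF_PARAMS,
    EnsembleModel,
    predict_severity,
    train_balanced_ensemble,
)

__all__ = ["SeverityMarkerModel", "SeverityMarkerResults"]


class SeverityMarkerModel:
    """Severity-marker analysis for one toxicity symptom.

    Parameters
    ----------
    dataset
        Per-symptom dataset (expression + severity + drug labels); raw,
        not yet standardised.
    method
        Marker-selection method: ``'slda'`` (default), ``'anova'`` or
        ``'ttest'``.
    n_markers
        Marker panel size ``m``.
    lam2
        Ridge weight of the sparse-discriminant elastic net.
    n_models
        Number of balanced ensemble members.
    rf_params
        Forest settings per member, e.g. ``{"n_trees": 10,
        "max_depth": None}``.
    normalize
        ``'global'`` standardises genes over the full dataset before
        modelling; ``'per-fold'`` defers standardisation to the
        training split of each CV fold.
    """

    def __init__(
        self,
        dataset: SymptomDataset,
        method: str = "slda",
        n_markers: int = 32,
        lam2: float = 1e-3,
        n_models: int = 100,
        rf_params: dict | None = None,
        ttest_variant: str = "welch",
        normalize: str = "global",
    ) -> None:
        if method not in METHODS:
            raise ConfigError(f"unknown selection method {method!r}")
        if normalize not in ("global", "per-fold"):
            raise ConfigError(f"unknown normalization mode {normalize!r}")
        self.dataset = dataset
        self.method = method
        self.n_markers = n_markers
        self.lam2 = lam2
        self.n_models = n_models
        self.rf_params = {**DEFAULT_RF_PARAMS, **(rf_params or {})}
        self.ttest_variant = ttest_variant
        self.normalize = normalize

    @classmethod
    def from_dataframes(
        cls,
        expression: pd.DataFrame,
        samples: pd.DataFrame,
        symptom: str,
        **kwargs,
    ) -> "SeverityMarkerModel":
        """Build from a genes × samples expression frame and a sample
        metadata frame (``sample_id``, ``drug_id``,
        ``severity.<symptom>``, ``spontaneous.<symptom>`` columns)."""
        expr = ExpressionMatrix.from_frame(expression)
        symptoms = sorted(
            c[len("severity."):] for c in samples.columns if c.startswith("severity.")
        )
        table = SampleTable(frame=samples.copy(), symptoms=symptoms)
        return cls(build_dataset(expr, table, symptom), **kwargs)

    @classmethod
    def from_files(
        cls, expression_path, samples_path, symptom: str, **kwargs
    ) -> "SeverityMarkerModel":
        from .dataio import read_expression, read_samples

        expr = read_expression(expression_path)
        table = read_samples(samples_path)
        return cls(build_dataset(expr, table, symptom), **kwargs)

    def _standardised(self) -> ExpressionMatrix:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            return zscore_genes(self.dataset.X)

    def fit(self, seed: int = 0) -> "SeverityMarkerResults":
        """Select the marker panel and train the balanced ensemble on
        the full dataset; returns the results object."""
        ds = self.dataset
        Xz = self._standardised()
        markers = select_markers(
            Xz.values.T,
            ds.severity,
            ds.occurrence,
            Xz.gene_ids,
            method=self.method,
            m=self.n_markers,
            symptom=ds.symptom,
            lam2=self.lam2,
            ttest_variant=self.ttest_variant,
        )
        zds = SymptomDataset(
            X=Xz,
            severity=ds.severity,
            occurrence=ds.occurrence,
            drug_of=ds.drug_of,
            symptom=ds.symptom,
        )
        ensemble = train_balanced_ensemble(
            zds,
            markers,
            n_models=self.n_models,
            rf_params=self.rf_params,
            seed=seed,
        )
        fitted = predict_severity(ensemble, Xz)
        return SeverityMarkerResults(
            model=self, markers=markers, ensemble=ensemble, fittedvalues=fitted
        )

    def cross_validate(self, k: int = 10, seed: int = 0, **kwargs) -> EvaluationResult:
        """Drug-unit k-fold CV with in-fold marker selection."""
        return cross_validate(
            self.dataset,
            method=self.method,
            m=self.n_markers,
            k=k,
            n_models=self.n_models,
            rf_params=self.rf_params,
            lam2=self.lam2,
            ttest_variant=self.ttest_variant,
            normalize=self.normalize,
            seed=seed,
            **kwargs,
        )


@dataclass
class SeverityMarkerResults:
    """Fitted marker panel + ensemble with in-sample diagnostics."""

    model: SeverityMarkerModel
    markers: MarkerSet
    ensemble: EnsembleModel
    fittedvalues: np.ndarray
    _insample_scc: float | None = field(default=None, repr=False)

    @property
    def insample_scc(self) -> float:
        """Spearman correlation of actual vs fitted severity on the
        training data (optimistic; use cross_validate for honest
        numbers)."""
        if self._insample_scc is None:
            self._insample_scc = spearman(self.model.dataset.severity, self.fittedvalues)
        return self._insample_scc

    @property
    def insample_auc(self) -> float:
        _, a = roc_auc(self.fittedvalues, self.model.dataset.occurrence)
        return a

    def predict(self, X: ExpressionMatrix | pd.DataFrame) -> np.ndarray:
        """Predicted continuous severity for new samples.

        ``X`` must be standardised the same way as the training data
        and provide every marker gene.
        """
        if isinstance(X, pd.DataFrame):
            X = ExpressionMatrix.from_frame(X)
        return predict_severity(self.ensemble, X)

    def marker_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.markers) + 1),
                "gene_id": self.markers.genes,
                "score": self.markers.scores,
            }
        )

    def summary(self) -> str:
        """Plain-text summary in the spirit of a regression results
        table: settings, in-sample metrics, and the marker panel."""
        ds = self.model.dataset
        lines = [
            "Severity Marker Model Results",
            "=" * 46,
            f"Symptom:              {ds.symptom}",
            f"Selection method:     {self.markers.method}",
            f"Markers requested m:  {self.markers.m}",
            f"Markers selected:     {len(self.markers)}",
            f"Samples (cases):      {ds.n_samples} ({ds.n_cases})",
            f"Drugs:                {len(set(ds.drug_of))}",
            f"Ensemble members:     {self.ensemble.n_models}",
            f"Trees per member:     {self.ensemble.rf_params['n_trees']}",
            f"In-sample SCC:        {self.insample_scc:.3f}",
            f"In-sample AUC:        {self.insample_auc:.3f}",
            "-" * 46,
            f"{'rank':>4}  {'gene_id':<12} {'score':>10}",
        ]
        for i, (g, s) in enumerate(zip(self.markers.genes, self.markers.scores), 1):
            lines.append(f"{i:>4}  {g:<12} {s:>10.4f}")
        return "\n".join(lines)
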