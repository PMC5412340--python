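"""Assemble the per-symptom modelling dataset.

For one symptom this means: drop samples whose positive finding was
flagged spontaneous (not drug-induced), derive the binary occurrence
label (grade >= 1), and z-score every gene. Spontaneous flags on
grade-0 records are ignored — only positive findings can be excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dataio import ExpressionMatrix, SampleTable
from .errors import DegenerateDatasetError, LookupError_

__all__ = ["SymptomDataset", "build_dataset", "zscore_genes"]


@dataclass
class SymptomDataset:
    """Expression plus aligned labels for one toxicity symptom.

    ``severity`` holds the ordinal grade 0–4 used as the regression
    target; ``occurrence`` is its binarisation (grade >= 1); ``drug_of``
    carries each sample's dosing compound, the unit by which
    cross-validation folds are cut.
    """

    X: ExpressionMatrix
    severity: np.ndarray
    occurrence: np.ndarray
    drug_of: np.ndarray
    symptom: str

    def __post_init__(self) -> None:
        n = self.X.n_samples
        self.severity = np.asarray(self.severity, dtype=int)
        self.occurrence = np.asarray(self.occurrence, dtype=bool)
        self.drug_of = np.asarray(self.drug_of, dtype=object)
        if not (len(self.severity) == len(self.occurrence) == len(self.drug_of) == n):
            raise ValueError("label vectors must match the sample dimension of X")
        if not np.array_equal(self.occurrence, self.severity >= 1):
            raise ValueError("occurrence must equal severity >= 1")

    @property
    def n_samples(self) -> int:
        return self.X.n_samples

    @property
    def n_cases(self) -> int:
        return int(self.occurrence.sum())

    @property
    def sample_ids(self) -> list[str]:
        return self.X.sample_ids

    def subset(self, mask: np.ndarray) -> "SymptomDataset":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        ids = [self.X.sample_ids[i] for i in idx]
        return SymptomDataset(
            X=self.X.subset_samples(ids),
            severity=self.severity[idx],
            occurrence=self.severity[idx] >= 1,
            drug_of=self.drug_of[idx],
            symptom=self.symptom,
        )


def build_dataset(
    expr: ExpressionMatrix, samples: SampleTable, symptom: str
) -> SymptomDataset:
    """Build the modelling dataset for ``symptom``.

    Samples with a spontaneous positive finding (flag set and grade >= 1)
    are removed; spontaneous flags on controls are retained because a
    grade-0 record carries no finding to exclude. Expression values are
    only subset, never altered.
    """
    if symptom not in samples.symptoms:
        raise LookupError_(f"unknown symptom {symptom!r}; known: {samples.symptoms}")
    expr_index = set(expr.sample_ids)
    missing = [s for s in samples.sample_ids if s not in expr_index]
    if missing:
        raise LookupError_(
            f"sample {missing[0]!r} in sample table but not in expression matrix"
        )
    severity = samples.severity(symptom)
    spontaneous = samples.spontaneous(symptom)
    keep = ~(spontaneous & (severity >= 1))
    kept_ids = [s for s, k in zip(samples.sample_ids, keep) if k]
    severity = severity[keep]
    if not np.any(severity >= 1):
        raise DegenerateDatasetError(
            f"no drug-induced case samples remain for symptom {symptom!r}"
        )
    return SymptomDataset(
        X=expr.subset_samples(kept_ids),
        severity=severity,
        occurrence=severity >= 1,
        drug_of=samples.drug_ids[keep],
        symptom=symptom,
    )


def zscore_genes(X: ExpressionMatrix) -> ExpressionMatrix:
    """Standardise every gene to mean 0, SD 1 across samples.

    The population standard deviation (denominator *n*) is used. Genes
    with zero variance cannot be scaled; they are centred to all-zero
    rows and reported in a single warning.
    """
    values = X.values
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    constant = sd[:, 0] == 0.0
    if np.any(constant):
        names = [g for g, c in zip(X.gene_ids, constant) if c]
        warnings.warn(
            f"{len(names)} zero-variance gene(s) set to 0 after centering: "
            f"{names[:10]}{'...' if len(names) > 10 else ''}",
            UserWarning,
            stacklevel=2,
        )
    safe_sd = np.where(sd == 0.0, 1.0, sd)
    out = (values - mean) / safe_sd
    return ExpressionMatrix(list(X.gene_ids), list(X.sample_ids), out)


def zscore_with_stats(
    values: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardise rows and return (standardised, mean, sd) for reuse.

    Used for per-fold normalisation where the training statistics must be
    applied to held-out samples. Zero-SD rows are centred only.
    """
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    safe_sd = np.where(sd == 0.0, 1.0, sd)
    return (values - mean) / safe_sd, mean, safe_sd
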