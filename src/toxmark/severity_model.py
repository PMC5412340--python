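"""Balanced random-forest ensemble for severity regression.

Toxicogenomics cohorts are control-heavy: for a given symptom, most
samples never show it. A single regressor trained on everything would be
dominated by grade-0 samples. Instead, every ensemble member is trained
on *all* case samples plus an equal-size random subset of controls, and
the ensemble prediction is the plain average of the member predictions.
The regression target is the raw integer grade, so the averaged output
is a continuous severity score.

Each member is a small regression forest (10 trees by default, unlimited
depth). Feature subsampling at splits is disabled so every marker gene
is a candidate at every split — with a few dozen features the trees are
meant to use the full marker panel, not random subsets of it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .dataio import ExpressionMatrix
from .errors import DegenerateDatasetError, FeatureMismatchError, ValidationError
from .preprocess import SymptomDataset
from .selection import MarkerSet

__all__ = ["EnsembleModel", "train_balanced_ensemble", "predict_severity"]

DEFAULT_RF_PARAMS = {"n_trees": 10, "max_depth": None, "bootstrap": True}


@dataclass
class EnsembleModel:
    """Collection of per-subsample forests whose mean output is the
    predicted severity."""

    members: list[RandomForestRegressor]
    marker_gene_ids: list[str]
    n_models: int
    rf_params: dict
    subsample_log: list[list[str]]
    seed: int

    def __post_init__(self) -> None:
        if len(self.members) != self.n_models:
            raise ValidationError("member count does not match n_models")
        if len(self.subsample_log) != self.n_models:
            raise ValidationError("subsample log does not match n_models")

    def save(self, directory) -> None:
        """Persist as a directory: params JSON + member pickles + log TSV."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        params = {
            "format_version": 1,
            "n_models": self.n_models,
            "rf_params": self.rf_params,
            "marker_gene_ids": self.marker_gene_ids,
            "seed": self.seed,
        }
        (d / "params.json").write_text(json.dumps(params, indent=2))
        with open(d / "subsample_log.tsv", "wt") as fh:
            fh.write("member\tsample_ids\n")
            for i, ids in enumerate(self.subsample_log):
                fh.write(f"{i}\t{','.join(ids)}\n")
        joblib.dump(self.members, d / "members.joblib")

    @classmethod
    def load(cls, directory) -> "EnsembleModel":
        d = Path(directory)
        params = json.loads((d / "params.json").read_text())
        members = joblib.load(d / "members.joblib")
        log: list[list[str]] = []
        with open(d / "subsample_log.tsv") as fh:
            next(fh)
            for line in fh:
                _, ids = line.rstrip("\n").split("\t")
                log.append(ids.split(","))
        return cls(
            members=members,
            marker_gene_ids=params["marker_gene_ids"],
            n_models=params["n_models"],
            rf_params=params["rf_params"],
            subsample_log=log,
            seed=params["seed"],
        )


def _marker_matrix(X: ExpressionMatrix, marker_gene_ids: list[str]) -> np.ndarray:
    index = {g: i for i, g in enumerate(X.gene_ids)}
    rows = []
    for g in marker_gene_ids:
        if g not in index:
            raise FeatureMismatchError(f"marker gene {g!r} absent from expression matrix")
        rows.append(index[g])
    return X.values[rows, :].T  # samples x markers


def train_balanced_ensemble(
    ds: SymptomDataset,
    markers: MarkerSet,
    n_models: int = 100,
    rf_params: dict | None = None,
    seed: int = 0,
) -> EnsembleModel:
    """Train ``n_models`` forests, each on all cases plus an equal-size
    random control subset (drawn without replacement, independently per
    member). Fully deterministic for a fixed ``seed``."""
    rf_params = {**DEFAULT_RF_PARAMS, **(rf_params or {})}
    case_idx = np.flatnonzero(ds.occurrence)
    control_idx = np.flatnonzero(~ds.occurrence)
    if case_idx.size == 0:
        raise DegenerateDatasetError("cannot train: dataset has no case samples")
    if control_idx.size == 0:
        raise DegenerateDatasetError("cannot train: dataset has no control samples")
    replace = control_idx.size < case_idx.size
    if replace:
        warnings.warn(
            "fewer controls than cases; sampling controls with replacement",
            UserWarning,
            stacklevel=2,
        )
    feats = _marker_matrix(ds.X, markers.genes)
    y = ds.severity.astype(float)
    ids = ds.sample_ids
    rng = np.random.default_rng(seed)

    members: list[RandomForestRegressor] = []
    log: list[list[str]] = []
    for _ in range(n_models):
        ctrl = rng.choice(control_idx, size=case_idx.size, replace=replace)
        train_idx = np.concatenate([case_idx, ctrl])
        rf = RandomForestRegressor(
            n_estimators=rf_params["n_trees"],
            max_depth=rf_params["max_depth"],
            max_features=1.0,  # every marker is a split candidate
            bootstrap=rf_params.get("bootstrap", True),
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        rf.fit(feats[train_idx], y[train_idx])
        members.append(rf)
        log.append([ids[i] for i in train_idx])
    return EnsembleModel(
        members=members,
        marker_gene_ids=list(markers.genes),
        n_models=n_models,
        rf_params=rf_params,
        subsample_log=log,
        seed=seed,
    )


def predict_severity(model: EnsembleModel, X: ExpressionMatrix) -> np.ndarray:
    """Continuous predicted severity: the arithmetic mean of the member
    predictions, unclipped."""
    feats = _marker_matrix(X, model.marker_gene_ids)
    preds = np.stack([member.predict(feats) for member in model.members])
    return preds.mean(axis=0)
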