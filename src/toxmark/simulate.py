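"""Synthetic toxicogenomics cohorts with known ground truth.

The generator emulates the statistical structure of a large multi-drug
in vivo liver cohort: many compounds, most of them non-toxic for the
simulated symptom (control-heavy imbalance), ordinal severity grades
0–4 that rise with a latent dose index within each toxic compound,
correlated blocks of co-expressed genes, and a planted panel of marker
genes whose mean expression shifts linearly with the grade.

Two deliberate stress features:

* a *correlated weak pair* — two markers that share a strong common
  latent factor (mutually correlated ~0.9) while each carries only half
  the marker effect, with opposite signs. Univariately each pair member
  is weak, but their difference cancels the shared factor and carries
  the full effect at a fraction of the noise, so joint (multivariate)
  selection can find what per-gene screens miss;
* spontaneous flags on a small random subset of positive findings,
  exercising the drug-induced-only filter downstream.

Expression is unit-variance by construction, so ``effect_size`` reads
directly as a per-grade mean shift in SD units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import (
    MAX_GRADE,
    AnnotationTable,
    ExpressionMatrix,
    SampleTable,
    TermRecord,
)
from .errors import ValidationError

__all__ = ["CohortConfig", "GroundTruth", "simulate_cohort", "simulate_annotation"]

SYMPTOM = "necrosis"  # name of the single simulated symptom

#: correlation of the two weak-pair members through their shared factor
WEAK_PAIR_RHO = 0.9
#: fraction of positive findings flagged spontaneous
SPONTANEOUS_RATE = 0.03
#: fraction of marker genes included in the planted annotation term
PLANTED_FRACTION = 0.7


@dataclass
class CohortConfig:
    """Generator settings; defaults give a mid-sized cohort with the
    imbalance and signal strength the analysis is designed around."""

    n_drugs: int = 40
    samples_per_drug: int = 20
    n_genes: int = 2000
    n_markers: int = 24
    effect_size: float = 0.8  # per-grade mean shift, SD units
    block_size: int = 10  # genes per correlated latent block
    block_rho: float = 0.3  # within-block correlation
    frac_toxic_drugs: float = 0.3
    max_grade: int = MAX_GRADE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_drugs < 1 or self.samples_per_drug < 1 or self.n_genes < 1:
            raise ValidationError("cohort dimensions must be positive")
        if not 0 <= self.n_markers <= self.n_genes:
            raise ValidationError("n_markers must be in 0..n_genes")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be non-negative")
        if self.block_size < 1:
            raise ValidationError("block_size must be >= 1")
        if not 0.0 <= self.block_rho < 1.0:
            raise ValidationError("block_rho must be in [0, 1)")
        if not 0.0 < self.frac_toxic_drugs <= 1.0:
            raise ValidationError("frac_toxic_drugs must be in (0, 1]")
        if not 1 <= self.max_grade <= MAX_GRADE:
            raise ValidationError(f"max_grade must be in 1..{MAX_GRADE}")


@dataclass
class GroundTruth:
    """What was planted: the marker panel with effect directions, each
    drug's maximum induced grade (0 = non-toxic), and the id of the
    annotation term built around the markers."""

    marker_gene_ids: list[str]
    directions: np.ndarray  # +1 / -1 per marker
    drug_profile: dict  # drug id -> max induced grade
    planted_term_id: str = "TERM_PLANTED"
    weak_pair: tuple[str, str] | None = None


def _severity_schedule(n_samples: int, max_grade: int) -> np.ndarray:
    """Grades monotone in the within-drug dose index, every grade
    0..max_grade guaranteed present when n_samples >= max_grade + 1."""
    chunks = np.array_split(np.arange(n_samples), max_grade + 1)
    sev = np.empty(n_samples, dtype=int)
    for grade, chunk in enumerate(chunks):
        sev[chunk] = grade
    return sev


def simulate_cohort(
    config: CohortConfig,
) -> tuple[ExpressionMatrix, SampleTable, GroundTruth]:
    """Generate (expression, samples, truth); bit-identical per seed."""
    rng = np.random.default_rng(config.seed)
    n_drugs, spd = config.n_drugs, config.samples_per_drug
    n = n_drugs * spd
    p = config.n_genes

    gene_ids = [f"G{i:05d}" for i in range(p)]
    sample_ids = [f"S{i:05d}" for i in range(n)]
    drug_ids = [f"D{i:03d}" for i in range(n_drugs)]

    # --- design: which drugs are toxic, and how severe -----------------
    toxic = rng.random(n_drugs) < config.frac_toxic_drugs
    drug_max = np.where(
        toxic, rng.integers(1, config.max_grade + 1, size=n_drugs), 0
    )
    severity = np.zeros(n, dtype=int)
    drug_of = np.empty(n, dtype=object)
    for d in range(n_drugs):
        lo = d * spd
        drug_of[lo : lo + spd] = drug_ids[d]
        if drug_max[d] > 0:
            severity[lo : lo + spd] = _severity_schedule(spd, int(drug_max[d]))

    # --- expression: block factors + noise ------------------------------
    n_blocks = int(np.ceil(p / config.block_size))
    block_of = np.arange(p) // config.block_size
    Z = rng.standard_normal((n_blocks, n))  # latent factor per block
    noise = rng.standard_normal((p, n))
    r = config.block_rho
    X = np.sqrt(r) * Z[block_of, :] + np.sqrt(1.0 - r) * noise

    # --- planted markers -------------------------------------------------
    marker_idx = np.sort(rng.choice(p, size=config.n_markers, replace=False))
    directions = rng.choice([-1.0, 1.0], size=config.n_markers)
    grade = severity.astype(float)
    for mi, (gi, sign) in enumerate(zip(marker_idx, directions)):
        if mi in (0, 1):
            continue  # weak pair handled below
        X[gi, :] += sign * config.effect_size * grade

    weak_pair = None
    if config.n_markers >= 2:
        g1, g2 = int(marker_idx[0]), int(marker_idx[1])
        u = rng.standard_normal(n)
        e1 = rng.standard_normal(n)
        e2 = rng.standard_normal(n)
        c = WEAK_PAIR_RHO
        half = 0.5 * config.effect_size
        X[g1, :] = np.sqrt(c) * u + np.sqrt(1 - c) * e1 + half * grade
        X[g2, :] = np.sqrt(c) * u + np.sqrt(1 - c) * e2 - half * grade
        directions[0], directions[1] = 1.0, -1.0
        weak_pair = (gene_ids[g1], gene_ids[g2])

    # --- spontaneous flags on a few positive findings --------------------
    spontaneous = np.zeros(n, dtype=bool)
    cases = np.flatnonzero(severity >= 1)
    if cases.size:
        flagged = cases[rng.random(cases.size) < SPONTANEOUS_RATE]
        spontaneous[flagged] = True

    expr = ExpressionMatrix(gene_ids, sample_ids, X)
    frame = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "drug_id": drug_of,
            f"severity.{SYMPTOM}": severity,
            f"spontaneous.{SYMPTOM}": spontaneous,
        }
    )
    samples = SampleTable(frame=frame, symptoms=[SYMPTOM])
    truth = GroundTruth(
        marker_gene_ids=[gene_ids[i] for i in marker_idx],
        directions=directions,
        drug_profile={drug_ids[d]: int(drug_max[d]) for d in range(n_drugs)},
        weak_pair=weak_pair,
    )
    return expr, samples, truth


def simulate_annotation(
    truth: GroundTruth,
    gene_ids: list[str],
    n_terms: int = 50,
    term_size: int = 40,
    seed: int = 0,
) -> AnnotationTable:
    """Annotation table with one planted term built around the markers.

    The planted term contains ``PLANTED_FRACTION`` of the marker genes
    (at least 60%) padded with random non-marker genes up to
    ``term_size``; the remaining ``n_terms - 1`` terms are uniform
    random draws from the gene universe.
    """
    if n_terms < 1:
        raise ValidationError("n_terms must be >= 1")
    if term_size > len(gene_ids):
        raise ValidationError("term_size exceeds the gene universe")
    markers = [g for g in truth.marker_gene_ids if g in set(gene_ids)]
    if set(truth.marker_gene_ids) - set(gene_ids):
        raise ValidationError("ground-truth markers missing from gene universe")
    rng = np.random.default_rng(seed)
    n_plant = min(term_size, int(np.ceil(PLANTED_FRACTION * len(markers))))
    planted_markers = [markers[i] for i in rng.permutation(len(markers))[:n_plant]]
    others = sorted(set(gene_ids) - set(planted_markers))
    pad = [others[i] for i in rng.permutation(len(others))[: term_size - n_plant]]
    terms = [
        TermRecord(
            truth.planted_term_id,
            "planted severity-marker term",
            frozenset(planted_markers + pad),
        )
    ]
    all_genes = list(gene_ids)
    for t in range(1, n_terms):
        members = rng.choice(len(all_genes), size=term_size, replace=False)
        terms.append(
            TermRecord(
                f"TERM_{t:04d}",
                f"random term {t}",
                frozenset(all_genes[i] for i in members),
            )
        )
    return AnnotationTable(terms)


def benchmark_scenario(seed: int = 1) -> CohortConfig:
    """Mid-sized benchmark cohort: clear per-grade signal (0.8 SD) and a
    24-gene panel, used for marker-recovery and pipeline-signal checks."""
    return CohortConfig(
        n_drugs=40,
        samples_per_drug=20,
        n_genes=2000,
        n_markers=24,
        effect_size=0.8,
        frac_toxic_drugs=0.3,
        seed=seed,
    )


def weak_pair_scenario(seed: int = 1) -> CohortConfig:
    """Method-comparison cohort sized so the correlated weak pair matters.

    Eight markers at 0.4 SD per grade put per-gene effects near the
    univariate detection margin for ~100 cases against 400 genes, and
    the pair (each member carrying half the effect) accounts for a
    material share of the severity-informative signal — the regime
    where joint and per-gene selection genuinely part ways.
    """
    return CohortConfig(
        n_drugs=30,
        samples_per_drug=15,
        n_genes=400,
        n_markers=8,
        effect_size=0.4,
        frac_toxic_drugs=0.4,
        seed=seed,
    )
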