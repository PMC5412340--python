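"""Tabular input/output and the validated domain containers.

Three plain-text formats are supported:

* expression matrices — TSV, genes in rows, samples in columns, a header
  row of sample ids and a first column of gene ids;
* sample tables — TSV with ``sample_id``, ``drug_id`` and one
  ``severity.<symptom>`` / ``spontaneous.<symptom>`` column pair per
  scored histopathology symptom;
* gene-set annotations — standard GMT (term, description, member genes).

All readers validate into the domain types below and fail loudly on the
first violated invariant; nothing is silently coerced or imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, LookupError_, ValidationError

SEVERITY_PREFIX = "severity."
SPONTANEOUS_PREFIX = "spontaneous."

MAX_GRADE = 4  # ordinal pathology scale: 0 none .. 4 severe

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


def _find_duplicate(items: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return None


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes × samples numeric matrix with unique row/column identifiers.

    Values are on an arbitrary log-like scale; downstream modelling
    z-scores each gene, so only relative changes matter.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        dup = _find_duplicate(self.gene_ids)
        if dup is not None:
            raise ValidationError(f"duplicate gene id: {dup!r}")
        dup = _find_duplicate(self.sample_ids)
        if dup is not None:
            raise ValidationError(f"duplicate sample id: {dup!r}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite expression value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        """Return a copy restricted to ``sample_ids`` (in the given order)."""
        index = {s: j for j, s in enumerate(self.sample_ids)}
        try:
            cols = [index[s] for s in sample_ids]
        except KeyError as exc:  # pragma: no cover - message path
            raise LookupError_(f"unknown sample id: {exc.args[0]!r}") from None
        return ExpressionMatrix(
            list(self.gene_ids), list(sample_ids), self.values[:, cols].copy()
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise LookupError_(f"unknown gene id: {missing[0]!r}")
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(
            list(gene_ids), list(self.sample_ids), self.values[rows, :].copy()
        )


def read_expression(path) -> ExpressionMatrix:
    """Read a genes × samples TSV into a validated :class:`ExpressionMatrix`."""
    raw = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if raw.shape[0] < 2 or raw.shape[1] < 2:
        raise FormatError(f"{path}: expression table needs a header row and >=1 gene row")
    sample_ids = [str(s) for s in raw.iloc[0, 1:]]
    gene_ids = [str(g) for g in raw.iloc[1:, 0]]
    dup = _find_duplicate(gene_ids)
    if dup is not None:
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    dup = _find_duplicate(sample_ids)
    if dup is not None:
        raise FormatError(f"{path}: duplicate sample id {dup!r}")
    body = raw.iloc[1:, 1:]
    try:
        # numpy's string->float conversion is correctly rounded, so a
        # write/read cycle reproduces every value bit-for-bit (pandas'
        # default fast parser is not)
        values = body.to_numpy(dtype=str).astype(np.float64)
    except ValueError:
        coerced = body.apply(pd.to_numeric, errors="coerce")
        i, j = np.argwhere(coerced.isna().to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric value {body.iat[i, j]!r} at gene "
            f"{gene_ids[i]!r}, sample {sample_ids[j]!r}"
        ) from None
    return ExpressionMatrix(gene_ids, sample_ids, values)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Sample table
# ---------------------------------------------------------------------------


@dataclass
class SampleTable:
    """Per-sample metadata: dosing drug plus per-symptom pathology findings.

    ``severity[symptom]`` is an ordinal grade in {0..4}; grade 0 means the
    symptom was not observed in that sample. ``spontaneous[symptom]`` marks
    findings judged not drug-induced; the exclusion of spontaneous positive
    findings happens downstream, not here.
    """

    frame: pd.DataFrame = field(repr=False)
    symptoms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        f = self.frame
        for col in ("sample_id", "drug_id"):
            if col not in f.columns:
                raise ValidationError(f"sample table missing column {col!r}")
        dup = _find_duplicate([str(s) for s in f["sample_id"]])
        if dup is not None:
            raise ValidationError(f"duplicate sample id: {dup!r}")
        for sym in self.symptoms:
            sev_col = SEVERITY_PREFIX + sym
            sp_col = SPONTANEOUS_PREFIX + sym
            if sev_col not in f.columns or sp_col not in f.columns:
                raise ValidationError(f"missing severity/spontaneous columns for {sym!r}")
            sev = f[sev_col].to_numpy()
            if not np.all((sev >= 0) & (sev <= MAX_GRADE)):
                bad = sev[(sev < 0) | (sev > MAX_GRADE)][0]
                raise ValidationError(
                    f"severity grade {bad} for symptom {sym!r} outside 0..{MAX_GRADE}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.frame["sample_id"]]

    @property
    def drug_ids(self) -> np.ndarray:
        return self.frame["drug_id"].to_numpy(dtype=object)

    def severity(self, symptom: str) -> np.ndarray:
        self._check_symptom(symptom)
        return self.frame[SEVERITY_PREFIX + symptom].to_numpy(dtype=int)

    def spontaneous(self, symptom: str) -> np.ndarray:
        self._check_symptom(symptom)
        return self.frame[SPONTANEOUS_PREFIX + symptom].to_numpy(dtype=bool)

    def _check_symptom(self, symptom: str) -> None:
        if symptom not in self.symptoms:
            raise LookupError_(
                f"unknown symptom {symptom!r}; known: {sorted(self.symptoms)}"
            )

    def __len__(self) -> int:
        return len(self.frame)


def _parse_bool(value: str, where: str) -> bool:
    v = str(value).strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise FormatError(f"{where}: cannot parse boolean {value!r}")


def read_samples(path) -> SampleTable:
    """Read the per-sample metadata TSV into a validated :class:`SampleTable`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns or "drug_id" not in df.columns:
        raise FormatError(f"{path}: first columns must be sample_id, drug_id")
    symptoms = sorted(
        c[len(SEVERITY_PREFIX):] for c in df.columns if c.startswith(SEVERITY_PREFIX)
    )
    for sym in symptoms:
        col = SEVERITY_PREFIX + sym
        sev = pd.to_numeric(df[col], errors="coerce")
        if sev.isna().any() or not np.allclose(sev, sev.round()):
            bad = df[col][sev.isna() | ~np.isclose(sev, sev.round())].iloc[0]
            raise ValidationError(f"{path}: non-integer severity {bad!r} for {sym!r}")
        sev = sev.astype(int)
        if ((sev < 0) | (sev > MAX_GRADE)).any():
            bad = sev[(sev < 0) | (sev > MAX_GRADE)].iloc[0]
            raise ValidationError(
                f"{path}: severity grade {bad} for {sym!r} outside 0..{MAX_GRADE}"
            )
        df[col] = sev
        sp_col = SPONTANEOUS_PREFIX + sym
        if sp_col not in df.columns:
            raise FormatError(f"{path}: missing column {sp_col!r}")
        df[sp_col] = [
            _parse_bool(v, f"{path} row {i}") for i, v in enumerate(df[sp_col])
        ]
    return SampleTable(frame=df, symptoms=symptoms)


def write_samples(table: SampleTable, path) -> None:
    out = table.frame.copy()
    for sym in table.symptoms:
        col = SPONTANEOUS_PREFIX + sym
        out[col] = np.where(out[col].astype(bool), "true", "false")
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene-set annotation (GMT)
# ---------------------------------------------------------------------------


@dataclass
class TermRecord:
    term_id: str
    term_name: str
    member_gene_ids: frozenset[str]


@dataclass
class AnnotationTable:
    """Collection of gene sets used as the enrichment vocabulary."""

    terms: list[TermRecord]

    def __post_init__(self) -> None:
        dup = _find_duplicate([t.term_id for t in self.terms])
        if dup is not None:
            raise ValidationError(f"duplicate term id: {dup!r}")
        for t in self.terms:
            if not t.member_gene_ids:
                raise ValidationError(f"term {t.term_id!r} has an empty member set")

    def __len__(self) -> int:
        return len(self.terms)

    def __getitem__(self, term_id: str) -> TermRecord:
        for t in self.terms:
            if t.term_id == term_id:
                return t
        raise LookupError_(f"unknown term id {term_id!r}")


def read_gmt(path) -> AnnotationTable:
    """Read a GMT file; member genes are deduplicated within each term."""
    terms: list[TermRecord] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            term_id, term_name = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise FormatError(f"{path}:{lineno}: term {term_id!r} has no genes")
            terms.append(TermRecord(term_id, term_name, genes))
    return AnnotationTable(terms)


def write_gmt(annotation: AnnotationTable, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for t in annotation.terms:
            genes = "\t".join(sorted(t.member_gene_ids))
            fh.write(f"{t.term_id}\t{t.term_name}\t{genes}\n")
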