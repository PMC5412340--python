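"""Hypergeometric over-representation screening of marker sets.

For a marker set of size ``n`` drawn from a universe of ``N`` genes, a
term with ``K`` members in the universe and ``k`` members among the
markers gets the upper-tail hypergeometric p-value

    p = sum_{i=k}^{min(K, n)} C(K, i) C(N-K, n-i) / C(N, n),

the probability of an overlap at least as large under random marker
draws. ``mode='ease'`` applies the conservative EASE convention of
scoring ``k - 1`` successes instead of ``k``. Genes outside the
supplied universe never count toward ``k`` or ``n``. Significance is
flagged at a raw p-value threshold (default 0.01); optional
Benjamini–Hochberg correction is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataio import AnnotationTable
from .errors import ValidationError
from .selection import MarkerSet

__all__ = ["EnrichmentResult", "enrich", "hypergeom_tail"]


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # markers in term
    K: int  # term size in universe
    n: int  # marker-set size in universe
    N: int  # universe size
    p_value: float
    significant: bool

    def __post_init__(self) -> None:
        if self.k > min(self.K, self.n):
            raise ValidationError("overlap exceeds term or marker-set size")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError("p-value outside [0, 1]")


def hypergeom_tail(k: int, K: int, n: int, N: int, mode: str = "plain") -> float:
    """Upper-tail hypergeometric probability P(overlap >= k).

    ``mode='ease'`` substitutes ``k - 1`` for ``k`` (floored at 0).
    """
    if mode not in ("plain", "ease"):
        raise ValidationError(f"unknown enrichment mode {mode!r}")
    kk = max(k - 1, 0) if mode == "ease" else k
    if kk <= 0:
        return 1.0
    # sf(kk - 1) = P(X >= kk) for X ~ Hypergeom(N, K, n)
    return float(stats.hypergeom.sf(kk - 1, N, K, n))


def enrich(
    markers: MarkerSet,
    annotation: AnnotationTable,
    universe: set[str],
    alpha: float = 0.01,
    mode: str = "plain",
    correction: str | None = None,
) -> list[EnrichmentResult]:
    """Screen every term for over-representation in ``markers``.

    Results are sorted by ascending p-value (ties by term id); terms
    with zero overlap are reported with p = 1. ``correction='bh'``
    applies Benjamini–Hochberg before flagging significance.
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    universe = set(universe)
    if not universe:
        raise ValidationError("empty background universe")
    marker_genes = set(markers.genes) & universe
    if not marker_genes:
        raise ValidationError("no marker genes remain after universe intersection")
    N = len(universe)
    n = len(marker_genes)
    rows: list[EnrichmentResult] = []
    for term in annotation.terms:
        members = term.member_gene_ids & universe
        K = len(members)
        k = len(members & marker_genes)
        p = hypergeom_tail(k, K, n, N, mode=mode) if k > 0 else 1.0
        rows.append(
            EnrichmentResult(
                term_id=term.term_id,
                term_name=term.term_name,
                k=k,
                K=K,
                n=n,
                N=N,
                p_value=p,
                significant=False,
            )
        )
    rows.sort(key=lambda r: (r.p_value, r.term_id))
    if correction == "bh":
        pvals = np.array([r.p_value for r in rows])
        T = len(pvals)
        adj = np.minimum.accumulate((pvals * T / np.arange(1, T + 1))[::-1])[::-1]
        adj = np.minimum(adj, 1.0)
        for r, q in zip(rows, adj):
            r.significant = bool(q < alpha)
    elif correction is None:
        for r in rows:
            r.significant = bool(r.p_value < alpha)
    else:
        raise ValidationError(f"unknown correction {correction!r}")
    return rows
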