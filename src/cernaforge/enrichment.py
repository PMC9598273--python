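"""Generic over-representation analysis against user-supplied term maps.

The test is the standard one-sided hypergeometric ORA: for a query of n
genes drawn from a background of N, a term with K annotated genes and k
query hits gets p = P[X >= k], X ~ Hypergeom(N, K, n), with
Benjamini-Hochberg adjustment across the tested terms.  Term content
(GO, KEGG or anything else) is always supplied as a table; no live
database queries, so results are database-version independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import InvalidArgumentError


@dataclass
class TermMap:
    terms: dict[str, set[str]]  # term id -> gene ids
    names: dict[str, str]  # term id -> display name
    background: set[str]

    def __post_init__(self) -> None:
        for t, genes in self.terms.items():
            if not genes <= self.background:
                raise InvalidArgumentError(
                    f"term {t} contains genes outside the background"
                )

    @classmethod
    def from_tsv(cls, path: str | Path, background: set[str] | None = None) -> "TermMap":
        """Read a (term_id, term_name, gene_id) table; background defaults
        to the union of all annotated genes."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        terms: dict[str, set[str]] = {}
        names: dict[str, str] = {}
        for tid, tname, gid in df.itertuples(index=False):
            terms.setdefault(tid, set()).add(gid)
            names[tid] = tname
        bg = background if background is not None else set().union(*terms.values())
        return cls(terms, names, bg)


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # query hits in term
    n: int  # query size
    K: int  # term size
    N: int  # background size
    p_value: float
    bh_fdr: float


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q >= p elementwise)."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def ora(query: Iterable[str], term_map: TermMap) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of a query gene list.

    Query genes outside the background are dropped with a warning;
    empty terms are skipped.  Results are sorted by raw p, then term id.
    """
    if not term_map.background:
        raise InvalidArgumentError("background must be non-empty")
    query = set(query)
    stray = query - term_map.background
    if stray:
        warnings.warn(
            f"{len(stray)} query gene(s) outside the background were dropped"
        )
        query &= term_map.background
    N = len(term_map.background)
    n = len(query)
    results = []
    for tid in sorted(term_map.terms):
        genes = term_map.terms[tid]
        K = len(genes)
        if K == 0:
            continue
        k = len(query & genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        results.append((tid, k, K, min(p, 1.0)))
    qvals = bh_adjust([r[3] for r in results])
    out = [
        EnrichmentResult(
            tid, term_map.names.get(tid, tid), k, n, K, N, p, float(q)
        )
        for (tid, k, K, p), q in zip(results, qvals)
    ]
    out.sort(key=lambda r: (r.p_value, r.term_id))
    return out


def enrichment_table(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.term_id, r.term_name, r.k, r.n, r.K, r.N, r.p_value, r.bh_fdr)
            for r in results
        ],
        columns=["term_id", "term_name", "k", "n", "K", "N", "p_value", "bh_fdr"],
    )
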