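"""Hypergeometric term enrichment of candidate gene sets.

Given a universe of N annotated genes, a candidate set of n genes, and a
term covering M genes of which m are candidates, the enrichment p-value is
the upper hypergeometric tail

    P = 1 - sum_{i=0}^{m-1} C(M, i) C(N-M, n-i) / C(N, n)

i.e. the probability of drawing at least m term genes in n draws without
replacement.  GO-style analyses adjust with the Bonferroni correction at a
0.05 cut-off; pathway-style analyses use Benjamini-Hochberg FDR <= 0.05.
Only terms with at least one candidate overlap are tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Set

import numpy as np
from scipy.stats import hypergeom

__all__ = [
    "AnnotationUniverse",
    "EnrichmentResult",
    "hypergeom_p",
    "bonferroni",
    "bh_fdr",
    "run_enrichment",
    "load_gene2term",
]

logger = logging.getLogger(__name__)


def hypergeom_p(N: int, n: int, M: int, m: int) -> float:
    """Upper-tail hypergeometric probability P(overlap >= m).

    Parameters follow the enrichment convention: *N* genes in the annotated
    universe, *n* candidate genes, *M* genes carrying the term, *m*
    candidates carrying the term.  The empty sum (m = 0) gives 1.0.
    """
    if not (0 <= M <= N and 0 <= n <= N):
        raise ValueError("require 0 <= M <= N and 0 <= n <= N")
    if m < 0 or m > min(n, M):
        raise ValueError(f"overlap m={m} exceeds min(n={n}, M={M})")
    # survival function at m-1 == P(X >= m); scipy works in log space
    return float(hypergeom.sf(m - 1, N, M, n))


def bonferroni(pvalues: Sequence[float]) -> List[float]:
    """Bonferroni family-wise correction: p * k, capped at 1."""
    k = len(pvalues)
    return [min(1.0, p * k) for p in pvalues]


def bh_fdr(pvalues: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up q-values with enforced monotonicity."""
    p = np.asarray(pvalues, dtype=float)
    k = len(p)
    if k == 0:
        return []
    order = np.argsort(p, kind="stable")
    ranked = p[order] * k / np.arange(1, k + 1)
    # enforce monotone non-decreasing q along increasing p
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(k)
    out[order] = q
    return out.tolist()


@dataclass
class AnnotationUniverse:
    """Gene-to-term annotation background for one enrichment mode."""

    term_genes: Dict[str, Set[str]]
    genes: Set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.genes:
            self.genes = set().union(*self.term_genes.values()) if self.term_genes else set()

    @property
    def N(self) -> int:
        return len(self.genes)


@dataclass
class EnrichmentResult:
    term: str
    N: int
    n: int
    M: int
    m: int
    p_raw: float
    p_adjusted: float
    significant: bool


def load_gene2term(path) -> AnnotationUniverse:
    """Read a gene<TAB>term (optional third namespace column) table."""
    term_genes: Dict[str, Set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed gene2term line: {line!r}")
            gene, term = parts[0], parts[1]
            term_genes.setdefault(term, set()).add(gene)
    return AnnotationUniverse(term_genes=term_genes)


def run_enrichment(
    candidates: Iterable[str],
    universe: AnnotationUniverse,
    mode: str = "GO",
    alpha: float = 0.05,
) -> List[EnrichmentResult]:
    """Test every term with >= 1 candidate overlap and rank the results.

    ``mode="GO"`` applies Bonferroni, ``mode="pathway"`` applies BH FDR;
    significance is adjusted p <= *alpha*.  Candidate genes absent from the
    universe are dropped from n (with a logged tally).  Output is sorted by
    adjusted then raw p-value, then term id.
    """
    if mode not in ("GO", "pathway"):
        raise ValueError(f"unknown enrichment mode: {mode!r}")
    cand = set(candidates)
    unknown = cand - universe.genes
    if unknown:
        logger.warning(
            "%d candidate gene(s) absent from the %s universe; ignored",
            len(unknown),
            mode,
        )
    cand &= universe.genes
    N, n = universe.N, len(cand)
    rows = []
    for term in sorted(universe.term_genes):
        genes = universe.term_genes[term]
        m = len(cand & genes)
        if m == 0:
            continue
        rows.append((term, len(genes), m, hypergeom_p(N, n, len(genes), m)))
    raw = [r[3] for r in rows]
    adj = bonferroni(raw) if mode == "GO" else bh_fdr(raw)
    results = [
        EnrichmentResult(
            term=term,
            N=N,
            n=n,
            M=M,
            m=m,
            p_raw=p,
            p_adjusted=q,
            significant=q <= alpha,
        )
        for (term, M, m, p), q in zip(rows, adj)
    ]
    results.sort(key=lambda r: (r.p_adjusted, r.p_raw, r.term))
    return results


def write_enrichment_tsv(results: Sequence[EnrichmentResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("term\tN\tn\tM\tm\tp_raw\tp_adjusted\tsignificant\n")
        for r in results:
            fh.write(
                f"{r.term}\t{r.N}\t{r.n}\t{r.M}\t{r.m}\t"
                f"{r.p_raw:.6g}\t{r.p_adjusted:.6g}\t{int(r.significant)}\n"
            )
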