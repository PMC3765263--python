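"""Two-library differential expression of miRNA counts.

Compares raw per-miRNA counts between two sequencing libraries of clean-read
totals N1 (control) and N2 (treatment) with the Audic-Claverie exact test
for digital expression data.  Given a count *x* in the control library, the
probability of observing *y* in the treatment library is

    p(y | x) = (N2/N1)^y * (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) )

which is a negative-binomial tail in *y*.  Significance is the two-sided
tail probability 2 * min(P(y' <= y), P(y' >= y)), capped at 1.  Expression
is normalised to tags per million (TPM = 1e6 * count / clean total); zero
TPMs are revised to 0.01 so the fold change is defined, and miRNAs whose
revised TPM is below 1 in both libraries are excluded as too low to call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "ComparisonPair",
    "DEResult",
    "tpm_normalize",
    "revise_low_expression",
    "fold_change",
    "ac_pvalue",
    "classify",
    "compare_pair",
    "cluster_profiles",
    "sig_class_fractions",
]

SIG_STRONG = "p<0.01"
SIG_WEAK = "0.01<=p<0.05"
SIG_NS = "NS"

RATIO_UP = "ratio>2"
RATIO_MID = "1/2<ratio<=2"
RATIO_DOWN = "ratio<=1/2"


@dataclass(frozen=True)
class ComparisonPair:
    """One control/treatment library pair with clean-read totals N1, N2."""

    control_stage: str
    treatment_stage: str
    N1: int
    N2: int

    def __post_init__(self) -> None:
        if self.N1 <= 0 or self.N2 <= 0:
            raise ValueError("library totals N1, N2 must be positive")


@dataclass
class DEResult:
    mirna_id: str
    x: int
    y: int
    tpm_control: float
    tpm_treatment: float
    log2fc: float
    pvalue: float
    sig_class: str
    ratio_class: str
    excluded: bool


def tpm_normalize(count: float, clean_total: int) -> float:
    """Tags-per-million normalisation: 1e6 * count / clean_total."""
    if clean_total <= 0:
        raise ValueError("clean_total must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return 1e6 * count / clean_total


def revise_low_expression(
    tpm_control: float, tpm_treatment: float, *, only_when_both_zero: bool = False
) -> Tuple[float, float, bool]:
    """Apply the low-expression revision to a TPM pair.

    Zero TPMs are replaced by 0.01 (by default any zero; with
    ``only_when_both_zero`` only when both are zero).  Returns the revised
    pair and an ``excluded`` flag, set when both revised TPMs are < 1.
    """
    c, t = tpm_control, tpm_treatment
    if only_when_both_zero:
        if c == 0 and t == 0:
            c = t = 0.01
    else:
        c = 0.01 if c == 0 else c
        t = 0.01 if t == 0 else t
    excluded = c < 1 and t < 1
    return c, t, excluded


def fold_change(tpm_treatment: float, tpm_control: float) -> float:
    """log2(treatment / control) of revised TPMs."""
    if tpm_treatment <= 0 or tpm_control <= 0:
        raise ValueError("fold change requires positive (revised) TPMs")
    return math.log2(tpm_treatment / tpm_control)


def _log_pmf(ys: np.ndarray, x: int, log_r: float) -> np.ndarray:
    """log p(y|x) for an array of y, with r = N2/N1."""
    return (
        gammaln(x + ys + 1)
        - gammaln(x + 1)
        - gammaln(ys + 1)
        + ys * log_r
        - (x + ys + 1) * np.log1p(math.exp(log_r))
    )


def ac_pvalue(x: int, y: int, pair: ComparisonPair) -> float:
    """Two-sided Audic-Claverie p-value for counts x (control), y (treatment).

    Tails are accumulated in log space; the infinite upper tail is taken as
    the complement of the finite lower sum, so only the lower tail is ever
    summed explicitly.
    """
    if x < 0 or y < 0 or x != int(x) or y != int(y):
        raise ValueError("counts must be non-negative integers")
    log_r = math.log(pair.N2) - math.log(pair.N1)
    ys = np.arange(0, y + 1)
    logs = _log_pmf(ys, x, log_r)
    lower = float(np.exp(logsumexp(logs)))  # P(y' <= y)
    upper = 1.0 - lower + float(np.exp(logs[-1]))  # P(y' >= y)
    lower = min(lower, 1.0)
    upper = min(max(upper, 0.0), 1.0)
    return min(1.0, 2.0 * min(lower, upper))


def _sig_class(p: float) -> str:
    if p < 0.01:
        return SIG_STRONG
    if p < 0.05:
        return SIG_WEAK
    return SIG_NS


def _ratio_class(ratio: float) -> str:
    if ratio > 2:
        return RATIO_UP
    if ratio > 0.5:
        return RATIO_MID
    return RATIO_DOWN


def classify(results: Iterable[DEResult]) -> None:
    """(Re)assign significance and ratio classes in place.

    Significance bands: ``p < 0.01``, ``0.01 <= p < 0.05``, else NS.
    Ratio bands on revised TPM treatment/control: ``> 2``,
    ``1/2 < ratio <= 2`` and ``<= 1/2``.
    """
    for r in results:
        r.sig_class = _sig_class(r.pvalue)
        r.ratio_class = _ratio_class(r.tpm_treatment / r.tpm_control)


def compare_pair(
    counts_control: Mapping[str, int],
    counts_treatment: Mapping[str, int],
    pair: ComparisonPair,
    *,
    only_when_both_zero: bool = False,
) -> List[DEResult]:
    """Full two-library comparison over the union of miRNA ids.

    The p-value is computed from raw counts and library totals; exclusion
    and the classification bands operate on revised TPM.
    """
    ids = sorted(set(counts_control) | set(counts_treatment))
    out: List[DEResult] = []
    for mid in ids:
        x = int(counts_control.get(mid, 0))
        y = int(counts_treatment.get(mid, 0))
        tc = tpm_normalize(x, pair.N1)
        tt = tpm_normalize(y, pair.N2)
        rc, rt, excluded = revise_low_expression(
            tc, tt, only_when_both_zero=only_when_both_zero
        )
        p = ac_pvalue(x, y, pair)
        res = DEResult(
            mirna_id=mid,
            x=x,
            y=y,
            tpm_control=rc,
            tpm_treatment=rt,
            log2fc=fold_change(rt, rc),
            pvalue=p,
            sig_class=_sig_class(p),
            ratio_class=_ratio_class(rt / rc),
            excluded=excluded,
        )
        out.append(res)
    return out


def sig_class_fractions(results: Sequence[DEResult]) -> Dict[str, float]:
    """Fraction of (non-excluded) miRNAs in each significance band."""
    kept = [r for r in results if not r.excluded]
    n = len(kept)
    frac = {SIG_STRONG: 0.0, SIG_WEAK: 0.0, SIG_NS: 0.0}
    for r in kept:
        frac[r.sig_class] += 1
    return {k: (v / n if n else 0.0) for k, v in frac.items()}


def cluster_profiles(
    profiles: Mapping[str, Sequence[float]], k: int = 5
) -> Dict[str, int]:
    """Cluster per-miRNA log2 fold-change profiles across stage pairs.

    Agglomerative hierarchical clustering with Euclidean distance and
    average linkage, cut at *k* clusters.  Deterministic for a fixed input
    order (ids are sorted internally).  With fewer profiles than *k*, each
    miRNA gets its own cluster.
    """
    from scipy.cluster.hierarchy import fcluster, linkage

    ids = sorted(profiles)
    if not ids:
        return {}
    if len(ids) <= k:
        return {mid: i + 1 for i, mid in enumerate(ids)}
    mat = np.asarray([profiles[mid] for mid in ids], dtype=float)
    Z = linkage(mat, method="average", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return {mid: int(lab) for mid, lab in zip(ids, labels)}
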