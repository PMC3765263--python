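"""Rule-based miRNA target-site prediction in 3'UTR sequences.

Every miRNA-length window of every UTR is tested as an ungapped
antiparallel duplex (miRNA 5'->3' against the UTR window 3'->5').  A site
is accepted when it passes all of:

* weighted mismatches <= 4 (a G:U wobble counts 0.5),
* no run of more than two consecutive mismatch positions anywhere,
* no adjacent mismatch positions within miRNA positions 2-12,
* no mismatch at positions 10-11 (the cleavage-site core),
* weighted mismatches within positions 1-12 <= 2.5,
* duplex hybridisation energy at least 75% of the energy of the miRNA
  bound to its perfect Watson-Crick complement.

Positions are 1-based from the miRNA 5' end.  G:U wobbles contribute 0.5
to the weighted counts but count as full mismatch *positions* for the
adjacency and positional-exclusion rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

from .structure import (
    EnergyModel,
    DEFAULT_MODEL,
    classify_pairs,
    duplex_energy,
    perfect_complement_energy,
)

__all__ = [
    "TargetRules",
    "TargetSite",
    "align_site",
    "check_rules",
    "scan_utrs",
]

logger = logging.getLogger(__name__)

RULE_NAMES = (
    "max_mismatches",
    "max_adjacent_mm",
    "no_adjacent_mm_2_12",
    "no_mm_10_11",
    "max_mm_1_12",
    "min_mfe_ratio",
)


@dataclass(frozen=True)
class TargetRules:
    """Thresholds of the positional target-site rules."""

    max_mismatches: float = 4.0
    max_adjacent_mm: int = 2
    no_adjacent_region: Tuple[int, int] = (2, 12)
    no_mm_positions: Tuple[int, int] = (10, 11)
    max_mm_1_12: float = 2.5
    min_mfe_ratio: float = 0.75


def align_site(mirna: str, utr_window: str) -> List[str]:
    """Position-wise classification of the ungapped antiparallel duplex.

    Returns, per miRNA position 1..L, one of ``"WC"``, ``"GU"``, ``"MM"``.
    """
    return classify_pairs(mirna, utr_window)


def _mm_weight(c: str) -> float:
    return 1.0 if c == "MM" else (0.5 if c == "GU" else 0.0)


def check_rules(
    classification: Sequence[str],
    rules: TargetRules = TargetRules(),
    mfe_ratio: float | None = None,
) -> Tuple[Dict[str, bool], bool]:
    """Evaluate every rule on a classified duplex.

    *mfe_ratio* is |duplex energy| / |perfect-complement energy|; pass
    ``None`` to skip the energy rule (it is then recorded as passing).
    Returns (per-rule verdicts, accept = all pass).
    """
    L = len(classification)
    is_mm_pos = [c in ("MM", "GU") for c in classification]  # positional rules
    weights = [_mm_weight(c) for c in classification]

    verdicts: Dict[str, bool] = {}
    verdicts["max_mismatches"] = sum(weights) <= rules.max_mismatches

    # longest run of consecutive mismatch positions
    longest = run = 0
    for flag in is_mm_pos:
        run = run + 1 if flag else 0
        longest = max(longest, run)
    verdicts["max_adjacent_mm"] = longest <= rules.max_adjacent_mm

    lo, hi = rules.no_adjacent_region
    region = is_mm_pos[lo - 1 : hi]  # 1-based inclusive
    adjacent_in_region = any(a and b for a, b in zip(region, region[1:]))
    verdicts["no_adjacent_mm_2_12"] = not adjacent_in_region

    p0, p1 = rules.no_mm_positions
    verdicts["no_mm_10_11"] = not any(is_mm_pos[p0 - 1 : p1])

    verdicts["max_mm_1_12"] = sum(weights[:12]) <= rules.max_mm_1_12

    verdicts["min_mfe_ratio"] = (
        True if mfe_ratio is None else mfe_ratio >= rules.min_mfe_ratio
    )
    return verdicts, all(verdicts.values())


@dataclass
class TargetSite:
    """One accepted (or evaluated) miRNA binding site in a UTR."""

    mirna_id: str
    gene_id: str
    start: int  # 0-based half-open in the UTR
    end: int
    mismatch_score: float
    mfe: float
    mfe_ratio: float
    rule_verdicts: Dict[str, bool] = field(default_factory=dict)
    accepted: bool = False


def scan_utrs(
    mirnas: Mapping[str, str],
    utrs: Mapping[str, str],
    rules: TargetRules = TargetRules(),
    model: EnergyModel = DEFAULT_MODEL,
    keep_rejected: bool = False,
) -> List[TargetSite]:
    """Scan every UTR window of every miRNA and collect accepted sites.

    UTRs shorter than the miRNA are skipped with a logged warning.  Results
    are deduplicated per (miRNA, gene, position) and sorted.
    """
    sites: Dict[Tuple[str, str, int], TargetSite] = {}
    for mid in sorted(mirnas):
        mirna = mirnas[mid]
        L = len(mirna)
        pce = perfect_complement_energy(mirna, model)
        for gene in sorted(utrs):
            utr = utrs[gene]
            if len(utr) < L:
                logger.warning(
                    "UTR of %s (%d nt) shorter than %s (%d nt); skipped",
                    gene,
                    len(utr),
                    mid,
                    L,
                )
                continue
            for off in range(len(utr) - L + 1):
                window = utr[off : off + L]
                cls = align_site(mirna, window)
                score = sum(_mm_weight(c) for c in cls)
                if score > rules.max_mismatches and not keep_rejected:
                    continue
                dup = duplex_energy(mirna, window, model=model)
                ratio = abs(dup) / abs(pce) if pce != 0 else 0.0
                verdicts, accept = check_rules(cls, rules, mfe_ratio=ratio)
                if accept or keep_rejected:
                    key = (mid, gene, off)
                    sites[key] = TargetSite(
                        mirna_id=mid,
                        gene_id=gene,
                        start=off,
                        end=off + L,
                        mismatch_score=score,
                        mfe=dup,
                        mfe_ratio=ratio,
                        rule_verdicts=verdicts,
                        accepted=accept,
                    )
    return [sites[k] for k in sorted(sites)]


def write_sites_tsv(sites: Sequence[TargetSite], path) -> None:
    with open(path, "w") as fh:
        cols = ["mirna_id", "gene_id", "start", "end", "mismatch_score",
                "mfe", "mfe_ratio", "accepted"] + list(RULE_NAMES)
        fh.write("\t".join(cols) + "\n")
        for s in sites:
            row = [s.mirna_id, s.gene_id, str(s.start), str(s.end),
                   f"{s.mismatch_score:g}", f"{s.mfe:.2f}",
                   f"{s.mfe_ratio:.4f}", str(int(s.accepted))]
            row += [str(int(s.rule_verdicts.get(r, True))) for r in RULE_NAMES]
            fh.write("\t".join(row) + "\n")
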