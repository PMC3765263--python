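"""Conserved miRNA identification and quantification.

Clean tags are compared against a reference set of miRNA precursors and
mature sequences (miRBase-style, typically from a close relative when the
species itself has no deposited miRNAs).  A tag is credited to a mature
miRNA when it aligns inside the precursor with at most 2 mismatches and its
5' end falls within +/- 4 nt of the annotated mature 5' end — the usual
tolerance for isomiR-aware counting.  Each tag is credited to at most one
miRNA (fewest mismatches, then smallest 5' offset, then lexicographic id).
Per-stage counts feed stage-membership (Venn) analysis and top-expressed
tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from Bio import SeqIO

from .preprocess import CleanLibrary

__all__ = [
    "MirnaReference",
    "ExpressionRecord",
    "StageMembership",
    "load_reference",
    "match_known",
    "build_expression_records",
    "stage_membership",
    "venn_counts",
    "top_expressed",
]

STAGES = ("anagen", "catagen", "telogen")


@dataclass(frozen=True)
class ReferenceEntry:
    mature_id: str
    precursor_id: str
    precursor_seq: str  # DNA alphabet
    mature_start: int
    mature_len: int


@dataclass
class MirnaReference:
    """Reference precursor/mature pairs with mature coordinates located."""

    entries: List[ReferenceEntry]

    @property
    def mature_ids(self) -> List[str]:
        return sorted(e.mature_id for e in self.entries)


def _dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def load_reference(precursor_fasta, mature_fasta) -> MirnaReference:
    """Parse reference FASTAs and locate each mature inside a precursor.

    Raises ``ValueError`` naming any mature id that is not a subsequence of
    any precursor.
    """
    precursors = {
        rec.id: _dna(str(rec.seq)) for rec in SeqIO.parse(str(precursor_fasta), "fasta")
    }
    entries: List[ReferenceEntry] = []
    for rec in SeqIO.parse(str(mature_fasta), "fasta"):
        mat = _dna(str(rec.seq))
        placed = False
        for pid, pseq in sorted(precursors.items()):
            pos = pseq.find(mat)
            if pos >= 0:
                entries.append(
                    ReferenceEntry(
                        mature_id=rec.id,
                        precursor_id=pid,
                        precursor_seq=pseq,
                        mature_start=pos,
                        mature_len=len(mat),
                    )
                )
                placed = True
                break
        if not placed:
            raise ValueError(
                f"mature miRNA {rec.id!r} is not a subsequence of any precursor"
            )
    return MirnaReference(entries=entries)


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def match_known(
    library: CleanLibrary,
    reference: MirnaReference,
    max_mismatches: int = 2,
    max_offset: int = 4,
) -> Dict[str, int]:
    """Per-miRNA raw counts for one library.

    For each tag the best-scoring credit across all reference matures is
    taken; ties break toward the smaller 5' offset, then the
    lexicographically smaller miRNA id.
    """
    counts: Dict[str, int] = {}
    for tag, count in library.tags.items():
        tag_dna = _dna(tag)
        best: Optional[Tuple[int, int, str]] = None
        for e in reference.entries:
            lo = max(0, e.mature_start - max_offset)
            hi = min(
                e.mature_start + max_offset, len(e.precursor_seq) - len(tag_dna)
            )
            for p in range(lo, hi + 1):
                mm = _hamming(tag_dna, e.precursor_seq[p : p + len(tag_dna)])
                if mm > max_mismatches:
                    continue
                key = (mm, abs(p - e.mature_start), e.mature_id)
                if best is None or key < best:
                    best = key
        if best is not None:
            counts[best[2]] = counts.get(best[2], 0) + count
    return counts


@dataclass
class ExpressionRecord:
    """Raw counts and TPM for one miRNA across the stage libraries."""

    mirna_id: str
    counts: Dict[str, int] = field(default_factory=dict)
    tpm: Dict[str, float] = field(default_factory=dict)


def build_expression_records(
    stage_counts: Mapping[str, Mapping[str, int]],
    clean_totals: Mapping[str, int],
) -> List[ExpressionRecord]:
    """Combine per-stage count maps into records with TPM normalisation."""
    ids = sorted({m for counts in stage_counts.values() for m in counts})
    records = []
    for mid in ids:
        counts = {s: int(stage_counts[s].get(mid, 0)) for s in stage_counts}
        tpm = {
            s: 1e6 * counts[s] / clean_totals[s] if clean_totals[s] else 0.0
            for s in stage_counts
        }
        records.append(ExpressionRecord(mirna_id=mid, counts=counts, tpm=tpm))
    return records


@dataclass(frozen=True)
class StageMembership:
    mirna_id: str
    present_in: frozenset


def stage_membership(
    records: Iterable[ExpressionRecord], min_count: int = 1
) -> List[StageMembership]:
    """Presence per stage: raw count >= *min_count* (default 1)."""
    out = []
    for rec in records:
        present = frozenset(s for s, c in rec.counts.items() if c >= min_count)
        if present:
            out.append(StageMembership(mirna_id=rec.mirna_id, present_in=present))
    return out


def venn_counts(
    memberships: Iterable[StageMembership], stages: Sequence[str] = STAGES
) -> Dict[str, int]:
    """Counts of the 7 Venn regions over the given stages.

    Region keys are '&'-joined sorted stage names (e.g. ``"anagen"`` for
    anagen-specific, ``"anagen&catagen&telogen"`` for all three); regions
    partition the detected miRNAs.
    """
    regions: Dict[str, int] = {}
    for m in memberships:
        key = "&".join(s for s in stages if s in m.present_in)
        regions[key] = regions.get(key, 0) + 1
    return regions


def top_expressed(
    records: Iterable[ExpressionRecord], n: int, stage: str
) -> List[Tuple[str, int]]:
    """Top-*n* miRNAs of one stage by raw count (ties lexicographic)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = sorted(
        ((r.mirna_id, r.counts.get(stage, 0)) for r in records),
        key=lambda t: (-t[1], t[0]),
    )
    return ranked[:n]


def write_expression_tsv(records: Sequence[ExpressionRecord], path) -> None:
    stages = sorted({s for r in records for s in r.counts})
    with open(path, "w") as fh:
        header = ["mirna_id"]
        header += [f"count_{s}" for s in stages] + [f"tpm_{s}" for s in stages]
        fh.write("\t".join(header) + "\n")
        for r in sorted(records, key=lambda r: r.mirna_id):
            row = [r.mirna_id]
            row += [str(r.counts.get(s, 0)) for s in stages]
            row += [f"{r.tpm.get(s, 0.0):.4f}" for s in stages]
            fh.write("\t".join(row) + "\n")
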