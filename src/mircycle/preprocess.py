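"""Raw small-RNA read cleaning and tag collapsing.

Raw FASTQ reads are classified, in a fixed precedence order, into the
contamination accounting used for library quality reporting:

1. low quality (> 2 N bases or > 20% of bases below Phred 10),
2. 3' adapter absent,
3. empty insert after adapter trimming,
4. 5' adapter present in the insert (adapter-adapter ligation),
5. poly(A) insert (>= 90% adenine),
6. insert shorter than 18 nt,
7. (optionally) insert longer than the configured maximum,
8. clean.

Each read lands in exactly one category, so the contaminant counts plus
clean reads partition the high-quality reads.  Clean inserts are collapsed
to unique tags with per-library counts; tags are the unit of all downstream
mapping, annotation and quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "FilterPolicy",
    "FilterStats",
    "CleanLibrary",
    "filter_reads",
    "collapse_tags",
    "length_distribution",
]

CONTAMINANT_CATEGORIES = (
    "adapter3_null",
    "insert_null",
    "adapter5_contaminants",
    "smaller_than_18nt",
    "polyA",
)


@dataclass(frozen=True)
class FilterPolicy:
    """Tunable thresholds of the read-cleaning rules."""

    max_n_bases: int = 2
    max_low_qual_frac: float = 0.20
    low_qual_phred: int = 10
    adapter_seed_len: int = 6
    polya_frac: float = 0.90
    min_insert_len: int = 18
    max_insert_len: Optional[int] = 30  # None disables the upper cap


@dataclass
class FilterStats:
    """Per-library read accounting (the contamination table row set)."""

    total_reads: int = 0
    high_quality: int = 0
    adapter3_null: int = 0
    insert_null: int = 0
    adapter5_contaminants: int = 0
    smaller_than_18nt: int = 0
    polyA: int = 0
    longer_than_max: int = 0
    clean_reads: int = 0

    @property
    def low_quality(self) -> int:
        return self.total_reads - self.high_quality

    @property
    def percentages(self) -> Dict[str, float]:
        """Each category as a percent of high-quality reads."""
        denom = self.high_quality
        cats = CONTAMINANT_CATEGORIES + ("longer_than_max", "clean_reads")
        if denom == 0:
            return {c: 0.0 for c in cats}
        return {c: 100.0 * getattr(self, c) / denom for c in cats}

    def check_partition(self) -> None:
        total = (
            self.adapter3_null
            + self.insert_null
            + self.adapter5_contaminants
            + self.smaller_than_18nt
            + self.polyA
            + self.longer_than_max
            + self.clean_reads
        )
        if total != self.high_quality:
            raise AssertionError(
                f"category counts ({total}) do not partition "
                f"high-quality reads ({self.high_quality})"
            )

    @classmethod
    def from_category_counts(
        cls,
        total_reads: int,
        high_quality: int,
        adapter3_null: int,
        insert_null: int,
        adapter5_contaminants: int,
        smaller_than_18nt: int,
        polyA: int,
        longer_than_max: int = 0,
    ) -> "FilterStats":
        """Build stats from known contaminant counts, deriving clean reads
        as the high-quality remainder (the accounting identity)."""
        clean = high_quality - (
            adapter3_null
            + insert_null
            + adapter5_contaminants
            + smaller_than_18nt
            + polyA
            + longer_than_max
        )
        stats = cls(
            total_reads=total_reads,
            high_quality=high_quality,
            adapter3_null=adapter3_null,
            insert_null=insert_null,
            adapter5_contaminants=adapter5_contaminants,
            smaller_than_18nt=smaller_than_18nt,
            polyA=polyA,
            longer_than_max=longer_than_max,
            clean_reads=clean,
        )
        stats.check_partition()
        return stats

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("type\tcount\tpercent_of_high_quality\n")
            fh.write(f"total_reads\t{self.total_reads}\t\n")
            fh.write(f"high_quality\t{self.high_quality}\t100.00\n")
            pct = self.percentages
            for cat in CONTAMINANT_CATEGORIES + ("clean_reads",):
                fh.write(f"{cat}\t{getattr(self, cat)}\t{pct[cat]:.2f}\n")


@dataclass
class CleanLibrary:
    """Collapsed unique insert tags with counts for one stage library."""

    stage: str
    tags: Dict[str, int] = field(default_factory=dict)

    @property
    def total_clean(self) -> int:
        return sum(self.tags.values())

    @property
    def n_unique(self) -> int:
        return len(self.tags)

    def write_fasta(self, path) -> None:
        """Collapsed tags as FASTA with ``tag<serial>_x<count>`` headers."""
        with open(path, "w") as fh:
            for i, (tag, count) in enumerate(sorted(self.tags.items()), 1):
                fh.write(f">tag{i}_x{count}\n{tag}\n")


def _classify_read(
    seq: str, qual: str, adapter3: str, adapter5: str, policy: FilterPolicy
) -> Tuple[str, Optional[str]]:
    """Return (category, insert-or-None) for one read."""
    seq = seq.upper()
    # 1. quality
    if seq.count("N") > policy.max_n_bases:
        return "low_quality", None
    n_low = sum(1 for q in qual if ord(q) - 33 < policy.low_qual_phred)
    if len(qual) > 0 and n_low / len(qual) > policy.max_low_qual_frac:
        return "low_quality", None
    # 2. 3' adapter: leftmost exact match of the adapter's first 6 bases
    seed3 = adapter3[: policy.adapter_seed_len].upper()
    pos = seq.find(seed3)
    if pos < 0:
        return "adapter3_null", None
    insert = seq[:pos]
    # 3. empty insert
    if not insert:
        return "insert_null", None
    # 4. 5' adapter contamination inside the insert
    seed5 = adapter5[: policy.adapter_seed_len].upper()
    if seed5 in insert:
        return "adapter5_contaminants", None
    # 5. poly(A)
    if insert.count("A") / len(insert) >= policy.polya_frac:
        return "polyA", None
    # 6./7. length window
    if len(insert) < policy.min_insert_len:
        return "smaller_than_18nt", None
    if policy.max_insert_len is not None and len(insert) > policy.max_insert_len:
        return "longer_than_max", None
    return "clean", insert


def filter_reads(
    fastq_path,
    adapter3: str,
    adapter5: str,
    stage: str = "library",
    policy: FilterPolicy = FilterPolicy(),
) -> Tuple[CleanLibrary, FilterStats]:
    """Clean one raw FASTQ library into collapsed tags plus accounting.

    Raises ``ValueError`` naming the record index on a malformed FASTQ
    record; an empty file yields zero stats and an empty library.
    """
    if not adapter3 or not adapter5:
        raise ValueError("adapters must be non-empty")
    stats = FilterStats()
    tags: Dict[str, int] = {}
    with open(fastq_path) as fh:
        it = FastqGeneralIterator(fh)
        index = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                break
            except ValueError as exc:
                raise ValueError(
                    f"malformed FASTQ record at index {index} "
                    f"in {fastq_path}: {exc}"
                ) from exc
            index += 1
            stats.total_reads += 1
            category, insert = _classify_read(seq, qual, adapter3, adapter5, policy)
            if category == "low_quality":
                continue
            stats.high_quality += 1
            if category == "clean":
                stats.clean_reads += 1
                tags[insert] = tags.get(insert, 0) + 1
            else:
                setattr(stats, category, getattr(stats, category) + 1)
    stats.check_partition()
    library = CleanLibrary(stage=stage, tags=dict(sorted(tags.items())))
    return library, stats


def collapse_tags(clean_reads: Iterable[str], stage: str = "library") -> CleanLibrary:
    """Merge identical insert sequences, summing counts.

    Tag ordering in the resulting library (and all writers) is
    lexicographic, so outputs are deterministic.
    """
    tags: Dict[str, int] = {}
    for read in clean_reads:
        read = read.upper().replace("U", "T")
        tags[read] = tags.get(read, 0) + 1
    return CleanLibrary(stage=stage, tags=dict(sorted(tags.items())))


def length_distribution(
    libraries: Iterable[CleanLibrary],
) -> Dict[str, Dict[str, Dict[int, int]]]:
    """Abundance-weighted and distinct-tag length histograms per library."""
    out: Dict[str, Dict[str, Dict[int, int]]] = {}
    for lib in libraries:
        total: Dict[int, int] = {}
        distinct: Dict[int, int] = {}
        for tag, count in lib.tags.items():
            L = len(tag)
            total[L] = total.get(L, 0) + count
            distinct[L] = distinct.get(L, 0) + 1
        out[lib.stage] = {
            "total": dict(sorted(total.items())),
            "distinct": dict(sorted(distinct.items())),
        }
    return out


def write_length_distribution_tsv(dists, path) -> None:
    with open(path, "w") as fh:
        fh.write("stage\tlength\ttotal_count\tdistinct_tags\n")
        for stage, hists in dists.items():
            lengths = sorted(set(hists["total"]) | set(hists["distinct"]))
            for L in lengths:
                fh.write(
                    f"{stage}\t{L}\t{hists['total'].get(L, 0)}\t"
                    f"{hists['distinct'].get(L, 0)}\n"
                )
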