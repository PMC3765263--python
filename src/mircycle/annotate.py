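"""Genome mapping of unique tags and single-class annotation.

Tags are matched exactly and full-length against both genome strands; every
locus is reported.  Each tag then receives exactly one annotation class by
a fixed priority: the structural ncRNAs (rRNA, tRNA, snRNA, snoRNA, scRNA,
srpRNA; GenBank-sourced entries outrank Rfam-sourced ones) beat known miRNA
precursors, which beat repeats, exons and introns in that order.  Exon and
intron assignments are split into sense/antisense by strand agreement
(sense preferred when a tag touches both orientations).  Unmapped tags, or
mapped tags overlapping no feature, are "unan" (unannotated) — the pool
novel-miRNA prediction draws from.  The abundance-weighted rRNA fraction
doubles as a sample-quality indicator: animal small-RNA libraries are
expected to stay below 40%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from intervaltree import IntervalTree

__all__ = [
    "TagHit",
    "Feature",
    "AnnotationSummary",
    "GenomeIndex",
    "map_tags",
    "annotate_tags",
    "rrna_quality_check",
    "load_bed",
    "load_gff3",
    "revcomp",
]

logger = logging.getLogger(__name__)

NCRNA_CLASSES = ("rRNA", "scRNA", "snRNA", "snoRNA", "srpRNA", "tRNA")
FEATURE_CLASSES = NCRNA_CLASSES + ("miRNA", "repeat", "exon", "intron")

ANNOTATION_CLASSES = (
    "exon_antisense",
    "exon_sense",
    "intron_antisense",
    "intron_sense",
    "miRNA",
    "rRNA",
    "repeat",
    "scRNA",
    "snRNA",
    "snoRNA",
    "srpRNA",
    "tRNA",
    "unan",
)

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class TagHit:
    """One exact genomic match of a tag (0-based half-open interval)."""

    tag: str
    chrom: str
    start: int
    end: int
    strand: str


@dataclass(frozen=True)
class Feature:
    """One annotated genomic feature with its class and evidence source."""

    chrom: str
    start: int
    end: int
    strand: str
    cls: str
    source: str = "genbank"  # genbank | rfam | other

    def __post_init__(self) -> None:
        if self.cls not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class label: {self.cls!r}")


class GenomeIndex:
    """Seed-and-verify exact matcher over a small genome.

    Indexes every k-mer (k = minimum tag length) of the forward strand;
    minus-strand hits are found by looking up the reverse complement.
    """

    def __init__(self, genome: Mapping[str, str], k: int = 18):
        self.k = k
        self.genome = {name: seq.upper() for name, seq in genome.items()}
        self._index: Dict[str, List[Tuple[str, int]]] = {}
        for name, seq in self.genome.items():
            for i in range(len(seq) - k + 1):
                self._index.setdefault(seq[i : i + k], []).append((name, i))

    def find(self, tag: str) -> List[TagHit]:
        """All exact full-length loci of *tag* on both strands."""
        tag = tag.upper()
        hits: List[TagHit] = []
        if len(tag) < self.k:
            return hits
        for query, strand in ((tag, "+"), (revcomp(tag), "-")):
            for chrom, pos in self._index.get(query[: self.k], ()):
                if self.genome[chrom][pos : pos + len(query)] == query:
                    hits.append(TagHit(tag, chrom, pos, pos + len(query), strand))
        hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
        return hits


def map_tags(
    tags: Iterable[str],
    genome: Mapping[str, str] | GenomeIndex,
    max_loci: int = 20,
) -> Tuple[Dict[str, List[TagHit]], Dict[str, int], int]:
    """Map unique tags to the genome.

    Returns (hits per tag, per-tag locus counts flagged over *max_loci*,
    count of skipped non-ACGT tags).  Tags hitting more than *max_loci*
    loci keep their hits but are flagged for downstream exclusion (the
    copy-number cap of hairpin prediction).
    """
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    hits: Dict[str, List[TagHit]] = {}
    flagged: Dict[str, int] = {}
    skipped = 0
    for tag in tags:
        if set(tag.upper()) - set("ACGT"):
            skipped += 1
            continue
        h = index.find(tag)
        if h:
            hits[tag] = h
            if len(h) > max_loci:
                flagged[tag] = len(h)
    if skipped:
        logger.warning("skipped %d tag(s) with non-ACGT characters", skipped)
    return hits, flagged, skipped


def _feature_trees(features: Iterable[Feature]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for f in features:
        trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f)
    return trees


_SOURCE_RANK = {"genbank": 0, "rfam": 1}


def _priority_key(f: Feature, hit: TagHit) -> Tuple:
    """Sort key; lower wins.  ncRNA (GenBank > Rfam) > miRNA > repeat >
    exon > intron; within exon/intron, sense beats antisense."""
    if f.cls in NCRNA_CLASSES:
        return (0, _SOURCE_RANK.get(f.source, 2), NCRNA_CLASSES.index(f.cls), 0)
    tier = {"miRNA": 1, "repeat": 2, "exon": 3, "intron": 4}[f.cls]
    antisense = 1 if (f.cls in ("exon", "intron") and f.strand != hit.strand) else 0
    return (tier, antisense, 0, 0)


def _final_label(f: Feature, hit: TagHit) -> str:
    if f.cls in ("exon", "intron"):
        suffix = "sense" if f.strand == hit.strand else "antisense"
        return f"{f.cls}_{suffix}"
    return f.cls


@dataclass
class AnnotationSummary:
    """Per-class tag and read counts plus the rRNA quality fraction."""

    unique_counts: Dict[str, int] = field(default_factory=dict)
    read_counts: Dict[str, int] = field(default_factory=dict)
    total_unique: int = 0
    total_reads: int = 0

    @property
    def rrna_fraction(self) -> float:
        """Abundance-weighted rRNA percentage of all clean reads."""
        if self.total_reads == 0:
            return 0.0
        return 100.0 * self.read_counts.get("rRNA", 0) / self.total_reads

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("class\tunique_tags\ttotal_reads\n")
            for cls in ANNOTATION_CLASSES:
                fh.write(
                    f"{cls}\t{self.unique_counts.get(cls, 0)}\t"
                    f"{self.read_counts.get(cls, 0)}\n"
                )


def annotate_tags(
    tag_counts: Mapping[str, int],
    tag_hits: Mapping[str, Sequence[TagHit]],
    features: Iterable[Feature],
) -> Tuple[Dict[str, str], AnnotationSummary]:
    """Assign each tag its single highest-priority class.

    A tag's candidate features are collected over *all* its genomic loci
    (>= 1 base of overlap counts), then the priority rule is applied once.
    Returns the per-tag class map and the class summary on both the
    unique-tag and abundance-weighted bases.
    """
    trees = _feature_trees(features)
    classes: Dict[str, str] = {}
    summary = AnnotationSummary()
    for tag in sorted(tag_counts):
        count = tag_counts[tag]
        best: Optional[Tuple[Tuple, str]] = None
        for hit in tag_hits.get(tag, ()):
            tree = trees.get(hit.chrom)
            if tree is None:
                continue
            for iv in tree.overlap(hit.start, hit.end):
                f: Feature = iv.data
                key = _priority_key(f, hit)
                if best is None or key < best[0]:
                    best = (key, _final_label(f, hit))
        label = best[1] if best is not None else "unan"
        classes[tag] = label
        summary.unique_counts[label] = summary.unique_counts.get(label, 0) + 1
        summary.read_counts[label] = summary.read_counts.get(label, 0) + count
        summary.total_unique += 1
        summary.total_reads += count
    return classes, summary


def rrna_quality_check(
    summary: AnnotationSummary, threshold: float = 40.0
) -> Tuple[str, float]:
    """Sample-quality verdict from the abundance-weighted rRNA fraction.

    PASS when strictly below *threshold* percent (the animal-sample rule);
    WARN otherwise, returning the fraction either way.
    """
    frac = summary.rrna_fraction
    return ("PASS" if frac < threshold else "WARN"), frac


def load_bed(path) -> List[Feature]:
    """Read features from BED (0-based half-open; columns
    chrom/start/end/name/score/strand, name = class[:source])."""
    feats: List[Feature] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"BED line needs 6 columns: {line!r}")
            chrom, start, end, name, _score, strand = parts[:6]
            cls, _, source = name.partition(":")
            feats.append(
                Feature(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    cls=cls,
                    source=source or "genbank",
                )
            )
    return feats


def load_gff3(path) -> List[Feature]:
    """Read features from GFF3 (1-based inclusive, converted internally)."""
    feats: List[Feature] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ValueError(f"GFF3 line needs 9 columns: {line!r}")
            chrom, source, cls, start, end, _score, strand = parts[:7]
            feats.append(
                Feature(
                    chrom=chrom,
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand,
                    cls=cls,
                    source=source.lower(),
                )
            )
    return feats


def write_bed(features: Iterable[Feature], path) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(
                f"{f.chrom}\t{f.start}\t{f.end}\t{f.cls}:{f.source}\t0\t{f.strand}\n"
            )


def write_tag_classes_tsv(classes: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("tag\tclass\n")
        for tag in sorted(classes):
            fh.write(f"{tag}\t{classes[tag]}\n")
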