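"""Novel miRNA prediction from unannotated mapped tags.

Unannotated tags that map to the genome are clustered by locus; for each
cluster the deepest tag is the putative mature miRNA, a genomic window
large enough to hold the mature, a star arm on either side and short
flanks is excised, folded, and screened against the hairpin criteria used
by Mireap-style predictors:

* mature length 18-26 nt, genomic copy length 20-24 nt,
* precursor minimum free energy <= -18 kcal/mol,
* mature and star arms on opposite sides of one stem, separated by
  at most 35 nt,
* >= 14 base pairs between mature and star,
* largest bulge within either arm of the duplex <= 4 nt,
* arm asymmetry (unpaired mature minus unpaired star) <= 5 nt,
* >= 3 reads sharing the mature 5' end (the Drosha/Dicer cut site),
* tags mapping to more than 20 genomic loci are excluded up front.

Observed star reads, when present, must additionally sit within 2 nt of
the 5' end implied by a 2-nt 3' duplex overhang; with no star reads the
overhang check is skipped (star support is not required).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .annotate import TagHit, revcomp
from .structure import DEFAULT_MODEL, EnergyModel, FoldResult, fold_mfe

__all__ = [
    "NovelParams",
    "HairpinCandidate",
    "NovelPrediction",
    "build_candidates",
    "evaluate_candidate",
    "predict_novel",
    "first_base_stats",
]

CRITERIA = (
    "mature_len",
    "ref_len",
    "copy_number",
    "mfe",
    "opposite_arms",
    "max_space",
    "min_pairs",
    "max_bulge",
    "max_asymmetry",
    "cut_depth",
    "star_overhang",
)


@dataclass(frozen=True)
class NovelParams:
    """The hairpin-screening thresholds (defaults are the Mireap set)."""

    min_mirna_len: int = 18
    max_mirna_len: int = 26
    min_ref_len: int = 20
    max_ref_len: int = 24
    min_cut_depth: int = 3
    max_copy_number: int = 20
    max_precursor_mfe: float = -18.0
    max_mirna_star_space: int = 35
    min_pairs_mirna_star: int = 14
    max_bulge: int = 4
    max_asymmetry: int = 5
    flank_len: int = 10

    def __post_init__(self) -> None:
        if self.max_precursor_mfe >= 0:
            raise ValueError("max_precursor_mfe must be negative")
        for lo, hi in (
            (self.min_mirna_len, self.max_mirna_len),
            (self.min_ref_len, self.max_ref_len),
        ):
            if not (0 < lo <= hi):
                raise ValueError("length bounds must satisfy 0 < min <= max")


@dataclass
class ClusterTag:
    """One tag of a genomic cluster, in precursor-window coordinates later."""

    tag: str
    start: int
    end: int
    depth: int


@dataclass
class HairpinCandidate:
    """An excised genomic window with a putative mature arm."""

    chrom: str
    start: int
    end: int
    strand: str
    precursor_seq: str  # DNA, precursor orientation (5'->3')
    mature_offset: int  # 0-based within precursor_seq
    mature_len: int
    mature_seq: str
    cut_depth: int
    copy_number: int
    cluster_tags: List[ClusterTag] = field(default_factory=list)
    truncated: bool = False
    fold: Optional[FoldResult] = None
    star_offset: Optional[int] = None
    star_len: Optional[int] = None
    verdicts: Dict[str, bool] = field(default_factory=dict)

    @property
    def star_seq(self) -> Optional[str]:
        if self.star_offset is None or self.star_len is None:
            return None
        return self.precursor_seq[self.star_offset : self.star_offset + self.star_len]


@dataclass
class NovelPrediction:
    """A candidate that passed every hairpin criterion."""

    candidate: HairpinCandidate
    counts: Dict[str, int] = field(default_factory=dict)

    @property
    def first_base(self) -> str:
        return self.candidate.mature_seq[0].replace("T", "U")

    @property
    def mature_rna(self) -> str:
        return self.candidate.mature_seq.replace("T", "U")


def _five_prime(start: int, end: int, strand: str) -> int:
    return start if strand == "+" else end - 1


def build_candidates(
    tag_hits: Mapping[str, Sequence[TagHit]],
    tag_depths: Mapping[str, int],
    genome: Mapping[str, str],
    params: NovelParams = NovelParams(),
) -> List[HairpinCandidate]:
    """Cluster unannotated tag loci and excise hairpin windows.

    Tags whose locus count exceeds the copy-number cap are excluded before
    clustering.  Loci on one chromosome/strand are clustered when they
    overlap or lie within ``max_mirna_star_space`` of each other.  For each
    cluster the deepest tag (ties: 5'-most) becomes the putative mature,
    and two windows are excised — star arm upstream and star arm
    downstream — each with ``flank_len`` extra bases; windows clipped at
    contig ends are flagged ``truncated``.
    """
    # gather loci per (chrom, strand)
    by_cs: Dict[Tuple[str, str], List[Tuple[int, int, str]]] = {}
    for tag, hits in tag_hits.items():
        if len(hits) > params.max_copy_number:
            continue
        for h in hits:
            by_cs.setdefault((h.chrom, h.strand), []).append((h.start, h.end, tag))

    candidates: List[HairpinCandidate] = []
    for (chrom, strand), loci in sorted(by_cs.items()):
        loci.sort()
        contig = genome[chrom].upper()
        clusters: List[List[Tuple[int, int, str]]] = []
        for locus in loci:
            if clusters and locus[0] <= clusters[-1][-1][1] + params.max_mirna_star_space:
                clusters[-1].append(locus)
            else:
                clusters.append([locus])
        for cluster in clusters:
            tags = [
                ClusterTag(tag=t, start=s, end=e, depth=tag_depths.get(t, 0))
                for s, e, t in cluster
            ]
            # deepest tag, ties toward the 5'-most start
            def order(ct: ClusterTag):
                five = _five_prime(ct.start, ct.end, strand)
                return (-ct.depth, five if strand == "+" else -five)

            mature = min(tags, key=order)
            m5 = _five_prime(mature.start, mature.end, strand)
            cut_depth = sum(
                ct.depth
                for ct in tags
                if _five_prime(ct.start, ct.end, strand) == m5
            )
            copy_number = len(tag_hits[mature.tag])
            m_len = mature.end - mature.start
            arm_space = params.max_mirna_star_space + m_len
            for side in ("downstream", "upstream"):
                if side == "downstream":
                    w_start = mature.start - params.flank_len
                    w_end = mature.end + arm_space + params.flank_len
                else:
                    w_start = mature.start - arm_space - params.flank_len
                    w_end = mature.end + params.flank_len
                truncated = w_start < 0 or w_end > len(contig)
                w_start = max(0, w_start)
                w_end = min(len(contig), w_end)
                window = contig[w_start:w_end]
                if strand == "-":
                    precursor = revcomp(window)
                    offset = w_end - mature.end
                else:
                    precursor = window
                    offset = mature.start - w_start
                ctags = []
                for ct in tags:
                    if ct.start >= w_start and ct.end <= w_end:
                        if strand == "-":
                            ps, pe = w_end - ct.end, w_end - ct.start
                        else:
                            ps, pe = ct.start - w_start, ct.end - w_start
                        ctags.append(
                            ClusterTag(tag=ct.tag, start=ps, end=pe, depth=ct.depth)
                        )
                candidates.append(
                    HairpinCandidate(
                        chrom=chrom,
                        start=w_start,
                        end=w_end,
                        strand=strand,
                        precursor_seq=precursor,
                        mature_offset=offset,
                        mature_len=m_len,
                        mature_seq=precursor[offset : offset + m_len],
                        cut_depth=cut_depth,
                        copy_number=copy_number,
                        cluster_tags=ctags,
                        truncated=truncated,
                    )
                )
    return candidates


def _longest_unpaired_run(paired_flags: Sequence[bool]) -> int:
    longest = run = 0
    for p in paired_flags:
        run = 0 if p else run + 1
        longest = max(longest, run)
    return longest


def evaluate_candidate(
    cand: HairpinCandidate,
    params: NovelParams = NovelParams(),
    model: EnergyModel = DEFAULT_MODEL,
) -> Tuple[bool, Dict[str, bool]]:
    """Fold one candidate and record a pass/fail verdict per criterion.

    Rejections are data, not errors: the verdict map is stored on the
    candidate either way, and the candidate is accepted iff every
    criterion passes.
    """
    v: Dict[str, bool] = {}
    L = cand.mature_len
    v["mature_len"] = params.min_mirna_len <= L <= params.max_mirna_len
    # genomic copy (reference) length: exact mapping makes this the tag span
    v["ref_len"] = params.min_ref_len <= L <= params.max_ref_len
    v["copy_number"] = cand.copy_number <= params.max_copy_number
    v["cut_depth"] = cand.cut_depth >= params.min_cut_depth

    fold = fold_mfe(cand.precursor_seq, model)
    cand.fold = fold
    v["mfe"] = fold.mfe <= params.max_precursor_mfe

    o = cand.mature_offset
    mature_pos = range(o, o + L)
    partners = [fold.pair_table[i] for i in mature_pos if i in fold.pair_table]
    intra = [p for p in partners if o <= p < o + L]
    # the star arm must lie within max_space of the mature (plus its own
    # length and the 2-nt overhang); partners outside that zone are
    # opportunistic flank pairs of the loop-cost-free model and are treated
    # as unpaired for the duplex metrics
    zone = params.max_mirna_star_space + params.max_mirna_len + 2
    left = [p for p in partners if o - zone <= p < o]
    right = [p for p in partners if o + L <= p < o + L + zone]
    side = right if len(right) >= len(left) else left
    # partners scatter when the fold bulges single bases out of the stem
    # to grab stray loop/flank pairs; the star arm is the dominant cluster
    # of partner positions (split where the positional gap exceeds the
    # largest admissible bulge)
    clusters: List[List[int]] = []
    for p in sorted(side):
        if clusters and p - clusters[-1][-1] <= params.max_bulge + 1:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    star_side: List[int] = max(clusters, key=len) if clusters else []
    v["opposite_arms"] = not intra and bool(star_side)

    if v["opposite_arms"]:
        smin, smax = min(star_side), max(star_side)
        star_right = smin >= o + L
        # 2-nt 3' overhang extension of the star arm
        star_start, star_end = smin, min(len(cand.precursor_seq), smax + 3)
        cand.star_offset, cand.star_len = star_start, star_end - star_start
        gap = (smin - (o + L)) if star_right else (o - smax - 1)
        v["max_space"] = 0 <= gap <= params.max_mirna_star_space
        v["min_pairs"] = len(star_side) >= params.min_pairs_mirna_star

        star_range = (smin, smax)

        def to_star(i: int) -> bool:
            p = fold.pair_table.get(i)
            return p is not None and star_range[0] <= p <= star_range[1]

        def from_mature(i: int) -> bool:
            p = fold.pair_table.get(i)
            return p is not None and o <= p < o + L

        paired_m = [to_star(i) for i in mature_pos]
        # trim to the duplex span (first..last paired position of each arm)
        def duplex_span(flags: List[bool]) -> List[bool]:
            if not any(flags):
                return []
            first, last = flags.index(True), len(flags) - 1 - flags[::-1].index(True)
            return flags[first : last + 1]

        paired_s = [from_mature(i) for i in range(smin, smax + 1)]
        span_m, span_s = duplex_span(paired_m), duplex_span(paired_s)
        bulge = max(_longest_unpaired_run(span_m), _longest_unpaired_run(span_s))
        v["max_bulge"] = bulge <= params.max_bulge
        asym = abs(span_m.count(False) - span_s.count(False))
        v["max_asymmetry"] = asym <= params.max_asymmetry

        # soft check: observed star reads must agree with the 2-nt overhang
        star_reads = [
            ct
            for ct in cand.cluster_tags
            if ct.start >= star_start - 2 and ct.end <= star_end + 2
            and not (o <= ct.start < o + L)
        ]
        if star_reads:
            v["star_overhang"] = all(
                abs(ct.start - star_start) <= 2 for ct in star_reads
            )
        else:
            v["star_overhang"] = True
    else:
        v["max_space"] = False
        v["min_pairs"] = False
        v["max_bulge"] = False
        v["max_asymmetry"] = False
        v["star_overhang"] = True

    cand.verdicts = v
    return all(v.values()), v


def predict_novel(
    stage_tag_counts: Mapping[str, Mapping[str, int]],
    tag_hits: Mapping[str, Sequence[TagHit]],
    genome: Mapping[str, str],
    params: NovelParams = NovelParams(),
    model: EnergyModel = DEFAULT_MODEL,
) -> List[NovelPrediction]:
    """End-to-end prediction over unannotated tags of all stage libraries.

    Tag depths are pooled across stages for clustering and cut-site depth;
    per-stage counts of the accepted mature (all cluster tags sharing its
    5' end) are reported on each prediction.  Overlapping windows from one
    cluster yield at most one prediction (the first accepted).
    """
    depths: Dict[str, int] = {}
    for counts in stage_tag_counts.values():
        for tag, c in counts.items():
            depths[tag] = depths.get(tag, 0) + c
    candidates = build_candidates(tag_hits, depths, genome, params)

    predictions: List[NovelPrediction] = []
    seen_loci: List[Tuple[str, str, int, int]] = []
    for cand in candidates:
        ok, _ = evaluate_candidate(cand, params, model)
        if not ok:
            continue
        # one prediction per mature locus (the two windows overlap)
        m_start = cand.start + cand.mature_offset
        if cand.strand == "-":
            m_start = cand.end - cand.mature_offset - cand.mature_len
        key = (cand.chrom, cand.strand, m_start, cand.mature_len)
        if key in seen_loci:
            continue
        seen_loci.append(key)
        o, L = cand.mature_offset, cand.mature_len
        mature_tags = [
            ct.tag
            for ct in cand.cluster_tags
            if ct.start == o  # shares the mature 5' end in precursor coords
        ]
        counts = {
            stage: sum(int(c.get(t, 0)) for t in mature_tags)
            for stage, c in stage_tag_counts.items()
        }
        predictions.append(NovelPrediction(candidate=cand, counts=counts))
    predictions.sort(key=lambda p: (p.candidate.chrom, p.candidate.start))
    return predictions


def first_base_stats(
    predictions: Sequence[NovelPrediction],
) -> Tuple[Dict[int, Dict[str, int]], float]:
    """5'-first-nucleotide composition by mature length, plus overall
    uridine fraction.  Empty input yields an empty table and 0.0."""
    table: Dict[int, Dict[str, int]] = {}
    n_u = 0
    for p in predictions:
        L = p.candidate.mature_len
        base = p.first_base
        table.setdefault(L, {})[base] = table.get(L, {}).get(base, 0) + 1
        if base == "U":
            n_u += 1
    frac_u = n_u / len(predictions) if predictions else 0.0
    return table, frac_u


def write_predictions(predictions: Sequence[NovelPrediction], fasta_path, bed_path, tsv_path) -> None:
    """Write precursor/mature FASTA, locus BED and a criterion-verdict TSV."""
    with open(fasta_path, "w") as fa, open(bed_path, "w") as bed, open(tsv_path, "w") as tsv:
        tsv.write("id\tchrom\tstart\tend\tstrand\tmfe\tcut_depth\t"
                  + "\t".join(CRITERIA) + "\n")
        for i, p in enumerate(predictions, 1):
            c = p.candidate
            name = f"novel-mir-{i}"
            fa.write(f">{name}-precursor\n{c.precursor_seq}\n")
            fa.write(f">{name}-mature\n{c.mature_seq}\n")
            bed.write(f"{c.chrom}\t{c.start}\t{c.end}\t{name}\t0\t{c.strand}\n")
            mfe = f"{c.fold.mfe:.1f}" if c.fold else ""
            tsv.write(
                f"{name}\t{c.chrom}\t{c.start}\t{c.end}\t{c.strand}\t{mfe}\t"
                f"{c.cut_depth}\t"
                + "\t".join(str(int(c.verdicts.get(k, False))) for k in CRITERIA)
                + "\n"
            )
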