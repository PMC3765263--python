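"""Synthetic small-RNA study generator with planted ground truth.

Builds a toy genome carrying planted miRNA hairpins (conserved and novel),
structural ncRNA loci, repeats and exon/intron pairs, then simulates three
stage-labelled FASTQ libraries (anagen / catagen / telogen) whose reads are
mature-miRNA or feature fragments ligated to a 3' adapter, plus injected
contaminant reads of every accounting category (low quality, missing 3'
adapter, empty insert, 5' adapter carry-over, short inserts, poly(A)).

Planted hairpins are built as mature arm + loop (8-20 nt) + near-reverse-
complement star arm: a few G:U wobbles are written into the star so that
the mature tag maps uniquely to its own arm, while the stem still folds
with every mature base paired and an MFE far below the -18 kcal/mol
acceptance threshold.  Per-miRNA per-stage counts are drawn Poisson around
the configured means (the simplest count process consistent with the
digital-expression test downstream); ``count_noise="exact"`` plants the
means verbatim.  Everything the generator decides is recorded in a
ground-truth manifest so downstream recovery can be scored.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .annotate import Feature, revcomp

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "PlantedPrecursor",
    "GenomeCapacityError",
    "default_config",
    "generate_genome",
    "simulate_reads",
    "write_outputs",
    "target_rule_fixture",
]

STAGES = ("anagen", "catagen", "telogen")
NCRNA_CLASSES = ("rRNA", "scRNA", "snRNA", "snoRNA", "srpRNA", "tRNA")

# Illumina-style small-RNA adapters
DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"
DEFAULT_ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"

BASES = np.array(list("ACGT"))

# insert-length weights for background fragments; the mode is 22 nt, the
# canonical Dicer product size
_LENGTH_WEIGHTS = {
    18: 2, 19: 3, 20: 6, 21: 10, 22: 30, 23: 10, 24: 6,
    25: 4, 26: 3, 27: 2, 28: 2, 29: 1, 30: 1,
}


class GenomeCapacityError(ValueError):
    """The configured genome is too small to host all planted features."""


@dataclass
class SimulationConfig:
    genome_length: int = 120_000
    n_conserved_precursors: int = 14
    n_novel_precursors: int = 6
    n_ncrna_loci_per_class: int = 4
    n_repeats: int = 8
    n_exons: int = 10
    reads_per_library: int = 50_000
    adapter3: str = DEFAULT_ADAPTER3
    adapter5: str = DEFAULT_ADAPTER5
    # per-category contaminant fractions of each library
    contamination_rates: Dict[str, float] = field(
        default_factory=lambda: {
            "low_quality": 0.006,
            "adapter3_null": 0.0034,
            "insert_null": 0.0062,
            "adapter5_contaminants": 0.0018,
            "smaller_than_18nt": 0.034,
            "polyA": 0.0002,
        }
    )
    # stage -> miRNA id -> expected clean-read count
    stage_profiles: Dict[str, Dict[str, float]] = field(default_factory=dict)
    # (mirna, control_stage, treatment_stage, fold) planted fold changes
    de_spec: List[Tuple[str, str, str, float]] = field(default_factory=list)
    count_noise: str = "poisson"  # or "exact"
    frac_u_start: float = 0.7  # uridine bias of mature 5' ends
    background_class_weights: Dict[str, float] = field(
        default_factory=lambda: {
            "rRNA": 0.42, "tRNA": 0.08, "snRNA": 0.04, "snoRNA": 0.04,
            "scRNA": 0.02, "srpRNA": 0.02, "repeat": 0.13, "exon": 0.15,
            "intron": 0.10,
        }
    )
    n_utr_genes: int = 40
    seed: int = 7

    def validate(self) -> None:
        rates = self.contamination_rates
        if any(not (0 <= r <= 1) for r in rates.values()) or sum(rates.values()) >= 1:
            raise ValueError("contamination rates must lie in [0,1] and sum < 1")
        if self.reads_per_library <= 0:
            raise ValueError("reads_per_library must be positive")
        if self.count_noise not in ("poisson", "exact"):
            raise ValueError("count_noise must be 'poisson' or 'exact'")


@dataclass
class PlantedPrecursor:
    mirna_id: str
    kind: str  # conserved | novel
    chrom: str
    start: int
    end: int
    strand: str
    precursor_seq: str  # DNA, precursor (5'->3') orientation
    mature_seq: str
    star_seq: str
    mature_offset: int


@dataclass
class GroundTruth:
    precursors: List[PlantedPrecursor] = field(default_factory=list)
    features: List[Feature] = field(default_factory=list)
    true_abundance: Dict[str, Dict[str, float]] = field(default_factory=dict)
    de_spec: List[Tuple[str, str, str, float]] = field(default_factory=list)
    realized_counts: Dict[str, Dict[str, int]] = field(default_factory=dict)
    injected: Dict[str, Dict[str, int]] = field(default_factory=dict)
    utr_sites: Dict[str, List[str]] = field(default_factory=dict)  # gene -> miRNA ids
    utrs: Dict[str, str] = field(default_factory=dict)
    gene2go: List[Tuple[str, str]] = field(default_factory=list)
    gene2pathway: List[Tuple[str, str]] = field(default_factory=list)

    def conserved(self) -> List[PlantedPrecursor]:
        return [p for p in self.precursors if p.kind == "conserved"]

    def novel(self) -> List[PlantedPrecursor]:
        return [p for p in self.precursors if p.kind == "novel"]

    def to_json(self, path) -> None:
        doc = {
            "precursors": [asdict(p) for p in self.precursors],
            "features": [asdict(f) for f in self.features],
            "true_abundance": self.true_abundance,
            "de_spec": [list(t) for t in self.de_spec],
            "realized_counts": self.realized_counts,
            "injected": self.injected,
            "utr_sites": self.utr_sites,
            "gene2go": [list(t) for t in self.gene2go],
            "gene2pathway": [list(t) for t in self.gene2pathway],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            doc = json.load(fh)
        truth = cls()
        truth.precursors = [PlantedPrecursor(**p) for p in doc["precursors"]]
        truth.features = [Feature(**f) for f in doc["features"]]
        truth.true_abundance = doc["true_abundance"]
        truth.de_spec = [tuple(t) for t in doc["de_spec"]]
        truth.realized_counts = doc["realized_counts"]
        truth.injected = doc["injected"]
        truth.utr_sites = doc["utr_sites"]
        truth.gene2go = [tuple(t) for t in doc["gene2go"]]
        truth.gene2pathway = [tuple(t) for t in doc["gene2pathway"]]
        return truth


def default_config(**overrides) -> SimulationConfig:
    """The default simulated study: 14 conserved + 6 novel hairpins, three
    50k-read libraries, planted stage-specific and 4-fold DE miRNAs."""
    cfg = SimulationConfig(**overrides)
    if not cfg.stage_profiles:
        ids = [f"bta-miR-s{i:02d}" for i in range(1, cfg.n_conserved_precursors + 1)]
        novel_ids = [f"novel-s{i}" for i in range(1, cfg.n_novel_precursors + 1)]
        prof: Dict[str, Dict[str, float]] = {s: {} for s in STAGES}
        flat = [1500, 1200, 1000, 800, 600, 400, 200]
        for k, mid in enumerate(ids):
            if k == 0:  # 4-fold up in anagen
                means = {"anagen": 2000, "catagen": 500, "telogen": 500}
            elif k == 1:  # 4-fold up in catagen
                means = {"anagen": 500, "catagen": 2000, "telogen": 500}
            elif k == 2:  # 4-fold up in telogen
                means = {"anagen": 500, "catagen": 500, "telogen": 2000}
            elif k < 10:
                v = flat[(k - 3) % len(flat)]
                means = {s: v for s in STAGES}
            elif k == 10:
                means = {"anagen": 80, "catagen": 0, "telogen": 0}
            elif k == 11:
                means = {"anagen": 0, "catagen": 80, "telogen": 0}
            else:
                means = {"anagen": 0, "catagen": 0, "telogen": 80}
            for s in STAGES:
                prof[s][mid] = float(means[s])
        for j, nid in enumerate(novel_ids):
            for s in STAGES:
                prof[s][nid] = float(60 + 20 * (j % 3))
        cfg.stage_profiles = prof
        if not cfg.de_spec:
            cfg.de_spec = [
                (ids[0], "catagen", "anagen", 4.0),
                (ids[0], "telogen", "anagen", 4.0),
                (ids[1], "anagen", "catagen", 4.0),
                (ids[2], "catagen", "telogen", 4.0),
            ]
    cfg.validate()
    return cfg


# ---------------------------------------------------------------- sequences


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))

_GU_STAR = {"G": "T", "T": "G"}  # wobble partners (DNA alphabet)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _junction_safe(insert: str, adapter3: str) -> bool:
    """True when trimming finds the 3' adapter exactly at the insert end
    (no spurious seed formed across the insert/adapter junction)."""
    return (insert + adapter3).find(adapter3[:6]) == len(insert)


def _clean_random_seq(rng, n, forbidden: Sequence[str]) -> str:
    """Random sequence free of the forbidden substrings (adapter seeds)."""
    for _ in range(200):
        s = _rand_seq(rng, n)
        if not any(f in s for f in forbidden):
            return s
    raise RuntimeError("could not draw a sequence avoiding adapter seeds")


def _make_hairpin(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    used_matures: set,
    m_len: Optional[int] = None,
) -> Tuple[str, str, str, int]:
    """Build (precursor, mature, star, mature_offset) as a perfect stem
    with one centrally placed G:U wobble in the star arm.

    The single wobble makes the star differ from the exact reverse
    complement, so the mature tag maps only to its own arm; placing it
    centrally, flanked by Watson-Crick pairs, keeps the minimum-energy
    structure from trading stem pairs for opportunistic flank pairs."""
    seeds = (cfg.adapter3[:6], cfg.adapter5[:6])
    while True:
        if m_len is None:
            m_len = int(rng.choice([20, 21, 22, 22, 22, 23, 24]))
        mature = _clean_random_seq(rng, m_len, seeds)
        if rng.random() < cfg.frac_u_start:
            mature = "T" + mature[1:]
        candidates = [i for i in range(6, m_len - 6) if mature[i] in _GU_STAR]
        if (
            not candidates
            or mature[:18] in used_matures
            or not _junction_safe(mature, cfg.adapter3)
        ):
            continue
        wobble = {min(candidates, key=lambda i: abs(i - m_len // 2))}
        star_bases = []
        for i in range(m_len - 1, -1, -1):
            if i in wobble:
                star_bases.append(_GU_STAR[mature[i]])
            else:
                star_bases.append(_COMP[mature[i]])
        star = "".join(star_bases)
        loop = _clean_random_seq(rng, int(rng.integers(8, 21)), seeds)
        precursor = mature + loop + star
        if any(f in precursor for f in seeds):
            continue
        used_matures.add(mature[:18])
        return precursor, mature, star, 0


def generate_genome(cfg: SimulationConfig) -> Tuple[Dict[str, str], GroundTruth]:
    """Assemble the toy genome and record all planted features.

    Features are placed sequentially with random inter-feature gaps, so
    nothing overlaps; raises :class:`GenomeCapacityError` when the genome
    cannot host every feature.  The same (config, seed) always yields a
    byte-identical genome and truth.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 0])
    truth = GroundTruth(de_spec=list(cfg.de_spec))
    seeds = (cfg.adapter3[:6], cfg.adapter5[:6])
    used = set()

    # (kind, class, strand, seq, payload) blocks to place
    blocks: List[Tuple[str, str, str, str, Optional[dict]]] = []
    mirna_ids = sorted(
        {m for prof in cfg.stage_profiles.values() for m in prof},
    )
    conserved_ids = [m for m in mirna_ids if not m.startswith("novel")]
    novel_ids = [m for m in mirna_ids if m.startswith("novel")]
    # mature lengths 20-24 with the canonical 22 nt dominating; the most
    # abundant roster slots are pinned at 22 so the library's modal insert
    # length is 22 regardless of the count draws
    conserved_lens = [22, 22, 22, 21, 23, 22, 20, 24, 22, 22, 21, 23, 22, 24]
    novel_lens = [22, 21, 23, 22, 22, 24]
    for k, mid in enumerate(conserved_ids):
        prec, mat, star, off = _make_hairpin(
            rng, cfg, used, conserved_lens[k % len(conserved_lens)]
        )
        blocks.append(("conserved", "miRNA", "+", prec,
                       {"id": mid, "mature": mat, "star": star, "offset": off}))
    for j, mid in enumerate(novel_ids):
        prec, mat, star, off = _make_hairpin(
            rng, cfg, used, novel_lens[j % len(novel_lens)]
        )
        strand = "-" if j == len(novel_ids) - 1 and len(novel_ids) > 1 else "+"
        blocks.append(("novel", "novel", strand, prec,
                       {"id": mid, "mature": mat, "star": star, "offset": off}))
    for cls in NCRNA_CLASSES:
        for i in range(cfg.n_ncrna_loci_per_class):
            seq = _clean_random_seq(rng, int(rng.integers(80, 201)), seeds)
            source = "genbank" if i % 2 == 0 else "rfam"
            blocks.append(("feature", cls, "+", seq, {"source": source}))
    for _ in range(cfg.n_repeats):
        seq = _clean_random_seq(rng, int(rng.integers(100, 301)), seeds)
        blocks.append(("feature", "repeat", "+", seq, {"source": "genbank"}))
    for _ in range(cfg.n_exons):
        strand = "+" if rng.random() < 0.5 else "-"
        exon = _clean_random_seq(rng, int(rng.integers(150, 401)), seeds)
        intron = _clean_random_seq(rng, int(rng.integers(100, 301)), seeds)
        blocks.append(("feature", "exon", strand, exon, {"source": "genbank"}))
        blocks.append(("feature", "intron", strand, intron, {"source": "genbank"}))

    total_feature_len = sum(len(b[3]) for b in blocks)
    min_gap = 50
    needed = total_feature_len + min_gap * (len(blocks) + 1)
    if needed > cfg.genome_length:
        raise GenomeCapacityError(
            f"genome_length={cfg.genome_length} cannot host {len(blocks)} "
            f"features needing >= {needed} bases"
        )

    slack = cfg.genome_length - total_feature_len
    gaps = rng.multinomial(slack - min_gap * (len(blocks) + 1),
                           [1.0 / (len(blocks) + 1)] * (len(blocks) + 1))
    gaps = gaps + min_gap

    chrom = "chr1"
    parts: List[str] = []
    pos = 0
    for (kind, cls, strand, seq, payload), gap in zip(blocks, gaps[:-1]):
        parts.append(_rand_seq(rng, int(gap)))
        pos += int(gap)
        start, end = pos, pos + len(seq)
        genome_seq = revcomp(seq) if strand == "-" else seq
        parts.append(genome_seq)
        if kind in ("conserved", "novel"):
            truth.precursors.append(
                PlantedPrecursor(
                    mirna_id=payload["id"],
                    kind=kind,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    precursor_seq=seq,
                    mature_seq=payload["mature"],
                    star_seq=payload["star"],
                    mature_offset=payload["offset"],
                )
            )
            if kind == "conserved":  # known precursors are annotated features
                truth.features.append(
                    Feature(chrom=chrom, start=start, end=end, strand=strand,
                            cls="miRNA", source="genbank")
                )
        else:
            truth.features.append(
                Feature(chrom=chrom, start=start, end=end, strand=strand,
                        cls=cls, source=payload["source"])
            )
        pos = end
    parts.append(_rand_seq(rng, int(gaps[-1])))
    genome = {"chr1": "".join(parts)}

    truth.true_abundance = {
        mid: {s: cfg.stage_profiles[s].get(mid, 0.0) for s in cfg.stage_profiles}
        for mid in mirna_ids
    }
    _plant_utrs(rng, cfg, truth, seeds)
    return genome, truth


def _plant_utrs(rng, cfg, truth: GroundTruth, seeds) -> None:
    """UTR set with perfect-complement sites of the first conserved miRNAs
    planted into the first genes, plus GO/pathway gene-term tables."""
    conserved = truth.conserved()
    n_sites = min(5, len(conserved))
    genes = [f"g{i:03d}" for i in range(1, cfg.n_utr_genes + 1)]
    for i, gene in enumerate(genes):
        utr = _clean_random_seq(rng, 150, seeds)
        if i < n_sites:
            mir = conserved[i]
            site = revcomp(mir.mature_seq)
            k = int(rng.integers(20, 120 - len(site)))
            utr = utr[:k] + site + utr[k + len(site):]
            truth.utr_sites[gene] = [mir.mirna_id]
        truth.utrs[gene] = utr
    target_genes = genes[:n_sites]
    # one GO term exactly covering the planted target genes, plus background
    truth.gene2go = [(g, "GO:0000001") for g in target_genes]
    truth.gene2pathway = [(g, "path:ko0001") for g in target_genes]
    for t in range(2, 9):
        members = rng.choice(genes, size=8, replace=False)
        truth.gene2go += [(g, f"GO:{t:07d}") for g in sorted(members)]
    for t in range(2, 6):
        members = rng.choice(genes, size=10, replace=False)
        truth.gene2pathway += [(g, f"path:ko{t:04d}") for g in sorted(members)]
    # every gene carries at least one annotation so the universe is complete
    truth.gene2go += [(g, "GO:9999999") for g in genes]
    truth.gene2pathway += [(g, "path:ko9999") for g in genes]


# ------------------------------------------------------------------- reads


def _draw_lengths(rng, n: int) -> np.ndarray:
    lens = np.array(list(_LENGTH_WEIGHTS))
    w = np.array(list(_LENGTH_WEIGHTS.values()), dtype=float)
    return rng.choice(lens, size=n, p=w / w.sum())


def simulate_reads(
    genome: Mapping[str, str],
    truth: GroundTruth,
    cfg: SimulationConfig,
) -> Dict[str, List[Tuple[str, str]]]:
    """Simulate the three stage libraries as (sequence, quality) reads.

    Clean reads are a planted-mature or feature fragment plus the full 3'
    adapter at constant high quality; contaminants of every accounting
    category are injected at the configured rates (counts are exact:
    ``floor(rate * reads_per_library)``), and the remainder of each library
    is filled with background feature fragments.  Per-category injected
    counts and realized per-miRNA counts are recorded on the truth object.
    """
    cfg.validate()
    libraries: Dict[str, List[Tuple[str, str]]] = {}
    mature_by_id = {p.mirna_id: p.mature_seq for p in truth.precursors}
    for mid in {m for prof in cfg.stage_profiles.values() for m in prof}:
        if mid not in mature_by_id:
            raise ValueError(f"stage profile references unknown miRNA {mid!r}")
    features_by_class: Dict[str, List[Feature]] = {}
    for f in truth.features:
        if f.cls != "miRNA":
            features_by_class.setdefault(f.cls, []).append(f)
    seeds = (cfg.adapter3[:6], cfg.adapter5[:6])

    for si, stage in enumerate(STAGES):
        rng = np.random.default_rng([cfg.seed, 1 + si])
        n_total = cfg.reads_per_library
        injected = {
            cat: int(rate * n_total) for cat, rate in cfg.contamination_rates.items()
        }
        profile = cfg.stage_profiles.get(stage, {})
        realized: Dict[str, int] = {}
        inserts: List[str] = []
        for mid in sorted(profile):
            mean = profile[mid]
            if cfg.count_noise == "poisson":
                k = int(rng.poisson(mean)) if mean > 0 else 0
            else:
                k = int(round(mean))
            realized[mid] = k
            inserts.extend([mature_by_id[mid]] * k)
        n_contam = sum(injected.values())
        n_background = max(0, n_total - n_contam - len(inserts))

        classes = sorted(cfg.background_class_weights)
        weights = np.array([cfg.background_class_weights[c] for c in classes])
        weights = weights / weights.sum()
        chosen = rng.choice(len(classes), size=n_background, p=weights)
        lengths = _draw_lengths(rng, n_background)
        genome_seqs = {c: genome[c] for c in genome}
        bg_counts: Dict[str, int] = {}
        for ci, L in zip(chosen, lengths):
            cls = classes[ci]
            flist = features_by_class.get(cls)
            if not flist:
                continue
            frag = None
            for _ in range(30):
                f = flist[int(rng.integers(len(flist)))]
                span = f.end - f.start
                if span < L:
                    continue
                s = f.start + int(rng.integers(0, span - L + 1))
                piece = genome_seqs[f.chrom][s : s + int(L)]
                if f.strand == "-":
                    piece = revcomp(piece)
                if (
                    any(x in piece for x in seeds)
                    or piece.count("A") / len(piece) >= 0.9
                    or not _junction_safe(piece, cfg.adapter3)
                ):
                    continue
                frag = piece
                break
            if frag is not None:
                inserts.append(frag)
                bg_counts[cls] = bg_counts.get(cls, 0) + 1

        reads: List[Tuple[str, str]] = []
        for ins in inserts:
            seq = ins + cfg.adapter3
            reads.append((seq, "I" * len(seq)))

        # --- contaminants, each built to land in exactly one category ---
        for _ in range(injected.get("low_quality", 0)):
            ins = _clean_random_seq(rng, 22, seeds)
            seq = list(ins + cfg.adapter3)
            for p in rng.choice(len(seq), size=4, replace=False):
                seq[int(p)] = "N"
            s = "".join(seq)
            reads.append((s, "I" * len(s)))
        for _ in range(injected.get("adapter3_null", 0)):
            s = _clean_random_seq(rng, 40, (cfg.adapter3[:6],))
            reads.append((s, "I" * len(s)))
        for _ in range(injected.get("insert_null", 0)):
            reads.append((cfg.adapter3, "I" * len(cfg.adapter3)))
        for _ in range(injected.get("adapter5_contaminants", 0)):
            ins = cfg.adapter5 + _clean_random_seq(rng, 8, seeds)
            s = ins + cfg.adapter3
            reads.append((s, "I" * len(s)))
        for _ in range(injected.get("smaller_than_18nt", 0)):
            ins = _clean_random_seq(rng, int(rng.integers(10, 18)), seeds)
            while ins.count("A") / len(ins) >= 0.9:
                ins = _clean_random_seq(rng, len(ins), seeds)
            s = ins + cfg.adapter3
            reads.append((s, "I" * len(s)))
        for _ in range(injected.get("polyA", 0)):
            s = "A" * 22 + cfg.adapter3
            reads.append((s, "I" * len(s)))

        order = rng.permutation(len(reads))
        libraries[stage] = [reads[i] for i in order]
        truth.realized_counts[stage] = realized
        injected["background"] = sum(bg_counts.values())
        injected["background_by_class"] = bg_counts  # type: ignore[assignment]
        truth.injected[stage] = injected
    return libraries


# ------------------------------------------------------------------ output


def write_fastq(reads: Sequence[Tuple[str, str]], stage: str, path) -> None:
    with open(path, "w") as fh:
        for i, (seq, qual) in enumerate(reads, 1):
            fh.write(f"@{stage}_{i}\n{seq}\n+\n{qual}\n")


def write_outputs(outdir, cfg: SimulationConfig) -> Tuple[Dict[str, str], GroundTruth]:
    """Generate everything and write the full artifact set.

    Writes genome FASTA, annotation BED, reference precursor/mature FASTA
    (conserved set), UTR FASTA, gene-to-term TSVs, three FASTQ libraries
    and the ground-truth manifest JSON.  Returns (genome, truth).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, truth = generate_genome(cfg)
    libraries = simulate_reads(genome, truth, cfg)

    with open(outdir / "genome.fa", "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    from .annotate import write_bed

    write_bed(truth.features, outdir / "annotation.bed")
    with open(outdir / "reference_hairpin.fa", "w") as fa_h, open(
        outdir / "reference_mature.fa", "w"
    ) as fa_m:
        for p in truth.conserved():
            fa_h.write(f">{p.mirna_id}-precursor\n{p.precursor_seq}\n")
            fa_m.write(f">{p.mirna_id}\n{p.mature_seq}\n")
    with open(outdir / "utr.fa", "w") as fh:
        for gene in sorted(truth.utrs):
            fh.write(f">{gene}\n{truth.utrs[gene]}\n")
    with open(outdir / "gene2go.tsv", "w") as fh:
        for gene, term in truth.gene2go:
            fh.write(f"{gene}\t{term}\n")
    with open(outdir / "gene2pathway.tsv", "w") as fh:
        for gene, term in truth.gene2pathway:
            fh.write(f"{gene}\t{term}\n")
    for stage, reads in libraries.items():
        write_fastq(reads, stage, outdir / f"{stage}.fastq")
    truth.to_json(outdir / "ground_truth.json")
    return genome, truth


# ------------------------------------------------- target-rule test fixture


def target_rule_fixture() -> Tuple[Dict[str, str], Dict[str, str], Dict[str, str]]:
    """Deterministic positive/decoy UTR set for the target-site rules.

    Returns (mirnas, utrs, expectations) where expectations maps gene id to
    ``"positive"`` or the name of the single rule its planted window
    violates.  Five genes carry perfect-complement sites; five carry decoy
    windows that each break exactly one rule (total mismatches, the
    10-11 core, the global adjacency run, adjacency within 2-12, and the
    duplex-energy floor).
    """
    # 22-nt let-7a-like guide; positions 14,16,18,20,22 are weak (A/U) so
    # mismatching them cannot break the 75% energy floor
    m1 = "TGAGGTAGTAGGTTGTATAGTT"
    # 20-nt guide whose only strong (G/C) bases sit at 13,15,17,19:
    # mismatching exactly those four drops the duplex below 75%; the
    # weak-base region is aperiodic so shifted registers cannot re-match
    m2 = "TTAATATTAATAGACACAGA"
    mirnas = {"mir-p1": m1, "mir-p2": m2}

    gu_partner = {"G": "T", "T": "G"}

    def window(mirna: str, mismatch_at: Sequence[int]) -> str:
        """Target window (5'->3') complementary to *mirna* except at the
        given 1-based miRNA positions (full mismatches, never wobbles)."""
        L = len(mirna)
        w = [_COMP[b] for b in mirna[::-1]]  # perfect complement window
        for p in mismatch_at:
            i = L - p  # window index facing miRNA position p
            excluded = {_COMP[mirna[p - 1]], gu_partner.get(mirna[p - 1], "")}
            w[i] = next(b for b in "ACGT" if b not in excluded)
        return "".join(w)

    rng = np.random.default_rng(20130728)
    specs = [
        ("pos1", "mir-p1", [], "positive"),
        ("pos2", "mir-p1", [], "positive"),
        ("pos3", "mir-p1", [], "positive"),
        ("pos4", "mir-p2", [], "positive"),
        ("pos5", "mir-p2", [], "positive"),
        ("dec_total", "mir-p1", [14, 16, 18, 20, 22], "max_mismatches"),
        ("dec_core", "mir-p1", [10], "no_mm_10_11"),
        ("dec_run", "mir-p1", [14, 15, 16], "max_adjacent_mm"),
        ("dec_seed", "mir-p1", [5, 6], "no_adjacent_mm_2_12"),
        ("dec_energy", "mir-p2", [13, 15, 17, 19], "min_mfe_ratio"),
    ]
    utrs: Dict[str, str] = {}
    expectations: Dict[str, str] = {}
    for gene, mid, mm, label in specs:
        site = window(mirnas[mid], mm)
        flank5 = _rand_seq(rng, 30)
        flank3 = _rand_seq(rng, 30)
        utrs[gene] = flank5 + site + flank3
        expectations[gene] = label
    return mirnas, utrs, expectations
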