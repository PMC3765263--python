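"""End-to-end orchestration of the analysis on file artifacts.

``run_all`` executes the stages in dependency order — read cleaning,
mapping + annotation, conserved quantification, novel-hairpin prediction,
target scanning, pairwise differential expression and term enrichment —
writing each stage's TSV/FASTA/BED artifacts plus a machine-readable
summary JSON with every headline number.  Outputs are pure functions of
(inputs, config, seed): rerunning with the same configuration reproduces
them byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from . import annotate as ann
from . import conserved as cons
from . import diffexp as de
from . import enrichment as enr
from . import novel as nov
from . import preprocess as pre
from . import targets as tgt
from .structure import EnergyModel
from Bio import SeqIO

logger = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = 1
STAGES = ("anagen", "catagen", "telogen")


@dataclass
class PipelineConfig:
    """Paths and parameter blocks for a full run."""

    genome_fasta: str
    annotation_bed: str
    reference_hairpin_fasta: str
    reference_mature_fasta: str
    utr_fasta: str
    gene2go_tsv: str
    gene2pathway_tsv: str
    fastq: Dict[str, str] = field(default_factory=dict)  # stage -> path
    outdir: str = "results"
    adapter3: str = "TGGAATTCTCGGGTGCCAAGG"
    adapter5: str = "GTTCAGAGTTCTACAGTCCGACGATC"
    novel_params: nov.NovelParams = field(default_factory=nov.NovelParams)
    target_rules: tgt.TargetRules = field(default_factory=tgt.TargetRules)
    energy_model: EnergyModel = field(default_factory=EnergyModel)
    filter_policy: pre.FilterPolicy = field(default_factory=pre.FilterPolicy)
    cluster_k: int = 5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        blocks = {}
        for key, factory in (
            ("novel_params", nov.NovelParams),
            ("target_rules", tgt.TargetRules),
            ("filter_policy", pre.FilterPolicy),
            ("energy_model", EnergyModel),
        ):
            if key in doc:
                blocks[key] = factory(**doc.pop(key))
        cfg = cls(**doc, **blocks)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        missing = []
        for attr in (
            "genome_fasta",
            "annotation_bed",
            "reference_hairpin_fasta",
            "reference_mature_fasta",
            "utr_fasta",
            "gene2go_tsv",
            "gene2pathway_tsv",
        ):
            path = getattr(self, attr)
            if not Path(path).exists():
                missing.append(f"{attr}={path}")
        for stage, path in self.fastq.items():
            if not Path(path).exists():
                missing.append(f"fastq[{stage}]={path}")
        if missing:
            raise FileNotFoundError(
                "pipeline config references missing input(s): " + ", ".join(missing)
            )


def _load_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def run_all(config: PipelineConfig) -> Dict:
    """Run every stage and return (and write) the summary dictionary."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "INCOMPLETE"
    marker.write_text("run in progress\n")
    stage_name = "setup"
    try:
        summary: Dict = {"schema_version": SUMMARY_SCHEMA_VERSION, "stages": {}}

        # ---- preprocess -------------------------------------------------
        stage_name = "preprocess"
        libraries: Dict[str, pre.CleanLibrary] = {}
        stats: Dict[str, pre.FilterStats] = {}
        for stage in sorted(config.fastq):
            lib, st = pre.filter_reads(
                config.fastq[stage],
                config.adapter3,
                config.adapter5,
                stage=stage,
                policy=config.filter_policy,
            )
            libraries[stage] = lib
            stats[stage] = st
            st.to_tsv(out / f"filter_stats_{stage}.tsv")
            lib.write_fasta(out / f"tags_{stage}.fa")
            logger.info(
                "preprocess[%s]: %d reads in, %d clean, %d unique tags",
                stage, st.total_reads, st.clean_reads, lib.n_unique,
            )
        dists = pre.length_distribution(libraries.values())
        pre.write_length_distribution_tsv(dists, out / "length_distribution.tsv")
        summary["stages"]["preprocess"] = {
            stage: {
                "total_reads": stats[stage].total_reads,
                "high_quality": stats[stage].high_quality,
                "clean_reads": stats[stage].clean_reads,
                "unique_tags": libraries[stage].n_unique,
                "percentages": {
                    k: round(v, 2) for k, v in stats[stage].percentages.items()
                },
                "modal_length": max(
                    dists[stage]["total"], key=lambda L: dists[stage]["total"][L]
                )
                if dists[stage]["total"]
                else None,
            }
            for stage in sorted(libraries)
        }

        # ---- map + annotate --------------------------------------------
        stage_name = "annotate"
        genome = _load_fasta(config.genome_fasta)
        index = ann.GenomeIndex(genome)
        features = ann.load_bed(config.annotation_bed)
        all_tags: Dict[str, int] = {}
        for lib in libraries.values():
            for tag, c in lib.tags.items():
                all_tags[tag] = all_tags.get(tag, 0) + c
        hits, flagged, skipped = ann.map_tags(
            sorted(all_tags), index, config.novel_params.max_copy_number
        )
        classes, summary_ann = ann.annotate_tags(all_tags, hits, features)
        ann.write_tag_classes_tsv(classes, out / "tag_classes.tsv")
        summary_ann.to_tsv(out / "annotation_summary.tsv")
        verdict, frac = ann.rrna_quality_check(summary_ann)
        logger.info(
            "annotate: %d tags, %d mapped, rRNA %.2f%% (%s)",
            len(all_tags), len(hits), frac, verdict,
        )
        summary["stages"]["annotate"] = {
            "unique_tags": len(all_tags),
            "mapped_tags": len(hits),
            "skipped_non_acgt": skipped,
            "class_unique_counts": dict(sorted(summary_ann.unique_counts.items())),
            "class_read_counts": dict(sorted(summary_ann.read_counts.items())),
            "rrna_fraction": round(frac, 2),
            "rrna_verdict": verdict,
        }

        # ---- conserved ---------------------------------------------------
        stage_name = "conserved"
        reference = cons.load_reference(
            config.reference_hairpin_fasta, config.reference_mature_fasta
        )
        stage_counts = {
            stage: cons.match_known(libraries[stage], reference)
            for stage in sorted(libraries)
        }
        clean_totals = {s: libraries[s].total_clean for s in libraries}
        records = cons.build_expression_records(stage_counts, clean_totals)
        cons.write_expression_tsv(records, out / "conserved_expression.tsv")
        members = cons.stage_membership(records)
        venn = cons.venn_counts(members, tuple(sorted(libraries)))
        with open(out / "venn.tsv", "w") as fh:
            fh.write("region\tcount\n")
            for region in sorted(venn):
                fh.write(f"{region}\t{venn[region]}\n")
        top = {
            s: cons.top_expressed(records, 10, s) for s in sorted(libraries)
        }
        logger.info("conserved: %d miRNAs detected", len(members))
        summary["stages"]["conserved"] = {
            "n_detected": len(members),
            "venn": venn,
            "top10": {s: [[m, c] for m, c in rows] for s, rows in top.items()},
        }

        # ---- novel -------------------------------------------------------
        stage_name = "novel"
        unan_tags = {t for t, c in classes.items() if c == "unan"}
        stage_unan_counts = {
            s: {t: c for t, c in libraries[s].tags.items() if t in unan_tags}
            for s in sorted(libraries)
        }
        unan_hits = {t: hits[t] for t in unan_tags if t in hits}
        predictions = nov.predict_novel(
            stage_unan_counts,
            unan_hits,
            genome,
            config.novel_params,
            config.energy_model,
        )
        nov.write_predictions(
            predictions,
            out / "novel_predictions.fa",
            out / "novel_predictions.bed",
            out / "novel_verdicts.tsv",
        )
        fb_table, frac_u = nov.first_base_stats(predictions)
        logger.info("novel: %d predictions (5' U fraction %.2f)", len(predictions), frac_u)
        summary["stages"]["novel"] = {
            "n_predictions": len(predictions),
            "first_base_u_fraction": round(frac_u, 3),
            "counts": {
                f"novel-{i+1}": p.counts for i, p in enumerate(predictions)
            },
        }

        # ---- targets -----------------------------------------------------
        stage_name = "targets"
        utrs = _load_fasta(config.utr_fasta)
        matures = {
            e.mature_id: e.precursor_seq[e.mature_start : e.mature_start + e.mature_len]
            for e in reference.entries
        }
        sites = tgt.scan_utrs(matures, utrs, config.target_rules, config.energy_model)
        tgt.write_sites_tsv(sites, out / "target_sites.tsv")
        target_genes = sorted({s.gene_id for s in sites})
        logger.info("targets: %d sites in %d genes", len(sites), len(target_genes))
        summary["stages"]["targets"] = {
            "n_sites": len(sites),
            "n_target_genes": len(target_genes),
        }

        # ---- diffexp -----------------------------------------------------
        stage_name = "diffexp"
        stage_list = sorted(libraries)
        pairs = [
            (stage_list[i], stage_list[j])
            for i in range(len(stage_list))
            for j in range(i + 1, len(stage_list))
        ]
        de_summary = {}
        profiles: Dict[str, List[float]] = {}
        for ctrl, treat in pairs:
            pair = de.ComparisonPair(
                control_stage=ctrl,
                treatment_stage=treat,
                N1=clean_totals[ctrl],
                N2=clean_totals[treat],
            )
            results = de.compare_pair(stage_counts[ctrl], stage_counts[treat], pair)
            name = f"{treat}_vs_{ctrl}"
            with open(out / f"de_{name}.tsv", "w") as fh:
                fh.write(
                    "mirna_id\tx\ty\ttpm_control\ttpm_treatment\tlog2fc\t"
                    "pvalue\tsig_class\tratio_class\texcluded\n"
                )
                for r in results:
                    fh.write(
                        f"{r.mirna_id}\t{r.x}\t{r.y}\t{r.tpm_control:.4f}\t"
                        f"{r.tpm_treatment:.4f}\t{r.log2fc:.4f}\t{r.pvalue:.4g}\t"
                        f"{r.sig_class}\t{r.ratio_class}\t{int(r.excluded)}\n"
                    )
            de_summary[name] = {
                "n_tested": sum(1 for r in results if not r.excluded),
                "sig_fractions": {
                    k: round(v, 4) for k, v in de.sig_class_fractions(results).items()
                },
            }
            for r in results:
                profiles.setdefault(r.mirna_id, []).append(r.log2fc)
        clusters = de.cluster_profiles(
            {m: p for m, p in profiles.items() if len(p) == len(pairs)},
            k=config.cluster_k,
        )
        with open(out / "clusters.tsv", "w") as fh:
            fh.write("mirna_id\tcluster\n")
            for mid in sorted(clusters):
                fh.write(f"{mid}\t{clusters[mid]}\n")
        summary["stages"]["diffexp"] = de_summary
        summary["stages"]["clustering"] = {
            "k": config.cluster_k,
            "n_profiles": len(clusters),
        }

        # ---- enrichment ---------------------------------------------------
        stage_name = "enrichment"
        go_universe = enr.load_gene2term(config.gene2go_tsv)
        kegg_universe = enr.load_gene2term(config.gene2pathway_tsv)
        go_results = enr.run_enrichment(target_genes, go_universe, mode="GO")
        kegg_results = enr.run_enrichment(target_genes, kegg_universe, mode="pathway")
        enr.write_enrichment_tsv(go_results, out / "enrichment_go.tsv")
        enr.write_enrichment_tsv(kegg_results, out / "enrichment_pathway.tsv")
        summary["stages"]["enrichment"] = {
            "go_significant": [r.term for r in go_results if r.significant],
            "pathway_significant": [r.term for r in kegg_results if r.significant],
            "go_tested": len(go_results),
            "pathway_tested": len(kegg_results),
        }

        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
        marker.unlink()
        return summary
    except Exception as exc:
        marker.write_text(f"failed during stage {stage_name}: {exc}\n")
        raise RuntimeError(f"pipeline failed during stage {stage_name!r}: {exc}") from exc
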