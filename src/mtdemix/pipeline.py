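"""End-to-end orchestration: preprocess -> observations -> EM -> report.

The pipeline is fully deterministic given its configuration: running the same
config twice yields byte-identical report files.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from .align import KmerAligner
from .deconvolve import (
    DeconvolutionResult,
    deconvolute,
    deconvolute_with_knowns,
)
from .fileio import (
    RunConfig,
    fragments_from_sam,
    load_fasta_sequence,
    load_knowns,
    load_primers,
    load_reference,
    load_tree,
    read_fastq_pair,
)
from .preprocess import preprocess_pairs

log = logging.getLogger("mtdemix")

REPORT_SCHEMA_VERSION = 1


def result_to_dict(result: DeconvolutionResult) -> dict:
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "contributors": [
            {
                "haplogroup": c.haplogroup,
                "proportion": round(c.proportion, 6),
                "raw_pi": round(c.raw_pi, 6),
                "n_strong_fragments": c.n_strong_fragments,
                "is_known": c.is_known,
                "aliases": c.aliases,
                "no_coverage": c.no_coverage,
                "partial_haplotype": c.partial_haplotype,
                "diagnostic_snps": [
                    {
                        "position": d.position,
                        "expected_allele": d.expected_allele,
                        "covering_fragments": d.covering_fragments,
                        "derived_fragments": d.derived_fragments,
                        "observed_fraction": round(d.observed_fraction, 4),
                    }
                    for d in c.diagnostics
                ],
            }
            for c in result.contributors
        ],
        "warnings": result.warnings,
        "fragments": {
            "informative": result.n_fragments,
            "uninformative": result.n_uninformative,
            "unaligned": result.n_unaligned,
        },
    }


def render_report_text(report: dict) -> str:
    """Human-readable rendering of a report dictionary."""
    lines = ["mtDNA mixture deconvolution report", ""]
    frs = report["fragments"]
    lines.append(
        f"fragments: {frs['informative']} informative, "
        f"{frs['uninformative']} uninformative, {frs['unaligned']} unaligned"
    )
    lines.append("")
    for c in report["contributors"]:
        tag = " (known haplotype)" if c["is_known"] else ""
        alias = f" [= {', '.join(c['aliases'])}]" if c["aliases"] else ""
        lines.append(
            f"contributor {c['haplogroup']}{alias}{tag}: "
            f"proportion {c['proportion']:.3f} "
            f"({c['n_strong_fragments']} uniquely supporting fragments)"
        )
        if c["no_coverage"]:
            lines.append("  no coverage of this haplogroup's diagnostic SNPs")
        for d in c["diagnostic_snps"]:
            lines.append(
                f"  {d['position']}{d['expected_allele']}: "
                f"{d['derived_fragments']}/{d['covering_fragments']} fragments "
                f"({d['observed_fraction']:.3f})"
            )
        if c["partial_haplotype"]:
            lines.append("  partial haplotype: " + " ".join(c["partial_haplotype"]))
        lines.append("")
    for w in report["warnings"]:
        lines.append(f"warning: {w}")
    return "\n".join(lines).rstrip() + "\n"


def run_pipeline(config: RunConfig) -> tuple[DeconvolutionResult, dict]:
    """Execute the full pipeline and write report/metrics files to the outdir.

    Stages: pair correction -> primer trimming -> NUMT removal ->
    observation building -> EM -> contributor selection (with grafted known
    haplotypes when provided) -> diagnostic SNP report.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    ref = load_reference(config.mito_fasta)
    tree = load_tree(config.tree_path, ref)
    primers = load_primers(config.primers_path) if config.primers_path else None
    knowns = load_knowns(config.knowns_path) if config.knowns_path else []
    nuclear = load_fasta_sequence(config.nuclear_fasta) if config.nuclear_fasta else None
    mito_aligner = KmerAligner(ref.sequence, circular=True, k=config.preprocess.aligner_k)

    metrics: dict = {}
    if config.bam is not None:
        log.warning("BAM/SAM input: pair correction and primer trimming are skipped")
        fragments = fragments_from_sam(config.bam)
        metrics["input_reads"] = len(fragments)
        if nuclear is not None:
            from .preprocess import AlignmentRecord, classify_numts, numt_candidates

            nuc_aligner = KmerAligner(nuclear, circular=False, k=config.preprocess.aligner_k)
            recs, nuc_dist = [], {}
            for f in fragments:
                pl = nuc_aligner.align(f.seq)
                recs.append(AlignmentRecord(f.frag_id, "nuclear", pl.mapped, pl.soft_clipped, pl.lev))
                nuc_dist[f.frag_id] = pl.lev
            cands = numt_candidates(recs)
            mito_dist = {
                f.frag_id: mito_aligner.align(f.seq).lev for f in fragments if f.frag_id in cands
            }
            removed = classify_numts(cands, nuc_dist, mito_dist)
            metrics["numt_candidates"] = len(cands)
            metrics["numts_removed"] = len(removed)
            fragments = [f for f in fragments if f.frag_id not in removed]
    else:
        pairs = read_fastq_pair(config.fastq1, config.fastq2)
        if config.skip_preprocess:
            from .preprocess import merge_pair

            fragments = []
            n = 0
            for p in pairs:
                n += 1
                frag = merge_pair(p, config.preprocess.min_overlap)
                if frag is not None:
                    fragments.append(frag)
            metrics["input_reads"] = n
        else:
            prep = preprocess_pairs(
                pairs, primers, ref, nuclear, config.preprocess, mito_aligner=mito_aligner
            )
            fragments = prep.fragments
            metrics.update(prep.metrics)

    log.info("preprocessing done: %s", metrics)
    if knowns:
        result = deconvolute_with_knowns(
            fragments, tree, knowns, ref, config.deconvolve, aligner=mito_aligner
        )
    else:
        result = deconvolute(fragments, tree, ref, config.deconvolve, aligner=mito_aligner)

    report = result_to_dict(result)
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
    (outdir / "report.txt").write_text(render_report_text(report))
    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=1, sort_keys=True) + "\n")
    return result, metrics
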