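"""End-to-end orchestration: simulate -> filter -> bin -> annotate ->
profile -> cluster -> rarefy -> report.

Stages communicate only via files (FASTA/TSV/JSON) so each one is
independently testable and substitutable with real search-tool output.  The
whole run is deterministic under a fixed seed; every output table carries the
run-config hash in a header comment, and the JSON report contains the
summary statistics plus stage provenance (seed, thresholds, config hash).
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from pathlib import Path

import numpy as np

from . import __version__
from .cazy_annotation import (
    annotate_contigs,
    bin_identity,
    call_modules,
    family_contig_counts,
    resolve_architectures,
)
from .comparative_profiler import (
    build_profile_matrix,
    default_reference_profiles,
    gh_only,
    pearson_distance,
    to_newick,
    upgma,
)
from .core_io import (
    RunConfig,
    read_fasta,
    read_hit_table,
    read_taxonomy,
    write_fasta,
    write_hit_table,
    write_taxonomy,
)
from .expression_profiler import (
    ExpressionRecord,
    count_reads_per_contig,
    coverage,
    discovery_rate,
    rank_by_expression,
    summarize_run,
)
from .ncrna_filter import classify_ncrna, estimate_removal_efficiency
from .rarefaction import collectors_curve, effort_at_richness
from .synthetic_data import (
    default_family_universe,
    default_taxonomy,
    generate_community,
    generate_hit_tables,
    generate_reads,
    model_label_map,
    read_truth_reads,
    split_alignment_hits,
    write_truth_contigs,
    write_truth_reads,
)
from .taxon_binning import aggregate_rank, bin_top_hit

log = logging.getLogger("rumenmt")

INPUT_FILES = {
    "contigs": "contigs.fasta",
    "reads": "reads.fasta",
    "taxonomy": "taxonomy.tsv",
    "alignment_hits": "hits_alignment.tsv",
    "domain_hits": "hits_domain.tsv",
    "hmm_flags": "hmm_flags.txt",
    "read_origins": "truth_reads.tsv",
}


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def simulate(config: RunConfig, outdir: Path) -> None:
    """Generate the synthetic inputs under ``outdir`` (seeded)."""
    taxonomy = default_taxonomy()
    families = default_family_universe()
    contigs, truth = generate_community(
        n_contigs=config.n_contigs,
        family_defs=families,
        taxonomy=taxonomy,
        expression_law=(config.expression_mu, config.expression_sigma),
        gc_target=config.gc_target,
        seed=config.seed,
    )
    reads, truth = generate_reads(
        contigs, truth, config.n_reads, read_len=config.read_len,
        ncrna_fraction=config.ncrna_fraction, ncrna_gc=config.ncrna_gc,
        seed=config.seed + 1,
    )
    alignment, domain, hmm_flags = generate_hit_tables(
        truth, fn_rate=config.fn_rate, fp_rate=config.fp_rate,
        score_jitter=config.score_jitter, seed=config.seed + 2,
        min_score=config.min_score, max_evalue=config.max_evalue,
        min_overlap=config.min_overlap,
    )
    tag = f"config_hash={config.config_hash}"
    write_fasta(contigs, outdir / INPUT_FILES["contigs"])
    write_fasta(reads, outdir / INPUT_FILES["reads"])
    write_taxonomy(taxonomy, outdir / INPUT_FILES["taxonomy"], header_extra=tag)
    write_hit_table(alignment, outdir / INPUT_FILES["alignment_hits"],
                    "alignment", header_extra=tag)
    write_hit_table(domain, outdir / INPUT_FILES["domain_hits"],
                    "domain", header_extra=tag)
    with open(outdir / INPUT_FILES["hmm_flags"], "w") as fh:
        for rid in sorted(hmm_flags):
            fh.write(rid + "\n")
    write_truth_contigs(truth, outdir / "truth_contigs.tsv")
    write_truth_reads(truth, outdir / INPUT_FILES["read_origins"])


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage from one configuration and return the JSON report.

    With ``config.simulate`` the inputs are generated first; otherwise all
    input files must already exist under ``config.outdir`` (a missing one is
    a named error raised before any output is written).  The report is also
    written to ``<outdir>/report.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"config_hash={config.config_hash}"

    if config.simulate:
        _stage("simulate")(simulate)(config, outdir)
    else:
        missing = [f for f in INPUT_FILES.values() if not (outdir / f).exists()]
        if missing:
            raise FileNotFoundError(
                f"missing input file(s) under {outdir}: {', '.join(sorted(missing))}")

    # ---- load inputs ----------------------------------------------------
    contigs = read_fasta(outdir / INPUT_FILES["contigs"])
    reads = read_fasta(outdir / INPUT_FILES["reads"])
    taxonomy = read_taxonomy(outdir / INPUT_FILES["taxonomy"])
    alignment = read_hit_table(outdir / INPUT_FILES["alignment_hits"], "alignment")
    domain = read_hit_table(outdir / INPUT_FILES["domain_hits"], "domain")
    with open(outdir / INPUT_FILES["hmm_flags"]) as fh:
        hmm_flags = {line.strip() for line in fh if line.strip()}
    origins = read_truth_reads(outdir / INPUT_FILES["read_origins"])
    rrna_hits, protein_hits = split_alignment_hits(alignment)

    # ---- ncRNA filter ---------------------------------------------------
    @_stage("filter-ncrna")
    def _filter():
        read_ids = [r.id for r in reads]
        calls, summary = classify_ncrna(
            read_ids, rrna_hits, hmm_flags, max_evalue=config.max_evalue,
            min_bit=config.min_bit, min_overlap=config.min_overlap)
        with open(outdir / "ncrna_calls.tsv", "w") as fh:
            fh.write(f"# columns: read_id is_ncrna evidence\n# {tag}\n")
            for c in calls:
                fh.write(f"{c.read_id}\t{int(c.is_ncrna)}\t{c.evidence}\n")
        return calls, summary

    ncrna_calls, ncrna_summary = _filter()
    nc_ids = {c.read_id for c in ncrna_calls if c.is_ncrna}
    removal = estimate_removal_efficiency(ncrna_summary["fraction"], 0.95)

    # ---- taxonomic binning ----------------------------------------------
    @_stage("bin-taxa")
    def _bin():
        coding_ids = [r.id for r in reads if r.id not in nc_ids]
        read_hits = [h for h in protein_hits if not h.query_id.startswith("contig")]
        read_hits = [h for h in read_hits if h.query_id not in nc_ids]
        assignments = bin_top_hit(read_hits, taxonomy, config.max_evalue,
                                  query_ids=coding_ids)
        table = aggregate_rank(assignments, taxonomy, config.rank)
        table.to_csv(outdir / "taxon_bins.tsv", sep="\t", index=False)
        return assignments, table

    assignments, taxon_table = _bin()

    # ---- CAZy annotation ------------------------------------------------
    @_stage("annotate-cazy")
    def _annotate():
        families = default_family_universe()
        direct = model_label_map(families)
        calls = call_modules(domain, direct_models=direct,
                             min_score=config.min_score)
        lengths = {c.id: len(c) for c in contigs}
        coding = {r: o for r, o in origins.items()
                  if o != "ncRNA" and r not in nc_ids}
        read_counts = count_reads_per_contig(coding, lengths)
        contig_hits = {h.query_id: h for h in protein_hits
                       if h.query_id in lengths}
        annotations = annotate_contigs(calls, lengths, read_counts, contig_hits)
        with open(outdir / "module_calls.tsv", "w") as fh:
            fh.write(f"# columns: contig_id label q_start q_end score source\n# {tag}\n")
            for c in calls:
                fh.write(f"{c.contig_id}\t{c.label}\t{c.q_start}\t{c.q_end}"
                         f"\t{c.score}\t{c.source}\n")
        arch = resolve_architectures(annotations, min_len=config.min_len)
        ident = bin_identity(annotations)
        return calls, annotations, arch, ident, read_counts

    calls, annotations, architectures, identity_bins, read_counts = _annotate()

    # ---- expression profiling -------------------------------------------
    @_stage("profile")
    def _profile():
        lengths = {c.id: len(c) for c in contigs}
        by_contig = {a.contig_id: a for a in annotations}
        records = [
            ExpressionRecord(
                cid, n, coverage(n, config.read_len, lengths[cid]),
                labels=sorted(by_contig[cid].labels) if cid in by_contig else [],
            )
            for cid, n in read_counts.items()
        ]
        ranked = rank_by_expression(records, config.min_reads)
        with open(outdir / "expression.tsv", "w") as fh:
            fh.write(f"# columns: contig_id read_count coverage labels\n# {tag}\n")
            for r in sorted(records, key=lambda r: (-r.read_count, r.contig_id)):
                fh.write(f"{r.contig_id}\t{r.read_count}\t{r.coverage:.1f}"
                         f"\t{';'.join(r.labels)}\n")
        return records, ranked

    expression_records, ranked = _profile()

    # ---- comparative clustering -----------------------------------------
    @_stage("cluster")
    def _cluster():
        sample_counts = {k: int(v) for k, v in
                         family_contig_counts(calls).items()}
        profiles = {"sample": sample_counts}
        profiles.update(default_reference_profiles())
        universe = sorted({f for p in profiles.values() for f in p})
        if config.family_universe == "GH":
            universe = gh_only(universe)
        matrix = build_profile_matrix(profiles, universe)
        ids, dmat = pearson_distance(matrix)
        tree = upgma(dmat, ids)
        (outdir / "tree.nwk").write_text(to_newick(tree) + "\n")
        with open(outdir / "distances.tsv", "w") as fh:
            fh.write("# Pearson distance d = 1 - r over percent profiles\n")
            fh.write(f"# {tag}\n\t" + "\t".join(ids) + "\n")
            for i, sid in enumerate(ids):
                fh.write(sid + "\t" + "\t".join(f"{x:.6f}" for x in dmat[i]) + "\n")
        return matrix, to_newick(tree)

    profile_matrix, newick = _cluster()

    # ---- rarefaction -----------------------------------------------------
    @_stage("rarefy")
    def _rarefy():
        coding = {r: o for r, o in origins.items()
                  if o != "ncRNA" and r not in nc_ids}
        curve = collectors_curve(coding, list(config.rarefaction_fractions),
                                 n_reps=config.rarefaction_reps,
                                 seed=config.seed + 3)
        with open(outdir / "rarefaction.tsv", "w") as fh:
            fh.write(f"# columns: effort_fraction mean_richness replicate_sd\n# {tag}\n")
            for f, m, s in zip(curve.effort_fractions, curve.mean_richness,
                               curve.replicate_sd):
                fh.write(f"{f}\t{m:.2f}\t{s:.3f}\n")
        return curve

    curve = _rarefy()

    # ---- report ----------------------------------------------------------
    summary = summarize_run(reads=reads, contigs=contigs,
                            ncrna_calls=ncrna_calls, taxon_table=taxon_table)
    total_gb = len(reads) * config.read_len / 1e9
    n_cazy_contigs = len({c.contig_id for c in calls})
    report = {
        "schema_version": 1,
        "summary": summary,
        "ncrna": {
            **ncrna_summary,
            "removal_efficiency_pct": round(100 * removal, 1),
        },
        "cazy": {
            "n_cazy_contigs": n_cazy_contigs,
            "family_contig_counts": {
                k: int(v) for k, v in sorted(family_contig_counts(calls).items())
            },
            "architectures": {
                k: v for k, v in architectures.items() if k != "cooccurrence"
            },
            "identity_bins": identity_bins,
            "discovery_rate_per_gb": (discovery_rate(n_cazy_contigs, total_gb)
                                      if total_gb > 0 else 0),
        },
        "expression": {
            "n_ranked": len(ranked),
            "top": [
                {"contig_id": r.contig_id, "read_count": r.read_count,
                 "coverage": round(r.coverage, 1), "labels": r.labels}
                for r in ranked[:25]
            ],
        },
        "clustering": {"newick": newick,
                       "samples": profile_matrix.sample_ids},
        "rarefaction": {
            "effort_fractions": curve.effort_fractions,
            "mean_richness": [round(m, 2) for m in curve.mean_richness],
            "total_richness": curve.total_richness,
            "effort_at_80pct_richness": round(effort_at_richness(curve, 0.8), 4),
        },
        "provenance": {
            "package_version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash,
            "thresholds": {
                "max_evalue": config.max_evalue, "min_bit": config.min_bit,
                "min_overlap": config.min_overlap, "min_score": config.min_score,
                "min_len": config.min_len, "min_reads": config.min_reads,
            },
        },
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
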