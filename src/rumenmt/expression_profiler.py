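"""Expression, coverage and run-level summary statistics.

Read counts per contig proxy expression level; fold coverage is
``read_count x mean_read_len / contig_len``.  Report rounding mirrors the
field's conventions: gigabases to one decimal, percents to one decimal,
discovery rates to whole genes per gigabase.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import SequenceRecord
from .ncrna_filter import NcrnaCall


@dataclass
class ExpressionRecord:
    contig_id: str
    read_count: int
    coverage: float
    labels: list[str] = field(default_factory=list)
    top_hit_summary: dict | None = None

    def __post_init__(self):
        if self.read_count < 0:
            raise ValueError(f"contig {self.contig_id}: negative read count")


def count_reads_per_contig(
    read_origin: Mapping[str, str],
    contig_ids: Iterable[str],
) -> dict[str, int]:
    """Exact per-contig read counts; contigs with zero reads appear with 0.

    ``read_origin`` maps read id to origin contig id (coding reads only); an
    origin not in ``contig_ids`` is an error.
    """
    counts = {cid: 0 for cid in contig_ids}
    tally = Counter(read_origin.values())
    unknown = set(tally) - set(counts)
    if unknown:
        raise KeyError(f"read origin references unknown contig(s): {sorted(unknown)[:5]}")
    counts.update({cid: int(n) for cid, n in tally.items()})
    return counts


def coverage(read_count: int, mean_read_len: float, contig_len: int) -> float:
    """Fold coverage of a contig: read_count x mean_read_len / contig_len."""
    if contig_len <= 0:
        raise ValueError("contig length must be positive")
    if read_count < 0:
        raise ValueError("read count must be non-negative")
    return read_count * mean_read_len / contig_len


def rank_by_expression(
    records: Sequence[ExpressionRecord],
    min_reads: int = 10000,
) -> list[ExpressionRecord]:
    """Records with at least ``min_reads`` reads, most-expressed first
    (ties broken by contig id)."""
    kept = [r for r in records if r.read_count >= min_reads]
    return sorted(kept, key=lambda r: (-r.read_count, r.contig_id))


def discovery_rate(n_cazy_genes: int, total_gigabases: float) -> int:
    """Carbohydrate-active genes discovered per gigabase of sequence,
    rounded to the nearest integer (2500 genes in 2.8 Gb -> 893/Gb)."""
    if total_gigabases <= 0:
        raise ValueError("total gigabases must be positive")
    if n_cazy_genes < 0:
        raise ValueError("gene count must be non-negative")
    return int(round(n_cazy_genes / total_gigabases))


def rate_ratio(rate_a: float, rate_b: float) -> float:
    """Fold difference between two discovery rates, one decimal."""
    if rate_b <= 0:
        raise ValueError("denominator rate must be positive")
    return round(rate_a / rate_b, 1)


def gc_content(seq: str) -> float | None:
    """GC percent of a DNA sequence; N excluded from the denominator.

    Returns None (missing) for a sequence of only Ns.
    """
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        return None
    return 100.0 * gc / (gc + at)


def gc_by_category(
    records: Sequence[SequenceRecord],
    category_map: Mapping[str, str],
) -> dict[str, float]:
    """Read-weighted mean GC percent per category.

    ``category_map`` maps record id to a category name; records without a
    category (or of only Ns) are skipped.
    """
    sums: dict[str, float] = {}
    ns: dict[str, int] = {}
    for rec in records:
        cat = category_map.get(rec.id)
        if cat is None:
            continue
        gc = gc_content(rec.sequence)
        if gc is None:
            continue
        sums[cat] = sums.get(cat, 0.0) + gc
        ns[cat] = ns.get(cat, 0) + 1
    return {cat: sums[cat] / ns[cat] for cat in sums}


def summarize_run(
    reads: Sequence[SequenceRecord] | None = None,
    contigs: Sequence[SequenceRecord] | None = None,
    ncrna_calls: Sequence[NcrnaCall] | None = None,
    taxon_table: pd.DataFrame | None = None,
    n_reads: int | None = None,
    mean_read_len: float | None = None,
    ncrna_count: int | None = None,
) -> dict:
    """Run-level summary: yield, contig stats, ncRNA share, GC, taxon bins.

    Works from either full records or from summary inputs (``n_reads``,
    ``mean_read_len``, ``ncrna_count``) — total bases use the arithmetic
    ``n_reads x mean read length``.  A run of zero reads yields an all-zero
    summary without division errors.
    """
    if n_reads is None:
        n_reads = len(reads) if reads is not None else 0
    if mean_read_len is None:
        mean_read_len = (float(np.mean([len(r) for r in reads]))
                         if reads else 0.0)
    if ncrna_count is None:
        ncrna_count = (sum(c.is_ncrna for c in ncrna_calls)
                       if ncrna_calls is not None else 0)
    total_bases = n_reads * mean_read_len
    summary = {
        "n_reads": n_reads,
        "mean_read_length": round(mean_read_len, 1),
        "total_gb": round(total_bases / 1e9, 1),
        "n_contigs": len(contigs) if contigs is not None else 0,
        "mean_contig_length": (round(float(np.mean([len(c) for c in contigs])), 1)
                               if contigs else 0.0),
        "ncrna_count": ncrna_count,
        "ncrna_percent": (round(100.0 * ncrna_count / n_reads, 1)
                          if n_reads else 0.0),
    }
    if reads is not None and ncrna_calls is not None:
        nc_ids = {c.read_id for c in ncrna_calls if c.is_ncrna}
        cat = {r.id: ("ncrna_reads" if r.id in nc_ids else "coding_reads")
               for r in reads}
        gc = gc_by_category(reads, cat)
        if contigs:
            gc.update(gc_by_category(contigs, {c.id: "contigs" for c in contigs}))
        summary["gc_percent"] = {k: round(v, 1) for k, v in sorted(gc.items())}
    if taxon_table is not None:
        summary["taxon_percents"] = {
            row["taxon"]: round(row["pct_universe"], 1)
            for _, row in taxon_table.iterrows()
        }
    return summary
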