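"""Top-hit taxonomic binning and rank-level aggregation.

Each query (read or contig) is assigned the taxon of its best significant
alignment hit, ordered by (bit score desc, e-value asc).  Queries whose best
score is tied between several subjects get the lowest common ancestor of the
tied taxa; queries with no significant hit are "unassigned".
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core_io import AlignmentHit, Taxonomy, RANKS

UNASSIGNED = "unassigned"
OTHER_NONE = "other/none"


@dataclass(frozen=True)
class TaxonAssignment:
    query_id: str
    taxon_id: str  # taxon id or UNASSIGNED
    basis: str  # "top_hit" or "lca_of_ties"


def bin_top_hit(
    hits: Iterable[AlignmentHit],
    taxonomy: Taxonomy,
    max_evalue: float = 1e-5,
    query_ids: Sequence[str] | None = None,
) -> list[TaxonAssignment]:
    """Assign each query to the taxon of its best significant hit.

    ``query_ids`` optionally names the full query universe so that queries
    with no hit at all are reported as unassigned; it defaults to the queries
    present in ``hits``.  A subject taxon missing from the taxonomy is an
    error naming the taxon.
    """
    grouped: dict[str, list[AlignmentHit]] = defaultdict(list)
    for h in hits:
        grouped[h.query_id].append(h)
    if query_ids is None:
        queries = sorted(grouped)
    else:
        queries = list(query_ids)
        stray = set(grouped) - set(queries)
        if stray:
            raise KeyError(f"hit query(ies) absent from query universe: {sorted(stray)[:5]}")

    out: list[TaxonAssignment] = []
    for q in queries:
        passing = [h for h in grouped.get(q, ()) if h.e_value <= max_evalue]
        if not passing:
            out.append(TaxonAssignment(q, UNASSIGNED, "top_hit"))
            continue
        best_key = min((-h.bit_score, h.e_value) for h in passing)
        tied = [h for h in passing if (-h.bit_score, h.e_value) == best_key]
        taxa = sorted({h.subject_taxon for h in tied})
        for t in taxa:
            if t not in taxonomy:
                raise KeyError(f"subject taxon {t!r} of query {q!r} absent from taxonomy")
        if len(taxa) == 1:
            out.append(TaxonAssignment(q, taxa[0], "top_hit"))
        else:
            out.append(TaxonAssignment(q, taxonomy.lca(taxa), "lca_of_ties"))
    return out


def aggregate_counts(
    counts_by_taxon: Mapping[str, int],
    taxonomy: Taxonomy,
    rank: str,
    n_unassigned: int = 0,
) -> pd.DataFrame:
    """Lift per-taxon counts to ``rank`` and tabulate counts and percents.

    Taxa whose lineage has no node at the requested rank (including taxa
    already coarser than it) fall into the "other/none" bucket.  Percents are
    reported both over the full universe (assigned + unassigned) and over the
    assigned subset.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    lifted: dict[str, int] = defaultdict(int)
    for taxon, n in counts_by_taxon.items():
        anc = taxonomy.ancestor_at_rank(taxon, rank)
        lifted[anc if anc is not None else OTHER_NONE] += n
    n_assigned = sum(lifted.values())
    universe = n_assigned + n_unassigned
    if n_unassigned:
        lifted[UNASSIGNED] = n_unassigned
    rows = []
    for taxon in sorted(lifted, key=lambda t: (-lifted[t], t)):
        n = lifted[taxon]
        rows.append({
            "taxon": taxon,
            "count": n,
            "pct_universe": 100.0 * n / universe if universe else 0.0,
            "pct_assigned": (100.0 * n / n_assigned
                             if n_assigned and taxon != UNASSIGNED else 0.0),
        })
    return pd.DataFrame(rows, columns=["taxon", "count", "pct_universe", "pct_assigned"])


def aggregate_rank(
    assignments: Sequence[TaxonAssignment],
    taxonomy: Taxonomy,
    rank: str,
) -> pd.DataFrame:
    """Aggregate taxon assignments at ``rank`` (see :func:`aggregate_counts`)."""
    counts: dict[str, int] = defaultdict(int)
    n_unassigned = 0
    for a in assignments:
        if a.taxon_id == UNASSIGNED:
            n_unassigned += 1
        else:
            counts[a.taxon_id] += 1
    return aggregate_counts(counts, taxonomy, rank, n_unassigned)


def format_percent(pct: float) -> str:
    """Report-style percent: whole number at >= 10%, one decimal below
    (e.g. 31.28 -> "31%", 3.41 -> "3.4%")."""
    if pct >= 10:
        return f"{pct:.0f}%"
    return f"{pct:.1f}%"
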