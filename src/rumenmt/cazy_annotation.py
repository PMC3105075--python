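"""CAZy module annotation: model-to-family association and module calling.

The association table links domain models to CAZy family labels through four
routes: (A) models published directly for a family; (B) models conservatively
associated by screening family members against the model collection — a model
is accepted for a single family when all its significant member hits come
from that family and at least 80% of the family's members conform to it, or
for a combined group ("CE2/CE3") when every implicated family passes the 80%
coverage bar; (C) BLAST hits against representative sequences for families
with no model, at a bit-score cutoff of 52; (D) externally built profiles for
the remainder, consumed as pre-labelled model ids.

Module calling keeps hits scoring at or above the cutoff (52 bits, boundary
inclusive), merges overlapping calls with the same label (span union, max
score) so fragmented hits on one domain do not inflate family counts, and
retains overlapping calls with distinct labels so genuinely stacked modules
(GH + CBM) survive.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core_io import AlignmentHit, DomainHit
from .synthetic_data import CazyFamilyDef

ASSOCIATION_STEPS = ("A", "B", "C", "D")
REJECTION_REASONS = ("impure", "low_coverage", "none")
UNCLASSIFIED = "unclassified"
COVERAGE_THRESHOLD = 0.80


@dataclass(frozen=True)
class AssociationEntry:
    model_id: str
    label: str  # single family ("GH6") or combined group ("CE2/CE3")
    step: str
    accepted: bool
    rejection_reason: str = "none"

    def __post_init__(self):
        if self.step not in ASSOCIATION_STEPS:
            raise ValueError(f"unknown association step {self.step!r}")
        if self.rejection_reason not in REJECTION_REASONS:
            raise ValueError(f"unknown rejection reason {self.rejection_reason!r}")
        if self.accepted and self.rejection_reason != "none":
            raise ValueError("accepted entries carry no rejection reason")


@dataclass(frozen=True)
class ModuleCall:
    contig_id: str
    label: str
    q_start: int
    q_end: int
    score: float
    source: str  # "hmm" or "blast"

    def __post_init__(self):
        if self.q_start > self.q_end:
            raise ValueError(f"module call {self.contig_id}/{self.label}: q_start > q_end")


@dataclass
class ContigAnnotation:
    contig_id: str
    length: int
    read_count: int
    modules: list[ModuleCall] = field(default_factory=list)
    top_hit: dict | None = None  # percent_identity, e_value, annotation

    def __post_init__(self):
        if self.read_count < 0:
            raise ValueError(f"contig {self.contig_id}: negative read count")
        self.modules = sorted(self.modules, key=lambda m: (m.q_start, m.q_end, m.label))

    @property
    def labels(self) -> set[str]:
        return {m.label for m in self.modules if m.label != UNCLASSIFIED}


# ---------------------------------------------------------------------------
# association table (Step B logic)
# ---------------------------------------------------------------------------


def build_association_table(
    family_defs: Sequence[CazyFamilyDef],
    member_model_hits: Iterable[tuple[str, str, bool]],
) -> list[AssociationEntry]:
    """Associate candidate models with CAZy families from member screening.

    ``member_model_hits`` rows are ``(member_id, model_id, significant)``.
    For each model, collect the set F of families whose members hit it
    significantly and the per-family coverage (hit members / family size):

    * |F| = 1 and coverage >= 0.80  -> accepted single-family entry;
    * |F| > 1 and every family >= 0.80 -> accepted combined entry, label the
      "/"-joined sorted family ids;
    * otherwise rejected: "impure" when coverages are mixed across the bar,
      "low_coverage" when no family reaches it.

    Order-independent: permuting the input rows yields the identical table.
    """
    member_family: dict[str, str] = {}
    family_size: dict[str, int] = {}
    for fam in family_defs:
        family_size[fam.family_id] = len(fam.member_ids)
        for m in fam.member_ids:
            if m in member_family:
                raise ValueError(f"member {m!r} belongs to more than one family")
            member_family[m] = fam.family_id

    model_hits: dict[str, dict[str, set[str]]] = defaultdict(lambda: defaultdict(set))
    for member_id, model_id, significant in member_model_hits:
        if member_id not in member_family:
            raise KeyError(f"unknown member id {member_id!r}")
        if significant:
            model_hits[model_id][member_family[member_id]].add(member_id)

    entries: list[AssociationEntry] = []
    for model_id in sorted(model_hits):
        coverage = {
            fam: len(members) / family_size[fam]
            for fam, members in model_hits[model_id].items()
        }
        families = sorted(coverage)
        label = "/".join(families)
        passing = [f for f in families if coverage[f] >= COVERAGE_THRESHOLD]
        if len(families) == 1:
            if passing:
                entries.append(AssociationEntry(model_id, label, "B", True))
            else:
                entries.append(AssociationEntry(model_id, label, "B", False, "low_coverage"))
        else:
            if len(passing) == len(families):
                entries.append(AssociationEntry(model_id, label, "B", True))
            elif passing:
                entries.append(AssociationEntry(model_id, label, "B", False, "impure"))
            else:
                entries.append(AssociationEntry(model_id, label, "B", False, "low_coverage"))
    return entries


# ---------------------------------------------------------------------------
# module calling
# ---------------------------------------------------------------------------


def merge_calls(calls: Iterable[ModuleCall]) -> list[ModuleCall]:
    """Merge overlapping same-label calls per contig (span union, max score).

    Calls with distinct labels are never merged.  Idempotent: re-merging the
    output changes nothing.  Result sorted by (contig_id, q_start).
    """
    grouped: dict[tuple[str, str, str], list[ModuleCall]] = defaultdict(list)
    for c in calls:
        grouped[(c.contig_id, c.label, c.source)].append(c)
    merged: list[ModuleCall] = []
    for (cid, label, source), group in grouped.items():
        group.sort(key=lambda c: (c.q_start, c.q_end))
        cur = group[0]
        for nxt in group[1:]:
            if nxt.q_start <= cur.q_end:  # 1-based inclusive overlap
                cur = ModuleCall(cid, label, cur.q_start, max(cur.q_end, nxt.q_end),
                                 max(cur.score, nxt.score), source)
            else:
                merged.append(cur)
                cur = nxt
        merged.append(cur)
    merged.sort(key=lambda c: (c.contig_id, c.q_start, c.q_end, c.label))
    return merged


def call_modules(
    domain_hits: Iterable[DomainHit],
    assoc: Sequence[AssociationEntry] = (),
    direct_models: Mapping[str, str] | None = None,
    blast_reps: Iterable[AlignmentHit] = (),
    rep_labels: Mapping[str, str] | None = None,
    min_score: float = 52.0,
) -> list[ModuleCall]:
    """Call CAZy modules on contigs/reads from domain and BLAST evidence.

    Labels resolve through ``direct_models`` (Steps A/D), then accepted
    association entries (Step B); ``blast_reps`` hits are labelled via
    ``rep_labels`` on their subject id (Step C).  Hits scoring below
    ``min_score`` are discarded (the boundary is inclusive); a model with no
    route to a label is warned about and labelled "unclassified".
    """
    direct_models = dict(direct_models or {})
    rep_labels = dict(rep_labels or {})
    assoc_labels = {e.model_id: e.label for e in assoc if e.accepted}
    raw: list[ModuleCall] = []
    unrouted: set[str] = set()
    for h in domain_hits:
        if h.bit_score < min_score:
            continue
        label = direct_models.get(h.model_id) or assoc_labels.get(h.model_id)
        if label is None:
            unrouted.add(h.model_id)
            label = UNCLASSIFIED
        raw.append(ModuleCall(h.query_id, label, h.q_start, h.q_end, h.bit_score, h.source))
    for h in blast_reps:
        if h.bit_score < min_score:
            continue
        label = rep_labels.get(h.subject_id)
        if label is None:
            unrouted.add(h.subject_id)
            label = UNCLASSIFIED
        raw.append(ModuleCall(h.query_id, label, h.q_start, h.q_end, h.bit_score, "blast"))
    if unrouted:
        warnings.warn(
            f"{len(unrouted)} model/representative id(s) with no route to a CAZy label "
            f"were called 'unclassified': {sorted(unrouted)[:5]}",
            stacklevel=2,
        )
    return merge_calls(raw)


def annotate_contigs(
    calls: Iterable[ModuleCall],
    contig_lengths: Mapping[str, int],
    read_counts: Mapping[str, int] | None = None,
    top_hits: Mapping[str, AlignmentHit] | None = None,
) -> list[ContigAnnotation]:
    """Assemble per-contig annotations for every contig carrying a call."""
    read_counts = read_counts or {}
    top_hits = top_hits or {}
    by_contig: dict[str, list[ModuleCall]] = defaultdict(list)
    for c in calls:
        by_contig[c.contig_id].append(c)
    annotations = []
    for cid in sorted(by_contig):
        if cid not in contig_lengths:
            raise KeyError(f"module call on unknown contig {cid!r}")
        hit = top_hits.get(cid)
        annotations.append(ContigAnnotation(
            contig_id=cid,
            length=contig_lengths[cid],
            read_count=int(read_counts.get(cid, 0)),
            modules=by_contig[cid],
            top_hit=(None if hit is None else {
                "percent_identity": hit.percent_identity,
                "e_value": hit.e_value,
                "annotation": hit.subject_annotation,
            }),
        ))
    return annotations


# ---------------------------------------------------------------------------
# architectures and identity bins
# ---------------------------------------------------------------------------


def resolve_architectures(
    annotations: Sequence[ContigAnnotation],
    min_len: int = 500,
) -> dict:
    """Multi-domain architecture summary over contigs >= ``min_len`` bp.

    A contig is multi-domain iff it carries calls with at least two distinct
    labels (two fragments of the same family do not count).  Co-occurrence
    counts each unordered label pair once per contig; per-label percents are
    |multi-domain contigs containing the label| / |multi-domain contigs|,
    one decimal.
    """
    considered = [a for a in annotations if a.length >= min_len]
    multi = [a for a in considered if len(a.labels) >= 2]
    cooccurrence: Counter[tuple[str, str]] = Counter()
    label_presence: Counter[str] = Counter()
    for a in multi:
        labels = sorted(a.labels)
        for l in labels:
            label_presence[l] += 1
        for i, la in enumerate(labels):
            for lb in labels[i + 1:]:
                cooccurrence[(la, lb)] += 1
    n_multi = len(multi)
    percents = {
        l: round(100.0 * n / n_multi, 1) for l, n in sorted(label_presence.items())
    } if n_multi else {}
    return {
        "n_considered": len(considered),
        "min_len": min_len,
        "multi_domain_contigs": [a.contig_id for a in multi],
        "n_multi_domain": n_multi,
        "cooccurrence": dict(cooccurrence),
        "label_percents": percents,
    }


IDENTITY_BINS = ("<50", "50-70", ">70")


def bin_identity(annotations: Sequence[ContigAnnotation]) -> dict:
    """Bin contigs by top-hit percent identity: [0,50), [50,70], (70,100].

    Contigs with no top hit are counted separately as ``no_hit``; percents
    are over contigs with a hit, one decimal.
    """
    counts = {b: 0 for b in IDENTITY_BINS}
    no_hit = 0
    for a in annotations:
        if a.top_hit is None:
            no_hit += 1
            continue
        ident = a.top_hit["percent_identity"]
        if not 0 <= ident <= 100:
            raise ValueError(
                f"contig {a.contig_id}: percent identity {ident} outside [0, 100]")
        if ident < 50:
            counts["<50"] += 1
        elif ident <= 70:
            counts["50-70"] += 1
        else:
            counts[">70"] += 1
    n_with_hit = sum(counts.values())
    percents = {
        b: round(100.0 * n / n_with_hit, 1) if n_with_hit else 0.0
        for b, n in counts.items()
    }
    return {"counts": counts, "no_hit": no_hit, "percents": percents,
            "n_with_hit": n_with_hit}


def family_contig_counts(calls: Iterable[ModuleCall]) -> Counter:
    """Number of distinct contigs carrying each family label."""
    seen: dict[str, set[str]] = defaultdict(set)
    for c in calls:
        if c.label != UNCLASSIFIED:
            seen[c.label].add(c.contig_id)
    return Counter({label: len(cids) for label, cids in seen.items()})
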