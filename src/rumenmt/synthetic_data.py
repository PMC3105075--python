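"""Synthetic community generator with fully known planted truth.

Emulates the statistical structure of a deep rumen eukaryotic
metatranscriptome so that every downstream stage is testable without any
download: a read population with a configurable non-coding-RNA fraction
(default 18.4%), contigs carrying planted CAZy module architectures with
heavy-tailed (log-normal) expression, alignment/domain hit tables consistent
with that truth plus configurable noise, and a small taxonomy with
rumen-eukaryote-like clades (anaerobic fungi, ciliate protozoa, a few
bacterial and archaeal lineages).

Defaults are the emulated study conditions: reads of 108 nt, contig lengths
log-normal with median 310 bp, contig GC ~ 37.9%, ncRNA GC ~ 51%, expression
weights log-normal(mu=3, sigma=1.5).  All generation is deterministic given a
seed (numpy PCG64 with integer seeding).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core_io import (
    AlignmentHit,
    DomainHit,
    SequenceRecord,
    Taxonomy,
    TaxonomyNode,
)

RRNA_SUBJECT_PREFIX = "rrna_"  # alignment hits against the rRNA database

# ---------------------------------------------------------------------------
# family universe
# ---------------------------------------------------------------------------

CAZY_CLASSES = ("GH", "CE", "PL", "CBM", "GT", "OTHER")


@dataclass(frozen=True)
class CazyFamilyDef:
    """One CAZy family: its class, reference members and associated models."""

    family_id: str
    class_code: str
    member_ids: tuple[str, ...]
    pfam_model_ids: tuple[str, ...] = ()

    def __post_init__(self):
        if self.class_code not in CAZY_CLASSES:
            raise ValueError(f"unknown CAZy class {self.class_code!r}")
        if not self.member_ids:
            raise ValueError(f"family {self.family_id}: member_ids must be non-empty")


_DEFAULT_FAMILY_NAMES = {
    "GH": ["GH1", "GH5", "GH6", "GH9", "GH10", "GH11", "GH16", "GH26", "GH43",
           "GH45", "GH48", "GH53", "GH94"],
    "CE": ["CE1", "CE4", "CE7"],
    "PL": ["PL1", "PL3", "PL6", "PL9", "PL11"],
    "CBM": ["CBM1", "CBM6", "CBM10", "CBM13", "CBM18", "CBM29"],
    "OTHER": ["SWO1"],  # swollenin
}


def default_family_universe(n_members: int = 10) -> list[CazyFamilyDef]:
    """The named catalytic/binding families exercised by the pipeline."""
    fams = []
    for cls, names in _DEFAULT_FAMILY_NAMES.items():
        for fam in names:
            members = tuple(f"{fam}_p{i:02d}" for i in range(1, n_members + 1))
            fams.append(CazyFamilyDef(fam, cls, members, (f"PF_{fam}",)))
    return fams


def model_label_map(family_defs: Sequence[CazyFamilyDef]) -> dict[str, str]:
    """model id -> family label for families with directly usable models."""
    out: dict[str, str] = {}
    for fam in family_defs:
        for model in fam.pfam_model_ids:
            out[model] = fam.family_id
    return out


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

_DEFAULT_TAXA = [
    # (taxon, parent, rank)
    ("root", "", "root"),
    ("Eukaryota", "root", "kingdom"),
    ("Bacteria", "root", "kingdom"),
    ("Archaea", "root", "kingdom"),
    ("Neocallimastigomycota", "Eukaryota", "phylum"),
    ("Neocallimastigomycetes", "Neocallimastigomycota", "class"),
    ("Neocallimastigales", "Neocallimastigomycetes", "order"),
    ("Neocallimastigaceae", "Neocallimastigales", "family"),
    ("Piromyces", "Neocallimastigaceae", "genus"),
    ("Neocallimastix", "Neocallimastigaceae", "genus"),
    ("Orpinomyces", "Neocallimastigaceae", "genus"),
    ("Anaeromyces", "Neocallimastigaceae", "genus"),
    ("Ciliophora", "Eukaryota", "phylum"),
    ("Litostomatea", "Ciliophora", "class"),
    ("Entodiniomorphida", "Litostomatea", "order"),
    ("Ophryoscolecidae", "Entodiniomorphida", "family"),
    ("Entodinium", "Ophryoscolecidae", "genus"),
    ("Epidinium", "Ophryoscolecidae", "genus"),
    ("Polyplastron", "Ophryoscolecidae", "genus"),
    ("Parabasalia", "Eukaryota", "phylum"),
    ("Trichomonadea", "Parabasalia", "class"),
    ("Trichomonadida", "Trichomonadea", "order"),
    ("Trichomonadidae", "Trichomonadida", "family"),
    ("Trichomonas", "Trichomonadidae", "genus"),
    ("Fibrobacteres", "Bacteria", "phylum"),
    ("Fibrobacteria", "Fibrobacteres", "class"),
    ("Fibrobacterales", "Fibrobacteria", "order"),
    ("Fibrobacteraceae", "Fibrobacterales", "family"),
    ("Fibrobacter", "Fibrobacteraceae", "genus"),
    ("Firmicutes", "Bacteria", "phylum"),
    ("Clostridia", "Firmicutes", "class"),
    ("Eubacteriales", "Clostridia", "order"),
    ("Ruminococcaceae", "Eubacteriales", "family"),
    ("Ruminococcus", "Ruminococcaceae", "genus"),
    ("Euryarchaeota", "Archaea", "phylum"),
    ("Methanobacteria", "Euryarchaeota", "class"),
    ("Methanobacteriales", "Methanobacteria", "order"),
    ("Methanobacteriaceae", "Methanobacteriales", "family"),
    ("Methanobrevibacter", "Methanobacteriaceae", "genus"),
]

#: Genus-level community composition: fungi and ciliates dominate, with a
#: small bacteria-like and archaeal tail.
DEFAULT_TAXON_WEIGHTS = {
    "Piromyces": 0.20,
    "Neocallimastix": 0.15,
    "Orpinomyces": 0.15,
    "Anaeromyces": 0.05,
    "Entodinium": 0.15,
    "Epidinium": 0.08,
    "Polyplastron": 0.04,
    "Trichomonas": 0.08,
    "Fibrobacter": 0.06,
    "Ruminococcus": 0.03,
    "Methanobrevibacter": 0.01,
}


def default_taxonomy() -> Taxonomy:
    return Taxonomy(TaxonomyNode(t, p, r, t) for t, p, r in _DEFAULT_TAXA)


# ---------------------------------------------------------------------------
# architectures
# ---------------------------------------------------------------------------


def default_architecture_distribution() -> dict[tuple[str, ...], float]:
    """Architecture -> probability over contigs.

    About 9% of contigs carry at least one CAZy module; the multi-domain
    architectures pair exo-cellulase families with the fungal dockerin-like
    binding module CBM10, mirroring anaerobic-fungal cellulases.
    """
    arch: dict[tuple[str, ...], float] = {
        ("GH48", "CBM10"): 0.008,
        ("GH6", "CBM10"): 0.007,
        ("GH45", "CBM10"): 0.005,
        ("GH1",): 0.006, ("GH5",): 0.005, ("GH9",): 0.004, ("GH10",): 0.005,
        ("GH11",): 0.006, ("GH16",): 0.003, ("GH26",): 0.002, ("GH43",): 0.004,
        ("GH48",): 0.004, ("GH53",): 0.002, ("GH94",): 0.002,
        ("CE1",): 0.002, ("CE4",): 0.004, ("CE7",): 0.002,
        ("PL1",): 0.001, ("PL3",): 0.001, ("PL6",): 0.002, ("PL9",): 0.001,
        ("PL11",): 0.001,
        ("CBM1",): 0.003, ("CBM18",): 0.004, ("CBM6",): 0.002,
        ("CBM13",): 0.002, ("CBM29",): 0.001,
        ("SWO1",): 0.002,
    }
    arch[()] = 1.0 - sum(arch.values())
    return arch


# ---------------------------------------------------------------------------
# truth containers
# ---------------------------------------------------------------------------


@dataclass
class ContigTruth:
    contig_id: str
    taxon_id: str
    length: int
    gc: float
    weight: float
    modules: tuple[tuple[str, int, int], ...]  # (label, q_start, q_end)


@dataclass
class CommunityTruth:
    """Everything the generator planted, serializable alongside the outputs."""

    contigs: dict[str, ContigTruth]
    family_defs: tuple[CazyFamilyDef, ...]
    seed: int
    gc_target: float
    ncrna_gc: float = 0.51
    ncrna_fraction: float | None = None
    read_len: int | None = None
    read_origins: dict[str, str] = field(default_factory=dict)  # read -> contig or "ncRNA"

    @property
    def ncrna_read_ids(self) -> set[str]:
        return {r for r, o in self.read_origins.items() if o == "ncRNA"}

    def coding_origins(self) -> dict[str, str]:
        return {r: o for r, o in self.read_origins.items() if o != "ncRNA"}


def write_truth_contigs(truth: CommunityTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write("# columns: contig_id taxon_id length gc weight modules"
                 " (modules: label:start-end;...)\n")
        for cid in sorted(truth.contigs):
            c = truth.contigs[cid]
            mods = ";".join(f"{l}:{s}-{e}" for l, s, e in c.modules)
            fh.write(f"{c.contig_id}\t{c.taxon_id}\t{c.length}\t{c.gc:.4f}"
                     f"\t{c.weight:.6g}\t{mods}\n")


def write_truth_reads(truth: CommunityTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write("# columns: read_id origin (origin: contig id or ncRNA)\n")
        for rid in sorted(truth.read_origins):
            fh.write(f"{rid}\t{truth.read_origins[rid]}\n")


def read_truth_reads(path) -> dict[str, str]:
    origins: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            rid, origin = line.split("\t")
            origins[rid] = origin
    return origins


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    """Random sequence whose realized composition matches ``gc`` exactly
    (shuffled base multiset), so per-sequence GC carries no binomial noise."""
    n_gc = int(round(length * gc))
    g = n_gc // 2
    c = n_gc - g
    a = (length - n_gc) // 2
    t = length - n_gc - a
    codes = np.repeat(np.arange(4), [a, c, g, t])
    rng.shuffle(codes)
    return "".join("ACGT"[k] for k in codes)


def _module_span(rng: np.random.Generator, label: str) -> int:
    # binding modules are short; catalytic modules span a few hundred bp
    if label.startswith("CBM"):
        return int(rng.integers(60, 181))
    return int(rng.integers(120, 401))


def generate_community(
    n_contigs: int,
    family_defs: Sequence[CazyFamilyDef] | None = None,
    taxonomy: Taxonomy | None = None,
    arch_distribution: Mapping[tuple[str, ...], float] | None = None,
    expression_law: tuple[float, float] = (3.0, 1.5),
    gc_target: float = 0.379,
    seed: int = 0,
    taxon_weights: Mapping[str, float] | None = None,
    length_law: tuple[float, float] = (math.log(310.0), 0.6),
) -> tuple[list[SequenceRecord], CommunityTruth]:
    """Generate contigs with planted taxa, architectures and expression.

    Contig lengths are log-normal (default median 310 bp), per-contig GC is
    drawn around ``gc_target`` and expression weights follow
    ``lognormal(*expression_law)``.  Deterministic given ``seed``.
    """
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    if family_defs is None:
        family_defs = default_family_universe()
    if taxonomy is None:
        taxonomy = default_taxonomy()
    if arch_distribution is None:
        arch_distribution = default_architecture_distribution()
    if taxon_weights is None:
        taxon_weights = DEFAULT_TAXON_WEIGHTS

    archs = sorted(arch_distribution.items())
    probs = np.array([p for _, p in archs], dtype=float)
    if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("architecture probabilities must be >= 0 and sum to 1")
    known_labels = {f.family_id for f in family_defs}
    cazy_prob = sum(p for a, p in archs if a)
    planted_labels = {l for a, _ in archs for l in a}
    if cazy_prob > 0 and not planted_labels:
        raise ValueError("nonzero CAZy architecture probability with empty architectures")
    missing = planted_labels - known_labels
    if missing:
        raise ValueError(f"architectures use families absent from the universe: {sorted(missing)}")

    taxa = sorted(taxon_weights)
    for t in taxa:
        if t not in taxonomy:
            raise ValueError(f"taxon weight references unknown taxon {t!r}")
    tprobs = np.array([taxon_weights[t] for t in taxa], dtype=float)
    tprobs = tprobs / tprobs.sum()

    rng = np.random.default_rng(seed)
    mu, sigma = expression_law
    lmu, lsigma = length_law
    width = len(str(n_contigs))
    records: list[SequenceRecord] = []
    contigs: dict[str, ContigTruth] = {}

    arch_idx = rng.choice(len(archs), size=n_contigs, p=probs)
    taxon_idx = rng.choice(len(taxa), size=n_contigs, p=tprobs)
    lengths = rng.lognormal(lmu, lsigma, size=n_contigs)
    # per-contig GC spread kept tight (sd 0.015) so read-weighted category
    # means stay identifiable under heavy-tailed expression weighting
    gcs = np.clip(rng.normal(gc_target, 0.015, size=n_contigs), 0.05, 0.95)
    weights = rng.lognormal(mu, sigma, size=n_contigs)

    for i in range(n_contigs):
        cid = f"contig{i + 1:0{width}d}"
        arch = archs[arch_idx[i]][0]
        modules: list[tuple[str, int, int]] = []
        pos = int(rng.integers(1, 31))
        for label in arch:
            span = _module_span(rng, label)
            modules.append((label, pos, pos + span - 1))
            pos = pos + span - 1 + int(rng.integers(10, 61))
        length = max(int(round(lengths[i])), 60)
        if modules:
            length = max(length, modules[-1][2] + int(rng.integers(5, 31)))
        gc = float(gcs[i])
        seq = _random_dna(rng, length, gc)
        taxon = taxa[taxon_idx[i]]
        records.append(SequenceRecord(cid, seq, f"taxon={taxon}"))
        contigs[cid] = ContigTruth(cid, taxon, length, gc, float(weights[i]),
                                   tuple(modules))

    truth = CommunityTruth(
        contigs=contigs,
        family_defs=tuple(family_defs),
        seed=seed,
        gc_target=gc_target,
    )
    return records, truth


def _rrna_pool(rng: np.random.Generator, ncrna_gc: float,
               n_refs: int = 40, ref_len: int = 3000) -> list[str]:
    return [_random_dna(rng, ref_len, ncrna_gc) for _ in range(n_refs)]


def generate_reads(
    contigs: Sequence[SequenceRecord],
    truth: CommunityTruth,
    n_reads: int,
    read_len: int = 108,
    ncrna_fraction: float = 0.184,
    ncrna_gc: float = 0.51,
    seed: int = 0,
) -> tuple[list[SequenceRecord], CommunityTruth]:
    """Sample reads from contigs (probability ∝ expression weight × length)
    plus ncRNA reads drawn from a dedicated rRNA pool.

    Records every read's origin in ``truth.read_origins`` ("ncRNA" or the
    source contig id) and returns the updated truth.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if not 0 <= ncrna_fraction <= 1:
        raise ValueError("ncrna_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    seqs = {r.id: r.sequence for r in contigs}
    cids = sorted(truth.contigs)
    w = np.array([truth.contigs[c].weight * truth.contigs[c].length for c in cids])
    p = w / w.sum()
    pool = _rrna_pool(rng, ncrna_gc)

    is_nc = rng.random(n_reads) < ncrna_fraction
    origin_idx = rng.choice(len(cids), size=n_reads, p=p)
    pool_idx = rng.integers(0, len(pool), size=n_reads)
    width = len(str(n_reads))
    reads: list[SequenceRecord] = []
    for i in range(n_reads):
        rid = f"read{i + 1:0{width}d}"
        if is_nc[i]:
            src = pool[pool_idx[i]]
            start = int(rng.integers(0, max(1, len(src) - read_len + 1)))
            seq = src[start : start + read_len]
            truth.read_origins[rid] = "ncRNA"
        else:
            cid = cids[origin_idx[i]]
            src = seqs[cid]
            start = int(rng.integers(0, max(1, len(src) - read_len + 1)))
            seq = src[start : start + read_len]
            truth.read_origins[rid] = cid
        reads.append(SequenceRecord(rid, seq))
    truth.ncrna_fraction = ncrna_fraction
    truth.read_len = read_len
    truth.ncrna_gc = ncrna_gc
    return reads, truth


_ANNOTATION_POOL = (
    "cellulase Cel48A precursor",
    "cellobiohydrolase II-like cellulase",
    "xylanase",
    "beta-glucosidase",
    "licheninase",
    "polysaccharide lyase",
    "carbohydrate esterase",
    "hypothetical protein",
    "predicted protein",
)


def generate_hit_tables(
    truth: CommunityTruth,
    fn_rate: float = 0.0,
    fp_rate: float = 0.0,
    score_jitter: float = 0.0,
    seed: int = 0,
    min_score: float = 52.0,
    max_evalue: float = 1e-5,
    min_overlap: int = 50,
    hmm_flag_fraction: float = 0.0,
) -> tuple[list[AlignmentHit], list[DomainHit], set[str]]:
    """Simulate search output consistent with the planted truth.

    Returns ``(alignment_hits, domain_hits, hmm_flags)``.  Alignment hits
    against the rRNA database have subject ids starting with
    ``RRNA_SUBJECT_PREFIX`` (see :func:`split_alignment_hits`).  Every planted
    module emits a domain hit with probability ``1 - fn_rate`` and a score at
    or above the cutoff; decoys are emitted at ``fp_rate`` with scores/e-values
    failing the cutoffs in expectation.  ``hmm_flag_fraction`` of ncRNA reads
    are additionally flagged by the HMM route.
    """
    for name, rate in (("fn_rate", fn_rate), ("fp_rate", fp_rate)):
        if not 0 <= rate <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    if truth.read_len is None:
        raise ValueError("truth carries no reads; call generate_reads first")
    rng = np.random.default_rng(seed)
    alignment: list[AlignmentHit] = []
    domain: list[DomainHit] = []
    hmm_flags: set[str] = set()
    labels = model_label_map(truth.family_defs)
    label_to_model = {v: k for k, v in labels.items()}
    all_models = sorted(labels)
    read_len = truth.read_len

    def passing_score() -> float:
        s = min_score + float(rng.uniform(5, 80)) + score_jitter * float(rng.standard_normal())
        return max(min_score, round(s, 1))

    # --- contig-level evidence -------------------------------------------
    for cid in sorted(truth.contigs):
        c = truth.contigs[cid]
        for label, qs, qe in c.modules:
            if fn_rate and rng.random() < fn_rate:
                continue
            domain.append(DomainHit(cid, label_to_model[label], passing_score(),
                                    10.0 ** -float(rng.uniform(6, 30)), qs, qe, "hmm"))
        if fp_rate and rng.random() < fp_rate:
            decoy = all_models[int(rng.integers(0, len(all_models)))]
            score = round(min_score - 10 + score_jitter * float(rng.standard_normal()), 1)
            qs = int(rng.integers(1, max(2, c.length // 2)))
            qe = min(c.length, qs + int(rng.integers(40, 200)))
            domain.append(DomainHit(cid, decoy, score, 1e-3, qs, qe, "hmm"))
        # top database hit: identity mixture mirrors a mostly-novel gene pool
        # (46% below 50% id, 37% between, 17% above 70%)
        if not (fn_rate and rng.random() < fn_rate):
            u = rng.random()
            if u < 0.46:
                ident = float(rng.uniform(25, 50))
            elif u < 0.83:
                ident = float(rng.uniform(50, 70))
            else:
                ident = float(rng.uniform(70.5, 95))
            alen = int(min(c.length, rng.integers(80, 400)))
            annot = _ANNOTATION_POOL[int(rng.integers(0, len(_ANNOTATION_POOL)))]
            alignment.append(AlignmentHit(
                cid, f"{c.taxon_id}_prot{int(rng.integers(1, 50)):02d}",
                round(ident, 1), alen, int(alen * (1 - ident / 100)), 0,
                1, alen, 1, alen, 10.0 ** -float(rng.uniform(6, 40)),
                passing_score(), c.taxon_id, annot))

    # --- read-level evidence ---------------------------------------------
    for rid in sorted(truth.read_origins):
        origin = truth.read_origins[rid]
        if origin == "ncRNA":
            if not (fn_rate and rng.random() < fn_rate):
                span = int(rng.integers(min_overlap, read_len + 1))
                qs = int(rng.integers(1, read_len - span + 2))
                alignment.append(AlignmentHit(
                    rid, f"{RRNA_SUBJECT_PREFIX}SSU_{int(rng.integers(1, 9))}",
                    round(float(rng.uniform(90, 100)), 1), span, 0, 0,
                    qs, qs + span - 1, 1, span,
                    max_evalue * 10.0 ** -float(rng.uniform(1, 15)),
                    passing_score(), "", "ribosomal RNA"))
            if hmm_flag_fraction and rng.random() < hmm_flag_fraction:
                hmm_flags.add(rid)
        else:
            taxon = truth.contigs[origin].taxon_id
            if not (fn_rate and rng.random() < fn_rate):
                alignment.append(AlignmentHit(
                    rid, f"{taxon}_prot{int(rng.integers(1, 50)):02d}",
                    round(float(rng.uniform(40, 95)), 1), read_len, 0, 0,
                    1, read_len, 1, read_len,
                    max_evalue * 10.0 ** -float(rng.uniform(1, 15)),
                    passing_score(), taxon,
                    _ANNOTATION_POOL[int(rng.integers(0, len(_ANNOTATION_POOL)))]))
            if fp_rate and rng.random() < fp_rate:
                # rRNA-like decoy that fails the e-value rule in expectation
                alignment.append(AlignmentHit(
                    rid, f"{RRNA_SUBJECT_PREFIX}LSU_decoy",
                    round(float(rng.uniform(60, 80)), 1), min_overlap + 10, 5, 1,
                    1, min_overlap + 10, 1, min_overlap + 10,
                    max_evalue * 10.0 ** float(rng.uniform(1, 3)),
                    round(min_score - 10, 1), "", "ribosomal RNA"))
    return alignment, domain, hmm_flags


def split_alignment_hits(
    hits: Iterable[AlignmentHit],
) -> tuple[list[AlignmentHit], list[AlignmentHit]]:
    """Split one alignment table into (rRNA-database hits, protein-database
    hits) by the subject-id naming convention."""
    rrna, protein = [], []
    for h in hits:
        (rrna if h.subject_id.startswith(RRNA_SUBJECT_PREFIX) else protein).append(h)
    return rrna, protein
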