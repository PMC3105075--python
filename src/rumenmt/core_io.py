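"""File formats, domain records and run configuration.

Every coordinate in this package is 1-based inclusive (BLAST convention); the
overlap length of a hit spanning positions ``a..b`` is ``b - a + 1``.  All
tab-separated tables may contain ``#`` comment lines.  Readers reject
malformed input with positional diagnostics (file and line number); every
writer/reader pair is an inverse on valid data so that outputs are
reproducible byte-for-byte given a seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

IUPAC_DNA = frozenset("ACGTN")

#: Taxonomic ranks from coarsest to finest.
RANKS = ("root", "kingdom", "phylum", "class", "order", "family", "genus", "species")

HIT_SOURCES = ("hmm", "blast")


class ParseError(ValueError):
    """Malformed input; message carries the offending path and line number."""

    def __init__(self, path, line_no: int, message: str):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = str(path)
        self.line_no = line_no


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequenceRecord:
    """A read or contig: DNA over {A,C,G,T,N}, upper-cased on read."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")
        if not self.sequence:
            raise ValueError(f"sequence of record {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentHit:
    """One row of a BLAST-tabular-like similarity search result.

    The standard 12 columns are kept verbatim; ``subject_taxon`` and
    ``subject_annotation`` ride along as two extra trailing columns so that
    taxonomic binning and ranked reports need no second join file.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    align_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float
    subject_taxon: str = ""
    subject_annotation: str = ""

    def __post_init__(self):
        if self.q_start > self.q_end:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: q_start {self.q_start} > q_end {self.q_end}"
            )
        if self.e_value < 0:
            raise ValueError(f"hit {self.query_id}: negative e-value {self.e_value}")
        if not 0 <= self.percent_identity <= 100:
            raise ValueError(
                f"hit {self.query_id}: percent identity {self.percent_identity} outside [0, 100]"
            )
        if self.align_length < 1:
            raise ValueError(f"hit {self.query_id}: align_length {self.align_length} < 1")

    @property
    def query_overlap(self) -> int:
        """Length of the query span covered by this hit (1-based inclusive)."""
        return self.q_end - self.q_start + 1


@dataclass(frozen=True)
class DomainHit:
    """One row of a domain-table-like (hmmsearch/BLAST fallback) result."""

    query_id: str
    model_id: str
    bit_score: float
    e_value: float
    q_start: int
    q_end: int
    source: str = "hmm"

    def __post_init__(self):
        if self.q_start > self.q_end:
            raise ValueError(
                f"domain hit {self.query_id}/{self.model_id}: q_start {self.q_start} > q_end {self.q_end}"
            )
        if self.e_value < 0:
            raise ValueError(f"domain hit {self.query_id}: negative e-value")
        if self.source not in HIT_SOURCES:
            raise ValueError(f"domain hit {self.query_id}: unknown source {self.source!r}")


@dataclass(frozen=True)
class TaxonomyNode:
    taxon_id: str
    parent_id: str
    rank: str
    name: str

    def __post_init__(self):
        if self.rank not in RANKS:
            raise ValueError(f"taxon {self.taxon_id}: unknown rank {self.rank!r}")


class Taxonomy:
    """A rooted taxonomy tree with lookup by id and by name.

    Exactly one root (parent empty or self-referential); parent links must be
    acyclic and connected.
    """

    def __init__(self, nodes: Iterable[TaxonomyNode]):
        self.nodes: dict[str, TaxonomyNode] = {}
        for node in nodes:
            if node.taxon_id in self.nodes:
                raise ValueError(f"duplicate taxon id {node.taxon_id!r}")
            self.nodes[node.taxon_id] = node
        if not self.nodes:
            raise ValueError("taxonomy is empty")
        roots = [
            n.taxon_id
            for n in self.nodes.values()
            if n.parent_id in ("", n.taxon_id)
        ]
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {len(roots)}: {roots}")
        self.root_id = roots[0]
        for node in self.nodes.values():
            if node.taxon_id != self.root_id and node.parent_id not in self.nodes:
                raise ValueError(
                    f"taxon {node.taxon_id!r} references missing parent {node.parent_id!r}"
                )
        self._lineages: dict[str, tuple[str, ...]] = {}
        for tid in self.nodes:
            self._lineage_of(tid)
        self.by_name: dict[str, str] = {}
        for node in self.nodes.values():
            self.by_name.setdefault(node.name, node.taxon_id)

    def _lineage_of(self, taxon_id: str) -> tuple[str, ...]:
        cached = self._lineages.get(taxon_id)
        if cached is not None:
            return cached
        chain = []
        seen = set()
        tid = taxon_id
        while True:
            if tid in seen:
                raise ValueError(f"cycle in taxonomy involving {tid!r}")
            seen.add(tid)
            chain.append(tid)
            if tid == self.root_id:
                break
            tid = self.nodes[tid].parent_id
        lineage = tuple(reversed(chain))
        self._lineages[taxon_id] = lineage
        return lineage

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def lineage(self, taxon_id: str) -> tuple[str, ...]:
        """Root-to-taxon chain of ids."""
        if taxon_id not in self.nodes:
            raise KeyError(f"unknown taxon {taxon_id!r}")
        return self._lineages[taxon_id]

    def rank_of(self, taxon_id: str) -> str:
        return self.nodes[taxon_id].rank

    def ancestor_at_rank(self, taxon_id: str, rank: str) -> str | None:
        """Ancestor (or self) of ``taxon_id`` at ``rank``, or None if the
        lineage has no node at that rank."""
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}")
        for tid in self.lineage(taxon_id):
            if self.nodes[tid].rank == rank:
                return tid
        return None

    def lca(self, taxon_ids: Sequence[str]) -> str:
        """Lowest common ancestor of a non-empty set of taxa."""
        ids = list(taxon_ids)
        if not ids:
            raise ValueError("lca of empty taxon set")
        lineages = [self.lineage(t) for t in ids]
        lca = self.root_id
        for level in zip(*lineages):
            if len(set(level)) == 1:
                lca = level[0]
            else:
                break
        return lca

    def leaves(self) -> list[str]:
        parents = {n.parent_id for n in self.nodes.values()}
        return sorted(t for t in self.nodes if t not in parents)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into validated records, order preserved.

    Sequence case is normalized to upper.  Duplicate ids, empty sequences and
    non-IUPAC characters are hard errors with positional diagnostics.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush(line_no: int):
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ParseError(path, header_line, f"record {header.split()[0]!r} has empty sequence")
        fields = header.split(None, 1)
        rid = fields[0]
        desc = fields[1] if len(fields) > 1 else ""
        if rid in seen:
            raise ParseError(path, header_line, f"duplicate sequence id {rid!r}")
        seen.add(rid)
        records.append(SequenceRecord(rid, seq, desc))
        header, chunks = None, []

    with open(path) as fh:
        line_no = 0
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no)
                header = line[1:].strip()
                header_line = line_no
                if not header:
                    raise ParseError(path, line_no, "empty FASTA header")
            else:
                if header is None:
                    raise ParseError(path, line_no, "sequence data before first '>' header")
                seq = line.strip().upper()
                bad = set(seq) - IUPAC_DNA
                if bad:
                    raise ParseError(
                        path, line_no, f"non-IUPAC character(s) {sorted(bad)} in sequence"
                    )
                chunks.append(seq)
        flush(line_no + 1)
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 80) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            head = f">{rec.id} {rec.description}".rstrip()
            fh.write(head + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# hit tables
# ---------------------------------------------------------------------------

_ALIGNMENT_HEADER = (
    "# columns: query_id subject_id percent_identity align_length mismatches "
    "gap_opens q_start q_end s_start s_end e_value bit_score subject_taxon "
    "subject_annotation (coordinates 1-based inclusive)"
)
_DOMAIN_HEADER = (
    "# columns: query_id model_id bit_score e_value q_start q_end source "
    "(coordinates 1-based inclusive)"
)


def _num(value: str, conv, path, line_no: int, col: str):
    try:
        return conv(value)
    except ValueError:
        raise ParseError(path, line_no, f"unparsable {col} value {value!r}") from None


def read_hit_table(path, kind: str) -> list[AlignmentHit] | list[DomainHit]:
    """Read a hit table of the given kind ("alignment" or "domain").

    Alignment tables carry the standard 12 BLAST-tabular columns plus two
    optional trailing columns (subject taxon, subject annotation); domain
    tables carry 7 columns.  ``#`` comment lines are skipped.
    """
    if kind not in ("alignment", "domain"):
        raise ValueError(f"unknown hit table kind {kind!r}")
    path = Path(path)
    hits: list = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            try:
                if kind == "alignment":
                    if len(cols) < 12 or len(cols) > 14:
                        raise ParseError(
                            path, line_no, f"expected 12-14 columns, found {len(cols)}"
                        )
                    hit = AlignmentHit(
                        query_id=cols[0],
                        subject_id=cols[1],
                        percent_identity=_num(cols[2], float, path, line_no, "percent_identity"),
                        align_length=_num(cols[3], int, path, line_no, "align_length"),
                        mismatches=_num(cols[4], int, path, line_no, "mismatches"),
                        gap_opens=_num(cols[5], int, path, line_no, "gap_opens"),
                        q_start=_num(cols[6], int, path, line_no, "q_start"),
                        q_end=_num(cols[7], int, path, line_no, "q_end"),
                        s_start=_num(cols[8], int, path, line_no, "s_start"),
                        s_end=_num(cols[9], int, path, line_no, "s_end"),
                        e_value=_num(cols[10], float, path, line_no, "e_value"),
                        bit_score=_num(cols[11], float, path, line_no, "bit_score"),
                        subject_taxon=cols[12] if len(cols) > 12 else "",
                        subject_annotation=cols[13] if len(cols) > 13 else "",
                    )
                else:
                    if len(cols) != 7:
                        raise ParseError(path, line_no, f"expected 7 columns, found {len(cols)}")
                    hit = DomainHit(
                        query_id=cols[0],
                        model_id=cols[1],
                        bit_score=_num(cols[2], float, path, line_no, "bit_score"),
                        e_value=_num(cols[3], float, path, line_no, "e_value"),
                        q_start=_num(cols[4], int, path, line_no, "q_start"),
                        q_end=_num(cols[5], int, path, line_no, "q_end"),
                        source=cols[6],
                    )
            except ValueError as exc:
                if isinstance(exc, ParseError):
                    raise
                raise ParseError(path, line_no, str(exc)) from None
            hits.append(hit)
    return hits


def _fmt(x: float) -> str:
    return repr(float(x))


def write_hit_table(hits: Iterable[AlignmentHit | DomainHit], path, kind: str,
                    header_extra: str = "") -> None:
    if kind not in ("alignment", "domain"):
        raise ValueError(f"unknown hit table kind {kind!r}")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write((_ALIGNMENT_HEADER if kind == "alignment" else _DOMAIN_HEADER) + "\n")
        if header_extra:
            fh.write(f"# {header_extra}\n")
        for h in hits:
            if kind == "alignment":
                fh.write(
                    "\t".join(
                        [
                            h.query_id, h.subject_id, _fmt(h.percent_identity),
                            str(h.align_length), str(h.mismatches), str(h.gap_opens),
                            str(h.q_start), str(h.q_end), str(h.s_start), str(h.s_end),
                            _fmt(h.e_value), _fmt(h.bit_score),
                            h.subject_taxon, h.subject_annotation,
                        ]
                    )
                    + "\n"
                )
            else:
                fh.write(
                    "\t".join(
                        [
                            h.query_id, h.model_id, _fmt(h.bit_score), _fmt(h.e_value),
                            str(h.q_start), str(h.q_end), h.source,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# taxonomy TSV
# ---------------------------------------------------------------------------


def read_taxonomy(path) -> Taxonomy:
    """Read a 4-column taxonomy TSV (taxon_id, parent_id, rank, name)."""
    path = Path(path)
    nodes = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise ParseError(path, line_no, f"expected 4 columns, found {len(cols)}")
            try:
                nodes.append(TaxonomyNode(*cols))
            except ValueError as exc:
                raise ParseError(path, line_no, str(exc)) from None
    return Taxonomy(nodes)


def write_taxonomy(taxonomy: Taxonomy, path, header_extra: str = "") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# columns: taxon_id parent_id rank name\n")
        if header_extra:
            fh.write(f"# {header_extra}\n")
        for tid in sorted(taxonomy.nodes):
            n = taxonomy.nodes[tid]
            fh.write(f"{n.taxon_id}\t{n.parent_id}\t{n.rank}\t{n.name}\n")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """All thresholds and simulation knobs for a pipeline run.

    Threshold defaults are the printed cutoffs of the emulated study design
    (significance e-value 1e-5, bit score 52, ncRNA overlap 50 bp, contig
    length 500 bp, ranked-report read floor 10,000).
    """

    seed: int = 7
    outdir: str = "run"
    simulate: bool = True
    # thresholds
    max_evalue: float = 1e-5
    min_bit: float = 52.0
    min_overlap: int = 50
    min_score: float = 52.0
    min_len: int = 500
    min_reads: int = 10000
    rank: str = "kingdom"
    family_universe: str = "GH"
    # simulation conditions
    n_contigs: int = 2000
    n_reads: int = 100000
    read_len: int = 108
    ncrna_fraction: float = 0.184
    gc_target: float = 0.379
    ncrna_gc: float = 0.51
    expression_mu: float = 3.0
    expression_sigma: float = 1.5
    fn_rate: float = 0.0
    fp_rate: float = 0.0
    score_jitter: float = 0.0
    # rarefaction
    rarefaction_fractions: tuple = (0.02, 0.05, 0.1, 0.2, 0.3, 0.5, 0.7, 1.0)
    rarefaction_reps: int = 5

    def __post_init__(self):
        for name in ("max_evalue", "min_bit", "min_overlap", "min_score",
                     "min_len", "min_reads"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        if self.rank not in RANKS:
            raise ValueError(f"unknown rank {self.rank!r}")
        if not 0 <= self.ncrna_fraction <= 1:
            raise ValueError("ncrna_fraction must lie in [0, 1]")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rarefaction_fractions"] = list(self.rarefaction_fractions)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "rarefaction_fractions" in d:
            d["rarefaction_fractions"] = tuple(d["rarefaction_fractions"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @property
    def config_hash(self) -> str:
        """Short stable digest of the configuration, embedded in output headers.

        The output path is excluded so that identical analyses written to
        different directories share a hash.
        """
        d = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]
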