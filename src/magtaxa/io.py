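"""Readers, writers and validated record types for the pipeline's formats.

Covers multi-record FASTA, the 15/16-column tab-separated alignment-hit
dialect (the BLAST ``-outfmt 6`` layout extended with ``qlen slen`` and an
optional ``stitle``), newick trees consumed in (neighbour-joining, maximum-
likelihood) pairs, and headered TSV tables for genome quality and sample
metadata.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import pandas as pd
from Bio import SeqIO

from .align import IUPAC_BITS

_PathLike = str | Path

# Amino-acid alphabet for protein-flagged records (IUPAC one-letter + X,*).
_AA_CODES = set("ACDEFGHIKLMNPQRSTVWYBZJUOX*")


@dataclass(frozen=True)
class SequenceRecord:
    """A 16S sequence, contig or protein with optional sample metadata.

    Residues are upper-cased on construction; for nucleotide records U is
    mapped to T and only IUPAC codes are accepted.
    """

    id: str
    residues: str
    metadata: Mapping[str, object] = field(default_factory=dict)
    is_protein: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        residues = self.residues.upper()
        if not self.is_protein:
            residues = residues.replace("U", "T")
            bad = set(residues) - set(IUPAC_BITS)
            if bad:
                raise ValueError(
                    f"record {self.id!r}: non-IUPAC nucleotide codes {sorted(bad)}")
        else:
            bad = set(residues) - _AA_CODES
            if bad:
                raise ValueError(
                    f"record {self.id!r}: unexpected amino-acid codes {sorted(bad)}")
        if not residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        object.__setattr__(self, "residues", residues)

    @property
    def length(self) -> int:
        return len(self.residues)


def read_fasta(path: _PathLike, *, is_protein: bool = False) -> list[SequenceRecord]:
    """Read a multi-record FASTA file (wrapped or unwrapped lines).

    The description after the first whitespace of the header, if any, is
    stored under ``metadata["description"]``.  Duplicate ids and empty files
    are errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip()
        meta = {"description": desc} if desc else {}
        records.append(SequenceRecord(rec.id, str(rec.seq), metadata=meta,
                                      is_protein=is_protein))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: _PathLike,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            desc = rec.metadata.get("description", "")
            header = f">{rec.id} {desc}".rstrip()
            fh.write(header + "\n")
            for i in range(0, rec.length, width):
                fh.write(rec.residues[i:i + width] + "\n")


@dataclass(frozen=True, slots=True)
class TabularHit:
    """One row of the 15/16-column tabular alignment dialect.

    Coordinates are 1-based inclusive.  Derived quantities (query coverage,
    aligned bases) are computed from ``length``/``qlen``/``slen``, never from
    coordinate subtraction, so they are strand-robust.
    """

    qseqid: str
    sseqid: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    qlen: int
    slen: int
    stitle: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.pident <= 100.0):
            raise ValueError(f"pident {self.pident} outside [0, 100]")
        if self.length < 1:
            raise ValueError("alignment length must be >= 1")
        if self.qend < self.qstart:
            raise ValueError("qend < qstart")
        if self.qlen < self.qend:
            raise ValueError("qlen < qend")
        if self.evalue < 0:
            raise ValueError("negative evalue")
        if self.qlen <= 0 or self.slen <= 0:
            raise ValueError("qlen and slen must be positive")
        if min(self.mismatch, self.gapopen) < 0:
            raise ValueError("negative mismatch/gapopen count")

    @property
    def qcov(self) -> float:
        """Query coverage = aligned length / query length."""
        return self.length / self.qlen


_HIT_FIELDS = [f.name for f in dataclasses.fields(TabularHit) if f.name != "stitle"]


# The two dialects share the 14 leading columns
#   qseqid sseqid pident length mismatch gapopen qstart qend sstart send
#   evalue bitscore qlen slen
# and the stitle dialect appends a free-text subject title that may itself
# contain tabs (trailing fields are re-joined).
_N_BASE_COLS = 14
_DIALECTS = {"qlen_slen": False, "qlen_slen_stitle": True,
             # aliases used by some callers
             "15col": False, "16col": True}


def read_hits(path: _PathLike, dialect: str = "qlen_slen") -> list[TabularHit]:
    """Parse a tab-separated, headerless hit table.

    Malformed rows (wrong column count, non-numeric numeric fields) raise
    with the offending line number.  Row order is preserved.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    want_stitle = _DIALECTS[dialect]
    hits: list[TabularHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if (not want_stitle and len(parts) != _N_BASE_COLS) or \
                    (want_stitle and len(parts) < _N_BASE_COLS + 1):
                raise ValueError(
                    f"{path} line {lineno}: expected "
                    f"{_N_BASE_COLS + want_stitle} columns, got {len(parts)}")
            try:
                hits.append(_parse_hit_row(parts, want_stitle))
            except ValueError as exc:
                raise ValueError(f"{path} line {lineno}: {exc}") from exc
    return hits


def _parse_hit_row(parts: list[str], want_stitle: bool) -> TabularHit:
    qseqid, sseqid = parts[0], parts[1]
    try:
        pident = float(parts[2])
    except ValueError:
        raise ValueError(f"non-numeric pident {parts[2]!r}")
    try:
        ints = [int(p) for p in parts[3:10]]
        evalue = float(parts[10])
        bitscore = float(parts[11])
        qlen, slen = int(parts[12]), int(parts[13])
    except ValueError as exc:
        raise ValueError(f"non-numeric field: {exc}")
    stitle = "\t".join(parts[_N_BASE_COLS:]) if want_stitle else None
    return TabularHit(qseqid, sseqid, pident, *ints, evalue, bitscore,
                      qlen, slen, stitle=stitle)


def write_hits(hits: Iterable[TabularHit], path: _PathLike) -> None:
    with open(path, "w") as fh:
        for h in hits:
            row = [h.qseqid, h.sseqid, f"{h.pident:g}", h.length, h.mismatch,
                   h.gapopen, h.qstart, h.qend, h.sstart, h.send,
                   f"{h.evalue:g}", f"{h.bitscore:g}", h.qlen, h.slen]
            if h.stitle is not None:
                row.append(h.stitle)
            fh.write("\t".join(str(x) for x in row) + "\n")


class CladeTree:
    """A rooted leaf-labelled tree supporting descendant-leaf-set queries.

    Trees are consumed in pairs tagged ``"NJ"`` and ``"ML"`` for monophyly
    checks.  The tree is treated as rooted as written; no re-rooting is done.
    """

    def __init__(self, tree: dendropy.Tree, method_tag: str = "NJ") -> None:
        tree.suppress_unifurcations()
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        dupes = {x for x in labels if labels.count(x) > 1}
        if dupes:
            raise ValueError(f"duplicate leaf labels: {sorted(dupes)}")
        self.tree = tree
        self.method_tag = method_tag
        self.leaf_set: frozenset[str] = frozenset(labels)
        self._leafsets: dict[int, frozenset[str]] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                self._leafsets[id(node)] = frozenset([node.taxon.label])
            else:
                self._leafsets[id(node)] = frozenset().union(
                    *(self._leafsets[id(c)] for c in node.child_nodes()))

    def node_leafset(self, node: dendropy.Node) -> frozenset[str]:
        return self._leafsets[id(node)]

    def clade_sets(self, min_size: int = 1) -> set[frozenset[str]]:
        """Descendant leaf sets of all internal nodes (the tree's clades)."""
        return {self._leafsets[id(n)] for n in self.tree.preorder_node_iter()
                if not n.is_leaf() and len(self._leafsets[id(n)]) >= min_size}

    def is_clade(self, leaves: Iterable[str]) -> bool:
        return frozenset(leaves) in self.clade_sets()

    def __len__(self) -> int:
        return len(self.leaf_set)


def read_newick(path: _PathLike, method_tag: str = "NJ") -> CladeTree:
    with open(path) as fh:
        return read_newick_string(fh.read(), method_tag)


def read_newick_string(newick: str, method_tag: str = "NJ") -> CladeTree:
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True,
                                 suppress_internal_node_taxa=True)
    except Exception as exc:
        raise ValueError(f"malformed newick: {exc}") from exc
    return CladeTree(tree, method_tag)


@dataclass(frozen=True)
class QualityRecord:
    """Completeness/contamination estimates and size for one genome or MAG."""

    genome: str
    completeness: float   # percent, (0, 100]
    contamination: float  # percent, >= 0
    assembly_size: int = 0
    origin: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.completeness <= 100.0):
            raise ValueError(f"{self.genome}: completeness outside (0, 100]")
        if self.contamination < 0:
            raise ValueError(f"{self.genome}: negative contamination")


def read_quality_table(path: _PathLike) -> list[QualityRecord]:
    """Read a headered TSV with columns genome, completeness, contamination
    and optionally assembly_size, origin."""
    df = pd.read_csv(path, sep="\t")
    required = {"genome", "completeness", "contamination"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(QualityRecord(
            genome=str(row.genome),
            completeness=float(row.completeness),
            contamination=float(row.contamination),
            assembly_size=int(getattr(row, "assembly_size", 0) or 0),
            origin=str(getattr(row, "origin", "") or "")))
    return out


def write_quality_table(records: Iterable[QualityRecord], path: _PathLike) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
        path, sep="\t", index=False)


def read_metadata_table(path: _PathLike) -> pd.DataFrame:
    """Sample metadata: sample_id, environment, latitude, longitude, total_reads."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing 'sample_id' column")
    return df


def read_annotation_table(path: _PathLike) -> pd.DataFrame:
    """Per-genome gene annotations: genome, gene and any of ko / cazy_family /
    symbol columns."""
    df = pd.read_csv(path, sep="\t")
    required = {"genome", "gene"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
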