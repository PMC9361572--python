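"""Readers and writers for the external formats the pipeline touches.

Every downstream module consumes only the domain types built here:
FASTA coding sequences, two-column gene-pair lists, five-column gene
locus tables (GFF-style 1-based inclusive coordinates on disk, 0-based
half-open in memory), rooted newick trees, and the tab-separated results
tables written by each pipeline stage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_STRANDS = {"+", "-"}


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over the alphabet {A, C, G, T, N, -}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence for {self.id!r} is empty")


@dataclass
class GeneLocus:
    """Gene coordinates, 0-based half-open, plus a gene-order rank.

    ``rank`` is the index of the gene along its chromosome when all loci
    are sorted by start coordinate; it is assigned by :func:`assign_ranks`
    (strand is ignored for ordering).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    rank: int | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"{self.gene_id}: negative start {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"{self.gene_id}: start {self.start} not below end {self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"{self.gene_id}: unknown strand {self.strand!r}")


@dataclass
class GenePairList:
    """Unordered, deduplicated gene pairs tagged with a homology relation."""

    pairs: list[tuple[str, str, str]] = field(default_factory=list)

    RELATIONS = frozenset({"ortholog", "paralog", "collinear", "homolog"})

    def gene_ids(self) -> set[str]:
        return {g for a, b, _ in self.pairs for g in (a, b)}

    def partners(self) -> dict[str, list[str]]:
        """Map each gene to its sorted list of partners."""
        adj: dict[str, set[str]] = {}
        for a, b, _ in self.pairs:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        return {g: sorted(p) for g, p in adj.items()}

    def __len__(self) -> int:
        return len(self.pairs)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased and RNA ``U`` is mapped to ``T``.
    Duplicate ids or an empty file raise ``ValueError``.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        records.append(SequenceRecord(rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def assign_ranks(loci: list[GeneLocus]) -> list[GeneLocus]:
    """Assign consecutive 0-based gene-order ranks per chromosome, in place.

    Ordering is by start coordinate within each chromosome; strand is
    ignored.  Returns the same list for convenience.
    """
    by_chrom: dict[str, list[GeneLocus]] = {}
    for loc in loci:
        by_chrom.setdefault(loc.chrom, []).append(loc)
    for chrom_loci in by_chrom.values():
        chrom_loci.sort(key=lambda l: (l.start, l.end, l.gene_id))
        for rank, loc in enumerate(chrom_loci):
            loc.rank = rank
    return loci


def read_locus_table(path: str | Path) -> list[GeneLocus]:
    """Read a five-column gene locus table.

    Columns: gene_id, chrom, start, end, strand (tab-separated, ``#``
    comments allowed).  On-disk coordinates are 1-based inclusive and are
    converted to 0-based half-open; gene-order ranks are assigned per
    chromosome.
    """
    loci: list[GeneLocus] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(
                    f"{path}:{lineno}: expected 5 tab-separated columns, got {len(parts)}"
                )
            gene_id, chrom, start_s, end_s, strand = parts
            if gene_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            start, end = int(start_s), int(end_s)
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start {start} >= end {end} for {gene_id}"
                )
            # 1-based inclusive on disk -> 0-based half-open in memory
            loci.append(GeneLocus(gene_id, chrom, start - 1, end, strand))
    return assign_ranks(loci)


def write_locus_table(loci: Sequence[GeneLocus], path: str | Path) -> None:
    """Write loci back to the on-disk 1-based inclusive convention."""
    with open(path, "w") as fh:
        fh.write("#gene_id\tchrom\tstart\tend\tstrand\n")
        for loc in loci:
            fh.write(
                f"{loc.gene_id}\t{loc.chrom}\t{loc.start + 1}\t{loc.end}\t{loc.strand}\n"
            )


def read_pair_list(path: str | Path, relation: str = "homolog") -> GenePairList:
    """Read a two-column TSV of gene ids into a canonical pair list.

    Pairs are canonicalized with the lexicographically smaller id first;
    duplicates (in either orientation) are collapsed with a warning.
    Self-pairs raise ``ValueError``.
    """
    if relation not in GenePairList.RELATIONS:
        raise ValueError(f"unknown relation {relation!r}")
    pairs: list[tuple[str, str, str]] = []
    seen: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            a, b = parts[0], parts[1]
            if a == b:
                raise ValueError(f"{path}:{lineno}: self-pair {a!r}")
            key = (a, b) if a < b else (b, a)
            if key in seen:
                logger.warning("%s:%d: duplicate pair %s collapsed", path, lineno, key)
                continue
            seen.add(key)
            pairs.append((*key, relation))
    return GenePairList(pairs)


def make_pair_list(
    pairs: Iterable[tuple[str, str]], relation: str = "homolog"
) -> GenePairList:
    """Build a canonical :class:`GenePairList` from in-memory id pairs."""
    if relation not in GenePairList.RELATIONS:
        raise ValueError(f"unknown relation {relation!r}")
    out: list[tuple[str, str, str]] = []
    seen: set[tuple[str, str]] = set()
    for a, b in pairs:
        if a == b:
            raise ValueError(f"self-pair {a!r}")
        key = (a, b) if a < b else (b, a)
        if key in seen:
            continue
        seen.add(key)
        out.append((*key, relation))
    return GenePairList(out)


def read_newick(path_or_string: str | Path) -> dendropy.Tree:
    """Parse a rooted newick tree from a file path or a literal string.

    Leaf names must be unique.  Polytomies are accepted but logged;
    callers that need binary trees check with :func:`is_binary`.
    """
    text = None
    p = Path(str(path_or_string))
    try:
        if p.exists() and p.is_file():
            text = p.read_text()
    except OSError:
        text = None
    if text is None:
        text = str(path_or_string)
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"newick parse error: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate leaf names: {dupes}")
    if not is_binary(tree):
        logger.warning("tree is not strictly binary (contains polytomies)")
    return tree


def is_binary(tree: dendropy.Tree) -> bool:
    """True iff every internal node of the rooted tree has exactly two children."""
    for node in tree.preorder_node_iter():
        if node.child_nodes() and len(node.child_nodes()) != 2:
            return False
    return True


def _format_cell(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        if math.isnan(value):
            return "NA"
        return f"{value:.4f}"
    return str(value)


def _record_items(record) -> list[tuple[str, object]]:
    if is_dataclass(record):
        return [(f.name, getattr(record, f.name)) for f in fields(record)]
    if isinstance(record, Mapping):
        return list(record.items())
    raise TypeError(f"unsupported record type {type(record).__name__}")


def write_results_tsv(
    records: Sequence, path: str | Path, columns: Sequence[str] | None = None
) -> None:
    """Write homogeneous result records as a TSV.

    Floats are printed with 4 decimals, NaN/None as ``NA``, booleans as
    0/1.  An empty record list produces a header-only file (``columns``
    supplies the header when it cannot be inferred from records).
    """
    with open(path, "w") as fh:
        if not records:
            fh.write(("\t".join(columns) if columns else "") + "\n")
            return
        keys = list(columns) if columns else [k for k, _ in _record_items(records[0])]
        fh.write("\t".join(keys) + "\n")
        for rec in records:
            items = _record_items(rec)
            if [k for k, _ in items] != keys:
                raise ValueError("records do not share a schema")
            fh.write("\t".join(_format_cell(v) for _, v in items) + "\n")
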