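"""Readers/writers and the shared data model for all external inputs.

Coordinates are 1-based inclusive internally (GFF3 convention).  BED input is
converted at the boundary.  Gene boundaries are taken exactly as annotated;
no UTR inference is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError, ValidationError

VALID_STRANDS = frozenset({"+", "-"})

DNDS_COLUMNS = (
    "pair_id",
    "species",
    "gene1_dS",
    "gene1_dN",
    "gene2_dS",
    "gene2_dN",
    "overlap_status",
)


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene: span, strand and exon structure on one sequence.

    ``start``/``end`` are 1-based inclusive.  ``exons`` is a tuple of
    (start, end) intervals, sorted ascending, non-overlapping, and contained
    in the gene span.  Intron count is derived: ``len(exons) - 1``.
    """

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]
    species: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exons:
            raise ValidationError(f"gene {self.gene_id}: no exons annotated")
        prev_end = None
        for (s, e) in self.exons:
            if s > e:
                raise ValidationError(
                    f"gene {self.gene_id}: exon ({s},{e}) has start > end"
                )
            if s < self.start or e > self.end:
                raise ValidationError(
                    f"gene {self.gene_id}: exon ({s},{e}) outside gene span "
                    f"[{self.start},{self.end}]"
                )
            if prev_end is not None and s <= prev_end:
                raise ValidationError(
                    f"gene {self.gene_id}: exons overlap or are unsorted at ({s},{e})"
                )
            prev_end = e

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons, exclusive of exon bases."""
        out = []
        for (a, b) in zip(self.exons, self.exons[1:]):
            if b[0] - a[1] > 1:
                out.append((a[1] + 1, b[0] - 1))
        return tuple(out)


@dataclass(frozen=True)
class OrthologMap:
    """Strictly one-to-one ortholog pairs between two species."""

    species_a: str
    species_b: str
    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        seen_a: set[str] = set()
        seen_b: set[str] = set()
        dup_a, dup_b = [], []
        for a, b in self.pairs:
            if a in seen_a:
                dup_a.append(a)
            if b in seen_b:
                dup_b.append(b)
            seen_a.add(a)
            seen_b.add(b)
        if dup_a or dup_b:
            raise ValidationError(
                "ortholog map is not one-to-one; duplicated ids: "
                + ", ".join(sorted(set(dup_a + dup_b)))
            )

    @property
    def a_to_b(self) -> dict[str, str]:
        return {a: b for a, b in self.pairs}

    @property
    def b_to_a(self) -> dict[str, str]:
        return {b: a for a, b in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)


class Phylogeny:
    """A rooted tree with unique leaf labels and non-negative branch lengths.

    Thin wrapper over a :class:`dendropy.Tree`; polytomies are resolved into
    binary nodes with zero-length branches at load time.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValidationError("duplicate leaf labels in tree")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise ValidationError(
                    "branch without length; pass default_branch_length to accept"
                )
            if edge.length < 0:
                raise ValidationError(f"negative branch length {edge.length}")
        self.leaf_labels: list[str] = labels

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


# ---------------------------------------------------------------------------
# gene tables
# ---------------------------------------------------------------------------


def read_gene_table(path: str | Path, format: str, species: str = "") -> list[GeneRecord]:
    """Read gene records from ``gff3``, ``bed`` or ``tsv``.

    BED (0-based half-open) is converted to 1-based inclusive; BED genes get a
    single synthetic exon covering the span.  Duplicate gene ids and exons
    outside the parent span raise :class:`ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "gff3":
        records = _read_gff3(path, species)
    elif format == "bed":
        records = _read_bed(path, species)
    elif format == "tsv":
        records = _read_gene_tsv(path, species)
    else:
        raise ValueError(f"unknown gene table format: {format!r}")
    seen: set[str] = set()
    for r in records:
        if r.gene_id in seen:
            raise ValidationError(f"duplicate gene_id {r.gene_id} in {path}")
        seen.add(r.gene_id)
    return records


def _read_gff3(path: Path, species: str) -> list[GeneRecord]:
    genes: dict[str, dict] = {}
    order: list[str] = []
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(
                    f"expected 9 tab-separated columns, got {len(cols)}",
                    path=str(path), line=lineno,
                )
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = cols
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(
                    f"non-integer coordinates {start_s!r}/{end_s!r}",
                    path=str(path), line=lineno,
                ) from None
            attr = _parse_gff3_attributes(attrs, path, lineno)
            if ftype == "gene":
                gid = attr.get("ID")
                if gid is None:
                    raise ParseError("gene feature without ID", str(path), lineno)
                if gid in genes:
                    raise ValidationError(f"duplicate gene_id {gid} in {path}")
                genes[gid] = dict(seq_id=seqid, start=start, end=end, strand=strand)
                order.append(gid)
            elif ftype == "exon":
                parent = attr.get("Parent")
                if parent is None:
                    raise ParseError("exon feature without Parent", str(path), lineno)
                exons.setdefault(parent, []).append((start, end))
    out = []
    for gid in order:
        g = genes[gid]
        ex = tuple(sorted(exons.get(gid, [])))
        if not ex:
            raise ValidationError(f"gene {gid}: no exon children in {path}")
        out.append(GeneRecord(gene_id=gid, species=species, exons=ex, **g))
    return out


def _parse_gff3_attributes(text: str, path: Path, lineno: int) -> dict[str, str]:
    attrs = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise ParseError(f"malformed attribute {chunk!r}", str(path), lineno)
        k, v = chunk.split("=", 1)
        attrs[k] = v
    return attrs


def _read_bed(path: Path, species: str) -> list[GeneRecord]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split()
            if len(cols) < 6:
                raise ParseError(
                    f"BED6 requires 6 fields, got {len(cols)}", str(path), lineno
                )
            chrom, start0, end0, name, _score, strand = cols[:6]
            try:
                start = int(start0) + 1
                end = int(end0)
            except ValueError:
                raise ParseError("non-integer BED coordinates", str(path), lineno) from None
            out.append(
                GeneRecord(
                    gene_id=name, seq_id=chrom, start=start, end=end,
                    strand=strand, exons=((start, end),), species=species,
                )
            )
    return out


def _read_gene_tsv(path: Path, species: str) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["gene_id", "seq_id", "start", "end", "strand", "exon_starts", "exon_ends"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"missing columns: {missing}", path=str(path))
    out = []
    for i, row in enumerate(df.itertuples(index=False), 2):
        try:
            starts = [int(x) for x in str(row.exon_starts).split(",") if x != ""]
            ends = [int(x) for x in str(row.exon_ends).split(",") if x != ""]
            start, end = int(row.start), int(row.end)
        except ValueError:
            raise ParseError("non-integer coordinate", str(path), i) from None
        if len(starts) != len(ends):
            raise ParseError("exon_starts/exon_ends length mismatch", str(path), i)
        out.append(
            GeneRecord(
                gene_id=row.gene_id, seq_id=row.seq_id, start=start, end=end,
                strand=row.strand, exons=tuple(zip(starts, ends)), species=species,
            )
        )
    return out


def write_gene_table(records: Iterable[GeneRecord], path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    records = list(records)
    if format == "tsv":
        rows = [
            dict(
                gene_id=r.gene_id, seq_id=r.seq_id, start=r.start, end=r.end,
                strand=r.strand,
                exon_starts=",".join(str(s) for s, _ in r.exons),
                exon_ends=",".join(str(e) for _, e in r.exons),
            )
            for r in records
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    elif format == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for r in records:
                fh.write(
                    f"{r.seq_id}\tgenoverlap\tgene\t{r.start}\t{r.end}\t.\t"
                    f"{r.strand}\t.\tID={r.gene_id}\n"
                )
                for j, (s, e) in enumerate(r.exons, 1):
                    fh.write(
                        f"{r.seq_id}\tgenoverlap\texon\t{s}\t{e}\t.\t{r.strand}\t.\t"
                        f"ID={r.gene_id}.exon{j};Parent={r.gene_id}\n"
                    )
    else:
        raise ValueError(f"unsupported output format: {format!r}")


# ---------------------------------------------------------------------------
# ortholog maps
# ---------------------------------------------------------------------------


def read_ortholog_map(path: str | Path, species_a: str, species_b: str) -> OrthologMap:
    """Read a two-column TSV of one-to-one ortholog gene ids."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    if df.empty:
        raise ValidationError(f"empty ortholog map: {path}")
    if df.shape[1] < 2:
        raise ParseError("ortholog map needs two columns", path=str(path))
    pairs = frozenset(zip(df.iloc[:, 0], df.iloc[:, 1]))
    return OrthologMap(species_a=species_a, species_b=species_b, pairs=pairs)


def write_ortholog_map(omap: OrthologMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(omap.pairs):
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# trees, sequences, expression, dN/dS
# ---------------------------------------------------------------------------


def read_newick(path: str | Path, default_branch_length: float | None = None) -> Phylogeny:
    """Read a rooted newick tree; polytomies become binary via 0-length edges.

    Missing branch lengths are an error unless ``default_branch_length`` is
    given, in which case every missing length is replaced by it.
    """
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    return _normalize_tree(tree, default_branch_length)


def newick_from_string(text: str, default_branch_length: float | None = None) -> Phylogeny:
    tree = dendropy.Tree.get(data=text, schema="newick")
    return _normalize_tree(tree, default_branch_length)


def _normalize_tree(tree: dendropy.Tree, default_branch_length: float | None) -> Phylogeny:
    for edge in tree.preorder_edge_iter():
        if edge.length is None and edge.head_node is not tree.seed_node:
            if default_branch_length is None:
                raise ValidationError(
                    "branch without length; pass default_branch_length to accept"
                )
            edge.length = default_branch_length
    tree.resolve_polytomies(limit=2)
    for edge in tree.preorder_edge_iter():
        if edge.length is None:  # root edge or edges created by resolution
            edge.length = 0.0
    return Phylogeny(tree)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_expression(path: str | Path) -> pd.DataFrame:
    """Gene-by-condition expression table; first column is gene_id."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    if df.shape[1] < 1:
        raise ValidationError("expression table has no condition columns")
    return df.astype(float)


def read_dnds_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_dnds_table(df)


def validate_dnds_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in DNDS_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"dN/dS table missing columns: {missing}")
    rates = df[["gene1_dS", "gene1_dN", "gene2_dS", "gene2_dN"]].astype(float)
    if (rates.values < 0).any():
        raise ValidationError("negative substitution rate in dN/dS table")
    status = set(df["overlap_status"].unique())
    if not status <= {0, 1}:
        raise ValidationError(f"overlap_status must be binary, got {status}")
    return df


def write_dnds_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_dnds_table(df).to_csv(path, sep="\t", index=False)
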