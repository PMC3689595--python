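"""Detection and classification of positionally overlapping gene pairs.

Two genes overlap when their annotated spans share at least one base on the
same sequence; strand is ignored for detection and classified afterwards as
orientation.  Connected components of the overlap graph with exactly two
members become classified pairs; components with three or more members are
reported as clusters and contribute no pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from .annotation_io import GeneRecord
from .errors import ValidationError


@dataclass(frozen=True)
class OverlapPair:
    """A classified overlapping gene pair.

    ``category`` is ``"EH"`` (nested: one span contained in the other) or
    ``"PO"`` (partial overlap).  For EH pairs ``host``/``embedded`` name the
    container and the contained gene.  ``identical_span`` flags the degenerate
    case of byte-identical intervals (classified EH with the lexicographically
    smaller gene_id as host).
    """

    gene_a: str
    gene_b: str
    category: str
    orientation: str
    overlap_len: int
    host: str | None = None
    embedded: str | None = None
    identical_span: bool = False
    embedded_in_intron: bool | None = None

    def __post_init__(self) -> None:
        if self.gene_a >= self.gene_b:
            raise ValidationError("pair members must be ordered gene_a < gene_b")
        if self.category not in ("EH", "PO"):
            raise ValidationError(f"bad category {self.category!r}")
        if self.overlap_len < 1:
            raise ValidationError("overlap_len must be >= 1")
        if self.category == "EH" and (self.host is None or self.host == self.embedded):
            raise ValidationError("EH pair requires distinct host and embedded")

    @property
    def members(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass(frozen=True)
class OverlapCluster:
    """Connected component of the overlap graph with >= 3 members."""

    seq_id: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.members) < 3:
            raise ValidationError("cluster requires >= 3 members")


def spans_overlap(a: GeneRecord, b: GeneRecord) -> bool:
    return a.seq_id == b.seq_id and a.start <= b.end and b.start <= a.end


def overlap_length(a: GeneRecord, b: GeneRecord) -> int:
    return min(a.end, b.end) - max(a.start, b.start) + 1

def classify_orientation(a: GeneRecord, b: GeneRecord) -> str:
    return "same" if a.strand == b.strand else "opposite"


def classify_pair(a: GeneRecord, b: GeneRecord) -> OverlapPair:
    """Classify two overlapping genes as an EH or PO pair.

    Containment is inclusive: equal boundary coordinates still count as
    nested.  Identical intervals are classified EH with the lexicographically
    smaller gene_id as host, and flagged.
    """
    if not spans_overlap(a, b):
        raise ValidationError(f"{a.gene_id} and {b.gene_id} do not overlap")
    if a.gene_id > b.gene_id:
        a, b = b, a
    a_in_b = b.start <= a.start and a.end <= b.end
    b_in_a = a.start <= b.start and b.end <= a.end
    common = dict(
        gene_a=a.gene_id,
        gene_b=b.gene_id,
        orientation=classify_orientation(a, b),
        overlap_len=overlap_length(a, b),
    )
    if a_in_b and b_in_a:  # identical intervals
        return OverlapPair(
            category="EH", host=a.gene_id, embedded=b.gene_id,
            identical_span=True, **common,
        )
    if b_in_a:
        return OverlapPair(category="EH", host=a.gene_id, embedded=b.gene_id, **common)
    if a_in_b:
        return OverlapPair(category="EH", host=b.gene_id, embedded=a.gene_id, **common)
    return OverlapPair(category="PO", **common)


def overlap_edges(genes: Sequence[GeneRecord]) -> list[tuple[str, str]]:
    """All unordered overlapping gene-id pairs, by per-seqid sweep."""
    edges: list[tuple[str, str]] = []
    by_seq: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_seq.setdefault(g.seq_id, []).append(g)
    for seq_genes in by_seq.values():
        seq_genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
        active: list[GeneRecord] = []
        for g in seq_genes:
            active = [h for h in active if h.end >= g.start]
            for h in active:
                edges.append(tuple(sorted((h.gene_id, g.gene_id))))  # type: ignore[arg-type]
            active.append(g)
    return edges


def find_overlaps(
    genes: Sequence[GeneRecord],
) -> tuple[list[OverlapPair], list[OverlapCluster]]:
    """Detect all overlapping pairs and clusters in one gene set.

    Returns classified two-member components as pairs (sorted by position)
    and >= 3-member components as clusters; cluster members contribute no
    pairs.  Raises on duplicate gene ids.
    """
    by_id: dict[str, GeneRecord] = {}
    for g in genes:
        if g.gene_id in by_id:
            raise ValidationError(f"duplicate gene_id {g.gene_id}")
        by_id[g.gene_id] = g

    edges = overlap_edges(genes)

    parent: dict[str, str] = {}

    def find(x: str) -> str:
        root = x
        while parent.get(root, root) != root:
            root = parent[root]
        while parent.get(x, x) != x:
            parent[x], x = root, parent[x]
        return root

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    for u, v in edges:
        union(u, v)

    components: dict[str, set[str]] = {}
    for u, v in edges:
        components.setdefault(find(u), set()).update((u, v))

    pairs: list[OverlapPair] = []
    clusters: list[OverlapCluster] = []
    for members in components.values():
        if len(members) == 2:
            a, b = sorted(members)
            pairs.append(classify_pair(by_id[a], by_id[b]))
        else:
            seq_id = by_id[next(iter(members))].seq_id
            clusters.append(OverlapCluster(seq_id=seq_id, members=tuple(sorted(members))))
    pairs.sort(key=lambda p: (by_id[p.gene_a].seq_id, by_id[p.gene_a].start, p.gene_a))
    clusters.sort(key=lambda c: (c.seq_id, c.members))
    return pairs, clusters


def embedded_in_intron(pair: OverlapPair, genes_by_id: dict[str, GeneRecord]) -> bool:
    """True iff the embedded gene lies entirely inside one host intron.

    A single-exon host has no introns and returns False (never an error).
    """
    if pair.category != "EH":
        raise ValidationError("embedded_in_intron applies to EH pairs only")
    host = genes_by_id[pair.host]
    emb = genes_by_id[pair.embedded]
    return any(s <= emb.start and emb.end <= e for s, e in host.introns)


def annotate_intron_embedding(
    pairs: Iterable[OverlapPair], genes_by_id: dict[str, GeneRecord]
) -> list[OverlapPair]:
    """Fill ``embedded_in_intron`` for every EH pair; PO pairs pass through."""
    out = []
    for p in pairs:
        if p.category == "EH":
            out.append(replace(p, embedded_in_intron=embedded_in_intron(p, genes_by_id)))
        else:
            out.append(p)
    return out


def pairs_to_frame(pairs: Iterable[OverlapPair], species: str = "") -> pd.DataFrame:
    rows = [
        dict(
            species=species, gene_a=p.gene_a, gene_b=p.gene_b, category=p.category,
            host=p.host or "", embedded=p.embedded or "", orientation=p.orientation,
            overlap_len=p.overlap_len, identical_span=p.identical_span,
            embedded_in_intron="" if p.embedded_in_intron is None else p.embedded_in_intron,
        )
        for p in pairs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "species", "gene_a", "gene_b", "category", "host", "embedded",
            "orientation", "overlap_len", "identical_span", "embedded_in_intron",
        ],
    )


def clusters_to_frame(clusters: Iterable[OverlapCluster]) -> pd.DataFrame:
    rows = [
        dict(seq_id=c.seq_id, member_count=len(c.members), members=",".join(c.members))
        for c in clusters
    ]
    return pd.DataFrame(rows, columns=["seq_id", "member_count", "members"])
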