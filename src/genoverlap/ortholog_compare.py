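"""Cross-species accounting of overlapping gene pairs via one-to-one orthologs.

Combines per-species overlap detection with ortholog maps to classify pair
age (young/old), profile localization patterns across genomes, build
intron/intronless contingency tables, binary overlap/orthology matrices, and
expression correlation by orientation.

"Overlapping in the other species" always means the two mapped orthologs
overlap *each other*, not merely that each participates in some overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_io import GeneRecord, OrthologMap
from .errors import ValidationError
from .overlap_core import (
    OverlapCluster,
    OverlapPair,
    classify_pair,
    find_overlaps,
    spans_overlap,
)
from .stats_kit import ContingencyTable2x2, TestResult, spearman

logger = logging.getLogger(__name__)

CODES = ("EH", "PO", "NOV", "ABS")

#: canonical order of the eight two-species localization categories
PATTERN_CATEGORIES = (
    ("EH", "EH"), ("PO", "PO"), ("EH", "PO"), ("PO", "EH"),
    ("EH", "NOV"), ("PO", "NOV"), ("NOV", "EH"), ("NOV", "PO"),
)


@dataclass
class SpeciesOverlap:
    """Overlap-detection results for one species, with pairwise lookup."""

    species: str
    genes: dict[str, GeneRecord]
    pairs: list[OverlapPair]
    clusters: list[OverlapCluster]
    cluster_members: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        self.cluster_members = frozenset(
            g for c in self.clusters for g in c.members
        )

    @classmethod
    def detect(cls, genes: Sequence[GeneRecord], species: str = "") -> "SpeciesOverlap":
        pairs, clusters = find_overlaps(genes)
        return cls(
            species=species or (genes[0].species if genes else ""),
            genes={g.gene_id: g for g in genes},
            pairs=pairs,
            clusters=clusters,
        )

    def relation(self, id1: str, id2: str) -> str:
        """Pairwise relation of two genes: EH, PO or NOV.

        Computed directly from coordinates, so genes inside a >=3 cluster are
        still coded by their pairwise relation (cluster membership is logged).
        """
        g1, g2 = self.genes.get(id1), self.genes.get(id2)
        if g1 is None or g2 is None:
            raise ValidationError(f"unknown gene id in species {self.species}")
        if not spans_overlap(g1, g2):
            return "NOV"
        if id1 in self.cluster_members or id2 in self.cluster_members:
            logger.info(
                "pair (%s, %s) in %s lies inside an overlap cluster; "
                "coding by pairwise relation", id1, id2, self.species,
            )
        return classify_pair(g1, g2).category


@dataclass(frozen=True)
class PairAgeClass:
    pair_id: str
    age_class: str  # young_young | old_old | young_old

    def __post_init__(self) -> None:
        if self.age_class not in ("young_young", "old_old", "young_old"):
            raise ValidationError(f"bad age class {self.age_class!r}")


def classify_pair_age(members: tuple[str, str], omap: OrthologMap,
                      pair_id: str = "") -> PairAgeClass:
    """young/old classification from presence of one-to-one orthologs."""
    mapped = omap.a_to_b
    n = sum(1 for g in members if g in mapped)
    cls = {2: "old_old", 0: "young_young", 1: "young_old"}[n]
    return PairAgeClass(pair_id=pair_id or "-".join(members), age_class=cls)


@dataclass(frozen=True)
class PairLocalizationProfile:
    """Per-species localization code for one ortholog pair."""

    pair_id: str
    reference: str
    codes: tuple[tuple[str, str], ...]  # (species, code)

    def __post_init__(self) -> None:
        code_map = dict(self.codes)
        ref_code = code_map.get(self.reference)
        if ref_code not in ("EH", "PO"):
            raise ValidationError(
                "reference-species code must be EH or PO (the pair overlaps there)"
            )
        for _, c in self.codes:
            if c not in CODES:
                raise ValidationError(f"bad localization code {c!r}")

    def code_for(self, species: str) -> str:
        return dict(self.codes)[species]


def localization_profile(
    pair: OverlapPair,
    reference: str,
    comparisons: Mapping[str, tuple[SpeciesOverlap, OrthologMap]],
) -> PairLocalizationProfile:
    """Localization code of one reference overlapping pair in each species.

    For each comparison species: ABS if either one-to-one ortholog is
    missing, else the pairwise relation of the two orthologs there.
    """
    codes = [(reference, pair.category)]
    for species, (overlap, omap) in comparisons.items():
        if omap.species_a != reference or omap.species_b != species:
            raise ValidationError(
                f"ortholog map {omap.species_a}->{omap.species_b} does not chain "
                f"{reference}->{species}"
            )
        mapped = omap.a_to_b
        o1, o2 = mapped.get(pair.gene_a), mapped.get(pair.gene_b)
        if o1 is None or o2 is None:
            codes.append((species, "ABS"))
        else:
            codes.append((species, overlap.relation(o1, o2)))
    return PairLocalizationProfile(
        pair_id=f"{pair.gene_a}-{pair.gene_b}", reference=reference,
        codes=tuple(codes),
    )


@dataclass(frozen=True)
class ProfiledPair:
    """One two-species localization profile with both species' gene ids."""

    pair_id: str
    genes_a: tuple[str, str]
    genes_b: tuple[str, str]
    code_a: str
    code_b: str


def two_species_localization(
    overlap_a: SpeciesOverlap,
    overlap_b: SpeciesOverlap,
    omap: OrthologMap,
) -> list[ProfiledPair]:
    """Profile every one-to-one ortholog pair overlapping in at least one
    of the two species; each underlying pair appears exactly once."""
    a2b = omap.a_to_b
    b2a = omap.b_to_a
    seen: dict[tuple[str, str], ProfiledPair] = {}
    for p in overlap_a.pairs:
        o1, o2 = a2b.get(p.gene_a), a2b.get(p.gene_b)
        if o1 is None or o2 is None:
            continue
        key = tuple(sorted((p.gene_a, p.gene_b)))
        seen[key] = ProfiledPair(
            pair_id=f"{p.gene_a}-{p.gene_b}",
            genes_a=(p.gene_a, p.gene_b),
            genes_b=(o1, o2),
            code_a=p.category,
            code_b=overlap_b.relation(o1, o2),
        )
    for p in overlap_b.pairs:
        r1, r2 = b2a.get(p.gene_a), b2a.get(p.gene_b)
        if r1 is None or r2 is None:
            continue
        key = tuple(sorted((r1, r2)))
        if key in seen:
            continue
        seen[key] = ProfiledPair(
            pair_id=f"{r1}-{r2}",
            genes_a=(r1, r2),
            genes_b=(p.gene_a, p.gene_b),
            code_a=overlap_a.relation(r1, r2),
            code_b=p.category,
        )
    return list(seen.values())


@dataclass(frozen=True)
class LocalizationSummary:
    counts: tuple[tuple[tuple[str, str], int], ...]
    retained: int
    rearranged: int
    total: int

    def count_for(self, category: tuple[str, str]) -> int:
        return dict(self.counts).get(category, 0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"code_a": a, "code_b": b, "n_pairs": n}
            for (a, b), n in self.counts
        ]
        return pd.DataFrame(rows)


def tabulate_localization_patterns(
    profiles: Iterable[ProfiledPair] | Mapping[tuple[str, str], int],
) -> LocalizationSummary:
    """Category counts plus retained/rearranged/total accounting.

    Accepts either profiled pairs or a mapping of the eight categories to
    counts.  retained = both-species-overlapping; rearranged = overlapping on
    exactly one side; retained + rearranged = total.
    """
    if isinstance(profiles, Mapping):
        counts = {cat: int(profiles.get(cat, 0)) for cat in PATTERN_CATEGORIES}
        extra = set(profiles) - set(PATTERN_CATEGORIES)
        if extra:
            raise ValidationError(f"unknown localization categories: {sorted(extra)}")
    else:
        counts = {cat: 0 for cat in PATTERN_CATEGORIES}
        for p in profiles:
            cat = (p.code_a, p.code_b)
            if cat not in counts:
                raise ValidationError(f"unexpected profile category {cat}")
            counts[cat] += 1
    overlap_codes = ("EH", "PO")
    retained = sum(
        n for (a, b), n in counts.items() if a in overlap_codes and b in overlap_codes
    )
    rearranged = sum(
        n for (a, b), n in counts.items()
        if (a in overlap_codes) != (b in overlap_codes)
    )
    total = sum(counts.values())
    assert retained + rearranged == total
    return LocalizationSummary(
        counts=tuple(counts.items()), retained=retained,
        rearranged=rearranged, total=total,
    )


# ---------------------------------------------------------------------------
# contingency tables
# ---------------------------------------------------------------------------


def intron_contingency(
    pairs_by_category: Mapping[str, Sequence[ProfiledPair]],
    genes_a: Mapping[str, GeneRecord],
    genes_b: Mapping[str, GeneRecord],
    species_labels: tuple[str, str] = ("species_a", "species_b"),
) -> ContingencyTable2x2:
    """2x2 table of summed intron counts (both pair members) by category
    (rows) and species (columns).  Introns per gene = exons - 1."""
    if len(pairs_by_category) != 2:
        raise ValidationError("intron contingency requires exactly two categories")
    rows = []
    labels = tuple(pairs_by_category)
    for label in labels:
        a_total = b_total = 0
        for p in pairs_by_category[label]:
            a_total += sum(genes_a[g].n_introns for g in p.genes_a)
            b_total += sum(genes_b[g].n_introns for g in p.genes_b)
        rows.append((a_total, b_total))
    return ContingencyTable2x2(
        counts=(tuple(rows[0]), tuple(rows[1])),
        row_labels=labels,  # type: ignore[arg-type]
        col_labels=species_labels,
    )


def intronless_contingency(
    genes: Mapping[str, GeneRecord],
    overlapping_ids: set[str],
) -> ContingencyTable2x2:
    """Counts of intronless vs intron-containing genes, overlapping vs not."""
    counts = np.zeros((2, 2), dtype=int)
    for gid, g in genes.items():
        row = 0 if gid in overlapping_ids else 1
        col = 0 if g.n_introns == 0 else 1
        counts[row, col] += 1
    return ContingencyTable2x2(
        counts=((int(counts[0, 0]), int(counts[0, 1])),
                (int(counts[1, 0]), int(counts[1, 1]))),
        row_labels=("overlapping", "non_overlapping"),
        col_labels=("intronless", "intron_containing"),
    )


# ---------------------------------------------------------------------------
# binary matrices and expression
# ---------------------------------------------------------------------------


def overlap_orthology_matrices(
    pairs: Sequence[OverlapPair],
    reference: str,
    species_list: Sequence[str],
    maps: Mapping[str, OrthologMap],
    genomes: Mapping[str, SpeciesOverlap],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair-by-species binary matrices: overlap presence and orthology
    presence.  The reference column of the overlap matrix is all ones by
    construction; an absent ortholog gives 0 in both matrices."""
    index = [f"{p.gene_a}-{p.gene_b}" for p in pairs]
    cols = [reference] + [s for s in species_list if s != reference]
    overlap_m = pd.DataFrame(0, index=index, columns=cols, dtype=int)
    orth_m = pd.DataFrame(0, index=index, columns=cols, dtype=int)
    overlap_m[reference] = 1
    orth_m[reference] = 1
    for species in cols[1:]:
        omap = maps[species]
        a2b = omap.a_to_b
        genome = genomes[species]
        for p in pairs:
            pid = f"{p.gene_a}-{p.gene_b}"
            o1, o2 = a2b.get(p.gene_a), a2b.get(p.gene_b)
            if o1 is None or o2 is None:
                continue
            orth_m.loc[pid, species] = 1
            if genome.relation(o1, o2) in ("EH", "PO"):
                overlap_m.loc[pid, species] = 1
    return overlap_m, orth_m


def expression_correlation_by_orientation(
    pairs: Sequence[OverlapPair],
    expression: pd.DataFrame,
) -> dict[str, TestResult]:
    """Spearman correlation of the two members' expression, per orientation.

    One scalar per gene: the mean over condition columns.  Pairs with a
    member absent from the expression table are skipped (logged).
    """
    means = expression.mean(axis=1)
    groups: dict[str, tuple[list[float], list[float]]] = {
        "same": ([], []), "opposite": ([], []),
    }
    skipped = 0
    for p in pairs:
        if p.gene_a not in means.index or p.gene_b not in means.index:
            skipped += 1
            continue
        xs, ys = groups[p.orientation]
        xs.append(float(means[p.gene_a]))
        ys.append(float(means[p.gene_b]))
    if skipped:
        logger.info("expression correlation: skipped %d pairs without data", skipped)
    out = {}
    for orientation, (xs, ys) in groups.items():
        if len(xs) >= 3:
            out[orientation] = spearman(xs, ys)
    return out
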