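"""Ground-truth generators for every pipeline input.

Each generator is deterministic under a fixed seed and emits both the data
and a truth table, so every analysis stage can be validated against known
structure: annotated toy genomes with controlled overlap architecture,
multi-species ortholog families with covariate-linked rearrangement,
sequences with implanted SSRs, orientation-correlated expression tables,
trait histories on trees, and logistic dS/dN datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .annotation_io import GeneRecord, OrthologMap, Phylogeny, newick_from_string
from .errors import ValidationError

BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def random_phylogeny(n_leaves: int, seed: int | None = None,
                     mean_branch: float = 0.5) -> Phylogeny:
    """Random binary rooted tree by iterative joining, exponential lengths."""
    if n_leaves < 2:
        raise ValidationError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    subtrees = [f"S{i+1}" for i in range(n_leaves)]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        right = subtrees.pop(j)
        left = subtrees.pop(i)
        bl, br = rng.exponential(mean_branch, size=2)
        subtrees.append(f"({left}:{bl:.6f},{right}:{br:.6f})")
    return newick_from_string(subtrees[0] + ";")


# ---------------------------------------------------------------------------
# genomes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSimParams:
    n_genes: int = 400
    n_seqids: int = 4
    gene_len_log_mean: float = 7.3
    gene_len_log_sd: float = 0.6
    frac_overlapping: float = 0.1
    eh_po_ratio: float = 1.0
    frac_eh_intronic: float = 0.87
    frac_opposite: float = 0.7
    mean_extra_exons: float = 2.0
    n_clusters: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        for f in (self.frac_overlapping, self.frac_eh_intronic, self.frac_opposite):
            if not 0.0 <= f <= 1.0:
                raise ValidationError("fractions must be in [0, 1]")
        if self.n_genes < 2:
            raise ValidationError("n_genes must be >= 2")
        if self.eh_po_ratio < 0:
            raise ValidationError("eh_po_ratio must be >= 0")


class _Layout:
    """Per-seqid cursor for non-overlapping placement of gene structures."""

    def __init__(self, n_seqids: int, rng: np.random.Generator):
        self.cursors = {f"chr{i+1}": 1 for i in range(n_seqids)}
        self.rng = rng

    def place(self, span: int) -> tuple[str, int]:
        seq_id = self.rng.choice(sorted(self.cursors))
        start = self.cursors[seq_id] + int(self.rng.integers(200, 2000))
        self.cursors[seq_id] = start + span
        return seq_id, start

    def append_beyond(self, seq_id: str, span: int) -> int:
        start = self.cursors[seq_id] + int(self.rng.integers(5000, 20000))
        self.cursors[seq_id] = start + span
        return start


def _draw_len(rng: np.random.Generator, p: GenomeSimParams, lo: int = 200,
              hi: int = 60000) -> int:
    return int(np.clip(rng.lognormal(p.gene_len_log_mean, p.gene_len_log_sd), lo, hi))


def _split_exons(rng: np.random.Generator, start: int, end: int,
                 n_exons: int) -> tuple[tuple[int, int], ...]:
    """Partition [start, end] into n_exons exons separated by introns >= 1 bp;
    the first and last base are exonic."""
    span = end - start + 1
    n_parts = 2 * n_exons - 1
    if n_exons <= 1 or span < 3 * n_parts:
        return ((start, end),)
    cuts = np.sort(rng.choice(np.arange(1, span - 1), size=n_parts - 1, replace=False))
    bounds = np.concatenate(([0], cuts, [span]))
    widths = np.diff(bounds)
    if (widths < 1).any():
        return ((start, end),)
    exons = []
    pos = start
    for i, w in enumerate(widths):
        if i % 2 == 0:
            exons.append((pos, pos + int(w) - 1))
        pos += int(w)
    return tuple(exons)


def _n_exons(rng: np.random.Generator, p: GenomeSimParams) -> int:
    return 1 + int(rng.poisson(p.mean_extra_exons))


def _strand_pair(rng: np.random.Generator, frac_opposite: float) -> tuple[str, str]:
    s1 = rng.choice(["+", "-"])
    if rng.random() < frac_opposite:
        return s1, ("-" if s1 == "+" else "+")
    return s1, s1


def generate_genome(params: GenomeSimParams) -> tuple[list[GeneRecord], pd.DataFrame]:
    """Emit gene records realizing the requested overlap architecture exactly,
    plus a truth table of every intended pair and cluster."""
    rng = np.random.default_rng(params.seed)
    n_pairs = int(round(params.n_genes * params.frac_overlapping / 2.0))
    r = params.eh_po_ratio
    n_eh = int(round(n_pairs * (r / (1.0 + r)))) if math.isfinite(r) else n_pairs
    n_po = n_pairs - n_eh
    n_background = params.n_genes - 2 * n_pairs - 3 * params.n_clusters
    if n_background < 0:
        raise ValidationError(
            "infeasible parameters: overlap/cluster genes exceed n_genes"
        )

    layout = _Layout(params.n_seqids, rng)
    genes: list[GeneRecord] = []
    truth_rows: list[dict] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"G{counter:05d}"

    for i in range(n_eh):
        in_intron = rng.random() < params.frac_eh_intronic
        genes_i, row = _make_eh_pair(rng, params, layout, next_id, in_intron)
        genes.extend(genes_i)
        truth_rows.append(row)
    for i in range(n_po):
        genes_i, row = _make_po_pair(rng, params, layout, next_id)
        genes.extend(genes_i)
        truth_rows.append(row)
    for i in range(params.n_clusters):
        genes_i, row = _make_cluster(rng, params, layout, next_id)
        genes.extend(genes_i)
        truth_rows.append(row)
    for i in range(n_background):
        glen = _draw_len(rng, params)
        seq_id, start = layout.place(glen)
        genes.append(
            GeneRecord(
                gene_id=next_id(), seq_id=seq_id, start=start, end=start + glen - 1,
                strand=str(rng.choice(["+", "-"])),
                exons=_split_exons(rng, start, start + glen - 1, _n_exons(rng, params)),
                species="sim",
            )
        )

    truth = pd.DataFrame(
        truth_rows,
        columns=["kind", "pair_id", "gene_a", "gene_b", "category", "host",
                 "embedded", "orientation", "in_intron", "members"],
    )
    order = rng.permutation(len(genes))
    return [genes[i] for i in order], truth


def _make_eh_pair(rng, params, layout, next_id, in_intron: bool):
    emb_len = _draw_len(rng, params, lo=150, hi=3000)
    host_id, emb_id = next_id(), next_id()
    margin = int(rng.integers(20, 200))
    flank = int(rng.integers(300, 2000))
    s_host = None
    if in_intron:
        # host: exon1 | intron containing the embedded gene | exon2
        exon1 = int(rng.integers(200, 1500))
        exon2 = int(rng.integers(200, 1500))
        intron_len = emb_len + 2 * margin
        host_len = exon1 + intron_len + exon2
        seq_id, s_host = layout.place(host_len)
        e_host = s_host + host_len - 1
        host_exons = ((s_host, s_host + exon1 - 1), (e_host - exon2 + 1, e_host))
        s_emb = s_host + exon1 + margin
    else:
        # single-exon host: embedded lies over exon sequence, not an intron
        host_len = emb_len + 2 * flank
        seq_id, s_host = layout.place(host_len)
        e_host = s_host + host_len - 1
        host_exons = ((s_host, e_host),)
        s_emb = s_host + flank
    e_emb = s_emb + emb_len - 1
    strand_h, strand_e = _strand_pair(rng, params.frac_opposite)
    host = GeneRecord(gene_id=host_id, seq_id=seq_id, start=s_host, end=e_host,
                      strand=strand_h, exons=host_exons, species="sim")
    emb = GeneRecord(gene_id=emb_id, seq_id=seq_id, start=s_emb, end=e_emb,
                     strand=strand_e,
                     exons=_split_exons(rng, s_emb, e_emb, _n_exons(rng, params)),
                     species="sim")
    a, b = sorted((host_id, emb_id))
    row = dict(kind="pair", pair_id=f"{a}-{b}", gene_a=a, gene_b=b, category="EH",
               host=host_id, embedded=emb_id,
               orientation="same" if strand_h == strand_e else "opposite",
               in_intron=in_intron, members="")
    return [host, emb], row


def _make_po_pair(rng, params, layout, next_id):
    l1 = _draw_len(rng, params)
    l2 = _draw_len(rng, params)
    ov = int(rng.integers(1, min(l1, l2)))  # 1 <= ov < min(l1, l2)
    id1, id2 = next_id(), next_id()
    seq_id, s1 = layout.place(l1 + l2 - ov)
    e1 = s1 + l1 - 1
    s2 = e1 - ov + 1
    e2 = s2 + l2 - 1
    strand1, strand2 = _strand_pair(rng, params.frac_opposite)
    g1 = GeneRecord(gene_id=id1, seq_id=seq_id, start=s1, end=e1, strand=strand1,
                    exons=_split_exons(rng, s1, e1, _n_exons(rng, params)),
                    species="sim")
    g2 = GeneRecord(gene_id=id2, seq_id=seq_id, start=s2, end=e2, strand=strand2,
                    exons=_split_exons(rng, s2, e2, _n_exons(rng, params)),
                    species="sim")
    a, b = sorted((id1, id2))
    row = dict(kind="pair", pair_id=f"{a}-{b}", gene_a=a, gene_b=b, category="PO",
               host="", embedded="",
               orientation="same" if strand1 == strand2 else "opposite",
               in_intron="", members="")
    return [g1, g2], row


def _make_cluster(rng, params, layout, next_id):
    """Chain of three genes: g1-g2 and g2-g3 overlap, g1 and g3 do not."""
    lens = [int(_draw_len(rng, params, lo=1000)) for _ in range(3)]
    ids = [next_id() for _ in range(3)]
    total = sum(lens)
    seq_id, s1 = layout.place(total)
    ov12 = int(rng.integers(1, min(lens[0], lens[1]) // 2))
    ov23 = int(rng.integers(1, min(lens[1], lens[2]) // 2))
    e1 = s1 + lens[0] - 1
    s2 = e1 - ov12 + 1
    e2 = s2 + lens[1] - 1
    s3 = e2 - ov23 + 1
    e3 = s3 + lens[2] - 1
    assert s3 > e1, "chain cluster must not close into a triangle"
    coords = [(s1, e1), (s2, e2), (s3, e3)]
    out = [
        GeneRecord(gene_id=g, seq_id=seq_id, start=s, end=e,
                   strand=str(rng.choice(["+", "-"])),
                   exons=_split_exons(rng, s, e, _n_exons(rng, params)),
                   species="sim")
        for g, (s, e) in zip(ids, coords)
    ]
    row = dict(kind="cluster", pair_id="", gene_a="", gene_b="", category="",
               host="", embedded="", orientation="", in_intron="",
               members=",".join(sorted(ids)))
    return out, row


# ---------------------------------------------------------------------------
# ortholog families with covariate-linked rearrangement
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FamilySimParams:
    tree: Phylogeny
    rearrange_prob: float = 0.3
    birth_rate: float = 0.0
    loss_prob: float = 0.0
    intron_effect: float = 0.0  # logistic effect of pair intron count (standardized)
    ssr_effect: float = 0.0  # logistic effect of the per-pair SSR covariate
    intron_loss_on_rearrange: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for p in (self.rearrange_prob, self.loss_prob, self.intron_loss_on_rearrange):
            if not 0.0 <= p <= 1.0:
                raise ValidationError("probabilities must be in [0, 1]")


@dataclass
class FamilyResult:
    genomes: dict[str, list[GeneRecord]]
    maps: dict[tuple[str, str], OrthologMap]
    truth: pd.DataFrame  # pair_id, species, code
    covariates: pd.DataFrame  # pair_id, intron_z, ssr_z

    def ortholog_map(self, species_a: str, species_b: str) -> OrthologMap:
        return self.maps[(species_a, species_b)]


def _merge_random_introns(gene: GeneRecord, p_loss: float,
                          rng: np.random.Generator) -> GeneRecord:
    exons = list(gene.exons)
    merged: list[tuple[int, int]] = [exons[0]]
    for nxt in exons[1:]:
        if rng.random() < p_loss:
            merged[-1] = (merged[-1][0], nxt[1])  # intron absorbed into exon
        else:
            merged.append(nxt)
    return replace(gene, exons=tuple(merged))


def generate_family(
    params: FamilySimParams,
    base: tuple[list[GeneRecord], pd.DataFrame],
) -> FamilyResult:
    """Evolve a base genome along the species tree.

    Each overlapping pair independently rearranges per branch with odds
    modified by the implanted covariates (logistic link); rearrangement moves
    the pair's second gene to a distant position and is irreversible along a
    lineage.  Gene births add lineage-specific genes; losses delete genes.
    On rearrangement each intron of the moved pair's genes is deleted with
    probability ``intron_loss_on_rearrange``.
    """
    rng = np.random.default_rng(params.seed)
    base_genes, base_truth = base
    pair_rows = base_truth[base_truth["kind"] == "pair"]
    pair_partner = {}  # pair_id -> (kept_gene, moved_gene)
    pair_category = {}
    for row in pair_rows.itertuples(index=False):
        moved = row.embedded if row.category == "EH" else row.gene_b
        kept = row.host if row.category == "EH" else row.gene_a
        pair_partner[row.pair_id] = (kept, moved)
        pair_category[row.pair_id] = row.category

    intron_counts = {g.gene_id: g.n_introns for g in base_genes}
    pair_ids = list(pair_partner)
    intron_raw = np.array(
        [intron_counts[a] + intron_counts[b]
         for a, b in (pair_partner[p] for p in pair_ids)], dtype=float
    )
    intron_z = ((intron_raw - intron_raw.mean()) / (intron_raw.std() or 1.0)
                if len(intron_raw) else intron_raw)
    ssr_z = rng.standard_normal(len(pair_ids))
    cov = pd.DataFrame({"pair_id": pair_ids, "intron_z": intron_z, "ssr_z": ssr_z})

    base_logit = math.log(params.rearrange_prob / (1 - params.rearrange_prob)) \
        if 0 < params.rearrange_prob < 1 else (-math.inf if params.rearrange_prob == 0 else math.inf)
    p_rearr = {}
    for pid, iz, sz in zip(pair_ids, intron_z, ssr_z):
        eta = base_logit + params.intron_effect * iz + params.ssr_effect * sz
        p_rearr[pid] = 1.0 / (1.0 + math.exp(-eta)) if math.isfinite(eta) else (
            0.0 if eta == -math.inf else 1.0)

    tree = params.tree.tree
    genomes: dict[str, list[GeneRecord]] = {}
    truth_rows: list[dict] = []
    birth_counter = [0]

    def evolve(node, genes: dict[str, GeneRecord], rearranged: set[str],
               lost: set[str]) -> None:
        for child in node.child_nodes():
            c_genes = dict(genes)
            c_rearr = set(rearranged)
            c_lost = set(lost)
            # pair rearrangement
            for pid, (kept, moved) in pair_partner.items():
                if pid in c_rearr or kept in c_lost or moved in c_lost:
                    continue
                if rng.random() < p_rearr[pid]:
                    c_rearr.add(pid)
                    g = c_genes[moved]
                    far = max(x.end for x in c_genes.values() if x.seq_id == g.seq_id)
                    shift = far + int(rng.integers(10000, 50000)) - g.start
                    c_genes[moved] = replace(
                        g, start=g.start + shift, end=g.end + shift,
                        exons=tuple((s + shift, e + shift) for s, e in g.exons),
                    )
                    if params.intron_loss_on_rearrange > 0:
                        for gid in (kept, moved):
                            c_genes[gid] = _merge_random_introns(
                                c_genes[gid], params.intron_loss_on_rearrange, rng
                            )
            # losses (never pair members, so pair codes stay interpretable)
            pair_member_ids = {g for pr in pair_partner.values() for g in pr}
            if params.loss_prob > 0:
                for gid in list(c_genes):
                    if gid in pair_member_ids:
                        continue
                    if rng.random() < params.loss_prob:
                        del c_genes[gid]
                        c_lost.add(gid)
            # births
            n_birth = rng.poisson(params.birth_rate)
            for _ in range(n_birth):
                birth_counter[0] += 1
                gid = f"B{birth_counter[0]:05d}"
                glen = int(rng.integers(500, 5000))
                seq_id = sorted({g.seq_id for g in c_genes.values()})[0]
                far = max(g.end for g in c_genes.values() if g.seq_id == seq_id)
                start = far + int(rng.integers(10000, 50000))
                c_genes[gid] = GeneRecord(
                    gene_id=gid, seq_id=seq_id, start=start, end=start + glen - 1,
                    strand=str(rng.choice(["+", "-"])),
                    exons=((start, start + glen - 1),), species="sim",
                )
            if child.is_leaf():
                label = child.taxon.label
                genomes[label] = [
                    replace(g, gene_id=f"{label}|{gid}", species=label)
                    for gid, g in sorted(c_genes.items())
                ]
                for pid, (kept, moved) in pair_partner.items():
                    if kept in c_lost or moved in c_lost:
                        code = "ABS"
                    elif pid in c_rearr:
                        code = "NOV"
                    else:
                        code = pair_category[pid]
                    truth_rows.append({"pair_id": pid, "species": label, "code": code})
            else:
                evolve(child, c_genes, c_rearr, c_lost)

    root_genes = {g.gene_id: g for g in base_genes}
    evolve(tree.seed_node, root_genes, set(), set())

    maps: dict[tuple[str, str], OrthologMap] = {}
    species = sorted(genomes)
    lineage = {
        sp: {gid.split("|", 1)[1]: gid for gid in (g.gene_id for g in genomes[sp])}
        for sp in species
    }
    for sa in species:
        for sb in species:
            if sa == sb:
                continue
            shared = set(lineage[sa]) & set(lineage[sb])
            maps[(sa, sb)] = OrthologMap(
                species_a=sa, species_b=sb,
                pairs=frozenset((lineage[sa][l], lineage[sb][l]) for l in shared),
            )
    return FamilyResult(
        genomes=genomes, maps=maps,
        truth=pd.DataFrame(truth_rows, columns=["pair_id", "species", "code"]),
        covariates=cov,
    )


# ---------------------------------------------------------------------------
# sequences with implanted SSRs
# ---------------------------------------------------------------------------


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(BASES, size=length))


def implant_ssrs(
    length: int,
    n_repeats: int,
    motifs: tuple[str, ...] = ("AC", "AAG", "AT", "A", "ACGT"),
    seed: int | None = None,
    span_range: tuple[int, int] = (18, 40),
    imperfect_frac: float = 0.0,
) -> tuple[str, list[dict]]:
    """Random sequence with perfect (and optionally imperfect) repeats
    implanted at known, well-separated coordinates.

    Imperfect implants carry 1-2 isolated internal mismatches (never at the
    ends, never adjacent), so they remain single valid hits under the
    scanning rules.  Returns (sequence, truth hits) with 1-based coordinates.
    """
    rng = np.random.default_rng(seed)
    seq = list(random_sequence(length, rng))
    margin = 10
    slot = (length - margin) // max(n_repeats, 1)
    if slot < span_range[1] + 2 * margin:
        raise ValidationError("sequence too short for requested implants")
    truth = []
    for i in range(n_repeats):
        motif = str(rng.choice(motifs))
        span = int(rng.integers(span_range[0], span_range[1] + 1))
        units = -(-span // len(motif))
        repeat = (motif * units)[:span]
        start = i * slot + margin + int(rng.integers(0, slot - span - 2 * margin))
        n_mism = 0
        if imperfect_frac > 0 and rng.random() < imperfect_frac:
            n_mism = int(rng.integers(1, 3))
            positions = rng.choice(
                np.arange(2, span - 2, 2), size=n_mism, replace=False
            )
            repeat = list(repeat)
            for pos in positions:
                current = repeat[pos]
                repeat[pos] = str(rng.choice([b for b in "ACGT" if b != current]))
            repeat = "".join(repeat)
        seq[start : start + span] = list(repeat)
        truth.append(
            dict(start=start + 1, end=start + span, motif=motif, n_mismatches=n_mism)
        )
    return "".join(seq), truth


# ---------------------------------------------------------------------------
# expression and logistic dS/dN data
# ---------------------------------------------------------------------------


def generate_expression(
    pairs,
    orientation_effect: float,
    n_conditions: int,
    seed: int | None = None,
    noise_sd: float = 0.1,
) -> pd.DataFrame:
    """Expression table where same-orientation pair members are correlated
    across pairs with the given coefficient; opposite pairs are independent."""
    if n_conditions < 2:
        raise ValidationError("need at least 2 conditions for expression analysis")
    if not -1.0 <= orientation_effect <= 1.0:
        raise ValidationError("orientation_effect must be a correlation in [-1, 1]")
    rng = np.random.default_rng(seed)
    rows = {}
    eff = orientation_effect
    for p in pairs:
        za = rng.standard_normal()
        if p.orientation == "same":
            zb = eff * za + math.sqrt(max(0.0, 1 - eff * eff)) * rng.standard_normal()
        else:
            zb = rng.standard_normal()
        rows[p.gene_a] = za + noise_sd * rng.standard_normal(n_conditions)
        rows[p.gene_b] = zb + noise_sd * rng.standard_normal(n_conditions)
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=[f"cond{i+1}" for i in range(n_conditions)])
    df.index.name = "gene_id"
    return df


def generate_logit_data(beta, n: int, seed: int | None = None) -> pd.DataFrame:
    """dS/dN rows with Bernoulli overlap status under a logistic model.

    ``beta`` is (intercept, b_gene1_dS, b_gene1_dN, b_gene2_dS, b_gene2_dN).
    dS values are gamma(2, 0.5); dN values gamma(2, 0.15).
    """
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (5,):
        raise ValidationError("beta must have 5 entries (intercept + 4 slopes)")
    rng = np.random.default_rng(seed)
    g1ds = rng.gamma(2.0, 0.5, size=n)
    g1dn = rng.gamma(2.0, 0.15, size=n)
    g2ds = rng.gamma(2.0, 0.5, size=n)
    g2dn = rng.gamma(2.0, 0.15, size=n)
    X = np.column_stack([np.ones(n), g1ds, g1dn, g2ds, g2dn])
    p = 1.0 / (1.0 + np.exp(-np.clip(X @ beta, -30, 30)))
    y = (rng.random(n) < p).astype(int)
    return pd.DataFrame(
        {
            "pair_id": [f"P{i+1:05d}" for i in range(n)],
            "species": "sim",
            "gene1_dS": g1ds,
            "gene1_dN": g1dn,
            "gene2_dS": g2ds,
            "gene2_dN": g2dn,
            "overlap_status": y,
        }
    )
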