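from collections import Counter

import numpy as np
import pandas as pd
import pytest

from genoverlap.annotation_io import OrthologMap
from genoverlap.errors import ValidationError
from genoverlap.overlap_core import OverlapPair
from genoverlap.ortholog_compare import (
    PATTERN_CATEGORIES,
    SpeciesOverlap,
    classify_pair_age,
    expression_correlation_by_orientation,
    intron_contingency,
    intronless_contingency,
    localization_profile,
    overlap_orthology_matrices,
    tabulate_localization_patterns,
    two_species_localization,
)
from genoverlap.stats_kit import yates_chi_square
from genoverlap.synthetic_data import (
    FamilySimParams,
    GenomeSimParams,
    generate_expression,
    generate_family,
    generate_genome,
    random_phylogeny,
)

from conftest import make_gene

TABLE1_COUNTS = dict(zip(PATTERN_CATEGORIES, (75, 54, 3, 7, 43, 140, 103, 74)))


def simple_map(*pairs):
    return OrthologMap("A", "B", frozenset(pairs))


@pytest.fixture(scope="module")
def family():
    base = generate_genome(GenomeSimParams(
        n_genes=400, frac_overlapping=0.4, seed=21, mean_extra_exons=3.0))
    tree = random_phylogeny(3, seed=22, mean_branch=1.0)
    params = FamilySimParams(tree=tree, rearrange_prob=0.35, loss_prob=0.02,
                             birth_rate=3.0, seed=23)
    return base, generate_family(params, base)


class TestPairAge:
    def test_both_mapped(self):
        m = simple_map(("a1", "b1"), ("a2", "b2"))
        assert classify_pair_age(("a1", "a2"), m).age_class == "old_old"

    def test_neither_mapped(self):
        m = simple_map(("x", "y"))
        assert classify_pair_age(("a1", "a2"), m).age_class == "young_young"

    def test_one_mapped(self):
        m = simple_map(("a1", "b1"))
        assert classify_pair_age(("a1", "a2"), m).age_class == "young_old"

    def test_symmetric_in_member_order(self):
        m = simple_map(("a1", "b1"))
        assert (classify_pair_age(("a1", "a2"), m).age_class
                == classify_pair_age(("a2", "a1"), m).age_class)

    def test_generator_truth(self, family):
        base, fam = family
        sa = SpeciesOverlap.detect(fam.genomes["S1"], "S1")
        omap = fam.ortholog_map("S1", "S2")
        mapped = omap.a_to_b
        for p in sa.pairs:
            expected = {2: "old_old", 1: "young_old", 0: "young_young"}[
                sum(g in mapped for g in p.members)]
            assert classify_pair_age(p.members, omap).age_class == expected


class TestLocalizationProfile:
    def build_two_species(self):
        # species A: EH pair (a1 hosts a2); species B: orthologs far apart
        ga = [make_gene("a1", 100, 1000), make_gene("a2", 300, 400)]
        gb = [make_gene("b1", 100, 1000), make_gene("b2", 2_000_300, 2_000_400)]
        sa = SpeciesOverlap.detect(ga, "A")
        sb = SpeciesOverlap.detect(gb, "B")
        return sa, sb

    def test_orthologs_far_apart_nov(self):
        sa, sb = self.build_two_species()
        omap = simple_map(("a1", "b1"), ("a2", "b2"))
        prof = localization_profile(sa.pairs[0], "A", {"B": (sb, omap)})
        assert prof.code_for("A") == "EH"
        assert prof.code_for("B") == "NOV"

    def test_orthologs_overlap_eh(self):
        ga = [make_gene("a1", 100, 1000), make_gene("a2", 300, 400)]
        gb = [make_gene("b1", 500, 2000), make_gene("b2", 700, 800)]
        sa, sb = SpeciesOverlap.detect(ga, "A"), SpeciesOverlap.detect(gb, "B")
        omap = simple_map(("a1", "b1"), ("a2", "b2"))
        prof = localization_profile(sa.pairs[0], "A", {"B": (sb, omap)})
        assert prof.code_for("B") == "EH"

    def test_missing_ortholog_abs(self):
        sa, sb = self.build_two_species()
        omap = simple_map(("a1", "b1"))
        prof = localization_profile(sa.pairs[0], "A", {"B": (sb, omap)})
        assert prof.code_for("B") == "ABS"

    def test_inconsistent_map_chain_rejected(self):
        sa, sb = self.build_two_species()
        omap = OrthologMap("X", "B", frozenset([("a1", "b1")]))
        with pytest.raises(ValidationError, match="chain"):
            localization_profile(sa.pairs[0], "A", {"B": (sb, omap)})


class TestTabulate:
    def test_published_category_counts(self):
        s = tabulate_localization_patterns(TABLE1_COUNTS)
        assert s.retained == 139
        assert s.rearranged == 360
        assert s.total == 499

    def test_all_retained(self):
        s = tabulate_localization_patterns({("EH", "EH"): 10})
        assert s.rearranged == 0 and s.retained == 10 and s.total == 10

    def test_counts_partition_total(self, rng):
        counts = {cat: int(rng.integers(0, 50)) for cat in PATTERN_CATEGORIES}
        s = tabulate_localization_patterns(counts)
        assert s.retained + s.rearranged == s.total == sum(counts.values())

    def test_unknown_category_rejected(self):
        with pytest.raises(ValidationError):
            tabulate_localization_patterns({("EH", "XX"): 1})

    def test_family_truth_roundtrip(self, family):
        base, fam = family
        sa = SpeciesOverlap.detect(fam.genomes["S1"], "S1")
        sb = SpeciesOverlap.detect(fam.genomes["S2"], "S2")
        profiles = two_species_localization(sa, sb, fam.ortholog_map("S1", "S2"))
        got = tabulate_localization_patterns(profiles)

        truth = fam.truth.pivot(index="pair_id", columns="species", values="code")
        expected = Counter()
        for _, row in truth.iterrows():
            c1, c2 = row["S1"], row["S2"]
            if "ABS" in (c1, c2):
                continue
            if c1 in ("EH", "PO") or c2 in ("EH", "PO"):
                expected[(c1, c2)] += 1
        for cat in PATTERN_CATEGORIES:
            assert got.count_for(cat) == expected.get(cat, 0), cat
        assert got.total == sum(expected.values())


class TestIntronContingency:
    def test_single_pair_contribution(self):
        ga = {"a1": make_gene("a1", 1, 300, exons=[(1, 50), (100, 150), (200, 300)]),
              "a2": make_gene("a2", 400, 500)}
        gb = {"b1": make_gene("b1", 1, 100), "b2": make_gene("b2", 200, 400)}
        from genoverlap.ortholog_compare import ProfiledPair

        pp = ProfiledPair("a1-a2", ("a1", "a2"), ("b1", "b2"), "EH", "NOV")
        pp2 = ProfiledPair("x", ("a2", "a1"), ("b2", "b1"), "NOV", "EH")
        t = intron_contingency({"fwd": [pp], "rev": [pp2]}, ga, gb)
        assert t.array[0, 0] == 2 + 0  # a1 has 2 introns, a2 none
        assert t.array[0, 1] == 0

    def test_totals_match_independent_sum(self, family):
        base, fam = family
        sa = SpeciesOverlap.detect(fam.genomes["S1"], "S1")
        sb = SpeciesOverlap.detect(fam.genomes["S2"], "S2")
        profiles = two_species_localization(sa, sb, fam.ortholog_map("S1", "S2"))
        fwd = [p for p in profiles if p.code_a == "EH" and p.code_b == "NOV"]
        rev = [p for p in profiles if p.code_a == "NOV" and p.code_b == "EH"]
        if not fwd or not rev:
            pytest.skip("seed produced an empty category")
        t = intron_contingency({"fwd": fwd, "rev": rev}, sa.genes, sb.genes)
        expected00 = sum(sa.genes[g].n_exons - 1 for p in fwd for g in p.genes_a)
        assert t.array[0, 0] == expected00

    def test_implanted_intron_loss_detected(self):
        base = generate_genome(GenomeSimParams(
            n_genes=600, frac_overlapping=0.5, seed=31, mean_extra_exons=4.0))
        tree = random_phylogeny(2, seed=32, mean_branch=1.0)
        fam = generate_family(FamilySimParams(
            tree=tree, rearrange_prob=0.35, intron_loss_on_rearrange=0.7, seed=33),
            base)
        sa = SpeciesOverlap.detect(fam.genomes["S1"], "S1")
        sb = SpeciesOverlap.detect(fam.genomes["S2"], "S2")
        profiles = two_species_localization(sa, sb, fam.ortholog_map("S1", "S2"))
        rows = {
            "one_sided_a": [p for p in profiles
                            if p.code_a in ("EH", "PO") and p.code_b == "NOV"],
            "one_sided_b": [p for p in profiles
                            if p.code_a == "NOV" and p.code_b in ("EH", "PO")],
        }
        t = intron_contingency(rows, sa.genes, sb.genes)
        assert yates_chi_square(t).p_value < 0.01

    def test_no_effect_calibrated(self):
        base = generate_genome(GenomeSimParams(
            n_genes=600, frac_overlapping=0.5, seed=41, mean_extra_exons=4.0))
        tree = random_phylogeny(2, seed=42, mean_branch=1.0)
        fam = generate_family(FamilySimParams(
            tree=tree, rearrange_prob=0.35, intron_loss_on_rearrange=0.0, seed=43),
            base)
        sa = SpeciesOverlap.detect(fam.genomes["S1"], "S1")
        sb = SpeciesOverlap.detect(fam.genomes["S2"], "S2")
        profiles = two_species_localization(sa, sb, fam.ortholog_map("S1", "S2"))
        rows = {
            "one_sided_a": [p for p in profiles
                            if p.code_a in ("EH", "PO") and p.code_b == "NOV"],
            "one_sided_b": [p for p in profiles
                            if p.code_a == "NOV" and p.code_b in ("EH", "PO")],
        }
        t = intron_contingency(rows, sa.genes, sb.genes)
        assert yates_chi_square(t).p_value > 0.05


class TestIntronless:
    def test_classification(self):
        genes = {
            "g1": make_gene("g1", 1, 100),  # single exon
            "g2": make_gene("g2", 200, 400, exons=[(200, 250), (300, 400)]),
            "g3": make_gene("g3", 500, 600),
        }
        t = intronless_contingency(genes, overlapping_ids={"g1", "g2"})
        assert t.array[0, 0] == 1  # overlapping intronless: g1
        assert t.array[0, 1] == 1  # overlapping intron-containing: g2
        assert t.array[1, 0] == 1  # non-overlapping intronless: g3

    def test_matches_direct_count(self, small_genome):
        genes, _ = small_genome
        by_id = {g.gene_id: g for g in genes}
        from genoverlap.overlap_core import find_overlaps

        pairs, _ = find_overlaps(genes)
        ov = {g for p in pairs for g in p.members}
        t = intronless_contingency(by_id, ov)
        assert t.array.sum() == len(genes)
        assert t.array[0].sum() == len(ov)


class TestMatrices:
    def test_reference_column_all_ones_and_abs_zero(self, family):
        base, fam = family
        species = sorted(fam.genomes)
        ref = species[0]
        genomes = {s: SpeciesOverlap.detect(fam.genomes[s], s) for s in species}
        maps = {s: fam.ortholog_map(ref, s) for s in species if s != ref}
        pairs = genomes[ref].pairs[:30]
        ov_m, orth_m = overlap_orthology_matrices(pairs, ref, species, maps, genomes)
        assert (ov_m[ref] == 1).all()
        assert (orth_m[ref] == 1).all()
        assert ov_m.shape == orth_m.shape
        # no overlap without orthology
        assert int((ov_m.values > orth_m.values).sum()) == 0

    def test_truth_table_exact(self, family):
        base, fam = family
        species = sorted(fam.genomes)
        ref = species[0]
        genomes = {s: SpeciesOverlap.detect(fam.genomes[s], s) for s in species}
        maps = {s: fam.ortholog_map(ref, s) for s in species if s != ref}
        pairs = genomes[ref].pairs
        ov_m, orth_m = overlap_orthology_matrices(pairs, ref, species, maps, genomes)
        truth = fam.truth.pivot(index="pair_id", columns="species", values="code")
        strip = lambda gid: gid.split("|", 1)[1]
        for p in pairs:
            lineage_pair = "-".join(sorted((strip(p.gene_a), strip(p.gene_b))))
            if lineage_pair not in truth.index:
                continue  # incidental overlap, not a simulated pair
            pid = f"{p.gene_a}-{p.gene_b}"
            for s in species[1:]:
                code = truth.loc[lineage_pair, s]
                assert ov_m.loc[pid, s] == (1 if code in ("EH", "PO") else 0)


class TestExpressionCorrelation:
    @staticmethod
    def fake_pairs(n_same=30, n_opp=30):
        pairs = []
        for i in range(n_same + n_opp):
            orient = "same" if i < n_same else "opposite"
            pairs.append(OverlapPair(
                gene_a=f"ga{i:03d}", gene_b=f"gb{i:03d}", category="PO",
                orientation=orient, overlap_len=10))
        return pairs

    def test_identical_expression_rho_one(self):
        pairs = self.fake_pairs(5, 0)
        rows = {}
        for i, p in enumerate(pairs):
            v = np.full(3, float(i))
            rows[p.gene_a] = v
            rows[p.gene_b] = v
        expr = pd.DataFrame.from_dict(rows, orient="index",
                                      columns=["c1", "c2", "c3"])
        res = expression_correlation_by_orientation(pairs, expr)
        assert res["same"].statistic == pytest.approx(1.0)

    def test_implanted_orientation_effect(self):
        pairs = self.fake_pairs(30, 30)
        expr = generate_expression(pairs, orientation_effect=0.8,
                                   n_conditions=4, seed=7)
        res = expression_correlation_by_orientation(pairs, expr)
        assert res["same"].p_value < 0.01
        assert res["opposite"].p_value > 0.01

    def test_independent_noise_near_zero(self):
        pairs = self.fake_pairs(40, 40)
        expr = generate_expression(pairs, orientation_effect=0.0,
                                   n_conditions=4, seed=8)
        res = expression_correlation_by_orientation(pairs, expr)
        assert abs(res["same"].statistic) < 0.35
        assert abs(res["opposite"].statistic) < 0.35
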