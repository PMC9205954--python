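"""Variant-set construction: rule truth table, boundaries, provenance."""
import numpy as np
import pandas as pd
import pytest

from gsassoc.variant_sets import (
    build_cna_set, build_functional_set, build_gwas_set,
)
from conftest import make_annotation_bundle


def _variants(rows):
    return pd.DataFrame(rows, columns=["id", "chrom", "pos"])


class TestGwasSet:
    def _stats(self, pvals):
        return pd.DataFrame({
            "chrom": "1", "pos": np.arange(len(pvals)) + 1,
            "id": [f"s{i}" for i in range(len(pvals))],
            "ref": "A", "alt": "G", "eaf": 0.3, "beta": 0.0, "se": 1.0,
            "p": pvals,
        })

    def test_strict_inequality_at_cutoff(self):
        vs = build_gwas_set(self._stats([9.9e-6, 1e-5, 0.5]), ["gA"], 1e-5)
        assert list(vs.pairs["variant_id"]) == ["s0"]

    def test_passing_variants_pair_with_every_gene(self):
        pvals = [1e-7] * 17 + [0.3] * 23
        vs = build_gwas_set(self._stats(pvals), ["gA", "gB", "gC"], 1e-5)
        assert vs.n_pairs == 17 * 3
        assert set(vs.pairs["gene"]) == {"gA", "gB", "gC"}

    def test_empty_stats_rejected(self):
        with pytest.raises(ValueError):
            build_gwas_set(self._stats([]).iloc[:0], ["gA"])


@pytest.fixture()
def functional_fixture():
    genes = [
        ("GX", "1", "+", 1_000_000, 1_000_000, 1_050_000),
        ("GY", "2", "-", 2_000_000, 1_950_000, 2_000_000),
    ]
    exons = [
        ("GX", "1", 1_000_000, 1_000_200),
        ("GX", "1", 1_049_800, 1_050_000),
        ("GY", "2", 1_950_000, 1_950_200),
    ]
    vels = [
        ("1", 1_149_900, 1_150_100),   # near GX
        ("1", 1_249_950, 1_250_050),   # exactly 200 kb from GX body
        ("1", 1_399_900, 1_400_100),   # distal, overlaps expression link
        ("1", 1_499_900, 1_500_100),   # distal VEL without any link
    ]
    links = [
        ("1", 1_099_900, 1_100_100, "GX", "digestive", False),
        ("1", 1_100_400, 1_100_600, "GX", "brain", False),
        ("1", 1_399_900, 1_400_100, "GX", "other", True),
        ("1", 1_449_900, 1_450_100, "GX", "other", True),  # link, no VEL
    ]
    return make_annotation_bundle(genes, exons, vels, links,
                                  [("1", 1, 2, "R0", "gain")])


class TestFunctionalSet:
    def rules_for(self, annot, variants, gene="GX"):
        vs = build_functional_set(variants, annot, [gene])
        return dict(zip(vs.pairs["variant_id"], vs.pairs["rules"]))

    def test_rule_truth_table(self, functional_fixture):
        variants = _variants([
            ("vex", "1", 1_000_100),        # exon
            ("vprom", "1", 999_500),        # 500 bp upstream, + strand
            ("vprom_edge", "1", 999_000),   # exactly 1000 bp upstream
            ("vprom_out", "1", 998_999),    # 1001 bp: outside the window
            ("vnear_vel", "1", 1_150_000),  # 100 kb away, inside VEL
            ("vnear_bare", "1", 1_160_000), # 110 kb away, no annotation
            ("vtissue", "1", 1_100_000),    # digestive enhancer of GX
            ("vbrain", "1", 1_100_500),     # wrong tissue
            ("vfar_evel", "1", 1_400_000),  # >200 kb, expr link AND VEL
            ("vfar_link", "1", 1_450_000),  # >200 kb, expr link, no VEL
            ("vfar_vel", "1", 1_500_000),   # >200 kb, VEL, no link
        ])
        rules = self.rules_for(functional_fixture, variants)
        assert rules["vex"] == "exon"
        assert rules["vprom"] == "promoter"
        assert rules["vprom_edge"] == "promoter"
        assert "vprom_out" not in rules
        assert rules["vnear_vel"] == "vel_near"
        assert "vnear_bare" not in rules
        assert rules["vtissue"] == "enhancer_near"
        assert "vbrain" not in rules
        assert rules["vfar_evel"] == "distal_expr_vel"
        assert "vfar_link" not in rules
        assert "vfar_vel" not in rules

    def test_distance_boundary_inclusive(self, functional_fixture):
        # 1_250_000 is exactly 200 kb from the gene body end (1_050_000)
        rules = self.rules_for(functional_fixture,
                               _variants([("vedge", "1", 1_250_000)]))
        assert rules["vedge"] == "vel_near"

    def test_promoter_rule_is_strand_aware(self, functional_fixture):
        variants = _variants([
            ("vup_minus", "2", 2_000_500),   # downstream in + terms: upstream of -
            ("vdown_minus", "2", 1_999_500), # inside gene, not upstream
        ])
        rules = self.rules_for(functional_fixture, variants, gene="GY")
        assert rules.get("vup_minus") == "promoter"
        assert "vdown_minus" not in rules or "promoter" not in rules["vdown_minus"]

    def test_gene_without_model_dropped_with_warning(self, functional_fixture,
                                                     caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="gsassoc.variant_sets"):
            vs = build_functional_set(_variants([("vex", "1", 1_000_100)]),
                                      functional_fixture, ["GX", "GZ"])
        assert "GZ" in caplog.text
        assert set(vs.pairs["gene"]) == {"GX"}

    def test_sex_chromosome_exclusion_list(self, functional_fixture):
        vs = build_functional_set(_variants([("vex", "1", 1_000_100)]),
                                  functional_fixture, ["GX", "AMER1"])
        assert set(vs.pairs["gene"]) == {"GX"}

    def test_enlarging_annotation_never_removes_pairs(self, functional_fixture):
        variants = _variants([("vnear_bare", "1", 1_160_000),
                              ("vnear_vel", "1", 1_150_000)])
        before = build_functional_set(variants, functional_fixture, ["GX"])
        bigger = functional_fixture
        bigger.vels = pd.concat([
            bigger.vels,
            pd.DataFrame([("1", 1_159_900, 1_160_100)],
                         columns=["chrom", "start", "end"])],
            ignore_index=True)
        after = build_functional_set(variants, bigger, ["GX"])
        pairs_before = set(map(tuple, before.pairs[["variant_id", "gene"]].values))
        pairs_after = set(map(tuple, after.pairs[["variant_id", "gene"]].values))
        assert pairs_before < pairs_after

    def test_generator_fixtures_exercise_every_rule(self, small_cohort):
        vs = build_functional_set(
            small_cohort.genotypes.variants, small_cohort.annotations,
            small_cohort.somatic.genes)
        seen = set()
        for r in vs.pairs["rules"]:
            seen.update(r.split(","))
        assert {"exon", "promoter", "vel_near", "enhancer_near",
                "distal_expr_vel"} <= seen


class TestCnaSet:
    def test_same_chromosome_pairing_only(self):
        regions = pd.DataFrame([("4", 186_000_000, 187_500_000, "TLR3", "loss")],
                               columns=["chrom", "start", "end", "label",
                                        "direction"])
        variants = _variants([("rs78963230like", "4", 186_990_948)])
        vs = build_cna_set(variants, regions,
                           {"FBXW7like": "4", "CUX1like": "7"})
        assert vs.n_pairs == 1
        row = vs.pairs.iloc[0]
        assert (row["variant_id"], row["gene"]) == ("rs78963230like", "FBXW7like")
        assert row["rules"] == "cna:TLR3"

    def test_gene_subset_on_cna_chromosomes(self):
        # regions cover chromosomes 1..9 only; 12 genes sit on 1..12,
        # so exactly 9 genes receive pairs
        regions = pd.DataFrame(
            [(str(c), 1_000_000, 2_000_000, f"R{c}", "gain") for c in range(1, 10)],
            columns=["chrom", "start", "end", "label", "direction"])
        variants = _variants([(f"v{c}", str(c), 1_500_000) for c in range(1, 10)])
        gene_chroms = {f"g{c}": str(c) for c in range(1, 13)}
        vs = build_cna_set(variants, regions, gene_chroms)
        assert vs.pairs["gene"].nunique() == 9

    def test_variant_outside_all_regions_unpaired(self):
        regions = pd.DataFrame([("4", 100, 200, "R", "gain")],
                               columns=["chrom", "start", "end", "label",
                                        "direction"])
        vs = build_cna_set(_variants([("v", "4", 300)]), regions, {"g": "4"})
        assert vs.n_pairs == 0

    def test_no_regions_rejected(self):
        with pytest.raises(ValueError):
            build_cna_set(_variants([("v", "1", 5)]),
                          pd.DataFrame(columns=["chrom", "start", "end",
                                                "label", "direction"]),
                          {"g": "1"})


def test_no_duplicate_pairs_and_provenance_nonempty(small_cohort):
    vs = build_cna_set(
        small_cohort.genotypes.variants,
        small_cohort.annotations.cna_regions,
        small_cohort.annotations.gene_chrom())
    assert not vs.pairs.duplicated(["variant_id", "gene"]).any()
    assert (vs.pairs["rules"].str.len() > 0).all()
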