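"""Coverage-weighted profiles: hand-enumeration oracles and the GH table."""

from __future__ import annotations

import pytest

from mgcompare import (
    SampleGroup,
    ValidationError,
    category_subtotal,
    cazy_class_comparison,
    gh_relative_profile,
    load_crossbiome_profiles,
    load_gh_categories,
    pathway_cumulative_profile,
    weighted_feature_profile,
)
from mgcompare.model import FunctionCatalog

from conftest import make_cds, make_coverage


class TestWeightedFeatureProfile:
    def test_single_annotated_cds_self_normalizes(self, gh_catalog):
        for depth in (0.5, 1.0, 42.0):
            cds = [make_cds("a", "ctg1", cazy=("GH5",))]
            cov = make_coverage({"ctg1": depth})
            prof = weighted_feature_profile(cds, cov, "s1")
            assert prof.weights == {"GH5": pytest.approx(1.0)}

    def test_hand_enumeration(self):
        # ctg1 depth 10: CDSs (GH5), (GH10); ctg2 depth 30: (GH5), (none)
        cds = [
            make_cds("a", "ctg1", cazy=("GH5",)),
            make_cds("b", "ctg1", cazy=("GH10",)),
            make_cds("c", "ctg2", cazy=("GH5",)),
            make_cds("d", "ctg2"),
        ]
        cov = make_coverage({"ctg1": 10.0, "ctg2": 30.0})
        prof = weighted_feature_profile(cds, cov, "s1")
        assert prof.weights["GH5"] == pytest.approx(40.0 / 80.0)
        assert prof.weights["GH10"] == pytest.approx(10.0 / 80.0)

    def test_scale_invariance(self):
        cds = [
            make_cds("a", "ctg1", cazy=("GH5",)),
            make_cds("b", "ctg2", cazy=("GH10", "GH5")),
            make_cds("c", "ctg3"),
        ]
        cov1 = make_coverage({"ctg1": 2.0, "ctg2": 5.0, "ctg3": 11.0})
        cov7 = make_coverage({"ctg1": 14.0, "ctg2": 35.0, "ctg3": 77.0})
        p1 = weighted_feature_profile(cds, cov1, "s1").weights
        p7 = weighted_feature_profile(cds, cov7, "s1").weights
        assert set(p1) == set(p7)
        for f in p1:
            assert p1[f] == pytest.approx(p7[f], rel=1e-12)

    def test_repeated_domains_of_same_family_count_once(self):
        cds = [
            make_cds("a", "ctg1", cazy=("GH5", "GH5")),
            make_cds("b", "ctg1"),
        ]
        cov = make_coverage({"ctg1": 4.0})
        prof = weighted_feature_profile(cds, cov, "s1")
        assert prof.weights["GH5"] == pytest.approx(0.5)

    def test_empty_cds_list_and_missing_sample(self):
        cov = make_coverage({"ctg1": 1.0})
        with pytest.raises(ValidationError):
            weighted_feature_profile([], cov, "s1")
        with pytest.raises(ValidationError):
            weighted_feature_profile([make_cds("a", "ctg1")], cov, "nope")


class TestGHRelativeProfile:
    def test_single_family_is_hundred_percent(self, gh_catalog):
        cds = [make_cds("a", "ctg1", cazy=("GH5",))]
        cov = make_coverage({"ctg1": 3.0})
        table = gh_relative_profile(cds, cov, gh_catalog)
        assert table.family_percent["GH5"] == pytest.approx(100.0)
        assert table.subtotals["cellulase"] == pytest.approx(100.0)

    def test_two_equal_families_split_evenly(self, gh_catalog):
        cds = [
            make_cds("a", "ctg1", cazy=("GH5",)),
            make_cds("b", "ctg2", cazy=("GH2",)),
        ]
        cov = make_coverage({"ctg1": 6.0, "ctg2": 6.0})
        table = gh_relative_profile(cds, cov, gh_catalog)
        assert table.family_percent["GH5"] == pytest.approx(50.0)
        assert table.subtotals["cellulase"] == pytest.approx(50.0)
        assert table.subtotals["oligosaccharide_degrading"] == pytest.approx(50.0)

    def test_percent_of_all_cds_counts_unique_cds(self, gh_catalog):
        cds = [make_cds(f"g{i}", "ctg1") for i in range(397)]
        cds += [
            make_cds("l1", "ctg1", cazy=("GH5", "GH10")),  # multi-domain: once
            make_cds("l2", "ctg1", cazy=("GH2",)),
            make_cds("l3", "ctg1", cazy=("GH43",)),
        ]
        cov = make_coverage({"ctg1": 1.0})
        table = gh_relative_profile(cds, cov, gh_catalog)
        assert table.total_ligno_cds == 3
        assert table.percent_of_all_cds == pytest.approx(0.75)

    def test_no_lignocellulolytic_cds_is_error(self, gh_catalog):
        cds = [make_cds("a", "ctg1", cazy=("GH13",))]  # other_gh only
        cov = make_coverage({"ctg1": 1.0})
        with pytest.raises(ValidationError):
            gh_relative_profile(cds, cov, gh_catalog)


class TestCategorySubtotal:
    def test_published_profile_cells(self, gh_catalog):
        lit = load_crossbiome_profiles()
        assert category_subtotal(lit["wallaby_foregut"], gh_catalog, "cellulase") == 3.7
        assert (
            category_subtotal(lit["koala"], gh_catalog, "oligosaccharide_degrading")
            == 65.8
        )

    def test_empty_map_is_zero(self, gh_catalog):
        assert category_subtotal({}, gh_catalog, "cellulase") == 0.0

    def test_unknown_families_excluded(self, gh_catalog):
        pcts = {"GH5": 10.0, "GH9999": 90.0}
        assert category_subtotal(pcts, gh_catalog, "cellulase") == 10.0


class TestBundledCatalog:
    def test_family_role_memberships(self, gh_catalog):
        by_cat = {}
        for fam, cat in gh_catalog.gh_category.items():
            by_cat.setdefault(cat, set()).add(fam)
        assert by_cat["cellulase"] == {"GH5", "GH6", "GH7", "GH9", "GH44", "GH45", "GH48"}
        assert by_cat["endohemicellulase"] == {
            "GH8", "GH10", "GH11", "GH12", "GH26", "GH28", "GH53",
        }
        assert by_cat["accessory_hemicellulase"] == {
            "GH16", "GH17", "GH51", "GH54", "GH62", "GH67", "GH74", "GH78", "GH81",
        }
        assert by_cat["oligosaccharide_degrading"] == {
            "GH1", "GH2", "GH3", "GH29", "GH35", "GH38", "GH39", "GH42", "GH43", "GH52",
        }
        assert len(gh_catalog.gh_category) == 33

    def test_family_classification_fallbacks(self, gh_catalog):
        assert gh_catalog.classify_family("GH5") == "cellulase"
        assert gh_catalog.classify_family("GH13") == "other_gh"
        assert gh_catalog.classify_family("AA2") == "auxiliary_activity"


class TestPathwayProfile:
    def test_pathway_weight_sums_member_ko_weights(self, toy_pathway_catalog):
        cds = [
            make_cds("a", "ctg1", ko="K1"),
            make_cds("b", "ctg1", ko="K2"),
            make_cds("c", "ctg2", ko="K3"),
            make_cds("d", "ctg2"),
        ]
        cov = make_coverage({"ctg1": 10.0, "ctg2": 30.0})
        prof = pathway_cumulative_profile(cds, cov, toy_pathway_catalog, "s1")
        # pwX has 3 observed KOs: K1 (10) + K2 (10) + K3 (30), denominator 80
        assert prof["pwX"] == pytest.approx(50.0 / 80.0)

    def test_small_pathways_excluded(self, toy_pathway_catalog):
        cds = [
            make_cds("a", "ctg1", ko="K6"),
            make_cds("b", "ctg1", ko="K7"),
            make_cds("c", "ctg1", ko="K1"),
            make_cds("d", "ctg1", ko="K2"),
            make_cds("e", "ctg1", ko="K3"),
        ]
        cov = make_coverage({"ctg1": 1.0})
        prof = pathway_cumulative_profile(cds, cov, toy_pathway_catalog, "s1")
        assert "pwZ" not in prof  # only 2 observed KOs
        assert "pwX" in prof

    def test_shared_ko_contributes_fully_to_both_pathways(self, toy_pathway_catalog):
        cds = [
            make_cds("a", "ctg1", ko="K1"),
            make_cds("b", "ctg1", ko="K2"),
            make_cds("c", "ctg1", ko="K3"),
            make_cds("d", "ctg1", ko="K4"),
            make_cds("e", "ctg1", ko="K5"),
        ]
        cov = make_coverage({"ctg1": 1.0})
        prof = pathway_cumulative_profile(cds, cov, toy_pathway_catalog, "s1")
        # K3 is in both pwX and pwY and contributes its full 0.2 weight to each
        assert prof["pwX"] == pytest.approx(0.6)
        assert prof["pwY"] == pytest.approx(0.6)


class TestCazyClassComparison:
    def _groups(self):
        return (
            SampleGroup("A", ("a1", "a2")),
            SampleGroup("B", ("b1", "b2")),
        )

    def test_identical_groups_no_difference(self, gh_catalog):
        cds = [make_cds("a", "ctg1", cazy=("GH5",)), make_cds("b", "ctg1")]
        cov = make_coverage(
            {"ctg1": {"a1": 2.0, "a2": 2.0, "b1": 2.0, "b2": 2.0}},
            samples=("a1", "a2", "b1", "b2"),
        )
        _, results = cazy_class_comparison([(cds, cov)], gh_catalog, self._groups())
        assert all(r.effect == pytest.approx(0.0) for r in results)

    def test_aa_families_only_in_one_group(self, gh_catalog):
        cds_a = [make_cds("a", "ctgA", cazy=("AA2",)), make_cds("b", "ctgA")]
        cds_b = [make_cds("c", "ctgB", cazy=("GH5",)), make_cds("d", "ctgB")]
        cov_a = make_coverage({"ctgA": 3.0}, samples=("a1", "a2"))
        cov_b = make_coverage({"ctgB": 3.0}, samples=("b1", "b2"))
        fractions, _ = cazy_class_comparison(
            [(cds_a, cov_a), (cds_b, cov_b)], gh_catalog, self._groups()
        )
        aux = fractions["auxiliary_activity"]
        assert min(aux["a1"], aux["a2"]) > max(aux["b1"], aux["b2"])
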