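"""Population-genome metrics: filters, abundance, coverage, scores, PCA."""

from __future__ import annotations

import numpy as np
import pytest

from mgcompare import (
    GenomeBin,
    ValidationError,
    community_genome_size_summary,
    contributor_score,
    filter_bins,
    genome_abundance,
    genome_pathway_pca,
    load_urea_config,
    pathway_coverage,
    top_n_genomes,
    urea_screen,
)
from mgcompare.catalog import default_catalog
from mgcompare.genomes import bin_ko_sets, pathway_coverage_matrix, pathway_universe

from conftest import make_cds, make_coverage


def bin_of(bin_id, contigs, completeness=80.0, contamination=0.0, size=0):
    return GenomeBin(bin_id, frozenset(contigs), completeness, contamination, size)


class TestFilterBins:
    @pytest.mark.parametrize(
        "completeness,contamination,passes",
        [
            (50.0, 10.0, True),  # boundary inclusive on both
            (49.9, 0.0, False),
            (95.0, 10.1, False),
            (100.0, 0.0, True),
        ],
    )
    def test_boundaries(self, completeness, contamination, passes):
        b = bin_of("b", {"c1"}, completeness, contamination)
        assert (filter_bins([b]) == [b]) is passes


class TestGenomeAbundance:
    def test_bin_with_all_contigs_is_one(self):
        cov = make_coverage({"c1": 2.0, "c2": 5.0}, lengths={"c1": 100, "c2": 300})
        b = bin_of("b", {"c1", "c2"})
        assert genome_abundance(b, cov, "s1") == pytest.approx(1.0)

    def test_equal_length_hand_value(self):
        cov = make_coverage({"c1": 10.0, "c2": 30.0})
        b = bin_of("b", {"c1"})
        assert genome_abundance(b, cov, "s1") == pytest.approx(0.25)

    def test_length_weighting(self):
        cov = make_coverage({"c1": 10.0, "c2": 10.0}, lengths={"c1": 100, "c2": 300})
        b = bin_of("b", {"c1"})
        assert genome_abundance(b, cov, "s1") == pytest.approx(0.25)

    def test_zero_total_coverage_rejected(self):
        cov = make_coverage({"c1": 0.0, "c2": 0.0})
        with pytest.raises(ValidationError):
            genome_abundance(bin_of("b", {"c1"}), cov, "s1")


class TestTopN:
    def test_median_ordering(self):
        bins = [bin_of(b, {b}) for b in ("x", "y", "z")]
        abund = {
            "x": {"s1": 0.02, "s2": 0.02},
            "y": {"s1": 0.05, "s2": 0.05},
            "z": {"s1": 0.01, "s2": 0.01},
        }
        top = top_n_genomes(bins, abund, n=2)
        assert [b.bin_id for b in top] == ["y", "x"]

    def test_median_tie_broken_by_mean(self):
        bins = [bin_of(b, {b}) for b in ("x", "y")]
        abund = {
            "x": {"s1": 0.0, "s2": 0.0, "s3": 0.03},  # median 0, mean 0.01
            "y": {"s1": 0.0, "s2": 0.0, "s3": 0.006},  # median 0, mean 0.002
        }
        top = top_n_genomes(bins, abund, n=2)
        assert [b.bin_id for b in top] == ["x", "y"]

    def test_n_zero_and_n_too_large(self):
        bins = [bin_of("x", {"x"})]
        abund = {"x": {"s1": 0.5}}
        assert top_n_genomes(bins, abund, n=0) == []
        with pytest.warns(UserWarning):
            assert len(top_n_genomes(bins, abund, n=15)) == 1


class TestPathwayCoverage:
    def test_set_arithmetic(self):
        assert pathway_coverage(frozenset({"K1", "K3"}), frozenset("K1 K2 K3 K4".split())) == 0.5
        assert pathway_coverage(frozenset({"K1", "K2"}), frozenset({"K1", "K2"})) == 1.0
        assert pathway_coverage(frozenset(), frozenset({"K1"})) == 0.0

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError):
            pathway_coverage(frozenset({"K1"}), frozenset())

    def test_universe_spans_all_bins_and_coverage_is_monotone(self):
        catalog = default_catalog(
            {
                "K1": frozenset({"pw"}),
                "K2": frozenset({"pw"}),
                "K3": frozenset({"pw"}),
                "K4": frozenset({"pw"}),
            }
        )
        ko_sets = {"b1": frozenset({"K1", "K2"}), "b2": frozenset({"K3"})}
        uni = pathway_universe(ko_sets, catalog)
        assert uni["pw"] == frozenset({"K1", "K2", "K3"})  # K4 unobserved
        m1 = pathway_coverage_matrix(ko_sets, catalog)
        grown = {"b1": ko_sets["b1"] | {"K3"}, "b2": ko_sets["b2"]}
        m2 = pathway_coverage_matrix(grown, catalog)
        assert m2["b1"]["pw"] >= m1["b1"]["pw"]

    def test_bin_ko_sets_from_cds(self):
        bins = [bin_of("b1", {"c1"}), bin_of("b2", {"c2"})]
        cds = [
            make_cds("a", "c1", ko="K1"),
            make_cds("b", "c1", ko="K1"),
            make_cds("c", "c2", ko="K2"),
            make_cds("d", "c3", ko="K9"),  # unbinned contig ignored
        ]
        assert bin_ko_sets(bins, cds) == {
            "b1": frozenset({"K1"}),
            "b2": frozenset({"K2"}),
        }


class TestPCA:
    def test_identical_genomes_zero_variance(self):
        props = {f"b{i}": {"pw1": 0.5, "pw2": 0.5} for i in range(4)}
        res = genome_pathway_pca(props)
        assert np.allclose(res.explained_variance, 0.0)
        assert np.allclose(res.coordinates, 0.0)

    def test_two_cluster_toy_matches_hand_svd(self):
        # 4 genomes x 2 pathways; clusters differ on pathway axis 1 only
        props = {
            "a1": {"pw1": 0.9, "pw2": 0.1},
            "a2": {"pw1": 0.9, "pw2": 0.1},
            "b1": {"pw1": 0.1, "pw2": 0.9},
            "b2": {"pw1": 0.1, "pw2": 0.9},
        }
        res = genome_pathway_pca(props)
        # centered matrix has rank 1: all variance on PC1
        assert res.explained_variance[0] == pytest.approx(1.0)
        pc1 = dict(zip(res.bin_ids, res.coordinates[:, 0]))
        assert pc1["a1"] == pytest.approx(pc1["a2"])
        assert pc1["a1"] == pytest.approx(-pc1["b1"])
        # hand SVD: singular value = sqrt(4 * 0.4^2 * 2) = 0.8*sqrt(2)
        assert abs(pc1["a1"]) == pytest.approx(0.4 * np.sqrt(2))

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        props = {
            f"b{i}": {f"pw{j}": float(v) for j, v in enumerate(rng.random(5))}
            for i in range(6)
        }
        res = genome_pathway_pca(props)
        assert float(res.explained_variance.sum()) == pytest.approx(1.0)

    def test_needs_three_genomes(self):
        with pytest.raises(ValidationError):
            genome_pathway_pca({"a": {"p": 1.0}, "b": {"p": 0.5}})


class TestContributorScore:
    def _catalog(self, n_kos=40):
        return default_catalog(
            {f"K{i:03d}": frozenset({"diff_pw"}) for i in range(n_kos)}
        )

    def test_formula_by_construction(self):
        catalog = self._catalog(40)
        kos = frozenset(f"K{i:03d}" for i in range(40))
        assert contributor_score(kos, frozenset({"diff_pw"}), catalog, 80.0) == pytest.approx(50.0)

    def test_full_completeness_gives_raw_count(self):
        catalog = self._catalog(7)
        kos = frozenset(f"K{i:03d}" for i in range(7))
        assert contributor_score(kos, frozenset({"diff_pw"}), catalog, 100.0) == 7.0

    def test_no_qualifying_kos(self):
        catalog = self._catalog(5)
        assert contributor_score(frozenset({"K999"}), frozenset({"diff_pw"}), catalog, 90.0) == 0.0

    def test_zero_completeness_rejected(self):
        with pytest.raises(ValidationError):
            contributor_score(frozenset(), frozenset(), self._catalog(1), 0.0)


class TestUreaScreen:
    def test_default_config_statuses(self):
        cfg = load_urea_config()
        urt = cfg["urt_subunits"]
        urease = cfg["urease_structural"]
        utp = cfg["utp"]
        assert urea_screen(urt | urease, cfg).status == "full_suite"
        assert urea_screen(urease, cfg).status == "ureolysis_only"
        assert urea_screen(frozenset(list(urt)[:4]), cfg).status == "none"
        assert urea_screen(utp, cfg).status == "transport_only"
        assert urea_screen(utp | urease, cfg).status == "full_suite"

    def test_accessory_completeness_reported(self):
        cfg = load_urea_config()
        acc = sorted(cfg["urease_accessory"])
        res = urea_screen(frozenset(acc[:2]), cfg)
        assert res.accessory_fraction == pytest.approx(2 / len(acc))

    def test_malformed_config_rejected(self):
        with pytest.raises(ValidationError):
            urea_screen(frozenset(), {"urt_subunits": frozenset({"K1"})})


class TestGenomeSizeSummary:
    def test_completeness_correction(self):
        b = bin_of("b", {"c"}, completeness=50.0, size=2_000_000)
        assert community_genome_size_summary([b], {"b": 0.1}) == pytest.approx(4_000_000)

    def test_equal_abundance_mean(self):
        bins = [
            bin_of("b1", {"c1"}, completeness=100.0, size=2_000_000),
            bin_of("b2", {"c2"}, completeness=100.0, size=4_000_000),
        ]
        out = community_genome_size_summary(bins, {"b1": 0.2, "b2": 0.2})
        assert out == pytest.approx(3_000_000)

    def test_no_bins_rejected(self):
        with pytest.raises(ValidationError):
            community_genome_size_summary([], {})
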