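import numpy as np
import pandas as pd
import pytest

from autozygmap.core import HET, HOM_ALT, HOM_REF, MISSING, GenomicInterval
from autozygmap.synthetic import build_gene_fixture, build_panel_fixture
from autozygmap.variants import (
    VariantTable,
    classify_coding,
    panel_segregation_filter,
    recessive_compatible,
    restrict_to_region,
)


def _table(positions, genotypes, roster, chrom="13"):
    sites = pd.DataFrame(
        {
            "chrom": [chrom] * len(positions),
            "pos": positions,
            "ref": ["A"] * len(positions),
            "alt": ["C"] * len(positions),
            "vclass": ["SNP"] * len(positions),
        }
    )
    return VariantTable(
        sites=sites, genotypes=np.asarray(genotypes, dtype=np.int8), roster=roster
    )


@pytest.fixture()
def small_roster():
    return pd.DataFrame(
        {
            "individual": ["case1", "ctrl1", "ctrl2", "p1", "p2", "p3"],
            "cohort": ["case", "control", "control", "panel", "panel", "panel"],
            "breed": ["SwedishRed", "Fleckvieh", "BrownSwiss",
                      "Ayrshire", "Fleckvieh", "Angus"],
        }
    )


class TestRestrictToRegion:
    def test_inclusive_boundaries(self, small_roster):
        t = _table([99, 100, 500, 501], np.zeros((4, 6)), small_roster)
        region = GenomicInterval("13", 100, 500)
        kept = restrict_to_region(t, region)
        assert kept.sites["pos"].tolist() == [100, 500]

    def test_random_table_matches_recount(self, small_roster, rng):
        positions = np.sort(rng.choice(np.arange(1, 10_000), 200, replace=False))
        t = _table(positions, np.zeros((200, 6)), small_roster)
        region = GenomicInterval("13", 2_000, 7_000)
        kept = restrict_to_region(t, region)
        assert kept.n_sites == int(((positions >= 2000) & (positions <= 7000)).sum())


class TestRecessiveCompatible:
    def test_case_hom_alt_controls_hom_ref_retained(self, small_roster):
        g = [[HOM_ALT, HOM_REF, HOM_REF, HOM_REF, HOM_REF, HOM_REF]]
        t = _table([100], g, small_roster)
        kept, report = recessive_compatible(t, ["case1"], ["ctrl1", "ctrl2"])
        assert kept.n_sites == 1
        assert report.loc[0, "n_control_called"] == 2

    @pytest.mark.parametrize(
        "case_gt, ctrl1_gt",
        [(HET, HOM_REF), (HOM_REF, HOM_REF), (MISSING, HOM_REF),
         (HOM_ALT, HET), (HOM_ALT, HOM_ALT)],
    )
    def test_incompatible_sites_dropped(self, small_roster, case_gt, ctrl1_gt):
        g = [[case_gt, ctrl1_gt, HOM_REF, HOM_REF, HOM_REF, HOM_REF]]
        kept, _ = recessive_compatible(
            _table([100], g, small_roster), ["case1"], ["ctrl1", "ctrl2"]
        )
        assert kept.n_sites == 0

    def test_missing_control_is_neutral_up_to_call_fraction(self, small_roster):
        g = [[HOM_ALT, MISSING, HOM_REF, HOM_REF, HOM_REF, HOM_REF]]
        t = _table([100], g, small_roster)
        kept, _ = recessive_compatible(t, ["case1"], ["ctrl1", "ctrl2"], 0.5)
        assert kept.n_sites == 1
        kept, _ = recessive_compatible(t, ["case1"], ["ctrl1", "ctrl2"], 0.9)
        assert kept.n_sites == 0  # only 50 % of controls called

    def test_empty_case_set_errors(self, small_roster):
        t = _table([100], np.zeros((1, 6)), small_roster)
        with pytest.raises(ValueError):
            recessive_compatible(t, [], ["ctrl1"])

    def test_matches_brute_force_row_scan(self, small_roster, rng):
        n = 300
        g = rng.choice(
            [HOM_REF, HET, HOM_ALT, MISSING], size=(n, 6), p=[0.6, 0.2, 0.15, 0.05]
        ).astype(np.int8)
        t = _table(np.arange(1, n + 1) * 10, g, small_roster)
        kept, _ = recessive_compatible(t, ["case1"], ["ctrl1", "ctrl2"], 0.9)
        expected = []
        for i in range(n):
            case_ok = g[i, 0] == HOM_ALT
            ctrl = g[i, 1:3]
            called = [x for x in ctrl if x != MISSING]
            ok = (
                case_ok
                and all(x == HOM_REF for x in called)
                and len(called) >= 0.9 * 2
            )
            if ok:
                expected.append((i + 1) * 10)
        assert kept.sites["pos"].tolist() == expected

    def test_enlarging_controls_never_adds_survivors(self, small_roster, rng):
        g = rng.choice([HOM_REF, HET, HOM_ALT], size=(100, 6)).astype(np.int8)
        t = _table(np.arange(1, 101) * 5, g, small_roster)
        few, _ = recessive_compatible(t, ["case1"], ["ctrl1"])
        many, _ = recessive_compatible(t, ["case1"], ["ctrl1", "ctrl2"])
        assert set(many.sites["pos"]) <= set(few.sites["pos"])


class TestPanelSegregationFilter:
    def test_alt_only_in_excluded_breed_is_retained(self, small_roster):
        # p1 is Ayrshire (excluded); p2/p3 are not
        g = [[HOM_ALT, HOM_REF, HOM_REF, HET, HOM_REF, HOM_REF]]
        t = _table([100], g, small_roster)
        kept = panel_segregation_filter(t, excluded_breeds=("Ayrshire",))
        assert kept.n_sites == 1

    def test_alt_in_non_excluded_panel_drops_site(self, small_roster):
        g = [[HOM_ALT, HOM_REF, HOM_REF, HOM_REF, HET, HOM_REF]]
        t = _table([100], g, small_roster)
        kept = panel_segregation_filter(t, excluded_breeds=("Ayrshire",))
        assert kept.n_sites == 0

    def test_unknown_excluded_breed_warns(self, small_roster):
        t = _table([100], np.zeros((1, 6)), small_roster)
        with pytest.warns(UserWarning, match="NoSuchBreed"):
            panel_segregation_filter(t, excluded_breeds=("NoSuchBreed",))

    def test_panel_fixture_retains_42_of_77(self):
        """77 recessive-compatible sites, 35 segregating in the kept panel -> 42 survive."""
        table, model = build_panel_fixture(seed=0)
        assert table.n_sites == 77
        kept = panel_segregation_filter(
            table, excluded_breeds=("Ayrshire", "SwedishRed", "DanishRed")
        )
        assert kept.n_sites == 42
        labels = classify_coding(kept, [model])
        assert int((labels == "coding").sum()) == 1
        assert int((labels == "non-coding").sum()) == 41


class TestClassifyCoding:
    def test_cds_intron_and_untranslated_exon(self, gene_fixture):
        model, _ = gene_fixture
        exon1 = model.exons[0]
        intron_pos = model.exons[0].end + 5
        cds_pos = model.cds_start
        roster = pd.DataFrame(
            {"individual": ["x"], "cohort": ["case"], "breed": ["B"]}
        )
        t = _table([exon1.start, intron_pos, cds_pos], np.zeros((3, 1)), roster)
        labels = classify_coding(t, [model])
        assert list(labels) == ["non-coding", "non-coding", "coding"]

    def test_deletion_reaching_into_cds_is_coding(self, gene_fixture):
        model, _ = gene_fixture
        # anchor base in the intron, deleted base is the first CDS base
        roster = pd.DataFrame({"individual": ["x"], "cohort": ["case"], "breed": ["B"]})
        sites = pd.DataFrame(
            {"chrom": [model.chrom], "pos": [model.cds_start - 1],
             "ref": ["AA"], "alt": ["A"], "vclass": ["indel"]}
        )
        t = VariantTable(sites=sites, genotypes=np.zeros((1, 1), dtype=np.int8), roster=roster)
        assert list(classify_coding(t, [model])) == ["coding"]


class TestFilterComposition:
    def test_filters_commute_with_region_restriction(self, small_roster, rng):
        g = rng.choice([HOM_REF, HET, HOM_ALT], size=(150, 6), p=[0.5, 0.2, 0.3]).astype(np.int8)
        t = _table(np.arange(1, 151) * 7, g, small_roster)
        region = GenomicInterval("13", 100, 700)
        a, _ = recessive_compatible(restrict_to_region(t, region), ["case1"], ["ctrl1", "ctrl2"])
        b_full, _ = recessive_compatible(t, ["case1"], ["ctrl1", "ctrl2"])
        b = restrict_to_region(b_full, region)
        assert a.sites["pos"].tolist() == b.sites["pos"].tolist()
        np.testing.assert_array_equal(a.genotypes, b.genotypes)
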