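import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylomap.methylome_calling import (
    DEFAULT_MODALITIES,
    Methylome,
    call_methylome,
    classify_site,
    compute_site_ratio,
    crossvalidate_calls,
    intersect_methylomes,
    normalize_to_protein,
    sites_per_protein,
)
from .oracles import hypergeom_tail_oracle


class TestSiteRatio:
    @pytest.mark.parametrize(
        "L,H,ratio,log2",
        [(1000, 500, 0.5, -1.0), (800, 800, 1.0, 0.0), (100, 400, 4.0, 2.0)],
    )
    def test_closed_form(self, L, H, ratio, log2):
        r, l2 = compute_site_ratio(L, H)
        assert r == pytest.approx(ratio)
        assert l2 == pytest.approx(log2)

    def test_heavy_absent_gives_absent_ratio(self):
        r, l2 = compute_site_ratio(1000, None)
        assert math.isnan(r) and math.isnan(l2)

    def test_zero_heavy_coerced_to_absent(self):
        r, _ = compute_site_ratio(1000, 0.0)
        assert math.isnan(r)


class TestClassify:
    @pytest.mark.parametrize(
        "L,H,expected",
        [
            (1000, 500, "decreased"),  # ratio 0.5, inclusive boundary
            (1000, 510, "unchanged"),  # just above the boundary
            (1000, None, "abolished"),  # detected light-only
            (1000, 0.0, "abolished"),  # zero heavy = detector floor
            (None, 500, "not_quantified"),
            (1000, 2000, "increased"),
            (1000, 999, "unchanged"),
        ],
    )
    def test_status(self, L, H, expected):
        assert classify_site(L, H, fold_change=2.0) == expected

    @given(
        L=st.floats(min_value=1.0, max_value=1e9),
        H=st.one_of(st.none(), st.floats(min_value=0.0, max_value=1e9)),
    )
    @settings(max_examples=200, deadline=None)
    def test_total_function(self, L, H):
        assert classify_site(L, H) in {
            "not_quantified",
            "unchanged",
            "decreased",
            "abolished",
            "increased",
        }

    def test_fold_change_must_exceed_one(self):
        with pytest.raises(ValueError):
            classify_site(10, 10, fold_change=1.0)


class TestNormalize:
    def test_drop_explained_by_protein(self):
        norm, explained = normalize_to_protein(0.4, 0.4, "decreased")
        assert norm == pytest.approx(1.0)
        assert explained

    def test_genuine_methylation_drop(self):
        norm, explained = normalize_to_protein(0.4, 1.0, "decreased")
        assert norm == pytest.approx(0.4)
        assert not explained

    def test_absent_protein_ratio_retains_site(self):
        norm, explained = normalize_to_protein(0.4, None, "decreased")
        assert math.isnan(norm)
        assert not explained

    def test_zero_protein_ratio_warns(self, caplog):
        with caplog.at_level("WARNING"):
            norm, explained = normalize_to_protein(0.4, 0.0, "decreased")
        assert math.isnan(norm) and not explained


class TestCallMethylome:
    def test_hnrnpa1_rgg_sites_recovered(self, site_table, protein_table):
        m, tally = call_methylome(
            site_table, protein_table, "PRMT7", {"MMA"}, fold_change=2.0
        )
        assert m.proteins == {"hnRNPA1"}
        assert m.site_keys == {
            ("hnRNPA1", p) for p in (194, 206, 218, 225, 232)
        }
        assert tally["sites_decreased"] == 5

    def test_all_unchanged_gives_empty_methylome(self, protein_table):
        table = pd.DataFrame(
            [
                {
                    "protein": "OTHER1",
                    "position": 10,
                    "methyl_type": "MMA",
                    "intensity_L": 100.0,
                    "intensity_H": 99.0,
                }
            ]
        )
        m, tally = call_methylome(table, protein_table, "PRMT7", {"MMA"})
        assert len(m) == 0
        assert tally["sites_decreased"] == 0

    def test_protein_explained_site_excluded_but_tallied(self):
        table = pd.DataFrame(
            [
                {
                    "protein": "PX",
                    "position": 4,
                    "methyl_type": "MMA",
                    "intensity_L": 1000.0,
                    "intensity_H": 400.0,
                }
            ]
        )
        prot = pd.DataFrame(
            [{"protein": "PX", "intensity_L": 1000.0, "intensity_H": 400.0}]
        )
        m, tally = call_methylome(table, prot, "PRMT7", {"MMA"})
        assert len(m) == 0
        assert tally["sites_protein_explained"] == 1
        assert tally["proteins_protein_explained"] == 1

    def test_duplicate_sites_counted_once(self, site_table, protein_table):
        doubled = pd.concat([site_table, site_table], ignore_index=True)
        m, tally = call_methylome(doubled, protein_table, "PRMT7", {"MMA"})
        assert tally["sites_detected"] == 6
        assert len(m) == 5

    def test_modality_filter_excludes_other_types(self, protein_table):
        table = pd.DataFrame(
            [
                {
                    "protein": "PX",
                    "position": 4,
                    "methyl_type": "sDMA",
                    "intensity_L": 1000.0,
                    "intensity_H": 100.0,
                }
            ]
        )
        m, tally = call_methylome(table, protein_table, "PRMT4", {"MMA", "aDMA"})
        assert tally["sites_detected"] == 0 and len(m) == 0

    def test_tally_monotone_on_synthetic_run(self, default_sim):
        for lab in ("PRMT4", "PRMT5", "PRMT7"):
            _, tally = call_methylome(
                default_sim.methyl[lab]["sites"],
                default_sim.methyl[lab]["proteins"],
                lab,
                DEFAULT_MODALITIES[lab],
            )
            assert (
                tally["sites_detected"]
                >= tally["sites_quantified_incl_abolished"]
                >= tally["sites_decreased"]
                >= tally["sites_abolished"]
            )

    def test_normalization_neutral_when_protein_ratios_one(self, site_table):
        flat = pd.DataFrame(
            [
                {"protein": p, "intensity_L": 1e5, "intensity_H": 1e5}
                for p in site_table["protein"].unique()
            ]
        )
        with_norm, _ = call_methylome(site_table, flat, "PRMT7", {"MMA"})
        without, _ = call_methylome(site_table, None, "PRMT7", {"MMA"})
        assert with_norm.site_keys == without.site_keys


class TestIntersect:
    def _methylome(self, label, positions, protein="hnRNPA1"):
        return Methylome(
            label,
            pd.DataFrame(
                {
                    "protein": [protein] * len(positions),
                    "position": list(positions),
                    "methyl_type": ["MMA"] * len(positions),
                    "ratio_HL": [0.2] * len(positions),
                    "normalized_ratio": [np.nan] * len(positions),
                    "status": ["decreased"] * len(positions),
                    "protein_explained": [False] * len(positions),
                }
            ),
        )

    def test_hnrnpa1_position_partition(self):
        # the RGG-domain site sets reported for the three enzymes
        m4 = self._methylome("PRMT4", [206, 218, 225, 232])
        m5 = self._methylome("PRMT5", [194, 196, 206, 218])
        m7 = self._methylome("PRMT7", [194, 206, 218, 225, 232])
        res = intersect_methylomes([m4, m5, m7], level="position")
        classes = res.classes
        assert classes[3] == {("hnRNPA1", 206), ("hnRNPA1", 218)}
        assert classes[1] == {("hnRNPA1", 196)}
        assert classes[2] == {
            ("hnRNPA1", 194),
            ("hnRNPA1", 225),
            ("hnRNPA1", 232),
        }

    def test_identical_sets_all_by3(self):
        ms = [self._methylome(l, [1, 14]) for l in ("A", "B", "C")]
        res = intersect_methylomes(ms, level="position")
        assert res.class_counts() == {1: 0, 2: 0, 3: 2}

    def test_disjoint_sets_all_by1(self):
        ms = [
            self._methylome("A", [1]),
            self._methylome("B", [14]),
            self._methylome("C", [27]),
        ]
        res = intersect_methylomes(ms, level="position")
        assert res.class_counts() == {1: 3, 2: 0, 3: 0}

    def test_partition_is_complete_and_disjoint(self, default_sim):
        from methylomap.methylome_calling import call_methylome

        ms = [
            call_methylome(
                default_sim.methyl[lab]["sites"],
                default_sim.methyl[lab]["proteins"],
                lab,
                DEFAULT_MODALITIES[lab],
            )[0]
            for lab in ("PRMT4", "PRMT5", "PRMT7")
        ]
        res = intersect_methylomes(ms, level="protein")
        classes = res.classes
        union_classes = set().union(*classes.values())
        assert union_classes == set().union(*[m.proteins for m in ms])
        assert sum(len(c) for c in classes.values()) == len(union_classes)

    def test_duplicate_label_rejected(self):
        m = self._methylome("A", [1])
        with pytest.raises(ValueError, match="duplicate"):
            intersect_methylomes([m, m])


class TestSitesPerProtein:
    def test_histogram_fractions(self):
        sites = pd.DataFrame(
            {
                "protein": ["A", "B", "C", "C", "D"] + ["E"] * 8,
                "position": [1, 1, 1, 20, 1] + list(range(1, 9)),
            }
        )
        m = Methylome("X", sites)
        hist = sites_per_protein(m)
        assert hist == {1: pytest.approx(0.6), 2: pytest.approx(0.2), 8: pytest.approx(0.2)}
        assert sum(hist.values()) == pytest.approx(1.0)

    def test_empty_methylome_rejected(self):
        with pytest.raises(ValueError):
            sites_per_protein(Methylome("X", pd.DataFrame(columns=["protein", "position"])))


class TestCrossvalidate:
    def _methylome_of(self, label, proteins):
        return Methylome(
            label,
            pd.DataFrame(
                {
                    "protein": list(proteins),
                    "position": [1] * len(proteins),
                }
            ),
        )

    def test_identical_sets_fraction_one(self):
        universe = {f"U{i}" for i in range(50)}
        a = self._methylome_of("kd", set(list(universe)[:10]))
        frac, p = crossvalidate_calls(a, a, universe)
        assert frac == 1.0
        assert p < 1e-6

    def test_disjoint_sets(self):
        universe = {f"U{i}" for i in range(100)}
        items = sorted(universe)
        a = self._methylome_of("kd", items[:10])
        b = self._methylome_of("inh", items[10:20])
        frac, p = crossvalidate_calls(a, b, universe)
        assert frac == 0.0
        assert p > 0.3  # overlap of zero lies deep in the null

    def test_overlap_p_matches_enumeration_oracle(self):
        universe = {f"U{i}" for i in range(500)}
        items = sorted(universe)
        a = set(items[:20])
        b = set(items[5:20]) | set(items[100:115])  # overlap 15, |B| = 30
        ma, mb = self._methylome_of("kd", a), self._methylome_of("inh", b)
        frac, p = crossvalidate_calls(ma, mb, universe)
        assert frac == pytest.approx(15 / 20)
        assert p == pytest.approx(hypergeom_tail_oracle(15, 500, 20, 30), rel=1e-9)
        assert p == pytest.approx(1.0990590182342455e-16, rel=1e-6)

    def test_universe_must_cover_union(self):
        a = self._methylome_of("kd", {"A"})
        with pytest.raises(ValueError, match="universe"):
            crossvalidate_calls(a, a, {"B"})
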