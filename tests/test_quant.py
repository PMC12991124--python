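"""Normalization, ratio formation, and site/protein rollup."""

import numpy as np
import pandas as pd
import pytest

from cysreact.datamodel import ChannelAssignment, PlexLayout, ProteinDatabase
from cysreact.quant import (
    PeptideMappingError,
    QuantError,
    condition_ratios,
    intersect_sites,
    normalize_channels,
    rollup_proteins,
    rollup_sites,
)

from conftest import make_record


class TestNormalizeChannels:
    def test_total_method_matches_hand_arithmetic(self, two_channel_layout):
        """Column sums (600, 300), mean 450 -> factors (0.75, 1.5)."""
        records = [
            make_record("P1", "CATR", [1], {"126": 400.0, "127N": 100.0}),
            make_record("P2", "ACDEFGHIK", [], {"126": 200.0, "127N": 200.0}),
        ]
        normalized, factors = normalize_channels(records, [two_channel_layout], method="total")
        f = factors.set_index("channel")["factor"]
        assert f["126"] == pytest.approx(0.75)
        assert f["127N"] == pytest.approx(1.5)
        sums = {
            label: sum(r.intensities[label] for r in normalized) for label in ("126", "127N")
        }
        assert sums["126"] == pytest.approx(450.0)
        assert sums["127N"] == pytest.approx(450.0)

    def test_equal_sums_leave_data_unchanged(self, two_channel_layout):
        records = [
            make_record("P1", "CATR", [1], {"126": 100.0, "127N": 300.0}),
            make_record("P2", "ACDEFGHIK", [], {"126": 300.0, "127N": 100.0}),
        ]
        for method in ("total", "median"):
            normalized, factors = normalize_channels(
                records, [two_channel_layout], method=method
            )
            for before, after in zip(records, normalized):
                for label in before.intensities:
                    assert after.intensities[label] == pytest.approx(
                        before.intensities[label]
                    )

    @pytest.mark.parametrize("method", ["total", "median"])
    def test_idempotent(self, two_channel_layout, rng, method):
        records = [
            make_record(
                "P1", "CATR", [1],
                {"126": float(v1), "127N": float(v2)},
            )
            for v1, v2 in rng.lognormal(8, 1, size=(30, 2))
        ]
        once, _ = normalize_channels(records, [two_channel_layout], method=method)
        twice, _ = normalize_channels(once, [two_channel_layout], method=method)
        for a, b in zip(once, twice):
            for label in a.intensities:
                assert b.intensities[label] == pytest.approx(a.intensities[label], rel=1e-12)

    def test_zero_total_channel_is_an_error(self, two_channel_layout):
        records = [make_record("P1", "CATR", [1], {"126": 0.0, "127N": 5.0})]
        with pytest.raises(QuantError, match="zero"):
            normalize_channels(records, [two_channel_layout], method="total")

    def test_incomplete_records_do_not_bias_factors(self, two_channel_layout):
        complete = [
            make_record("P1", "CATR", [1], {"126": 300.0, "127N": 300.0}),
        ]
        with_partial = complete + [
            make_record("P2", "ACDEFGHIK", [], {"126": 1e6}),  # missing 127N
        ]
        _, f_complete = normalize_channels(complete, [two_channel_layout], method="total")
        _, f_partial = normalize_channels(with_partial, [two_channel_layout], method="total")
        pd.testing.assert_frame_equal(f_complete, f_partial)


class TestConditionRatios:
    def test_fourfold_condition_gives_log2_two(self, two_channel_layout):
        records = [make_record("P1", "CATR", [1], {"126": 100.0, "127N": 400.0})]
        ratios = condition_ratios(records, [two_channel_layout])
        row = ratios[ratios["condition"] == "D8C"].iloc[0]
        assert row["log2_ratio"] == pytest.approx(2.0)
        ref = ratios[ratios["condition"] == "D2"].iloc[0]
        assert ref["log2_ratio"] == pytest.approx(0.0)

    def test_all_channels_equal_gives_zero(self, ten_channel_layouts):
        records = [
            make_record("P1", "CATR", [1], {l: 50.0 for l in ten_channel_layouts[0].channel_labels})
        ]
        ratios = condition_ratios(records, ten_channel_layouts)
        assert np.allclose(ratios["log2_ratio"], 0.0)

    def test_condition_swap_antisymmetry(self, ten_channel_layouts):
        labels = ten_channel_layouts[0].channel_labels
        values = {l: 100.0 for l in labels}
        values.update({"128C": 400.0, "129N": 400.0})   # D4C up 4x
        values.update({"130C": 25.0, "131": 25.0})      # D8C down 4x
        records = [make_record("P1", "CATR", [1], values)]
        ratios = condition_ratios(records, ten_channel_layouts).set_index("condition")
        d4c = ratios.loc["D4C", "log2_ratio"]
        d8c = ratios.loc["D8C", "log2_ratio"]
        assert d4c == pytest.approx(-d8c) == pytest.approx(2.0)

    def test_record_without_reference_channel_is_dropped(self, two_channel_layout):
        records = [make_record("P1", "CATR", [1], {"127N": 400.0})]
        ratios = condition_ratios(records, [two_channel_layout])
        assert len(ratios) == 0

    def test_reference_is_geometric_mean_of_reference_channels(self):
        layout = PlexLayout(
            "p1",
            [
                ChannelAssignment("126", "D2", 1),
                ChannelAssignment("127N", "D2", 2),
                ChannelAssignment("127C", "D8C", 1),
            ],
        )
        # geometric mean of (100, 400) = 200; D8C 800 -> log2 ratio 2
        records = [make_record("P1", "CATR", [1], {"126": 100.0, "127N": 400.0, "127C": 800.0})]
        ratios = condition_ratios(records, [layout]).set_index("condition")
        assert ratios.loc["D8C", "log2_ratio"] == pytest.approx(2.0)


class TestRollupSites:
    def test_residue_numbering_from_first_occurrence(self, two_channel_layout, tiny_database):
        records = [make_record("P1", "CATR", [1], {"126": 100.0, "127N": 100.0})]
        ratios = condition_ratios(records, [two_channel_layout])
        sites = rollup_sites(ratios, tiny_database)
        assert set(sites["site_id"]) == {"P1_C3"}

    def test_median_of_three_peptide_forms(self, two_channel_layout):
        """Three forms covering one cysteine: site ratio is the median (1.2)."""
        db = ProteinDatabase({"P1": "AAAGGKWWCDDKLLLPPK"})
        forms = [("WWCDDK", 3, 0.8), ("AAAGGKWWCDDK", 9, 1.2), ("WWCDDKLLLPPK", 3, 3.0)]
        records = [
            make_record("P1", seq, [off], {"126": 100.0, "127N": 100.0 * 2**log2fc})
            for seq, off, log2fc in forms
        ]
        sites = rollup_sites(condition_ratios(records, [two_channel_layout]), db)
        d8c = sites[sites["condition"] == "D8C"]
        assert set(sites["site_id"]) == {"P1_C9"}
        assert d8c["log2_ratio"].iloc[0] == pytest.approx(1.2)
        assert d8c["n_peptides"].iloc[0] == 3

    def test_same_site_median_and_n_peptides(self, two_channel_layout):
        # two distinct peptide forms covering the same cysteine (missed cleavage)
        db = ProteinDatabase({"P1": "AAAGGKWWCDDKLLLPPK"})
        records = [
            make_record("P1", "WWCDDK", [3], {"126": 100.0, "127N": 100.0 * 2**0.8}),
            make_record("P1", "AAAGGKWWCDDK", [9], {"126": 100.0, "127N": 100.0 * 2**1.2}),
        ]
        ratios = condition_ratios(records, [two_channel_layout])
        sites = rollup_sites(ratios, db)
        assert set(sites["site_id"]) == {"P1_C9"}
        d8c = sites[sites["condition"] == "D8C"].iloc[0]
        assert d8c["log2_ratio"] == pytest.approx(1.0)  # median of (0.8, 1.2)
        assert d8c["n_peptides"] == 2

    def test_multi_cysteine_peptide_maps_to_composite_site(self, two_channel_layout, tiny_database):
        records = [make_record("P2", "CCDEFGHIK", [1, 2], {"126": 10.0, "127N": 10.0})]
        ratios = condition_ratios(records, [two_channel_layout])
        sites = rollup_sites(ratios, tiny_database)
        assert set(sites["site_id"]) == {"P2_C6_C7"}
        assert sites["composite"].all()

    def test_unmappable_peptide_raises_naming_it(self, two_channel_layout, tiny_database):
        records = [make_record("P1", "CCCWWW", [1], {"126": 10.0, "127N": 10.0})]
        ratios = condition_ratios(records, [two_channel_layout])
        with pytest.raises(PeptideMappingError, match="CCCWWW"):
            rollup_sites(ratios, tiny_database)

    def test_hspa9_style_fixture_only_elevated_site_exceeds_200pct(self, two_channel_layout):
        """Three cysteines; only the nucleotide-pocket one exceeds 200% of reference."""
        seq = (
            "A" * 59 + "AAACAAK"          # C ~ residue 63
            + "A" * 244 + "WWCDDK"        # C ~ residue 313
            + "A" * 43 + "GGCEEK"
        )
        db = ProteinDatabase({"HSPA9L": seq})
        c_positions = [i + 1 for i, ch in enumerate(seq) if ch == "C"]
        peptides = [("AAACAAK", 4, 1.0), ("WWCDDK", 3, 4.0), ("GGCEEK", 3, 1.1)]
        records = [
            make_record("HSPA9L", pep, [off], {"126": 100.0, "127N": 100.0 * fc})
            for pep, off, fc in peptides
        ]
        sites = rollup_sites(condition_ratios(records, [two_channel_layout]), db)
        d8c = sites[sites["condition"] == "D8C"].copy()
        d8c["pct_of_ref"] = 100 * 2 ** d8c["log2_ratio"]
        above = d8c[d8c["pct_of_ref"] > 200]
        assert len(above) == 1
        assert above["site_id"].iloc[0] == f"HSPA9L_C{c_positions[1]}"


class TestRollupProteins:
    def test_single_peptide_passthrough(self, two_channel_layout):
        records = [make_record("P1", "ACDEFGHIK", [], {"126": 100.0, "127N": 800.0})]
        proteins = rollup_proteins(condition_ratios(records, [two_channel_layout]))
        assert proteins[proteins["condition"] == "D8C"]["log2_ratio"].iloc[0] == pytest.approx(3.0)
        assert proteins["n_peptides"].iloc[0] == 1

    def test_order_invariance(self, two_channel_layout, rng):
        records = [
            make_record("P1", seq, [], {"126": 100.0, "127N": float(v)})
            for seq, v in [("AAADEFK", 300), ("CCDEFGHIK"[1:], 500), ("WWDEFK", 100)]
        ]
        fwd = rollup_proteins(condition_ratios(records, [two_channel_layout]))
        rev = rollup_proteins(condition_ratios(records[::-1], [two_channel_layout]))
        pd.testing.assert_frame_equal(fwd, rev)

    def test_median_bounded_by_inputs(self, two_channel_layout):
        values = [100.0, 900.0, 50.0, 400.0]
        records = [
            make_record("P1", f"{'ADEFGHIL'[i] * 6}K", [], {"126": 100.0, "127N": v})
            for i, v in enumerate(values)
        ]
        ratios = condition_ratios(records, [two_channel_layout])
        proteins = rollup_proteins(ratios)
        d8c = proteins[proteins["condition"] == "D8C"]["log2_ratio"].iloc[0]
        assert ratios["log2_ratio"].min() <= d8c <= ratios["log2_ratio"].max()


class TestCrossDonorRobustness:
    def test_single_corrupted_donor_cannot_move_the_median(self):
        layouts = [
            PlexLayout(
                f"p{d}",
                [ChannelAssignment("126", "D2", 1), ChannelAssignment("127N", "D8C", 1)],
            )
            for d in range(1, 6)
        ]
        db = ProteinDatabase({"P1": "AAACAAK"})
        records = []
        for d, layout in enumerate(layouts, start=1):
            fc = 2 ** (1.0 + (5.0 if d == 3 else 0.0))  # donor 3 corrupted by +5 log2
            records.append(
                make_record("P1", "AAACAAK", [4], {"126": 100.0, "127N": 100.0 * fc},
                            plex=layout.plex_id)
            )
        sites = rollup_sites(condition_ratios(records, layouts), db)
        cross_donor = sites[sites["condition"] == "D8C"]["log2_ratio"].median()
        assert cross_donor == pytest.approx(1.0)


class TestIntersectSites:
    def test_set_identities(self):
        a = pd.DataFrame({"site_id": ["s1", "s2", "s3"]})
        b = pd.DataFrame({"site_id": ["s2", "s3", "s4"]})
        both, counts = intersect_sites(a, b)
        assert both == ["s2", "s3"]
        assert counts == {"both": 2, "a_only": 1, "b_only": 1}
        assert counts["both"] + counts["a_only"] == a["site_id"].nunique()

    def test_disjoint_and_identical(self):
        a = pd.DataFrame({"site_id": ["s1"]})
        b = pd.DataFrame({"site_id": ["s9"]})
        assert intersect_sites(a, b)[0] == []
        both, counts = intersect_sites(a, a)
        assert both == ["s1"] and counts["a_only"] == 0
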