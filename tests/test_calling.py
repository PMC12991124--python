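"""Reactivity-change calling: verdict rules, tiers, and a brute-force oracle."""

import math

import numpy as np
import pandas as pd
import pytest

from cysreact.calling import CallParams, CallingError, call_reactivity, summarize_calls
from cysreact.datamodel import AnnotationSet
from cysreact.quant import condition_ratios, normalize_channels, rollup_proteins, rollup_sites
from cysreact.simulate import SimulationConfig, simulate_experiment, simulate_proteome


def site_row(site, acc, cond, plex, ratio, n_pep=3, composite=False):
    return {
        "site_id": site, "accession": acc, "composite": composite,
        "condition": cond, "plex": plex, "log2_ratio": ratio, "n_peptides": n_pep,
    }


def protein_row(acc, cond, plex, ratio, n_pep=4):
    return {
        "accession": acc, "condition": cond, "plex": plex,
        "log2_ratio": ratio, "n_peptides": n_pep,
    }


def one_call(sites, proteins, **params):
    calls = call_reactivity(
        pd.DataFrame(sites),
        pd.DataFrame(proteins) if proteins else None,
        CallParams(**params),
    )
    assert len(calls) == 1
    return calls.iloc[0]


class TestVerdictRules:
    def test_zero_raw_is_no_change(self):
        row = one_call(
            [site_row("P1_C3", "P1", "D8C", "p1", 0.0)],
            [protein_row("P1", "D8C", "p1", 0.0)],
        )
        assert row["verdict"] == "no_change"

    def test_flat_protein_shifted_site_is_reactivity_change(self):
        row = one_call(
            [site_row("P1_C3", "P1", "D8C", "p1", 1.5)],
            [protein_row("P1", "D8C", "p1", 0.0)],
        )
        assert row["verdict"] == "reactivity_change"
        assert row["direction"] == "higher"
        assert row["evidence_tier"] == "multi_peptide"
        assert row["corrected_log2fc"] == pytest.approx(1.5)

    def test_site_tracking_protein_is_expression_coupled(self):
        row = one_call(
            [site_row("P1_C3", "P1", "D8C", "p1", 1.5)],
            [protein_row("P1", "D8C", "p1", 1.4)],
        )
        assert row["verdict"] == "expression_coupled"
        assert row["corrected_log2fc"] == pytest.approx(0.1)

    def test_single_cysteine_without_proteome_is_insufficient(self):
        row = one_call([site_row("P1_C3", "P1", "D8C", "p1", 2.0, n_pep=1)], None)
        assert row["verdict"] == "insufficient_evidence"
        assert row["evidence_tier"] == "insufficient_evidence"

    def test_single_peptide_with_proteome_tier(self):
        row = one_call(
            [site_row("P1_C3", "P1", "D8C", "p1", 2.0, n_pep=1)],
            [protein_row("P1", "D8C", "p1", 0.0)],
        )
        assert row["verdict"] == "reactivity_change"
        assert row["evidence_tier"] == "single_peptide_with_proteome"

    def test_leave_one_out_median_cysteine_baseline(self):
        sites = [
            site_row("P1_C3", "P1", "D8C", "p1", 2.2, n_pep=1),
            site_row("P1_C9", "P1", "D8C", "p1", 0.1, n_pep=1),
            site_row("P1_C15", "P1", "D8C", "p1", -0.1, n_pep=1),
        ]
        calls = call_reactivity(pd.DataFrame(sites), None, CallParams())
        c3 = calls.set_index("site_id").loc["P1_C3"]
        assert c3["baseline_source"] == "median_cysteine"
        assert c3["baseline_log2fc"] == pytest.approx(0.0)
        assert c3["verdict"] == "reactivity_change"

    def test_loo_needs_two_other_sites(self):
        sites = [
            site_row("P1_C3", "P1", "D8C", "p1", 2.2, n_pep=1),
            site_row("P1_C9", "P1", "D8C", "p1", 0.1, n_pep=1),
        ]
        calls = call_reactivity(pd.DataFrame(sites), None, CallParams())
        assert (calls["verdict"] == "insufficient_evidence").all()

    def test_composite_sites_are_excluded_from_calling(self):
        sites = [
            site_row("P1_C3_C5", "P1", "D8C", "p1", 3.0, composite=True),
            site_row("P1_C9", "P1", "D8C", "p1", 0.0),
        ]
        calls = call_reactivity(
            pd.DataFrame(sites),
            pd.DataFrame([protein_row("P1", "D8C", "p1", 0.0)]),
            CallParams(),
        )
        assert set(calls["site_id"]) == {"P1_C9"}

    def test_empty_input_is_an_error(self):
        with pytest.raises(CallingError, match="empty"):
            call_reactivity(pd.DataFrame(), None, CallParams())

    def test_cross_donor_median_is_used(self):
        sites = [
            site_row("P1_C3", "P1", "D8C", p, r)
            for p, r in [("p1", 1.8), ("p2", 2.0), ("p3", 2.4), ("p4", 0.0), ("p5", 2.2)]
        ]
        row = one_call(sites, [protein_row("P1", "D8C", "p1", 0.0)])
        assert row["raw_log2fc"] == pytest.approx(2.0)
        assert row["n_donors_observed"] == 5
        assert row["n_donors_pass"] == 4

    def test_threshold_monotonicity(self):
        """Raising the fold-change threshold never creates new calls."""
        rng = np.random.default_rng(5)
        sites = [
            site_row(f"P{i}_C3", f"P{i}", "D8C", "p1", float(rng.normal(0, 1.5)))
            for i in range(60)
        ]
        proteins = [protein_row(f"P{i}", "D8C", "p1", float(rng.normal(0, 0.3))) for i in range(60)]
        called_sets = []
        for fc in (1.5, 2.0, 3.0, 4.0):
            calls = call_reactivity(
                pd.DataFrame(sites), pd.DataFrame(proteins), CallParams(fc_threshold=fc)
            )
            called_sets.append(
                set(calls.loc[calls["verdict"] == "reactivity_change", "site_id"])
            )
        for smaller, larger in zip(called_sets[1:], called_sets[:-1]):
            assert smaller <= larger


def brute_force_calls(sites, proteins, fc_threshold=2.0, min_cys_peptides=2, reference="D2"):
    """Literal re-implementation of the calling rules with plain dicts/loops."""
    thr = math.log2(fc_threshold)
    sites = sites[~sites["composite"].astype(bool)]
    conditions = sorted(c for c in set(sites["condition"]) if c != reference)
    raw = {}
    for _, r in sites.iterrows():
        raw.setdefault((r["site_id"], r["condition"]), []).append(r["log2_ratio"])
    prot = {}
    if proteins is not None:
        for _, r in proteins.iterrows():
            prot.setdefault((r["accession"], r["condition"]), []).append(r["log2_ratio"])
    prot_med = {k: float(np.median(v)) for k, v in prot.items()}
    acc_of = dict(zip(sites["site_id"], sites["accession"]))
    npep = dict(zip(sites["site_id"], sites["n_peptides"]))
    prot_pep = {}
    for s in set(sites["site_id"]):
        prot_pep[acc_of[s]] = prot_pep.get(acc_of[s], 0) + npep[s]
    out = {}
    for (site, cond), values in raw.items():
        if cond not in conditions:
            continue
        acc = acc_of[site]
        r = float(np.median(values))
        baseline = None
        if (acc, cond) in prot_med:
            baseline = prot_med[(acc, cond)]
        else:
            others = [
                float(np.median(v))
                for (s2, c2), v in raw.items()
                if c2 == cond and s2 != site and acc_of[s2] == acc
            ]
            if len(others) >= 2:
                baseline = float(np.median(others))
        if prot_pep[acc] >= min_cys_peptides:
            tier = "multi_peptide"
        elif (acc, cond) in prot_med:
            tier = "single_peptide_with_proteome"
        else:
            tier = "insufficient_evidence"
        if tier == "insufficient_evidence" or baseline is None:
            verdict = "insufficient_evidence"
        elif abs(r) >= thr and abs(r - baseline) >= thr:
            verdict = "reactivity_change"
        elif abs(r) >= thr:
            verdict = "expression_coupled"
        else:
            verdict = "no_change"
        out[(site, cond)] = (verdict, "higher" if r > 0 else ("lower" if r < 0 else ""))
    return out


class TestAgainstBruteForce:
    def test_full_synthetic_run_matches_literal_rules(self):
        cfg = SimulationConfig(seed=42, n_proteins=300)
        proteome, truth = simulate_proteome(cfg)
        enriched, unenriched, layouts = simulate_experiment(cfg, proteome, truth)
        enriched, _ = normalize_channels(enriched, layouts)
        unenriched, _ = normalize_channels(unenriched, layouts)
        sq = rollup_sites(condition_ratios(enriched, layouts), proteome.database)
        pq = rollup_proteins(condition_ratios(unenriched, layouts))
        calls = call_reactivity(sq, pq, CallParams())
        expected = brute_force_calls(sq, pq)
        assert len(calls) == len(expected)
        for row in calls.itertuples():
            verdict, direction = expected[(row.site_id, row.condition)]
            assert row.verdict == verdict, (row.site_id, row.condition)
            if verdict == "reactivity_change":
                assert row.direction == direction


class TestSummarize:
    def test_no_calls_gives_zero_table(self):
        calls = pd.DataFrame(
            [{"site_id": "P1_C3", "accession": "P1", "condition": "D8C",
              "direction": "higher", "verdict": "no_change"}]
        )
        summary = summarize_calls(calls)
        assert summary["total"].sum() == 0

    def test_counts_per_condition_and_direction(self):
        rows = []
        for i in range(3):
            rows.append({"site_id": f"A{i}_C1", "accession": f"A{i}", "condition": "D8C",
                         "direction": "higher", "verdict": "reactivity_change"})
        for i in range(2):
            rows.append({"site_id": f"B{i}_C1", "accession": f"B{i}", "condition": "D8C",
                         "direction": "lower", "verdict": "reactivity_change"})
        summary = summarize_calls(pd.DataFrame(rows))
        row = summary.set_index("condition").loc["D8C"]
        assert (row["higher"], row["lower"], row["total"]) == (3, 2, 5)

    def test_partitioning_classes_conserve_totals(self):
        rows = [
            {"site_id": f"P{i}_C1", "accession": f"P{i}", "condition": "D8C",
             "direction": "higher", "verdict": "reactivity_change"}
            for i in range(6)
        ]
        ann = AnnotationSet(
            {"evens": {f"P{i}" for i in range(0, 6, 2)},
             "odds": {f"P{i}" for i in range(1, 6, 2)}}
        )
        summary = summarize_calls(pd.DataFrame(rows), ann).set_index("class")
        assert (
            summary.loc["evens", "total"] + summary.loc["odds", "total"]
            == summary.loc["all", "total"]
        )
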