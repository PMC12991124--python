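"""ATP add-back: find nucleotide-occluded cysteines and state-specific losses.

Simulates a 16-plex add-back experiment (D2/D8A/D8C x control/+ATP, two
donors) in which occluded sites lose probe labeling upon ATP only in
chronically stimulated (D8C) cells, then applies the within-state two-fold
rule and the cross-state ratio-of-fold-change rule, and tests whether hits
are enriched for nucleotide-binding proteins.
"""

from cysreact import (
    SimulationConfig,
    call_ligand_sensitivity,
    class_enrichment,
    cross_state_sensitivity,
    simulate_atp_addback,
    simulate_proteome,
)

cfg = SimulationConfig(seed=1, n_proteins=300, atp_class_odds=25.0, planted_atp=(0.10, 2.0))
proteome, truth = simulate_proteome(cfg)
records, layouts = simulate_atp_addback(cfg, proteome, truth)

calls = call_ligand_sensitivity(records, layouts, proteome.database, threshold=2.0)
sensitive = calls[calls["sensitive"] & (calls["direction"] == "decreased")]
print("ATP-sensitive (two-fold labeling loss) site-states per state:")
print(sensitive.groupby("state").size().to_string())

cross = cross_state_sensitivity(calls, "D8C", "D2", threshold=2.0)
flagged = cross[cross["flagged"]]
print(f"\nsites with D8C-vs-D2 differential ATP response: {len(flagged)} "
      f"of {len(cross)} quantified in both states")

hits = sorted(set(flagged["accession"]))
background = sorted(set(cross["accession"]))
enrich = class_enrichment(hits, background, proteome.annotations).set_index("class_name")
row = enrich.loc["nucleotide_binding"]
print(f"nucleotide_binding enrichment among hits: OR {row['odds_ratio']:.1f}, "
      f"one-sided p {row['p_one_sided']:.2e}")
# an odds ratio far above 1 with small p reproduces the expected pattern:
# ATP-occluded reactivity losses concentrate in nucleotide-binding proteins
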