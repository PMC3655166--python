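"""Assemble the candidate marker panel along the three routes.

Tissue route: FDR q < 0.025 up-regulation in both disease datasets +
consensus-network membership + clustering coefficient >= 0.25. Blood
route: unadjusted p < 0.05 up-regulation in blood, expression above the
lower 25th quantile, positive fold change in both tissue datasets.
Curated route: a literature list taken verbatim. The union is screened for
PCR detectability (CT < 40 cycles in >= 80% of screening samples).
"""

import warnings

import coexmark as cm

cohort = cm.generate_cohort(cm.SimulationConfig(seed=1))
net = cm.consensus_network(cohort.tissue_a, cohort.tissue_b,
                           cohort.background, threshold=0.8)
topo = cm.clustering_coefficients(net)

de_a = cm.differential_expression(cohort.tissue_a)
de_b = cm.differential_expression(cohort.tissue_b)
de_blood = cm.differential_expression(cohort.blood)

truth = cohort.truth
tissue = cm.tissue_route(de_a, de_b, net, topo, allowlist=truth.tissue_allowlist)
blood = cm.blood_route(de_blood, de_a, de_b, cohort.blood,
                       allowlist=truth.blood_allowlist)
print("tissue route:", len(tissue), "genes")
print("blood route:", len(blood), "genes")
print("curated route:", len(truth.curated_panel), "genes")

panel = cm.assemble_panel(tissue, blood, truth.curated_panel)
print("candidate panel:", len(panel), "genes")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    screened = cm.detectability_screen(panel, cohort.ct_tables["train"])
print("detectable in blood:", len(screened), "genes")

# the shipped reference panel fixture (51 transcript symbols)
print("\nreference panel:", len(cm.load_reference_panel()), "symbols, e.g.",
      cm.load_reference_panel()[:5])
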