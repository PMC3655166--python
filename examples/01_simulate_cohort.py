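"""Generate a synthetic multi-cohort study with planted structure.

The cohort contains two disease tissue datasets sharing planted
disease-specific co-expression modules, background datasets with generic
modules, a blood transcriptome, three qPCR CT cohorts and a single-analyte
comparator — everything the pipeline consumes, with ground truth attached.
"""

import coexmark as cm

cohort = cm.generate_cohort(cm.SimulationConfig(seed=1))

print("tissue A:", cohort.tissue_a.values.shape, "(genes x samples)")
print("tissue B:", cohort.tissue_b.values.shape)
print("background datasets:", [ds.name for ds in cohort.background])
print("blood:", cohort.blood.values.shape)
for name, table in cohort.ct_tables.items():
    counts = table.labels.value_counts().to_dict()
    print(f"CT cohort {name}: {table.ct.shape[1]} samples {counts}")
print("analyte samples:", len(cohort.analyte_values))

truth = cohort.truth
print("\nplanted truth:")
print("  disease-module genes:", len(truth.disease_genes))
print("  blood-elevated markers:", len(truth.blood_allowlist))
print("  candidate panel:", len(truth.panel_genes),
      "-> detectable:", len(truth.detectable_genes),
      "-> carrying the CT shift:", len(truth.informative_genes))
# Disease modules are correlated only in tissue A/B; generic modules
# everywhere. The detectable/informative split mirrors a real assay screen.
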