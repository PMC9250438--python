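"""Type-I error of the module scan on null cohorts.

Twenty replicate cohorts with no injected enrichment (every odds ratio
1): the fraction of modules reaching P < 0.05 estimates the scan's
per-module type-I error.  Because the exact test is discrete and module
carrier counts are small, the realised rate sits well below the nominal
5% - the scan is conservative, never anti-conservative.
"""

import numpy as np

from metamod import EnrichmentConfig, SimConfig, run_enrichment, simulate_cohort
from metamod.synthetic import matrix_from_truth

genes = {f"G{i:02d}": float(p) for i, p in enumerate(np.geomspace(0.005, 0.15, 20))}

rejected = tested = 0
for rep in range(20):
    config = SimConfig(
        cancer_type="NULL", n_metastatic=1000, n_early=1000, genes=genes,
        enriched_modules=[], msi_h_fraction=0.0, seed=900 + rep,
    )
    _, _, truth = simulate_cohort(config)
    results = run_enrichment(
        matrix_from_truth(truth), list(genes), EnrichmentConfig(max_module_size=2)
    )
    rejected += sum(r.p_value < 0.05 for r in results)
    tested += len(results)

print(f"{tested} module tests across 20 null cohorts")
print(f"rejection rate at P < 0.05: {rejected / tested:.4f} (nominal 0.05)")
print()
print("a rate at or below 0.05 means the scan does not manufacture")
print("metastasis biomarkers out of noise; the shortfall reflects the")
print("discreteness of exact tests at low carrier counts.")
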