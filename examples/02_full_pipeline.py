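"""Run the full two-stage pipeline and print the declared QTL report.

Stage 1 scans the genome with a random-effect mixed model; stage 2 puts
all the scan peaks into one empirical-Bayes multi-locus model, screens the
shrunken effects with an F-test at 0.01, declares survivors at LOD >= 2.5,
corrects the phenotype by the declared effects and repeats once.
"""

from gcim import (
    SimulationConfig,
    fill_expected,
    gcim_full,
    insert_pseudo_markers,
    simulate,
)

cfg = SimulationConfig(
    n=400,
    chrom_length=1000.0,
    marker_spacing=5.0,
    qtl=((250.0, 0.10), (620.0, 0.05), (640.0, 0.04)),
    seed=2,
)
data = simulate(cfg)
grid = insert_pseudo_markers(data.gmap, 1.0)
filled = fill_expected(data.geno, grid)

result = gcim_full(data.y, filled, grid)
print(f"stage 1 candidates (curve peaks): {len(result.candidates)}")
print(f"stage 2 F-screen survivors:      {result.n_screened}")
print("\ndeclared QTL:")
print(
    result.report[["position_cM", "marker_interval", "effect", "lod", "r2_percent"]]
    .to_string(index=False)
)
print("\ntrue QTL:")
print(data.truth[["position_cM", "effect", "r2"]].to_string(index=False))
print(
    "\nThe two linked QTL at 620 and 640 cM (20 cM apart) are the hard case\n"
    "the multi-locus second stage exists for: a single-locus method tends to\n"
    "merge them into one misplaced signal."
)
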