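"""Simulate a backcross population and run the single-locus genome scan.

A small population (n=200) with one QTL at 320 cM explaining 15% of the
phenotypic variance; the scan fits the polygenic background once via the
marker kinship matrix and tests every true and pseudo locus.
"""

import numpy as np

from gcim import (
    SimulationConfig,
    fill_expected,
    genome_scan,
    insert_pseudo_markers,
    simulate,
)

cfg = SimulationConfig(
    n=200, chrom_length=600.0, marker_spacing=5.0, qtl=((320.0, 0.15),), seed=4
)
data = simulate(cfg)
grid = insert_pseudo_markers(data.gmap, 1.0)
filled = fill_expected(data.geno, grid)

scan = genome_scan(filled, grid, data.y)
print(f"scan grid: {grid.n_loci} loci ({int(grid.is_pseudo.sum())} pseudo)")
print(f"polygenic variance ratio lambda = {scan.lambda0:.4f}")

top = scan.table.nlargest(3, "neglog10p")[
    ["position_cM", "effect", "wald", "neglog10p"]
]
print("\nstrongest scan positions:")
print(top.to_string(index=False))
print(
    "\nThe -log10 p curve peaks at the simulated QTL position (320 cM); the\n"
    "effect column is the shrunken (BLUP) estimate of the allele-substitution\n"
    "effect, close to the simulated value "
    f"{np.sqrt(0.15 * 10 / 0.85):.3f}."
)
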