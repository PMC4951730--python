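# gcim — genome-wide composite interval mapping for BC/DH populations

`gcim` maps quantitative trait loci (QTL) in backcross (BC) and
doubled-haploid (DH) populations, where every locus has exactly two
genotype classes. Classical composite interval mapping controls the
genetic background by picking marker co-factors, and its results depend
on how those co-factors are chosen — especially for small-effect and
closely linked QTL. `gcim` instead controls the background the way mixed
model association studies do, and then resolves individual QTL with a
multi-locus shrinkage model:

**Stage 1 — random-effect genome scan.** For phenotypes *y* and a locus
code *z<sub>k</sub>* ∈ {+1, −1} (conditional expectations at pseudo and
missing positions), the model is

> y = Xα + z<sub>k</sub>γ<sub>k</sub> + ξ + ε,  γ<sub>k</sub> ~ N(0, φ<sub>k</sub>²),  ξ ~ N(0, Kφ²),  ε ~ N(0, Iσ²)

with K the marker-inferred kinship matrix. The polygenic ratio
λ = φ²/σ² is estimated once by REML under the pure polygenic model and
frozen (the P3D shortcut); the eigen-decomposition K = UΔU′ turns every
per-locus fit into a rank-one problem solved by Newton iteration in the
locus ratio λ<sub>k</sub> = φ<sub>k</sub>²/σ². Each locus gets a BLUP
effect, a Wald statistic and a p-value; pseudo markers inserted every
*d* cM (default 1) make the scan cover the whole genome.

**Stage 2 — empirical-Bayes multi-locus model.** Every peak of the
−log₁₀ p curve enters one model y = Xα + Σ z<sub>k</sub>γ<sub>k</sub> + ε
with per-effect prior variances estimated by EM (Xu-style empirical
Bayes). Null candidates shrink to zero; survivors of an F-test at 0.01
face a drop-one likelihood-ratio test and are declared QTL at
LOD ≥ 2.5 (p ≤ 0.000691). Declared effects are subtracted from the
phenotype and the whole procedure runs once more to pick up masked
signals.

The package also contains the Monte Carlo machinery used to evaluate the
method: a BC genotype/phenotype simulator with four preset experiments
(20 additive QTL; plus polygenic background; plus epistatic background;
pure noise) and power / false-positive-rate / MAD / MSE scoring.

## Worked example

```python
from gcim import (SimulationConfig, simulate, insert_pseudo_markers,
                  fill_expected, gcim_full)

cfg = SimulationConfig(n=400, chrom_length=1000.0, marker_spacing=5.0,
                       qtl=((250.0, 0.10), (620.0, 0.05), (640.0, 0.04)),
                       seed=2)
data = simulate(cfg)
grid = insert_pseudo_markers(data.gmap, 1.0)        # 1 cM scan grid
filled = fill_expected(data.geno, grid)             # conditional expectations
result = gcim_full(data.y, filled, grid)
print(result.report[["position_cM", "marker_interval", "effect", "lod",
                     "r2_percent"]])
```

prints

```
 position_cM marker_interval   effect       lod  r2_percent
       250.0           m0050 1.300782 13.893209   11.506992
       616.0     m0123~m0124 1.118676 10.438321    8.197499
       645.0           m0129 0.465982  2.897316    1.477028
```

Three QTL were simulated at 250, 620 and 640 cM with effects 1.11, 0.79
and 0.70; all three are declared, including the closely linked pair 20 cM
apart — the case single-locus methods tend to merge into one misplaced
signal. `effect` is the empirical-Bayes estimate of the
allele-substitution effect, `lod` the drop-one LOD score, and
`r2_percent` the fraction of phenotypic variance explained. The scripts
in `examples/` run this and two other scenarios end to end.

A thin command-line interface mirrors the library:

```bash
gcim simulate --experiment I --n 400 --seed 1 --out sim/
gcim full --map sim/map.csv --geno sim/geno.csv --pheno sim/pheno.csv --out run/
```

writing the scan curve, the candidate list and the QTL report as CSV.

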