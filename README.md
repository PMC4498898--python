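# meiocross

Simulation and statistics for meiotic crossover (CO) control in a
five-chromosome plant genome (Arabidopsis-like).  The package is aimed at
plant meiosis and recombination researchers who want to (a) simulate
meioses under wild-type and anti-CO-mutant regimes — genotypes in which
the interference-insensitive class II crossover pathway is released
(*figl1*, *fancm*), the interference-sensitive class I pathway is lost
(*zmm*), or recombination is abolished (*sds*, *spo11*) — and (b) run the
standard genetic analyses on tetrad and F2 data, simulated or real.

## The models and statistics

**Simulator.** Class I COs follow a stationary gamma-renewal process on
the genetic coordinate with shape ν (ν = 1 is the no-interference
Poisson limit) at a bivalent-level rate of 2 events per Morgan, with an
optional obligate-CO constraint (resample until ≥ 1 event per bivalent).
Class II COs are Poisson with a per-bivalent mean, positions uniform on
the genetic coordinate.  Each CO involves one chromatid of each homolog,
drawn uniformly (no chromatid interference); the four meiotic products
are the paths through the resulting junction graph, so 2:2 segregation
holds at every position.  A chromosome pair with ≥ 1 CO is a bivalent at
metaphase I; a CO-free pair yields two univalents.

**Tetrad statistics.** For pollen tetrads scored at three linked
fluorescent markers (intervals I1 = m1–m2, I2 = m2–m3), tetrads are
classified into the 12 classes A–L, and per interval into parental
ditype / tetratype / non-parental ditype.  Genetic distance uses the
Perkins equation

    D = 100 · (t + 6n) / 2   cM,   t = T/N,  n = NPD/N,

with a delta-method sampling variance, compared across genotypes by
Z-tests.  Interference is quantified by the Interference Ratio
IR = D₁/D₂ (distance of one interval among tetrads with vs. without a
CO in the adjacent interval; χ² homogeneity test of D₁ = D₂) and by the
Coefficient of Coincidence CoC = f_o(2CO)/[f_e(CO_I1)·f_e(CO_I2)]
(χ² test of observed vs. expected double-CO counts).

**F2 landscape analysis.** From a plants × markers codominant genotype
matrix: per-plant CO counts (genotype transitions, AA↔BB counting 2),
Welch two-sided t-tests between genotypes, per-interval
recombinant-chromatid counts, Kosambi maps
d = 25·ln((1+2r)/(1−2r)) with cM/Mb profiles, and comparison of pooled
recombinant counts in ~5 Mb super-intervals by 2×2 χ² with genome-wide
Benjamini–Hochberg control (`**` = 5% FDR, `***` = 1% FDR).

## Worked example

```python
import numpy as np
import meiocross as mc

genome, model, panel = mc.ftl_interval_model(10.0, 10.0, nu=5.0)
patterns = mc.simulate_tetrads(5000, genome, model, panel, np.random.default_rng(2))
counts = mc.TetradClassCounts.from_patterns(patterns, genotype="wild_type")
report = mc.tetrad_report([counts])
print(report[["D_I1_cM", "D_I2_cM", "IR_I1_given_I2", "CoC"]].round(3))
```

prints

```
   D_I1_cM  D_I2_cM  IR_I1_given_I2    CoC
0     9.85    10.06           0.061  0.076
```

Both intervals were simulated at a true size of 10 cM and the Perkins
estimates recover them (9.85 and 10.06 cM, SE ≈ 0.28).  With strong
interference (ν = 5) a CO in one interval almost eliminates COs in its
neighbour, so the Interference Ratio and the Coefficient of Coincidence
are far below 1 (their χ² p-values in the full report are ≪ 0.01);
rerunning with `nu=1.0` gives IR and CoC statistically compatible
with 1.

The same analyses run from the shell on CSV files:

```sh
meiocross simulate-tetrads --n 2000 --preset figl1 --seed 4 --out figl1.tetrads.csv
meiocross analyze-tetrads  --input figl1.tetrads.csv --out figl1.report.csv
meiocross run --config examples/demo_config.yaml --out scratch/demo
```

The `run` pipeline simulates wild-type and *figl1* F2 populations,
writes their genotype matrices, Kosambi interval maps and the
super-interval χ²/FDR comparison; outputs embed the seed and parameter
echo as `#` header lines, and the same config + seed reproduce
byte-identical files.

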