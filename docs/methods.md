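# Methods

## Crossover model

Each meiosis places crossovers (COs) independently on the five
bivalents.  Two pathways are superimposed:

**Class I (interference-sensitive).**  Event locations on the genetic
coordinate follow a *stationary gamma-renewal process*: inter-event gaps
are Gamma(ν, θ) with shape ν ≥ 1 and mean 1/λ, where the bivalent-level
rate is λ = 2 events per Morgan of gamete map length (so a chromosome
with a 100 cM map carries on average 2 class I COs per bivalent and 1
per gamete).  ν = 1 reduces to a Poisson process (no interference);
larger ν spaces events apart.  Stationarity is sampled exactly for any
real ν via the length-biased construction: the gap covering the origin
is Gamma(ν + 1, θ) and the origin sits uniformly inside it, so the first
event lies at U·Gamma(ν + 1, θ).  The gamma-renewal counting model is
the field-standard phenomenological description of CO interference; it
is not mechanistic.

**Obligate CO.**  With the obligate flag, whole event sets are
resampled until at least one event occurs (rejection sampling, count
recorded).  This matches the observed near-universal "obligate
chiasma" of wild-type bivalents exactly at the level of the invariant
it serves (every bivalent has ≥ 1 CO) at the price of inflating the
realized map length relative to the nominal rate — which is why
parameter-recovery studies in the test suite switch it off.

**Class II (interference-free).**  Counts are Poisson with mean
`class2_mean_per_bivalent × class2_multiplier × fancm_factor`;
positions are uniform on the genetic coordinate.  The physical
landscape (below) then shapes both classes identically.

**Chromatid choice.**  Every CO involves one chromatid of each homolog,
drawn uniformly among the four pairs and independently across events
(no chromatid interference).  The four meiotic products are computed by
treating the events as junctions between the *original* chromatid
molecules and following the paths through the junction graph from left
to right (a junction on molecules (x, y) swaps the two paths currently
travelling on x and y).  This concurrent-resolution bookkeeping — as
opposed to applying exchanges sequentially to already-recombined
contents — is what makes a three-strand double CO a tetratype in both
intervals, reproduces the classical 1 PD : 2 T : 1 NPD ratio for double
COs in one interval, preserves 2:2 segregation at every position, and
keeps the Perkins estimator unbiased (E[D] = 50·E[events]).

## Genome, landscape and markers

The default genome has five chromosomes with Arabidopsis-like physical
lengths (30.4, 19.7, 23.5, 18.6, 27.0 Mb) and centromere intervals.
The recombination landscape is piecewise constant: relative intensity 1
on the arms and 0.05 inside the centromere interval (configurable;
1 disables suppression), emulating low pericentromeric recombination.
The landscape defines the genetic↔physical coordinate mapping used to
place events in Mb.  Marker panels are either an FTL triple (three
pollen-expressed fluorescent markers on one chromosome, defining
intervals I1 and I2) or a codominant SNP grid (default spacing 1.5 Mb,
optionally flush with the telomeres for full map coverage).

## Genotype presets (phenomenological calibration)

The wild type uses a 330 cM total class I map (split across chromosomes
proportionally to physical length), ν = 5, obligate CO on, and a class
II mean of 0.30 per bivalent — together ≈ 8 detectable COs per F2
plant, the right scale for Arabidopsis.  Mutants override intensities:

| preset        | class I | class II mean | notes |
|---------------|---------|---------------|-------|
| `wild_type`   | 330 cM  | 0.30          | |
| `zmm`         | 0       | 0.30          | bivalents ≈ 5(1−e^−0.3) ≈ 1.3 per meiosis |
| `figl1`       | 330 cM  | ×5            | released class II, never attenuated |
| `fancm`       | 330 cM  | ×10           | excess attenuated ×0.1 in hybrids |
| `figl1_fancm` | 330 cM  | ×50           | multiplicative composition |
| `sds`/`spo11` | 0       | 0             | 10 univalents |

The per-interval magnitudes are calibration choices, not measured
constants: the multipliers are set so a typical interval (≈ 18% class
II in the wild type) increases ≈ 1.7× in `figl1` and ≈ 2.7× in `fancm`
inbreds, while the `fancm` hybrid attenuation (0.1 on the excess)
reduces its effect to tens of percent.  The double mutant composes the
two multipliers, which guarantees the qualitative ordering
wild type < single mutants < double mutant but overstates the double
mutant's absolute increase; only the ordering should be read
biologically.  Hybrid attenuation is a single multiplicative factor on
the *fancm*-released excess — phenomenological, silent on mechanism.

## Tetrad statistics

A tetrad at three linked dominant markers is the unordered multiset of
four presence/absence haplotypes; 2:2 segregation is validated on
input.  Brute-force enumeration over 0–2 COs per interval and all
chromatid assignments yields exactly 12 distinguishable patterns — the
classes A–L — and adding 3-CO configurations creates none.  Of the
(T,T) type there are four distinguishable patterns (two-strand;
three-strand in two mirror forms; four-strand) and of (NPD,NPD) exactly
one; the letter table in `meiocross.tetrads` assigns
D/E/F/G to the four (T,T) patterns and L to (NPD,NPD), which satisfies
the fixed class-membership sets (CO-in-I1 = {C,D,E,F,G,I,J,K,L},
CO-in-I2 = {B,D,E,F,G,H,J,K,L}, both = {D,E,F,G,J,K,L}) exactly.  Any
alternative table consistent with those sets can be supplied.

Perkins distance D = 100(t + 6n)/2 cM.  Its variance is the delta
method on the multinomial (PD, T, NPD) proportions,
Var(D) = [50²·t(1−t) + 300²·n(1−n) − 2·50·300·t·n]/N, cross-checked
against a multinomial bootstrap (agreement within 5% at N = 1000).
Z-tests use these variances (the choice of delta method over pooled
variances is a package decision; a bootstrap option exists for
cross-checking).  The IR χ² is a 2×3 homogeneity test on the
(subpopulation × PD/T/NPD) table — homogeneity implies D₁ = D₂ and is
the natural count-level null; all-zero columns are dropped first.  The
CoC χ² is a df = 1 observed-vs-expected test on double-CO counts
without continuity correction, with an exact binomial fallback when
the expected count is below 5.  Zero denominators and empty
subpopulations are flagged rather than raised.

## F2 conventions

Per-plant CO counts sum the absolute genotype-dose changes between
consecutive non-missing calls within each chromosome (AA↔AB = 1,
AA↔BB = 2); missing calls are skipped, scoring the transition across
the gap (an alternative would drop such plants; gap-skipping keeps more
data and is exact when at most one CO falls in the gap).  Interval
recombinant chromatids are |dose_left − dose_right| per plant with
het↔het pairs scored 0: without phase the two double-recombinant AB/AB
configurations are indistinguishable from the non-recombinant one.
This biases r̂ down by r²/2 per interval (≈ 3–4% of the map at 1.5 Mb
spacing), quantified in the parameter-recovery tests and covered by
their 10% tolerance.  Maps use Kosambi's function
d = 25·ln((1+2r)/(1−2r)); r ≥ 0.5 is clipped with a warning.
Super-intervals merge adjacent intervals greedily left-to-right until
≥ 5 Mb, the terminal remainder joining the previous group.  Comparisons
are 2×2 χ² on pooled recombinant/non-recombinant chromatids (Fisher's
exact test when an expected cell < 5), with Benjamini–Hochberg applied
genome-wide across all super-intervals in one family and reported at
5% and 1% FDR tiers.  Welch's unequal-variance t-test is used for
per-plant counts (two-sided); two zero-variance groups use the limit
convention p = 1 (equal means) / p = 0.

## What the simulations do and do not show

The generator reproduces the study-design features that the statistics
rely on — qrt-style tetrads with three linked fluorescent markers, F2
selfing progeny on a ~1.5 Mb codominant grid, obligate class I COs with
interference, interference-free class II COs, centromere-suppressed
landscapes, and mutant presets — under idealized conditions: no
genotyping error, no segregation distortion, no marker dropout beyond
missing-completely-at-random, no DSB/repair mechanism (presets scale
intensities only), and no chromatid interference.  Passing
parameter-recovery and calibration tests therefore validates the
estimators and their sampling distributions under the declared model,
not the biological magnitudes of real mutants.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen so sampling error
is well inside the asserted tolerances: 1,000–10,000 meioses for
bivalent counts, 5,000 tetrads for Perkins recovery (3 SE), 2,000
plants for 100 cM map recovery (10%, absorbing the het↔het bias),
1,000 replicates for type-I-error calibration (binomial 99% bounds),
20,000 bootstrap draws for the SE cross-check.  All randomness flows
from one `numpy.random.Generator` per run, seeded explicitly; seeds are
echoed in every output header.  Ties and degenerate inputs: zero-total
tetrad tables are refused; empty IR subpopulations, zero CoC marginals
and r ≥ 0.5 are flagged/clipped with warnings rather than errors;
duplicate marker positions are rejected.

## Known limitations

Class II uniformity on the genetic coordinate means the two CO classes
share one landscape shape; a class-specific landscape would need a
second intensity track.  The obligate constraint conditions the whole
event set, slightly distorting inter-event spacing relative to a
conditional renewal construction.  The F2 analysis deliberately
implements direct counting + Kosambi rather than multipoint/EM map
estimation or an error-correcting HMM; with real (error-prone)
genotyping data its map lengths will be inflated by miscalls.
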