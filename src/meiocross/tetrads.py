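"""Three-marker tetrad classification and tetrad-based recombination statistics.

A tetrad scored at three linked dominant (fluorescent) markers is the
unordered multiset of the four grains' presence/absence haplotypes.
Under 2:2 segregation exactly 12 distinguishable patterns exist — the
classes A to L.  For each of the two adjacent intervals (I1 = m1–m2,
I2 = m2–m3) a tetrad is a parental ditype (PD, 0 recombinant spores),
tetratype (T, 2) or non-parental ditype (NPD, 4).

Statistics implemented:

* Perkins genetic distance ``D = 100 * (t + 6 * n) / 2`` cM with ``t``
  and ``n`` the tetratype and NPD frequencies, with a delta-method
  sampling variance on the multinomial (PD, T, NPD) proportions.
* Z-tests comparing two Perkins distances.
* Interference Ratio ``IR = D1 / D2``: the distance of one interval
  among tetrads with (D1) versus without (D2) a crossover in the
  adjacent interval, with a 2x3 chi-square homogeneity test of
  H0: D1 = D2 at the count level.
* Coefficient of Coincidence
  ``CoC = f_o(2CO) / (f_e(CO_I1) * f_e(CO_I2))`` with a one-cell
  chi-square (df = 1) of observed versus expected double-crossover
  tetrad counts (exact binomial fallback when the expected count is
  small).

Letter table (the field's three-colour scheme fixes three class sets:
crossover-in-I1 = {C,D,E,F,G,I,J,K,L}, crossover-in-I2 =
{B,D,E,F,G,H,J,K,L}, both = {D,E,F,G,J,K,L}; within those constraints
this package uses):

====== ========= ========= =========================================
class  I1 type   I2 type   extra rule
====== ========= ========= =========================================
A      PD        PD
B      PD        T
C      T         PD
D      T         T         2 shared recombinant spores (two-strand)
E      T         T         1 shared; double recombinant carries m1
F      T         T         1 shared; double recombinant lacks m1
G      T         T         0 shared (four-strand)
H      PD        NPD
I      NPD       PD
J      T         NPD
K      NPD       T
L      NPD       NPD
====== ========= ========= =========================================

Any alternative table consistent with the three class sets can be
supplied via the ``table`` argument of :func:`classify_tetrad`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import sqrt

import numpy as np
from scipy import stats

from .errors import InputError, InvalidTetradError

__all__ = [
    "Haplotype",
    "Pattern",
    "canonical_pattern",
    "interval_tetrad_type",
    "classify_tetrad",
    "enumerate_tetrad_classes",
    "validate_class_table",
    "CLASS_LETTERS",
    "CO_I1_CLASSES",
    "CO_I2_CLASSES",
    "DOUBLE_CO_CLASSES",
    "I1_TYPE",
    "I2_TYPE",
    "IntervalTypeCounts",
    "TetradClassCounts",
    "GeneticDistanceEstimate",
    "interval_counts_from_classes",
    "perkins_distance",
    "perkins_bootstrap_se",
    "z_test_distances",
    "InterferenceRatioResult",
    "interference_ratio",
    "CoincidenceResult",
    "coefficient_of_coincidence",
    "tetrad_report",
]

Haplotype = tuple[int, int, int]
Pattern = tuple[Haplotype, Haplotype, Haplotype, Haplotype]

CLASS_LETTERS = tuple("ABCDEFGHIJKL")

#: Classes with at least one crossover in I1 / I2 / both.
CO_I1_CLASSES = frozenset("CDEFGIJKL")
CO_I2_CLASSES = frozenset("BDEFGHJKL")
DOUBLE_CO_CLASSES = frozenset("DEFGJKL")

#: Tetrad type (PD/T/NPD) of each class for each interval.
I1_TYPE = {
    "A": "PD", "B": "PD", "C": "T", "D": "T", "E": "T", "F": "T",
    "G": "T", "H": "PD", "I": "NPD", "J": "T", "K": "NPD", "L": "NPD",
}
I2_TYPE = {
    "A": "PD", "B": "T", "C": "PD", "D": "T", "E": "T", "F": "T",
    "G": "T", "H": "NPD", "I": "PD", "J": "NPD", "K": "T", "L": "NPD",
}

_INTERVAL_LOCI = {"I1": (0, 1), "I2": (1, 2)}


def canonical_pattern(haplotypes) -> Pattern:
    """Canonical (sorted) form of a four-haplotype tetrad pattern.

    Validates shape, binary alleles and 2:2 segregation at each locus.
    """
    haps = [tuple(int(a) for a in h) for h in haplotypes]
    if len(haps) != 4 or any(len(h) != 3 for h in haps):
        raise InvalidTetradError("a tetrad pattern is four haplotypes over three loci")
    if any(a not in (0, 1) for h in haps for a in h):
        raise InvalidTetradError("alleles must be 0/1 presence bits")
    for locus in range(3):
        if sum(h[locus] for h in haps) != 2:
            raise InvalidTetradError(f"2:2 segregation violated at locus {locus + 1}")
    return tuple(sorted(haps, reverse=True))  # type: ignore[return-value]


def interval_tetrad_type(pattern, interval: str) -> str:
    """PD, T or NPD for one interval of a tetrad pattern."""
    if interval not in _INTERVAL_LOCI:
        raise InputError("interval must be 'I1' or 'I2'")
    i, j = _INTERVAL_LOCI[interval]
    pattern = canonical_pattern(pattern)
    recombinants = sum(1 for h in pattern if h[i] != h[j])
    types = {0: "PD", 2: "T", 4: "NPD"}
    if recombinants not in types:
        raise InvalidTetradError(
            f"{recombinants} recombinant spores in {interval}: violates 2:2 segregation"
        )
    return types[recombinants]


def classify_tetrad(pattern, table: dict[Pattern, str] | None = None) -> str:
    """Class letter (A–L) of a tetrad pattern.

    With ``table`` given (a mapping from canonical pattern to letter,
    checked by :func:`validate_class_table`), classification is a
    lookup; otherwise the rule-based default table documented in the
    module docstring is applied.
    """
    pattern = canonical_pattern(pattern)
    if table is not None:
        try:
            return table[pattern]
        except KeyError:
            raise InvalidTetradError(f"pattern {pattern} not in supplied class table") from None
    t1 = interval_tetrad_type(pattern, "I1")
    t2 = interval_tetrad_type(pattern, "I2")
    simple = {
        ("PD", "PD"): "A", ("PD", "T"): "B", ("T", "PD"): "C",
        ("PD", "NPD"): "H", ("NPD", "PD"): "I", ("T", "NPD"): "J",
        ("NPD", "T"): "K", ("NPD", "NPD"): "L",
    }
    if (t1, t2) in simple:
        return simple[(t1, t2)]
    # (T, T): distinguish by the doubly recombinant spores
    double = [h for h in pattern if h[0] != h[1] and h[1] != h[2]]
    if len(double) == 2:
        return "D"
    if len(double) == 0:
        return "G"
    return "E" if double[0][0] == 1 else "F"


def _apply_swaps(alleles: list[int], pairs) -> list[int]:
    out = list(alleles)
    for a, b in pairs:
        out[a], out[b] = out[b], out[a]
    return out


def enumerate_tetrad_classes(max_cos_per_interval: int = 2) -> list[Pattern]:
    """Brute-force enumeration of the distinguishable tetrad patterns.

    Generates every pattern reachable from 0..``max_cos_per_interval``
    crossovers in each interval across all chromatid-pair assignments
    (each crossover exchanging the distal segments of one chromatid of
    each homolog), deduplicates by unordered-haplotype equality and
    returns the sorted distinct patterns.  Serves as the independent
    oracle for :func:`classify_tetrad`.
    """
    pairs = [(a, b) for a in (0, 1) for b in (2, 3)]
    base = [1, 1, 0, 0]  # parent A carries the markers on chromatids 0, 1
    patterns: set[Pattern] = set()
    for n1 in range(max_cos_per_interval + 1):
        for n2 in range(max_cos_per_interval + 1):
            for p1 in itertools.product(pairs, repeat=n1):
                a2 = _apply_swaps(base, p1)
                for p2 in itertools.product(pairs, repeat=n2):
                    a3 = _apply_swaps(a2, p2)
                    patterns.add(canonical_pattern(list(zip(base, a2, a3))))
    return sorted(patterns, reverse=True)


def validate_class_table(table: dict[Pattern, str]) -> None:
    """Check a letter table against the fixed class-membership sets."""
    if sorted(table.values()) != sorted(CLASS_LETTERS):
        raise InputError("class table must assign each letter A..L exactly once")
    for pattern, letter in table.items():
        t1 = interval_tetrad_type(pattern, "I1")
        t2 = interval_tetrad_type(pattern, "I2")
        if (letter in CO_I1_CLASSES) != (t1 != "PD"):
            raise InputError(f"class {letter}: I1 crossover membership inconsistent")
        if (letter in CO_I2_CLASSES) != (t2 != "PD"):
            raise InputError(f"class {letter}: I2 crossover membership inconsistent")


@dataclass(frozen=True)
class IntervalTypeCounts:
    """PD/T/NPD tetrad counts for one interval."""

    pd_count: int
    t_count: int
    npd_count: int

    def __post_init__(self) -> None:
        if min(self.pd_count, self.t_count, self.npd_count) < 0:
            raise InputError("tetrad type counts must be >= 0")

    @property
    def total(self) -> int:
        return self.pd_count + self.t_count + self.npd_count

    def as_array(self) -> np.ndarray:
        return np.array([self.pd_count, self.t_count, self.npd_count])


@dataclass
class TetradClassCounts:
    """Counts of tetrads per class A..L for one genotype / interval pair."""

    counts: dict[str, int]
    genotype: str = ""
    interval_pair: str = ""

    def __post_init__(self) -> None:
        missing = set(CLASS_LETTERS) - set(self.counts)
        if missing:
            raise InputError(f"missing classes {sorted(missing)}")
        if any(self.counts[c] < 0 for c in CLASS_LETTERS):
            raise InputError("class counts must be >= 0")
        self.counts = {c: int(self.counts[c]) for c in CLASS_LETTERS}

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @classmethod
    def from_patterns(
        cls,
        patterns,
        genotype: str = "",
        interval_pair: str = "",
        table: dict[Pattern, str] | None = None,
    ) -> "TetradClassCounts":
        counts = dict.fromkeys(CLASS_LETTERS, 0)
        for p in patterns:
            counts[classify_tetrad(p, table)] += 1
        return cls(counts, genotype, interval_pair)

    def subset_total(self, classes) -> int:
        return sum(self.counts[c] for c in classes)


def interval_counts_from_classes(
    counts: TetradClassCounts, interval: str, classes=None
) -> IntervalTypeCounts:
    """PD/T/NPD composition of one interval, optionally within a class subset."""
    type_of = {"I1": I1_TYPE, "I2": I2_TYPE}.get(interval)
    if type_of is None:
        raise InputError("interval must be 'I1' or 'I2'")
    classes = CLASS_LETTERS if classes is None else classes
    tally = {"PD": 0, "T": 0, "NPD": 0}
    for c in classes:
        tally[type_of[c]] += counts.counts[c]
    return IntervalTypeCounts(tally["PD"], tally["T"], tally["NPD"])


@dataclass(frozen=True)
class GeneticDistanceEstimate:
    """A Perkins distance (cM) with its sampling variance (cM^2)."""

    d_cm: float
    variance: float
    n_tetrads: int

    @property
    def se(self) -> float:
        return sqrt(self.variance)


def perkins_distance(counts: IntervalTypeCounts) -> GeneticDistanceEstimate:
    """Perkins genetic distance D = 100 * (t + 6n) / 2 cM.

    ``t`` and ``n`` are the tetratype and non-parental-ditype
    frequencies.  The variance is the delta method on the multinomial
    (PD, T, NPD) proportions:
    ``Var(D) = [50^2 t(1-t) + 300^2 n(1-n) - 2*50*300*t*n] / N``.
    """
    total = counts.total
    if total == 0:
        raise InputError("cannot compute a Perkins distance from zero tetrads")
    t = counts.t_count / total
    n = counts.npd_count / total
    d = 50.0 * t + 300.0 * n
    var = (2500.0 * t * (1 - t) + 90000.0 * n * (1 - n) - 30000.0 * t * n) / total
    return GeneticDistanceEstimate(d, var, total)


def perkins_bootstrap_se(
    counts: IntervalTypeCounts, n_boot: int = 10000, rng=None
) -> float:
    """Multinomial-bootstrap standard error of the Perkins distance."""
    total = counts.total
    if total == 0:
        raise InputError("cannot bootstrap zero tetrads")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    probs = counts.as_array() / total
    draws = rng.multinomial(total, probs, size=n_boot)
    d = (50.0 * draws[:, 1] + 300.0 * draws[:, 2]) / total
    return float(d.std(ddof=1))


def z_test_distances(
    a: GeneticDistanceEstimate, b: GeneticDistanceEstimate
) -> tuple[float, float]:
    """Two-sided Z-test of H0: D_a = D_b using the delta-method variances."""
    denom = a.variance + b.variance
    if denom == 0.0:
        if a.d_cm == b.d_cm:
            return 0.0, 1.0
        raise InputError("both variances are zero but the distances differ")
    z = (a.d_cm - b.d_cm) / sqrt(denom)
    return z, float(2.0 * stats.norm.sf(abs(z)))


@dataclass
class InterferenceRatioResult:
    """IR = D1/D2 of one interval conditioned on a crossover in the other."""

    direction: str
    d_with: GeneticDistanceEstimate | None
    d_without: GeneticDistanceEstimate | None
    ir: float
    chi2: float
    pvalue: float
    df: int
    flags: list[str] = field(default_factory=list)


def interference_ratio(
    counts: TetradClassCounts, direction: str = "I1_given_I2"
) -> InterferenceRatioResult:
    """Interference Ratio of the measured interval given the conditioning one.

    ``direction = 'I1_given_I2'`` measures I1, splitting tetrads into
    those with (D1) and without (D2) a crossover in I2 (per the fixed
    class sets).  H0: D1 = D2 is tested by a chi-square homogeneity
    test on the 2x3 (subpopulation x PD/T/NPD) contingency table
    (df = 2); all-zero tetrad-type columns are dropped first.
    """
    if direction == "I1_given_I2":
        measured, cond_classes = "I1", CO_I2_CLASSES
    elif direction == "I2_given_I1":
        measured, cond_classes = "I2", CO_I1_CLASSES
    else:
        raise InputError("direction must be 'I1_given_I2' or 'I2_given_I1'")
    with_classes = [c for c in CLASS_LETTERS if c in cond_classes]
    without_classes = [c for c in CLASS_LETTERS if c not in cond_classes]
    with_counts = interval_counts_from_classes(counts, measured, with_classes)
    without_counts = interval_counts_from_classes(counts, measured, without_classes)

    flags: list[str] = []
    d_with = d_without = None
    ir = float("nan")
    if with_counts.total == 0:
        flags.append("empty conditioning subpopulation")
    else:
        d_with = perkins_distance(with_counts)
    if without_counts.total == 0:
        flags.append("empty complement subpopulation")
    else:
        d_without = perkins_distance(without_counts)
    if d_with is not None and d_without is not None:
        if d_without.d_cm == 0.0:
            flags.append("IR undefined (D2 = 0)")
        else:
            ir = d_with.d_cm / d_without.d_cm

    chi2 = pvalue = float("nan")
    df = 0
    if with_counts.total > 0 and without_counts.total > 0:
        table = np.vstack([with_counts.as_array(), without_counts.as_array()])
        table = table[:, table.sum(axis=0) > 0]
        if table.shape[1] >= 2:
            chi2, pvalue, df, _ = stats.chi2_contingency(table, correction=False)
        else:
            flags.append("degenerate contingency table (single tetrad type)")
    else:
        flags.append("no homogeneity test")
    return InterferenceRatioResult(
        direction, d_with, d_without, ir, float(chi2), float(pvalue), int(df), flags
    )


@dataclass
class CoincidenceResult:
    """Coefficient of coincidence with its goodness-of-fit test."""

    f_obs_double: float
    f_exp_i1: float
    f_exp_i2: float
    coc: float
    chi2: float
    pvalue: float
    method: str
    flags: list[str] = field(default_factory=list)


def coefficient_of_coincidence(counts: TetradClassCounts) -> CoincidenceResult:
    """CoC = f_o(2CO) / [f_e(CO_I1) * f_e(CO_I2)].

    ``f_o(2CO)`` is the frequency of tetrads with a crossover in both
    intervals; the expected frequency is the product of the marginal
    crossover frequencies.  H0: observed = expected double-crossover
    count is tested by a df = 1 chi-square without continuity
    correction, falling back to an exact binomial test when the expected
    double-crossover count is below 5.
    """
    total = counts.total
    if total == 0:
        raise InputError("cannot compute a CoC from zero tetrads")
    n_double = counts.subset_total(DOUBLE_CO_CLASSES)
    fe1 = counts.subset_total(CO_I1_CLASSES) / total
    fe2 = counts.subset_total(CO_I2_CLASSES) / total
    fo = n_double / total
    flags: list[str] = []
    if fe1 == 0.0 or fe2 == 0.0:
        flags.append("CoC undefined (zero marginal crossover frequency)")
        return CoincidenceResult(
            fo, fe1, fe2, float("nan"), float("nan"), float("nan"), "none", flags
        )
    fe = fe1 * fe2
    coc = fo / fe
    expected = np.array([total * fe, total * (1.0 - fe)])
    observed = np.array([n_double, total - n_double])
    if expected.min() < 5.0:
        flags.append("expected count < 5: exact binomial test")
        pvalue = stats.binomtest(n_double, total, fe).pvalue
        return CoincidenceResult(fo, fe1, fe2, coc, float("nan"), float(pvalue), "binomial", flags)
    chi2, pvalue = stats.chisquare(observed, expected)
    return CoincidenceResult(fo, fe1, fe2, coc, float(chi2), float(pvalue), "chi2", flags)


def tetrad_report(counts_list) -> "pd.DataFrame":
    """Summary table: Perkins distances, IR (both directions) and CoC.

    One row per :class:`TetradClassCounts` (genotype / interval pair).
    """
    import pandas as pd

    rows = []
    for counts in counts_list:
        row: dict = {
            "genotype": counts.genotype,
            "interval_pair": counts.interval_pair,
            "n_tetrads": counts.total,
        }
        for interval in ("I1", "I2"):
            itc = interval_counts_from_classes(counts, interval)
            est = perkins_distance(itc)
            row[f"{interval}_PD"] = itc.pd_count
            row[f"{interval}_T"] = itc.t_count
            row[f"{interval}_NPD"] = itc.npd_count
            row[f"D_{interval}_cM"] = est.d_cm
            row[f"SE_{interval}_cM"] = est.se
        for direction in ("I1_given_I2", "I2_given_I1"):
            res = interference_ratio(counts, direction)
            row[f"IR_{direction}"] = res.ir
            row[f"IR_{direction}_p"] = res.pvalue
        coc = coefficient_of_coincidence(counts)
        row["CoC"] = coc.coc
        row["CoC_p"] = coc.pvalue
        rows.append(row)
    return pd.DataFrame(rows)
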