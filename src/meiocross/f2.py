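"""Genome-wide crossover analysis of F2 marker-segregation data.

Inputs are a plants x markers matrix of codominant genotype calls
(dose of the B-parent allele: 0 = AA, 1 = AB, 2 = BB, NaN = missing)
together with a physical marker map.  The module implements:

* per-plant crossover counting (sum of genotype transitions along each
  chromosome, missing calls skipped),
* Welch two-sided t-tests comparing per-plant counts between genotypes,
* per-interval recombinant-chromatid counting and Kosambi genetic maps
  with cM/Mb profiles,
* merging of adjacent intervals into ~5 Mb super-intervals and
  chi-square comparison of pooled recombinant/non-recombinant chromatid
  counts between two genotypes with genome-wide Benjamini-Hochberg
  false-discovery-rate control at 5% (**) and 1% (***) tiers.

Counting conventions (the choices are documented because different
rules are defensible): an AA<->AB or BB<->AB transition contributes one
crossover, AA<->BB contributes two; adjacent heterozygous calls
contribute zero recombinant chromatids, because without phase the two
double-recombinant AB/AB configurations cannot be distinguished from
the non-recombinant one — a small downward bias on dense maps,
quantified in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError

__all__ = [
    "F2GenotypeMatrix",
    "IntervalRecombination",
    "count_crossovers_per_plant",
    "count_crossovers",
    "compare_mean_co",
    "MeanCOComparison",
    "interval_recombination",
    "kosambi_cm",
    "inverse_kosambi",
    "build_genetic_map",
    "merge_super_intervals",
    "compare_superintervals",
    "bh_tiers",
]


@dataclass
class F2GenotypeMatrix:
    """Plants x markers genotype calls plus the physical marker map.

    ``genotypes``: DataFrame indexed by plant, one column per marker,
    values in {0.0, 1.0, 2.0, NaN} (dose of the B-parent allele).
    ``marker_map``: DataFrame with columns marker / chromosome /
    position_mb, sorted by chromosome then position.
    """

    genotypes: pd.DataFrame
    marker_map: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"marker", "chromosome", "position_mb"}
        if not required.issubset(self.marker_map.columns):
            raise InputError(f"marker map needs columns {sorted(required)}")
        self.marker_map = (
            self.marker_map.sort_values(["chromosome", "position_mb"], kind="stable")
            .reset_index(drop=True)
        )
        map_markers = list(self.marker_map["marker"])
        if set(map_markers) != set(self.genotypes.columns):
            raise InputError("marker map and genotype columns disagree")
        self.genotypes = self.genotypes[map_markers]
        values = self.genotypes.to_numpy(dtype=float)
        bad = ~(np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0)))
        if bad.any():
            raise InputError("genotype calls must be 0/1/2 or missing")

    @property
    def n_plants(self) -> int:
        return len(self.genotypes)

    def chromosome_markers(self) -> dict[str, pd.DataFrame]:
        return {
            str(chrom): sub
            for chrom, sub in self.marker_map.groupby("chromosome", sort=False)
        }


def count_crossovers_per_plant(row: pd.Series, marker_map: pd.DataFrame) -> int:
    """Observed crossovers of one plant: genotype transitions summed.

    Per chromosome, consecutive non-missing calls are scanned; each
    unit change of allele dose contributes one crossover (AA<->BB
    contributes two: both chromatids recombinant).  Missing calls are
    skipped, i.e. the transition is scored across the gap.
    """
    total = 0
    for _, sub in marker_map.groupby("chromosome", sort=False):
        vals = row[list(sub["marker"])].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            warnings.warn("all calls missing on one chromosome; contributes 0")
            continue
        total += int(np.abs(np.diff(vals)).sum())
    return total


def count_crossovers(matrix: F2GenotypeMatrix) -> pd.Series:
    """Per-plant observed crossover counts for a whole population."""
    blocks = []
    for _, sub in matrix.marker_map.groupby("chromosome", sort=False):
        arr = matrix.genotypes[list(sub["marker"])].to_numpy(dtype=float)
        if not np.isnan(arr).any():
            blocks.append(np.abs(np.diff(arr, axis=1)).sum(axis=1))
        else:
            counts = np.empty(arr.shape[0])
            for i, row in enumerate(arr):
                vals = row[~np.isnan(row)]
                counts[i] = np.abs(np.diff(vals)).sum() if vals.size else 0.0
            blocks.append(counts)
    return pd.Series(
        np.sum(blocks, axis=0).astype(int), index=matrix.genotypes.index, name="n_co"
    )


@dataclass(frozen=True)
class MeanCOComparison:
    t: float
    pvalue: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    n_a: int
    n_b: int


def compare_mean_co(group_a, group_b) -> MeanCOComparison:
    """Welch two-sided t-test on per-plant crossover counts.

    With zero variance in both groups the limit convention applies:
    p = 1 for equal means, p = 0 otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("each group needs at least two plants")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        equal = a.mean() == b.mean()
        t, p = (0.0, 1.0) if equal else (float("inf"), 0.0)
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return MeanCOComparison(
        float(t), float(p),
        float(a.mean()), float(a.std(ddof=1)),
        float(b.mean()), float(b.std(ddof=1)),
        a.size, b.size,
    )


@dataclass
class IntervalRecombination:
    """Recombinant-chromatid counts across one marker interval."""

    chromosome: str
    left_marker: str
    right_marker: str
    left_mb: float
    right_mb: float
    recombinant: int
    informative: int  # 2 per plant with both flanking calls
    r: float
    d_cm: float

    @property
    def span_mb(self) -> float:
        return self.right_mb - self.left_mb


def kosambi_cm(r, max_r: float = 0.4999) -> np.ndarray | float:
    """Kosambi map distance d = 25 * ln((1 + 2r) / (1 - 2r)) cM.

    Recombination fractions at or above 0.5 are clipped to ``max_r``
    with a warning.
    """
    r_arr = np.asarray(r, dtype=float)
    if (r_arr < 0).any():
        raise InputError("recombination fraction must be >= 0")
    if (r_arr >= 0.5).any():
        warnings.warn(f"recombination fraction >= 0.5 clipped to {max_r}")
        r_arr = np.minimum(r_arr, max_r)
    d = 25.0 * np.log((1.0 + 2.0 * r_arr) / (1.0 - 2.0 * r_arr))
    return float(d) if np.isscalar(r) else d


def inverse_kosambi(d_cm) -> np.ndarray | float:
    """Recombination fraction from a Kosambi distance: r = tanh(2d/100)/2."""
    d = np.asarray(d_cm, dtype=float)
    r = 0.5 * np.tanh(2.0 * d / 100.0)
    return float(r) if np.isscalar(d_cm) else r


def _recombinant_counts(left_vals: np.ndarray, right_vals: np.ndarray) -> tuple[int, int]:
    """(recombinant, informative) chromatids over plants with both calls.

    The recombinant-chromatid count per plant is |dose_left - dose_right|
    (equal homozygous 0; hom<->het 1; opposite homozygous 2; het<->het 0
    by the phase-ambiguity convention).
    """
    both = ~(np.isnan(left_vals) | np.isnan(right_vals))
    rec = int(np.abs(left_vals[both] - right_vals[both]).sum())
    return rec, 2 * int(both.sum())


def interval_recombination(
    matrix: F2GenotypeMatrix, left_marker: str, right_marker: str
) -> IntervalRecombination:
    """Recombination fraction and Kosambi distance of one marker interval."""
    mmap = matrix.marker_map.set_index("marker")
    for m in (left_marker, right_marker):
        if m not in mmap.index:
            raise InputError(f"unknown marker {m!r}")
    lrow, rrow = mmap.loc[left_marker], mmap.loc[right_marker]
    if lrow["chromosome"] != rrow["chromosome"]:
        raise InputError("interval markers must lie on one chromosome")
    if not lrow["position_mb"] < rrow["position_mb"]:
        raise InputError("interval markers must be ordered left < right")
    rec, informative = _recombinant_counts(
        matrix.genotypes[left_marker].to_numpy(dtype=float),
        matrix.genotypes[right_marker].to_numpy(dtype=float),
    )
    r = rec / informative if informative else float("nan")
    d = kosambi_cm(r) if informative else float("nan")
    return IntervalRecombination(
        str(lrow["chromosome"]), left_marker, right_marker,
        float(lrow["position_mb"]), float(rrow["position_mb"]),
        rec, informative, r, d,
    )


@dataclass
class GeneticMap:
    """Per-interval Kosambi map with cM/Mb profile and per-chromosome totals."""

    intervals: pd.DataFrame
    chromosome_cm: pd.Series
    total_cm: float


def build_genetic_map(matrix: F2GenotypeMatrix) -> GeneticMap:
    """Kosambi genetic map over all consecutive marker intervals.

    Requires at least two markers per chromosome; cM/Mb is the interval
    Kosambi distance divided by its physical span.
    """
    rows = []
    for chrom, sub in matrix.marker_map.groupby("chromosome", sort=False):
        markers = list(sub["marker"])
        if len(markers) < 2:
            raise InputError(f"chromosome {chrom} needs >= 2 markers")
        for left, right in zip(markers[:-1], markers[1:]):
            iv = interval_recombination(matrix, left, right)
            rows.append(
                {
                    "chromosome": iv.chromosome,
                    "left_marker": iv.left_marker,
                    "right_marker": iv.right_marker,
                    "left_mb": iv.left_mb,
                    "right_mb": iv.right_mb,
                    "span_mb": iv.span_mb,
                    "recombinant": iv.recombinant,
                    "informative": iv.informative,
                    "r": iv.r,
                    "d_cm": iv.d_cm,
                    "cm_per_mb": iv.d_cm / iv.span_mb if iv.span_mb > 0 else float("nan"),
                }
            )
    intervals = pd.DataFrame(rows)
    chromosome_cm = intervals.groupby("chromosome", sort=False)["d_cm"].sum()
    return GeneticMap(intervals, chromosome_cm, float(chromosome_cm.sum()))


def merge_super_intervals(spans_mb, min_mb: float = 5.0) -> list[list[int]]:
    """Greedy left-to-right grouping of adjacent intervals into super-intervals.

    Accumulates interval indices until the cumulative physical span
    reaches ``min_mb``, which closes the group; a terminal remainder
    below ``min_mb`` is merged into the previous group (or stands alone
    with a warning when it is the only group).
    """
    spans = list(spans_mb)
    if not spans:
        return []
    groups: list[list[int]] = []
    current: list[int] = []
    acc = 0.0
    for i, span in enumerate(spans):
        current.append(i)
        acc += span
        if acc >= min_mb:
            groups.append(current)
            current, acc = [], 0.0
    if current:
        if groups:
            groups[-1].extend(current)
        else:
            warnings.warn(
                f"total span {acc:.2f} Mb below the {min_mb} Mb super-interval size"
            )
            groups.append(current)
    return groups


def compare_superintervals(
    matrix_a: F2GenotypeMatrix,
    matrix_b: F2GenotypeMatrix,
    min_mb: float = 5.0,
    fdr_tiers: tuple[float, float] = (0.05, 0.01),
) -> pd.DataFrame:
    """Super-interval chi-square comparison of two genotypes' landscapes.

    Both populations must be genotyped on the identical marker map.
    Adjacent ~1.5 Mb intervals are merged into super-intervals of at
    least ``min_mb``; pooled (recombinant, non-recombinant) chromatid
    counts are compared by a 2x2 chi-square without continuity
    correction (Fisher's exact test when an expected cell is below 5),
    and Benjamini-Hochberg control is applied genome-wide across all
    super-intervals, reported at the two FDR tiers (default ``**`` = 5%
    and ``***`` = 1%).
    """
    if not matrix_a.marker_map.equals(matrix_b.marker_map):
        raise InputError("the two populations must share one marker map")
    map_a = build_genetic_map(matrix_a).intervals
    map_b = build_genetic_map(matrix_b).intervals
    rows = []
    for chrom in matrix_a.marker_map["chromosome"].unique():
        sub_a = map_a[map_a["chromosome"] == chrom].reset_index(drop=True)
        sub_b = map_b[map_b["chromosome"] == chrom].reset_index(drop=True)
        for group in merge_super_intervals(sub_a["span_mb"], min_mb):
            ga, gb = sub_a.loc[group], sub_b.loc[group]
            rec_a, inf_a = int(ga["recombinant"].sum()), int(ga["informative"].sum())
            rec_b, inf_b = int(gb["recombinant"].sum()), int(gb["informative"].sum())
            table = np.array([[rec_a, inf_a - rec_a], [rec_b, inf_b - rec_b]])
            if table.sum() == 0:
                chi2, p, method = float("nan"), 1.0, "none"
            else:
                expected = stats.contingency.expected_freq(table)
                if (expected < 5).any() or (table.sum(axis=1) == 0).any():
                    chi2 = float("nan")
                    p = stats.fisher_exact(table)[1]
                    method = "fisher"
                else:
                    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
                    method = "chi2"
            rows.append(
                {
                    "chromosome": str(chrom),
                    "start_mb": float(ga["left_mb"].iloc[0]),
                    "end_mb": float(ga["right_mb"].iloc[-1]),
                    "n_intervals": len(group),
                    "rec_a": rec_a,
                    "informative_a": inf_a,
                    "rec_b": rec_b,
                    "informative_b": inf_b,
                    "chi2": float(chi2),
                    "pvalue": float(p),
                    "test": method,
                }
            )
    out = pd.DataFrame(rows)
    sig5, sig1, tiers = bh_tiers(out["pvalue"], fdr_tiers)
    out["significant_fdr5"] = sig5
    out["significant_fdr1"] = sig1
    out["tier"] = tiers
    return out


def bh_tiers(
    pvalues, fdr_tiers: tuple[float, float] = (0.05, 0.01)
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Benjamini-Hochberg significance at two FDR tiers.

    Returns boolean rejection vectors at the loose and strict tiers plus
    the tier labels ('' / '**' / '***') used in landscape plots.  BH is
    monotone in alpha, so every strict-tier rejection is also a
    loose-tier rejection.
    """
    loose, strict = max(fdr_tiers), min(fdr_tiers)
    pvalues = np.asarray(pvalues, dtype=float)
    sig5 = multipletests(pvalues, alpha=loose, method="fdr_bh")[0]
    sig1 = multipletests(pvalues, alpha=strict, method="fdr_bh")[0]
    tiers = np.where(sig1, "***", np.where(sig5, "**", ""))
    return sig5, sig1, tiers
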