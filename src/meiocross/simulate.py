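"""Meiosis and crossover simulation.

Two crossover classes coexist on each bivalent:

* class I — interference-sensitive; counts and positions follow a
  stationary gamma-renewal process on the genetic coordinate with shape
  ``nu`` (``nu = 1`` is the no-interference Poisson limit) and
  bivalent-level rate 2 per Morgan of gamete map length.  An optional
  obligate-crossover constraint resamples whole event sets until at
  least one event occurs (emulating the near-universal guarantee of one
  chiasma per wild-type bivalent).
* class II — interference-free; Poisson counts with a per-bivalent mean,
  positions uniform on the genetic coordinate (hence following the
  physical landscape shape after conversion to Mb).

Mutant presets are phenomenological dials on these intensities:
``zmm`` removes class I, ``figl1`` and ``fancm`` release extra class II
crossovers (the *fancm* excess is attenuated in hybrid context), and
``sds``/``spo11`` abolish all crossovers.

Each crossover event involves exactly one chromatid of each homolog,
drawn uniformly among the four possible pairs (no chromatid
interference).  Chromatids 0 and 1 belong to parent A (the parent
carrying the fluorescent transgenes), chromatids 2 and 3 to parent B.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InputError
from .genome import GenomeModel, MarkerPanel, default_genome
from .tetrads import canonical_pattern, Pattern
from .f2 import F2GenotypeMatrix

__all__ = [
    "CrossoverModel",
    "MutantPreset",
    "PRESETS",
    "preset_model",
    "CrossoverEvent",
    "MeiosisOutcome",
    "sample_class1_positions",
    "sample_class2_positions",
    "assign_chromatids",
    "simulate_meiosis",
    "count_bivalents",
    "chromatid_origins",
    "make_tetrad",
    "simulate_tetrads",
    "make_f2_population",
    "ftl_interval_model",
]

#: Default wild-type class I map length for the whole genome (cM), split
#: across chromosomes proportionally to physical length.
WT_CLASS1_TOTAL_CM = 330.0
#: Default wild-type class II mean per bivalent (Poisson).
WT_CLASS2_MEAN = 0.30


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass
class CrossoverModel:
    """Per-meiosis crossover intensities and interference parameters.

    ``class1_map_length_cm`` is the gamete-level class I genetic length
    per chromosome (cM); a scalar is broadcast to every chromosome.
    ``class2_mean_per_bivalent`` is the wild-type class II Poisson mean;
    ``class2_multiplier`` scales it (never attenuated; e.g. the *figl1*
    release) while ``fancm_multiplier`` is attenuated in hybrid context:
    its excess over 1 is multiplied by ``hybrid_attenuation``.
    """

    class1_map_length_cm: dict[str, float] | float = 0.0
    interference_shape_nu: float = 1.0
    obligate_class1: bool = False
    class2_mean_per_bivalent: float = 0.0
    class2_multiplier: float = 1.0
    fancm_multiplier: float = 1.0
    hybrid_attenuation: float = 0.1
    context: str = "inbred"

    def __post_init__(self) -> None:
        if self.interference_shape_nu < 1.0:
            raise InputError("interference shape nu must be >= 1")
        lengths = (
            self.class1_map_length_cm.values()
            if isinstance(self.class1_map_length_cm, dict)
            else [self.class1_map_length_cm]
        )
        if any(v < 0 for v in lengths):
            raise InputError("class I map length must be >= 0")
        if self.class2_mean_per_bivalent < 0:
            raise InputError("class II mean must be >= 0")
        if self.class2_multiplier <= 0 or self.fancm_multiplier <= 0:
            raise InputError("class II multipliers must be > 0")
        if not (0.0 <= self.hybrid_attenuation <= 1.0):
            raise InputError("hybrid_attenuation must be in [0, 1]")
        if self.context not in ("inbred", "hybrid"):
            raise InputError("context must be 'inbred' or 'hybrid'")

    def class1_length_cm(self, chrom_name: str) -> float:
        if isinstance(self.class1_map_length_cm, dict):
            try:
                return self.class1_map_length_cm[chrom_name]
            except KeyError:
                raise InputError(f"no class I map length for {chrom_name!r}") from None
        return float(self.class1_map_length_cm)

    def effective_class2_mean(self) -> float:
        """Class II Poisson mean per bivalent after mutant/context effects."""
        fancm_eff = self.fancm_multiplier
        if self.context == "hybrid":
            fancm_eff = 1.0 + self.hybrid_attenuation * (self.fancm_multiplier - 1.0)
        return self.class2_mean_per_bivalent * self.class2_multiplier * fancm_eff


@dataclass(frozen=True)
class MutantPreset:
    """A named genotype: partial overrides of the wild-type model."""

    name: str
    overrides: dict


def _wt_class1(genome: GenomeModel, total_cm: float = WT_CLASS1_TOTAL_CM) -> dict[str, float]:
    total_mb = sum(c.length_mb for c in genome.chromosomes)
    return {c.name: total_cm * c.length_mb / total_mb for c in genome.chromosomes}


PRESETS: dict[str, MutantPreset] = {
    "wild_type": MutantPreset("wild_type", {}),
    "zmm": MutantPreset("zmm", {"class1_map_length_cm": 0.0, "obligate_class1": False}),
    "figl1": MutantPreset("figl1", {"class2_multiplier": 5.0}),
    "fancm": MutantPreset("fancm", {"fancm_multiplier": 10.0}),
    "figl1_fancm": MutantPreset(
        "figl1_fancm", {"class2_multiplier": 5.0, "fancm_multiplier": 10.0}
    ),
    "sds": MutantPreset(
        "sds",
        {
            "class1_map_length_cm": 0.0,
            "class2_mean_per_bivalent": 0.0,
            "obligate_class1": False,
        },
    ),
    "spo11": MutantPreset(
        "spo11",
        {
            "class1_map_length_cm": 0.0,
            "class2_mean_per_bivalent": 0.0,
            "obligate_class1": False,
        },
    ),
}


def preset_model(
    name: str,
    genome: GenomeModel | None = None,
    context: str = "inbred",
    **overrides,
) -> CrossoverModel:
    """Build the :class:`CrossoverModel` for a named genotype preset."""
    if name not in PRESETS:
        raise InputError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    genome = genome or default_genome()
    base = CrossoverModel(
        class1_map_length_cm=_wt_class1(genome),
        interference_shape_nu=5.0,
        obligate_class1=True,
        class2_mean_per_bivalent=WT_CLASS2_MEAN,
        context=context,
    )
    merged = {**PRESETS[name].overrides, **overrides}
    return replace(base, **merged)


@dataclass(frozen=True)
class CrossoverEvent:
    position_mb: float
    co_class: int  # 1 or 2
    chromatids: tuple[int, int]  # (a in {0,1}, b in {2,3})


@dataclass
class MeiosisOutcome:
    """Crossover events per chromosome for one meiosis, position-sorted."""

    events: dict[str, list[CrossoverEvent]]
    class1_rejections: int = 0


def _stationary_gamma_positions(
    length_cm: float, nu: float, rng: np.random.Generator
) -> np.ndarray:
    """Event positions (cM) of a stationary gamma-renewal process.

    Bivalent-level rate is 2 events per Morgan (0.02 per cM); inter-event
    gaps are Gamma(nu, scale) with mean 1/rate.  The first event uses the
    exact stationary construction: the gap covering the origin is
    length-biased (Gamma(nu + 1, scale)) and the origin sits uniformly
    inside it, so the forward recurrence time is U * Gamma(nu + 1).
    """
    rate_per_cm = 0.02
    scale = 1.0 / (rate_per_cm * nu)
    positions = []
    x = rng.uniform() * rng.gamma(nu + 1.0, scale)
    while x < length_cm:
        positions.append(x)
        x += rng.gamma(nu, scale)
    return np.array(positions)


def sample_class1_positions(
    chrom, model: CrossoverModel, rng
) -> tuple[np.ndarray, int]:
    """Sample class I crossover positions (cM along the chromosome's map).

    Returns ``(positions, n_rejections)`` where the rejection count is
    the number of empty event sets discarded under the obligate-crossover
    constraint.
    """
    rng = _as_rng(rng)
    name = chrom if isinstance(chrom, str) else chrom.name
    length_cm = model.class1_length_cm(name)
    if length_cm == 0.0:
        return np.empty(0), 0
    nu = model.interference_shape_nu
    rejections = 0
    while True:
        pos = _stationary_gamma_positions(length_cm, nu, rng)
        if pos.size > 0 or not model.obligate_class1:
            return pos, rejections
        rejections += 1


def sample_class2_positions(chrom, model: CrossoverModel, rng) -> np.ndarray:
    """Sample class II positions as fractions of the genetic coordinate."""
    rng = _as_rng(rng)
    mean = model.effective_class2_mean()
    n = rng.poisson(mean) if mean > 0 else 0
    return np.sort(rng.uniform(0.0, 1.0, n))


def assign_chromatids(
    positions_mb, co_classes, rng
) -> list[CrossoverEvent]:
    """Assign each event one of the four equally likely chromatid pairs."""
    rng = _as_rng(rng)
    positions_mb = np.asarray(positions_mb, dtype=float)
    n = positions_mb.size
    a = rng.integers(0, 2, n)
    b = 2 + rng.integers(0, 2, n)
    events = [
        CrossoverEvent(float(p), int(c), (int(ai), int(bi)))
        for p, c, ai, bi in zip(positions_mb, co_classes, a, b)
    ]
    events.sort(key=lambda e: e.position_mb)
    return events


def simulate_meiosis(
    genome: GenomeModel, model: CrossoverModel, rng
) -> MeiosisOutcome:
    """Simulate one meiosis: crossover events on every bivalent."""
    rng = _as_rng(rng)
    events: dict[str, list[CrossoverEvent]] = {}
    rejections = 0
    for chrom in genome.chromosomes:
        c1_cm, rej = sample_class1_positions(chrom, model, rng)
        rejections += rej
        length_cm = model.class1_length_cm(chrom.name)
        frac1 = c1_cm / length_cm if length_cm > 0 else c1_cm
        frac2 = sample_class2_positions(chrom, model, rng)
        fracs = np.concatenate([frac1, frac2])
        classes = [1] * frac1.size + [2] * frac2.size
        mb = genome.genetic_to_physical(chrom.name, fracs) if fracs.size else fracs
        events[chrom.name] = assign_chromatids(mb, classes, rng)
    return MeiosisOutcome(events, rejections)


def count_bivalents(outcome: MeiosisOutcome) -> tuple[int, int]:
    """(bivalents, univalent pairs) at metaphase I.

    A chromosome pair is a bivalent iff it carries at least one
    crossover of either class; a crossover-free pair yields two
    univalent chromosomes (one univalent pair).
    """
    bivalents = sum(1 for evs in outcome.events.values() if evs)
    return bivalents, len(outcome.events) - bivalents


def chromatid_origins(
    events: list[CrossoverEvent], positions_mb
) -> np.ndarray:
    """Parental origin (0 = parent A, 1 = parent B) of the four chromatids.

    Returns a ``(4, len(positions))`` array.  Crossovers resolve
    concurrently on the original molecules: each event is a junction
    between one chromatid of each homolog, and the four meiotic
    products are the paths through the junction graph.  Walking
    left-to-right, a junction on molecules ``(x, y)`` swaps the two
    paths currently travelling on ``x`` and ``y`` (a three-strand
    double crossover therefore yields a tetratype in both intervals,
    as in classical tetrad analysis), and 2:2 segregation holds at
    every position.
    """
    positions_mb = np.asarray(positions_mb, dtype=float)
    order = np.argsort(positions_mb, kind="stable")
    molecule_of = [0, 1, 2, 3]  # path slot -> original molecule
    path_of = [0, 1, 2, 3]  # original molecule -> path slot
    out = np.empty((4, positions_mb.size), dtype=np.int8)
    ei = 0
    for idx in order:
        p = positions_mb[idx]
        while ei < len(events) and events[ei].position_mb <= p:
            x, y = events[ei].chromatids
            i, j = path_of[x], path_of[y]
            molecule_of[i], molecule_of[j] = molecule_of[j], molecule_of[i]
            path_of[x], path_of[y] = j, i
            ei += 1
        for c in range(4):
            out[c, idx] = 0 if molecule_of[c] < 2 else 1
    return out


def make_tetrad(outcome: MeiosisOutcome, panel: MarkerPanel) -> Pattern:
    """Fluorescence pattern of the four pollen grains at the marker triple.

    Presence of a fluorophore means the grain carries the parent-A
    allele at that marker; the returned pattern is the unordered multiset
    of the four three-bit haplotypes.
    """
    m1, m2, m3 = panel.ftl_triple()
    pos = np.array([m1.position_mb, m2.position_mb, m3.position_mb])
    origins = chromatid_origins(outcome.events.get(m1.chromosome, []), pos)
    presence = (origins == 0).astype(int)
    return canonical_pattern([tuple(row) for row in presence])


def simulate_tetrads(
    n: int, genome: GenomeModel, model: CrossoverModel, panel: MarkerPanel, rng
) -> list[Pattern]:
    """Simulate ``n`` tetrads and return their fluorescence patterns."""
    rng = _as_rng(rng)
    return [make_tetrad(simulate_meiosis(genome, model, rng), panel) for _ in range(n)]


def _gamete_doses(
    genome: GenomeModel,
    model: CrossoverModel,
    positions_by_chrom: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    """Parental-origin vector (0/1 = dose of parent-B allele) of one gamete."""
    outcome = simulate_meiosis(genome, model, rng)
    parts = []
    for name, pos in positions_by_chrom.items():
        origins = chromatid_origins(outcome.events[name], pos)
        parts.append(origins[int(rng.integers(4))])
    return np.concatenate(parts)


def make_f2_population(
    n_plants: int,
    genome: GenomeModel,
    model: CrossoverModel,
    panel: MarkerPanel,
    rng,
    missing_rate: float = 0.0,
) -> F2GenotypeMatrix:
    """Simulate an F2 selfing population genotyped at a codominant panel.

    Each plant is the fusion of two gametes from independent meioses of
    the same F1; genotypes are the dose of the parent-B allele
    (0 = AA, 1 = AB, 2 = BB), with optional missing-completely-at-random
    calls encoded as NaN.
    """
    if n_plants < 1:
        raise InputError("n_plants must be >= 1")
    if not (0.0 <= missing_rate < 1.0):
        raise InputError("missing_rate must be in [0, 1)")
    rng = _as_rng(rng)
    panel.validate_against(genome)
    by_chrom = panel.by_chromosome()
    positions_by_chrom = {
        name: np.array([m.position_mb for m in ms]) for name, ms in by_chrom.items()
    }
    marker_names = [m.name for ms in by_chrom.values() for m in ms]
    geno = np.empty((n_plants, len(marker_names)), dtype=float)
    for i in range(n_plants):
        g1 = _gamete_doses(genome, model, positions_by_chrom, rng)
        g2 = _gamete_doses(genome, model, positions_by_chrom, rng)
        geno[i] = g1 + g2
    if missing_rate > 0:
        geno[rng.uniform(size=geno.shape) < missing_rate] = np.nan
    genotypes = pd.DataFrame(
        geno,
        index=pd.Index([f"plant_{i + 1:05d}" for i in range(n_plants)], name="plant_id"),
        columns=marker_names,
    )
    marker_map = pd.DataFrame(
        {
            "marker": marker_names,
            "chromosome": [m.chromosome for ms in by_chrom.values() for m in ms],
            "position_mb": [m.position_mb for ms in by_chrom.values() for m in ms],
        }
    )
    return F2GenotypeMatrix(genotypes, marker_map)


def ftl_interval_model(
    i1_cm: float = 10.0,
    i2_cm: float = 10.0,
    nu: float = 1.0,
    length_mb: float = 20.0,
    flank_cm: float = 15.0,
    class2_mean: float = 0.0,
    obligate: bool = False,
):
    """A single-chromosome setup with an FTL triple spanning known cM sizes.

    Convenience for calibration studies: returns ``(genome, model,
    panel)`` where the uniform landscape places the marker triple so the
    two adjacent intervals have class I genetic sizes ``i1_cm`` and
    ``i2_cm``, with ``flank_cm`` of map outside them on each side.
    """
    from .genome import Marker, single_chromosome_genome

    total_cm = i1_cm + i2_cm + 2 * flank_cm
    genome = single_chromosome_genome(length_mb)
    mb_per_cm = length_mb / total_cm
    p1 = flank_cm * mb_per_cm
    p2 = (flank_cm + i1_cm) * mb_per_cm
    p3 = (flank_cm + i1_cm + i2_cm) * mb_per_cm
    panel = MarkerPanel(
        [
            Marker("m1", genome.chromosomes[0].name, p1, "ftl_fluorescent"),
            Marker("m2", genome.chromosomes[0].name, p2, "ftl_fluorescent"),
            Marker("m3", genome.chromosomes[0].name, p3, "ftl_fluorescent"),
        ]
    )
    model = CrossoverModel(
        class1_map_length_cm=total_cm,
        interference_shape_nu=nu,
        obligate_class1=obligate,
        class2_mean_per_bivalent=class2_mean,
    )
    return genome, model, panel
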