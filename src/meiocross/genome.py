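"""Genome model and marker panels.

A :class:`GenomeModel` describes the physical chromosomes of a diploid
plant (lengths in Mb, centromere intervals) together with a
piecewise-constant recombination landscape (relative crossover intensity
in cM/Mb over physical coordinates).  The landscape defines the mapping
between the genetic coordinate on which crossovers are sampled and the
physical coordinate on which markers live; by default intensity is
uniform along each arm and strongly suppressed inside the centromere
interval, emulating the low pericentromeric recombination of
*Arabidopsis thaliana*.

Physical positions are 0-based real Mb; intervals are half-open
``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "Chromosome",
    "GenomeModel",
    "Marker",
    "MarkerPanel",
    "default_genome",
    "single_chromosome_genome",
    "default_ftl_panel",
]


@dataclass(frozen=True)
class Chromosome:
    """One chromosome: physical length and centromere interval (Mb)."""

    name: str
    length_mb: float
    centromere_mb: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.length_mb <= 0:
            raise InputError(f"chromosome {self.name}: length must be > 0")
        lo, hi = self.centromere_mb
        if not (0.0 <= lo <= hi <= self.length_mb):
            raise InputError(
                f"chromosome {self.name}: centromere interval must lie in [0, length]"
            )


@dataclass
class GenomeModel:
    """A set of chromosomes plus a relative recombination landscape.

    Parameters
    ----------
    chromosomes
        Ordered chromosomes.
    centromere_suppression
        Relative crossover intensity inside the centromere interval
        (1.0 disables suppression).  The landscape is piecewise constant:
        1.0 on the arms, this factor inside the centromere.
    """

    chromosomes: list[Chromosome]
    centromere_suppression: float = 0.05
    _by_name: dict = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise InputError("genome must contain at least one chromosome")
        if not (0.0 <= self.centromere_suppression <= 1.0):
            raise InputError("centromere_suppression must be in [0, 1]")
        self._by_name = {c.name: c for c in self.chromosomes}
        if len(self._by_name) != len(self.chromosomes):
            raise InputError("duplicate chromosome names")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def chromosome(self, name: str) -> Chromosome:
        try:
            return self._by_name[name]
        except KeyError:
            raise InputError(f"unknown chromosome {name!r}") from None

    def landscape(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """Piecewise-constant relative intensity: (bin edges Mb, intensity)."""
        chrom = self.chromosome(name)
        lo, hi = chrom.centromere_mb
        if hi <= lo or self.centromere_suppression == 1.0:
            return np.array([0.0, chrom.length_mb]), np.array([1.0])
        edges = [0.0, lo, hi, chrom.length_mb]
        intens = [1.0, self.centromere_suppression, 1.0]
        # drop zero-width arms (centromere touching a telomere)
        keep = [i for i in range(3) if edges[i + 1] > edges[i]]
        return (
            np.array([edges[0]] + [edges[i + 1] for i in keep]),
            np.array([intens[i] for i in keep]),
        )

    def _cumulative(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        edges, intens = self.landscape(name)
        cum = np.concatenate([[0.0], np.cumsum(np.diff(edges) * intens)])
        total = cum[-1]
        if total <= 0:
            raise InputError(f"chromosome {name}: landscape integrates to zero")
        return edges, cum / total

    def genetic_to_physical(self, name: str, fractions) -> np.ndarray:
        """Map genetic-coordinate fractions in [0, 1] to physical Mb."""
        edges, cum = self._cumulative(name)
        return np.interp(np.asarray(fractions, dtype=float), cum, edges)

    def physical_to_genetic(self, name: str, positions_mb) -> np.ndarray:
        """Map physical Mb positions to genetic-coordinate fractions."""
        edges, cum = self._cumulative(name)
        return np.interp(np.asarray(positions_mb, dtype=float), edges, cum)


@dataclass(frozen=True)
class Marker:
    name: str
    chromosome: str
    position_mb: float
    kind: str = "codominant_snp"  # or "ftl_fluorescent"


@dataclass
class MarkerPanel:
    """An ordered marker panel (sorted by chromosome then position)."""

    markers: list[Marker]

    def __post_init__(self) -> None:
        if not self.markers:
            raise InputError("marker panel is empty")
        key = lambda m: (m.chromosome, m.position_mb)
        self.markers = sorted(self.markers, key=key)
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise InputError("duplicate marker names")
        by_chrom: dict[str, list[float]] = {}
        for m in self.markers:
            by_chrom.setdefault(m.chromosome, []).append(m.position_mb)
        for chrom, pos in by_chrom.items():
            if len(set(pos)) != len(pos):
                raise InputError(f"duplicate marker positions on {chrom}")

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.markers]

    def by_chromosome(self) -> dict[str, list[Marker]]:
        out: dict[str, list[Marker]] = {}
        for m in self.markers:
            out.setdefault(m.chromosome, []).append(m)
        return out

    def ftl_triple(self) -> tuple[Marker, Marker, Marker]:
        """The three fluorescent markers defining intervals I1 (m1-m2) and I2 (m2-m3).

        Raises :class:`InputError` unless the panel carries exactly three
        fluorescent markers, all on one chromosome.
        """
        ftl = [m for m in self.markers if m.kind == "ftl_fluorescent"]
        if len(ftl) != 3:
            raise InputError(f"expected exactly 3 fluorescent markers, found {len(ftl)}")
        if len({m.chromosome for m in ftl}) != 1:
            raise InputError("fluorescent marker triple must be collinear on one chromosome")
        return ftl[0], ftl[1], ftl[2]

    def validate_against(self, genome: GenomeModel) -> None:
        for m in self.markers:
            chrom = genome.chromosome(m.chromosome)
            if not (0.0 <= m.position_mb <= chrom.length_mb):
                raise InputError(
                    f"marker {m.name} at {m.position_mb} Mb outside {m.chromosome}"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": self.names,
                "chromosome": [m.chromosome for m in self.markers],
                "position_mb": [m.position_mb for m in self.markers],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, kind: str = "codominant_snp") -> "MarkerPanel":
        required = {"marker", "chromosome", "position_mb"}
        if not required.issubset(df.columns):
            raise InputError(f"marker map needs columns {sorted(required)}")
        return cls(
            [
                Marker(str(r.marker), str(r.chromosome), float(r.position_mb), kind)
                for r in df.itertuples()
            ]
        )

    @classmethod
    def snp_grid(
        cls, genome: GenomeModel, spacing_mb: float = 1.5, flush_ends: bool = False
    ) -> "MarkerPanel":
        """An evenly spaced codominant marker grid over the whole genome.

        With ``flush_ends`` the grid runs telomere to telomere (markers at
        0 and at the chromosome end), so the map covers the full genetic
        length; otherwise markers start half a spacing in, as real marker
        panels do.
        """
        markers = []
        for chrom in genome.chromosomes:
            if flush_ends:
                n = max(int(round(chrom.length_mb / spacing_mb)), 1)
                pos = np.linspace(0.0, chrom.length_mb, n + 1)
            else:
                pos = np.arange(spacing_mb / 2.0, chrom.length_mb, spacing_mb)
            for i, p in enumerate(pos):
                markers.append(
                    Marker(f"{chrom.name}_m{i + 1:03d}", chrom.name, float(p))
                )
        return cls(markers)


def default_genome(centromere_suppression: float = 0.05) -> GenomeModel:
    """Five-chromosome genome with Arabidopsis-like sizes and centromeres."""
    return GenomeModel(
        chromosomes=[
            Chromosome("chr1", 30.4, (13.7, 15.9)),
            Chromosome("chr2", 19.7, (2.45, 5.5)),
            Chromosome("chr3", 23.5, (11.3, 14.3)),
            Chromosome("chr4", 18.6, (1.8, 5.15)),
            Chromosome("chr5", 27.0, (11.0, 13.35)),
        ],
        centromere_suppression=centromere_suppression,
    )


def single_chromosome_genome(length_mb: float = 20.0, name: str = "chr1") -> GenomeModel:
    """One chromosome with a uniform landscape (no centromere suppression)."""
    return GenomeModel([Chromosome(name, length_mb)], centromere_suppression=1.0)


def default_ftl_panel(
    genome: GenomeModel | None = None,
    chromosome: str | None = None,
    positions_mb: tuple[float, float, float] = (2.0, 6.0, 10.0),
) -> MarkerPanel:
    """A three-marker fluorescent panel on one chromosome."""
    genome = genome or default_genome()
    chromosome = chromosome or genome.chromosomes[0].name
    markers = [
        Marker(name, chromosome, p, "ftl_fluorescent")
        for name, p in zip(("m1", "m2", "m3"), positions_mb)
    ]
    panel = MarkerPanel(markers)
    panel.validate_against(genome)
    return panel
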