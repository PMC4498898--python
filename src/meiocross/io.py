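"""File formats and run configuration.

All artifacts are UTF-8 CSV with explicit headers, "." decimal
separator and "NA" as the missing token.  Metadata (seed, preset,
parameter echo) is written as leading ``# key: value`` comment lines so
every randomized output records how to reproduce it.

Formats
-------
* tetrad phenotype CSV: ``tetrad_id`` then presence bits
  ``g1_m1 .. g4_m3`` (grain x marker).
* tetrad class-count CSV: ``genotype, interval_pair, A .. L``.
* F2 genotype CSV: ``plant_id`` then one column per marker with
  ``AA/AB/BB/NA`` calls.
* marker map CSV: ``marker, chromosome, position_mb``.

Configuration is YAML (keys: chromosomes, centromere_suppression,
preset, context, nu, class2 settings, n, seed, spacing_mb, ftl);
command-line flags override config values.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, InputError
from .f2 import F2GenotypeMatrix
from .genome import Chromosome, GenomeModel, Marker, MarkerPanel, default_genome
from .tetrads import CLASS_LETTERS, Pattern, TetradClassCounts, canonical_pattern

__all__ = [
    "write_tetrad_patterns",
    "read_tetrad_patterns",
    "write_class_counts",
    "read_tetrad_counts",
    "write_f2",
    "read_marker_map",
    "read_genotype_csv",
    "write_dataframe",
    "load_config",
    "genome_from_config",
    "panel_from_config",
]

_GENO_TOKEN = {0.0: "AA", 1.0: "AB", 2.0: "BB"}
_TOKEN_GENO = {"AA": 0.0, "AB": 1.0, "BA": 1.0, "BB": 2.0, "NA": float("nan")}


def _write_meta(handle, meta: dict | None) -> None:
    for key, value in (meta or {}).items():
        handle.write(f"# {key}: {value}\n")


def _read_meta(path: Path) -> tuple[dict, int]:
    meta: dict[str, str] = {}
    n_comment = 0
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            if not line.startswith("#"):
                break
            n_comment += 1
            body = line[1:].strip()
            if ":" in body:
                key, value = body.split(":", 1)
                meta[key.strip()] = value.strip()
    return meta, n_comment


def write_tetrad_patterns(
    path, patterns, marker_names=("m1", "m2", "m3"), meta: dict | None = None
) -> None:
    """Write simulated tetrad fluorescence patterns (one row per tetrad)."""
    path = Path(path)
    columns = [f"g{g}_{m}" for g in range(1, 5) for m in marker_names]
    with open(path, "w", encoding="utf-8", newline="") as handle:
        _write_meta(handle, meta)
        writer = csv.writer(handle)
        writer.writerow(["tetrad_id", *columns])
        for i, pattern in enumerate(patterns, start=1):
            bits = [b for hap in pattern for b in hap]
            writer.writerow([f"tetrad_{i:06d}", *bits])


def read_tetrad_patterns(path) -> tuple[list[Pattern], dict]:
    """Read a tetrad phenotype CSV back into canonical patterns."""
    path = Path(path)
    meta, skip = _read_meta(path)
    df = pd.read_csv(path, skiprows=skip)
    bit_cols = [c for c in df.columns if c != "tetrad_id"]
    if len(bit_cols) != 12:
        raise FormatError(f"{path.name}: expected 12 presence-bit columns, found {len(bit_cols)}")
    patterns = []
    for _, row in df.iterrows():
        bits = row[bit_cols].to_numpy(dtype=int)
        patterns.append(canonical_pattern(bits.reshape(4, 3)))
    return patterns, meta


def write_class_counts(path, counts_list, meta: dict | None = None) -> None:
    """Write tetrad class counts: genotype, interval_pair, A..L."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as handle:
        _write_meta(handle, meta)
        writer = csv.writer(handle)
        writer.writerow(["genotype", "interval_pair", *CLASS_LETTERS])
        for counts in counts_list:
            writer.writerow(
                [counts.genotype, counts.interval_pair]
                + [counts.counts[c] for c in CLASS_LETTERS]
            )


def read_tetrad_counts(path) -> list[TetradClassCounts]:
    """Read a pre-tabulated class-count CSV (columns genotype, interval_pair, A..L)."""
    path = Path(path)
    _, skip = _read_meta(path)
    df = pd.read_csv(path, skiprows=skip)
    missing = [c for c in CLASS_LETTERS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing class columns {missing}")
    out = []
    for _, row in df.iterrows():
        counts = {c: int(row[c]) for c in CLASS_LETTERS}
        if any(v < 0 for v in counts.values()):
            raise FormatError(f"{path.name}: negative class count")
        out.append(
            TetradClassCounts(
                counts,
                genotype=str(row.get("genotype", "")),
                interval_pair=str(row.get("interval_pair", "")),
            )
        )
    return out


def write_f2(geno_path, map_path, matrix: F2GenotypeMatrix, meta: dict | None = None) -> None:
    """Write an F2 population: genotype CSV (AA/AB/BB/NA) + marker map CSV."""
    geno_path, map_path = Path(geno_path), Path(map_path)
    with open(geno_path, "w", encoding="utf-8", newline="") as handle:
        _write_meta(handle, meta)
        writer = csv.writer(handle)
        writer.writerow(["plant_id", *matrix.genotypes.columns])
        for plant_id, row in matrix.genotypes.iterrows():
            tokens = [
                "NA" if np.isnan(v) else _GENO_TOKEN[float(v)] for v in row.to_numpy()
            ]
            writer.writerow([plant_id, *tokens])
    matrix.marker_map.to_csv(map_path, index=False)


def read_marker_map(path) -> pd.DataFrame:
    path = Path(path)
    _, skip = _read_meta(path)
    df = pd.read_csv(path, skiprows=skip)
    required = {"marker", "chromosome", "position_mb"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path.name}: marker map needs columns {sorted(required)}")
    return df


def read_genotype_csv(path, marker_map: pd.DataFrame) -> F2GenotypeMatrix:
    """Read an F2 genotype CSV, validating against the marker map.

    Unknown genotype tokens become missing calls (a summary warning
    reports how many); a ragged row raises a :class:`FormatError`
    naming the line.
    """
    path = Path(path)
    _, skip = _read_meta(path)
    with open(path, encoding="utf-8") as handle:
        reader = csv.reader(handle)
        rows = list(reader)
    rows = rows[skip:]
    if not rows:
        raise FormatError(f"{path.name}: empty file")
    header = rows[0]
    if header[0] != "plant_id":
        raise FormatError(f"{path.name}: first column must be plant_id")
    markers = header[1:]
    if set(markers) != set(marker_map["marker"]):
        raise FormatError(f"{path.name}: genotype columns disagree with the marker map")
    plant_ids, data = [], []
    n_unknown = 0
    for lineno, row in enumerate(rows[1:], start=skip + 2):
        if not row:
            continue
        if len(row) != len(header):
            raise FormatError(
                f"{path.name} line {lineno}: expected {len(header)} fields, got {len(row)}"
            )
        plant_ids.append(row[0])
        vals = []
        for token in row[1:]:
            token = token.strip().upper()
            if token in _TOKEN_GENO:
                vals.append(_TOKEN_GENO[token])
            else:
                n_unknown += 1
                vals.append(float("nan"))
        data.append(vals)
    if n_unknown:
        warnings.warn(f"{path.name}: {n_unknown} unknown genotype tokens read as missing")
    genotypes = pd.DataFrame(
        data, index=pd.Index(plant_ids, name="plant_id"), columns=markers
    )
    return F2GenotypeMatrix(genotypes, marker_map)


def write_dataframe(path, df: pd.DataFrame, meta: dict | None = None) -> None:
    """Write an analysis result table with a metadata header."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as handle:
        _write_meta(handle, meta)
        df.to_csv(handle, index=False)


def load_config(path) -> dict:
    """Load a YAML run configuration."""
    with open(path, encoding="utf-8") as handle:
        config = yaml.safe_load(handle) or {}
    if not isinstance(config, dict):
        raise FormatError(f"{path}: configuration must be a mapping")
    return config


def genome_from_config(config: dict) -> GenomeModel:
    """Build the genome from config (defaults to the five-chromosome genome)."""
    chrom_cfg = config.get("chromosomes")
    suppression = float(config.get("centromere_suppression", 0.05))
    if not chrom_cfg:
        return default_genome(centromere_suppression=suppression)
    chromosomes = []
    for entry in chrom_cfg:
        try:
            chromosomes.append(
                Chromosome(
                    str(entry["name"]),
                    float(entry["length_mb"]),
                    tuple(entry.get("centromere_mb", (0.0, 0.0))),
                )
            )
        except KeyError as exc:
            raise FormatError(f"chromosome entry missing key {exc}") from None
    return GenomeModel(chromosomes, centromere_suppression=suppression)


def panel_from_config(config: dict, genome: GenomeModel, kind: str) -> MarkerPanel:
    """Build a marker panel: FTL triple or codominant grid."""
    if kind == "ftl":
        ftl = config.get("ftl", {})
        chrom = ftl.get("chromosome", genome.chromosomes[0].name)
        positions = ftl.get("positions_mb", (2.0, 6.0, 10.0))
        if len(positions) != 3:
            raise FormatError("ftl.positions_mb must list three positions")
        panel = MarkerPanel(
            [
                Marker(name, chrom, float(p), "ftl_fluorescent")
                for name, p in zip(("m1", "m2", "m3"), positions)
            ]
        )
    elif kind == "snp":
        spacing = float(config.get("spacing_mb", 1.5))
        panel = MarkerPanel.snp_grid(genome, spacing)
    else:
        raise InputError("panel kind must be 'ftl' or 'snp'")
    panel.validate_against(genome)
    return panel
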