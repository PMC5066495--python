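"""Configuration objects for the simulator and the genome scan.

Both configs are plain dataclasses with eager validation, loadable from
YAML or JSON mappings so that a whole run is reproducible from one file
plus a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import yaml

#: Canonical VCF sample names emitted by the simulator and expected by the
#: scan defaults.  The B-efficient parent is 'QY10'-like, the B-inefficient
#: parent 'W10'-like; bulks are pools of the phenotypic extremes.
SAMPLE_PARENT_BE = "parent_QY10"
SAMPLE_PARENT_BINE = "parent_W10"
SAMPLE_BULK_BE = "bulk_BE"
SAMPLE_BULK_BINE = "bulk_BinE"


class ConfigError(ValueError):
    """Raised when a configuration value violates an invariant."""


@dataclass(frozen=True)
class PlantedQtl:
    """A trait locus planted by the simulator.

    ``effect`` is the trait increment (grams of low-B dry biomass) added
    per allele inherited from the B-efficient parent.  A negative effect
    means the B-inefficient parent's allele raises the trait, and the
    locus is expected to surface with a negative Δ(SNP-index).
    """

    chromosome: str
    position: int
    effect: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ConfigError(f"QTL position must be >= 1, got {self.position}")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study design the package emulates: a 190-line DH
    population, bulks of the 22 most extreme lines per tail, ~18x parent
    and ~45x bulk sequencing depth, and a low-B dry-biomass trait with a
    61% coefficient of variation spanning 0.0085-0.24 g per plant.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"A01": 8_000_000, "C02": 8_000_000}
    )
    n_lines: int = 190
    bulk_size: int = 22
    parent_depth: float = 18.0
    bulk_depth: float = 45.0
    marker_spacing: int = 10_000
    cm_per_mb: float = 2.0
    qtls: list[PlantedQtl] = field(default_factory=list)
    trait_cv: float = 0.61
    trait_range: tuple[float, float] = (0.0085, 0.24)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ConfigError("chrom_lengths must be non-empty")
        for name, length in self.chrom_lengths.items():
            if length <= 0:
                raise ConfigError(f"chromosome {name!r} has non-positive length {length}")
        if self.n_lines < 2:
            raise ConfigError("n_lines must be >= 2")
        if not 1 <= self.bulk_size <= self.n_lines // 2:
            raise ConfigError(
                f"bulk_size must satisfy 1 <= bulk_size <= n_lines/2 "
                f"(got {self.bulk_size} with {self.n_lines} lines)"
            )
        if self.marker_spacing <= 0:
            raise ConfigError("marker_spacing must be positive")
        if self.cm_per_mb < 0:
            raise ConfigError("cm_per_mb must be >= 0")
        if self.trait_cv < 0:
            raise ConfigError("trait_cv must be >= 0")
        lo, hi = self.trait_range
        if not lo < hi:
            raise ConfigError(f"trait_range min must be < max, got {self.trait_range}")
        if lo < 0:
            raise ConfigError("trait_range must be non-negative")
        self.qtls = [q if isinstance(q, PlantedQtl) else PlantedQtl(**q) for q in self.qtls]
        for q in self.qtls:
            if q.chromosome not in self.chrom_lengths:
                raise ConfigError(f"QTL {q.label!r} on unknown chromosome {q.chromosome!r}")
            if q.position > self.chrom_lengths[q.chromosome]:
                raise ConfigError(
                    f"QTL {q.label!r} position {q.position} exceeds chromosome length"
                )

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "trait_range" in d:
            d["trait_range"] = tuple(d["trait_range"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(_load_mapping(path))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["trait_range"] = list(self.trait_range)
        return d


@dataclass
class ScanConfig:
    """Parameters of the Δ(SNP-index) sliding-window scan.

    The window geometry (1 Mb window, 10 kb step), the per-bulk minimum
    depth of 7 and the both-bulks SNP-index < 0.3 filter follow standard
    QTL-seq practice; the null band is computed for a DH bulk design
    (homozygous lines, no heterozygotes).
    """

    window_size: int = 1_000_000
    step: int = 10_000
    min_depth: int = 7
    low_index_filter: float = 0.3
    low_index_filter_on: bool = True
    min_snps_per_window: int = 10
    ci_level: float = 0.99
    bulk_size: int = 22
    n_null_reps: int | None = None  # None -> exact enumeration
    min_consecutive_windows: int = 5
    bulk_be: str = SAMPLE_BULK_BE
    bulk_bine: str = SAMPLE_BULK_BINE
    parent_be: str | None = SAMPLE_PARENT_BE
    parent_bine: str | None = SAMPLE_PARENT_BINE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_size <= 0 or self.step <= 0:
            raise ConfigError("window_size and step must be positive")
        if self.step > self.window_size:
            raise ConfigError("step must be <= window_size")
        if self.min_depth < 0:
            raise ConfigError("min_depth must be >= 0")
        if not 0.0 <= self.low_index_filter <= 1.0:
            raise ConfigError("low_index_filter must lie in [0, 1]")
        if not 0.5 < self.ci_level < 1.0:
            raise ConfigError("ci_level must lie in (0.5, 1)")
        if self.bulk_size < 1:
            raise ConfigError("bulk_size must be >= 1")
        if self.min_snps_per_window < 1:
            raise ConfigError("min_snps_per_window must be >= 1")
        if self.min_consecutive_windows < 1:
            raise ConfigError("min_consecutive_windows must be >= 1")
        if self.n_null_reps is not None and self.n_null_reps < 100:
            raise ConfigError("n_null_reps must be >= 100 (or None for exact)")

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScanConfig":
        return cls(**dict(d))

    @classmethod
    def from_file(cls, path: str | Path) -> "ScanConfig":
        return cls.from_dict(_load_mapping(path))

    def to_dict(self) -> dict:
        return asdict(self)


def _load_mapping(path: str | Path) -> dict:
    """Load a YAML or JSON mapping from disk."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"{path} does not contain a mapping")
    return data
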