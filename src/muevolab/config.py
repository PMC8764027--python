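"""Run-level configuration and reproducible seed derivation.

A single global seed is stored in :class:`RunConfig`; every stochastic
operation derives a child seed from ``(global seed, operation name, group
keys)`` so that results are reproducible and independent of the order in
which treatment groups are processed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, fields

import numpy as np
import yaml

CULTURE_TYPES = ("TRP_mono", "TYR_mono", "CO")
ANTIBIOTICS = ("AMP", "KAN", "CHL", "TET")
STRAINS = ("TRP", "TYR")

#: sampling grid (hours) of the colony-count growth-kinetics assay
TIME_GRID_H = (0, 3, 6, 9, 12, 15, 18, 21, 24, 30, 42, 48, 54, 66, 72)


def child_seed(seed: int, *keys) -> int:
    """Derive a reproducible child seed below 2**31 from a global seed and keys."""
    h = zlib.crc32("|".join(str(k) for k in keys).encode("utf-8"))
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, h])
    return int(ss.generate_state(1)[0] % (2**31))


def child_rng(seed: int, *keys) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, *keys))


@dataclass
class RunConfig:
    """Experiment-wide constants of the ramping evolution design.

    Defaults encode the standard design: 15 serial transfers every 72 h,
    1/25 dilution (40 µl into 960 µl), extinction below OD600 0.01, sub-MIC
    threshold zone OD600 0.05 +/- 0.005, 100 µM amino-acid supplementation
    for monocultures, and 16 lineages x 5 technical replicates = 80
    replicates per treatment cell.
    """

    random_seed: int = 0
    n_transfers: int = 15
    death_threshold: float = 0.01
    zone_center: float = 0.05
    zone_halfwidth: float = 0.005
    dilution_factor: float = 1.0 / 25.0
    supplement_conc: float = 100.0  # µM, each amino acid
    n_permutations: int = 10**6
    n_lineages: int = 16
    n_technical: int = 5
    end_factor: float = 1.1  # ramp endpoint = end_factor * working concentration
    doubling_start_transfer: int = 2

    def __post_init__(self) -> None:
        if self.n_transfers <= 0:
            raise ValueError("n_transfers must be positive")
        for name in ("death_threshold", "zone_center", "zone_halfwidth",
                     "supplement_conc", "end_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.zone_halfwidth >= self.zone_center:
            raise ValueError("zone_halfwidth must be smaller than zone_center")
        if not 0.0 < self.dilution_factor < 1.0:
            raise ValueError("dilution_factor must lie in (0, 1)")
        if self.n_permutations < 1 or self.n_lineages < 1 or self.n_technical < 1:
            raise ValueError("counts must be at least 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({f.name: getattr(self, f.name) for f in fields(self)}, fh)
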