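"""Sub-MIC determination, antibiotic ramp generation, and experiment design.

The ramping design has two phases. During the first two transfers no
antibiotic is applied, letting populations equilibrate. From transfer 2 the
concentration doubles each transfer, starting at one-eighth of the
experimentally determined sub-MIC and reaching the sub-MIC at transfer 5.
Afterwards the concentration increases linearly up to an endpoint slightly
above the antibiotic's standard working concentration (endpoint =
``end_factor`` x working concentration, default 1.1x).

The sub-MIC itself is read off a dose-response plate: it is the
concentration whose replicate OD600 readings sit inside the threshold zone
(OD 0.05 +/- 0.005), with averaging rules for multiple or partial hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import ANTIBIOTICS, CULTURE_TYPES, RunConfig

#: sub-MIC values (µg/ml) determined for the ancestral consortia
DEFAULT_SUB_MIC = {"AMP": 0.75, "CHL": 3.25, "KAN": 1.25, "TET": 1.35}
#: standard selective working concentrations (µg/ml)
DEFAULT_WORKING_CONC = {"AMP": 100.0, "CHL": 25.0, "KAN": 50.0, "TET": 15.0}

#: number of doubling steps from sub_mic/8 up to sub_mic
N_DOUBLING_STEPS = 4


class SubMICError(ValueError):
    """No concentration on the plate intersects the threshold zone."""


@dataclass(frozen=True)
class ThresholdZone:
    """Closed OD600 interval [center - halfwidth, center + halfwidth]."""

    center: float = 0.05
    halfwidth: float = 0.005

    def __post_init__(self) -> None:
        if not 0 < self.halfwidth < self.center:
            raise ValueError("require 0 < halfwidth < center")

    @property
    def lo(self) -> float:
        return self.center - self.halfwidth

    @property
    def hi(self) -> float:
        return self.center + self.halfwidth

    def contains(self, od) -> np.ndarray:
        od = np.asarray(od, dtype=float)
        return (od >= self.lo) & (od <= self.hi)


def _group_ods(plate) -> list[tuple[float, np.ndarray]]:
    """Normalise a plate to an ascending list of (concentration, OD array)."""
    if isinstance(plate, pd.DataFrame):
        pairs = [(float(c), sub["od600"].astype(float).to_numpy())
                 for c, sub in plate.groupby("concentration")]
    elif isinstance(plate, Mapping):
        pairs = [(float(c), np.atleast_1d(np.asarray(v, dtype=float)))
                 for c, v in plate.items()]
    else:
        raise TypeError("plate must be a DataFrame or a mapping conc -> ODs")
    pairs.sort(key=lambda p: p[0])
    if len(pairs) < 2:
        raise ValueError("need at least 2 concentrations to resolve a sub-MIC")
    if any(len(v) == 0 for _, v in pairs):
        raise ValueError("every concentration needs at least one OD reading")
    return pairs


def determine_sub_mic(plate, zone: ThresholdZone | None = None) -> float:
    """Determine the sub-MIC concentration from a dose-response plate.

    Scanning concentrations in ascending order:

    * exactly one concentration has *all* replicate ODs inside the zone ->
      that concentration;
    * several concentrations are fully inside -> their arithmetic mean;
    * otherwise, at the lowest concentration with a *partial* overlap: if a
      higher concentration was measured, return the mean of the two; if it
      is the last measured concentration, return it as is.

    Raises :class:`SubMICError` when no OD reading intersects the zone,
    reporting the reading closest to the zone.
    """
    zone = zone or ThresholdZone()
    pairs = _group_ods(plate)

    full = [c for c, ods in pairs if zone.contains(ods).all()]
    if len(full) == 1:
        return full[0]
    if len(full) > 1:
        return float(np.mean(full))

    partial_idx = [i for i, (_, ods) in enumerate(pairs)
                   if zone.contains(ods).any()]
    if partial_idx:
        i = partial_idx[0]
        c = pairs[i][0]
        if i + 1 < len(pairs):
            return (c + pairs[i + 1][0]) / 2.0
        return c

    all_ods = np.concatenate([ods for _, ods in pairs])
    nearest = all_ods[np.argmin(np.abs(all_ods - zone.center))]
    raise SubMICError(
        f"no sub-MIC resolvable: no OD inside [{zone.lo}, {zone.hi}]; "
        f"nearest OD = {nearest:.4g}")


@dataclass(frozen=True)
class RampSchedule:
    """Per-transfer antibiotic concentration of the ramping design."""

    antibiotic: str
    sub_mic: float
    working_conc: float
    end_conc: float
    conc_by_transfer: tuple[float, ...]

    @property
    def n_transfers(self) -> int:
        return len(self.conc_by_transfer) - 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"transfer": np.arange(len(self.conc_by_transfer)),
                             "concentration": self.conc_by_transfer})


def build_ramp(sub_mic: float, working_conc: float,
               cfg: RunConfig | None = None, *,
               antibiotic: str = "NONE") -> RampSchedule:
    """Build the doubling-then-linear concentration schedule.

    Transfers 0-1 are antibiotic-free; transfers 2-5 double from
    ``sub_mic/8`` to ``sub_mic``; transfers 6..n increase linearly with a
    constant increment up to ``end_factor * working_conc``.
    """
    cfg = cfg or RunConfig()
    if not 0 < sub_mic < working_conc:
        raise ValueError(
            f"require 0 < sub_mic < working_conc, got {sub_mic} >= {working_conc}")
    start = cfg.doubling_start_transfer
    last_doubling = start + N_DOUBLING_STEPS - 1
    n = cfg.n_transfers
    if n < last_doubling + 1:
        raise ValueError(
            f"n_transfers={n} leaves no room for the linear phase "
            f"(doubling ends at transfer {last_doubling})")
    end_conc = cfg.end_factor * working_conc
    conc = np.zeros(n + 1)
    for k in range(N_DOUBLING_STEPS):
        conc[start + k] = sub_mic / 2 ** (N_DOUBLING_STEPS - 1 - k)
    increment = (end_conc - sub_mic) / (n - last_doubling)
    for t in range(last_doubling + 1, n + 1):
        conc[t] = sub_mic + increment * (t - last_doubling)
    conc[n] = end_conc  # guard against float drift at the endpoint
    return RampSchedule(antibiotic=antibiotic, sub_mic=float(sub_mic),
                        working_conc=float(working_conc),
                        end_conc=float(end_conc),
                        conc_by_transfer=tuple(float(c) for c in conc))


def default_ramps(cfg: RunConfig | None = None) -> dict[str, RampSchedule]:
    """Ramp schedules for all four antibiotics with the standard constants."""
    cfg = cfg or RunConfig()
    return {ab: build_ramp(DEFAULT_SUB_MIC[ab], DEFAULT_WORKING_CONC[ab],
                           cfg, antibiotic=ab)
            for ab in ANTIBIOTICS}


@dataclass
class ExperimentDesign:
    """Full factorial design: culture types x antibiotics x replicates."""

    culture_types: tuple[str, ...]
    antibiotics: tuple[str, ...]
    n_lineages: int
    n_technical: int
    table: pd.DataFrame = field(repr=False)

    @property
    def replicates_per_cell(self) -> int:
        return self.n_lineages * self.n_technical

    def cell(self, culture_type: str, antibiotic: str) -> pd.DataFrame:
        t = self.table
        return t[(t["culture_type"] == culture_type)
                 & (t["antibiotic"] == antibiotic)]


def build_design(cfg: RunConfig | None = None,
                 culture_types: Sequence[str] = CULTURE_TYPES,
                 antibiotics: Sequence[str] = ANTIBIOTICS) -> ExperimentDesign:
    """Enumerate every replicate lineage of the evolution experiment.

    Each (culture type, antibiotic) cell holds ``n_lineages`` founder
    lineages, each split into ``n_technical`` technical replicates at the
    start of the antibiotic treatment. Monocultures are supplemented with
    both amino acids (100 µM each); cocultures are not.
    """
    cfg = cfg or RunConfig()
    rows = []
    for ct in culture_types:
        for ab in antibiotics:
            for lin in range(cfg.n_lineages):
                for tech in range(cfg.n_technical):
                    rows.append({
                        "culture_type": ct,
                        "antibiotic": ab,
                        "lineage": lin,
                        "technical": tech,
                        "replicate_id": f"{ct}:{ab}:L{lin:02d}T{tech}",
                        "supplemented": ct != "CO",
                    })
    return ExperimentDesign(culture_types=tuple(culture_types),
                            antibiotics=tuple(antibiotics),
                            n_lineages=cfg.n_lineages,
                            n_technical=cfg.n_technical,
                            table=pd.DataFrame(rows))
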