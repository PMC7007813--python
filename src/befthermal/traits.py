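"""Species trait records and the simulation configuration.

A :class:`SpeciesTraits` record carries everything the simulator needs to
know about one phytoplankton species: the four Sharpe-Schoolfield
parameters describing its acute thermal performance curve for gross
photosynthesis, its true thermal optimum, its cell volume, its chlorophyll-a
content per cell, and the log-scale location/spread of its flow-cytometry
cluster in the forward-scatter (FSC), side-scatter (SSC) and red
fluorescence (FL3) channels.

:class:`SimulationConfig` collects every tunable of the synthetic
experiment (species pool, assay protocol, treatment structure, noise
levels) in one frozen, file-round-trippable object, so that a single seed
fully determines every generated table.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Tuple

import numpy as np

from .constants import BOLTZMANN_EV, CELSIUS_OFFSET


@dataclass(frozen=True)
class SpeciesTraits:
    """Thermal and cytometric parameters for one species.

    Thermal parameters follow the high-temperature-deactivation
    Sharpe-Schoolfield form: ``lnb_tc`` is the log rate at the reference
    temperature (log ug O2 cell^-1 h^-1), ``E`` the activation energy (eV),
    ``Eh`` the deactivation energy (eV), ``Th`` the high-temperature
    inflection (K). ``topt_true`` (K) is the closed-form optimum implied by
    (E, Eh, Th). Cytometry cluster parameters are means/sds on the log10
    channel scale.
    """

    species_id: str
    lnb_tc: float
    E: float
    Eh: float
    Th: float
    topt_true: float
    cell_volume: float          # um^3
    chl_per_cell: float         # pg cell^-1
    fl3_mu: float
    fl3_sigma: float
    fsc_mu: float
    fsc_sigma: float
    ssc_mu: float
    ssc_sigma: float

    def __post_init__(self):
        if not (self.Eh > self.E > 0):
            raise ValueError(
                f"{self.species_id}: need Eh > E > 0 for a unimodal "
                f"left-skewed curve, got E={self.E}, Eh={self.Eh}"
            )
        if self.Th <= 0:
            raise ValueError(f"{self.species_id}: Th must be positive (K)")
        if not self.topt_true < self.Th:
            raise ValueError(f"{self.species_id}: topt_true must lie below Th")
        for name in ("fl3_sigma", "fsc_sigma", "ssc_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{self.species_id}: {name} must be > 0")
        if self.chl_per_cell <= 0:
            raise ValueError(f"{self.species_id}: chl_per_cell must be > 0")
        if self.cell_volume <= 0:
            raise ValueError(f"{self.species_id}: cell_volume must be > 0")

    @property
    def topt_true_C(self) -> float:
        return self.topt_true - CELSIUS_OFFSET


def _divisor_levels(n: int) -> Tuple[int, ...]:
    return tuple(d for d in (1, 2, 4, 8, 16) if n % d == 0 and d <= n)


@dataclass(frozen=True)
class SimulationConfig:
    """All tunables of the synthetic experiment.

    Defaults reproduce the study conditions: a 16-species pool whose
    thermal optima span 11.7 degC, acute assays from 7 to 49 degC,
    treatment temperatures 15/25/30 degC, 5 independent partitions of the
    pool at richness levels 1/2/4/8/16 with 3 replicates each, and a total
    inoculum of 1600 cells/mL split evenly among the species present.
    """

    n_species: int = 16
    topt_range: Tuple[float, float] = (21.5, 33.2)       # degC
    assay_temperatures: Tuple[float, ...] = tuple(
        float(t) for t in range(7, 50, 3)
    )                                                     # degC, 15 levels
    irradiances: Tuple[float, ...] = (
        0.0, 25.0, 50.0, 100.0, 200.0, 400.0, 800.0, 1200.0, 1800.0
    )                                                     # umol m^-2 s^-1
    noise_sd_rate: float = 0.10       # sd of ln-rate measurement noise
    temperatures: Tuple[float, ...] = (15.0, 25.0, 30.0)  # treatment, degC
    richness_levels: Tuple[int, ...] | None = None        # default: divisors
    n_partitions: int = 5
    n_replicates: int = 3
    inoculation_density: float = 1600.0                   # cells mL^-1 total
    # community outcome model
    capacity_scale: float = 5e4       # pg chl a mL^-1 at 15 degC at peak
    biomass_decline_rate: float = 0.10   # per degC, equilibrium decline
    dominance_exponent: float = 2.0      # selection-effect strength
    well_noise_sd: float = 0.5           # sd of ln well-level noise
    respiration_fraction: float = 0.3    # R as a fraction of GP
    pi_saturation_irradiance: float = 150.0  # umol m^-2 s^-1 (= NPmax/alpha)
    # cytometry
    debris_fraction: float = 0.2
    cluster_sigma: float = 0.10          # log10 channel units
    min_cluster_separation: float = 0.5  # log10 Euclidean distance
    calibration_slope: float = 1.0       # log10 chl ~ slope*log10 FL3 + b
    calibration_intercept: float = -5.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.topt_range
        if not lo < hi:
            raise ValueError(f"invalid topt_range: min {lo} >= max {hi}")
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        levels = self.richness_levels
        if levels is None:
            levels = _divisor_levels(self.n_species)
            object.__setattr__(self, "richness_levels", levels)
        for s in levels:
            if self.n_species % s != 0:
                raise ValueError(
                    f"richness level {s} does not divide the pool size "
                    f"{self.n_species}"
                )
        if len(self.assay_temperatures) == 0:
            raise ValueError("assay_temperatures must be non-empty")
        for name in ("noise_sd_rate", "well_noise_sd", "debris_fraction"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.cluster_sigma <= 0:
            raise ValueError("cluster_sigma must be > 0")
        if self.inoculation_density <= 0:
            raise ValueError("inoculation_density must be > 0")

    # -- plain-text (key = value) round trip --------------------------------

    def to_file(self, path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, tuple):
                v = ",".join(str(x) for x in v)
            lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "SimulationConfig":
        raw = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            raw[key.strip()] = val.strip()
        kwargs = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for key, val in raw.items():
            if key not in fields:
                raise ValueError(f"unknown config key: {key!r}")
            kwargs[key] = _parse_field(fields[key], val)
        return cls(**kwargs)


def _parse_field(field: dataclasses.Field, text: str):
    if text == "None":
        return None
    base = str(field.type)
    if "Tuple" in base or "tuple" in base:
        parts = [p for p in text.split(",") if p.strip()]
        if "int" in base:
            return tuple(int(float(p)) for p in parts)
        return tuple(float(p) for p in parts)
    if field.name in ("n_species", "n_partitions", "n_replicates", "seed"):
        return int(text)
    return float(text)


def substream(seed: int, name: str) -> np.random.Generator:
    """A named, independent random substream derived from one master seed.

    Each pipeline stage draws from its own substream so stages can be
    re-run independently with identical results.
    """
    import zlib

    key = zlib.crc32(name.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))
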