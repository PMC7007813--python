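"""Synthetic data generator for the biodiversity x warming experiment.

Everything downstream of the wet lab is testable against this module: it
generates (i) a pool of species with heterogeneous thermal optima and
distinguishable cytometry clusters, (ii) simulated thermal assays (raw
photosynthesis-irradiance measurements or reduced gross-photosynthesis
tables) following each species' Sharpe-Schoolfield curve, (iii) endpoint
community outcomes over a random-partition design, and (iv) flow-cytometry
event tables with per-species lognormal clusters plus sub-threshold debris.

All randomness flows through named substreams of one master seed
(:func:`befthermal.traits.substream`), so a config plus seed determines
every output bit-for-bit and stages can be re-run independently.

The community outcome model
---------------------------
The experiment measures a single endpoint, so no population dynamics are
simulated.  Resources, not cell numbers, set the ceiling: each species
has a monoculture biomass carrying capacity (total chlorophyll a, pg/mL)

    C_i(T) = C0 * g_i(T) * exp(-lambda * (T - 15))

where g_i(T) is the species' Sharpe-Schoolfield performance normalised to
its own peak (a 0..1 thermal suitability, so cell-size differences in
per-cell metabolic rate do not leak into biomass capacities) and the
exponential factor encodes the decline of equilibrium biomass with
temperature.  A community's total biomass is a dominance-weighted average
of the capacities of its members, with weights w_i proportional to
g_i(T)^theta: theta -> infinity gives a pure selection effect (the
community performs like its best member), theta = 0 gives even
allocation.  Per-species biomass is the community total split by the same
weights; per-species abundance divides each biomass share by the species'
chlorophyll per cell; one lognormal noise factor per well.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .constants import CELSIUS_OFFSET, BOLTZMANN_EV as KB
from .design import DesignTable, SPECIES_SEP, generate_full_design
from .thermal import sharpe_schoolfield_ln_rate, thermal_optimum
from .traits import SimulationConfig, SpeciesTraits, substream

__all__ = [
    "generate_species_pool", "simulate_tpc_assay", "simulate_pi_assays",
    "simulate_community_experiment", "simulate_cytometry_events",
    "simulate_bef_response", "default_design", "CommunityExperiment",
]


# ---------------------------------------------------------------------------
# Species pool
# ---------------------------------------------------------------------------

def _th_from_topt(topt_K: np.ndarray, E: np.ndarray, Eh: np.ndarray) -> np.ndarray:
    """Invert the closed-form optimum: Th giving the requested Topt."""
    L = np.log(Eh / E - 1.0)
    return topt_K * Eh / (Eh - KB * topt_K * L)


def _repel_centres(centres: np.ndarray, min_sep: float,
                   floors: np.ndarray, max_iter: int = 500) -> np.ndarray:
    """Deterministically push cluster centres apart to a minimum distance.

    Pairs closer than ``min_sep`` move symmetrically apart along their
    connecting vector; coordinates are clamped to the live-cell floors so
    no centre drifts into the debris gate.
    """
    c = centres.copy()
    n = len(c)
    for _ in range(max_iter):
        d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        if d[i, j] >= min_sep:
            break
        v = c[i] - c[j]
        norm = np.linalg.norm(v)
        if norm < 1e-9:
            v = np.array([1.0, -1.0, 1.0]) / np.sqrt(3.0)
            norm = 1.0
        shift = (min_sep - d[i, j]) / 2.0 * 1.05 * v / norm
        c[i] = np.maximum(floors, c[i] + shift)
        c[j] = np.maximum(floors, c[j] - shift)
        # if clamped at a floor, push the pair apart along the free axes
        if np.linalg.norm(c[i] - c[j]) < d[i, j] + 1e-12:
            c[i] = c[i] + np.abs(shift)
    return c


def generate_species_pool(config: SimulationConfig) -> List[SpeciesTraits]:
    """Draw a pool of species traits under the configured conditions.

    Thermal optima are spread evenly across ``config.topt_range``;
    activation/deactivation energies are drawn in ranges typical for
    photosynthesis (E ~ 0.5-0.9 eV, Eh ~ 2.2-4.5 eV) and the inflection
    temperature Th is solved so the closed form reproduces the intended
    optimum.  Cell volume spans picoplankton to large microplankton
    (2-1500 um^3) in a random order relative to the thermal optima, so
    size and thermal tolerance are decoupled traits.  Cytometry cluster
    centres follow cell volume (FSC, SSC) and chlorophyll content (FL3)
    with independent jitter, redrawn until all pairwise centre distances
    reach ``config.min_cluster_separation`` (classifier separability is a
    property of the pool, with configurable overlap via the jitter and
    ``cluster_sigma``).
    """
    rng = substream(config.seed, "pool")
    n = config.n_species
    lo, hi = config.topt_range
    topt_C = np.linspace(lo, hi, n)
    topt_K = topt_C + CELSIUS_OFFSET
    E = rng.uniform(0.5, 0.9, n)
    Eh = rng.uniform(3.0, 6.0, n)
    Th = _th_from_topt(topt_K, E, Eh)

    ln_vol = np.linspace(np.log(2.0), np.log(1500.0), n)
    ln_vol = ln_vol[rng.permutation(n)]
    volume = np.exp(ln_vol)
    lnb_tc = -14.0 + 0.35 * ln_vol + rng.normal(0.0, 0.3, n)

    sig = config.cluster_sigma
    chl_jitter = rng.normal(0.0, 0.35, n)
    log_chl = np.log10(0.05) + 0.8 * np.log10(volume) + chl_jitter
    fl3_mu = np.maximum(3.8, log_chl - config.calibration_intercept) \
        / config.calibration_slope
    fsc_mu = np.maximum(5.35, 5.25 + 0.45 * np.log10(volume)
                        + rng.normal(0.0, 0.20, n))
    ssc_mu = np.maximum(5.35, 5.20 + 0.40 * np.log10(volume)
                        + rng.normal(0.0, 0.25, n))
    centres = np.column_stack([fsc_mu, ssc_mu, fl3_mu])
    centres = _repel_centres(centres, config.min_cluster_separation,
                             floors=np.array([5.35, 5.35, 3.8]))
    fsc_mu, ssc_mu, fl3_mu = centres.T
    # chlorophyll per cell is defined to be exactly consistent with the
    # calibration curve applied downstream
    chl = 10.0 ** (config.calibration_slope * fl3_mu
                   + config.calibration_intercept)

    width = int(np.ceil(np.log10(n + 1)))
    pool = []
    for i in range(n):
        pool.append(SpeciesTraits(
            species_id=f"sp{i + 1:0{max(width, 2)}d}",
            lnb_tc=float(lnb_tc[i]), E=float(E[i]), Eh=float(Eh[i]),
            Th=float(Th[i]),
            topt_true=float(thermal_optimum(E[i], Eh[i], Th[i])),
            cell_volume=float(volume[i]), chl_per_cell=float(chl[i]),
            fl3_mu=float(fl3_mu[i]), fl3_sigma=sig,
            fsc_mu=float(fsc_mu[i]), fsc_sigma=sig,
            ssc_mu=float(ssc_mu[i]), ssc_sigma=sig,
        ))
    return pool


def pool_to_frame(pool: Sequence[SpeciesTraits]) -> pd.DataFrame:
    return pd.DataFrame([vars(sp) for sp in pool])


# ---------------------------------------------------------------------------
# Thermal assays
# ---------------------------------------------------------------------------

def _ln_gp(traits: SpeciesTraits, temp_C, tc_ref=291.15):
    return sharpe_schoolfield_ln_rate(
        np.asarray(temp_C, float), traits.lnb_tc, traits.E, traits.Eh,
        traits.Th, tc_ref
    )


def simulate_tpc_assay(
    traits: SpeciesTraits,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Simulated gross-photosynthesis rates at each assay temperature.

    Rates are the Sharpe-Schoolfield expectation times multiplicative
    lognormal noise with log-scale sd ``config.noise_sd_rate``; strictly
    positive by construction.
    """
    if len(config.assay_temperatures) == 0:
        raise ValueError("assay_temperatures must be non-empty")
    if rng is None:
        rng = substream(config.seed, f"tpc:{traits.species_id}")
    temps = np.asarray(config.assay_temperatures, float)
    gp = np.exp(_ln_gp(traits, temps)
                + config.noise_sd_rate * rng.standard_normal(len(temps)))
    return pd.DataFrame({
        "species_id": traits.species_id,
        "assay_temp_C": temps,
        "gp_rate": gp,
    })


def simulate_pi_assays(
    pool: Sequence[SpeciesTraits],
    config: SimulationConfig,
    cell_density: float = 5e5,
) -> pd.DataFrame:
    """Raw photosynthesis-irradiance assays for every species.

    At each assay temperature the net O2 evolution rate is measured over
    the irradiance gradient (dark rows, irradiance 0, record respiration
    as O2 consumption, i.e. negative rates).  NPmax = (1 - f_R) * GP and
    R = f_R * GP with f_R = ``config.respiration_fraction``; the light
    response is saturating (tanh) with saturation irradiance
    ``config.pi_saturation_irradiance``.  Multiplicative lognormal noise
    applies per measurement.  Output columns match the rates CSV contract:
    species_id, assay_temp_C, irradiance_umol_m2_s, o2_rate,
    cell_density_per_mL.
    """
    rng = substream(config.seed, "pi_assays")
    irr = np.asarray(config.irradiances, float)
    rows = []
    for traits in pool:
        for t in config.assay_temperatures:
            gp = float(np.exp(_ln_gp(traits, t)))
            resp = config.respiration_fraction * gp
            npmax = gp - resp
            alpha = npmax / config.pi_saturation_irradiance
            mean = np.where(
                irr > 0, npmax * np.tanh(alpha * irr / max(npmax, 1e-300)),
                -resp,
            )
            noise = np.exp(config.noise_sd_rate
                           * rng.standard_normal(len(irr)))
            rows.append(pd.DataFrame({
                "species_id": traits.species_id,
                "assay_temp_C": float(t),
                "irradiance_umol_m2_s": irr,
                "o2_rate": mean * noise,
                "cell_density_per_mL": cell_density,
            }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Community outcomes
# ---------------------------------------------------------------------------

@dataclass
class CommunityExperiment:
    """Endpoint outcomes of the simulated biodiversity experiment."""

    units: pd.DataFrame            # one row per well, with totals
    species_abundances: pd.DataFrame  # long: unit_id x species_id -> cells/mL


def _normalised_performance(traits: SpeciesTraits, temp_C: float) -> float:
    """Thermal performance at temp scaled to the species' own peak (0..1]."""
    ln_at_t = float(_ln_gp(traits, temp_C))
    ln_at_peak = float(_ln_gp(traits, traits.topt_true_C))
    return float(np.exp(ln_at_t - ln_at_peak))


def monoculture_capacity(traits: SpeciesTraits, temp_C: float,
                         config: SimulationConfig) -> float:
    """Expected monoculture biomass capacity (pg chl a/mL) at a temperature."""
    g = _normalised_performance(traits, temp_C)
    decline = np.exp(-config.biomass_decline_rate * (temp_C - 15.0))
    return float(config.capacity_scale * g * decline)


def simulate_community_experiment(
    pool: Sequence[SpeciesTraits],
    design: DesignTable,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> CommunityExperiment:
    """Simulate the endpoint outcome of every well in the design.

    See the module docstring for the generating model.  Raises if the
    design references species absent from the pool.
    """
    if rng is None:
        rng = substream(config.seed, "community")
    by_id = {sp.species_id: sp for sp in pool}
    missing = set(design.species_pool) - set(by_id)
    if missing:
        raise ValueError(f"design references species not in pool: "
                         f"{sorted(missing)}")

    theta = config.dominance_exponent
    temps = sorted(design.frame["temperature_C"].unique())
    g = {(sid, t): _normalised_performance(by_id[sid], t)
         for sid in by_id for t in temps}
    cap = {(sid, t): monoculture_capacity(by_id[sid], t, config)
           for sid in by_id for t in temps}

    unit_rows = []
    sp_rows = []
    for row in design.frame.itertuples(index=False):
        members = row.species.split(SPECIES_SEP)
        t = row.temperature_C
        perf = np.array([g[(m, t)] for m in members])
        caps = np.array([cap[(m, t)] for m in members])
        if np.isinf(theta):
            w = (perf == perf.max()).astype(float)
        else:
            w = perf ** theta
        w = w / w.sum() if w.sum() > 0 else np.full(len(members),
                                                    1.0 / len(members))
        total = float(w @ caps)
        noise = float(np.exp(config.well_noise_sd * rng.standard_normal()))
        chl_i = w * total * noise                     # pg chl/mL per species
        per_cell = np.array([by_id[m].chl_per_cell for m in members])
        n_i = chl_i / per_cell                        # cells/mL per species
        unit_rows.append({
            "unit_id": row.unit_id, "temperature_C": t,
            "partition": row.partition, "richness": row.richness,
            "assemblage_id": row.assemblage_id, "replicate": row.replicate,
            "species": row.species,
            "abundance": float(n_i.sum()), "total_chl": float(chl_i.sum()),
        })
        for m, a in zip(members, n_i):
            sp_rows.append({"unit_id": row.unit_id, "species_id": m,
                            "abundance": float(a)})
    units = pd.DataFrame(unit_rows)
    units["log2_richness"] = np.log2(units["richness"])
    with np.errstate(divide="ignore"):
        units["ln_chl"] = np.log(units["total_chl"])
        units["ln_abundance"] = np.log(units["abundance"])
    return CommunityExperiment(units=units,
                               species_abundances=pd.DataFrame(sp_rows))


def default_design(config: SimulationConfig) -> DesignTable:
    """The full random-partition design implied by a config."""
    pool_ids = [f"sp{i + 1:02d}" for i in range(config.n_species)]
    return generate_full_design(
        pool_ids, levels=config.richness_levels,
        n_partitions=config.n_partitions,
        n_replicates=config.n_replicates,
        temperatures=config.temperatures,
        seed=substream(config.seed, "design"),
    )


# ---------------------------------------------------------------------------
# Cytometry events
# ---------------------------------------------------------------------------

def simulate_cytometry_events(
    abundances: Mapping[str, float],
    pool: Sequence[SpeciesTraits],
    volume_uL: float = 20.0,
    config: Optional[SimulationConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Simulate one well's flow-cytometry event table.

    Per-species event counts are Poisson with mean abundance (cells/mL)
    times counted volume (converted to mL); channel values are lognormal
    around the species' cluster centre.  A configurable fraction of
    additional debris events is drawn uniformly on the sub-threshold
    region of log-channel space (log10 FSC in [3.5, 4.95] and log10 FL3 in
    [1.5, 3.45], both below the live-cell gates, log10 SSC in [3.5, 6]).

    Returns a frame with linear-scale ``fsc``, ``ssc``, ``fl3`` columns
    and the true ``species_id`` label ("debris" for debris events) for
    simulation bookkeeping; real instrument tables carry no label.
    """
    if config is None:
        config = SimulationConfig()
    if volume_uL <= 0:
        raise ValueError("counted volume must be > 0")
    if rng is None:
        rng = substream(config.seed, "cytometry")
    by_id = {sp.species_id: sp for sp in pool}
    frames = []
    total_mean = 0.0
    for sid, abund in abundances.items():
        if abund < 0:
            raise ValueError(f"negative abundance for {sid}")
        if sid not in by_id:
            raise ValueError(f"unknown species in abundances: {sid}")
        mean = abund * volume_uL / 1000.0  # cells/mL * mL counted
        total_mean += mean
        k = int(rng.poisson(mean))
        if k == 0:
            continue
        sp = by_id[sid]
        frames.append(pd.DataFrame({
            "fsc": 10.0 ** rng.normal(sp.fsc_mu, sp.fsc_sigma, k),
            "ssc": 10.0 ** rng.normal(sp.ssc_mu, sp.ssc_sigma, k),
            "fl3": 10.0 ** rng.normal(sp.fl3_mu, sp.fl3_sigma, k),
            "species_id": sid,
        }))
    f = config.debris_fraction
    if f > 0 and total_mean > 0:
        k = int(rng.poisson(total_mean * f / (1.0 - f)))
        if k:
            frames.append(pd.DataFrame({
                "fsc": 10.0 ** rng.uniform(3.5, 4.95, k),
                "ssc": 10.0 ** rng.uniform(3.5, 6.0, k),
                "fl3": 10.0 ** rng.uniform(1.5, 3.45, k),
                "species_id": "debris",
            }))
    if not frames:
        return pd.DataFrame(columns=["fsc", "ssc", "fl3", "species_id"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Parametric response generator (for calibrating the statistical engine)
# ---------------------------------------------------------------------------

DEFAULT_INTERCEPTS = {15.0: 8.5, 25.0: 7.5, 30.0: 6.5}
DEFAULT_SLOPES_NULL = {15.0: 1.5, 25.0: 1.5, 30.0: 1.5}
DEFAULT_SLOPES_INTERACTION = {15.0: 1.5, 25.0: 2.25, 30.0: 3.0}
#: residual sd (ln chlorophyll scale) matching the magnitude of
#: well-to-well scatter in this kind of microcosm experiment
DEFAULT_RESPONSE_SD = 3.7


def simulate_bef_response(
    design: DesignTable,
    intercepts: Mapping[float, float] = None,
    slopes: Mapping[float, float] = None,
    noise_sd: float = DEFAULT_RESPONSE_SD,
    rng: Optional[np.random.Generator] = None,
    species_effects: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Draw a linear-model response over a design.

    ln production = a(T) + b(T) * log2(richness) [+ sum of per-species
    increments for species present] + Gaussian noise.  Used for type-I
    error, power and species-coefficient calibration studies where the
    truth must be known exactly.  Default interaction slopes double the
    richness slope at 30 degC relative to 15 degC, with intercepts
    declining with warming.
    """
    if intercepts is None:
        intercepts = DEFAULT_INTERCEPTS
    if slopes is None:
        slopes = DEFAULT_SLOPES_INTERACTION
    if rng is None:
        rng = np.random.default_rng(0)
    frame = design.frame
    t = frame["temperature_C"].to_numpy()
    a = np.array([intercepts[x] for x in t])
    b = np.array([slopes[x] for x in t])
    y = a + b * np.log2(frame["richness"].to_numpy())
    if species_effects:
        sets = design.species_sets()
        y = y + np.array([
            sum(species_effects.get(sp, 0.0) for sp in st) for st in sets
        ])
    y = y + noise_sd * rng.standard_normal(len(frame))
    out = frame.copy()
    out["log2_richness"] = np.log2(out["richness"])
    out["ln_chl"] = y
    return out
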