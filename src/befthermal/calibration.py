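"""Simulation studies validating the statistical engine.

Each study generates data with known truth from the synthetic generator
and measures how the analysis recovers it: the type-I error and power of
the temperature x richness interaction test, thermal-optimum recovery
from noisy assays, and species-coefficient rank recovery for a
constructed above-average species.  These are the package's own
calibration experiments; they are deliberately cheap enough to re-run
routinely.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .bef import _design_matrices, gaussian_aic, species_coefficients
from .design import DesignTable
from .simulate import (
    DEFAULT_INTERCEPTS, DEFAULT_RESPONSE_SD, DEFAULT_SLOPES_INTERACTION,
    DEFAULT_SLOPES_NULL, default_design, generate_species_pool,
    simulate_tpc_assay,
)
from .thermal import fit_sharpe_schoolfield
from .traits import SimulationConfig, substream


class _FastSequentialFit:
    """Precomputed projections for repeated sequential fits on one design."""

    def __init__(self, design: DesignTable):
        frame = design.frame
        t = frame["temperature_C"].to_numpy(float)
        x = np.log2(frame["richness"].to_numpy(float))
        self.mats, self.levels, _ = _design_matrices(t, x)
        self.qs = [np.linalg.qr(X)[0] for X in self.mats]
        self.n = len(frame)
        self.dfs = [self.n - X.shape[1] for X in self.mats]
        self.ks = [X.shape[1] for X in self.mats]

    def rss(self, y: np.ndarray) -> list:
        yy = float(y @ y)
        return [yy - float((q.T @ y) @ (q.T @ y)) for q in self.qs]

    def interaction_f(self, y: np.ndarray) -> float:
        r = self.rss(y)
        d_df = self.dfs[2] - self.dfs[3]
        return ((r[2] - r[3]) / d_df) / (r[3] / self.dfs[3])

    def interaction_f_crit(self, alpha: float = 0.05) -> float:
        return float(stats.f.ppf(1 - alpha, self.dfs[2] - self.dfs[3],
                                 self.dfs[3]))

    def best_aic_step(self, y: np.ndarray) -> int:
        r = self.rss(y)
        aics = [gaussian_aic(rss, self.n, k) for rss, k in zip(r, self.ks)]
        return int(np.argmin(aics))


@dataclass
class InteractionCalibration:
    """Rejection rates of the interaction F test over simulated responses."""

    rejection_rate: float
    aic_selects_interaction_rate: float
    n_sims: int
    alpha: float


def interaction_test_calibration(
    design: Optional[DesignTable] = None,
    slopes: Optional[Mapping[float, float]] = None,
    intercepts: Optional[Mapping[float, float]] = None,
    noise_sd: float = DEFAULT_RESPONSE_SD,
    n_sims: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> InteractionCalibration:
    """Monte-Carlo calibration of the interaction test on a design.

    With equal slopes (the default null) the rejection rate estimates the
    type-I error at level ``alpha``; with the interaction slopes (30 degC
    slope double the 15 degC slope) it estimates power.  Gaussian noise
    at ``noise_sd`` (ln-production scale) throughout.
    """
    if design is None:
        design = default_design(SimulationConfig())
    if slopes is None:
        slopes = DEFAULT_SLOPES_NULL
    if intercepts is None:
        intercepts = DEFAULT_INTERCEPTS
    fast = _FastSequentialFit(design)
    frame = design.frame
    t = frame["temperature_C"].to_numpy(float)
    x = np.log2(frame["richness"].to_numpy(float))
    mean = np.array([intercepts[v] for v in t]) \
        + np.array([slopes[v] for v in t]) * x
    rng = substream(seed, "interaction-calibration")
    crit = fast.interaction_f_crit(alpha)
    rej = 0
    aic_sel = 0
    for _ in range(n_sims):
        y = mean + noise_sd * rng.standard_normal(fast.n)
        if fast.interaction_f(y) > crit:
            rej += 1
        if fast.best_aic_step(y) == 3:
            aic_sel += 1
    return InteractionCalibration(
        rejection_rate=rej / n_sims,
        aic_selects_interaction_rate=aic_sel / n_sims,
        n_sims=n_sims, alpha=alpha,
    )


@dataclass
class ToptRecovery:
    """Thermal-optimum recovery on a synthetic species ensemble."""

    errors_C: np.ndarray          # |fitted - true| per species
    median_abs_error_C: float
    max_closed_form_vs_grid_K: float   # closed form vs dense grid argmax
    n_species: int
    n_converged: int


def topt_recovery_study(
    n_species: int = 200,
    noise_sd_rate: float = 0.10,
    seed: int = 0,
    grid_step: float = 0.01,
) -> ToptRecovery:
    """Fit noisy simulated assays for many species; measure Topt recovery.

    Each species gets one assay over the default 15 temperatures (7-49
    degC) with multiplicative lognormal rate noise; the closed-form
    optimum of every converged fit is also checked against a dense
    grid argmax of the fitted curve.
    """
    cfg = replace(SimulationConfig(seed=seed), n_species=n_species,
                  richness_levels=(1,), noise_sd_rate=noise_sd_rate)
    pool = generate_species_pool(cfg)
    rng = substream(seed, "topt-recovery")
    errors = []
    grid_dev = []
    n_conv = 0
    for sp in pool:
        assay = simulate_tpc_assay(sp, cfg, rng=rng)
        res = fit_sharpe_schoolfield(assay)
        if not res.converged:
            continue
        n_conv += 1
        errors.append(abs(res.topt_C - sp.topt_true_C))
        grid_dev.append(abs(res.grid_argmax(step=grid_step) - res.topt))
    errors = np.asarray(errors)
    return ToptRecovery(
        errors_C=errors,
        median_abs_error_C=float(np.median(errors)),
        max_closed_form_vs_grid_K=float(np.max(grid_dev)),
        n_species=n_species, n_converged=n_conv,
    )


@dataclass
class CoefficientRecovery:
    """Rank recovery of a constructed above-average species."""

    top_rank_rate: float
    mean_constructed_coefficient: float
    max_abs_coefficient_sum: float
    n_sims: int


def coefficient_recovery_study(
    delta: float = 1.0,
    noise_sd: float = 0.5,
    temperature: float = 30.0,
    n_sims: int = 200,
    seed: int = 0,
    design: Optional[DesignTable] = None,
) -> CoefficientRecovery:
    """How reliably does the residual regression find a boosted species?

    One species adds a fixed increment ``delta`` to ln production
    whenever present; all others are exchangeable.  At replicate-level
    noise ``noise_sd`` (composition effects are explicit here, so only
    well-to-well noise applies) the boosted species should hold the top
    coefficient rank in nearly every simulation.
    """
    if design is None:
        design = default_design(SimulationConfig())
    frame = design.frame
    sub = frame[frame["temperature_C"] == temperature].reset_index(drop=True)
    sub_table = DesignTable(sub)
    presence = sub_table.presence_matrix()
    target = presence.columns[-1]
    x = np.log2(sub["richness"].to_numpy(float))
    base = 6.0 + 0.5 * x + delta * presence[target].to_numpy(float)
    rng = substream(seed, "coefficient-recovery")
    top = 0
    coefs = []
    max_sum = 0.0
    records = sub.copy()
    for _ in range(n_sims):
        records["ln_chl"] = base + noise_sd * rng.standard_normal(len(sub))
        cf = species_coefficients(records, presence).set_index("species_id")
        c = cf["coefficient"]
        max_sum = max(max_sum, abs(float(c.sum())))
        if c.idxmax() == target:
            top += 1
        coefs.append(float(c[target]))
    return CoefficientRecovery(
        top_rank_rate=top / n_sims,
        mean_constructed_coefficient=float(np.mean(coefs)),
        max_abs_coefficient_sum=max_sum,
        n_sims=n_sims,
    )
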