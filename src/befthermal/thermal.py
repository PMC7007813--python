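"""Thermal performance curve fitting.

The acute thermal performance curve (TPC) of gross photosynthesis is
described by the modified Sharpe-Schoolfield model with high-temperature
deactivation, fitted on the log-rate scale:

    ln GP(T) = ln b(Tc) + (E/k)(1/Tc - 1/T) - ln(1 + exp[(Eh/k)(1/Th - 1/T)])

with activation energy E (eV), deactivation energy Eh (eV), inflection
temperature Th (K), Boltzmann constant k, and a fixed reference
temperature Tc.  For Eh > E > 0 the curve is unimodal and left-skewed with
a closed-form optimum

    Topt = Eh * Th / (Eh + k * Th * ln(Eh/E - 1)) < Th.

Gross photosynthesis itself is assembled from a photosynthesis-irradiance
(PI) curve at each assay temperature: GP = NPmax + R, where NPmax is the
light-saturated net photosynthesis (the PI-curve asymptote) and R the dark
respiration magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, least_squares

from .constants import BOLTZMANN_EV as KB
from .constants import CELSIUS_OFFSET, as_kelvin

DEFAULT_TC_REF = 291.15  # K (18 degC), mid-range of the assay temperatures


def sharpe_schoolfield_ln_rate(temp, lnb_tc, E, Eh, Th, tc_ref=DEFAULT_TC_REF):
    """Log rate of the modified Sharpe-Schoolfield model.

    ``temp`` may be in degC or K (values < 200 are treated as degC).
    """
    T = as_kelvin(temp)
    arrhenius = lnb_tc + (E / KB) * (1.0 / tc_ref - 1.0 / T)
    deactivation = np.logaddexp(0.0, (Eh / KB) * (1.0 / Th - 1.0 / T))
    return arrhenius - deactivation


def sharpe_schoolfield_rate(temp, lnb_tc, E, Eh, Th, tc_ref=DEFAULT_TC_REF):
    """Rate (linear scale) of the modified Sharpe-Schoolfield model."""
    return np.exp(sharpe_schoolfield_ln_rate(temp, lnb_tc, E, Eh, Th, tc_ref))


def thermal_optimum(E: float, Eh: float, Th: float) -> float:
    """Closed-form thermal optimum (K) of the Sharpe-Schoolfield curve.

    Defined only for Eh > E > 0; approaches Th from below as Eh/E grows.
    """
    if not (Eh > E > 0):
        raise ValueError(
            f"thermal optimum undefined unless Eh > E > 0 (got E={E}, Eh={Eh})"
        )
    return Eh * Th / (Eh + KB * Th * np.log(Eh / E - 1.0))


def gross_photosynthesis(np_max, respiration):
    """GP = NPmax + R with R the positive magnitude of dark O2 consumption."""
    if np.any(np.asarray(respiration) < 0):
        raise ValueError(
            "respiration must be supplied as a positive magnitude of O2 "
            "consumption"
        )
    return np.asarray(np_max) + np.asarray(respiration)


# ---------------------------------------------------------------------------
# Photosynthesis-irradiance curves
# ---------------------------------------------------------------------------

def _pi_tanh(I, p_max, alpha):
    with np.errstate(over="ignore", invalid="ignore"):
        return p_max * np.tanh(alpha * I / p_max)


def _pi_exp(I, p_max, alpha):
    with np.errstate(over="ignore", invalid="ignore"):
        return p_max * (1.0 - np.exp(-alpha * I / p_max))


_PI_MODELS = {"tanh": _pi_tanh, "exponential": _pi_exp}


@dataclass
class PIFit:
    """Light-saturated net photosynthesis and initial slope of a PI curve."""

    np_max: float
    alpha: float
    rss: float
    converged: bool
    n_points: int
    model: str = "tanh"
    message: str = ""

    def predict(self, irradiance):
        return _PI_MODELS[self.model](np.asarray(irradiance, float),
                                      self.np_max, self.alpha)


def fit_pi_curve(
    irradiance: Sequence[float],
    np_rate: Sequence[float],
    model: str = "tanh",
) -> PIFit:
    """Fit a saturating PI model and return its asymptote as NPmax.

    Requires at least 4 points spanning low and saturating irradiance.
    Non-convergence and degenerate inputs (all rates <= 0) are reported in
    the ``converged`` flag and ``message``, never as silent NaN.
    """
    I = np.asarray(irradiance, float)
    y = np.asarray(np_rate, float)
    if model not in _PI_MODELS:
        raise ValueError(f"unknown PI model {model!r}")
    if len(I) != len(y):
        raise ValueError("irradiance and rate must have equal length")
    if len(I) < 4:
        raise ValueError("need >= 4 PI points spanning low and high light")
    if np.any(I < 0):
        raise ValueError("irradiance must be >= 0")
    if np.all(y <= 0):
        return PIFit(np.nan, np.nan, np.nan, False, len(I), model,
                     "all rates non-positive; no light response to fit")

    p0_max = float(np.max(y))
    # initial slope from the lowest positive-irradiance point
    pos = I > 0
    alpha0 = float(np.clip(np.max(y[pos] / I[pos]), 1e-6, None)) if pos.any() \
        else p0_max / 100.0
    try:
        popt, _ = curve_fit(
            _PI_MODELS[model], I, y,
            p0=[p0_max if p0_max > 0 else 1.0, alpha0],
            bounds=([1e-12, 0.0], [np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - rare
        return PIFit(np.nan, np.nan, np.nan, False, len(I), model, str(exc))
    resid = y - _PI_MODELS[model](I, *popt)
    return PIFit(float(popt[0]), float(popt[1]), float(resid @ resid),
                 True, len(I), model)


# ---------------------------------------------------------------------------
# Sharpe-Schoolfield fitting
# ---------------------------------------------------------------------------

PARAM_NAMES = ("lnb_tc", "E", "Eh", "Th")


@dataclass
class SharpeSchoolfieldResults:
    """Parameter estimates and diagnostics of one TPC fit."""

    params: pd.Series
    bse: pd.Series
    rss: float
    n_points: int
    n_dropped: int
    n_converged_starts: int
    converged: bool
    one_sided: bool
    tc_ref: float
    message: str = ""

    @property
    def topt(self) -> float:
        """Thermal optimum in K (closed form)."""
        p = self.params
        return thermal_optimum(p["E"], p["Eh"], p["Th"])

    @property
    def topt_C(self) -> float:
        return self.topt - CELSIUS_OFFSET

    def predict(self, temp):
        p = self.params
        return sharpe_schoolfield_rate(
            temp, p["lnb_tc"], p["E"], p["Eh"], p["Th"], self.tc_ref
        )

    def grid_argmax(self, step: float = 0.01, span: float = 40.0) -> float:
        """Numerical argmax (K) of the fitted curve on a dense grid.

        Independent check of the closed-form optimum; the two agree within
        one grid step for any valid fit.
        """
        lo = self.topt - span / 2
        grid = np.arange(lo, lo + span, step)
        ln = sharpe_schoolfield_ln_rate(
            grid, *(self.params[k] for k in PARAM_NAMES), self.tc_ref
        )
        return float(grid[np.argmax(ln)])

    def summary(self) -> str:
        lines = [
            "Sharpe-Schoolfield thermal performance fit",
            "=" * 46,
            f"n points (positive rate): {self.n_points}"
            + (f"  [{self.n_dropped} non-positive dropped]" if self.n_dropped else ""),
            f"converged starts: {self.n_converged_starts}   "
            f"status: {'ok' if self.converged else 'FAILED'}"
            + ("  (one-sided: Eh poorly identified)" if self.one_sided else ""),
            f"reference temperature Tc: {self.tc_ref:.2f} K",
            "",
            f"{'param':>8} {'estimate':>12} {'std err':>12}",
        ]
        for k in PARAM_NAMES:
            lines.append(f"{k:>8} {self.params[k]:>12.4f} {self.bse[k]:>12.4f}")
        if self.converged:
            lines.append("")
            lines.append(
                f"Topt: {self.topt:.2f} K ({self.topt_C:.2f} degC); "
                f"residual SS (ln rate): {self.rss:.4g}"
            )
        return "\n".join(lines)

    def plot(self, ax=None, temps=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if temps is None:
            temps = np.linspace(self.topt_C - 20, self.topt_C + 10, 200)
        ax.plot(temps, self.predict(temps), "-", label="fitted TPC")
        ax.axvline(self.topt_C, ls="--", color="grey", label="Topt")
        ax.set_xlabel("temperature (degC)")
        ax.set_ylabel("gross photosynthesis")
        ax.legend()
        return ax


class SharpeSchoolfield:
    """Nonlinear least-squares model for one species' TPC.

    Parameters
    ----------
    temperature : array-like
        Assay temperatures, degC or K (auto-converted).
    rate : array-like
        Gross photosynthesis rates (ug O2 cell^-1 h^-1); non-positive
        values are excluded from the ln-scale fit and counted.
    tc_ref : float
        Reference temperature (K) at which ``lnb_tc`` is defined.

    Examples
    --------
    >>> model = SharpeSchoolfield(temps_C, gp_rates)
    >>> res = model.fit()
    >>> res.topt_C
    """

    def __init__(self, temperature, rate, tc_ref: float = DEFAULT_TC_REF):
        T = np.asarray(as_kelvin(np.asarray(temperature, float)))
        r = np.asarray(rate, float)
        if T.shape != r.shape:
            raise ValueError("temperature and rate must have equal length")
        keep = np.isfinite(r) & (r > 0) & np.isfinite(T)
        self.n_dropped = int((~keep).sum())
        self.temp_K = T[keep]
        self.ln_rate = np.log(r[keep])
        self.tc_ref = float(as_kelvin(tc_ref))
        if len(self.temp_K) < 6:
            raise ValueError(
                f"need >= 6 positive-rate points to fit a TPC, got "
                f"{len(self.temp_K)} ({self.n_dropped} dropped)"
            )

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, temperature: str = "assay_temp_C",
                       rate: str = "gp_rate", tc_ref: float = DEFAULT_TC_REF):
        return cls(frame[temperature].to_numpy(), frame[rate].to_numpy(), tc_ref)

    def _residuals(self, theta):
        return sharpe_schoolfield_ln_rate(self.temp_K, *theta, self.tc_ref) \
            - self.ln_rate

    def fit(self, e_starts=(0.3, 0.7, 1.2), eh_starts=(1.5, 3.0, 5.0),
            th_offsets=(-1.0, 4.0, 9.0)) -> SharpeSchoolfieldResults:
        """Multi-start nonlinear least squares on the ln-rate scale.

        The default 27-point grid spans E in [0.2, 1.5], Eh in [1, 6] and
        Th around the empirical peak; the best (lowest residual SS)
        converged start with Eh > E wins, ties broken by lowest E.
        """
        T, y = self.temp_K, self.ln_rate
        t_peak = float(T[np.argmax(y)])
        one_sided = t_peak in (float(T.min()), float(T.max()))

        lo = np.array([-np.inf, 1e-4, 2e-4, float(T.min())])
        hi = np.array([np.inf, 10.0, 40.0, 420.0])
        best = None
        n_conv = 0
        for E0 in e_starts:
            for Eh0 in eh_starts:
                if Eh0 <= E0:
                    continue
                for dTh in th_offsets:
                    Th0 = float(np.clip(t_peak + dTh, lo[3] + 1e-3, hi[3] - 1e-3))
                    # profile out lnb: with lnb=0 the residual mean is -lnb_hat
                    base = sharpe_schoolfield_ln_rate(T, 0.0, E0, Eh0, Th0,
                                                      self.tc_ref)
                    lnb0 = float(np.mean(y - base))
                    try:
                        sol = least_squares(
                            self._residuals, x0=[lnb0, E0, Eh0, Th0],
                            bounds=(lo, hi), method="trf", max_nfev=2000,
                        )
                    except Exception:  # pragma: no cover
                        continue
                    if not sol.success:
                        continue
                    lnb, E, Eh, Th = sol.x
                    if not (Eh > E > 0):
                        continue
                    n_conv += 1
                    ss = float(2 * sol.cost)
                    key = (ss, E)
                    if best is None or key < best[0]:
                        best = (key, sol)

        if best is None:
            nanp = pd.Series(np.nan, index=list(PARAM_NAMES))
            return SharpeSchoolfieldResults(
                params=nanp, bse=nanp.copy(), rss=np.nan,
                n_points=len(T), n_dropped=self.n_dropped,
                n_converged_starts=0, converged=False, one_sided=one_sided,
                tc_ref=self.tc_ref,
                message="no start converged to a valid (Eh > E > 0) optimum",
            )

        sol = best[1]
        params = pd.Series(sol.x, index=list(PARAM_NAMES))
        rss = float(2 * sol.cost)
        dof = max(len(T) - 4, 1)
        s2 = rss / dof
        try:
            cov = s2 * np.linalg.pinv(sol.jac.T @ sol.jac)
            bse = pd.Series(np.sqrt(np.clip(np.diag(cov), 0, None)),
                            index=list(PARAM_NAMES))
        except np.linalg.LinAlgError:  # pragma: no cover
            bse = pd.Series(np.nan, index=list(PARAM_NAMES))
        return SharpeSchoolfieldResults(
            params=params, bse=bse, rss=rss, n_points=len(T),
            n_dropped=self.n_dropped, n_converged_starts=n_conv,
            converged=True, one_sided=one_sided, tc_ref=self.tc_ref,
            message="one-sided temperature coverage; Eh poorly identified"
            if one_sided else "",
        )


def fit_sharpe_schoolfield(points: pd.DataFrame, tc_ref: float = DEFAULT_TC_REF,
                           temperature: str = "assay_temp_C",
                           rate: str = "gp_rate") -> SharpeSchoolfieldResults:
    """Functional wrapper: fit one species' TPC from a measurement table."""
    return SharpeSchoolfield.from_dataframe(
        points, temperature=temperature, rate=rate, tc_ref=tc_ref
    ).fit()


def fit_tpc_table(rates: pd.DataFrame, tc_ref: float = DEFAULT_TC_REF,
                  species_col: str = "species_id",
                  temperature: str = "assay_temp_C",
                  rate: str = "gp_rate") -> pd.DataFrame:
    """Fit every species in a long rates table; one row of estimates each.

    Returns a frame with the four parameters, their standard errors, the
    derived optimum in degC and fit diagnostics.
    """
    rows = []
    for sp, grp in rates.groupby(species_col, sort=True):
        res = fit_sharpe_schoolfield(grp, tc_ref=tc_ref,
                                     temperature=temperature, rate=rate)
        row = {species_col: sp}
        row.update({k: res.params[k] for k in PARAM_NAMES})
        row.update({f"{k}_se": res.bse[k] for k in PARAM_NAMES})
        row.update(
            topt_C=res.topt_C if res.converged else np.nan,
            rss=res.rss, n_points=res.n_points, n_dropped=res.n_dropped,
            n_converged_starts=res.n_converged_starts,
            converged=res.converged, one_sided=res.one_sided,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def gp_from_pi_assays(rates: pd.DataFrame, model: str = "tanh",
                      species_col: str = "species_id",
                      temperature: str = "assay_temp_C",
                      irradiance: str = "irradiance_umol_m2_s",
                      o2: str = "o2_rate") -> pd.DataFrame:
    """Reduce raw PI assays to one gross-photosynthesis rate per assay temp.

    Dark rows (irradiance == 0) give respiration as the magnitude of O2
    consumption; light rows are fitted with a saturating PI model to get
    NPmax; GP = NPmax + R.
    """
    rows = []
    for (sp, t), grp in rates.groupby([species_col, temperature], sort=True):
        dark = grp[grp[irradiance] == 0]
        light = grp[grp[irradiance] > 0]
        resp = float(np.clip(-dark[o2].mean(), 0.0, None)) if len(dark) else 0.0
        fit = fit_pi_curve(light[irradiance], light[o2], model=model)
        gp = gross_photosynthesis(fit.np_max, resp) if fit.converged else np.nan
        rows.append({species_col: sp, temperature: t, "np_max": fit.np_max,
                     "alpha": fit.alpha, "respiration": resp, "gp_rate": gp,
                     "pi_converged": fit.converged})
    return pd.DataFrame(rows)
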