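"""The biodiversity-ecosystem functioning statistical engine.

Implements the random-partition analysis-of-variance workflow: a
sequential linear-model build (intercept, + temperature as a 3-level
factor, + log2 richness, + their interaction) summarised Table-1 style
with residual df/SS, added-term df/SS/F, cumulative R^2 and Gaussian AIC;
per-temperature richness slopes with Tukey-adjusted pairwise contrasts;
species coefficients from residual regression on presence/absence;
trait-coefficient regressions; monoculture-polyculture regressions; and
net/transgressive overyielding with bootstrap intervals.

The response is log ecosystem production: natural log of total
chlorophyll a (pg/mL) by default, ln total abundance (cells/mL) as the
alternate.  Temperature always enters as an unordered factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

GAUSS_AIC_CONST = np.log(2.0 * np.pi) + 1.0

STEP_LABELS = ["Intercept", "+ T", "+ log2(R)", "+ T x log2(R)"]


def gaussian_aic(rss: float, n: int, k_mean_params: int) -> float:
    """Gaussian profile AIC, n ln(RSS/n) + 2(k+1) + n(ln 2pi + 1).

    ``k_mean_params`` counts mean parameters; the error variance adds one.
    Matches the convention of mainstream statistical software so model
    tables are directly comparable.
    """
    return float(n * np.log(rss / n) + 2 * (k_mean_params + 1)
                 + n * GAUSS_AIC_CONST)


def _design_matrices(temperature: np.ndarray, log2_richness: np.ndarray):
    """Nested design matrices for the four sequential models.

    Returns (list of matrices, temperature levels, column names of the
    full interaction matrix).
    """
    levels = np.array(sorted(pd.unique(temperature)))
    n = len(temperature)
    ones = np.ones((n, 1))
    dummies = np.column_stack([
        (temperature == lev).astype(float) for lev in levels[1:]
    ]) if len(levels) > 1 else np.empty((n, 0))
    x = log2_richness.reshape(-1, 1)
    X0 = ones
    X1 = np.hstack([ones, dummies])
    X2 = np.hstack([ones, dummies, x])
    X3 = np.hstack([ones, dummies, x, dummies * x])
    names = (["Intercept"]
             + [f"T[{lev:g}]" for lev in levels[1:]]
             + ["log2R"]
             + [f"T[{lev:g}]:log2R" for lev in levels[1:]])
    return [X0, X1, X2, X3], levels, names


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design: matrix has {X.shape[1]} columns but "
            f"rank {rank}; check for empty factor cells or constant "
            f"covariates"
        )
    r = y - X @ beta
    return float(r @ r)


def sequential_model_selection(
    records: pd.DataFrame,
    response: str = "ln_chl",
    temperature: str = "temperature_C",
    richness: str = "richness",
) -> pd.DataFrame:
    """Build the sequential model table (Table-1 style).

    Four rows: intercept only; + temperature factor; + log2(richness);
    + temperature x log2(richness).  Each row reports residual df and SS,
    the added term's df, SS and F (tested against the current step's
    residual mean square), cumulative R^2 and the Gaussian AIC.  The best
    model is the one with the lowest AIC.
    """
    t = records[temperature].to_numpy(float)
    if len(pd.unique(t)) < 2:
        raise ValueError("need >= 2 temperature levels")
    r = records[richness].to_numpy(float)
    if len(pd.unique(r)) < 2:
        raise ValueError("need >= 2 richness levels")
    y = records[response].to_numpy(float)
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    mats, _, _ = _design_matrices(t, np.log2(r))
    n = len(y)
    rows = []
    tss = None
    prev_rss, prev_df = None, None
    for step, (label, X) in enumerate(zip(STEP_LABELS, mats)):
        rss = _rss(X, y)
        res_df = n - X.shape[1]
        if tss is None:
            tss = rss
        if prev_rss is None:
            treat_df = treat_ss = f_stat = np.nan
        else:
            treat_df = prev_df - res_df
            treat_ss = prev_rss - rss
            f_stat = (treat_ss / treat_df) / (rss / res_df)
        rows.append({
            "step": step, "model": label, "res_df": res_df, "res_ss": rss,
            "treat_df": treat_df, "treat_ss": treat_ss, "F": f_stat,
            "r_squared": 1.0 - rss / tss,
            "aic": gaussian_aic(rss, n, X.shape[1]),
        })
        prev_rss, prev_df = rss, res_df
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Interaction model + slope contrasts
# ---------------------------------------------------------------------------

@dataclass
class SlopeContrasts:
    slopes: pd.DataFrame      # per temperature: slope, se
    contrasts: pd.DataFrame   # pairwise: estimate, se, t, p_tukey
    df_resid: int


def _fit_interaction(records, response, temperature, richness):
    t = records[temperature].to_numpy(float)
    x = np.log2(records[richness].to_numpy(float))
    y = records[response].to_numpy(float)
    mats, levels, names = _design_matrices(t, x)
    X = mats[3]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient interaction design")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    s2 = float(resid @ resid) / df
    cov = s2 * XtX_inv
    return beta, cov, df, levels, names


def slope_contrasts(
    records: pd.DataFrame,
    response: str = "ln_chl",
    temperature: str = "temperature_C",
    richness: str = "richness",
) -> SlopeContrasts:
    """Per-temperature richness slopes and Tukey-adjusted differences.

    Slopes come from the interaction model; each pairwise slope
    difference is tested with the studentized-range (Tukey) adjustment,
    p = P(q_{k,df} > sqrt(2) |t|), which for two levels reduces to the
    unadjusted t-test.
    """
    levels_all = pd.unique(records[temperature])
    if len(levels_all) < 2:
        raise ValueError("need >= 2 temperature levels for slope contrasts")
    beta, cov, df, levels, names = _fit_interaction(
        records, response, temperature, richness
    )
    k = len(levels)
    idx_slope = names.index("log2R")
    contrast_vecs = {}
    for j, lev in enumerate(levels):
        c = np.zeros(len(names))
        c[idx_slope] = 1.0
        if j > 0:
            c[names.index(f"T[{lev:g}]:log2R")] = 1.0
        contrast_vecs[lev] = c
    slopes = pd.DataFrame([
        {"temperature_C": lev,
         "slope": float(c @ beta),
         "se": float(np.sqrt(c @ cov @ c))}
        for lev, c in contrast_vecs.items()
    ])
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = levels[j], levels[i]
            c = contrast_vecs[a] - contrast_vecs[b]
            est = float(c @ beta)
            se = float(np.sqrt(c @ cov @ c))
            tval = est / se
            p = float(stats.studentized_range.sf(np.sqrt(2.0) * abs(tval),
                                                 k, df))
            rows.append({"contrast": f"{a:g} - {b:g}", "estimate": est,
                         "se": se, "t": tval, "p_tukey": p})
    return SlopeContrasts(slopes=slopes, contrasts=pd.DataFrame(rows),
                          df_resid=df)


# ---------------------------------------------------------------------------
# Species coefficients
# ---------------------------------------------------------------------------

def species_coefficients(
    records: pd.DataFrame,
    presence: pd.DataFrame,
    response: str = "ln_chl",
    richness: str = "richness",
) -> pd.DataFrame:
    """Per-species contributions to production, relative to the average.

    ``records`` must be restricted to one temperature; ``presence`` is the
    units x species 0/1 matrix aligned with it.  Residuals of
    response ~ log2(richness) are regressed jointly on the presence
    indicators (no intercept) and the coefficients centred to mean zero,
    so positive values mark above-average contributions.  Species absent
    from every unit get an undefined (NaN) coefficient and a flag.
    """
    if len(records) != len(presence):
        raise ValueError("records and presence matrix must align row-wise")
    y = records[response].to_numpy(float)
    x = np.log2(records[richness].to_numpy(float))
    X = np.column_stack([np.ones(len(y)), x])
    resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]

    P = presence.to_numpy(float)
    present_any = P.sum(axis=0) > 0
    cols = np.flatnonzero(present_any)
    Psub = P[:, cols]
    beta, _, rank, _ = np.linalg.lstsq(Psub, resid, rcond=None)
    if rank < Psub.shape[1]:
        raise ValueError(
            "presence matrix is rank-deficient at this temperature; "
            "species coefficients are not identifiable"
        )
    r2 = resid - Psub @ beta
    df = len(y) - Psub.shape[1]
    s2 = float(r2 @ r2) / max(df, 1)
    cov = s2 * np.linalg.inv(Psub.T @ Psub)
    se_sub = np.sqrt(np.diag(cov))

    coef = np.full(P.shape[1], np.nan)
    se = np.full(P.shape[1], np.nan)
    coef[cols] = beta - beta.mean()
    se[cols] = se_sub
    return pd.DataFrame({
        "species_id": presence.columns,
        "coefficient": coef,
        "se": se,
        "n_present": P.sum(axis=0).astype(int),
        "flagged_absent": ~present_any,
    })


# ---------------------------------------------------------------------------
# Simple regressions (traits, monoculture vs polyculture)
# ---------------------------------------------------------------------------

@dataclass
class RegressionSummary:
    slope: float
    intercept: float
    se: float
    t: float
    p: float
    r_squared: float
    n: int

    def __str__(self) -> str:
        return (f"slope = {self.slope:.4g} +/- {self.se:.4g} "
                f"(t = {self.t:.3g}, p = {self.p:.3g}, "
                f"R^2 = {self.r_squared:.3f}, n = {self.n})")


def linear_regression(x, y) -> RegressionSummary:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError(f"need >= 3 paired observations, got {len(x)}")
    res = stats.linregress(x, y)
    se = float(res.stderr)
    tval = float(res.slope / se) if se > 0 else float(np.inf * np.sign(res.slope))
    return RegressionSummary(
        slope=float(res.slope), intercept=float(res.intercept),
        se=se, t=tval,
        p=float(res.pvalue), r_squared=float(res.rvalue ** 2), n=len(x),
    )


def trait_correlation(coefficients, traits) -> RegressionSummary:
    """OLS of species coefficients (or monoculture yields) on a trait."""
    return linear_regression(traits, coefficients)


def mono_poly_regression(
    species_abundances: pd.DataFrame,
    units: pd.DataFrame,
    temperature: float,
    temperature_col: str = "temperature_C",
    log_scale: bool = True,
) -> RegressionSummary:
    """Regress polyculture abundance on monoculture abundance per species.

    For each species, its monoculture abundance is the mean over that
    species' monoculture replicate wells at the temperature; its
    polyculture abundance is the mean over replicates within each
    full-richness community.  The regression is on log-transformed means
    by default.
    """
    u = units[units[temperature_col] == temperature]
    if u.empty:
        raise ValueError(f"no units at temperature {temperature}")
    max_rich = u["richness"].max()
    mono_units = u[u["richness"] == 1]
    poly_units = u[u["richness"] == max_rich]
    ab = species_abundances.merge(
        u[["unit_id", "richness", "assemblage_id"]], on="unit_id"
    )
    mono = (ab[ab["unit_id"].isin(mono_units["unit_id"])]
            .groupby("species_id")["abundance"].mean())
    poly = (ab[ab["unit_id"].isin(poly_units["unit_id"])]
            .groupby(["assemblage_id", "species_id"])["abundance"].mean()
            .reset_index())
    poly = poly[poly["species_id"].isin(mono.index)]
    if poly.empty:
        raise ValueError("no species overlap between monocultures and "
                         "polycultures at this temperature")
    x = mono.loc[poly["species_id"]].to_numpy()
    y = poly["abundance"].to_numpy()
    if log_scale:
        ok = (x > 0) & (y > 0)
        x, y = np.log(x[ok]), np.log(y[ok])
    return linear_regression(x, y)


# ---------------------------------------------------------------------------
# Overyielding
# ---------------------------------------------------------------------------

@dataclass
class OveryieldingSummary:
    temperature: float
    mean_poly: float
    mean_monos: float
    best_mono: float
    best_mono_species: str
    net_oy: float
    trans_oy: float
    net_ci: tuple
    trans_ci: tuple
    n_poly_wells: int
    n_mono_wells: int


def overyielding(
    units: pd.DataFrame,
    temperature: float,
    response: str = "ln_chl",
    temperature_col: str = "temperature_C",
    n_boot: int = 1000,
    rng: Optional[np.random.Generator] = None,
    expected_species: Optional[Sequence[str]] = None,
) -> OveryieldingSummary:
    """Net and transgressive overyielding of the full polyculture.

    net = mean polyculture production - mean over species of monoculture
    means; transgressive = mean polyculture production - the best
    monoculture species' mean.  Bootstrap CIs resample replicate wells
    (within species for the monocultures).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    u = units[units[temperature_col] == temperature]
    max_rich = u["richness"].max()
    poly = u[u["richness"] == max_rich][response].to_numpy(float)
    monos = u[u["richness"] == 1]
    if len(poly) == 0:
        raise ValueError(f"no full polyculture wells at {temperature}")
    mono_by_sp = {sp: grp[response].to_numpy(float)
                  for sp, grp in monos.groupby("species")}
    if expected_species is not None:
        missing = sorted(set(expected_species) - set(mono_by_sp))
        if missing:
            raise ValueError(f"missing monocultures at {temperature}: "
                             f"{missing}")
    if not mono_by_sp:
        raise ValueError(f"no monoculture wells at {temperature}")
    mono_means = {sp: float(v.mean()) for sp, v in mono_by_sp.items()}
    best_sp = max(mono_means, key=mono_means.get)
    mean_poly = float(poly.mean())
    mean_monos = float(np.mean(list(mono_means.values())))
    best = mono_means[best_sp]

    net_bs = np.empty(n_boot)
    trans_bs = np.empty(n_boot)
    sp_list = list(mono_by_sp)
    for b in range(n_boot):
        p = poly[rng.integers(0, len(poly), len(poly))].mean()
        mm = np.array([
            mono_by_sp[sp][rng.integers(0, len(mono_by_sp[sp]),
                                        len(mono_by_sp[sp]))].mean()
            for sp in sp_list
        ])
        net_bs[b] = p - mm.mean()
        trans_bs[b] = p - mm.max()
    return OveryieldingSummary(
        temperature=temperature, mean_poly=mean_poly, mean_monos=mean_monos,
        best_mono=best, best_mono_species=best_sp,
        net_oy=mean_poly - mean_monos, trans_oy=mean_poly - best,
        net_ci=tuple(np.percentile(net_bs, [2.5, 97.5])),
        trans_ci=tuple(np.percentile(trans_bs, [2.5, 97.5])),
        n_poly_wells=len(poly),
        n_mono_wells=int(len(monos)),
    )


# ---------------------------------------------------------------------------
# Model object
# ---------------------------------------------------------------------------

class BEFModel:
    """Linear-model analysis of a biodiversity-function experiment.

    Parameters
    ----------
    data : DataFrame
        One row per experimental unit with at least ``temperature_C``,
        ``richness``, a ``species`` column (semicolon-joined ids) and the
        response column.
    response : str
        ``"ln_chl"`` (ln total chlorophyll a, default) or
        ``"ln_abundance"`` (ln cells/mL), or any ln-scale column present.

    Examples
    --------
    >>> model = BEFModel(units, response="ln_chl")
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(self, data: pd.DataFrame, response: str = "ln_chl",
                 temperature: str = "temperature_C",
                 richness: str = "richness"):
        for col in (response, temperature, richness):
            if col not in data.columns:
                raise ValueError(f"data lacks required column {col!r}")
        self.data = data.reset_index(drop=True)
        self.response = response
        self.temperature = temperature
        self.richness = richness

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "BEFModel":
        return cls(data, **kwargs)

    def fit(self) -> "BEFResults":
        table = sequential_model_selection(
            self.data, self.response, self.temperature, self.richness
        )
        return BEFResults(self, table)


class BEFResults:
    """Fitted sequential models plus the downstream analyses."""

    def __init__(self, model: BEFModel, model_table: pd.DataFrame):
        self.model = model
        self.model_table = model_table

    @property
    def best_step(self) -> int:
        return int(self.model_table.loc[self.model_table["aic"].idxmin(),
                                        "step"])

    @property
    def aic(self) -> float:
        return float(self.model_table["aic"].min())

    @property
    def r_squared(self) -> float:
        """R^2 of the lowest-AIC model."""
        return float(self.model_table.loc[self.model_table["aic"].idxmin(),
                                          "r_squared"])

    def slope_contrasts(self) -> SlopeContrasts:
        m = self.model
        return slope_contrasts(m.data, m.response, m.temperature, m.richness)

    def species_coefficients(self, temperature: float) -> pd.DataFrame:
        m = self.model
        sub = m.data[m.data[m.temperature] == temperature]
        if sub.empty:
            raise ValueError(f"no units at temperature {temperature}")
        from .design import DesignTable
        presence = DesignTable(
            sub.assign(unit_id=sub.get("unit_id", sub.index.astype(str)))
            [["unit_id", m.temperature, "partition", m.richness,
              "assemblage_id", "replicate", "species"]]
            .rename(columns={m.temperature: "temperature_C",
                             m.richness: "richness"})
        ).presence_matrix()
        return species_coefficients(sub, presence, m.response, m.richness)

    def overyielding(self, temperature: float, n_boot: int = 1000,
                     rng=None) -> OveryieldingSummary:
        m = self.model
        return overyielding(m.data, temperature, m.response, m.temperature,
                            n_boot=n_boot, rng=rng)

    def summary(self) -> str:
        tbl = self.model_table.copy()
        lines = [
            "Biodiversity-ecosystem functioning: sequential linear models",
            "=" * 72,
            f"response: {self.model.response}   n = {len(self.model.data)}",
            "",
            f"{'step':>4} {'model':<16} {'res.df':>7} {'res.SS':>12} "
            f"{'tr.df':>6} {'tr.SS':>10} {'F':>8} {'R2':>6} {'AIC':>10}",
        ]
        for _, r in tbl.iterrows():
            lines.append(
                f"{int(r['step']):>4} {r['model']:<16} {int(r['res_df']):>7} "
                f"{r['res_ss']:>12.1f} "
                f"{'' if np.isnan(r['treat_df']) else int(r['treat_df']):>6} "
                f"{'' if np.isnan(r['treat_ss']) else format(r['treat_ss'], '.1f'):>10} "
                f"{'' if np.isnan(r['F']) else format(r['F'], '.1f'):>8} "
                f"{r['r_squared']:>6.2f} {r['aic']:>10.1f}"
            )
        lines.append("")
        lines.append(f"best model (lowest AIC): step {self.best_step} "
                     f"({STEP_LABELS[self.best_step]}), "
                     f"R^2 = {self.r_squared:.2f}")
        try:
            sc = self.slope_contrasts()
            lines.append("")
            lines.append("richness slopes by temperature "
                         "(ln production per log2 richness):")
            for _, r in sc.slopes.iterrows():
                lines.append(f"  {r['temperature_C']:g} degC: "
                             f"{r['slope']:.3f} +/- {r['se']:.3f}")
            lines.append("Tukey-adjusted pairwise slope differences:")
            for _, r in sc.contrasts.iterrows():
                lines.append(f"  {r['contrast']}: {r['estimate']:.3f} "
                             f"(p = {r['p_tukey']:.3g})")
        except ValueError:
            pass
        return "\n".join(lines)

    def plot(self, ax=None):
        """Production vs log2 richness with fitted per-temperature lines."""
        import matplotlib.pyplot as plt

        m = self.model
        if ax is None:
            _, ax = plt.subplots()
        x = np.log2(m.data[m.richness].to_numpy(float))
        y = m.data[m.response].to_numpy(float)
        sc = self.slope_contrasts()
        beta, cov, df, levels, names = _fit_interaction(
            m.data, m.response, m.temperature, m.richness
        )
        for lev in levels:
            mask = m.data[m.temperature] == lev
            ax.scatter(x[mask], y[mask], s=6, alpha=0.3, label=f"{lev:g} degC")
            grid = np.linspace(x.min(), x.max(), 20)
            c0 = np.zeros(len(names)); c0[0] = 1.0
            if lev != levels[0]:
                c0[names.index(f"T[{lev:g}]")] = 1.0
            slope = sc.slopes.set_index("temperature_C").loc[lev, "slope"]
            ax.plot(grid, float(c0 @ beta) + slope * grid, "-")
        ax.set_xlabel("log2 species richness")
        ax.set_ylabel(m.response)
        ax.legend()
        return ax


def load_merged_csv(path, response: str = "ln_chl") -> BEFModel:
    """Adapter for an externally prepared analysis CSV.

    Expects unit_id, temperature_C, richness, species and production
    columns; computes the ln response if only the linear-scale column
    (total_chl or abundance) is present.
    """
    frame = pd.read_csv(path)
    if response not in frame.columns:
        src = {"ln_chl": "total_chl", "ln_abundance": "abundance"}.get(response)
        if src is None or src not in frame.columns:
            raise ValueError(f"cannot derive response {response!r}")
        frame[response] = np.log(frame[src])
    return BEFModel(frame, response=response)
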