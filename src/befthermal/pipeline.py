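"""End-to-end orchestration of the synthetic experiment and its analysis.

One :func:`run_pipeline` call sequences the stages -- design generation,
trait-pool simulation, thermal assays and TPC fits, community outcomes,
cytometry for monocultures and polycultures, and the BEF statistics --
writing plain-CSV stage outputs plus a text report.  Every stage output
can equally be produced standalone from its persisted inputs; CSV is the
inter-stage contract, so any stage can be swapped for real data.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import bef, cytometry, thermal
from .design import validate_design
from .simulate import (
    CommunityExperiment, default_design, generate_species_pool,
    pool_to_frame, simulate_community_experiment, simulate_cytometry_events,
    simulate_pi_assays,
)
from .traits import SimulationConfig, substream

log = logging.getLogger("befthermal")


@dataclass
class RunConfig:
    """Parameters of one orchestrated run."""

    out_dir: str = "befthermal_run"
    seed: int = 0
    response: str = "ln_chl"
    tc_ref: float = 291.15
    volume_uL: float = 20.0
    n_boot: int = 500
    run_cytometry: bool = True
    sim: SimulationConfig = None

    def __post_init__(self):
        if self.sim is None:
            self.sim = dataclasses.replace(SimulationConfig(), seed=self.seed)
        if self.response not in ("ln_chl", "ln_abundance"):
            raise ValueError("response must be ln_chl or ln_abundance")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"run config not found: {path}")
        raw = {}
        for line in path.read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            raw[key.strip()] = val.strip()
        kwargs = {}
        sim_kwargs = {}
        for key, val in raw.items():
            if key.startswith("sim."):
                sim_kwargs[key[4:]] = val
            elif key in ("seed", "n_boot"):
                kwargs[key] = int(val)
            elif key in ("tc_ref", "volume_uL"):
                kwargs[key] = float(val)
            elif key == "run_cytometry":
                kwargs[key] = val.lower() in ("1", "true", "yes")
            elif key in ("out_dir", "response"):
                kwargs[key] = val
            else:
                raise ValueError(f"unknown run-config key: {key!r}")
        cfg = cls(**kwargs)
        if sim_kwargs:
            import dataclasses as dc
            fields = {f.name: f for f in dc.fields(SimulationConfig)}
            from .traits import _parse_field
            parsed = {k: _parse_field(fields[k], v)
                      for k, v in sim_kwargs.items()}
            parsed.setdefault("seed", cfg.seed)
            cfg.sim = dc.replace(SimulationConfig(**parsed))
        return cfg

    def echo(self) -> str:
        lines = [f"{f.name} = {getattr(self, f.name)}"
                 for f in dataclasses.fields(self) if f.name != "sim"]
        lines += [f"sim.{f.name} = {getattr(self.sim, f.name)}"
                  for f in dataclasses.fields(self.sim)]
        return "\n".join(lines)


def run_pipeline(config: RunConfig) -> str:
    """Run every stage and return the text report.

    Stage outputs (design.csv, species_pool.csv, rates.csv, tpc_fits.csv,
    units.csv, species_abundances.csv, bef_table.csv, contrasts.csv,
    coefficients.csv, overyielding.csv, report.txt, run.log) land in
    ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    report = []
    try:
        log.info("run config:\n%s", config.echo())
        sim = config.sim

        log.info("stage 1: design")
        design = default_design(sim)
        design.to_csv(out / "design.csv")
        validation = validate_design(design)
        n_per_t = design.frame.groupby("temperature_C").size()
        report += [
            "befthermal pipeline report",
            "=" * 72,
            "",
            "DESIGN",
            f"  experimental units: {len(design)}",
            "  units per temperature: "
            + ", ".join(f"{t:g} degC: {k}" for t, k in n_per_t.items()),
            f"  richness levels: {sim.richness_levels}; "
            f"{sim.n_partitions} partitions x {sim.n_replicates} replicates",
            f"  inoculation: {sim.inoculation_density:g} cells/mL total "
            f"({sim.inoculation_density / sim.n_species:g} per species in "
            f"{sim.n_species}-species wells)",
            "  validation: " + ("all checks pass" if validation.passed
                                else "FAILED\n" + str(validation)),
        ]
        if not validation.passed:
            raise RuntimeError("design validation failed:\n" + str(validation))

        log.info("stage 2: species pool + thermal assays")
        pool = generate_species_pool(sim)
        pool_to_frame(pool).to_csv(out / "species_pool.csv", index=False)
        rates = simulate_pi_assays(pool, sim)
        rates.to_csv(out / "rates.csv", index=False)
        gp = thermal.gp_from_pi_assays(rates)
        fits = thermal.fit_tpc_table(gp, tc_ref=config.tc_ref)
        fits.to_csv(out / "tpc_fits.csv", index=False)
        truth = {sp.species_id: sp.topt_true_C for sp in pool}
        err = (fits.set_index("species_id")["topt_C"]
               - pd.Series(truth)).abs()
        report += [
            "",
            "THERMAL PERFORMANCE",
            f"  species fitted: {int(fits['converged'].sum())}/{len(fits)}",
            f"  thermal optima span "
            f"{fits['topt_C'].min():.1f}-{fits['topt_C'].max():.1f} degC "
            f"(range {fits['topt_C'].max() - fits['topt_C'].min():.1f} degC)",
            f"  median |Topt - truth|: {err.median():.2f} degC",
        ]

        log.info("stage 3: community outcomes")
        expt = simulate_community_experiment(pool, design, sim)
        expt.units.to_csv(out / "units.csv", index=False)
        expt.species_abundances.to_csv(out / "species_abundances.csv",
                                       index=False)

        if config.run_cytometry:
            log.info("stage 4: cytometry (monocultures + polycultures)")
            mono_poly = _cytometry_stage(expt, pool, design, sim, config, out)
            report += mono_poly
        else:
            report += ["", "CYTOMETRY", "  skipped by config"]

        log.info("stage 5: BEF statistics")
        res = bef.BEFModel(expt.units, response=config.response).fit()
        res.model_table.to_csv(out / "bef_table.csv", index=False)
        sc = res.slope_contrasts()
        sc.slopes.to_csv(out / "slopes.csv", index=False)
        sc.contrasts.to_csv(out / "contrasts.csv", index=False)
        coef_frames = []
        trait_lines = []
        topt = pd.Series({sp.species_id: sp.topt_true_C for sp in pool})
        vol = pd.Series({sp.species_id: np.log(sp.cell_volume)
                         for sp in pool})
        for t in sim.temperatures:
            cf = res.species_coefficients(t).assign(temperature_C=t)
            coef_frames.append(cf)
            merged = cf.set_index("species_id")
            reg_t = bef.trait_correlation(merged["coefficient"],
                                          topt.loc[merged.index])
            reg_v = bef.trait_correlation(merged["coefficient"],
                                          vol.loc[merged.index])
            trait_lines.append(
                f"  {t:g} degC: coeff ~ Topt: {reg_t}; "
                f"coeff ~ ln volume: {reg_v}"
            )
        pd.concat(coef_frames).to_csv(out / "coefficients.csv", index=False)
        oy_rows = []
        rng_oy = substream(config.seed, "overyielding")
        for t in sim.temperatures:
            oy = res.overyielding(t, n_boot=config.n_boot, rng=rng_oy)
            oy_rows.append(dataclasses.asdict(oy))
        pd.DataFrame(oy_rows).to_csv(out / "overyielding.csv", index=False)

        report += ["", "BEF STATISTICS", res.summary(), "",
                   "TRAIT CORRELATIONS (species coefficients)"]
        report += trait_lines
        report += ["", "OVERYIELDING (ln production scale)"]
        for row in oy_rows:
            report.append(
                f"  {row['temperature']:g} degC: net = {row['net_oy']:.3f} "
                f"[{row['net_ci'][0]:.3f}, {row['net_ci'][1]:.3f}], "
                f"transgressive = {row['trans_oy']:.3f} "
                f"[{row['trans_ci'][0]:.3f}, {row['trans_ci'][1]:.3f}] "
                f"(best mono: {row['best_mono_species']})"
            )
        text = "\n".join(report) + "\n"
        (out / "report.txt").write_text(text)
        log.info("pipeline complete")
        return text
    except Exception:
        log.exception("pipeline failed")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()


def _cytometry_stage(expt: CommunityExperiment, pool, design, sim,
                     config: RunConfig, out: Path):
    """Simulate + process cytometry for monoculture and polyculture wells."""
    units = expt.units
    ab = expt.species_abundances.set_index(["unit_id", "species_id"])
    cal = cytometry.CalibrationCurve(sim.calibration_slope,
                                     sim.calibration_intercept)
    rng = substream(config.seed, "cytometry-stage")
    lines = ["", "CYTOMETRY"]
    metrics_rows = []
    regs = []
    for t in sim.temperatures:
        ut = units[units["temperature_C"] == t]
        mono = ut[ut["richness"] == 1]
        poly = ut[ut["richness"] == ut["richness"].max()]
        mono_events = {}
        measured_rows = []
        for row in mono.itertuples(index=False):
            sid = row.species
            ev = simulate_cytometry_events(
                {sid: ab.loc[(row.unit_id, sid), "abundance"]}, pool,
                config.volume_uL, sim, rng,
            )
            mono_events.setdefault(sid, []).append(ev)
            m = cytometry.events_to_metrics(ev, cal, config.volume_uL,
                                            unit_id=row.unit_id)
            metrics_rows.append(dataclasses.asdict(m))
            measured_rows.append({"unit_id": row.unit_id, "species_id": sid,
                                  "abundance": m.abundance})
        labelled = {
            sid: pd.concat([e for e in evs if len(e)], ignore_index=True)
            for sid, evs in mono_events.items()
        }
        clf = cytometry.train_species_classifier(
            labelled, expected_species=[sp.species_id for sp in pool],
            random_state=config.seed,
        )
        assigned_rows = []
        for row in poly.itertuples(index=False):
            members = row.species.split(";")
            abund = {m: ab.loc[(row.unit_id, m), "abundance"]
                     for m in members}
            ev = simulate_cytometry_events(abund, pool, config.volume_uL,
                                           sim, rng)
            m = cytometry.events_to_metrics(ev, cal, config.volume_uL,
                                            unit_id=row.unit_id)
            metrics_rows.append(dataclasses.asdict(m))
            asg = cytometry.assign_species(ev, clf, config.volume_uL)
            for sid, a in asg.abundances.items():
                assigned_rows.append({"unit_id": row.unit_id,
                                      "species_id": sid, "abundance": a,
                                      "flagged": asg.flagged})
        assigned = pd.DataFrame(assigned_rows)
        measured = pd.concat(
            [pd.DataFrame(measured_rows),
             assigned[~assigned["flagged"]][["unit_id", "species_id",
                                             "abundance"]]],
            ignore_index=True,
        )
        reg = bef.mono_poly_regression(measured, units, t)
        regs.append((t, clf.per_class_accuracy.mean(), reg))
    pd.DataFrame(metrics_rows).to_csv(out / "cytometry_metrics.csv",
                                      index=False)
    for t, acc, reg in regs:
        lines.append(f"  {t:g} degC: classifier mean OOB accuracy "
                     f"{acc:.2f}; polyculture ~ monoculture abundance "
                     f"(ln scale): {reg}")
    return lines
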