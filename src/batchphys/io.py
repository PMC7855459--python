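"""File formats, run configuration and the end-to-end pipeline.

CSV dialect: comma-separated, UTF-8, dot decimal, header row required.
Time-series files carry columns ``time_h, value, sd`` (``sd`` optional,
filled from a default relative sd); off-gas files carry
``time_h, o2_volpct, co2_volpct`` with optional ``sd_o2``/``sd_co2``.

The pipeline sequences the whole analysis for one reactor:
window detection → joint rate fit → bootstrap → gas balance →
carbon balance, and writes a tidy results table (one row per parameter:
name, estimate, lower, upper, unit) plus a run log recording every
default and decision value actually used (p, T, α, n, seed, ω_C …).
Replicate reactors are summarized separately by the envelope rule:
per parameter, the minimum of the lower bounds and the maximum of the
upper bounds over all replicate cultivations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bootstrap import bootstrap_fit
from .carbon import instantaneous_theta, propagate_theta_error
from .core import (
    BatchDataset,
    CarbonParams,
    GasConditions,
    MeasurementSeries,
    validate_dataset,
)
from .fitting import fit_rates
from .offgas import balance_offgas
from .phase import PhaseWindow, detect_window

logger = logging.getLogger("batchphys")

ENVELOPE_RULE = (
    "minimum of the lower bound and the maximum of the upper bound "
    "of each parameter over all replicate cultivations"
)


@dataclass
class RunConfig:
    """Everything one pipeline run needs, overridable from CLI flags."""

    biomass_csv: str = "biomass.csv"
    glucose_csv: str = "glucose.csv"
    offgas_csv: str = "offgas.csv"
    out_dir: str = "results"
    strain_label: str = ""
    reactor_volume: float = 1.0           # L
    gas_flow: float = 0.06                # m3/h (1 vvm on 1 L)
    pressure: float = 101325.0            # Pa
    temperature: float = 273.15           # K
    phi_o2_in: float = 20.95              # vol%
    phi_co2_in: float = 0.04              # vol%
    omega_c: float = 0.45                 # gC/gCDW
    sd_omega_c: float = 0.05
    n_boot: int = 1000
    alpha: float = 0.25
    seed: int = 0
    default_rel_sd: float = 0.05
    t_start: float | None = None          # window overrides
    t_end: float | None = None

    def gas_conditions(self) -> GasConditions:
        return GasConditions(
            F=self.gas_flow,
            p=self.pressure,
            T=self.temperature,
            phi_o2_in=self.phi_o2_in,
            phi_co2_in=self.phi_co2_in,
        )

    def carbon_params(self) -> CarbonParams:
        return CarbonParams(omega_c=self.omega_c, sd_omega_c=self.sd_omega_c)


def load_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def read_timeseries_csv(path, quantity_tag: str, default_rel_sd: float = 0.05) -> MeasurementSeries:
    """Read one measurement series from the standard CSV dialect.

    A missing ``sd`` column is filled as ``default_rel_sd · value``;
    rows with a blank value are dropped with a logged count.  Raises on
    an empty file, unparseable numerics or non-increasing times (naming
    the offending row).
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty time-series file")
    for col in ("time_h", "value"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    n0 = len(df)
    df = df.dropna(subset=["value"])
    if len(df) < n0:
        logger.info("%s: dropped %d blank-value rows", path, n0 - len(df))
    if df.empty:
        raise ValueError(f"{path}: no usable rows")
    times = pd.to_numeric(df["time_h"], errors="raise").to_numpy(dtype=float)
    values = pd.to_numeric(df["value"], errors="raise").to_numpy(dtype=float)
    bad = np.nonzero(np.diff(times) <= 0)[0]
    if bad.size:
        raise ValueError(
            f"{path}: times not strictly increasing at row {bad[0] + 3} "
            f"(t={times[bad[0] + 1]})"
        )
    if "sd" in df.columns:
        sds = pd.to_numeric(df["sd"], errors="raise").to_numpy(dtype=float)
    else:
        sds = default_rel_sd * np.abs(values)
    return MeasurementSeries(times, values, sds, quantity_tag)


def read_offgas_csv(path, abs_sd: float = 0.02):
    """Read the two off-gas series (time_h, o2_volpct, co2_volpct)."""
    df = pd.read_csv(path)
    for col in ("time_h", "o2_volpct", "co2_volpct"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    t = df["time_h"].to_numpy(dtype=float)
    sd_o2 = df["sd_o2"].to_numpy(float) if "sd_o2" in df else np.full(len(df), abs_sd)
    sd_co2 = df["sd_co2"].to_numpy(float) if "sd_co2" in df else np.full(len(df), abs_sd)
    o2 = MeasurementSeries(t, df["o2_volpct"].to_numpy(float), sd_o2, "o2_out")
    co2 = MeasurementSeries(t, df["co2_volpct"].to_numpy(float), sd_co2, "co2_out")
    return o2, co2


def write_timeseries_csv(series: MeasurementSeries, path):
    pd.DataFrame(
        {"time_h": series.times, "value": series.values, "sd": series.sds}
    ).to_csv(path, index=False)


def write_dataset(ds: BatchDataset, out_dir) -> dict:
    """Write one dataset as the standard CSV trio plus a conditions file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_timeseries_csv(ds.biomass, out / "biomass.csv")
    write_timeseries_csv(ds.glucose, out / "glucose.csv")
    pd.DataFrame(
        {
            "time_h": ds.offgas_o2.times,
            "o2_volpct": ds.offgas_o2.values,
            "co2_volpct": ds.offgas_co2.values,
            "sd_o2": ds.offgas_o2.sds,
            "sd_co2": ds.offgas_co2.sds,
        }
    ).to_csv(out / "offgas.csv", index=False)
    conditions = {
        "strain_label": ds.strain_label,
        "reactor_volume": ds.reactor_volume,
        "gas_flow": ds.gas.F,
        "pressure": ds.gas.p,
        "temperature": ds.gas.T,
        "phi_o2_in": ds.gas.phi_o2_in,
        "phi_co2_in": ds.gas.phi_co2_in,
        "biomass_tag": ds.biomass.quantity_tag,
    }
    with open(out / "conditions.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(conditions, fh, sort_keys=True)
    return conditions


def load_dataset(cfg: RunConfig) -> BatchDataset:
    """Assemble a :class:`BatchDataset` from the files a config points at."""
    for p in (cfg.biomass_csv, cfg.glucose_csv, cfg.offgas_csv):
        if not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")
    biomass = read_timeseries_csv(cfg.biomass_csv, "biomass_cdw", cfg.default_rel_sd)
    glucose = read_timeseries_csv(cfg.glucose_csv, "glucose", cfg.default_rel_sd)
    o2, co2 = read_offgas_csv(cfg.offgas_csv)
    return BatchDataset(
        biomass=biomass,
        glucose=glucose,
        offgas_o2=o2,
        offgas_co2=co2,
        gas=cfg.gas_conditions(),
        reactor_volume=cfg.reactor_volume,
        strain_label=cfg.strain_label,
    )


_UNITS = {
    "X0": "g/L",
    "mu": "1/h",
    "pi_glc": "mmol/gCDW/h",
    "C": "mmol/L",
    "pi_co2": "mmol/gCDW/h",
    "theta": "-",
}


def run_pipeline(cfg: RunConfig) -> pd.DataFrame:
    """Execute the full single-reactor analysis and write its outputs.

    Stages: load & validate → window detection (or overrides) → joint
    fit → bootstrap → off-gas balance → carbon balance.  Fails fast with
    the first stage error; output files are only written once every
    stage has succeeded, so no partial results are left behind.
    """
    ds = load_dataset(cfg)
    issues = validate_dataset(ds)
    if issues:
        raise ValueError("invalid dataset: " + "; ".join(issues))

    if cfg.t_start is not None and cfg.t_end is not None:
        n_pts = int(
            np.sum((ds.biomass.times >= cfg.t_start) & (ds.biomass.times <= cfg.t_end))
        )
        window = PhaseWindow(cfg.t_start, cfg.t_end, n_points_in_window=n_pts)
    else:
        window = detect_window(ds.offgas_co2, ds.biomass, glucose=ds.glucose)
        if cfg.t_start is not None:
            window.t_start = cfg.t_start
        if cfg.t_end is not None:
            window.t_end = cfg.t_end

    fit = fit_rates(ds, window)
    boot = bootstrap_fit(
        ds, window, n=cfg.n_boot, alpha=cfg.alpha, seed=cfg.seed, point_fit=fit
    )
    gbr = balance_offgas(ds, fit, window)

    cp = cfg.carbon_params()
    cb = instantaneous_theta(fit.mu, fit.pi_glc, gbr.pi_co2_mean, cp)
    hw = boot.half_widths()  # symmetric sd-like summaries from the IQR
    cb.sd_theta = propagate_theta_error(
        fit.mu, fit.pi_glc, gbr.pi_co2_mean, hw[1], hw[2], gbr.sd_pi_co2_mean, cp
    )

    point = {
        "X0": fit.X0, "mu": fit.mu, "pi_glc": fit.pi_glc, "C": fit.C,
        "pi_co2": gbr.pi_co2_mean, "theta": cb.theta,
    }
    lower = dict(zip(("X0", "mu", "pi_glc", "C"), boot.lower))
    upper = dict(zip(("X0", "mu", "pi_glc", "C"), boot.upper))
    lower["pi_co2"] = gbr.pi_co2_mean - gbr.sd_pi_co2_mean
    upper["pi_co2"] = gbr.pi_co2_mean + gbr.sd_pi_co2_mean
    lower["theta"] = cb.theta - cb.sd_theta
    upper["theta"] = cb.theta + cb.sd_theta

    results = pd.DataFrame(
        {
            "parameter": list(point),
            "estimate": [point[k] for k in point],
            "lower": [lower[k] for k in point],
            "upper": [upper[k] for k in point],
            "unit": [_UNITS[k] for k in point],
        }
    )

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    label = cfg.strain_label or "reactor"
    results.to_csv(out / f"{label}_results.csv", index=False)
    run_log = {
        "strain_label": label,
        "window_t_start": float(window.t_start),
        "window_t_end": float(window.t_end),
        "pressure": cfg.pressure,
        "temperature": cfg.temperature,
        "gas_flow": cfg.gas_flow,
        "phi_o2_in": cfg.phi_o2_in,
        "phi_co2_in": cfg.phi_co2_in,
        "reactor_volume": cfg.reactor_volume,
        "omega_c": cfg.omega_c,
        "sd_omega_c": cfg.sd_omega_c,
        "alpha": cfg.alpha,
        "n_boot": cfg.n_boot,
        "seed": cfg.seed,
        "default_rel_sd": cfg.default_rel_sd,
        "n_bootstrap_failed": boot.n_failed,
        "sse": fit.sse,
    }
    logger.info(
        "gas balance evaluated at p=%.0f Pa, T=%.2f K (configurable)",
        cfg.pressure, cfg.temperature,
    )
    with open(out / f"{label}_runlog.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(run_log, fh, sort_keys=True)
    return results


def read_results(path) -> pd.DataFrame:
    """Re-read a results table written by :func:`run_pipeline`."""
    return pd.read_csv(path)


def summarize_replicates(result_paths, out_path=None) -> pd.DataFrame:
    """Replicate envelope: min lower bound / max upper bound per parameter.

    The estimate column is the mean of the replicate estimates; the
    envelope rule itself is recorded in the output metadata so the
    provenance of the error bars is traceable.
    """
    frames = [read_results(p) for p in result_paths]
    allrep = pd.concat(frames)
    grouped = allrep.groupby("parameter", sort=False).agg(
        estimate=("estimate", "mean"),
        lower=("lower", "min"),
        upper=("upper", "max"),
        unit=("unit", "first"),
        n_replicates=("estimate", "size"),
    ).reset_index()
    grouped.attrs["envelope_rule"] = ENVELOPE_RULE
    if out_path is not None:
        with open(out_path, "w", encoding="utf-8") as fh:
            fh.write(f"# envelope rule: {ENVELOPE_RULE}\n")
            grouped.to_csv(fh, index=False)
    return grouped
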