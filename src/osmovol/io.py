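"""Readers, writers, run configuration and the end-to-end study driver.

All interchange is plain delimited text (comma, UTF-8, '.' decimal).
Trajectory tables are long format with header
``cell_id,time_min,volume_um3,area_um2[,condition]``; empty fields are
missing values.  Shock protocols use ``time_s,piso_over_p`` and shock
trajectories ``time_s,volume_um3,osm_ext_mM``.  Every output carries a
provenance comment line (package version, seed, config hash) and comment
lines starting with '#' are skipped on read.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import OsmovolError
from .fitting import (CellTrajectory, OnsetNotFoundError, align_spreading_onset,
                      classify_by_speed, fit_area_ansatz, fit_volume_params,
                      flux_regression, initial_fluxes)
from .mechano import MechanoParams, SpreadingAnsatz
from .pump_leak import OsmoticTrajectory, ShockProtocol
from .synthetic import CohortConfig, generate_spreading_cohort

__all__ = [
    "read_trajectories",
    "write_trajectories",
    "read_protocol",
    "write_protocol",
    "write_shock_trajectory",
    "RunConfig",
    "run_study",
]

logger = logging.getLogger(__name__)

_TRAJ_COLUMNS = ["cell_id", "time_min", "volume_um3", "area_um2"]


def _provenance_line(seed=None, config_hash=None) -> str:
    parts = [f"# osmovol {__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_hash is not None:
        parts.append(f"config_hash={config_hash}")
    return " ".join(parts)


def read_trajectories(path) -> list[CellTrajectory]:
    """Read a long-format trajectory table into per-cell trajectories.

    Rows are sorted by time within each cell; malformed rows (negative
    values, duplicate time stamps) raise with the offending line number.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    if "condition" not in df.columns:
        df["condition"] = ""
    df["_line"] = df.index + 2  # header is line 1
    for col in ("volume_um3", "area_um2"):
        bad = df.index[df[col] < 0]
        if len(bad):
            raise ValueError(
                f"{path}: negative {col} at line {int(df.loc[bad[0], '_line'])}"
            )
    dup = df.duplicated(subset=["cell_id", "time_min"], keep=False)
    if dup.any():
        line = int(df.loc[dup.idxmax(), "_line"])
        raise ValueError(f"{path}: duplicate (cell_id, time) pair near line {line}")
    out = []
    for cid, g in df.groupby("cell_id", sort=True):
        g = g.sort_values("time_min")
        cond = str(g["condition"].iloc[0]) if not pd.isna(g["condition"].iloc[0]) else ""
        out.append(CellTrajectory(
            cell_id=str(cid),
            times=g["time_min"].to_numpy(float),
            volumes=g["volume_um3"].to_numpy(float),
            areas=g["area_um2"].to_numpy(float),
            condition=cond,
        ))
    return out


def write_trajectories(path, trajectories: list[CellTrajectory],
                       seed=None, config_hash=None) -> None:
    path = Path(path)
    frames = []
    for tr in trajectories:
        frames.append(pd.DataFrame({
            "cell_id": tr.cell_id, "time_min": tr.times,
            "volume_um3": tr.volumes, "area_um2": tr.areas,
            "condition": tr.condition,
        }))
    df = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(_provenance_line(seed, config_hash) + "\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def read_protocol(path) -> ShockProtocol:
    """Read a shock protocol (``time_s,piso_over_p``); duration extends one
    sampling-free 10-min tail past the last event unless a trailing
    ``# duration_s=`` comment overrides it."""
    path = Path(path)
    duration = None
    dt = 1.0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                for tok in line[1:].replace(",", " ").split():
                    if tok.startswith("duration_s="):
                        duration = float(tok.split("=", 1)[1])
                    elif tok.startswith("dt_s="):
                        dt = float(tok.split("=", 1)[1])
    df = pd.read_csv(path, comment="#")
    if not {"time_s", "piso_over_p"} <= set(df.columns):
        raise ValueError(f"{path}: expected header time_s,piso_over_p")
    events = tuple((float(t), float(r))
                   for t, r in zip(df["time_s"], df["piso_over_p"]))
    if duration is None:
        duration = events[-1][0] + 600.0
    return ShockProtocol(events=events, duration=duration, dt=dt)


def write_protocol(path, protocol: ShockProtocol) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_line() + "\n")
        fh.write(f"# duration_s={protocol.duration} dt_s={protocol.dt}\n")
        fh.write("time_s,piso_over_p\n")
        for t, r in protocol.events:
            fh.write(f"{t:.10g},{r:.10g}\n")


def write_shock_trajectory(path, traj: OsmoticTrajectory, seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_line(seed) + "\n")
        fh.write("time_s,volume_um3,osm_ext_mM\n")
        for t, v, o in zip(traj.times, traj.V, traj.osm_ext):
            fh.write(f"{t:.10g},{v:.10g},{o:.10g}\n")


_RUN_STAGES = ("generate", "align", "fit_area", "fit_volume", "fluxes",
               "groups", "regressions")


@dataclass
class RunConfig:
    """Configuration of an end-to-end spreading study.

    ``stages`` selects which pipeline stages run (later stages require the
    earlier ones in the same run); ``input_table`` is used instead of the
    generator when 'generate' is not selected.  Unknown keys in a config
    file are rejected rather than silently ignored.
    """

    out_dir: str = "results"
    seed: int = 0
    stages: tuple = _RUN_STAGES
    input_table: str | None = None
    preset: str = "control"
    n_cells: int = 50
    duration: float = 60.0
    noise_cv: float = 0.01
    onset_threshold: float = 100.0
    flux_window: float = 10.0
    r_growth: float = 0.05
    log_level: str = "INFO"
    cohort_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def content_hash(self) -> str:
        """Hash of the scientifically relevant settings (paths excluded)."""
        d = asdict(self)
        d.pop("out_dir", None)
        d.pop("log_level", None)
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_study(config: RunConfig) -> dict:
    """Run the spreading-study pipeline and write its result bundle.

    Stages: generate (or load) -> onset alignment -> area-ansatz fit ->
    (ξ, τ) volume fit -> initial fluxes -> speed terciles -> flux
    regression.  Writes a per-cell results table and a machine-readable
    summary (JSON) with provenance; any stage failure aborts with context.
    Returns the summary dict.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = set(config.stages)
    unknown = stages - set(_RUN_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    chash = config.content_hash()
    summary: dict = {
        "provenance": {"package_version": __version__, "seed": config.seed,
                       "config_hash": chash},
        "warnings": [],
    }

    if "generate" in stages:
        cohort_cfg = CohortConfig.from_preset(
            config.preset, n_cells=config.n_cells, duration=config.duration,
            noise_cv=config.noise_cv, seed=config.seed,
            **config.cohort_overrides)
        trajectories, truth = generate_spreading_cohort(cohort_cfg)
        write_trajectories(out / "cohort.csv", trajectories,
                           seed=config.seed, config_hash=chash)
        truth.to_csv(out / "truth.csv", index=False)
        summary["n_generated"] = len(trajectories)
    elif config.input_table:
        trajectories = read_trajectories(config.input_table)
    else:
        raise ValueError("no input: select the 'generate' stage or set input_table")

    rows = []
    aligned = {}
    if "align" in stages:
        for tr in trajectories:
            try:
                aligned[tr.cell_id] = align_spreading_onset(
                    tr, area_threshold=config.onset_threshold)
            except OnsetNotFoundError as exc:
                summary["warnings"].append(str(exc))
        summary["n_aligned"] = len(aligned)
        summary["n_excluded"] = len(trajectories) - len(aligned)

    area_fits = {}
    if "fit_area" in stages:
        for cid, tr in aligned.items():
            try:
                area_fits[cid] = fit_area_ansatz(tr)
            except (ValueError, OsmovolError) as exc:
                summary["warnings"].append(f"area fit {cid}: {exc}")

    volume_fits = {}
    if "fit_volume" in stages:
        for cid, fit in area_fits.items():
            if not fit.converged:
                continue
            tr = aligned[cid]
            ansatz = SpreadingAnsatz(A_init=fit.params["A_init"],
                                     A0=fit.params["A0"],
                                     tau_a=fit.params["tau_a"])
            mech = MechanoParams(xi=1.0, tau=20.0,
                                 V_iso=float(np.nanmean(tr.volumes[:3])),
                                 r_growth=config.r_growth)
            try:
                volume_fits[cid] = fit_volume_params(tr, ansatz, mech)
            except (ValueError, OsmovolError) as exc:
                summary["warnings"].append(f"volume fit {cid}: {exc}")

    fluxes = {}
    if "fluxes" in stages:
        for cid, tr in aligned.items():
            fluxes[cid] = initial_fluxes(tr, window_min=config.flux_window)

    groups = None
    if "groups" in stages and fluxes:
        groups = classify_by_speed(list(fluxes.values()))
        summary["group_sizes"] = dict(zip(("slow", "moderate", "fast"),
                                          groups.sizes()))
        summary["groups_degenerate"] = groups.degenerate

    if "regressions" in stages and fluxes:
        try:
            reg = flux_regression(list(fluxes.values()))
            summary["flux_regression"] = {
                "slope": reg.slope, "intercept": reg.intercept,
                "r_squared": reg.r_squared, "n": reg.n,
                "stderr_slope": reg.stderr_slope,
            }
        except ValueError as exc:
            summary["warnings"].append(f"flux regression: {exc}")

    group_of = {}
    if groups is not None:
        for name, members in (("slow", groups.slow), ("moderate", groups.moderate),
                              ("fast", groups.fast)):
            for m in members:
                group_of[m.cell_id] = name

    for tr in trajectories:
        cid = tr.cell_id
        af = area_fits.get(cid)
        vf = volume_fits.get(cid)
        fx = fluxes.get(cid)
        rows.append({
            "cell_id": cid,
            "A_init": af.params.get("A_init") if af else np.nan,
            "A0": af.params.get("A0") if af else np.nan,
            "tau_a": af.params.get("tau_a") if af else np.nan,
            "xi": vf.params.get("xi") if vf else np.nan,
            "tau": vf.params.get("tau") if vf else np.nan,
            "dAdt": fx.dAdt if fx else np.nan,
            "dVdt": fx.dVdt if fx else np.nan,
            "group": group_of.get(cid, ""),
            "converged": bool(vf.converged) if vf else False,
        })
    if rows:
        per_cell = pd.DataFrame(rows)
        with open(out / "per_cell.csv", "w") as fh:
            fh.write(_provenance_line(config.seed, chash) + "\n")
            per_cell.to_csv(fh, index=False, float_format="%.8g")
        if volume_fits:
            xi_vals = [vf.params["xi"] for vf in volume_fits.values()
                       if vf.converged and "xi" in vf.params]
            tau_vals = [vf.params["tau"] for vf in volume_fits.values()
                        if vf.converged and "tau" in vf.params]
            summary["median_xi"] = float(np.median(xi_vals)) if xi_vals else None
            summary["median_tau"] = float(np.median(tau_vals)) if tau_vals else None
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
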