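"""File formats and run configuration.

All outputs are plain text: window coordinate dumps (two-column, '#'-comment
header, in the style of MD restraint-coordinate dumps so externally produced
window series can be post-processed), TSV tables, and JSON for configuration,
metadata and per-walker results.  Floats are written with ``repr`` (17
significant digits) so write/read round-trips are bitwise exact.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .binding import DEFAULT_CUTOFF_PERSISTENCE, DEFAULT_CUTOFF_THRESHOLD
from .constants import T_SIM_K, V0_A3
from .driver import (
    DEFAULT_DELTA_A,
    DEFAULT_N_WALKERS,
    DEFAULT_SPRING_K,
    WalkerRun,
    WindowSchedule,
)
from .dynamics import IntegratorParams, RestraintSpec, WindowTimeSeries
from .landscape import Landscape, LigandState

log = logging.getLogger("cpus.config")


class EmptySeriesError(ValueError):
    pass


def _fr(x) -> str:
    """Full-precision decimal text (17 significant digits, round-trip exact)."""
    return repr(float(x))


class ConfigError(ValueError):
    pass


# -- window coordinate dumps ---------------------------------------------


def write_window_file(series: WindowTimeSeries, path) -> None:
    """Two-column 'time_ps distance_A' dump with '#' header."""
    with open(path, "w") as fh:
        fh.write("# time_ps distance_A\n")
        if series.restraint is not None:
            fh.write(
                f"# spring_k_kcal_mol_A2={_fr(series.restraint.spring_k)} "
                f"target_A={_fr(series.restraint.target)}\n"
            )
        for t, d in zip(series.times, series.distances):
            fh.write(f"{_fr(t)} {_fr(d)}\n")


def read_window_file(path) -> WindowTimeSeries:
    """Read a two-column window dump; '#' lines are comments.

    Energy components are not part of this dialect and come back as NaN.
    A file with no data rows raises :class:`EmptySeriesError`; a malformed
    row raises ``ValueError`` naming the line number.
    """
    times: List[float] = []
    dists: List[float] = []
    restraint = None
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                if "spring_k_kcal_mol_A2=" in stripped and "target_A=" in stripped:
                    kv = dict(
                        tok.split("=", 1) for tok in stripped[1:].split() if "=" in tok
                    )
                    restraint = RestraintSpec(
                        spring_k=float(kv["spring_k_kcal_mol_A2"]),
                        target=float(kv["target_A"]),
                    )
                continue
            parts = stripped.split()
            if len(parts) != 2:
                raise ValueError(f"{path}: malformed line {ln}: {stripped!r}")
            try:
                t, d = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed line {ln}: {stripped!r}") from exc
            times.append(t)
            dists.append(d)
    if not times:
        raise EmptySeriesError(f"{path}: no samples (comments only)")
    nan = np.full(len(times), np.nan)
    return WindowTimeSeries(
        times=np.array(times),
        distances=np.array(dists),
        vdw=nan.copy(),
        elec=nan.copy(),
        restraint=restraint,
    )


# -- walker directories ---------------------------------------------------


def save_walker_run(run: WalkerRun, directory) -> None:
    """One directory per walker: win_0001.dat ..., energies.tsv, frames.tsv
    and meta.json (schedule, seeds, counts) -- enough to rebuild the run."""
    os.makedirs(directory, exist_ok=True)
    for i, w in enumerate(run.windows, start=1):
        write_window_file(w, os.path.join(directory, f"win_{i:04d}.dat"))
    with open(os.path.join(directory, "energies.tsv"), "w") as fh:
        fh.write("window_index\ttarget_A\tmean_vdw\tmean_elec\n")
        for w in run.windows:
            tgt = w.restraint.target if w.restraint is not None else float("nan")
            fh.write(f"{w.window_index}\t{_fr(tgt)}\t{_fr(w.mean_vdw)}\t{_fr(w.mean_elec)}\n")
    with open(os.path.join(directory, "frames.tsv"), "w") as fh:
        fh.write("time_ps\twindow_index\tbead_xyz_A...\n")
        for w in run.windows:
            if w.frames is None:
                continue
            for t, frame in zip(w.frame_times, w.frames):
                coords = "\t".join(_fr(v) for v in frame.reshape(-1))
                fh.write(f"{_fr(t)}\t{w.window_index}\t{coords}\n")
    meta = {
        "walker_id": run.walker_id,
        "master_seed": run.master_seed,
        "spring_k": run.spring_k,
        "d_ref": run.schedule.d_ref,
        "delta": run.schedule.delta,
        "n_forward": run.schedule.n_forward,
        "n_backward": run.schedule.n_backward,
        "n_windows": len(run.windows),
        **run.meta,
    }
    with open(os.path.join(directory, "meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def load_walker_run(directory) -> WalkerRun:
    """Rebuild a :class:`WalkerRun` from a walker directory.

    Window samples, restraints and frames are restored; per-sample energy
    components are only available as window means (energies.tsv), which is
    sufficient for WHAM, cutoff detection and path tracing.
    """
    meta_path = os.path.join(directory, "meta.json")
    if not os.path.exists(meta_path):
        raise FileNotFoundError(f"{directory}: missing meta.json")
    with open(meta_path) as fh:
        meta = json.load(fh)
    schedule = WindowSchedule(
        d_ref=meta["d_ref"],
        n_forward=meta["n_forward"],
        delta=meta["delta"],
        n_backward=meta["n_backward"],
    )
    windows = []
    energies = {}
    epath = os.path.join(directory, "energies.tsv")
    if os.path.exists(epath):
        with open(epath) as fh:
            next(fh)
            for line in fh:
                parts = line.split("\t")
                energies[int(parts[0])] = (float(parts[2]), float(parts[3]))
    frames_by_window = {}
    fpath = os.path.join(directory, "frames.tsv")
    if os.path.exists(fpath):
        with open(fpath) as fh:
            next(fh)
            for line in fh:
                parts = line.strip().split("\t")
                t = float(parts[0])
                widx = int(parts[1])
                coords = np.array([float(v) for v in parts[2:]]).reshape(-1, 3)
                frames_by_window.setdefault(widx, []).append((t, coords))
    for i in range(meta["n_windows"]):
        path = os.path.join(directory, f"win_{i + 1:04d}.dat")
        if not os.path.exists(path):
            raise FileNotFoundError(f"{directory}: missing window file {path}")
        w = read_window_file(path)
        w.window_index = i
        if i in energies:
            n = len(w)
            w.vdw = np.full(n, energies[i][0])
            w.elec = np.full(n, energies[i][1])
        if i in frames_by_window:
            items = frames_by_window[i]
            w.frame_times = np.array([t for t, _ in items])
            w.frames = np.stack([c for _, c in items])
        windows.append(w)
    return WalkerRun(
        schedule=schedule,
        windows=windows,
        walker_id=meta["walker_id"],
        master_seed=meta["master_seed"],
        spring_k=meta["spring_k"],
    )


# -- run configuration ----------------------------------------------------


@dataclass
class RunConfig:
    """Everything needed to reproduce a CPUS study from a JSON file."""

    landscape: Landscape
    d_ref: Optional[float] = None         # None means "auto" (estimate)
    delta: float = DEFAULT_DELTA_A
    n_forward: int = 120
    n_backward: int = 10
    dt: float = 0.01
    friction: float = 1.0
    rot_friction: float = 5.0
    n_walkers: int = DEFAULT_N_WALKERS
    temperature: float = T_SIM_K
    standard_volume: float = V0_A3
    spring_k: float = DEFAULT_SPRING_K
    n_steps: int = 10_000
    stride: int = 10
    path_stride: int = 10
    pre_samples: int = 1000
    n_beads: int = 1
    cutoff_threshold: float = DEFAULT_CUTOFF_THRESHOLD
    cutoff_persistence: int = DEFAULT_CUTOFF_PERSISTENCE
    wham_bin_width: float = 0.05
    max_path_r: float = 10.0
    master_seed: int = 0
    output_dir: str = "cpus_out"

    def integrator_params(self) -> IntegratorParams:
        return IntegratorParams(
            dt=self.dt,
            friction=self.friction,
            temperature=self.temperature,
            seed=self.master_seed,
            rot_friction=self.rot_friction,
        )

    def to_json_dict(self) -> dict:
        return {
            "landscape": self.landscape.to_json_dict(),
            "schedule": {
                "d_ref": "auto" if self.d_ref is None else self.d_ref,
                "delta_A": self.delta,
                "n_forward": self.n_forward,
                "n_backward": self.n_backward,
            },
            "integrator": {
                "dt_ps": self.dt,
                "friction_per_ps": self.friction,
                "rot_friction": self.rot_friction,
            },
            "n_walkers": self.n_walkers,
            "temperature_K": self.temperature,
            "standard_volume_A3": self.standard_volume,
            "spring_k_kcal_mol_A2": self.spring_k,
            "n_steps_per_window": self.n_steps,
            "stride": self.stride,
            "path_stride": self.path_stride,
            "pre_samples": self.pre_samples,
            "n_beads": self.n_beads,
            "cutoff": {
                "threshold_kcal_mol": self.cutoff_threshold,
                "persistence": self.cutoff_persistence,
            },
            "analysis": {
                "wham_bin_width_A": self.wham_bin_width,
                "max_path_r_A": self.max_path_r,
            },
            "master_seed": self.master_seed,
            "output_dir": self.output_dir,
        }

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)


_TOP_KEYS = {
    "landscape", "schedule", "integrator", "n_walkers", "temperature_K",
    "standard_volume_A3", "spring_k_kcal_mol_A2", "n_steps_per_window",
    "stride", "path_stride", "pre_samples", "n_beads", "cutoff", "analysis",
    "master_seed", "output_dir",
}


def _take(section: dict, section_name: str, mapping: dict, out: dict, defaults_applied: list):
    unknown = set(section) - set(mapping)
    if unknown:
        raise ConfigError(f"unknown key(s) in {section_name}: {sorted(unknown)}")
    for jk, attr in mapping.items():
        if jk in section:
            out[attr] = section[jk]
        else:
            defaults_applied.append(f"{section_name}.{jk}")


def config_from_dict(d: dict) -> RunConfig:
    """Validated configuration with defaults filled; every applied default is
    logged.  Unknown keys are rejected with the offending key name."""
    unknown = set(d) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    if "landscape" not in d:
        raise ConfigError("config must contain a 'landscape' section")
    kwargs: dict = {"landscape": Landscape.from_json_dict(d["landscape"])}
    defaults: list = []
    _take(d.get("schedule", {}), "schedule",
          {"d_ref": "d_ref", "delta_A": "delta",
           "n_forward": "n_forward", "n_backward": "n_backward"},
          kwargs, defaults)
    if kwargs.get("d_ref") == "auto":
        kwargs["d_ref"] = None
    _take(d.get("integrator", {}), "integrator",
          {"dt_ps": "dt", "friction_per_ps": "friction", "rot_friction": "rot_friction"},
          kwargs, defaults)
    _take(d.get("cutoff", {}), "cutoff",
          {"threshold_kcal_mol": "cutoff_threshold", "persistence": "cutoff_persistence"},
          kwargs, defaults)
    _take(d.get("analysis", {}), "analysis",
          {"wham_bin_width_A": "wham_bin_width", "max_path_r_A": "max_path_r"},
          kwargs, defaults)
    scalar_map = {
        "n_walkers": "n_walkers", "temperature_K": "temperature",
        "standard_volume_A3": "standard_volume", "spring_k_kcal_mol_A2": "spring_k",
        "n_steps_per_window": "n_steps", "stride": "stride",
        "path_stride": "path_stride", "pre_samples": "pre_samples",
        "n_beads": "n_beads", "master_seed": "master_seed", "output_dir": "output_dir",
    }
    for jk, attr in scalar_map.items():
        if jk in d:
            kwargs[attr] = d[jk]
        else:
            defaults.append(jk)
    cfg = RunConfig(**kwargs)
    # validation with field names in the message
    for name, positive in (
        ("delta", cfg.delta), ("dt", cfg.dt), ("friction", cfg.friction),
        ("spring_k", cfg.spring_k), ("temperature", cfg.temperature),
        ("standard_volume", cfg.standard_volume),
        ("cutoff_threshold", cfg.cutoff_threshold),
        ("wham_bin_width", cfg.wham_bin_width),
    ):
        if positive <= 0:
            raise ConfigError(f"{name} must be positive, got {positive}")
    for name, val in (
        ("n_forward", cfg.n_forward), ("n_walkers", cfg.n_walkers),
        ("n_steps", cfg.n_steps), ("stride", cfg.stride),
        ("cutoff_persistence", cfg.cutoff_persistence),
    ):
        if val < 1:
            raise ConfigError(f"{name} must be >= 1, got {val}")
    if cfg.n_backward < 0:
        raise ConfigError(f"n_backward must be >= 0, got {cfg.n_backward}")
    if cfg.d_ref is not None and cfg.d_ref <= 0:
        raise ConfigError(f"d_ref must be positive or 'auto', got {cfg.d_ref}")
    for key in defaults:
        log.info("config: default applied for %s", key)
    return cfg


def load_config(path) -> RunConfig:
    with open(path) as fh:
        try:
            d = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"{path}: invalid JSON: {exc}") from exc
    return config_from_dict(d)


# -- result reports -------------------------------------------------------


def write_result_json(result, path) -> None:
    d = {
        "walker_id": result.walker_id,
        "dg_pmf_kcal_mol": result.dg_pmf,
        "r_cut_A": result.r_cut,
        "bound_integral_A": result.bound_integral,
        "correction_kcal_mol": result.correction,
        "dg_bind0_kcal_mol": result.dg_bind0,
        "standard_volume_A3": result.standard_volume,
        "temperature_K": result.temperature,
        "d_final_A": result.d_final,
        "bound_region_A": list(result.bound_region),
    }
    with open(path, "w") as fh:
        json.dump(d, fh, indent=1)


def write_summary_tsv(results, selected_index: int, path) -> None:
    """Ensemble summary: one row per walker, exactly one flagged as the
    lower-bound selection."""
    with open(path, "w") as fh:
        fh.write(
            "walker_id\tdg_pmf\tr_cut\tbound_integral\tcorrection\tdg_bind0\tselected\n"
        )
        for i, r in enumerate(results):
            fh.write(
                f"{r.walker_id}\t{_fr(r.dg_pmf)}\t{_fr(r.r_cut)}\t{_fr(r.bound_integral)}"
                f"\t{_fr(r.correction)}\t{_fr(r.dg_bind0)}\t{int(i == selected_index)}\n"
            )


def write_path_tsv(path_trace, path) -> None:
    with open(path, "w") as fh:
        fh.write("r_A\twindow_index\tframe_index\tx_A\ty_A\tz_A\n")
        for r, wi, fi, p in zip(
            path_trace.targets_r, path_trace.window_indices,
            path_trace.frame_indices, path_trace.points,
        ):
            fh.write(f"{_fr(r)}\t{wi}\t{fi}\t{_fr(p[0])}\t{_fr(p[1])}\t{_fr(p[2])}\n")


def write_trace_tsv(trace, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# pair={trace.pair_label}\n")
        fh.write("time_ps\tdistance_A\twindow_index\n")
        for t, dd, wi in zip(trace.times, trace.distances, trace.window_index):
            fh.write(f"{_fr(t)}\t{_fr(dd)}\t{wi}\n")


def write_path_pdbish(path_trace, path) -> None:
    """Minimal multi-model coordinate file (one sphere per window) loadable
    by molecular viewers; occupancy column carries the window index."""
    with open(path, "w") as fh:
        for i, p in enumerate(path_trace.points):
            fh.write(f"MODEL     {i + 1:4d}\n")
            fh.write(
                "HETATM    1  C   PTH A   1    "
                f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}{float(i):6.2f}  0.00           C\n"
            )
            fh.write("ENDMDL\n")
        fh.write("END\n")
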