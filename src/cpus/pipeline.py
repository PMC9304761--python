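"""End-to-end CPUS studies: simulate -> WHAM -> standard-state correction.

Thin compositions of the library stages, shared by the command-line surface
and by reproduction scripts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

from .binding import (
    BindingFreeEnergyResult,
    detect_cutoff,
    select_lower_bound,
    standard_correction,
)
from .driver import PreparedRun, WalkerRun, prepare_run, run_ensemble
from .io import RunConfig
from .pmf import PMFProfile
from .wham import bin_windows, wham_solve


@dataclass
class StudyResult:
    """Everything a CPUS study produces, in memory."""

    config: RunConfig
    prepared: PreparedRun
    runs: List[WalkerRun]
    profiles: List[PMFProfile] = field(default_factory=list)
    results: List[BindingFreeEnergyResult] = field(default_factory=list)
    selected_index: int = -1

    @property
    def selected(self) -> BindingFreeEnergyResult:
        return self.results[self.selected_index]


def simulate(cfg: RunConfig) -> StudyResult:
    """Unbiased pre-run, reference-distance estimate, and the full ensemble."""
    params = cfg.integrator_params()
    prepared = prepare_run(
        cfg.landscape,
        params,
        n_forward=cfg.n_forward,
        n_backward=cfg.n_backward,
        delta=cfg.delta,
        n_beads=cfg.n_beads,
        pre_samples=cfg.pre_samples,
        stride=cfg.stride,
        d_ref=cfg.d_ref,
    )
    runs = run_ensemble(
        cfg.landscape,
        prepared.schedule,
        params,
        n_walkers=cfg.n_walkers,
        spring_k=cfg.spring_k,
        n_steps=cfg.n_steps,
        stride=cfg.stride,
        path_stride=cfg.path_stride,
        start_state=prepared.start_state,
        n_beads=cfg.n_beads,
    )
    return StudyResult(config=cfg, prepared=prepared, runs=runs)


def walker_profile(run: WalkerRun, cfg: RunConfig) -> PMFProfile:
    """WHAM profile of a single walker, with d_final at the last forward
    window target."""
    binned = bin_windows(run, bin_width=cfg.wham_bin_width)
    profile = wham_solve(binned, temperature=cfg.temperature)
    profile.d_final = float(run.schedule.forward_targets[-1] - run.d_ref)
    return profile


def pooled_profile(runs: List[WalkerRun], cfg: RunConfig) -> PMFProfile:
    """One WHAM solve over the windows of all walkers pooled -- the best use
    of the ensemble when the landscape is isotropic (all walkers sample the
    same radial statistics)."""
    binned = bin_windows(runs, bin_width=cfg.wham_bin_width, d_ref=runs[0].d_ref)
    profile = wham_solve(binned, temperature=cfg.temperature)
    profile.d_final = float(runs[0].schedule.forward_targets[-1] - runs[0].d_ref)
    return profile


def correct_walker(
    run: WalkerRun, profile: PMFProfile, cfg: RunConfig
) -> BindingFreeEnergyResult:
    """Cutoff detection on the walker's mean vdW series, then the
    standard-state correction of its profile."""
    targets, means = run.mean_vdw_by_window()
    cutoff = detect_cutoff(
        means,
        targets,
        threshold=cfg.cutoff_threshold,
        persistence=cfg.cutoff_persistence,
        d_ref=run.d_ref,
    )
    return standard_correction(
        profile,
        cutoff,
        temperature=cfg.temperature,
        standard_volume=cfg.standard_volume,
        walker_id=run.walker_id,
    )


def run_full_study(cfg: RunConfig) -> StudyResult:
    """simulate + per-walker WHAM + correction + lower-bound selection."""
    study = simulate(cfg)
    for run in study.runs:
        profile = walker_profile(run, cfg)
        study.profiles.append(profile)
        study.results.append(correct_walker(run, profile, cfg))
    study.selected_index, _ = select_lower_bound(study.results)
    return study
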