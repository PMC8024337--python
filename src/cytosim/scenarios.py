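"""Condition presets, run drivers, calibration, and file output.

Presets mirror the five simulated experimental conditions: control,
ligand over-expression (initial tip load ×10), longer cytonemes with five
contact events (PCP activation in the source cells), the combination of the
two, and a partial rescue with half the mean cytoneme number.
"""
from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis
from .cytonemes import cytoneme_step, decay_receivers
from .errors import CalibrationError, ParameterError
from .mechanics import mechanics_step
from .params import Params, write_config
from .population import apoptosis_step, division_step
from .tissue_init import (RECEIVER, SOURCE, TissueState, init_cytonemes,
                          seed_tissue)

__all__ = [
    "PRESET_NAMES", "preset", "SimResult", "EnsembleResult",
    "run_simulation", "run_ensemble", "pooled_length_mean",
    "max_deposits_per_cytoneme", "calibrate", "calibrate_control",
    "calibrate_vangl2", "write_outputs",
]

# Frozen calibration output (see calibrate): growth/turnover values for which
# the 10-run pooled end-state length fit hits the target normalised means
# (2.0 control, 3.8 long-cytoneme condition).
CONTROL_MU_G = 2.2
CONTROL_R_RETRACT = 2.4
VANGL2_LENGTH_SCALE = 1.65     # applied to mu_g and L_max
VANGL2_RETRACT_SCALE = 1.0     # applied to r_retract
WNT_OE_FACTOR = 10.0           # ligand over-expression: initial tip load x10
VANGL2_INVIVO_LENGTH_FACTOR = 1.33  # measured in-vivo length increase (+33%)
RESCUE_CYT_FACTOR = 0.5        # mean cytoneme count reduction for the rescue

PRESET_NAMES = (
    "control", "wnt8a_oe", "vangl2_longer", "vangl2_invivo33",
    "wnt8a_vangl2", "rescue_fewer",
)


def preset(name: str) -> Params:
    """Parameter registry for a named simulated condition."""
    control = Params(mu_g=CONTROL_MU_G, r_retract=CONTROL_R_RETRACT)
    if name == "control":
        return control.validate()
    if name == "wnt8a_oe":
        return control.replace(W0=control.W0 * WNT_OE_FACTOR)
    if name == "vangl2_longer":
        return control.replace(
            mu_g=control.mu_g * VANGL2_LENGTH_SCALE,
            L_max=control.L_max * VANGL2_LENGTH_SCALE,
            r_retract=control.r_retract * VANGL2_RETRACT_SCALE,
            f_dep=0.2,
        )
    if name == "vangl2_invivo33":
        return control.replace(mu_g=control.mu_g * VANGL2_INVIVO_LENGTH_FACTOR)
    if name == "wnt8a_vangl2":
        return preset("vangl2_longer").replace(W0=control.W0 * WNT_OE_FACTOR)
    if name == "rescue_fewer":
        return preset("wnt8a_vangl2").replace(
            lambda_cyt=control.lambda_cyt * RESCUE_CYT_FACTOR
        )
    raise ParameterError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


@dataclass
class SimResult:
    """Everything recorded from one realisation."""

    params: Params
    seed: int
    state: TissueState
    snapshots: list = field(default_factory=list)   # (time, cells-dataframe)
    coverage: list = field(default_factory=list)    # (time, coverage, thickness)

    @property
    def deposit_log(self):
        return self.state.deposit_log

    def final_lengths(self) -> np.ndarray:
        """End-state cytoneme lengths, zero-length (just replaced) excluded."""
        return np.array([c.length for c in self.state.cytonemes if c.length > 0])


@dataclass
class EnsembleResult:
    params: Params
    base_seed: int
    runs: list                      # list of SimResult
    profiles: list                  # per-run proportion arrays
    profile: analysis.BinnedFateProfile
    pooled_lengths: np.ndarray
    lognormal_mean: float | None
    hindbrain_counts: np.ndarray

    @property
    def mhb_bin(self):
        return self.profile.mhb_bin

    def incongruous_counts(self, mhb_bin: int | None = None) -> np.ndarray:
        """Per-run counts of receivers whose fate disagrees with their side of
        the (by default, ensemble) boundary."""
        m = self.profile.mhb_bin if mhb_bin is None else mhb_bin
        if m is None:
            raise ParameterError("boundary undefined; cannot score congruence")
        out = []
        for r in self.runs:
            margin = analysis.margin_edge_angle(r.state.cells, r.state.yolk)
            out.append(analysis.count_incongruous_fates(
                r.state.cells, r.state.yolk, margin, m, self.params.n_bins))
        return np.array(out)


def _snapshot_frame(state: TissueState) -> pd.DataFrame:
    cells = state.alive_cells()
    return pd.DataFrame({
        "cell_id": [c.id for c in cells],
        "x": [c.position[0] for c in cells],
        "y": [c.position[1] for c in cells],
        "role": [c.role for c in cells],
        "wnt": [c.wnt for c in cells],
        "fate": [c.fate for c in cells],
    })


def run_simulation(params: Params, seed: int, on_step=None) -> SimResult:
    """One full realisation.

    Per step, in order: mechanics, division, apoptosis, receiver decay,
    cytoneme transport.  Conservation and ledger invariants are asserted
    every ``validate_every`` steps.  ``on_step(state, step)``, if given, is
    called after every completed step.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    state = seed_tissue(params, rng)
    init_cytonemes(state, params, rng)
    result = SimResult(params=params, seed=seed, state=state)

    snap_due = sorted(params.snapshot_times)
    cov_period = max(1, round(params.coverage_interval / params.dt))
    n_steps = round(params.t_end / params.dt)

    def maybe_record(step: int):
        t = state.time
        while snap_due and snap_due[0] <= t + 1e-12:
            result.snapshots.append((snap_due.pop(0), _snapshot_frame(state)))
        if step % cov_period == 0 and state.alive_cells():
            cov, thick = analysis.coverage_and_thickness(state.cells, state.yolk)
            result.coverage.append((t, cov, thick))

    maybe_record(0)
    for step in range(1, n_steps + 1):
        mechanics_step(state, params, rng)
        division_step(state, params, rng)
        apoptosis_step(state, params, rng)
        decay_receivers(state, params)
        cytoneme_step(state, params, rng)
        state.time = step * params.dt
        if params.validate_every and step % params.validate_every == 0:
            state.validate()
        if on_step is not None:
            on_step(state, step)
        maybe_record(step)
    return result


def _run_profile(result: SimResult) -> np.ndarray:
    """Assign fates and bin one run's hindbrain proportions."""
    p = result.params
    analysis.assign_fates(result.state.cells, p.threshold)
    margin = analysis.margin_edge_angle(result.state.cells, result.state.yolk)
    return analysis.bin_fate_proportions(
        result.state.cells, p.n_bins, result.state.yolk, margin
    )


def run_ensemble(params: Params, n_sims: int, base_seed: int) -> EnsembleResult:
    """Run ``n_sims`` realisations with seeds ``base_seed .. base_seed+n-1``
    and aggregate fate profiles, boundary position, and pooled end-state
    cytoneme lengths."""
    if n_sims < 1:
        raise ParameterError(f"n_sims must be >= 1, got {n_sims}")
    runs = [run_simulation(params, base_seed + i) for i in range(n_sims)]
    profiles = [_run_profile(r) for r in runs]
    profile = analysis.ensemble_profile(profiles)
    pooled = (np.concatenate([r.final_lengths() for r in runs])
              if runs else np.array([]))
    ln_mean = (analysis.lognormal_mean(pooled, params.cell_diameter)
               if pooled.size else None)
    hb = np.array([
        sum(1 for c in r.state.cells
            if c.alive and c.role == RECEIVER and c.fate == "hindbrain")
        for r in runs
    ])
    return EnsembleResult(
        params=params, base_seed=base_seed, runs=runs, profiles=profiles,
        profile=profile, pooled_lengths=pooled, lognormal_mean=ln_mean,
        hindbrain_counts=hb,
    )


def pooled_length_mean(params: Params, n_sims: int, base_seed: int) -> float:
    """Fitted log-normal mean of pooled end-state lengths (cell diameters)."""
    return run_ensemble(params, n_sims, base_seed).lognormal_mean


def max_deposits_per_cytoneme(deposit_log) -> int:
    """Largest number of deposit events attributed to any single cytoneme."""
    if not deposit_log:
        return 0
    return max(Counter(e.cytoneme_id for e in deposit_log).values())


# --------------------------------------------------------------------------
# calibration

def _grid_search(base: Params, target: float, axes: dict, n_runs: int,
                 base_seed: int, rtol: float) -> Params:
    """Coarse-to-fine search over multiplicative scales of the given fields.

    ``axes`` maps field tuples to coarse scale grids; each candidate is scored
    by |fitted pooled-length mean - target| on a fixed-seed ensemble.
    """
    names = list(axes)
    current = {k: 1.0 for k in names}

    def evaluate(scales: dict) -> float:
        changes = {}
        for key, s in scales.items():
            for f in (key if isinstance(key, tuple) else (key,)):
                changes[f] = getattr(base, f) * s
        return pooled_length_mean(base.replace(**changes), n_runs, base_seed)

    best = None
    for stage, widen in enumerate((1.0, 0.25)):
        grids = {
            k: (axes[k] if stage == 0
                else [current[k] * (1 + widen * d) for d in (-0.5, -0.25, 0, 0.25, 0.5)])
            for k in names
        }
        import itertools
        for combo in itertools.product(*grids.values()):
            scales = dict(zip(names, combo))
            err = abs(evaluate(scales) - target)
            if best is None or err < best[0]:
                best = (err, dict(scales))
        current = best[1]
    err, scales = best
    if err > rtol * target:
        raise CalibrationError(
            f"target {target} unreachable on grid; best candidate {scales} "
            f"misses by {err:.3g}"
        )
    changes = {}
    for key, s in scales.items():
        for f in (key if isinstance(key, tuple) else (key,)):
            changes[f] = getattr(base, f) * s
    return base.replace(**changes)


def calibrate_control(base: Params, target: float = 2.0, n_runs: int = 10,
                      base_seed: int = 1000, rtol: float = 0.10) -> Params:
    """Tune (mu_g, r_retract) so the control pooled-length fitted mean hits
    the target (in cell diameters)."""
    if abs(pooled_length_mean(base, n_runs, base_seed) - target) <= rtol * target:
        return base
    axes = {
        ("mu_g",): [0.6, 0.8, 1.0, 1.25, 1.5],
        ("r_retract",): [0.7, 1.0, 1.4],
    }
    return _grid_search(base, target, axes, n_runs, base_seed, rtol)


def calibrate_vangl2(control: Params, target: float = 3.8, n_runs: int = 10,
                     base_seed: int = 1000, rtol: float = 0.10) -> Params:
    """Tune length/turnover scales (relative to the calibrated control) for
    the long-cytoneme condition; f_dep is fixed at 0.2 (five contacts)."""
    base = control.replace(f_dep=0.2)
    if abs(pooled_length_mean(base, n_runs, base_seed) - target) <= rtol * target:
        return base
    axes = {
        ("mu_g", "L_max"): [1.4, 1.7, 1.9, 2.1, 2.4],
        ("r_retract",): [0.8, 1.0],
    }
    return _grid_search(base, target, axes, n_runs, base_seed, rtol)


def calibrate(base: Params, targets: dict | None = None, n_runs: int = 10,
              base_seed: int = 1000) -> dict:
    """Calibrate the control and long-cytoneme presets; returns a dict of
    named Params.  Targets default to the normalised length means 2.0/3.8."""
    targets = targets or {"control": 2.0, "vangl2_longer": 3.8}
    out = {}
    control = calibrate_control(base, targets.get("control", 2.0),
                                n_runs, base_seed)
    out["control"] = control
    if "vangl2_longer" in targets:
        out["vangl2_longer"] = calibrate_vangl2(
            control, targets["vangl2_longer"], n_runs, base_seed
        )
    return out


# --------------------------------------------------------------------------
# output

def write_outputs(result: EnsembleResult, out_dir) -> None:
    """Write cells.csv, cytonemes.csv, deposits.csv, profile.csv,
    summary.json, and a config echo for an ensemble result."""
    if not result.runs:
        raise ParameterError("cannot write outputs for an empty ensemble")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    last = result.runs[-1]

    state = last.state
    yolk = state.yolk
    margin = analysis.margin_edge_angle(state.cells, yolk)
    cells = state.alive_cells()
    pd.DataFrame({
        "cell_id": [c.id for c in cells],
        "x": [c.position[0] for c in cells],
        "y": [c.position[1] for c in cells],
        "role": [c.role for c in cells],
        "angle": [analysis.angular_coordinate(c.position, yolk, margin)
                  for c in cells],
        "wnt": [c.wnt for c in cells],
        "fate": [c.fate for c in cells],
    }).to_csv(out / "cells.csv", index=False)

    pd.DataFrame({
        "cytoneme_id": [c.id for c in state.cytonemes],
        "source_id": [c.source_id for c in state.cytonemes],
        "theta": [c.theta for c in state.cytonemes],
        "length": [c.length for c in state.cytonemes],
        "tip_wnt": [c.tip_wnt for c in state.cytonemes],
        "n_deposits": [c.n_deposits for c in state.cytonemes],
    }).to_csv(out / "cytonemes.csv", index=False)

    pd.DataFrame(
        [(e.time, e.cytoneme_id, e.receiver_id, e.amount)
         for e in last.deposit_log],
        columns=["time", "cytoneme_id", "receiver_id", "amount"],
    ).to_csv(out / "deposits.csv", index=False)

    prof = result.profile
    pd.DataFrame({
        "bin_index": np.arange(prof.n_bins),
        "mean": prof.mean,
        "sd": prof.sd,
        "n_occupied": prof.n_runs,
    }).to_csv(out / "profile.csv", index=False)

    cov, thick = analysis.coverage_and_thickness(state.cells, yolk)
    summary = {
        "n_sims": len(result.runs),
        "base_seed": result.base_seed,
        "mhb_bin": result.mhb_bin,
        "coverage": cov,
        "thickness": thick,
        "lognormal_mean": result.lognormal_mean,
        "n_pooled_lengths": int(result.pooled_lengths.size),
        "mean_hindbrain_cells": float(result.hindbrain_counts.mean()),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    write_config(result.params, out / "config.yaml")
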