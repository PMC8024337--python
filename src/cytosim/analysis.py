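"""End-state analysis: fate calling, angular fate profiles, boundary
estimation, length-distribution fitting, coverage metrics.

The angular origin is the leading edge of the source margin (the most vegetal
source cell at the final state), with the coordinate increasing toward the
animal pole, so bin 0 abuts the margin and higher bins are more anterior.
The boundary (MHB) is the first bin whose ensemble-mean hindbrain proportion
falls below one half.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .tissue_init import (FATE_HINDBRAIN, FATE_OTHER, FATE_UNSET, RECEIVER,
                          SOURCE, Yolk)

__all__ = [
    "BinnedFateProfile", "assign_fates", "angular_coordinate",
    "margin_edge_angle", "bin_fate_proportions", "ensemble_profile",
    "estimate_mhb", "count_incongruous_fates", "fit_lognormal",
    "lognormal_mean",
    "coverage_and_thickness", "display_normalize_wnt",
]

TWO_PI = 2.0 * math.pi


@dataclass
class BinnedFateProfile:
    """Per-bin hindbrain proportions aggregated over an ensemble.

    ``mean``/``sd`` are NaN for bins never occupied by a receiver; ``n_runs``
    counts the runs in which each bin was occupied.
    """

    n_bins: int
    mean: np.ndarray
    sd: np.ndarray
    n_runs: np.ndarray
    mhb_bin: int | None = None

    @property
    def bin_width(self) -> float:
        return TWO_PI / self.n_bins


def assign_fates(cells, threshold: float):
    """Mark alive receivers hindbrain iff ``wnt > threshold`` (strict);
    everything else 'other'.  Sources keep the unset fate."""
    for cell in cells:
        if not cell.alive or cell.role == SOURCE:
            continue
        cell.fate = FATE_HINDBRAIN if cell.wnt > threshold else FATE_OTHER
    return cells


def angular_coordinate(position, yolk: Yolk, margin_edge_angle: float) -> float:
    """Angle in [0, 2π) of a point about the yolk centre, measured from the
    margin leading-edge direction and increasing toward the animal pole
    (counter-clockwise)."""
    rel = np.asarray(position, dtype=float) - yolk.centre
    if rel[0] == 0 and rel[1] == 0:
        raise ParameterError("point at the yolk centre has no angular coordinate")
    return (math.atan2(rel[1], rel[0]) - margin_edge_angle) % TWO_PI


def margin_edge_angle(cells, yolk: Yolk) -> float:
    """Standard angle of the most vegetal alive source cell (the leading edge
    of the margin): the source with the largest clockwise angle from the
    animal pole (+y)."""
    sources = [c for c in cells if c.alive and c.role == SOURCE]
    if not sources:
        raise ParameterError("no alive source cells; margin undefined")
    # clockwise angle from +y, in [0, 2π): vegetal-most source maximises it
    best = max(
        sources,
        key=lambda c: (math.pi / 2.0 - yolk.polar_angle(c.position)) % TWO_PI,
    )
    return yolk.polar_angle(best.position)


def bin_fate_proportions(cells, n_bins: int, yolk: Yolk,
                         margin_angle: float) -> np.ndarray:
    """Hindbrain proportion per equi-spaced angular bin (NaN for empty bins),
    over alive receivers with assigned fates."""
    counts = np.zeros(n_bins, dtype=int)
    hind = np.zeros(n_bins, dtype=int)
    width = TWO_PI / n_bins
    for cell in cells:
        if not cell.alive or cell.role != RECEIVER or cell.fate == FATE_UNSET:
            continue
        k = int(angular_coordinate(cell.position, yolk, margin_angle) // width)
        k = min(k, n_bins - 1)  # guards the angle == 2π float edge case
        counts[k] += 1
        if cell.fate == FATE_HINDBRAIN:
            hind[k] += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, hind / np.where(counts == 0, 1, counts), np.nan)


def ensemble_profile(profiles) -> BinnedFateProfile:
    """Per-bin mean and population s.d. over the runs in which each bin is
    occupied (NaN bins of individual runs are excluded, not zero-filled)."""
    profiles = [np.asarray(p, dtype=float) for p in profiles]
    if not profiles:
        raise ParameterError("ensemble_profile needs at least one profile")
    n_bins = len(profiles[0])
    if any(len(p) != n_bins for p in profiles):
        raise ParameterError("profiles have mismatched bin counts")
    stack = np.vstack(profiles)
    n_runs = np.sum(~np.isnan(stack), axis=0)
    mean = np.full(n_bins, np.nan)
    sd = np.full(n_bins, np.nan)
    occ = n_runs > 0
    if occ.any():
        mean[occ] = np.nanmean(stack[:, occ], axis=0)
        sd[occ] = np.nanstd(stack[:, occ], axis=0)
    prof = BinnedFateProfile(n_bins=n_bins, mean=mean, sd=sd, n_runs=n_runs)
    prof.mhb_bin = estimate_mhb(prof)
    return prof


def estimate_mhb(profile) -> int | None:
    """First bin (scanning anteriorly from the margin, skipping empty bins)
    whose mean hindbrain proportion is strictly below one half."""
    mean = profile.mean if isinstance(profile, BinnedFateProfile) else np.asarray(profile)
    for k, v in enumerate(mean):
        if np.isnan(v):
            continue
        if v < 0.5:
            return k
    return None


def count_incongruous_fates(cells, yolk: Yolk, margin_angle: float,
                            mhb_bin: int, n_bins: int) -> int:
    """Number of alive receivers whose fate disagrees with their side of the
    boundary: hindbrain anterior of the MHB bin, or non-hindbrain posterior of
    it.  A high count means an indistinct boundary."""
    width = TWO_PI / n_bins
    bad = 0
    for c in cells:
        if not c.alive or c.role != RECEIVER or c.fate == FATE_UNSET:
            continue
        k = int(angular_coordinate(c.position, yolk, margin_angle) // width)
        k = min(k, n_bins - 1)
        hind = c.fate == FATE_HINDBRAIN
        if (k < mhb_bin and not hind) or (k >= mhb_bin and hind):
            bad += 1
    return bad


def fit_lognormal(xs) -> tuple:
    """MLE of a log-normal on positive samples: mean and population variance
    of the logs.  Returns (mu, sigma)."""
    xs = np.asarray(xs, dtype=float)
    if xs.size == 0:
        raise ParameterError("cannot fit a log-normal to an empty sample")
    if np.any(xs <= 0):
        raise ParameterError("log-normal fit requires strictly positive samples")
    logs = np.log(xs)
    return float(np.mean(logs)), float(np.std(logs))


def lognormal_mean(lengths, cell_diameter: float) -> float:
    """Arithmetic mean ``exp(mu + sigma²/2)`` of the MLE log-normal fitted to
    lengths normalised by the cell diameter."""
    if cell_diameter <= 0:
        raise ParameterError(f"cell_diameter must be > 0, got {cell_diameter}")
    mu, sigma = fit_lognormal(np.asarray(lengths, dtype=float) / cell_diameter)
    return math.exp(mu + sigma ** 2 / 2.0)


def coverage_and_thickness(cells, yolk: Yolk) -> tuple:
    """(fraction of angular columns occupied, mean cells per occupied column).

    The circle is split into equal columns of angular width ``≈ 2 r_c / R_y``
    so one column spans roughly one cell diameter of arc.
    """
    alive = [c for c in cells if c.alive]
    if not alive:
        raise ParameterError("coverage undefined for an empty tissue")
    r_c = max(c.radius for c in alive)
    n_cols = max(1, int(math.ceil(TWO_PI / (2.0 * r_c / yolk.radius))))
    width = TWO_PI / n_cols
    counts = np.zeros(n_cols, dtype=int)
    for cell in alive:
        k = int((yolk.polar_angle(cell.position) % TWO_PI) // width)
        counts[min(k, n_cols - 1)] += 1
    occupied = counts > 0
    coverage = occupied.sum() / n_cols
    thickness = float(counts[occupied].mean())
    return coverage, thickness


def display_normalize_wnt(levels) -> np.ndarray:
    """Plotting transform: normalise by the global maximum and log-compress to
    [0, 1] via ``ln(1 + x (e - 1))``; strictly monotone in the level."""
    levels = np.asarray(levels, dtype=float)
    m = levels.max() if levels.size else 0.0
    if m <= 0:
        return np.zeros_like(levels)
    return np.log1p((levels / m) * (math.e - 1.0))
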