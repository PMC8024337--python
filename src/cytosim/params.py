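"""Parameter registry and config file round-tripping.

All model quantities live in a single flat :class:`Params` dataclass so that a
run is fully described by one YAML/JSON document plus a seed.  Units: lengths
in micrometres, times in hours, rates per hour, ligand amounts in arbitrary
units (AU).
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError

__all__ = ["Params", "read_config", "write_config"]


@dataclass
class Params:
    # --- geometry / initial condition ---
    R_y: float = 300.0          # yolk radius (µm)
    r_c: float = 10.0           # cell radius (µm); cell diameter = 2*r_c
    n_init: int = 230           # total initial cells (sources + receivers)
    n_source: int = 30          # marginal ligand-producing cells
    alpha0: float = 0.6         # half-width of the initial polar arc (rad)
    radial_jitter: float = 2.0  # radial placement noise (µm)

    # --- mechanics ---
    k_spring: float = 30.0      # linear spring constant between Delaunay neighbours
    k_out: float = 30.0         # outward yolk-surface restoring force
    k_in: float = 30.0          # inward intercalation force beyond the band
    band: float = 20.0          # free annulus thickness above the yolk surface (µm)
    eta: float = 1.0            # drag coefficient (overdamped dynamics)
    dt: float = 1.0 / 60.0      # time step (h)
    detach_factor: float = 1.5  # springs detach beyond detach_factor*(r_i+r_j)
    neighbor_cutoff: float = 60.0  # fallback pair cutoff for degenerate triangulations (µm)
    max_disp: float = 5.0       # per-step displacement cap (µm); keeps the crowded
                                # initial state from overshooting

    # --- population dynamics ---
    T_div_min: float = 2.0      # division clock, uniform lower bound (h)
    T_div_max: float = 4.0      # division clock, uniform upper bound (h)
    p_apop: float = 0.005       # apoptosis rate (per hour, receivers only)

    # --- cytoneme dynamics / ligand transport ---
    lambda_cyt: float = 5.7     # Poisson mean cytonemes per source cell
    mu_g: float = 2.2           # mean growth increment per step (µm)
    sigma_g: float = 1.0        # growth increment s.d. (µm)
    sigma_theta: float = 0.3    # angular spread around the oriented tangent (rad)
    r_retract: float = 2.4      # stochastic retraction rate (per hour)
    L_max: float = 120.0        # hard maximum cytoneme length (µm)
    k_dep: float = 2.0          # deposition rate while in contact (per hour)
    lambda_decay: float = 0.5   # receiver ligand decay rate (per hour)
    f_dep: float = 1.0          # fraction of the initial tip load per deposit
    W0: float = 400.0           # initial tip load (AU)
    tip_eps: float = 1e-9       # tip considered empty below this (AU)

    # --- analysis ---
    threshold: float = 100.0    # fate threshold (AU)
    n_bins: int = 100           # angular fate bins around the yolk

    # --- run control ---
    t_end: float = 10.0         # simulated duration (h)
    n_sims: int = 100           # default ensemble size
    seed: int = 0               # master seed
    snapshot_times: tuple = (0.0, 1.3, 4.5, 10.0)
    coverage_interval: float = 0.1  # coverage/thickness sampling period (h)
    validate_every: int = 1     # invariant check period in steps (0 disables)

    def validate(self) -> "Params":
        """Raise :class:`ParameterError` on any contract violation; return self."""
        if self.R_y <= 0:
            raise ParameterError(f"R_y must be > 0, got {self.R_y}")
        if self.r_c <= 0:
            raise ParameterError(f"r_c must be > 0, got {self.r_c}")
        if self.n_init < 0:
            raise ParameterError(f"n_init must be >= 0, got {self.n_init}")
        if not 0 <= self.n_source <= self.n_init:
            raise ParameterError(
                f"n_source must lie in [0, n_init]; got {self.n_source} of {self.n_init}"
            )
        if self.dt <= 0:
            raise ParameterError(f"dt must be > 0, got {self.dt}")
        if self.eta <= 0:
            raise ParameterError(f"eta must be > 0, got {self.eta}")
        if not 0 < self.f_dep <= 1:
            raise ParameterError(f"f_dep must lie in (0, 1], got {self.f_dep}")
        if self.t_end < 0:
            raise ParameterError(f"t_end must be >= 0, got {self.t_end}")
        if self.T_div_max < self.T_div_min or self.T_div_min < 0:
            raise ParameterError(
                f"division window invalid: [{self.T_div_min}, {self.T_div_max}]"
            )
        if self.n_bins < 1:
            raise ParameterError(f"n_bins must be >= 1, got {self.n_bins}")
        for name in (
            "k_spring", "k_out", "k_in", "band", "alpha0", "radial_jitter",
            "p_apop", "lambda_cyt", "mu_g", "sigma_g", "sigma_theta",
            "r_retract", "L_max", "k_dep", "lambda_decay", "W0", "tip_eps",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0, got {getattr(self, name)}")
        return self

    # -- convenience -------------------------------------------------------
    @property
    def cell_diameter(self) -> float:
        return 2.0 * self.r_c

    def replace(self, **changes) -> "Params":
        """Return a validated copy with fields overridden."""
        return dataclasses.replace(self, **changes).validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["snapshot_times"] = list(self.snapshot_times)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Params":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown config field(s): {sorted(unknown)}")
        d = dict(d)
        if "snapshot_times" in d:
            d["snapshot_times"] = tuple(d["snapshot_times"])
        return cls(**d).validate()


def read_config(path) -> Params:
    """Load a Params registry from a YAML or JSON file."""
    text = Path(path).read_text()
    try:
        if str(path).endswith(".json"):
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ParameterError(f"could not parse config {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ParameterError(f"config {path} must hold a mapping of fields")
    return Params.from_dict(data)


def write_config(params: Params, path) -> None:
    """Write a Params registry; read_config round-trips it exactly."""
    path = Path(path)
    if str(path).endswith(".json"):
        path.write_text(json.dumps(params.to_dict(), indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(params.to_dict(), sort_keys=True))
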