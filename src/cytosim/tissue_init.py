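"""Synthetic initial-condition generator: yolk, polar cell cluster, source margin.

Geometry convention: the yolk is a circle; the animal pole is the +y direction
from its centre.  The tissue models one lateral half of the embryo, so cells
start inside a narrow arc centred on the pole and the source margin sits at
the arc end with the larger clockwise angle from +y (the +x side).  Standard
mathematical angles (counter-clockwise from +x) are used internally; the
clockwise-from-pole angle is only a placement device.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import IntegrityError, ParameterError
from .params import Params

__all__ = [
    "Yolk", "Cell", "Cytoneme", "WntLedger", "TissueState",
    "SOURCE", "RECEIVER", "FATE_UNSET", "FATE_HINDBRAIN", "FATE_OTHER",
    "make_yolk", "seed_tissue", "init_cytonemes",
]

SOURCE = "source"
RECEIVER = "receiver"
FATE_UNSET = "unset"
FATE_HINDBRAIN = "hindbrain"
FATE_OTHER = "other"


@dataclass
class Yolk:
    """Circular substrate over which the tissue spreads."""

    centre: np.ndarray
    radius: float

    def __post_init__(self):
        self.centre = np.asarray(self.centre, dtype=float)
        if self.radius <= 0:
            raise ParameterError(f"yolk radius must be > 0, got {self.radius}")

    def polar_angle(self, position) -> float:
        """Standard angle (rad, CCW from +x) of a point about the centre."""
        d = np.asarray(position, dtype=float) - self.centre
        return math.atan2(d[1], d[0])


@dataclass(slots=True)
class Cell:
    id: int
    position: np.ndarray
    radius: float
    role: str
    wnt: float = 0.0
    fate: str = FATE_UNSET
    next_division_time: float | None = None
    alive: bool = True


@dataclass(slots=True)
class Cytoneme:
    """A straight, source-anchored filopodium with a ligand-loaded tip."""

    id: int
    source_id: int
    theta: float        # global growth direction, fixed for the lifetime
    length: float
    tip_wnt: float
    w0: float           # initial tip load; deposits are fractions of this
    n_deposits: int = 0


@dataclass
class WntLedger:
    """Global ligand book-keeping; makes conservation testable.

    Identity: loaded_total == in_tips + in_receivers + decayed + lost_to_death.
    """

    loaded_total: float = 0.0
    in_tips: float = 0.0
    in_receivers: float = 0.0
    decayed: float = 0.0
    lost_to_death: float = 0.0

    def check_identity(self, rtol: float = 1e-9) -> None:
        parts = self.in_tips + self.in_receivers + self.decayed + self.lost_to_death
        scale = max(abs(self.loaded_total), 1.0)
        if abs(parts - self.loaded_total) > rtol * scale:
            raise IntegrityError(
                f"ledger identity violated: loaded_total={self.loaded_total!r} "
                f"vs parts sum {parts!r}"
            )


@dataclass
class TissueState:
    time: float
    yolk: Yolk
    cells: list = field(default_factory=list)
    cytonemes: list = field(default_factory=list)
    ledger: WntLedger = field(default_factory=WntLedger)
    deposit_log: list = field(default_factory=list)
    n_cytonemes_target: int = 0
    _next_cell_id: int = 0
    _next_cyt_id: int = 0
    _cell_index: dict = field(default_factory=dict)

    # -- id management -----------------------------------------------------
    def new_cell(self, **kw) -> Cell:
        cell = Cell(id=self._next_cell_id, **kw)
        self._next_cell_id += 1
        self.cells.append(cell)
        self._cell_index[cell.id] = cell
        return cell

    def new_cytoneme(self, **kw) -> Cytoneme:
        cyt = Cytoneme(id=self._next_cyt_id, **kw)
        self._next_cyt_id += 1
        return cyt

    def cell_by_id(self, cid: int) -> Cell:
        try:
            return self._cell_index[cid]
        except KeyError:
            raise IntegrityError(f"dangling cell id {cid}") from None

    # -- views -------------------------------------------------------------
    def alive_cells(self) -> list:
        return [c for c in self.cells if c.alive]

    def alive_receivers(self) -> list:
        return [c for c in self.cells if c.alive and c.role == RECEIVER]

    def alive_sources(self) -> list:
        return [c for c in self.cells if c.alive and c.role == SOURCE]

    # -- invariants --------------------------------------------------------
    def validate(self, rtol: float = 1e-9) -> None:
        """Assert conservation and ledger identity; raise IntegrityError."""
        if len(self.cytonemes) != self.n_cytonemes_target:
            raise IntegrityError(
                f"cytoneme count {len(self.cytonemes)} != conserved target "
                f"{self.n_cytonemes_target}"
            )
        for cyt in self.cytonemes:
            src = self.cell_by_id(cyt.source_id)
            if not (src.alive and src.role == SOURCE):
                raise IntegrityError(
                    f"cytoneme {cyt.id} anchored to invalid cell {cyt.source_id}"
                )
        in_tips = math.fsum(c.tip_wnt for c in self.cytonemes)
        in_recv = math.fsum(c.wnt for c in self.cells if c.alive and c.role == RECEIVER)
        scale = max(abs(self.ledger.loaded_total), 1.0)
        if abs(in_tips - self.ledger.in_tips) > rtol * scale:
            raise IntegrityError(
                f"tip ledger drift: state {in_tips} vs ledger {self.ledger.in_tips}"
            )
        if abs(in_recv - self.ledger.in_receivers) > rtol * scale:
            raise IntegrityError(
                f"receiver ledger drift: state {in_recv} vs ledger "
                f"{self.ledger.in_receivers}"
            )
        self.ledger.check_identity(rtol)


def make_yolk(radius: float, centre=(0.0, 0.0)) -> Yolk:
    """Build the circular yolk substrate."""
    if radius <= 0:
        raise ParameterError(f"yolk radius must be > 0, got {radius}")
    return Yolk(centre=np.asarray(centre, dtype=float), radius=float(radius))


def seed_tissue(params: Params, rng: np.random.Generator) -> TissueState:
    """Place the initial cell cluster at the animal pole.

    Cells sit at radial distance ``R_y + r_c`` (plus small jitter) inside an
    arc of half-width ``alpha0`` centred on the pole; the ``n_source`` cells
    nearest the designated leading edge (smallest standard angle, i.e. the +x
    arc end) become sources.  Receivers get division clocks drawn from
    ``t0 + U(T_div_min, T_div_max)``; sources never divide.
    """
    params.validate()
    yolk = make_yolk(params.R_y)
    state = TissueState(time=0.0, yolk=yolk)
    n = params.n_init
    if n == 0:
        return state

    phi_cw = rng.uniform(-params.alpha0, params.alpha0, size=n)  # clockwise from +y
    psi = np.pi / 2.0 - phi_cw                                   # standard angle
    radial = params.R_y + params.r_c + rng.uniform(
        -params.radial_jitter, params.radial_jitter, size=n
    )
    order = np.argsort(psi, kind="stable")  # leading edge (+x side) first
    n_recv = n - params.n_source
    div_clocks = rng.uniform(params.T_div_min, params.T_div_max, size=n_recv)

    recv_i = 0
    for rank, idx in enumerate(order):
        pos = yolk.centre + radial[idx] * np.array(
            [math.cos(psi[idx]), math.sin(psi[idx])]
        )
        if rank < params.n_source:
            state.new_cell(position=pos, radius=params.r_c, role=SOURCE)
        else:
            state.new_cell(
                position=pos,
                radius=params.r_c,
                role=RECEIVER,
                next_division_time=state.time + div_clocks[recv_i],
            )
            recv_i += 1
    return state


def init_cytonemes(state: TissueState, params: Params,
                   rng: np.random.Generator) -> TissueState:
    """Attach the initial cytoneme cohort to the source cells.

    Each source receives ``k ~ Poisson(lambda_cyt)`` zero-length cytonemes
    with full tip load ``W0``; the resulting total count is conserved for the
    rest of the run.
    """
    if params.lambda_cyt < 0:
        raise ParameterError(f"lambda_cyt must be >= 0, got {params.lambda_cyt}")
    from .cytonemes import sample_cytoneme_angle  # deferred: avoids import cycle

    for src in state.alive_sources():
        k = rng.poisson(params.lambda_cyt)
        for _ in range(int(k)):
            theta = sample_cytoneme_angle(src, state.yolk, params.sigma_theta, rng)
            cyt = state.new_cytoneme(
                source_id=src.id, theta=theta, length=0.0,
                tip_wnt=params.W0, w0=params.W0,
            )
            state.cytonemes.append(cyt)
            state.ledger.loaded_total += params.W0
            state.ledger.in_tips += params.W0
    state.n_cytonemes_target = len(state.cytonemes)
    return state
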