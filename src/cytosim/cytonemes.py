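"""Cytoneme life cycle and ligand transport.

Each step a cytoneme either fully retracts (stochastically, on exceeding the
maximum length, or on an empty tip) and is instantaneously replaced at the
same source — keeping the global count constant — or it grows by a positive
normal increment along its fixed direction.  A tip within a receiver's radius
may fire a deposition event, transferring a fixed fraction of the *initial*
tip load; receiver ligand decays exponentially between events.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import IntegrityError, ParameterError
from .params import Params
from .tissue_init import Cell, Cytoneme, RECEIVER, TissueState, Yolk

__all__ = [
    "DepositEvent", "sample_growth_increment", "sample_cytoneme_angle",
    "tip_position", "retraction_due", "replace_cytoneme", "detect_contact",
    "deposition_fires", "deposit", "decay_receivers", "cytoneme_step",
]


@dataclass(slots=True, frozen=True)
class DepositEvent:
    time: float
    cytoneme_id: int
    receiver_id: int
    amount: float


def sample_growth_increment(mu_g: float, sigma_g: float,
                            rng: np.random.Generator) -> float:
    """One positive growth increment: ``N(mu_g, sigma_g)`` with negative draws
    discarded and redrawn."""
    if mu_g < 0 or sigma_g < 0 or (mu_g == 0 and sigma_g == 0):
        raise ParameterError(
            f"invalid growth parameters mu_g={mu_g}, sigma_g={sigma_g}"
        )
    if sigma_g == 0:
        return mu_g
    while True:
        x = rng.normal(mu_g, sigma_g)
        if x > 0:
            return x


def sample_cytoneme_angle(source_cell: Cell, yolk: Yolk, sigma_theta: float,
                          rng: np.random.Generator) -> float:
    """Growth direction ~ Normal(tangent, sigma_theta), with the tangent at the
    source's angular position oriented counter-clockwise — toward the animal
    pole and the receptive tissue."""
    rel = source_cell.position - yolk.centre
    if math.hypot(rel[0], rel[1]) == 0:
        raise ParameterError("source cell at the yolk centre has no tangent")
    tangent = math.atan2(rel[1], rel[0]) + math.pi / 2.0
    if sigma_theta == 0:
        return tangent
    return rng.normal(tangent, sigma_theta)


def tip_position(cytoneme: Cytoneme, state: TissueState) -> np.ndarray:
    """Tip = source position + length * (cos theta, sin theta); the base rides
    rigidly on the source cell."""
    src = state.cell_by_id(cytoneme.source_id)
    if not src.alive:
        raise IntegrityError(f"cytoneme {cytoneme.id} anchored to dead cell {src.id}")
    return src.position + cytoneme.length * np.array(
        [math.cos(cytoneme.theta), math.sin(cytoneme.theta)]
    )


def retraction_due(cytoneme: Cytoneme, params: Params,
                   rng: np.random.Generator) -> bool:
    """Poisson retraction (prob ``1 - exp(-r_retract dt)`` per step), plus the
    deterministic triggers: over-length and empty tip."""
    u = rng.random()
    return (
        u < 1.0 - math.exp(-params.r_retract * params.dt)
        or cytoneme.length > params.L_max
        or cytoneme.tip_wnt <= params.tip_eps
    )


def replace_cytoneme(state: TissueState, cytoneme: Cytoneme, params: Params,
                     rng: np.random.Generator) -> Cytoneme:
    """Instantaneous replacement: a fresh zero-length cytoneme with a full tip
    load at the same source.  Residual undeposited tip ligand is withdrawn
    (booked as decayed); the fresh load is added to ``loaded_total``."""
    residual = cytoneme.tip_wnt
    state.ledger.in_tips -= residual
    state.ledger.decayed += residual
    src = state.cell_by_id(cytoneme.source_id)
    theta = sample_cytoneme_angle(src, state.yolk, params.sigma_theta, rng)
    new = state.new_cytoneme(
        source_id=cytoneme.source_id, theta=theta, length=0.0,
        tip_wnt=params.W0, w0=params.W0,
    )
    state.ledger.loaded_total += params.W0
    state.ledger.in_tips += params.W0
    return new


def detect_contact(tip, receivers) -> int | None:
    """Id of the nearest alive receiver whose centre lies strictly within its
    own radius of the tip; ties break to the smaller id; None if no contact."""
    tip = np.asarray(tip, dtype=float)
    best = None
    for cell in receivers:
        if not (cell.alive and cell.role == RECEIVER):
            continue
        d = math.hypot(*(tip - cell.position))
        if d < cell.radius and (best is None or (d, cell.id) < best):
            best = (d, cell.id)
    return None if best is None else best[1]


def deposition_fires(params: Params, rng: np.random.Generator) -> bool:
    """Poisson deposition trigger: fires with probability ``1 - exp(-k_dep dt)``."""
    return rng.random() < 1.0 - math.exp(-params.k_dep * params.dt)


def deposit(cytoneme: Cytoneme, receiver: Cell, params: Params,
            state: TissueState) -> DepositEvent:
    """Transfer ``min(f_dep * w0, tip_wnt)`` from tip to receiver.

    The amount is a fraction of the *initial* load, so a cytoneme makes at
    most ``ceil(1 / f_dep)`` deposits before its tip empties.
    """
    if cytoneme.tip_wnt <= 0:
        raise IntegrityError(
            f"deposit from empty tip (cytoneme {cytoneme.id}); retraction overdue"
        )
    amount = min(params.f_dep * cytoneme.w0, cytoneme.tip_wnt)
    cytoneme.tip_wnt -= amount
    cytoneme.n_deposits += 1
    receiver.wnt += amount
    state.ledger.in_tips -= amount
    state.ledger.in_receivers += amount
    event = DepositEvent(
        time=state.time, cytoneme_id=cytoneme.id,
        receiver_id=receiver.id, amount=amount,
    )
    state.deposit_log.append(event)
    return event


def decay_receivers(state: TissueState, params: Params) -> TissueState:
    """Exponential receiver decay with the exact per-step factor
    ``exp(-lambda_decay dt)`` (no Euler discretisation error)."""
    if params.lambda_decay == 0:
        return state
    factor = math.exp(-params.lambda_decay * params.dt)
    lost = 0.0
    for cell in state.cells:
        if cell.alive and cell.role == RECEIVER and cell.wnt > 0:
            new = cell.wnt * factor
            lost += cell.wnt - new
            cell.wnt = new
    state.ledger.in_receivers -= lost
    state.ledger.decayed += lost
    return state


class _ReceiverIndex:
    """KD-tree contact index over the alive receivers of one step.

    Must agree exactly with :func:`detect_contact` (strict inequality against
    each receiver's own radius, ties to the smaller id).
    """

    def __init__(self, receivers):
        self.receivers = receivers
        if receivers:
            self.tree = cKDTree(np.array([c.position for c in receivers]))
            self.r_max = max(c.radius for c in receivers)
        else:
            self.tree = None

    def query(self, tip) -> Cell | None:
        if self.tree is None:
            return None
        best = None
        for idx in self.tree.query_ball_point(tip, self.r_max):
            cell = self.receivers[idx]
            d = math.hypot(*(tip - cell.position))
            if d < cell.radius and (best is None or (d, cell.id) < best[:2]):
                best = (d, cell.id, cell)
        return None if best is None else best[2]


def cytoneme_step(state: TissueState, params: Params,
                  rng: np.random.Generator) -> TissueState:
    """One transport step over all cytonemes in ascending id order.

    A cytoneme due for retraction is replaced in place; otherwise it grows,
    its tip is recomputed, and — if in contact with a receiver and the
    deposition process fires — it deposits.  Replacements created during the
    step are not processed until the next step.
    """
    index = _ReceiverIndex(state.alive_receivers())
    cyts = state.cytonemes
    order = sorted(range(len(cyts)), key=lambda i: cyts[i].id)
    for i in order:
        cyt = cyts[i]
        if retraction_due(cyt, params, rng):
            cyts[i] = replace_cytoneme(state, cyt, params, rng)
            continue
        cyt.length += sample_growth_increment(params.mu_g, params.sigma_g, rng)
        tip = tip_position(cyt, state)
        receiver = index.query(tip)
        if receiver is not None and deposition_fires(params, rng):
            deposit(cyt, receiver, params, state)
    if len(cyts) != state.n_cytonemes_target:
        raise IntegrityError("cytoneme count changed during cytoneme_step")
    return state
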