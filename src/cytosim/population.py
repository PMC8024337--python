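"""Receiver population dynamics: renewal-process division, Poisson apoptosis.

Source cells neither divide nor die, which keeps cytoneme anchors valid and
the global cytoneme count conservable.
"""
from __future__ import annotations

import math

import numpy as np

from .params import Params
from .tissue_init import RECEIVER, TissueState

__all__ = ["division_step", "apoptosis_step"]

_DAUGHTER_OFFSET = 0.3  # daughter placed at this fraction of r_c from the mother


def division_step(state: TissueState, params: Params,
                  rng: np.random.Generator) -> TissueState:
    """Divide every alive receiver whose clock has expired.

    The daughter appears at the mother's position plus a displacement of
    magnitude ``0.3 r_c`` in a uniform random direction, starts with zero
    ligand, and both cells draw fresh clocks ``t + U(T_div_min, T_div_max)``.
    Draw order per event: direction, mother clock, daughter clock.
    """
    t = state.time
    due = [c for c in state.cells
           if c.alive and c.role == RECEIVER
           and c.next_division_time is not None and c.next_division_time <= t]
    for mother in due:
        ang = rng.uniform(0.0, 2.0 * math.pi)
        offset = _DAUGHTER_OFFSET * mother.radius * np.array(
            [math.cos(ang), math.sin(ang)]
        )
        mother.next_division_time = t + rng.uniform(params.T_div_min, params.T_div_max)
        state.new_cell(
            position=mother.position + offset,
            radius=mother.radius,
            role=RECEIVER,
            next_division_time=t + rng.uniform(params.T_div_min, params.T_div_max),
        )
    return state


def apoptosis_step(state: TissueState, params: Params,
                   rng: np.random.Generator) -> TissueState:
    """Kill each alive receiver independently with probability
    ``1 - exp(-p_apop dt)``; a dead cell's ligand moves to the
    ``lost_to_death`` ledger bucket and the cell leaves mechanics, contact
    detection, and analysis."""
    if params.p_apop == 0:
        return state
    p = 1.0 - math.exp(-params.p_apop * params.dt)
    receivers = [c for c in state.cells if c.alive and c.role == RECEIVER]
    draws = rng.random(len(receivers))
    for cell, u in zip(receivers, draws):
        if u < p:
            cell.alive = False
            state.ledger.in_receivers -= cell.wnt
            state.ledger.lost_to_death += cell.wnt
    return state
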