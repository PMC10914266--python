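"""Flux variability analysis and the FVA-based differential direction call.

FVA computes, for each reaction, the minimum and maximum flux attainable
under the steady-state and bound constraints (optionally holding the
objective at a fraction of its optimum).  Comparing the FVA intervals of a
baseline (WT) and perturbed (MUT) state yields a coarse increase /
decrease / unchanged call per reaction: the comparator method against which
sampling-based scoring is benchmarked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lp import fba_optimum, solve_lp
from .model import MetabolicModel

__all__ = ["FvaResult", "DirectionCall", "run_fva", "fva_direction_call"]

#: absolute flux tolerance for calling a bound change real
DIRECTION_TOL = 1e-6
#: relative factor (of the WT bound) for calling a bound change real
DIRECTION_FACTOR = 0.01


@dataclass
class FvaResult:
    """Per-reaction (min_flux, max_flux) pairs."""

    reaction_ids: list
    min_flux: np.ndarray
    max_flux: np.ndarray
    fraction_of_optimum: float = 0.0

    def __post_init__(self):
        self.min_flux = np.asarray(self.min_flux, dtype=float)
        self.max_flux = np.asarray(self.max_flux, dtype=float)
        if np.any(self.min_flux > self.max_flux + 1e-9):
            raise ValueError("FVA minimum exceeds maximum")

    def interval(self, rxn_id) -> tuple:
        i = self.reaction_ids.index(rxn_id)
        return float(self.min_flux[i]), float(self.max_flux[i])

    def is_blocked(self, rxn_id, tol: float = DIRECTION_TOL) -> bool:
        lo, hi = self.interval(rxn_id)
        return abs(lo) <= tol and abs(hi) <= tol

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"reaction_id": self.reaction_ids,
             "min_flux": self.min_flux,
             "max_flux": self.max_flux}
        )


@dataclass
class DirectionCall:
    reaction_id: str
    direction: str  # increase | decrease | unchanged
    magnitude: float = 0.0


def run_fva(
    model: MetabolicModel,
    reactions=None,
    fraction_of_optimum: float = 0.0,
) -> FvaResult:
    """Minimum and maximum attainable flux per reaction.

    With ``fraction_of_optimum`` > 0 and a nonzero objective, every LP is
    additionally constrained to keep the objective at or above that fraction
    of its optimum; at 0 (the default used throughout) FVA is unconstrained
    by the objective.
    """
    if reactions is None:
        reactions = list(model.reaction_ids)
    extra_A, extra_b = None, None
    if fraction_of_optimum > 0 and np.any(model.objective_coeffs != 0):
        opt = fba_optimum(model)
        if not opt.ok:
            raise RuntimeError(f"FBA failed: status {opt.status}")
        extra_A = -model.objective_coeffs[None, :]
        extra_b = np.array([-fraction_of_optimum * opt.objective_value])

    mins = np.empty(len(reactions))
    maxs = np.empty(len(reactions))
    c = np.zeros(model.n_reactions)
    for i, rid in enumerate(reactions):
        j = model.reaction_index(rid)
        c[:] = 0.0
        c[j] = 1.0
        for sense, store in (("min", mins), ("max", maxs)):
            res = solve_lp(model, c, sense, extra_A_ub=extra_A, extra_b_ub=extra_b)
            if not res.ok:
                raise RuntimeError(
                    f"FVA {sense} failed for {rid!r}: status {res.status}"
                )
            store[i] = res.objective_value
    return FvaResult(list(reactions), mins, maxs, fraction_of_optimum)


def fva_direction_call(
    wt: FvaResult,
    mut: FvaResult,
    tol: float = DIRECTION_TOL,
    factor: float = DIRECTION_FACTOR,
) -> list:
    """Classify each reaction's FVA interval shift between two states.

    For each reaction take dmax = mut.max - wt.max and dmin = mut.min -
    wt.min; the magnitude is whichever has the larger absolute value (the
    greatest bound change; an exact tie resolves toward the upper bound).
    The direction is the sign of the magnitude if it exceeds
    ``max(tol, factor * |WT bound on that side|)``, otherwise unchanged.
    Swapping WT and MUT flips every call (antisymmetry).
    """
    if list(wt.reaction_ids) != list(mut.reaction_ids):
        raise ValueError("WT and MUT FVA results cover different reactions")
    calls = []
    for i, rid in enumerate(wt.reaction_ids):
        dmax = mut.max_flux[i] - wt.max_flux[i]
        dmin = mut.min_flux[i] - wt.min_flux[i]
        if abs(dmax) >= abs(dmin):
            magnitude, wt_side = dmax, wt.max_flux[i]
        else:
            magnitude, wt_side = dmin, wt.min_flux[i]
        threshold = max(tol, factor * abs(wt_side))
        if abs(magnitude) > threshold:
            direction = "increase" if magnitude > 0 else "decrease"
        else:
            direction = "unchanged"
        calls.append(DirectionCall(rid, direction, float(magnitude)))
    return calls
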