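"""Linear-programming layer: optimize c'v over {v : S v = 0, lb <= v <= ub}.

Everything that needs an LP (flux forcing, FVA, sampler warm-up) goes through
:func:`solve_lp`, so the backend is swappable in one place.  The default
backend is scipy's HiGHS, which is deterministic for a fixed model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel

__all__ = ["LpResult", "solve_lp", "optimize_reaction", "fba_optimum"]


@dataclass
class LpResult:
    status: str  # optimal | infeasible | unbounded
    objective_value: float | None
    solution: np.ndarray | None

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


_STATUS = {0: "optimal", 1: "infeasible", 2: "infeasible", 3: "unbounded", 4: "infeasible"}


def solve_lp(
    model: MetabolicModel,
    objective,
    sense: str = "max",
    extra_A_ub: np.ndarray | None = None,
    extra_b_ub: np.ndarray | None = None,
) -> LpResult:
    """Optimize a linear objective over the steady-state flux polytope.

    ``objective`` is a per-reaction weight vector; ``sense`` is ``max`` or
    ``min``.  Optional rows ``extra_A_ub v <= extra_b_ub`` support e.g. a
    fraction-of-optimum biomass constraint.  Infeasibility and unboundedness
    are reported in the returned status, never raised.
    """
    c = np.asarray(objective, dtype=float)
    if c.shape != (model.n_reactions,):
        raise ValueError("objective length does not match reaction count")
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    sign = -1.0 if sense == "max" else 1.0

    try:
        res = linprog(
            sign * c,
            A_eq=model.S,
            b_eq=np.zeros(model.n_metabolites),
            A_ub=extra_A_ub,
            b_ub=extra_b_ub,
            bounds=list(zip(model.lb, model.ub)),
            method="highs",
            options={"primal_feasibility_tolerance": 1e-9,
                     "dual_feasibility_tolerance": 1e-9},
        )
    except ValueError:
        # e.g. lb > ub injected after construction: an empty polytope
        return LpResult("infeasible", None, None)

    status = _STATUS.get(res.status, "infeasible")
    if status != "optimal":
        return LpResult(status, None, None)
    return LpResult("optimal", float(sign * res.fun), np.asarray(res.x))


def optimize_reaction(model: MetabolicModel, rxn_id, sense: str = "max",
                      **kw) -> LpResult:
    """Maximize or minimize the flux of a single reaction."""
    c = np.zeros(model.n_reactions)
    c[model.reaction_index(rxn_id)] = 1.0
    return solve_lp(model, c, sense, **kw)


def fba_optimum(model: MetabolicModel) -> LpResult:
    """Maximize the model's own objective (flux balance analysis)."""
    return solve_lp(model, model.objective_coeffs, "max")
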