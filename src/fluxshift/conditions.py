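"""Build the paired baseline (WT) and perturbed (MUT) models for a condition.

A perturbation is given as genes or reactions plus a mode:

* knockout — the affected reactions get bounds [0, 0] in MUT;
* knockdown — the affected reactions keep a fraction of their original
  bounds in MUT (maximum-capacity reduction).

The WT is *specific to the perturbation*: each affected reaction is forced
to carry nonzero flux (lower bound set to ``forcing_fraction`` of its
attainable maximum, default 5%, or the mirrored rule on the reverse side),
so the two sampled states genuinely differ on the reactions of interest
rather than both sitting at zero.

Order of operations: medium bounds -> biomass constraint -> forcing (WT) or
KO/KD (MUT), so that forcing respects the medium and both states share the
same medium and biomass bounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .lp import optimize_reaction
from .model import DEFAULT_BOUND, MetabolicModel, identify_exchanges

__all__ = [
    "ConditionSpec",
    "ConditionPair",
    "apply_medium_bounds",
    "apply_biomass_constraint",
    "gene_to_reactions",
    "build_mut",
    "build_wt",
    "build_condition_pair",
]

#: a reaction "can carry flux" if its attainable extreme exceeds this
FLUX_TOL = 1e-6


@dataclass
class ConditionSpec:
    """One perturbation scenario.

    medium_uptake_X bounds every exchange reaction to [-X, 1000]
    (None = keep the model's own bounds); biomass_fraction is the minimum
    fraction of the biomass optimum enforced in both states (0 disables it);
    forcing_fraction is the share of the attainable flux extreme imposed on
    each perturbed reaction in WT.
    """

    name: str
    perturbation_targets: list
    target_kind: str = "genes"  # genes | reactions
    mode: str = "knockout"  # knockout | knockdown
    knockdown_fraction: float | None = None
    medium_uptake_X: float | None = 1.0
    biomass_reaction: str | None = None
    biomass_fraction: float = 0.0
    forcing_fraction: float = 0.05
    forcing_mode: str = "sequential"  # sequential | joint

    def __post_init__(self):
        if self.target_kind not in ("genes", "reactions"):
            raise ValueError(f"target_kind must be genes|reactions: {self.target_kind!r}")
        if self.mode not in ("knockout", "knockdown"):
            raise ValueError(f"mode must be knockout|knockdown: {self.mode!r}")
        if self.mode == "knockdown":
            if self.knockdown_fraction is None:
                raise ValueError("knockdown mode requires knockdown_fraction")
            if not 0 <= self.knockdown_fraction < 1:
                raise ValueError("knockdown_fraction must be in [0, 1)")
        if self.medium_uptake_X is not None and self.medium_uptake_X < 0:
            raise ValueError("medium_uptake_X must be nonnegative")
        if not 0 < self.forcing_fraction <= 1:
            raise ValueError("forcing_fraction must be in (0, 1]")
        if not 0 <= self.biomass_fraction <= 1:
            raise ValueError("biomass_fraction must be in [0, 1]")
        if self.forcing_mode not in ("sequential", "joint"):
            raise ValueError(f"unknown forcing_mode: {self.forcing_mode!r}")


@dataclass
class ConditionPair:
    """A WT model and a MUT model derived from one perturbation spec."""

    wt: MetabolicModel
    mut: MetabolicModel
    affected_reactions: list
    unforceable_reactions: list = field(default_factory=list)
    provenance: list = field(default_factory=list)
    spec: ConditionSpec | None = None


def _record(provenance, model_tag, rxn, which, old, new, reason):
    provenance.append(
        {"model": model_tag, "reaction": rxn, "bound": which,
         "old": float(old), "new": float(new), "reason": reason}
    )


def apply_medium_bounds(model: MetabolicModel, X: float | None) -> MetabolicModel:
    """Set every exchange reaction's bounds to [-X, 1000].

    ``X`` limits uptake (import) while export stays open up to the
    conventional cap.  ``X = None`` is the pass-through option: the model's
    own exchange bounds are kept.
    """
    if X is None:
        return model.copy()
    if X < 0:
        raise ValueError("medium uptake bound X must be nonnegative")
    out = model.copy()
    for rid in identify_exchanges(out):
        j = out.reaction_index(rid)
        out.lb[j] = -X
        out.ub[j] = DEFAULT_BOUND
    return out


def apply_biomass_constraint(
    model: MetabolicModel, rxn_id: str, fraction: float
) -> MetabolicModel:
    """Pin the biomass reaction's lower bound to a fraction of its optimum."""
    out = model.copy()
    j = out.reaction_index(rxn_id)
    if fraction == 0:
        out.lb[j] = max(0.0, out.lb[j])
        return out
    res = optimize_reaction(out, rxn_id, "max")
    if not res.ok:
        raise RuntimeError(f"biomass optimization failed: status {res.status}")
    out.lb[j] = max(out.lb[j], fraction * res.objective_value)
    return out


def gene_to_reactions(model: MetabolicModel, genes) -> set:
    """Reactions inactivated when ``genes`` are knocked out (via GPR rules)."""
    genes = set(genes)
    unknown = genes - set(model.gene_ids)
    if unknown:
        warnings.warn(
            f"genes not present in any GPR: {sorted(unknown)}", stacklevel=2
        )
    hit = set()
    for rid, expr in zip(model.reaction_ids, model.gpr):
        if not expr.is_empty and not expr.evaluate(genes):
            hit.add(rid)
    return hit


def _resolve_targets(model: MetabolicModel, spec: ConditionSpec) -> list:
    if spec.target_kind == "genes":
        rxns = gene_to_reactions(model, spec.perturbation_targets)
    else:
        missing = [r for r in spec.perturbation_targets if r not in model.reaction_ids]
        if missing:
            raise KeyError(f"unknown reactions in perturbation spec: {missing}")
        rxns = set(spec.perturbation_targets)
    if not rxns:
        raise ValueError(
            f"perturbation {spec.name!r} resolves to no reactions "
            f"(targets: {spec.perturbation_targets})"
        )
    return sorted(rxns)


def build_mut(
    model: MetabolicModel, spec: ConditionSpec, provenance: list | None = None
) -> MetabolicModel:
    """Apply the knockout/knockdown bounds; ``model`` should already carry
    the medium and biomass constraints."""
    affected = _resolve_targets(model, spec)
    out = model.copy()
    prov = provenance if provenance is not None else []
    for rid in affected:
        j = out.reaction_index(rid)
        if spec.mode == "knockout":
            new_lb, new_ub = 0.0, 0.0
        else:
            f = spec.knockdown_fraction
            new_lb, new_ub = out.lb[j] * f, out.ub[j] * f
        _record(prov, "mut", rid, "lb", out.lb[j], new_lb, spec.mode)
        _record(prov, "mut", rid, "ub", out.ub[j], new_ub, spec.mode)
        out.lb[j], out.ub[j] = new_lb, new_ub
    return out


def build_wt(
    model: MetabolicModel, spec: ConditionSpec, provenance: list | None = None
) -> MetabolicModel:
    """Force nonzero flux through each perturbation-target reaction.

    For each affected reaction (lexicographic order, each optimization seeing
    the forcings already applied): maximize its flux; if the maximum exceeds
    tolerance, raise its lower bound to forcing_fraction * maximum.  If the
    reaction is forward-blocked, try the reverse direction and cap the upper
    bound at forcing_fraction * minimum (a negative value).  Reactions
    blocked in both directions are left untouched with a warning.
    """
    affected = _resolve_targets(model, spec)
    out = model.copy()
    prov = provenance if provenance is not None else []

    if spec.forcing_mode == "joint":
        return _build_wt_joint(out, affected, spec, prov)

    unforceable = []
    for rid in affected:
        j = out.reaction_index(rid)
        res = optimize_reaction(out, rid, "max")
        if not res.ok:
            raise RuntimeError(
                f"WT forcing infeasible at {rid!r} (status {res.status}); "
                f"already forced: {[r for r in affected if r < rid]}"
            )
        vmax = res.objective_value
        if vmax > FLUX_TOL:
            new_lb = spec.forcing_fraction * vmax
            _record(prov, "wt", rid, "lb", out.lb[j], new_lb, "forcing")
            out.lb[j] = new_lb
            continue
        res = optimize_reaction(out, rid, "min")
        if not res.ok:
            raise RuntimeError(f"WT forcing infeasible at {rid!r}")
        vmin = res.objective_value
        if vmin < -FLUX_TOL:
            new_ub = spec.forcing_fraction * vmin
            _record(prov, "wt", rid, "ub", out.ub[j], new_ub, "forcing")
            out.ub[j] = new_ub
        else:
            unforceable.append(rid)
            warnings.warn(
                f"reaction {rid!r} is blocked in both directions; "
                "left unforced in WT", stacklevel=2
            )
    out._unforceable = unforceable  # consumed by build_condition_pair
    return out


def _build_wt_joint(out, affected, spec, prov):
    """Joint variant: one LP maximizing the summed flux of all targets."""
    c = np.zeros(out.n_reactions)
    for rid in affected:
        c[out.reaction_index(rid)] = 1.0
    from .lp import solve_lp

    res = solve_lp(out, c, "max")
    if not res.ok:
        raise RuntimeError(f"joint WT forcing failed: status {res.status}")
    unforceable = []
    for rid in affected:
        j = out.reaction_index(rid)
        v = res.solution[j]
        if v > FLUX_TOL:
            new_lb = spec.forcing_fraction * v
            _record(prov, "wt", rid, "lb", out.lb[j], new_lb, "forcing-joint")
            out.lb[j] = new_lb
        elif v < -FLUX_TOL:
            new_ub = spec.forcing_fraction * v
            _record(prov, "wt", rid, "ub", out.ub[j], new_ub, "forcing-joint")
            out.ub[j] = new_ub
        else:
            unforceable.append(rid)
            warnings.warn(f"reaction {rid!r} carries no flux in the joint "
                          "forcing optimum; left unforced", stacklevel=3)
    out._unforceable = unforceable
    return out


def build_condition_pair(model: MetabolicModel, spec: ConditionSpec) -> ConditionPair:
    """Full WT/MUT construction: medium -> biomass -> forcing / KO-KD."""
    base = apply_medium_bounds(model, spec.medium_uptake_X)
    if spec.biomass_reaction is not None:
        base = apply_biomass_constraint(
            base, spec.biomass_reaction, spec.biomass_fraction
        )
    provenance = []
    wt = build_wt(base, spec, provenance)
    mut = build_mut(base, spec, provenance)
    affected = _resolve_targets(base, spec)
    return ConditionPair(
        wt=wt,
        mut=mut,
        affected_reactions=affected,
        unforceable_reactions=getattr(wt, "_unforceable", []),
        provenance=provenance,
        spec=spec,
    )
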