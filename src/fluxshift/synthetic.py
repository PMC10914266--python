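"""Synthetic fixture networks with analytically known perturbation effects.

Two generators keep the whole pipeline testable without downloading a
genome-scale reconstruction:

* :func:`toy_network` — a fixed small network (6 metabolites, 10 reactions,
  4 exchanges) in which one gene-associated internal reaction feeds a
  dedicated export branch.  Knocking the gene out collapses that branch, so
  its export must decrease and the bypass export must increase.

* :func:`random_viable_network` — randomized branched networks (unit
  stoichiometry) grown as a spanning tree from a single imported nutrient,
  with exports on several reachable metabolites.  One internal reaction is
  selected as the perturbation target and the *planted truth* (which
  exchanges change, and how) is derived from FVA on the actual WT/MUT
  condition pair, making the oracle exact and solver-deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .conditions import ConditionSpec, build_condition_pair
from .fva import fva_direction_call, run_fva
from .model import DEFAULT_BOUND, MetabolicModel, parse_gpr

__all__ = ["PlantedTruth", "toy_network", "random_viable_network"]


@dataclass
class PlantedTruth:
    """Ground truth for a planted perturbation: which exchange reactions are
    expected to change and in which direction."""

    affected: dict  # exchange reaction id -> increase | decrease
    unaffected: list
    target_reaction: str
    seed: int | None = None
    params: dict = field(default_factory=dict)

    @property
    def affected_exchange_ids(self) -> list:
        return sorted(self.affected)


def toy_network() -> MetabolicModel:
    """Fixed toy model: nutrient A feeds two branches exporting E and F.

    Topology (all internal reactions irreversible, unit coefficients)::

        EX_A <-> A -> B -> C -> E -> EX_E     (B->C carries gene g1)
                      B -> D -> F -> EX_F
                 A -> D                        (g2 and g3)
                      B -> EX_B

    Knocking out g1 blocks the C/E branch entirely: the E export collapses
    to [0, 0] while the D/F branch absorbs the flux.  The model is feasible
    with nonzero flux (uptake bound 10 on A).
    """
    mets = ["A", "B", "C", "D", "E", "F"]
    reactions = [
        # (id, stoichiometry, lb, ub, gpr)
        ("EX_A", {"A": -1}, -10.0, DEFAULT_BOUND, ""),
        ("EX_B", {"B": -1}, 0.0, DEFAULT_BOUND, ""),
        ("EX_E", {"E": -1}, 0.0, DEFAULT_BOUND, ""),
        ("EX_F", {"F": -1}, 0.0, DEFAULT_BOUND, ""),
        ("R_AB", {"A": -1, "B": 1}, 0.0, DEFAULT_BOUND, ""),
        ("R_AD", {"A": -1, "D": 1}, 0.0, DEFAULT_BOUND, "g2 and g3"),
        ("R_BC", {"B": -1, "C": 1}, 0.0, DEFAULT_BOUND, "g1"),
        ("R_BD", {"B": -1, "D": 1}, 0.0, DEFAULT_BOUND, ""),
        ("R_CE", {"C": -1, "E": 1}, 0.0, DEFAULT_BOUND, ""),
        ("R_DF", {"D": -1, "F": 1}, 0.0, DEFAULT_BOUND, ""),
    ]
    return _assemble(mets, reactions, name="toy")


def _assemble(met_ids, reactions, name) -> MetabolicModel:
    met_index = {m: i for i, m in enumerate(met_ids)}
    S = np.zeros((len(met_ids), len(reactions)))
    lb = np.empty(len(reactions))
    ub = np.empty(len(reactions))
    gpr = []
    rxn_ids = []
    for j, (rid, stoich, lo, hi, rule) in enumerate(reactions):
        rxn_ids.append(rid)
        for met, coeff in stoich.items():
            S[met_index[met], j] = coeff
        lb[j], ub[j] = lo, hi
        gpr.append(parse_gpr(rule))
    return MetabolicModel(
        metabolite_ids=list(met_ids),
        reaction_ids=rxn_ids,
        S=S,
        lb=lb,
        ub=ub,
        gpr=gpr,
        name=name,
    )


def _draw_topology(n_metabolites, n_reactions, n_exchanges, rng):
    """Spanning tree from m0 plus random forward shortcut edges."""
    mets = [f"m{i}" for i in range(n_metabolites)]
    edges = []  # (src, dst) internal reactions, src index < dst index
    for child in range(1, n_metabolites):
        parent = int(rng.integers(child))
        edges.append((parent, child))
    n_internal = n_reactions - n_exchanges
    if n_internal < n_metabolites - 1:
        raise ValueError(
            "n_reactions too small for a connected topology: need at least "
            f"{n_metabolites - 1 + n_exchanges}"
        )
    existing = set(edges)
    attempts = 0
    while len(edges) < n_internal and attempts < 200:
        attempts += 1
        i, j = sorted(rng.choice(n_metabolites, size=2, replace=False))
        if (int(i), int(j)) not in existing:
            edges.append((int(i), int(j)))
            existing.add((int(i), int(j)))
    if len(edges) < n_internal:
        raise RuntimeError("could not place the requested number of reactions")

    # exports on the deepest tree nodes (leaves first) so each sits on a branch
    children = {p for p, _ in edges}
    leaves = [i for i in range(1, n_metabolites) if i not in children]
    rng.shuffle(leaves)
    export_nodes = leaves[: n_exchanges - 1]
    pool = [i for i in range(1, n_metabolites) if i not in export_nodes]
    rng.shuffle(pool)
    export_nodes += pool[: n_exchanges - 1 - len(export_nodes)]

    reactions = [("EX_m0", {"m0": -1}, -10.0, DEFAULT_BOUND, "")]
    for node in sorted(export_nodes):
        reactions.append((f"EX_m{node}", {f"m{node}": -1}, 0.0, DEFAULT_BOUND, ""))
    for i, j in edges:
        reactions.append(
            (f"R_m{i}_m{j}", {f"m{i}": -1, f"m{j}": 1}, 0.0, DEFAULT_BOUND, "")
        )
    return mets, reactions


def random_viable_network(
    n_metabolites: int = 8,
    n_reactions: int = 12,
    n_exchanges: int = 3,
    seed: int = 0,
    medium_uptake_X: float = 1.0,
    forcing_fraction: float = 0.05,
    max_retries: int = 30,
) -> tuple:
    """Random feasible network plus a planted perturbation of known effect.

    Returns ``(model, truth)``.  The perturbation target is an internal
    reaction whose knockout (with WT flux forcing, under the given medium)
    changes at least one exchange reaction's FVA interval beyond the
    standard 1e-6 / 0.01 thresholds; the change directions recorded in the
    truth are the FVA direction calls on the same WT/MUT pair the sampling
    pipeline would compare.  Deterministic given the seed; topologies whose
    candidate targets all fail are redrawn up to ``max_retries`` times.
    """
    if n_exchanges < 2:
        raise ValueError("need at least an importer and one exporter")
    rng = np.random.default_rng(seed)
    last_err = None
    for _ in range(max_retries):
        try:
            mets, reactions = _draw_topology(
                n_metabolites, n_reactions, n_exchanges, rng
            )
        except RuntimeError as err:
            last_err = err
            continue
        model = _assemble(mets, reactions, name=f"rand{seed}")
        exchange_ids = sorted(r[0] for r in reactions if r[0].startswith("EX_"))

        # viability: every exchange must be able to carry flux in the medium
        from .conditions import apply_medium_bounds

        base = apply_medium_bounds(model, medium_uptake_X)
        fva_base = run_fva(base, exchange_ids)
        if any(fva_base.is_blocked(rid) for rid in exchange_ids):
            last_err = RuntimeError("draw produced a blocked exchange")
            continue

        internal = [r[0] for r in reactions if not r[0].startswith("EX_")]
        rng.shuffle(internal)
        for target in internal:
            truth = _plant_target(
                model, target, exchange_ids, medium_uptake_X, forcing_fraction
            )
            if truth is not None:
                truth.seed = seed
                truth.params = {
                    "n_metabolites": n_metabolites,
                    "n_reactions": n_reactions,
                    "n_exchanges": n_exchanges,
                }
                # gene-associate the target so gene-mode KOs work too
                j = model.reaction_index(target)
                model.gpr[j] = parse_gpr("g_ko")
                return model, truth
        last_err = RuntimeError("no internal reaction perturbs any exchange")
    raise RuntimeError(
        f"failed to build a viable planted network after {max_retries} draws: "
        f"{last_err}"
    )


def _plant_target(model, target, exchange_ids, X, forcing_fraction):
    spec = ConditionSpec(
        name=f"ko_{target}",
        perturbation_targets=[target],
        target_kind="reactions",
        mode="knockout",
        medium_uptake_X=X,
        forcing_fraction=forcing_fraction,
    )
    try:
        with warnings.catch_warnings():
            # candidate screening: unforceable targets are simply skipped
            warnings.simplefilter("ignore")
            pair = build_condition_pair(model, spec)
    except (RuntimeError, ValueError):
        return None
    if pair.unforceable_reactions:
        return None
    wt_fva = run_fva(pair.wt, exchange_ids)
    mut_fva = run_fva(pair.mut, exchange_ids)
    calls = fva_direction_call(wt_fva, mut_fva)
    affected = {
        c.reaction_id: c.direction for c in calls if c.direction != "unchanged"
    }
    if not affected:
        return None
    unaffected = [rid for rid in exchange_ids if rid not in affected]
    return PlantedTruth(
        affected=affected, unaffected=sorted(unaffected), target_reaction=target
    )
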