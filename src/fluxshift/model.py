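"""Constraint-based metabolic model container and GPR logic.

A metabolic network at steady state is the linear system ``S @ v = 0`` with
per-reaction flux bounds ``lb <= v <= ub``.  ``S`` is the stoichiometric
matrix (metabolites x reactions).  Exchange (boundary) reactions touch a
single metabolite and move it across the system boundary; by convention the
exchanged metabolite has coefficient -1 so that positive flux is export and
negative flux is import.

Gene-protein-reaction (GPR) rules are boolean expressions over gene
identifiers (AND = enzyme-complex subunits, OR = isozymes) and decide
whether a reaction survives a gene knockout.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GprExpression",
    "MetabolicModel",
    "ModelValidationError",
    "parse_gpr",
    "identify_exchanges",
    "evaluate_gpr",
    "validate_flux_vector",
]

#: default bound magnitude used when a file omits bounds (COBRA convention)
DEFAULT_BOUND = 1000.0

TOL_MASS_BALANCE = 1e-6
TOL_BOUNDS = 1e-6


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


# ---------------------------------------------------------------------------
# GPR expressions
# ---------------------------------------------------------------------------

_GPR_TOKEN = re.compile(r"\(|\)|[^\s()]+")


@dataclass(frozen=True)
class GprExpression:
    """Boolean AND/OR tree over gene identifiers.

    ``tree`` is ``None`` (empty rule: reaction not gene-associated), a gene
    identifier string, or ``(op, children)`` with ``op`` in {"and", "or"}.
    """

    tree: object = None

    @property
    def is_empty(self) -> bool:
        return self.tree is None

    @property
    def genes(self) -> frozenset:
        """All gene identifiers appearing in the expression."""

        def walk(node):
            if node is None:
                return
            if isinstance(node, str):
                yield node
                return
            _, children = node
            for child in children:
                yield from walk(child)

        return frozenset(walk(self.tree))

    def evaluate(self, knocked_genes) -> bool:
        """True if the reaction remains active when ``knocked_genes`` are off.

        Genes in ``knocked_genes`` evaluate FALSE, all others TRUE.  An empty
        expression is always active (not knockable via genes).
        """
        knocked = set(knocked_genes)

        def ev(node):
            if node is None:
                return True
            if isinstance(node, str):
                return node not in knocked
            op, children = node
            if op == "and":
                return all(ev(c) for c in children)
            return any(ev(c) for c in children)

        return ev(self.tree)

    def to_string(self) -> str:
        """Serialize back to a COBRA-style rule string."""

        def render(node, parent_op=None):
            if node is None:
                return ""
            if isinstance(node, str):
                return node
            op, children = node
            inner = f" {op} ".join(render(c, op) for c in children)
            if parent_op is not None and parent_op != op:
                return f"({inner})"
            return inner

        return render(self.tree)


def parse_gpr(text: str | None) -> GprExpression:
    """Parse a GPR rule string into a :class:`GprExpression`.

    ``and``/``or`` are matched case-insensitively; parentheses group; any
    other token is treated as a gene identifier (model dialects disagree on
    identifier syntax).  Empty/whitespace input yields the empty expression.
    """
    if text is None or not text.strip():
        return GprExpression(None)

    tokens = _GPR_TOKEN.findall(text)
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or():
        node = parse_and()
        terms = [node]
        while peek() is not None and peek().lower() == "or":
            take()
            terms.append(parse_and())
        if len(terms) == 1:
            return node
        return ("or", tuple(terms))

    def parse_and():
        node = parse_atom()
        terms = [node]
        while peek() is not None and peek().lower() == "and":
            take()
            terms.append(parse_atom())
        if len(terms) == 1:
            return node
        return ("and", tuple(terms))

    def parse_atom():
        tok = peek()
        if tok is None:
            raise ModelValidationError(f"truncated GPR expression: {text!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise ModelValidationError(f"unbalanced parentheses in GPR: {text!r}")
            take()
            return node
        if tok == ")":
            raise ModelValidationError(f"unexpected ')' in GPR: {text!r}")
        if tok.lower() in ("and", "or"):
            raise ModelValidationError(f"misplaced connective in GPR: {text!r}")
        return take()

    tree = parse_or()
    if pos != len(tokens):
        raise ModelValidationError(f"trailing tokens in GPR: {text!r}")
    return GprExpression(tree)


def evaluate_gpr(expr: GprExpression, knocked_genes) -> bool:
    """Functional form of :meth:`GprExpression.evaluate`."""
    return expr.evaluate(knocked_genes)


# ---------------------------------------------------------------------------
# The model container
# ---------------------------------------------------------------------------


@dataclass
class MetabolicModel:
    """Stoichiometric system with bounds, GPRs, objective and exchange set."""

    metabolite_ids: list
    reaction_ids: list
    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    gpr: list = None
    objective_coeffs: np.ndarray = None
    name: str = "model"
    metabolite_names: dict = field(default_factory=dict)

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        self.lb = np.asarray(self.lb, dtype=float).copy()
        self.ub = np.asarray(self.ub, dtype=float).copy()
        if self.gpr is None:
            self.gpr = [GprExpression(None)] * self.n_reactions
        if self.objective_coeffs is None:
            self.objective_coeffs = np.zeros(self.n_reactions)
        else:
            self.objective_coeffs = np.asarray(self.objective_coeffs, dtype=float)
        self.validate()

    # -- basic views ------------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def gene_ids(self) -> frozenset:
        return frozenset().union(*(g.genes for g in self.gpr)) if self.gpr else frozenset()

    @property
    def exchange_ids(self) -> list:
        return sorted(identify_exchanges(self))

    def reaction_index(self, rxn_id) -> int:
        try:
            return self.reaction_ids.index(rxn_id)
        except ValueError:
            raise KeyError(f"unknown reaction: {rxn_id!r}") from None

    def copy(self) -> "MetabolicModel":
        m = MetabolicModel(
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            S=self.S.copy(),
            lb=self.lb.copy(),
            ub=self.ub.copy(),
            gpr=list(self.gpr),
            objective_coeffs=self.objective_coeffs.copy(),
            name=self.name,
            metabolite_names=dict(self.metabolite_names),
        )
        return m

    def digest(self) -> str:
        """Stable content hash of structure and bounds, for provenance."""
        h = hashlib.sha256()
        h.update("\x00".join(map(str, self.metabolite_ids)).encode())
        h.update("\x00".join(map(str, self.reaction_ids)).encode())
        h.update(np.ascontiguousarray(self.S).tobytes())
        h.update(self.lb.tobytes())
        h.update(self.ub.tobytes())
        h.update("\x00".join(g.to_string() for g in self.gpr).encode())
        return h.hexdigest()[:16]

    # -- validation -------------------------------------------------------
    def validate(self):
        m, n = len(self.metabolite_ids), len(self.reaction_ids)
        if self.S.shape != (m, n):
            raise ModelValidationError(
                f"S has shape {self.S.shape}, expected ({m}, {n})"
            )
        if self.lb.shape != (n,) or self.ub.shape != (n,):
            raise ModelValidationError("bounds length does not match reaction count")
        bad = np.nonzero(self.lb > self.ub)[0]
        if bad.size:
            raise ModelValidationError(
                f"lb > ub for reaction {self.reaction_ids[bad[0]]!r}"
            )
        if len(self.gpr) != n:
            raise ModelValidationError("gpr list length does not match reaction count")
        if len(set(self.reaction_ids)) != n:
            raise ModelValidationError("duplicate reaction identifiers")
        if len(set(self.metabolite_ids)) != m:
            raise ModelValidationError("duplicate metabolite identifiers")

    # -- exchange helpers -------------------------------------------------
    def exchanged_metabolite(self, rxn_id) -> str:
        """The single metabolite touched by an exchange reaction."""
        j = self.reaction_index(rxn_id)
        rows = np.nonzero(self.S[:, j])[0]
        if rows.size != 1:
            raise ModelValidationError(f"{rxn_id!r} is not an exchange reaction")
        return self.metabolite_ids[rows[0]]


def identify_exchanges(model: MetabolicModel) -> dict:
    """Detect exchange reactions structurally.

    Returns ``{reaction_id: sign_flipped}`` for every reaction with exactly
    one nonzero stoichiometric entry.  ``sign_flipped`` is True when the
    coefficient is +1 (metabolite produced by positive flux), meaning the
    export-positive convention requires negating the flux downstream.
    Detection is purely structural; name prefixes like ``EX_`` play no role.
    """
    out = {}
    nz_count = np.count_nonzero(model.S, axis=0)
    for j in np.nonzero(nz_count == 1)[0]:
        coeff = model.S[np.nonzero(model.S[:, j])[0][0], j]
        out[model.reaction_ids[j]] = coeff > 0
    return out


def validate_flux_vector(
    model: MetabolicModel,
    v: np.ndarray,
    tol_mass_balance: float = TOL_MASS_BALANCE,
    tol_bounds: float = TOL_BOUNDS,
) -> bool:
    """Check the steady-state and bound invariants for one flux vector."""
    v = np.asarray(v, dtype=float)
    if v.shape != (model.n_reactions,):
        return False
    if np.max(np.abs(model.S @ v), initial=0.0) > tol_mass_balance:
        return False
    if np.any(v < model.lb - tol_bounds) or np.any(v > model.ub + tol_bounds):
        return False
    return True
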