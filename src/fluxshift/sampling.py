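"""Uniform sampling of the steady-state flux polytope.

The sampler is an artificial-centering hit-and-run (ACHR) chain in the
optGP style: warm-up points are FVA vertices (per-reaction minima and
maxima), the search direction at each step is a randomly chosen stored
point minus the running center of all accepted points, and the step length
is drawn uniformly over the feasible interval along that direction.
Because directions are differences of feasible points, ``S v = 0`` is
preserved automatically; accumulated floating-point drift is removed by
orthogonal projection back onto the null space of S.  Every ``thinning``-th
point is retained to reduce inter-sample correlation (the genome-scale
defaults in the literature are 100 000 samples with thinning 100; small
fixture models need far less).

Convergence is monitored with running means and the Gelman-Rubin potential
scale reduction factor (PSRF) across independent chains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import null_space

from .lp import optimize_reaction
from .model import MetabolicModel, TOL_BOUNDS, TOL_MASS_BALANCE

__all__ = [
    "FluxSamples",
    "ConvergenceReport",
    "generate_warmup",
    "sample_fluxes",
    "sample_chains",
    "convergence_diagnostics",
    "validate_samples",
    "write_samples_tsv",
    "read_samples_tsv",
]

#: drift threshold above which a point is re-projected onto {S v = 0}
DRIFT_TOL = 1e-8
#: minimum usable chord width / direction norm
DEGENERATE_TOL = 1e-12
MAX_DIRECTION_RETRIES = 100


@dataclass
class FluxSamples:
    """A matrix of feasible flux vectors (samples x reactions)."""

    matrix: np.ndarray
    reaction_ids: list
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    def column(self, rxn_id) -> np.ndarray:
        return self.matrix[:, self.reaction_ids.index(rxn_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.reaction_ids)


@dataclass
class ConvergenceReport:
    reaction_ids: list
    psrf: np.ndarray
    running_means: list  # one (n_samples x n_reactions) array per chain
    n_chains: int
    n_samples: int

    def max_psrf(self) -> float:
        return float(np.max(self.psrf))


def generate_warmup(model: MetabolicModel, count: int) -> list:
    """FVA-vertex warm-up: optima of individual reactions, both senses.

    Cycles through reactions (max then min each) until ``count`` points are
    collected.  Duplicate vertices are allowed but trigger a warning, since
    they reduce the direction diversity available to the chain.
    """
    if count < 4:
        raise ValueError("warm-up count must be at least 4")
    if count % 2:
        raise ValueError("warm-up count must be even")
    points = []
    n = model.n_reactions
    for idx in range(count):
        rid = model.reaction_ids[(idx // 2) % n]
        sense = "max" if idx % 2 == 0 else "min"
        res = optimize_reaction(model, rid, sense)
        if not res.ok:
            raise RuntimeError(
                f"warm-up LP failed on {rid!r} ({sense}): status {res.status}"
            )
        points.append(res.solution)
    arr = np.asarray(points)
    n_unique = np.unique(np.round(arr, 9), axis=0).shape[0]
    if n_unique < len(points):
        warnings.warn(
            f"warm-up produced {len(points) - n_unique} duplicate vertices",
            stacklevel=2,
        )
    return points


#: direction components smaller than this are treated as zero when
#: computing the feasible chord (they cannot move the point meaningfully
#: but would otherwise collapse the step interval on tight bounds)
DIRECTION_COMPONENT_TOL = 1e-10


def _chord_interval(x, d, lb, ub):
    """Feasible [alpha_min, alpha_max] for x + alpha * d within the bounds."""
    mask = np.abs(d) > DIRECTION_COMPONENT_TOL
    with np.errstate(divide="ignore", invalid="ignore"):
        lo = np.where(mask, (lb - x) / np.where(mask, d, 1.0), -np.inf)
        hi = np.where(mask, (ub - x) / np.where(mask, d, 1.0), np.inf)
    alpha_lo = np.where(d > 0, lo, hi)
    alpha_hi = np.where(d > 0, hi, lo)
    return np.max(alpha_lo[mask], initial=-np.inf), np.min(alpha_hi[mask], initial=np.inf)


def _achr_chain(model, warmup, n_keep, thinning, rng, nullspace):
    lb, ub = model.lb, model.ub
    # snap warm-up vertices exactly onto {S v = 0}: LP solutions carry
    # ~1e-9 residuals that direction normalization would otherwise amplify
    pool = [nullspace @ (nullspace.T @ np.asarray(p, dtype=float)) for p in warmup]
    arr = np.asarray(pool)

    # degenerate polytope: all warm-up vertices coincide -> a single point
    if np.max(arr.max(axis=0) - arr.min(axis=0), initial=0.0) < DEGENERATE_TOL:
        warnings.warn("flux polytope is a single point; samples are identical",
                      stacklevel=3)
        return np.tile(arr[0], (n_keep, 1))

    center = arr.mean(axis=0)
    n_center = len(pool)
    x = center.copy()
    # dense orthogonal projector onto {S v = 0}: applied every step so
    # rounding drift can never accumulate (steps with bound magnitudes up
    # to 1e3 amplify even 1e-12 residuals over long chains otherwise)
    projector = nullspace @ nullspace.T
    kept = np.empty((n_keep, model.n_reactions))
    n_kept = 0
    step = 0
    while n_kept < n_keep:
        for _ in range(MAX_DIRECTION_RETRIES):
            p = pool[rng.integers(len(pool))]
            d = p - center
            norm = np.linalg.norm(d)
            if norm < 1e-8:
                continue
            d = d / norm
            amin, amax = _chord_interval(x, d, lb, ub)
            if amax - amin > DEGENERATE_TOL:
                break
        else:
            raise RuntimeError(
                "no usable hit-and-run direction after "
                f"{MAX_DIRECTION_RETRIES} retries (degenerate polytope?)"
            )
        x = projector @ (x + rng.uniform(amin, amax) * d)
        # clamp float noise so tiny bound violations cannot empty later
        # chord intervals; corrections are ~1e-15 and re-projected next step
        np.clip(x, lb, ub, out=x)
        # artificial centering: the center tracks all accepted points
        n_center += 1
        center = center + (x - center) / n_center
        step += 1
        if step % thinning == 0:
            kept[n_kept] = x
            pool.append(x.copy())
            n_kept += 1
    return kept


def sample_chains(
    model: MetabolicModel,
    n_samples: int,
    thinning: int = 100,
    seed: int = 0,
    n_chains: int = 1,
    warmup_count: int | None = None,
) -> list:
    """Run ``n_chains`` independent ACHR chains of ``n_samples`` each.

    Chains share the warm-up vertex set but use independent sub-streams
    spawned deterministically from the master seed.
    """
    if n_samples < 1 or thinning < 1 or n_chains < 1:
        raise ValueError("n_samples, thinning and n_chains must be positive")
    if warmup_count is None:
        warmup_count = max(4, 2 * min(model.n_reactions, 50))
    if warmup_count % 2:
        warmup_count += 1
    warmup = generate_warmup(model, warmup_count)
    ns = null_space(model.S)
    digest = model.digest()
    streams = np.random.SeedSequence(seed).spawn(n_chains)
    chains = []
    for ci, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        kept = _achr_chain(model, warmup, n_samples, thinning, rng, ns)
        chains.append(
            FluxSamples(
                matrix=kept,
                reaction_ids=list(model.reaction_ids),
                meta={
                    "seed": seed,
                    "chain": ci,
                    "n_chains": n_chains,
                    "thinning": thinning,
                    "model_digest": digest,
                },
            )
        )
    return chains


def sample_fluxes(
    model: MetabolicModel,
    n_samples: int,
    thinning: int = 100,
    seed: int = 0,
    n_chains: int = 1,
    warmup_count: int | None = None,
) -> FluxSamples:
    """Uniform flux samples, concatenated across chains to ``n_samples`` rows."""
    per_chain = -(-n_samples // n_chains)  # ceil
    chains = sample_chains(model, per_chain, thinning, seed, n_chains, warmup_count)
    matrix = np.vstack([c.matrix for c in chains])[:n_samples]
    return FluxSamples(
        matrix=matrix,
        reaction_ids=list(model.reaction_ids),
        meta={
            "seed": seed,
            "n_chains": n_chains,
            "thinning": thinning,
            "model_digest": model.digest(),
        },
    )


def validate_samples(
    model: MetabolicModel,
    samples: FluxSamples,
    tol_mass_balance: float = TOL_MASS_BALANCE,
    tol_bounds: float = TOL_BOUNDS,
) -> bool:
    """True iff every row is mass-balanced and within bounds (with tolerance)."""
    V = samples.matrix
    if np.max(np.abs(model.S @ V.T), initial=0.0) > tol_mass_balance:
        return False
    if np.any(V < model.lb - tol_bounds) or np.any(V > model.ub + tol_bounds):
        return False
    return True


def write_samples_tsv(samples: FluxSamples, path) -> None:
    """Persist samples as TSV (reaction ids as header) with a YAML sidecar
    carrying the provenance meta block."""
    import yaml

    samples.to_frame().to_csv(path, sep="\t", index=False)
    with open(f"{path}.meta.yaml", "w") as fh:
        yaml.safe_dump(samples.meta, fh, sort_keys=True)


def read_samples_tsv(path) -> FluxSamples:
    import os

    import yaml

    df = pd.read_csv(path, sep="\t")
    meta = {}
    sidecar = f"{path}.meta.yaml"
    if os.path.exists(sidecar):
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
    return FluxSamples(df.to_numpy(dtype=float), list(df.columns), meta)


def convergence_diagnostics(chains: list) -> ConvergenceReport:
    """Running means and Gelman-Rubin PSRF per reaction.

    PSRF = sqrt((((n-1)/n) W + B/n) / W) with W the mean within-chain
    variance and B = n * variance of the chain means.  Reactions with zero
    within-chain variance get PSRF 1 when the chain means agree and +inf
    (divergent) when they do not.
    """
    if not chains:
        raise ValueError("at least one chain required")
    lengths = {c.n_samples for c in chains}
    if len(lengths) != 1:
        raise ValueError("chains have unequal lengths")
    n = lengths.pop()
    rxns = chains[0].reaction_ids
    running = []
    for c in chains:
        counts = np.arange(1, n + 1)[:, None]
        running.append(np.cumsum(c.matrix, axis=0) / counts)

    if len(chains) >= 2:
        mats = np.asarray([c.matrix for c in chains])  # chains x n x r
        chain_means = mats.mean(axis=1)
        W = mats.var(axis=1, ddof=1).mean(axis=0)
        B = n * chain_means.var(axis=0, ddof=1)
        var_hat = (n - 1) / n * W + B / n
        with np.errstate(divide="ignore", invalid="ignore"):
            psrf = np.sqrt(var_hat / W)
        # values below 1 (e.g. identical chains, where B = 0 deflates the
        # pooled variance by (n-1)/n) are estimation artifacts: floor at 1
        psrf = np.maximum(psrf, 1.0)
        zero_w = W <= 0
        psrf[zero_w & (B <= DEGENERATE_TOL)] = 1.0
        psrf[zero_w & (B > DEGENERATE_TOL)] = np.inf
    else:
        psrf = np.full(len(rxns), np.nan)

    return ConvergenceReport(
        reaction_ids=list(rxns),
        psrf=psrf,
        running_means=running,
        n_chains=len(chains),
        n_samples=n,
    )
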