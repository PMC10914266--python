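"""Score and rank exchanged metabolites from WT/MUT flux samples.

For each exchange reaction the two conditions give two sampled flux
distributions.  A *difference distribution* is formed by subtracting random,
unmatched pairs of values (MUT minus WT, indices drawn independently with
replacement), and the score is the z-score

    z = mean(dd) / sd(dd)

with the population standard deviation.  Positive z means the metabolite's
export increased (or import decreased) from WT to MUT; negative means the
opposite; z near 0 means the distributions barely moved.  Metabolites are
ranked by descending |z|, so rank 1 is the exchange predicted to change the
most.  Exchanges whose FVA interval is [0, 0] in both conditions are
*blocked* and reported unscored, as are metabolites without an exchange
reaction or absent from the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fva import FvaResult
from .model import MetabolicModel, identify_exchanges
from .sampling import FluxSamples

__all__ = [
    "DifferenceDistribution",
    "ExchangeScore",
    "MetabolicProfile",
    "difference_distribution",
    "z_score",
    "alt_metrics",
    "score_exchanges",
    "rank_by_abs_z",
]

#: finite stand-in for mean/0 z-scores so the ranking stays total
Z_SENTINEL = 1e9
#: |z| below this is direction "none"
DIRECTION_EPS = 1e-12
#: fold-change sentinel for x/0
FOLD_SENTINEL = 1e9


@dataclass
class DifferenceDistribution:
    values: np.ndarray
    reaction_id: str = ""
    seed: int | None = None

    def __len__(self):
        return len(self.values)


@dataclass
class ExchangeScore:
    metabolite_id: str
    exchange_reaction_id: str | None
    z: float | None = None
    direction: str = "none"  # increase | decrease | none
    rank: int | None = None
    status: str = "scored"  # scored | blocked | no_exchange | absent
    mean_diff: float | None = None
    median_diff: float | None = None
    fold_change: float | None = None
    degenerate: bool = False
    bimodal_warning: bool = False
    sign_flipped: bool = False


@dataclass
class MetabolicProfile:
    condition: str
    scores: list
    meta: dict = field(default_factory=dict)

    @property
    def n_scored(self) -> int:
        return sum(1 for s in self.scores if s.status == "scored")

    def score_for(self, metabolite_id) -> ExchangeScore:
        for s in self.scores:
            if s.metabolite_id == metabolite_id:
                return s
        raise KeyError(metabolite_id)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.scores:
            rows.append(
                {
                    "metabolite_id": s.metabolite_id,
                    "exchange_reaction_id": s.exchange_reaction_id,
                    "z_score": s.z,
                    "abs_z": abs(s.z) if s.z is not None else None,
                    "rank": s.rank,
                    "direction": s.direction,
                    "status": s.status,
                    "mean_diff": s.mean_diff,
                    "median_diff": s.median_diff,
                    "fold_change": s.fold_change,
                    "degenerate": s.degenerate,
                    "bimodal_warning": s.bimodal_warning,
                }
            )
        df = pd.DataFrame(rows)
        if len(df):
            df = df.sort_values(
                ["rank"], na_position="last", kind="mergesort"
            ).reset_index(drop=True)
        return df


def difference_distribution(
    wt_values,
    mut_values,
    n_pairs: int | None = None,
    seed: int = 0,
    rng: np.random.Generator | None = None,
    reaction_id: str = "",
) -> DifferenceDistribution:
    """MUT-minus-WT differences over random unmatched index pairs.

    Pairs are drawn independently and with replacement, so ``n_pairs`` is
    free of the sample counts; it defaults to the number of samples.
    """
    wt = np.asarray(wt_values, dtype=float)
    mut = np.asarray(mut_values, dtype=float)
    if wt.size == 0 or mut.size == 0:
        raise ValueError("empty sample column")
    if n_pairs is None:
        n_pairs = max(wt.size, mut.size)
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    i = rng.integers(wt.size, size=n_pairs)
    j = rng.integers(mut.size, size=n_pairs)
    return DifferenceDistribution(mut[j] - wt[i], reaction_id, seed)


def z_score(dd: DifferenceDistribution, sentinel: float = Z_SENTINEL) -> float:
    """Mean over population standard deviation of the difference distribution.

    A zero-spread distribution is degenerate: z is 0 for zero mean, else a
    signed finite sentinel (keeps the |z| ranking total).
    """
    values = np.asarray(dd.values if isinstance(dd, DifferenceDistribution) else dd,
                        dtype=float)
    if values.size == 0:
        raise ValueError("empty difference distribution")
    mu = values.mean()
    sd = values.std()  # population sd
    if sd == 0:
        return 0.0 if mu == 0 else float(np.sign(mu)) * sentinel
    return float(mu / sd)


def alt_metrics(wt_values, mut_values) -> tuple:
    """(mean difference, median difference, fold change of means)."""
    wt = np.asarray(wt_values, dtype=float)
    mut = np.asarray(mut_values, dtype=float)
    mean_diff = float(mut.mean() - wt.mean())
    median_diff = float(np.median(mut) - np.median(wt))
    mw, mm = wt.mean(), mut.mean()
    if mw == 0:
        fold = None if mm == 0 else float(np.sign(mm)) * FOLD_SENTINEL
    else:
        fold = float(mm / mw)
    return mean_diff, median_diff, fold


def _bimodality_flag(values: np.ndarray) -> bool:
    """Sarle's bimodality coefficient > 5/9 (the uniform's value) flags
    multi-modal MUT distributions that a mean/sd score may misrepresent."""
    v = np.asarray(values, dtype=float)
    if v.size < 4 or v.std() == 0:
        return False
    centered = v - v.mean()
    s = v.std()
    skew = np.mean(centered**3) / s**3
    kurt = np.mean(centered**4) / s**4
    return bool((skew**2 + 1) / kurt > 5 / 9 + 0.05)


def _direction(z: float) -> str:
    if z > DIRECTION_EPS:
        return "increase"
    if z < -DIRECTION_EPS:
        return "decrease"
    return "none"


def score_exchanges(
    wt: FluxSamples,
    mut: FluxSamples,
    model: MetabolicModel,
    wt_fva: FvaResult | None = None,
    mut_fva: FvaResult | None = None,
    n_pairs: int | None = None,
    seed: int = 0,
    condition: str = "condition",
    requested_metabolites=None,
) -> MetabolicProfile:
    """Score every exchanged metabolite and rank by |z|.

    ``wt_fva``/``mut_fva`` supply the blocked rule: an exchange with FVA
    interval [0, 0] in *both* conditions cannot carry flux and is reported
    with status ``blocked`` and no score.  Exchanges written with a +1
    stoichiometric coefficient have their fluxes sign-flipped so positive
    always means export.  ``requested_metabolites`` (optional) adds rows
    with status ``absent`` / ``no_exchange`` for metabolites the caller
    asked about that cannot be scored structurally.
    """
    if list(wt.reaction_ids) != list(mut.reaction_ids):
        raise ValueError("WT and MUT samples cover different reactions")
    exchanges = identify_exchanges(model)
    if not exchanges:
        raise ValueError("model has no exchange reactions")

    scores = []
    seen_metabolites = set()
    ss = np.random.SeedSequence(seed)
    for k, rid in enumerate(sorted(exchanges)):
        flipped = exchanges[rid]
        met = model.exchanged_metabolite(rid)
        seen_metabolites.add(met)
        if rid not in wt.reaction_ids:
            raise ValueError(f"exchange {rid!r} missing from samples")

        if (
            wt_fva is not None
            and mut_fva is not None
            and wt_fva.is_blocked(rid)
            and mut_fva.is_blocked(rid)
        ):
            scores.append(
                ExchangeScore(met, rid, status="blocked", sign_flipped=flipped)
            )
            continue

        sign = -1.0 if flipped else 1.0
        wt_col = sign * wt.column(rid)
        mut_col = sign * mut.column(rid)
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(k,)))
        dd = difference_distribution(
            wt_col, mut_col, n_pairs=n_pairs, rng=rng, reaction_id=rid
        )
        z = z_score(dd)
        mean_diff, median_diff, fold = alt_metrics(wt_col, mut_col)
        scores.append(
            ExchangeScore(
                metabolite_id=met,
                exchange_reaction_id=rid,
                z=z,
                direction=_direction(z),
                status="scored",
                mean_diff=mean_diff,
                median_diff=median_diff,
                fold_change=fold,
                degenerate=abs(z) >= Z_SENTINEL,
                bimodal_warning=_bimodality_flag(mut_col),
                sign_flipped=flipped,
            )
        )

    if requested_metabolites:
        model_mets = set(model.metabolite_ids)
        for met in requested_metabolites:
            if met in seen_metabolites:
                continue
            status = "no_exchange" if met in model_mets else "absent"
            scores.append(ExchangeScore(met, None, status=status))

    profile = MetabolicProfile(
        condition=condition,
        scores=scores,
        meta={"seed": seed, "n_pairs": n_pairs,
              "wt_meta": dict(wt.meta), "mut_meta": dict(mut.meta)},
    )
    return rank_by_abs_z(profile)


def profile_from_frame(df: pd.DataFrame, condition: str = "condition") -> MetabolicProfile:
    """Rebuild a profile from its TSV/DataFrame serialization."""
    scores = []
    for _, row in df.iterrows():
        rank = row.get("rank")
        z = row.get("z_score")
        scores.append(
            ExchangeScore(
                metabolite_id=row["metabolite_id"],
                exchange_reaction_id=row.get("exchange_reaction_id"),
                z=None if pd.isna(z) else float(z),
                direction=row.get("direction", "none"),
                rank=None if pd.isna(rank) else int(rank),
                status=row.get("status", "scored"),
            )
        )
    return MetabolicProfile(condition=condition, scores=scores)


def rank_by_abs_z(profile: MetabolicProfile) -> MetabolicProfile:
    """Assign ranks 1..n_scored by descending |z|; ties break on the
    exchange reaction id (ascending) so the ordering is deterministic."""
    scored = [s for s in profile.scores if s.status == "scored"]
    scored.sort(key=lambda s: (-abs(s.z), s.exchange_reaction_id))
    for i, s in enumerate(scored, start=1):
        s.rank = i
    for s in profile.scores:
        if s.status != "scored":
            s.rank = None
    return profile
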