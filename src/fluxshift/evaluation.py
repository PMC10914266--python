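"""Evaluate predicted metabolic profiles against observed metabolite changes.

Two complementary statistics:

* directional accuracy — among observed metabolites that match a prediction
  (optionally restricted to the top-n ranks), the fraction whose predicted
  change direction agrees with the observed one.  Predictions without a
  matching observation are disregarded entirely (false positives are not
  evaluable in metabolomics truth sets, and false negatives are likewise
  ignored by this score).

* hypergeometric enrichment — the probability of recovering at least k
  observed metabolites within the top n of N ranked predictions when K of
  them are observed, i.e. the survival tail P(X >= k) of a
  hypergeometric(N, K, n) variable.  Scanning cut-offs traces the
  significance of the ranking as a whole.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .scoring import MetabolicProfile

__all__ = [
    "ObservedSet",
    "EvaluationResult",
    "hypergeometric_enrichment",
    "accuracy_score",
    "rank_cutoff_scan",
    "read_observed_tsv",
]


@dataclass
class ObservedSet:
    """Observed differential metabolites with change directions."""

    directions: dict  # metabolite id -> increase | decrease | unknown
    source: str = ""

    def __post_init__(self):
        bad = {d for d in self.directions.values()} - {"increase", "decrease", "unknown"}
        if bad:
            raise ValueError(f"unknown observed directions: {sorted(bad)}")

    @property
    def metabolite_ids(self) -> set:
        return set(self.directions)

    def __len__(self):
        return len(self.directions)


@dataclass
class EvaluationResult:
    cutoff: int
    k: int  # observed metabolites within the top-cutoff predictions
    K: int  # observed metabolites mappable to scored predictions
    N: int  # scored predictions
    p_value: float
    accuracy: float | None


def hypergeometric_enrichment(N: int, K: int, n: int, k: int) -> float:
    """Survival probability P(X >= k), X ~ hypergeometric(N, K, n).

    Summed in log space (logsumexp over log-pmf terms) so deep tails at
    genome scale (N in the thousands) do not underflow.
    """
    if not (0 <= K <= N):
        raise ValueError(f"need 0 <= K <= N, got K={K}, N={N}")
    if not (0 <= n <= N):
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"need 0 <= k <= min(n, K), got k={k}")
    if k == 0:
        return 1.0
    support = np.arange(k, min(n, K) + 1)
    logp = hypergeom.logpmf(support, N, K, n)
    return float(min(1.0, np.exp(logsumexp(logp))))


def _top_predictions(profile: MetabolicProfile, cutoff: int | None):
    scored = [s for s in profile.scores if s.status == "scored"]
    if cutoff is None:
        return scored
    return [s for s in scored if s.rank is not None and s.rank <= cutoff]


def accuracy_score(
    profile: MetabolicProfile, observed: ObservedSet, cutoff: int | None = None
) -> float | None:
    """Direction agreement among matched observed metabolites.

    Restricts predictions to the top ``cutoff`` ranks (all when None),
    matches observations by metabolite id, and returns
    (#direction-agreeing matches) / (#matches with a predicted direction).
    Observations with unknown direction are excluded from the denominator;
    no matches at all yields None, not zero.
    """
    if not len(observed):
        raise ValueError("observed set is empty")
    agree = total = 0
    for s in _top_predictions(profile, cutoff):
        obs_dir = observed.directions.get(s.metabolite_id)
        if obs_dir is None or obs_dir == "unknown":
            continue
        if s.direction not in ("increase", "decrease"):
            continue
        total += 1
        agree += s.direction == obs_dir
    return agree / total if total else None


def rank_cutoff_scan(
    profile: MetabolicProfile, observed: ObservedSet, cutoffs
) -> list:
    """Enrichment and accuracy at each rank cut-off.

    N = scored predictions, K = observed metabolites among them; for each
    cutoff n, k counts observed metabolites in the top n and the p-value is
    the hypergeometric survival tail.
    """
    scored = [s for s in profile.scores if s.status == "scored"]
    N = len(scored)
    scored_ids = {s.metabolite_id for s in scored}
    K = len(observed.metabolite_ids & scored_ids)
    results = []
    for n in sorted(set(int(c) for c in cutoffs)):
        if not 1 <= n <= N:
            raise ValueError(f"cutoff {n} outside [1, {N}]")
        top_ids = {s.metabolite_id for s in scored if s.rank <= n}
        k = len(observed.metabolite_ids & top_ids)
        results.append(
            EvaluationResult(
                cutoff=n,
                k=k,
                K=K,
                N=N,
                p_value=hypergeometric_enrichment(N, K, n, k),
                accuracy=accuracy_score(profile, observed, cutoff=n),
            )
        )
    return results


def read_observed_tsv(path, source: str | None = None) -> ObservedSet:
    """Load an observed-set TSV with columns metabolite_id, direction."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "metabolite_id" not in df.columns:
        raise ValueError("observed TSV needs a metabolite_id column")
    directions = {}
    for _, row in df.iterrows():
        mid = row["metabolite_id"]
        if mid in directions:
            raise ValueError(f"duplicate observed metabolite: {mid!r}")
        directions[mid] = (row.get("direction") or "unknown").strip().lower()
    return ObservedSet(directions, source or str(path))


def scan_to_frame(results: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"cutoff": r.cutoff, "k": r.k, "K": r.K, "N": r.N,
             "p_value": r.p_value, "accuracy": r.accuracy}
            for r in results
        ]
    )
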