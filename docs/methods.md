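# Methods

## Model representation

A model is the tuple (metabolites, reactions, `S`, `lb`, `ub`, GPR rules,
objective). Steady state means `S·v = 0`; flux units are mmol/gDW/h by
convention but nothing depends on them. Exchange reactions are detected
**structurally** — exactly one nonzero stoichiometric entry — never by name
prefix, so synthetic fixtures and both file dialects (SBML L3+fbc via
python-libsbml, COBRA JSON) behave identically. The sign convention is
coefficient −1 on the exchanged metabolite, so positive flux is export and
negative flux is import; a boundary reaction written with +1 is accepted and
carries a sign-flip flag that the scorer applies before computing
directions. Bounds missing from a file default to ±1000, the conventional
"unbounded" magnitude in constraint-based modelling.

GPR rules are boolean AND/OR trees over gene identifiers (AND = complex
subunits, OR = isozymes). Parsing is case-insensitive on the connectives and
treats any other token as a gene id, since identifier syntax differs between
dialects. An empty rule means "not gene-associated": such a reaction is
never knocked out via genes.

## Condition construction

Order of operations: medium → biomass → forcing (WT) / knockout-knockdown
(MUT). The medium parameter `X ≥ 0` sets every exchange to `[-X, 1000]`
(default `X = 1`; `None` keeps the model's own bounds). The biomass
constraint maximizes the named reaction once on the medium-applied base
model and pins its lower bound to `fraction · optimum`; the default fraction
is 0, which leaves the bound at `max(0, lb)`. Because the base model is
shared, WT and MUT differ **only** in the bounds of the affected reactions
— an invariant the tests check field by field.

WT forcing processes affected reactions one at a time in lexicographic
order, each LP seeing the forcings already applied (a joint single-LP
variant is available via `forcing_mode="joint"`; sequential is the default
because it is reproducible and makes each bound attributable to one LP). For
each reaction: maximize; if the maximum exceeds 1e-6, set
`lb ← 0.05 · vmax`; otherwise minimize and, if the minimum is below −1e-6,
set `ub ← 0.05 · vmin`. Reactions blocked in both directions are recorded
as unforceable and left untouched with a warning — knocking them out still
yields a valid MUT, but the two states may then be indistinguishable on
that reaction. Knockdown scales both bounds multiplicatively by the retained
fraction, which reduces the maximum capacity of an irreversible reaction
while leaving its zero lower bound unchanged.

## Uniform sampling

The sampler is an artificial-centering hit-and-run chain in the optGP
style. Warm-up points are FVA vertices (per-reaction maxima and minima,
cycling until the requested count); all are projected exactly onto
`{S·v = 0}` before use, because LP solutions carry ~1e-9 residuals that
direction normalization would otherwise amplify. Each step picks a stored
point (warm-up ∪ kept samples) minus the running center of all accepted
points as direction, computes the feasible chord from the bounds, and draws
the step uniformly on it. Every `thinning`-th point is kept (default 100;
the conventional genome-scale setting is 100 000 samples at thinning 100,
while fixtures use ~1 000–10 000 at thinning 5–10). Chains are independent
given sub-streams spawned deterministically from the master seed, and
identical seeds reproduce samples bit for bit.

Numerical choices that matter:

* the current point is re-projected onto the null space of `S` **every
  step** via a precomputed orthogonal projector. With bound magnitudes up
  to 1e3, even 1e-12 per-step residuals would otherwise accumulate past the
  1e-6 mass-balance tolerance over long chains. The dense projector is
  O(n²) per step, perfectly cheap at fixture scale; genome-scale models
  would want a sparse factorization instead (known limitation).
* after each step the point is clamped to the bounds; corrections are
  ~1e-15 and exist only so that accumulated float noise cannot make every
  subsequent chord interval empty.
* direction components below 1e-10 are ignored in the chord computation
  (they cannot move the point meaningfully but would collapse the interval
  on `[c, c]` bounds); chords narrower than 1e-12 cause the direction to be
  resampled, up to 100 retries. A polytope whose warm-up vertices all
  coincide is a single point: the sampler returns identical rows with a
  warning rather than failing.

Convergence is reported as per-reaction running means and the Gelman–Rubin
potential scale reduction factor
`PSRF = sqrt((((n−1)/n)·W + B/n) / W)` with `W` the mean within-chain
variance and `B = n · var(chain means)`. Values below 1 are estimation
artifacts (identical chains give `sqrt((n−1)/n)`) and are floored at 1;
zero-variance reactions report 1 when the chain means agree and +inf when
they do not.

## Scoring

For each unblocked exchange the difference distribution draws index pairs
independently and **with replacement** (the pairing is unmatched by design;
with-replacement keeps the number of pairs free of the sample counts), with
`n_pairs` defaulting to the number of samples. The z-score is
`mean/sd` with the **population** standard deviation — at typical sample
counts the distinction from the sample sd is negligible, but fixing it makes
results deterministic. A zero-spread distribution is degenerate: z is 0 for
zero mean, otherwise a signed finite sentinel (1e9) so the |z| ranking stays
total; degenerate entries are flagged. Direction is the sign of z, with
|z| < 1e-12 reported as "none". Ranking sorts scored entries by descending
|z| with ties broken by exchange reaction id, so ranks are a permutation of
1..n_scored and deterministic. Blocked means FVA `[0, 0]` in **both**
conditions — an exchange blocked only in MUT (e.g. downstream of a
knockout) is precisely the signal the method exists to score. Auxiliary
metrics (mean difference, median difference, fold change of means) are
reported per exchange; fold change guards 0/0 as missing and x/0 as a
signed sentinel.

A z-score compares means scaled by spread, so a shift into a *bimodal*
mutant distribution with an unchanged mean is invisible to it. No
alternative statistic is provided; instead each exchange carries a warning
flag when Sarle's bimodality coefficient of the MUT samples exceeds the
uniform-distribution value 5/9 (plus a 0.05 margin against false alarms on
flat marginals).

## FVA comparator

`run_fva` is plain per-reaction LP minimization/maximization (optionally
with the objective held at a fraction of its optimum; the default fraction
0 means unconstrained). The direction call takes
`dmax = mut.max − wt.max` and `dmin = mut.min − wt.min`, keeps whichever
has the larger absolute value (exact ties resolve toward the upper bound),
and reports increase/decrease only when that magnitude exceeds
`max(1e-6, 0.01 · |WT bound on that side|)`. Raw bound differences are
used, not width-normalized ones. The call is antisymmetric under swapping
the two states.

## Evaluation

Directional accuracy restricts predictions to the top-n ranks, matches
observations by exact metabolite id (synonym mapping is the caller's
responsibility), and scores agreement only over matched pairs with a known
observed direction — unmatched predictions (potential false positives) and
unmatched observations (false negatives) are excluded by definition, and
zero matches yields "no score", not 0. The hypergeometric tail is the
inclusive survival probability `P(X ≥ k)` computed by logsumexp over
log-pmf terms, so deep tails at genome scale do not underflow; tests pin it
against exact rational enumeration for all populations up to 30.

## Synthetic fixtures

`toy_network` is a fixed 6-metabolite, 10-reaction, 4-exchange network with
one gene-carrying reaction feeding a dedicated export branch, chosen so the
knockout's consequences are hand-checkable by LP. `random_viable_network`
grows a spanning tree from one imported nutrient, adds random forward
shortcut edges (unit coefficients only, keeping LP oracles hand-checkable),
places exports on reachable leaves, verifies every exchange can carry flux
in the medium, and picks as perturbation target an internal reaction whose
knockout moves at least one exchange's FVA interval beyond the 1e-6/0.01
thresholds.

The planted truth is derived from FVA on the **actual WT/MUT condition
pair** (forced WT vs knockout MUT), not on the unforced base model: the
sampled states include the forcing, and a bypass branch that absorbs the
forced flux genuinely shifts — labelling it "unaffected" would make the
recovery tests check the wrong claim. Because the truth is FVA-derived it
is exact and solver-deterministic, at the price of inheriting the
comparator's thresholds.

What a green recovery test establishes: on small, fully connected,
unit-coefficient networks with a single knockout, truly affected exchanges
dominate the top ranks. What it does not establish: behavior under loops
and cofactor coupling, fractional stoichiometry, multi-gene perturbations,
realistic biomass objectives, or genome-scale mixing times — all absent
from the generator by design.

## Defaults

| parameter | default | meaning |
| --- | --- | --- |
| `medium_uptake_X` | 1 | exchange bounds `[-X, 1000]` |
| `biomass_fraction` | 0 | minimum fraction of biomass optimum |
| `forcing_fraction` | 0.05 | WT flux floor as share of attainable extreme |
| `n_samples` | 100 000 | kept samples per state (fixtures: ~1 000) |
| `thinning` | 100 | keep every k-th point (fixtures: 5–10) |
| `n_chains` | 2 | enables PSRF reporting |
| FVA call thresholds | 1e-6 / 0.01 | absolute / relative change floor |
| mass balance / bounds tolerance | 1e-6 | sample validation |
| `Z_SENTINEL` | 1e9 | stand-in for zero-spread z |

## Known limitations

* The per-step dense null-space projector and pure-Python chain loop target
  fixture-scale models; genome-scale use needs a sparse projector and a
  compiled inner loop.
* The z-score misses mean-preserving distributional changes (only flagged,
  not solved).
* Knockdown scales bounds multiplicatively; regulatory effects that change
  flux *direction* preferences are out of scope.
* Whether the reference approach pairs samples with or without replacement
  is unspecified in the literature the defaults follow; with-replacement is
  this package's choice and is recorded in profile metadata.
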