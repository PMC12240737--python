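# Methods

## Problem model

The package treats lead optimization as a constrained multi-objective
problem over molecules x:

    maximize  F(x) = (f1(x), ..., fm(x))
    subject to  sigma_c(x) = 0  for every constraint c,

where each f is a molecular property (QED, penalized-logP improvement over
the lead, Tanimoto similarity to the lead, normalized synthetic
accessibility, or a user plug-in such as a docking or activity surrogate)
and each sigma_c is a non-negative violation degree, zero exactly when the
constraint is satisfied. Objectives are stored maximization-oriented;
a minimize-direction objective is negated once, at evaluation, and nowhere
else. Two structural constraints ship with the package:

* **Ring size** — every ring (smallest set of smallest rings) should have 5
  or 6 atoms; the violation is the summed distance of every ring size r
  from that window, `sum_k max(r_k - 6, 0) + max(5 - r_k, 0)`. SSSR is the
  ring perception; fused systems can differ under alternative perceptions,
  which is why the choice is pinned here.
* **Structural alerts** — the number of *distinct* alert SMARTS patterns
  with at least one match in the molecule (set cardinality, not instance
  count; an instance-counting switch exists). The packaged list is a
  curated ~30-pattern subset of widely recognized reactive/toxic motifs;
  production screens should substitute a task-specific published deck via
  the alerts file.

For selection, per-constraint violations over the current molecule set psi
(the parent∪offspring union at the moment of selection) are aggregated by
max-normalization: each constraint column is divided by its maximum over
psi and the normalized columns are summed. A column whose maximum is zero
contributes nothing (an all-feasible constraint carries no discriminating
information). Feasibility is always decided on *raw* sigmas, so the
normalization never changes which molecules count as feasible.

## Search space and codecs

Search happens in the continuous space of an encoder-decoder codec.
Production use plugs in a pretrained generative codec (typically ~512
dimensions); the package ships two deterministic mocks so the entire loop is
testable without weights:

* `TableCodec` — a finite molecule world: exact lookup encoding,
  nearest-neighbour (Euclidean, lowest-index ties) decoding, unit-hypercube
  bounds, CSV serialization.
* `IdentityCodec` — "molecules" are coordinate strings; used by the
  analytic problem below.

Decoded batches are validity-filtered: decode failures and unparsable
strings are dropped, survivors canonicalized, and duplicates removed both
within the batch and (by default) against the current parent population.
The parent-dedupe default matters for nearest-neighbour mock decoding,
where many latent vectors decode to the same molecule and a population can
otherwise collapse onto copies of one structure.

## Reproduction

Offspring are produced pairwise: two distinct parents drawn uniformly, a
blended linear crossover `z' = z1 + (-d + (1+2d)u)(z2 - z1)` with fresh
u ~ U(0,1) per child, then fragmentation-based mutation of each child. The
mutation partitions the vector into `n_frag` contiguous near-equal
fragments (the first `D mod n_frag` are one gene longer), picks one
fragment uniformly, and perturbs each of its genes independently with
probability `p_m` by additive Gaussian noise; everything outside the chosen
fragment is untouched, and results are clamped to codec bounds. The
numeric form of the perturbation is a design choice of this package
(standard real-coded EA practice); its scale defaults to 0.1 of the
per-dimension bound range, or 0.1 absolute when the codec declares no
bounds.

Defaults: `d = 0.25` (the classic blend setting), `p_m = 0.5`,
`n_frag = 8`. The driver caps `n_frag` at the codec dimension so the same
defaults serve both 512-d production codecs and 2-d mock worlds. Mating is
uniform random pairing without self-pairing — no tournament.

## Initialization

A bank library is screened from a candidate database: keep molecules with
Tanimoto similarity to the lead >= `sim_min` and screening property
(default QED) >= `prop_min`, rank by property then similarity then input
order, take the top B, and encode them. The initial population crosses the
lead's latent vector with each bank member's in turn, decoding and
validity-filtering until P distinct molecules are collected (retry budget
10·P draws), padding with copies of the lead on shortfall. Package
defaults: `sim_min = 0.2`, appropriate for ZINC-scale databases where
thousands of candidates pass. The packaged toy world overrides this with
`sim_min = 0.05, prop_min = 0.3` (`fixtures.toy_screen`): random drug-like
pairs score ~0.05–0.15 Morgan-Tanimoto, so in a world of only tens of
molecules the database-scale cutoff empties the bank and forces the
population into duplicate lead copies.

## Two-stage selection

Each generation forms the union of P parents and the validity-filtered
offspring and keeps P survivors.

* **Stage 1 (unconstrained, G1 generations)** — NSGA-II environmental
  selection on objectives only: whole non-dominated fronts are admitted
  while they fit; the boundary front is truncated by discarding its
  smallest-crowding members. Constraints are evaluated and cached for every
  molecule but never consulted by selection (a tested invariant).
* **Stage 2 (constrained, G2 = T generations)** — ranking aggregation.
  Every union member gets a property-preference rank s1 (fronts by Pareto
  dominance, crowding descending within fronts, unique ranks 1..N) and a
  constraint-preference rank s2 (same procedure, fronts by the constraint
  dominance principle: feasible beats infeasible, smaller aggregate CV
  beats larger among infeasible, Pareto dominance decides among feasible;
  crowding still computed on objectives within CDP fronts). The survivors
  are the P smallest comprehensive scores

      S = alpha s1 + (1 - alpha) s2,
      alpha(t) = (1 + cos(t pi / T)) / 2,

  with t counting stage-2 generations from 0 at the stage switch. The
  cosine decay holds alpha near 1 early (property priority, exploiting
  infeasible but high-property molecules), drops fastest mid-stage and
  reaches 0 at t = T, where selection is purely constraint-preference.

Tie-breaking everywhere falls back to stable input index (crowding ties in
stage-1 truncation discard the later index first; stage-2 score ties prefer
the smaller s2, then the smaller index). None of this is forced by the
method — it is what makes runs deterministic and therefore testable. One
RNG stream seeded from the config drives bank order, pairing, blend draws,
fragment choice and mutation noise in a fixed order, so a run is fully
reproducible from (config, seed); two runs with the same seed produce
bitwise-identical result files.

The final deliverable is the feasible subset (all raw sigmas zero) of the
last population. An optional archive accumulates every feasible offspring
ever seen, for users who prefer not to rely on the last generation alone.

## Metrics

* **Success rate** — a lead counts as successfully optimized when its
  result set contains at least one feasible molecule beating every
  per-objective threshold; SR is the fraction of leads that succeed, and
  N_SR counts qualifying molecules per lead.
* **Hypervolume** — computed against the zero reference point on raw
  (unnormalized) maximization-oriented objectives, by a recursive
  last-objective sweep, exact for m <= 4. Coordinates below the reference
  are clipped rather than rejected, since objectives such as PlogP
  improvement are legitimately negative. The per-generation log records
  both the whole-population HV and the feasible-subset HV; the feasible-set
  value is the headline number, since expelling an infeasible
  high-similarity lead necessarily lowers the whole-population figure even
  as the run improves.

## Synthetic test surfaces

* **Analytic line-segment problem** — identity codec on [0,1]^2,
  objectives f1 = z1, f2 = 1 - z1, one constraint restricting z2 to
  [0.3, 0.7]. Every point satisfies f1 + f2 = 1, so the constrained Pareto
  front is the full segment reached inside the band and its hypervolume
  against the origin is exactly 0.5. The reference recovery runs use
  P = 40, G1 = G2 = 30, a 30-point database, an infeasible lead at
  (0.5, 0.1), and five seeds — sizes chosen so a run finishes in seconds
  while leaving the optimizer real work (the lead starts outside the band).
* **Toy molecule world** — n molecules (default 60) drawn seeded from a
  packaged pool of 114 validated drug-like SMILES that deliberately
  includes 3-, 4- and 7-membered-ring molecules and alert-bearing
  molecules, embedded at seeded uniform points of the unit square. The
  embedding is random, not chemically meaningful: the world exercises the
  full encode–vary–decode–filter–select loop without pretrained weights.
  Reference runs use P = 20, G1 = G2 = 15 and three seeds. Passing on this
  world demonstrates the loop's constraint handling and bookkeeping, not
  chemical realism — with a real codec the latent space is smooth and
  duplicates are rare, neither of which is true of a 60-entry
  nearest-neighbour table.

## Numerical and degenerate-input choices

* Feasibility tolerance is exact zero (both built-in sigmas are
  integer-valued); a tolerance argument exists for plug-in constraints.
* Crowding distance: boundary solutions get +inf per objective;
  zero-range objectives contribute 0; duplicated interior points get 0 via
  zero sorted-neighbour gaps.
* Infeasible molecules with equal CV are incomparable under the constraint
  dominance principle.
* If valid offspring fall short of P, selection proceeds on the smaller
  union; if the union itself is at or below P the whole union survives.
* Penalized logP uses the unstandardized form
  `logP - SA_raw - max(0, largest ring - 6)` by default (no external
  dataset dependency); a ZINC-250k-standardized variant is available by
  flag. Normalized SA maps the raw Ertl 1–10 score to [0,1] higher-better
  as (10 - SA_raw)/9.
* Fingerprints for similarity: Morgan (circular), radius 2, 2048 bits —
  the de-facto community default, configurable.

## Known limitations

* No pretrained codec ships with the package; real-molecule optimization
  quality depends entirely on the plug-in codec's latent geometry.
* Exact hypervolume is exponential in m; practical up to m = 4.
* The packaged alert list is a demonstrative subset, not a complete
  published screening deck.
* Equality constraints are representable through the violation interface
  (sigma = |h|) but no built-in uses one.
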