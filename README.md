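# cmomo

Constrained multi-objective molecular optimization in a continuous latent
space.

Lead optimization in drug discovery rarely means improving one number: a
candidate must trade off several properties at once (drug-likeness,
lipophilicity, similarity to the lead, predicted activity) *and* respect
hard structural criteria — rings of 5 or 6 atoms only, no toxic or
reactive substructures. Treating those criteria as extra objectives dilutes
them; discarding every violator wastes the search signal carried by
infeasible but high-property molecules. This package implements a two-stage
evolutionary optimizer that handles them as genuine constraints with a
dynamically shifting priority.

## Method

The problem is

    maximize  F(x) = (f1(x), ..., fm(x))    subject to  sigma_c(x) = 0,

with each sigma_c a non-negative violation degree (ring-size deviation from
the 5–6 window; count of matched structural-alert SMARTS). Search operates
on latent vectors z of an encoder-decoder codec. Reproduction is a blended
linear crossover

    z' = z1 + (-d + (1 + 2d) u)(z2 - z1),      u ~ U(0, 1),

followed by mutation of one randomly chosen contiguous fragment of the
vector (each gene in the fragment perturbed with probability p_m), which
keeps the effective search dimension small in ~512-d latent spaces.

Selection runs in two stages. The first G1 generations are purely
unconstrained NSGA-II (non-dominated sorting + crowding distance). For the
next G2 = T generations every parent∪offspring union member receives two
ranks — s1 from Pareto dominance on properties alone, s2 from the
constraint dominance principle (feasible ≺ infeasible, smaller aggregate
violation ≺ larger) — and the P smallest comprehensive scores

    S = alpha s1 + (1 - alpha) s2,     alpha = (1 + cos(t pi / T)) / 2,

survive. The cosine decay moves selection pressure smoothly from property
optimization (alpha = 1 at the stage switch) to constraint satisfaction
(alpha = 0 at the final generation), so the population migrates from the
unconstrained Pareto front onto the constrained one instead of being
truncated to it. The result of a run is the feasible subset of the final
population; success rate and hypervolume (zero reference point) are the
built-in evaluation metrics.

No pretrained codec ships with the package. The codec is a plug-in
contract (`dim`, `encode`, `decode`); two deterministic mocks — a
finite-table codec with nearest-neighbour decoding and an identity codec
for analytic problems — make the whole loop runnable and testable offline.

## Worked example

Optimize a nitroimidazole lead inside the packaged 60-molecule toy world
(QED and lead-similarity objectives, ring-size and structural-alert
constraints):

```python
from cmomo import RunConfig, run_cmomo
from cmomo.fixtures import make_toy_world, toy_problem, toy_screen

smiles, codec, thresholds = make_toy_world(seed=1, n=60)
cfg = RunConfig(lead_smiles=smiles[0], P=20, G1=15, G2=15, bank_size=15,
                seed=1, screen=toy_screen(), success_thresholds=thresholds)
res = run_cmomo(cfg, toy_problem(), codec, database=smiles)

g0, gT = res.per_generation_log[0], res.per_generation_log[-1]
print("lead:", smiles[0])
print(f"final population: {len(res.final_population)}  feasible: {len(res.feasible_set)}")
print(f"feasible fraction: {g0['feasible_fraction']:.2f} -> {gT['feasible_fraction']:.2f}")
for r in res.feasible_set[:3]:
    print(f"  {r.smiles}  qed={r.objectives[0]:.3f} sim={r.objectives[1]:.3f}")
```

prints

```
lead: Cc1ncc([N+](=O)[O-])n1CCO
final population: 20  feasible: 20
feasible fraction: 0.90 -> 1.00
  OC(CN1CCC(Cc2ccccc2)CC1)c1ccc(F)cc1  qed=0.907 sim=0.079
  O=C(NCCN1CCOCC1)c1ccc(Cl)cc1  qed=0.898 sim=0.121
  Oc1ccc(Cl)cc1Cc1cc(Cl)ccc1O  qed=0.865 sim=0.087
```

The lead itself carries a nitro structural alert; the run ends with a fully
feasible population of alert-free, 5/6-ring molecules with improved
drug-likeness. (With a 60-molecule world, similarity values stay modest —
the toy world exercises the machinery, not chemical realism; see
`docs/methods.md`.)

There is also a CLI: `cmomo run --config cfg.yaml --seed 1 --out results/`
(YAML config naming the lead, database, codec CSV, objectives and stage
lengths), `cmomo eval --population final_population.csv` to recompute
success counts and hypervolume for a result table, and
`cmomo fixtures --make toy-world --out DIR` to export the toy world.

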