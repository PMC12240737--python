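"""Synthetic test surfaces: an analytic problem with a known constrained
front, and a toy molecule world with a deterministic table codec.

The analytic problem exercises the whole optimizer against a closed-form
answer. Its latent space is the unit square with an identity codec;
objectives are f1 = z1 and f2 = 1 - z1 (every point is Pareto-optimal with
f1 + f2 = 1) and the single constraint restricts z2 to the band
[0.3, 0.7]. The constrained Pareto front is therefore the full segment
{(a, 1-a)} reached only inside the band, and its hypervolume against the
origin is exactly 0.5.

The toy world samples molecules from a packaged pool of drug-like SMILES
(seeded, reproducible) and embeds them at random points of the unit
hypercube via a TableCodec. The embedding is random, not chemically
meaningful: its job is to let the full molecular loop (encode, vary,
decode, filter, select) run without pretrained weights.
"""

from __future__ import annotations

from importlib import resources
from typing import Optional

import numpy as np

from .chem import CanonicalMolecule, ObjectiveSpec, parse_smiles, qed
from .codec import IdentityCodec, TableCodec, identity_parse
from .constraints import AlertLibrary, ConstraintSpec, builtin_constraints
from .errors import BadParams
from .problem import ProblemDefinition


def _coords(m: CanonicalMolecule) -> np.ndarray:
    return IdentityCodec.coords(m.smiles)


def analytic_sigma(m: CanonicalMolecule) -> float:
    """Band constraint on the second coordinate: zero inside [0.3, 0.7]."""
    z2 = _coords(m)[1]
    return max(0.0, 0.3 - z2) + max(0.0, z2 - 0.7)


def make_analytic_problem() -> tuple[ProblemDefinition, IdentityCodec]:
    """The closed-form line-segment problem and its identity codec."""
    objectives = (
        ObjectiveSpec("f1", lambda m, lead: _coords(m)[0]),
        ObjectiveSpec("f2", lambda m, lead: 1.0 - _coords(m)[0]),
    )
    constraints = (ConstraintSpec("band", analytic_sigma),)
    problem = ProblemDefinition(
        objectives=objectives, constraints=constraints, parse=identity_parse
    )
    return problem, IdentityCodec(dim=2)


ANALYTIC_TRUE_HV = 0.5  # hypervolume of {(a, 1-a)} against the origin


def load_toy_pool() -> list[str]:
    """The packaged pool of valid drug-like SMILES (with deliberate
    ring-size and structural-alert violators)."""
    text = resources.files("cmomo.data").joinpath("toy_pool.smi").read_text("utf-8")
    out = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        out.append(line.split("\t")[0].split()[0])
    return out


def make_toy_world(
    seed: int,
    n: int = 60,
    dim: int = 2,
    alerts: Optional[AlertLibrary] = None,
) -> tuple[list[str], TableCodec, dict[str, float]]:
    """A deterministic finite molecule world.

    Draws ``n`` molecules from the packaged pool and embeds them at seeded
    uniform points in [0, 1]^dim. Returns (SMILES list, TableCodec,
    default success thresholds). Thresholds are chosen so that some but not
    all pool molecules can succeed.
    """
    pool = load_toy_pool()
    if n > len(pool):
        raise BadParams(f"n={n} exceeds pool size {len(pool)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    smiles = [parse_smiles(pool[i]).smiles for i in idx]
    # distinct embeddings are guaranteed w.p. 1; regenerate on collision
    while True:
        Z = rng.random((n, dim))
        if len({tuple(row) for row in Z}) == n:
            break
    codec = TableCodec(list(zip(smiles, Z)))
    thresholds = {"qed": 0.55, "similarity": 0.1}
    return smiles, codec, thresholds


def toy_screen():
    """Bank screening criteria for toy-world runs.

    A finite world of tens of molecules cannot support the similarity
    cutoff appropriate for ZINC-scale databases (random drug-like pairs
    score ~0.05-0.15 Morgan-Tanimoto, so a 0.2 cutoff empties the bank
    here); the toy world instead screens on drug-likeness with a token
    similarity floor.
    """
    from .variation import ScreenParams

    return ScreenParams(sim_min=0.05, prop_min=0.3)


def toy_problem(alerts: Optional[AlertLibrary] = None) -> ProblemDefinition:
    """QED + lead-similarity objectives under the two structural constraints."""
    from .chem import tanimoto_similarity

    objectives = (
        ObjectiveSpec("qed", lambda m, lead: qed(m), success_threshold=0.55),
        ObjectiveSpec(
            "similarity",
            lambda m, lead: tanimoto_similarity(m, lead),
            success_threshold=0.1,
        ),
    )
    return ProblemDefinition(
        objectives=objectives, constraints=tuple(builtin_constraints(alerts))
    )
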