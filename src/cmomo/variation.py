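"""Latent-space reproduction: blended linear crossover, fragmentation-based
mutation, and bank-library population initialization.

The reproduction strategy works entirely in the codec's continuous space.
Crossover blends two parent vectors with a scalar factor drawn per child:

    z' = z1 + (-d + (1 + 2 d) u) (z2 - z1),   u ~ Uniform(0, 1)

``d = 0`` interpolates strictly between the parents; ``d > 0`` extrapolates
beyond them by up to a fraction d of the parent gap on each side. Mutation
then partitions the (possibly very long) child vector into ``n_frag``
contiguous fragments, picks one fragment uniformly at random, and perturbs
each of its genes independently with probability ``p_m`` by additive
Gaussian noise — restricting mutation to one fragment keeps the effective
search dimension small when the latent space is large (e.g. 512-d).

Initialization crosses the lead molecule's latent vector with each member of
a "bank" of high-property, lead-similar molecules screened from a candidate
database, so the initial population inherits genes of both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .chem import CanonicalMolecule, parse_smiles, qed, tanimoto_similarity
from .codec import Codec, clamp, decode_valid_batch
from .errors import (
    BadParams,
    DimensionMismatch,
    EmptyDatabase,
    InitializationFailed,
    InvalidSmiles,
    NoSurvivors,
    UnknownMolecule,
)


@dataclass(frozen=True)
class VariationParams:
    """Reproduction parameters, constant within a run.

    d: blend extrapolation parameter (>= 0); 0.25 is the classic setting.
    p_m: per-gene mutation probability within the chosen fragment.
    n_frag: number of contiguous fragments the vector is split into.
    mutation_scale: std of the Gaussian perturbation; ``None`` resolves to
        0.1 x the per-dimension bound range (0.1 absolute when unbounded).
    """

    d: float = 0.25
    p_m: float = 0.5
    n_frag: int = 8
    mutation_scale: Optional[float] = None

    def __post_init__(self):
        if self.d < 0:
            raise BadParams(f"d must be >= 0, got {self.d}")
        if not 0.0 <= self.p_m <= 1.0:
            raise BadParams(f"p_m must be in [0,1], got {self.p_m}")
        if self.n_frag < 1:
            raise BadParams(f"n_frag must be >= 1, got {self.n_frag}")


def _resolve_scale(params: VariationParams, dim: int, bounds) -> np.ndarray:
    if params.mutation_scale is not None:
        return np.full(dim, float(params.mutation_scale))
    if bounds is None:
        return np.full(dim, 0.1)
    lo, hi = bounds
    return 0.1 * (np.asarray(hi, float) - np.asarray(lo, float))


def blend_crossover(
    z1: np.ndarray,
    z2: np.ndarray,
    d: float,
    u1: float,
    u2: float,
    bounds=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Blended linear crossover with scalar blend factors u1, u2 in [0, 1].

    Both children are expressed from z1 along the (z2 - z1) direction; the
    result is clamped to codec bounds when declared.
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if z1.shape != z2.shape:
        raise DimensionMismatch(f"parent shapes differ: {z1.shape} vs {z2.shape}")
    if d < 0:
        raise BadParams(f"d must be >= 0, got {d}")
    diff = z2 - z1
    c1 = z1 + (-d + (1.0 + 2.0 * d) * u1) * diff
    c2 = z1 + (-d + (1.0 + 2.0 * d) * u2) * diff
    return clamp(c1, bounds), clamp(c2, bounds)


def fragment_bounds(dim: int, n_frag: int) -> list[tuple[int, int]]:
    """Contiguous near-equal partition of range(dim) into n_frag fragments.

    The first ``dim % n_frag`` fragments are one gene longer.
    """
    if n_frag > dim:
        raise BadParams(f"n_frag={n_frag} exceeds latent dimension {dim}")
    base, extra = divmod(dim, n_frag)
    out, start = [], 0
    for k in range(n_frag):
        length = base + (1 if k < extra else 0)
        out.append((start, start + length))
        start += length
    return out


def fragment_mutation(
    z: np.ndarray,
    params: VariationParams,
    rng: np.random.Generator,
    bounds=None,
) -> np.ndarray:
    """Mutate one uniformly chosen contiguous fragment of ``z``.

    Each gene in the chosen fragment is perturbed independently with
    probability ``p_m`` by N(0, mutation_scale) noise; all other genes are
    returned bit-identical. The result is clamped to bounds.
    """
    z = np.asarray(z, dtype=float)
    frags = fragment_bounds(z.shape[0], params.n_frag)
    lo_i, hi_i = frags[int(rng.integers(len(frags)))]
    scale = _resolve_scale(params, z.shape[0], bounds)
    out = z.copy()
    width = hi_i - lo_i
    mask = rng.random(width) < params.p_m
    noise = rng.normal(0.0, 1.0, size=width) * scale[lo_i:hi_i]
    out[lo_i:hi_i] = np.where(mask, out[lo_i:hi_i] + noise, out[lo_i:hi_i])
    return clamp(out, bounds)


def generate_offspring(
    parents: Sequence[np.ndarray],
    params: VariationParams,
    rng: np.random.Generator,
    bounds=None,
) -> list[np.ndarray]:
    """Produce exactly P offspring from P parents by crossover + mutation.

    ceil(P/2) times: two distinct parents are drawn uniformly, crossed with
    fresh u1, u2 ~ Uniform(0,1), and both children mutated; the list is
    truncated to P.
    """
    P = len(parents)
    if P < 2:
        raise BadParams(f"need at least 2 parents, got {P}")
    out: list[np.ndarray] = []
    for _ in range(math.ceil(P / 2)):
        i, j = rng.choice(P, size=2, replace=False)
        u1, u2 = rng.random(), rng.random()
        c1, c2 = blend_crossover(parents[i], parents[j], params.d, u1, u2, bounds)
        out.append(fragment_mutation(c1, params, rng, bounds))
        out.append(fragment_mutation(c2, params, rng, bounds))
    return out[:P]


# --------------------------------------------------------------------------
# Bank library and population initialization
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreenParams:
    """Bank screening criteria.

    Candidates must be at least ``sim_min`` Tanimoto-similar to the lead and
    have screening property >= ``prop_min``; survivors are ranked by
    descending property, ties by descending similarity, then input order.
    The screening property defaults to QED.
    """

    sim_min: float = 0.2
    prop_min: float = 0.0
    property_fn: Callable[[CanonicalMolecule], float] = field(default=qed)
    property_name: str = "qed"


@dataclass
class BankLibrary:
    """Screened set of high-property, lead-similar molecules with latents."""

    members: list[tuple[CanonicalMolecule, np.ndarray]]
    provenance: dict

    def __len__(self) -> int:
        return len(self.members)


def build_bank(
    lead: CanonicalMolecule,
    database: Sequence[str],
    codec: Codec,
    bank_size: int,
    screen: ScreenParams = ScreenParams(),
) -> BankLibrary:
    """Screen a SMILES database into a bank of at most ``bank_size`` members.

    Unparsable database entries and molecules the codec cannot encode are
    skipped. If fewer than ``bank_size`` survive the screen, all survivors
    are returned and the shortfall is recorded in the provenance.
    """
    if not database:
        raise EmptyDatabase("candidate database is empty")
    if bank_size < 1:
        raise BadParams(f"bank_size must be >= 1, got {bank_size}")
    scored: list[tuple[float, float, int, CanonicalMolecule]] = []
    for idx, s in enumerate(database):
        try:
            m = parse_smiles(s)
        except (InvalidSmiles, ValueError):
            continue
        sim = tanimoto_similarity(m, lead)
        prop = float(screen.property_fn(m))
        if sim >= screen.sim_min and prop >= screen.prop_min:
            scored.append((prop, sim, idx, m))
    if not scored:
        raise NoSurvivors(
            f"screen (sim >= {screen.sim_min}, {screen.property_name} >= "
            f"{screen.prop_min}) eliminated all {len(database)} candidates"
        )
    scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
    members: list[tuple[CanonicalMolecule, np.ndarray]] = []
    seen: set[str] = set()
    for prop, sim, idx, m in scored:
        if m.smiles in seen:
            continue
        try:
            z = codec.encode(m.smiles)
        except UnknownMolecule:
            continue
        seen.add(m.smiles)
        members.append((m, z))
        if len(members) == bank_size:
            break
    if not members:
        raise NoSurvivors("no screened molecule was encodable by the codec")
    provenance = {
        "sim_min": screen.sim_min,
        "prop_min": screen.prop_min,
        "property": screen.property_name,
        "requested": bank_size,
        "returned": len(members),
        "shortfall": max(0, bank_size - len(members)),
        "database_size": len(database),
    }
    return BankLibrary(members=members, provenance=provenance)


def initialize_latents(
    lead_z: np.ndarray,
    bank: BankLibrary,
    P: int,
    params: VariationParams,
    rng: np.random.Generator,
    codec: Codec,
    parse: Callable[[str], CanonicalMolecule] = parse_smiles,
    retry_factor: int = 10,
) -> list[tuple[CanonicalMolecule, np.ndarray]]:
    """Generate up to P distinct valid molecules by lead-bank crossover.

    Cycles over bank members; each crossover of (lead, member) yields two
    children which are decoded and validity-filtered. Stops when P distinct
    molecules are collected or the retry budget (``retry_factor * P`` draws)
    is exhausted.
    """
    if len(bank) == 0:
        raise InitializationFailed("bank library is empty")
    collected: list[tuple[CanonicalMolecule, np.ndarray]] = []
    seen: set[str] = set()
    draws = 0
    budget = retry_factor * P
    k = 0
    while len(collected) < P and draws < budget:
        _, member_z = bank.members[k % len(bank)]
        k += 1
        u1, u2 = rng.random(), rng.random()
        c1, c2 = blend_crossover(
            lead_z, member_z, params.d, u1, u2, getattr(codec, "bounds", None)
        )
        draws += 2
        for _, m, z in decode_valid_batch(codec, [c1, c2], parse=parse, exclude=seen):
            seen.add(m.smiles)
            collected.append((m, z))
            if len(collected) == P:
                break
    return collected
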