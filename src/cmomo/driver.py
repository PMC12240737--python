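"""The two-stage optimization loop, run configuration, and result I/O.

One run proceeds: screen a bank library from the candidate database,
initialize the population by lead-bank crossover, then iterate
generate-decode-evaluate-select. The first G1 generations select purely on
objectives (NSGA-II environmental selection, constraints evaluated and
cached but never consulted); the following G2 generations select by the
ranking-aggregation score with the cosine-decayed weight, t counting
generations within the constrained stage (t=0 at the switch, T=G2). The
final feasible set is the subset of the last population with all raw
constraint violations zero.

A single RNG stream seeded from the config drives bank order, parent
pairing, blend draws, fragment choice and mutation noise, in that fixed
order, so a run is fully reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .chem import (
    BUILTIN_EVALUATORS,
    CanonicalMolecule,
    ObjectiveSpec,
    read_smiles_file,
)
from .codec import Codec, decode_valid_batch
from .constraints import AlertLibrary, aggregate_cv, builtin_constraints, is_feasible
from .errors import BadParams, ConfigError, InitializationFailed
from .metrics import hypervolume
from .problem import ProblemDefinition
from .selection import (
    alpha,
    environmental_selection_stage1,
    environmental_selection_stage2,
    rank_table,
)
from .variation import (
    BankLibrary,
    ScreenParams,
    VariationParams,
    build_bank,
    generate_offspring,
    initialize_latents,
)


@dataclass
class MoleculeRecord:
    """One candidate with everything selection and reporting need."""

    molecule: CanonicalMolecule
    latent: np.ndarray
    objectives: np.ndarray
    sigmas: np.ndarray
    cv: float = 0.0
    feasible: bool = False
    front: int = 0
    crowding: float = 0.0
    s1: int = 0
    s2: int = 0
    score: float = 0.0

    @property
    def smiles(self) -> str:
        return self.molecule.smiles


class Population:
    """Ordered multiset of molecule records with a declared capacity."""

    def __init__(self, records: Sequence[MoleculeRecord], capacity: int):
        self.records = list(records)
        self.capacity = int(capacity)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def objective_matrix(self) -> np.ndarray:
        return np.array([r.objectives for r in self.records], dtype=float)

    def sigma_matrix(self) -> np.ndarray:
        return np.array([r.sigmas for r in self.records], dtype=float)

    def smiles_set(self) -> set[str]:
        return {r.smiles for r in self.records}


@dataclass
class RunConfig:
    """All parameters of one optimization run."""

    lead_smiles: str
    database_path: Optional[str] = None
    alerts_path: Optional[str] = None
    codec_spec: str = "table"  # "table" requires a codec object or CSV path
    codec_path: Optional[str] = None
    P: int = 20
    G1: int = 15
    G2: int = 15
    bank_size: int = 20
    seed: int = 0
    variation: VariationParams = field(default_factory=VariationParams)
    screen: ScreenParams = field(default_factory=ScreenParams)
    objective_names: tuple[str, ...] = ("qed", "similarity")
    success_thresholds: dict = field(default_factory=dict)
    dedupe_against_parents: bool = True
    archive_feasible: bool = False
    output_dir: Optional[str] = None

    def __post_init__(self):
        if self.P < 2:
            raise ConfigError(f"P must be >= 2, got {self.P}")
        if self.G1 < 0 or self.G2 < 0:
            raise ConfigError("G1 and G2 must be >= 0")
        if self.bank_size < 1:
            raise ConfigError(f"bank_size must be >= 1, got {self.bank_size}")
        if not self.lead_smiles:
            raise ConfigError("lead_smiles is required")


@dataclass
class OptimizationResult:
    final_population: Population
    feasible_set: list[MoleculeRecord]
    per_generation_log: list[dict]
    provenance: dict
    archive: list[MoleculeRecord] = field(default_factory=list)


def extract_feasible(pop: Population) -> list[MoleculeRecord]:
    """Records whose every raw constraint violation is zero, order preserved."""
    return [r for r in pop if is_feasible(r.sigmas)]


def _evaluate_new(
    molecules: Sequence[tuple[CanonicalMolecule, np.ndarray]],
    problem: ProblemDefinition,
    lead: CanonicalMolecule,
    cache: dict,
) -> list[MoleculeRecord]:
    out = []
    for m, z in molecules:
        if m.smiles in cache:
            obj, sig = cache[m.smiles]
        else:
            obj, sig = problem.evaluate(m, lead)
            cache[m.smiles] = (obj, sig)
        out.append(
            MoleculeRecord(
                molecule=m,
                latent=np.asarray(z, dtype=float),
                objectives=obj,
                sigmas=sig,
                feasible=is_feasible(sig),
            )
        )
    return out


def _annotate(union: list[MoleculeRecord], t: float, T: int) -> None:
    """Attach per-record ranking diagnostics after a stage-2 selection."""
    F = np.array([r.objectives for r in union])
    sig = np.array([r.sigmas for r in union])
    cv = aggregate_cv(sig) if sig.size else np.zeros(len(union))
    tbl = rank_table(F, cv, t, T)
    for i, r in enumerate(union):
        r.cv = float(cv[i])
        r.front = int(tbl["front"][i])
        r.crowding = float(tbl["crowding"][i])
        r.s1 = int(tbl["s1"][i])
        r.s2 = int(tbl["s2"][i])
        r.score = float(tbl["score"][i])


def _log_entry(
    gen: int, stage: int, pop: Population, problem: ProblemDefinition, a: Optional[float]
) -> dict:
    F = pop.objective_matrix()
    feas = np.array([is_feasible(r.sigmas) for r in pop], dtype=bool)
    ref = np.zeros(F.shape[1])
    entry = {
        "generation": gen,
        "stage": stage,
        "size": len(pop),
        "hv": float(hypervolume(F, ref)),
        # the headline metric: hypervolume of the feasible subset, the set
        # the run actually delivers
        "hv_feasible": float(hypervolume(F[feas], ref)) if feas.any() else 0.0,
        "feasible_fraction": float(feas.mean()) if len(pop) else 0.0,
        "alpha": a,
    }
    for k, name in enumerate(problem.objective_names):
        entry[f"mean_{name}"] = float(F[:, k].mean())
        entry[f"best_{name}"] = float(F[:, k].max())
    return entry


def run_cmomo(
    config: RunConfig,
    problem: ProblemDefinition,
    codec: Codec,
    database: Optional[Sequence[str]] = None,
) -> OptimizationResult:
    """Execute the full two-stage optimization and return the result.

    ``database`` defaults to the SMILES list at ``config.database_path``.
    """
    rng = np.random.default_rng(config.seed)
    if config.variation.n_frag > codec.dim:
        # fragment count cannot exceed the latent dimension; cap for small
        # mock codecs so one set of defaults serves every codec scale
        config = dataclasses.replace(
            config,
            variation=dataclasses.replace(config.variation, n_frag=codec.dim),
        )
    lead = problem.parse(config.lead_smiles)
    if database is None:
        if config.database_path is None:
            raise ConfigError("either database or database_path is required")
        database = read_smiles_file(config.database_path)

    bank = _build_bank_for(problem, lead, database, codec, config)
    lead_z = codec.encode(lead.smiles)
    cache: dict = {}

    init = initialize_latents(
        lead_z, bank, config.P, config.variation, rng, codec, parse=problem.parse
    )
    if not init:
        # not even one decodable child: fall back to the lead alone
        try:
            init = [(lead, lead_z)]
        except Exception as e:  # pragma: no cover
            raise InitializationFailed(str(e)) from e
    while len(init) < config.P:  # pad with copies of the lead
        init.append((lead, lead_z.copy()))
    records = _evaluate_new(init, problem, lead, cache)
    pop = Population(records, capacity=config.P)

    log: list[dict] = []
    archive: list[MoleculeRecord] = []
    bounds = getattr(codec, "bounds", None)
    gen = 0
    log.append(_log_entry(gen, 0, pop, problem, None))

    def _step(selector, stage: int, a: Optional[float]):
        nonlocal pop, gen
        parents = [r.latent for r in pop]
        offspring_z = generate_offspring(parents, config.variation, rng, bounds)
        exclude = pop.smiles_set() if config.dedupe_against_parents else None
        decoded = decode_valid_batch(
            codec, offspring_z, parse=problem.parse, exclude=exclude
        )
        children = _evaluate_new([(m, z) for _, m, z in decoded], problem, lead, cache)
        union = list(pop.records) + children
        if len(union) > config.P:
            keep = selector(union)
            pop = Population([union[i] for i in keep], capacity=config.P)
        else:
            pop = Population(union, capacity=config.P)
        if config.archive_feasible:
            archive.extend(r for r in children if r.feasible)
        gen += 1
        log.append(_log_entry(gen, stage, pop, problem, a))

    # Stage 1: unconstrained scenario — objectives only, CVs never consulted.
    for _ in range(config.G1):
        _step(
            lambda union: environmental_selection_stage1(
                np.array([r.objectives for r in union]), config.P
            ),
            stage=1,
            a=None,
        )

    # Stage 2: constrained scenario — ranking aggregation with cosine decay.
    T = max(config.G2, 1)
    for t in range(config.G2):
        a = alpha(t, T)

        def stage2_selector(union, t=t):
            F = np.array([r.objectives for r in union])
            cv = aggregate_cv(np.array([r.sigmas for r in union]))
            return environmental_selection_stage2(F, cv, config.P, t, T)

        _step(stage2_selector, stage=2, a=a)

    if config.G2 > 0 and len(pop) > 0:
        _annotate(list(pop.records), t=config.G2, T=T)
    feasible = extract_feasible(pop)
    provenance = {
        "config": config_to_dict(config),
        "seed": config.seed,
        "bank": bank.provenance,
        "version": __version__,
    }
    return OptimizationResult(
        final_population=pop,
        feasible_set=feasible,
        per_generation_log=log,
        provenance=provenance,
        archive=archive,
    )


def _build_bank_for(problem, lead, database, codec, config) -> BankLibrary:
    screen = config.screen
    if problem.parse is not None and problem.parse.__name__ == "identity_parse":
        # analytic problems: no chemistry — screen by first objective, no
        # similarity requirement
        f0 = problem.objectives[0]
        screen = ScreenParams(
            sim_min=0.0,
            prop_min=-np.inf,
            property_fn=lambda m: f0.evaluator(m, lead),
            property_name=f0.name,
        )
        members = []
        for s in database:
            m = problem.parse(s)
            members.append((m, codec.encode(m.smiles)))
        members = members[: config.bank_size]
        return BankLibrary(
            members=members,
            provenance={"mode": "analytic", "returned": len(members)},
        )
    return build_bank(lead, database, codec, config.bank_size, screen)


# --------------------------------------------------------------------------
# Config and result I/O
# --------------------------------------------------------------------------


def config_to_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["variation"] = dataclasses.asdict(config.variation)
    sp = dataclasses.asdict(config.screen)
    sp.pop("property_fn", None)
    d["screen"] = sp
    return d


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config fields: {sorted(unknown)}")
    if "variation" in raw:
        try:
            raw["variation"] = VariationParams(**raw["variation"])
        except TypeError as e:
            raise ConfigError(f"variation: {e}") from e
    if "screen" in raw:
        try:
            raw["screen"] = ScreenParams(**raw["screen"])
        except TypeError as e:
            raise ConfigError(f"screen: {e}") from e
    if "objective_names" in raw:
        raw["objective_names"] = tuple(raw["objective_names"])
    try:
        return RunConfig(**raw)
    except TypeError as e:
        raise ConfigError(str(e)) from e


def problem_from_config(config: RunConfig) -> ProblemDefinition:
    """Build a chemical problem from named built-in objectives + constraints."""
    objectives = []
    for name in config.objective_names:
        if name not in BUILTIN_EVALUATORS:
            raise ConfigError(
                f"unknown objective {name!r}; built-ins: {sorted(BUILTIN_EVALUATORS)}"
            )
        objectives.append(
            ObjectiveSpec(
                name,
                BUILTIN_EVALUATORS[name],
                success_threshold=config.success_thresholds.get(name),
            )
        )
    alerts = (
        AlertLibrary.from_file(config.alerts_path)
        if config.alerts_path
        else AlertLibrary.packaged()
    )
    return ProblemDefinition(
        objectives=tuple(objectives), constraints=tuple(builtin_constraints(alerts))
    )


def population_frame(pop: Population, problem: ProblemDefinition) -> pd.DataFrame:
    rows = []
    for r in pop:
        row = {"smiles": r.smiles}
        for k, name in enumerate(problem.objective_names):
            row[name] = r.objectives[k]
        for k, name in enumerate(problem.constraint_names):
            row[f"sigma_{name}"] = r.sigmas[k]
        row.update(
            cv=r.cv,
            feasible=is_feasible(r.sigmas),
            front=r.front,
            crowding=r.crowding,
            s1=r.s1,
            s2=r.s2,
            score=r.score,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def write_results(result: OptimizationResult, out_dir, problem: ProblemDefinition):
    """Write final_population.csv, feasible.smi, generations.jsonl, provenance.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    population_frame(result.final_population, problem).to_csv(
        out / "final_population.csv", index=False
    )
    with open(out / "feasible.smi", "w", encoding="utf-8") as fh:
        for r in result.feasible_set:
            fh.write(r.smiles + "\n")
    with open(out / "generations.jsonl", "w", encoding="utf-8") as fh:
        for entry in result.per_generation_log:
            fh.write(json.dumps(entry) + "\n")
    with open(out / "provenance.json", "w", encoding="utf-8") as fh:
        json.dump(result.provenance, fh, indent=2, default=str)
    return out
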