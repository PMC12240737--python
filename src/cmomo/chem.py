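"""Molecule parsing and the standard medicinal-chemistry objective functions.

Objectives implemented here are the descriptor-based ones used in lead
optimization: QED drug-likeness, penalized logP and its improvement over the
lead, Tanimoto fingerprint similarity to the lead, and a normalized
synthetic-accessibility score. Biological-activity objectives (docking
scores, activity surrogates) are user plug-ins implementing the same
evaluator contract; none are shipped.

All objectives are stored maximization-oriented: a minimize-direction spec
is negated exactly once, at evaluation time, and every later pipeline stage
(dominance, ranking, hypervolume) assumes larger-is-better.
"""

from __future__ import annotations

import os
import sys
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from rdkit import Chem, RDConfig, RDLogger
from rdkit.Chem import AllChem, Crippen
from rdkit.Chem import QED as _QED
from rdkit import DataStructs

from .errors import EvaluationError, InvalidSmiles

RDLogger.DisableLog("rdApp.*")

sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
import sascorer  # noqa: E402  (RDKit contrib, path injected above)


@dataclass(frozen=True)
class CanonicalMolecule:
    """A parsed molecule pinned to its canonical SMILES form.

    ``mol`` is the opaque parsed-structure handle (an RDKit ``Mol``); it is
    ``None`` for non-chemical "molecules" used by analytic test problems,
    where ``smiles`` is an arbitrary canonical token.
    """

    smiles: str
    mol: Optional[Chem.Mol] = field(default=None, compare=False, repr=False)


def parse_smiles(s: str) -> CanonicalMolecule:
    """Parse a SMILES string into its canonical form.

    Raises ``ValueError`` for empty input (a usage error, distinct from a
    chemically invalid string) and ``InvalidSmiles`` for unparsable SMILES.
    Canonicalization is idempotent: parsing the returned canonical string
    yields the same canonical string.
    """
    if not isinstance(s, str) or not s.strip():
        raise ValueError("empty SMILES string")
    mol = Chem.MolFromSmiles(s)
    if mol is None:
        raise InvalidSmiles(f"unparsable SMILES: {s!r}")
    return CanonicalMolecule(smiles=Chem.MolToSmiles(mol), mol=mol)


def _require_mol(m: CanonicalMolecule) -> Chem.Mol:
    if m.mol is None:
        raise EvaluationError(f"molecule {m.smiles!r} has no chemical structure")
    return m.mol


def qed(m: CanonicalMolecule) -> float:
    """Bickerton quantitative estimate of drug-likeness, in [0, 1]."""
    try:
        v = _QED.qed(_require_mol(m))
    except EvaluationError:
        raise
    except Exception as e:  # descriptor failure inside RDKit
        raise EvaluationError(f"QED failed on {m.smiles!r}: {e}") from e
    return float(min(1.0, max(0.0, v)))


def sa_raw(m: CanonicalMolecule) -> float:
    """Ertl synthetic-accessibility score on its native 1-10 scale (lower = easier)."""
    try:
        return float(sascorer.calculateScore(_require_mol(m)))
    except EvaluationError:
        raise
    except Exception as e:
        raise EvaluationError(f"SA score failed on {m.smiles!r}: {e}") from e


def normalized_sa(m: CanonicalMolecule) -> float:
    """Synthetic accessibility mapped to [0, 1], higher = easier: (10 - SA_raw)/9."""
    v = (10.0 - sa_raw(m)) / 9.0
    return float(min(1.0, max(0.0, v)))


def largest_ring_size(m: CanonicalMolecule) -> int:
    """Size of the largest ring in the SSSR ring set; 0 for acyclic molecules."""
    rings = _require_mol(m).GetRingInfo().AtomRings()
    return max((len(r) for r in rings), default=0)


def plogp(m: CanonicalMolecule, *, standardized: bool = False) -> float:
    """Penalized logP: logP - SA_raw - max(0, largest ring size - 6).

    The unstandardized form (no dataset z-scoring) is the default so the
    score has no external data dependency; ``standardized=True`` applies
    the common ZINC-250k standardization of the three components.
    """
    mol = _require_mol(m)
    try:
        logp = float(Crippen.MolLogP(mol))
    except Exception as e:
        raise EvaluationError(f"logP failed on {m.smiles!r}: {e}") from e
    sa = sa_raw(m)
    ring_penalty = float(max(0, largest_ring_size(m) - 6))
    if not standardized:
        return logp - sa - ring_penalty
    # ZINC-250k component means/stds, the convention of latent-space
    # optimization benchmarks.
    z_logp = (logp - 2.4570953396190123) / 1.434324401111988
    z_sa = (sa - 3.0525811293166134) / 0.8335207024513095
    z_ring = (ring_penalty - 0.0485696876403053) / 0.2860212110245455
    return z_logp - z_sa - z_ring


def plogp_imp(m: CanonicalMolecule, lead: CanonicalMolecule, **kw) -> float:
    """Improvement of penalized logP over the lead: plogp(m) - plogp(lead)."""
    return plogp(m, **kw) - plogp(lead, **kw)


@dataclass(frozen=True)
class FingerprintParams:
    """Binary fingerprint family used for Tanimoto similarity."""

    family: str = "morgan"  # circular (ECFP-like)
    radius: int = 2
    n_bits: int = 2048


_DEFAULT_FP = FingerprintParams()


def _fingerprint(mol: Chem.Mol, p: FingerprintParams):
    if p.family != "morgan":
        raise EvaluationError(f"unknown fingerprint family {p.family!r}")
    return AllChem.GetMorganFingerprintAsBitVect(mol, p.radius, nBits=p.n_bits)


def tanimoto_similarity(
    m: CanonicalMolecule,
    lead: CanonicalMolecule,
    fp_params: FingerprintParams = _DEFAULT_FP,
) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B| on binary fingerprints; symmetric."""
    try:
        fa = _fingerprint(_require_mol(m), fp_params)
        fb = _fingerprint(_require_mol(lead), fp_params)
        return float(DataStructs.TanimotoSimilarity(fa, fb))
    except EvaluationError:
        raise
    except Exception as e:
        raise EvaluationError(f"fingerprint failed: {e}") from e


# --------------------------------------------------------------------------
# Objective specification and evaluation
# --------------------------------------------------------------------------

Evaluator = Callable[[CanonicalMolecule, CanonicalMolecule], float]


@dataclass(frozen=True)
class ObjectiveSpec:
    """One optimization objective.

    ``evaluator`` takes (molecule, lead) and returns a finite real on the
    objective's natural scale; ``direction`` states whether that natural
    scale is maximized or minimized. Internally everything downstream is
    maximization: minimize objectives are negated once at evaluation.
    """

    name: str
    evaluator: Evaluator
    direction: str = "maximize"
    success_threshold: Optional[float] = None

    def __post_init__(self):
        if self.direction not in ("maximize", "minimize"):
            raise ValueError(f"direction must be maximize/minimize, got {self.direction!r}")


def evaluate_objectives(
    m: CanonicalMolecule,
    objectives: Sequence[ObjectiveSpec],
    lead: CanonicalMolecule,
) -> np.ndarray:
    """Evaluate all objectives on one molecule, maximization-oriented.

    Returns a float vector of length m (one entry per spec, spec order).
    A failing or non-finite evaluator raises ``EvaluationError`` naming the
    objective.
    """
    out = np.empty(len(objectives), dtype=float)
    for i, spec in enumerate(objectives):
        try:
            v = float(spec.evaluator(m, lead))
        except EvaluationError as e:
            raise EvaluationError(f"objective {spec.name!r}: {e}") from e
        except Exception as e:
            raise EvaluationError(f"objective {spec.name!r} failed on {m.smiles!r}: {e}") from e
        if not np.isfinite(v):
            raise EvaluationError(f"objective {spec.name!r} returned non-finite {v!r}")
        out[i] = -v if spec.direction == "minimize" else v
    return out


# Named evaluators resolvable from config files.
BUILTIN_EVALUATORS: dict[str, Evaluator] = {
    "qed": lambda m, lead: qed(m),
    "plogp": lambda m, lead: plogp(m),
    "plogp_imp": lambda m, lead: plogp_imp(m, lead),
    "similarity": lambda m, lead: tanimoto_similarity(m, lead),
    "normalized_sa": lambda m, lead: normalized_sa(m),
}


def read_smiles_file(path) -> list[str]:
    """Read a SMILES list file: one SMILES per line, optional tab-separated
    ID column, '#' comment lines and blank lines ignored."""
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            out.append(line.split("\t")[0].split()[0])
    return out
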