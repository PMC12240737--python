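"""Drug-likeness constraints: per-constraint violation degrees and their
population-normalized aggregation.

Two structural constraints are built in. The ring-size constraint penalizes
rings outside the synthetically tractable 5-6 atom window; its violation is
the summed distance of every SSSR ring size from that window. The
substructure constraint counts distinct structural-alert SMARTS patterns
(toxic or uncommon moieties) present in the molecule. Further constraints
plug in through the same evaluator contract.

Feasibility is decided on raw violations (every sigma exactly zero). The
aggregate CV used for selection normalizes each constraint column by its
maximum over the molecule set under consideration, so constraints with
different natural scales contribute comparably; normalization never changes
which molecules are feasible.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Callable, Optional, Sequence

import numpy as np
from rdkit import Chem

from .chem import CanonicalMolecule
from .errors import BadAlertPattern, EmptyPopulation, EvaluationError

ConstraintEvaluator = Callable[[CanonicalMolecule], float]


@dataclass(frozen=True)
class ConstraintSpec:
    """One inequality constraint, expressed as a violation degree.

    ``evaluator`` returns sigma(x) >= 0, with sigma == 0 iff satisfied.
    """

    name: str
    evaluator: ConstraintEvaluator


@dataclass(frozen=True)
class ViolationProfile:
    sigmas: tuple[float, ...]
    cv: float
    feasible: bool


def ring_size_cv(m: CanonicalMolecule) -> float:
    """Violation of the 5-6-membered-ring constraint.

    sum over SSSR rings of max(r_k - 6, 0) + max(5 - r_k, 0); zero for
    acyclic molecules and for molecules whose every ring has 5 or 6 atoms.
    """
    if m.mol is None:
        raise EvaluationError(f"molecule {m.smiles!r} has no chemical structure")
    try:
        rings = m.mol.GetRingInfo().AtomRings()
    except Exception as e:
        raise EvaluationError(f"ring perception failed on {m.smiles!r}: {e}") from e
    return float(sum(max(len(r) - 6, 0) + max(5 - len(r), 0) for r in rings))


class AlertLibrary:
    """A compiled, ordered list of structural-alert SMARTS patterns."""

    def __init__(self, patterns: Sequence[str], labels: Optional[Sequence[str]] = None):
        self.smarts: list[str] = []
        self.labels: list[str] = []
        self._compiled: list[Chem.Mol] = []
        labels = list(labels) if labels is not None else [""] * len(patterns)
        for i, (p, lab) in enumerate(zip(patterns, labels)):
            q = Chem.MolFromSmarts(p)
            if q is None:
                raise BadAlertPattern(f"alert pattern {i + 1} does not compile: {p!r}")
            self.smarts.append(p)
            self.labels.append(lab)
            self._compiled.append(q)

    def __len__(self) -> int:
        return len(self._compiled)

    def matches(self, m: CanonicalMolecule) -> list[int]:
        """Indices of alert patterns with at least one match in ``m``."""
        if m.mol is None:
            raise EvaluationError(f"molecule {m.smiles!r} has no chemical structure")
        return [i for i, q in enumerate(self._compiled) if m.mol.HasSubstructMatch(q)]

    @classmethod
    def from_file(cls, path) -> "AlertLibrary":
        """Load alerts from a text file: one SMARTS per line, optional
        tab-separated label, '#' comments. Compile failures report the line
        number."""
        patterns, labels, lines = [], [], []
        with open(path, "r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                patterns.append(parts[0].strip())
                labels.append(parts[1].strip() if len(parts) > 1 else "")
                lines.append(lineno)
        try:
            return cls(patterns, labels)
        except BadAlertPattern:
            # re-raise with the file line number attached
            for lineno, p in zip(lines, patterns):
                if Chem.MolFromSmarts(p) is None:
                    raise BadAlertPattern(
                        f"{path}, line {lineno}: SMARTS does not compile: {p!r}"
                    ) from None
            raise

    @classmethod
    def packaged(cls) -> "AlertLibrary":
        """The alert subset shipped with the package (common reactive/toxic
        motifs); replace with a task-specific list for production screens."""
        text = resources.files("cmomo.data").joinpath("alerts.smarts").read_text("utf-8")
        patterns, labels = [], []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            patterns.append(parts[0].strip())
            labels.append(parts[1].strip() if len(parts) > 1 else "")
        return cls(patterns, labels)


def substructure_cv(
    m: CanonicalMolecule, alerts: AlertLibrary, *, count_instances: bool = False
) -> float:
    """Number of distinct alert patterns matched in ``m`` (each pattern
    counts at most once); ``count_instances=True`` counts every match."""
    if not count_instances:
        return float(len(alerts.matches(m)))
    if m.mol is None:
        raise EvaluationError(f"molecule {m.smiles!r} has no chemical structure")
    return float(
        sum(len(m.mol.GetSubstructMatches(q)) for q in alerts._compiled)
    )


def evaluate_sigmas(
    m: CanonicalMolecule, constraints: Sequence[ConstraintSpec]
) -> np.ndarray:
    """Evaluate every constraint on one molecule; order preserved."""
    out = np.empty(len(constraints), dtype=float)
    for i, spec in enumerate(constraints):
        try:
            v = float(spec.evaluator(m))
        except EvaluationError as e:
            raise EvaluationError(f"constraint {spec.name!r}: {e}") from e
        except Exception as e:
            raise EvaluationError(
                f"constraint {spec.name!r} failed on {m.smiles!r}: {e}"
            ) from e
        if not np.isfinite(v) or v < 0:
            raise EvaluationError(
                f"constraint {spec.name!r} returned invalid violation {v!r}"
            )
        out[i] = v
    return out


def aggregate_cv(sigma_matrix: np.ndarray) -> np.ndarray:
    """Max-normalized aggregate constraint violation over a molecule set.

    ``sigma_matrix`` is (n_molecules, n_constraints) of raw violations over
    the set psi; each column is divided by its maximum over psi and the
    normalized columns are summed per molecule. A column whose maximum is
    zero (constraint satisfied set-wide) contributes nothing. Outputs lie in
    [0, n_constraints], and CV == 0 exactly for all-zero-sigma molecules.
    """
    sig = np.asarray(sigma_matrix, dtype=float)
    if sig.ndim == 1:
        sig = sig.reshape(1, -1)
    if sig.shape[0] == 0:
        raise EmptyPopulation("aggregate_cv over an empty molecule set")
    if np.any(sig < 0):
        raise ValueError("negative violation degree")
    col_max = sig.max(axis=0)
    scale = np.where(col_max > 0, col_max, 1.0)
    return (sig / scale).sum(axis=1)


def is_feasible(sigmas: Sequence[float], tol: float = 0.0) -> bool:
    """A molecule is feasible iff every raw violation is (numerically) zero."""
    return bool(np.all(np.asarray(sigmas, dtype=float) <= tol))


def make_profiles(sigma_matrix: np.ndarray) -> list[ViolationProfile]:
    """Bundle raw sigmas with their set-normalized CVs and feasibility."""
    sig = np.asarray(sigma_matrix, dtype=float)
    cvs = aggregate_cv(sig)
    return [
        ViolationProfile(tuple(row), float(cv), is_feasible(row))
        for row, cv in zip(sig, cvs)
    ]


def builtin_constraints(alerts: Optional[AlertLibrary] = None) -> list[ConstraintSpec]:
    """The two structural constraints: ring size (C1) and alerts (C2)."""
    if alerts is None:
        alerts = AlertLibrary.packaged()
    return [
        ConstraintSpec("ring_size", ring_size_cv),
        ConstraintSpec("alerts", lambda m: substructure_cv(m, alerts)),
    ]
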