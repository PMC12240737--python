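"""The optimization problem container tying objectives, constraints and
molecule parsing together."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .chem import CanonicalMolecule, ObjectiveSpec, evaluate_objectives, parse_smiles
from .constraints import ConstraintSpec, evaluate_sigmas


@dataclass(frozen=True)
class ProblemDefinition:
    """Ordered objectives and constraints defining one optimization run.

    ``parse`` canonicalizes a decoded string into a molecule; the default is
    SMILES parsing, while analytic test problems substitute a coordinate
    token parser. All downstream code sees objectives maximization-oriented.
    """

    objectives: tuple[ObjectiveSpec, ...]
    constraints: tuple[ConstraintSpec, ...] = ()
    parse: Callable[[str], CanonicalMolecule] = field(default=parse_smiles)

    def __post_init__(self):
        if not self.objectives:
            raise ValueError("a problem needs at least one objective")

    @property
    def n_objectives(self) -> int:
        return len(self.objectives)

    @property
    def n_constraints(self) -> int:
        return len(self.constraints)

    @property
    def objective_names(self) -> list[str]:
        return [o.name for o in self.objectives]

    @property
    def constraint_names(self) -> list[str]:
        return [c.name for c in self.constraints]

    def evaluate(
        self, m: CanonicalMolecule, lead: CanonicalMolecule
    ) -> tuple[np.ndarray, np.ndarray]:
        """(objective vector, raw sigma vector) for one molecule."""
        return (
            evaluate_objectives(m, self.objectives, lead),
            evaluate_sigmas(m, self.constraints),
        )

    def success_thresholds(self) -> dict[str, float]:
        return {
            o.name: o.success_threshold
            for o in self.objectives
            if o.success_threshold is not None
        }
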