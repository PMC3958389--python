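"""The in-memory cross-population container shared by all analysis modules."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

F2_DIRECTIONS = ("F", "Fprime")
BC_DIRECTIONS = ("BC1", "BC2", "BC3", "BC4")

#: cytoplasm indicator m per direction label (+1 = P2 mother line)
M_INDICATOR = {
    "F": -1, "Fprime": 1,
    "BC1": -1, "BC2": 1, "BC3": 1, "BC4": -1,
}


@dataclass
class Population:
    """Phenotypes, cross directions and marker genotypes for one cross family.

    ``genotypes`` holds unordered marker codes (0=HOM_A, 1=HET, 2=HOM_B,
    -1=missing) in the genetic map's global marker order.  ``direction``
    holds per-individual labels, all from one design family: "F"/"Fprime"
    for reciprocal F2, "BC1".."BC4" for reciprocal backcrosses.

    Simulated populations additionally carry the true ordered QTL genotype
    per individual and the generating scenario for provenance.
    """

    phenotype: np.ndarray
    direction: np.ndarray
    genotypes: np.ndarray
    marker_names: list[str]
    ids: np.ndarray | None = None
    true_qtl_genotype: np.ndarray | None = None
    scenario: Any = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phenotype = np.asarray(self.phenotype, dtype=float)
        self.direction = np.asarray(self.direction, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n = len(self.phenotype)
        if len(self.direction) != n or self.genotypes.shape[0] != n:
            raise ValueError("phenotype/direction/genotype lengths disagree")
        if self.genotypes.shape[1] != len(self.marker_names):
            raise ValueError("genotype columns do not match marker names")
        labels = set(self.direction.tolist())
        if labels <= set(F2_DIRECTIONS):
            self._family = "F2"
        elif labels <= set(BC_DIRECTIONS):
            self._family = "BC"
        else:
            raise ValueError(
                f"mixed or unknown cross-direction labels: {sorted(map(str, labels))}"
            )
        if self.ids is None:
            self.ids = np.array([f"ind{i+1}" for i in range(n)])

    @property
    def n(self) -> int:
        return len(self.phenotype)

    @property
    def family(self) -> str:
        """Design family, "F2" or "BC"."""
        return self._family

    @property
    def m(self) -> np.ndarray:
        """Cytoplasm indicator (+1/-1) per individual."""
        return np.array([M_INDICATOR[d] for d in self.direction], dtype=float)
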