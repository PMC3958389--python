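"""Genetic parameterization of cyto-nuclear epistasis subject to imprinting.

A single biallelic locus in a cross between two inbred lines P1 (allele A)
and P2 (allele B) is described by *ordered* genotypes that record the
parental origin of each allele: AmAf, AmBf, BmAf, BmBf (maternal allele
first).  The genotypic mean of an individual is modeled as

    mu + c*m + a*x_a + d*x_d + i*x_i + ica*(m*x_a) + icd*(m*x_d) + ici*(m*x_i)

where ``m`` is the cytoplasm indicator (+1 when the maternal line is P2,
-1 when it is P1), ``a``/``d``/``i`` are the additive, dominance and
imprinting effects of the locus, ``c`` is the cytoplasmic (maternal)
effect, and ``ica``/``icd``/``ici`` are the cytoplasm-by-additive,
cytoplasm-by-dominance and cytoplasm-by-imprinting interactions.

The indicator coding for the four ordered genotypes is

    =======  ====  ====  ====
    state    x_a   x_d   x_i
    =======  ====  ====  ====
    AmAf      +1    0     0
    AmBf       0    1    +1
    BmAf       0    1    -1
    BmBf      -1    0     0
    =======  ====  ====  ====

so the imprinting effect is the half-difference of the two reciprocal
heterozygotes.  Stacking the rows for all cytoplasm/genotype classes of a
design (reciprocal F2: 2 directions x 4 genotypes; reciprocal backcross:
4 backcrosses x 2 segregating genotypes) yields an invertible 8x8 design
matrix linking the eight class means to the eight effect parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from enum import Enum

import numpy as np

__all__ = [
    "EFFECT_NAMES",
    "OrderedGenotype",
    "CrossDirection",
    "BackcrossType",
    "EffectVector",
    "InvalidGenotypeError",
    "f2_design_row",
    "backcross_design_row",
    "design_matrix",
    "genotypic_means",
    "effects_from_means",
]

#: Parameter order used throughout the package (model-equation order).
EFFECT_NAMES: tuple[str, ...] = ("mu", "c", "a", "d", "i", "ica", "icd", "ici")


class OrderedGenotype(Enum):
    """Parent-of-origin-ordered genotype; the maternal allele is listed first."""

    AmAf = 0
    AmBf = 1
    BmAf = 2
    BmBf = 3


#: (x_a, x_d, x_i) indicator codes for each ordered genotype.
_X_CODES: dict[OrderedGenotype, tuple[int, int, int]] = {
    OrderedGenotype.AmAf: (1, 0, 0),
    OrderedGenotype.AmBf: (0, 1, 1),
    OrderedGenotype.BmAf: (0, 1, -1),
    OrderedGenotype.BmBf: (-1, 0, 0),
}

#: Genotype order used for mixture components and design-matrix rows.
F2_GENOTYPE_ORDER: tuple[OrderedGenotype, ...] = tuple(OrderedGenotype)


class CrossDirection(Enum):
    """Reciprocal F2 direction: which inbred line was the grand-maternal parent.

    ``F`` starts from a P1 mother (P1 cytoplasm, m = -1); ``FPRIME`` from a
    P2 mother (P2 cytoplasm, m = +1).
    """

    F = "F"
    FPRIME = "Fprime"

    @property
    def cytoplasm_indicator(self) -> int:
        return 1 if self is CrossDirection.FPRIME else -1


class BackcrossType(Enum):
    """The four reciprocal backcrosses, in the conventional tabulation order."""

    BC1 = "BC1"
    BC2 = "BC2"
    BC3 = "BC3"
    BC4 = "BC4"


#: Backcross -> (cytoplasm indicator, the two segregating ordered genotypes).
#: BC1: F1 mother (P1 cytoplasm) x P1 father; BC2: F1' mother x P1 father;
#: BC3: F1' mother (P2 cytoplasm) x P2 father; BC4: F1 mother x P2 father.
#: The pair is ordered (maternal allele A, maternal allele B).
_BC_INFO: dict[BackcrossType, tuple[int, tuple[OrderedGenotype, OrderedGenotype]]] = {
    BackcrossType.BC1: (-1, (OrderedGenotype.AmAf, OrderedGenotype.BmAf)),
    BackcrossType.BC2: (+1, (OrderedGenotype.AmAf, OrderedGenotype.BmAf)),
    BackcrossType.BC3: (+1, (OrderedGenotype.AmBf, OrderedGenotype.BmBf)),
    BackcrossType.BC4: (-1, (OrderedGenotype.AmBf, OrderedGenotype.BmBf)),
}


class InvalidGenotypeError(ValueError):
    """Raised when a genotype does not segregate in the requested backcross."""


@dataclass(frozen=True)
class EffectVector:
    """The eight genetic parameters, in trait units.

    Attributes
    ----------
    mu : overall mean
    c : cytoplasmic (maternal) effect
    a, d, i : additive, dominance and imprinting effects of the QTL
    ica, icd, ici : cytoplasm x additive / dominance / imprinting interactions
    """

    mu: float
    c: float = 0.0
    a: float = 0.0
    d: float = 0.0
    i: float = 0.0
    ica: float = 0.0
    icd: float = 0.0
    ici: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "EffectVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (8,):
            raise ValueError(f"expected 8 effects, got shape {arr.shape}")
        return cls(*arr.tolist())

    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in EFFECT_NAMES}


def _row(m: int, xa: int, xd: int, xi: int) -> np.ndarray:
    """Design row (1, m, x_a, x_d, x_i, m*x_a, m*x_d, m*x_i)."""
    return np.array([1, m, xa, xd, xi, m * xa, m * xd, m * xi], dtype=float)


def f2_design_row(direction: CrossDirection, genotype: OrderedGenotype) -> np.ndarray:
    """Design row of an F2 individual given its cross direction and ordered genotype."""
    xa, xd, xi = _X_CODES[genotype]
    return _row(direction.cytoplasm_indicator, xa, xd, xi)


def backcross_design_row(bc: BackcrossType, genotype: OrderedGenotype) -> np.ndarray:
    """Design row of a backcross individual.

    Raises
    ------
    InvalidGenotypeError
        If ``genotype`` is not one of the two genotypes segregating in ``bc``.
    """
    m, pair = _BC_INFO[bc]
    if genotype not in pair:
        raise InvalidGenotypeError(
            f"{genotype.name} does not segregate in {bc.value}; "
            f"expected one of {[g.name for g in pair]}"
        )
    xa, xd, xi = _X_CODES[genotype]
    return _row(m, xa, xd, xi)


def bc_genotypes(bc: BackcrossType) -> tuple[OrderedGenotype, OrderedGenotype]:
    """The two ordered genotypes segregating in a backcross (maternal A first)."""
    return _BC_INFO[bc][1]


def design_matrix(design: str = "F2") -> np.ndarray:
    """The 8x8 matrix linking the eight class means to the eight parameters.

    ``design="F2"`` stacks (direction F then F') x the four ordered genotypes;
    ``design="BC"`` stacks BC1..BC4 x their two segregating genotypes.  Both
    matrices are invertible.
    """
    if design == "F2":
        rows = [
            f2_design_row(direction, g)
            for direction in (CrossDirection.F, CrossDirection.FPRIME)
            for g in F2_GENOTYPE_ORDER
        ]
    elif design == "BC":
        rows = [
            backcross_design_row(bc, g)
            for bc in BackcrossType
            for g in _BC_INFO[bc][1]
        ]
    else:
        raise ValueError(f"unknown design {design!r}; expected 'F2' or 'BC'")
    return np.vstack(rows)


def genotypic_means(beta: EffectVector, design: str = "F2") -> np.ndarray:
    """The eight class means implied by an effect vector (matrix-vector product)."""
    return design_matrix(design) @ beta.as_array()


def effects_from_means(means, design: str = "F2") -> EffectVector:
    """Solve the 8x8 linear system for the effects given the eight class means.

    Exact inverse of :func:`genotypic_means`; the system matrix is constant
    and invertible, so no pseudo-inverse is needed.
    """
    means = np.asarray(means, dtype=float)
    if means.shape != (8,):
        raise ValueError(f"expected 8 class means, got shape {means.shape}")
    return EffectVector.from_array(np.linalg.solve(design_matrix(design), means))
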