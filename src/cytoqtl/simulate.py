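"""Seeded Monte Carlo simulator of reciprocal F2 and backcross populations.

Gametes are generated as Markov chains along each chromosome with no
crossover interference: the allele at the first locus is uniform, and each
subsequent interval switches parental phase with probability given by the
Haldane map function at the sex-specific distance (female distances for
maternal gametes, male for paternal ones, from the lambda map ratio).
Ordered genotypes at markers and at the QTL follow from one maternal and
one paternal gamete per individual; marker codes are then un-ordered, and
the phenotype is the design-row mean plus Gaussian residual noise.

Scenario presets reproduce the published simulation study conditions: a
single 100 cM linkage group with 6 equidistant markers, a QTL at 48 cM,
half the population from each reciprocal F2 direction, lambda = 1.25,
and either a printed residual variance (estimation study) or a variance
calibrated from broad-sense heritability (power study).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import (
    BackcrossType,
    EffectVector,
    OrderedGenotype,
    design_matrix,
    genotypic_means,
)
from .linkage import ChromosomeMap, GeneticMap, haldane_r, sex_split
from .population import Population

__all__ = [
    "SimulationScenario",
    "simulate_gamete",
    "simulate_population",
    "heritability_to_sigma2",
    "table_scenarios",
    "table2_scenario",
    "table3_scenario",
    "TABLE2_BETA",
    "TABLE2_SIGMA2",
]

#: Estimation-study truth: (mu, c, a, d, i, ica, icd, ici).
TABLE2_BETA = EffectVector(mu=10.0, c=1.0, a=1.0, d=0.8, i=0.0,
                           ica=0.6, icd=0.5, ici=0.0)

#: Printed residual variances per broad-sense heritability level.
TABLE2_SIGMA2 = {0.1: 3.81, 0.25: 2.04, 0.4: 1.26}

#: Calibrated cytoplasmic effect per variance proportion gamma_c.
TABLE3_CYTO = {0.0: 0.0, 0.05: 0.461, 0.10: 0.679}
#: Calibrated imprinting effect per variance proportion gamma_i.
TABLE3_IMPRINTING = {0.0: 0.0, 0.05: 0.680, 0.10: 1.020}


@dataclass(frozen=True)
class SimulationScenario:
    """All inputs needed to simulate one population reproducibly.

    Exactly one of ``sigma2`` (residual variance) and ``h2`` (broad-sense
    heritability, in (0, 1)) must be given; with ``h2`` the residual
    variance is derived via :func:`heritability_to_sigma2`.
    """

    n: int
    beta: EffectVector
    map_length: float = 100.0
    n_markers: int = 6
    qtl_position: float = 48.0
    direction_split: float = 0.5
    lam: float = 1.25
    sigma2: float | None = None
    h2: float | None = None
    seed: int | None = None
    family: str = "F2"
    bc_mix: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    name: str = "custom"

    def __post_init__(self) -> None:
        if (self.sigma2 is None) == (self.h2 is None):
            raise ValueError("specify exactly one of sigma2 and h2")
        if self.h2 is not None and not (0.0 < self.h2 < 1.0):
            raise ValueError("h2 must be in (0, 1)")
        if self.sigma2 is not None and self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        if not (0.0 <= self.qtl_position <= self.map_length):
            raise ValueError("QTL position outside the linkage group")
        if self.n_markers < 2:
            raise ValueError("need at least two markers")
        if self.family not in ("F2", "BC"):
            raise ValueError("family must be 'F2' or 'BC'")

    @property
    def marker_positions(self) -> np.ndarray:
        return np.linspace(0.0, self.map_length, self.n_markers)

    def genetic_map(self, chrom: str = "1") -> GeneticMap:
        markers = [f"M{i+1}" for i in range(self.n_markers)]
        return GeneticMap(
            [ChromosomeMap(chrom, markers, self.marker_positions)], lam=self.lam
        )

    def residual_variance(self) -> float:
        if self.sigma2 is not None:
            return self.sigma2
        return heritability_to_sigma2(self.beta, self.h2, self.family)


def heritability_to_sigma2(beta: EffectVector, h2: float, design: str = "F2") -> float:
    """Residual variance giving broad-sense heritability ``h2``.

    The genetic variance is the variance of the eight class means under
    equal class probabilities (balanced reciprocal directions, Mendelian
    1/4 genotype frequencies), and sigma2 = sigma2_g * (1 - h2) / h2.
    """
    if not (0.0 < h2 < 1.0):
        raise ValueError("h2 must be in (0, 1)")
    means = genotypic_means(beta, design)
    sigma2_g = float(np.var(means))
    if sigma2_g == 0.0:
        raise ValueError(
            "all genetic effects are zero: genetic variance is 0 and the "
            "residual variance is undefined for a target heritability"
        )
    return sigma2_g * (1.0 - h2) / h2


def _gamete_matrix(n: int, positions: np.ndarray, sex: str, lam: float, rng) -> np.ndarray:
    """(n, L) matrix of 0/1 parental-phase alleles for one gamete per row."""
    d_avg = np.diff(positions)
    d_f, d_m = sex_split(d_avg, lam)
    r = haldane_r(d_f if sex == "female" else d_m)
    L = len(positions)
    first = rng.integers(0, 2, size=n)
    if L == 1:
        return first[:, None].astype(np.int8)
    switches = (rng.random((n, L - 1)) < r).astype(np.int8)
    flips = np.concatenate([np.zeros((n, 1), np.int8), np.cumsum(switches, axis=1)], axis=1)
    return ((first[:, None] + flips) % 2).astype(np.int8)


def simulate_gamete(positions, sex: str, rng, lam: float = 1.25) -> np.ndarray:
    """One gamete's allele sequence (0=A, 1=B) over ordered loci.

    ``sex`` is "female" (maternal gamete; female map distances) or "male".
    """
    if sex not in ("female", "male"):
        raise ValueError("sex must be 'female' or 'male'")
    positions = np.asarray(positions, dtype=float)
    return _gamete_matrix(1, positions, sex, lam, rng)[0]


def _f2_directions(scenario: SimulationScenario) -> np.ndarray:
    n_f = int(round(scenario.n * scenario.direction_split))
    return np.array(["F"] * n_f + ["Fprime"] * (scenario.n - n_f), dtype=object)


def _bc_directions(scenario: SimulationScenario, rng) -> np.ndarray:
    labels = [bc.value for bc in BackcrossType]
    return rng.choice(labels, size=scenario.n, p=np.asarray(scenario.bc_mix))


def simulate_population(scenario: SimulationScenario, rng=None) -> Population:
    """Simulate one population under a scenario; bitwise-reproducible by seed."""
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    mpos = scenario.marker_positions
    if np.any(np.isclose(mpos, scenario.qtl_position)):
        # QTL coincides with a marker: no extra locus needed
        loci = mpos.copy()
        qi = int(np.argmin(np.abs(mpos - scenario.qtl_position)))
        marker_idx = np.arange(len(loci))
    else:
        loci = np.sort(np.append(mpos, scenario.qtl_position))
        qi = int(np.searchsorted(loci, scenario.qtl_position))
        marker_idx = np.array([k for k in range(len(loci)) if k != qi])

    n = scenario.n
    if scenario.family == "F2":
        directions = _f2_directions(scenario)
    else:
        directions = _bc_directions(scenario, rng)

    mat = _gamete_matrix(n, loci, "female", scenario.lam, rng)
    pat = _gamete_matrix(n, loci, "male", scenario.lam, rng)

    if scenario.family == "BC":
        # the paternal gamete comes from the recurrent inbred parent
        pat_allele = np.array([0 if d in ("BC1", "BC2") else 1 for d in directions],
                              dtype=np.int8)
        pat = np.broadcast_to(pat_allele[:, None], pat.shape).copy()

    qtl_geno = 2 * mat[:, qi] + pat[:, qi]  # 0..3 == OrderedGenotype values
    geno_codes = (mat + pat)[:, marker_idx].astype(np.int8)

    # class means indexed by (direction block, ordered genotype)
    if scenario.family == "F2":
        mean_table = design_matrix("F2") @ scenario.beta.as_array()
        dir_offset = np.where(directions == "F", 0, 4)
        means = mean_table[dir_offset + qtl_geno]
    else:
        from .design import backcross_design_row

        beta_arr = scenario.beta.as_array()
        means = np.array(
            [
                backcross_design_row(BackcrossType(d), OrderedGenotype(int(g)))
                @ beta_arr
                for d, g in zip(directions, qtl_geno)
            ]
        )

    sigma2 = scenario.residual_variance()
    phenotype = means + rng.normal(0.0, np.sqrt(sigma2), size=n)

    marker_names = [f"M{i+1}" for i in range(len(marker_idx))]
    return Population(
        phenotype=phenotype,
        direction=directions,
        genotypes=geno_codes,
        marker_names=marker_names,
        true_qtl_genotype=qtl_geno.astype(np.int8),
        scenario=scenario,
        meta={"seed": scenario.seed, "sigma2": sigma2},
    )


def table2_scenario(h2: float, n: int, seed: int | None = None) -> SimulationScenario:
    """Estimation-study preset: fixed effect truth, printed residual variance."""
    key = round(float(h2), 2)
    if key not in TABLE2_SIGMA2:
        raise ValueError(f"h2 must be one of {sorted(TABLE2_SIGMA2)}")
    return SimulationScenario(
        n=n,
        beta=TABLE2_BETA,
        sigma2=TABLE2_SIGMA2[key],
        seed=seed,
        name=f"table2-h2{key}",
    )


def table3_scenario(
    effect: str, gamma: float, h2: float, n: int, seed: int | None = None
) -> SimulationScenario:
    """Power-study preset: all effects 0.8 except the varied one.

    ``effect`` is "cyto" or "imprinting"; ``gamma`` the proportion of
    phenotypic variance attributed to the varied effect (0, 0.05 or 0.10),
    mapped to the calibrated effect values.  The residual variance is
    derived from the broad-sense heritability ``h2``.
    """
    key = round(float(gamma), 2)
    if effect == "cyto":
        if key not in TABLE3_CYTO:
            raise ValueError(f"gamma must be one of {sorted(TABLE3_CYTO)}")
        c, i = TABLE3_CYTO[key], 0.8
    elif effect == "imprinting":
        if key not in TABLE3_IMPRINTING:
            raise ValueError(f"gamma must be one of {sorted(TABLE3_IMPRINTING)}")
        c, i = 0.8, TABLE3_IMPRINTING[key]
    else:
        raise ValueError("effect must be 'cyto' or 'imprinting'")
    beta = EffectVector(mu=10.0, c=c, a=0.8, d=0.8, i=i, ica=0.8, icd=0.8, ici=0.8)
    return SimulationScenario(
        n=n, beta=beta, h2=h2, seed=seed, name=f"table3-{effect}-g{key}"
    )


def table_scenarios(name: str, **kwargs) -> SimulationScenario:
    """Dispatch to the named scenario preset ("table2" or "table3")."""
    if name == "table2":
        return table2_scenario(**kwargs)
    if name == "table3":
        return table3_scenario(**kwargs)
    raise ValueError(f"unknown preset {name!r}; expected 'table2' or 'table3'")
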