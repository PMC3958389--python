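"""Genome scan, permutation thresholds and the four-test battery.

The scan fits the full eight-parameter mixture model at every grid position
and compares it with the no-QTL null ``y = mu + c*m`` (fitted once, in
closed form), giving an LR/LOD profile whose peak is the maximum-likelihood
estimate of the QTL position.  Genome-wide significance comes from
phenotype permutations (Churchill-Doerge), by default stratified within
cross direction so the cytoplasm structure is preserved under the null.
At a detected QTL, four nested LR tests probe the cytoplasmic effect
(c=0, 1 df), imprinting (i=0, 1 df; optionally {i, ici}, 2 df),
cyto-nuclear interaction (ica=icd=ici=0, 3 df) and the additive/dominance
effects (a=d=0, 2 df), with chi-square or permutation p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .design import (
    EFFECT_NAMES,
    BackcrossType,
    CrossDirection,
    OrderedGenotype,
    backcross_design_row,
    bc_genotypes,
    f2_design_row,
)
from .linkage import GeneticMap, posteriors_at_grid, posteriors_at_position
from .mixture import (
    FULL_MODEL,
    Constraint,
    FitResult,
    em_fit,
    fit_no_qtl,
    lod_from_lr,
    lr_statistic,
)
from .population import Population

__all__ = [
    "ScanResult",
    "TestResult",
    "TestBattery",
    "PermutationResult",
    "genome_scan",
    "permutation_threshold",
    "test_battery",
]

#: effects whose sign the F2 design cannot identify (reciprocal heterozygote
#: labels are exchangeable when marker data are symmetric)
F2_SIGN_UNIDENTIFIED = ("i", "ici")


def design_tensor(pop: Population) -> np.ndarray:
    """Per-individual component design rows: (n, 4, 8) for F2, (n, 2, 8) for BC."""
    if pop.family == "F2":
        blocks = {
            direction.value: np.vstack(
                [f2_design_row(direction, g) for g in OrderedGenotype]
            )
            for direction in CrossDirection
        }
    else:
        blocks = {
            bc.value: np.vstack(
                [backcross_design_row(bc, g) for g in bc_genotypes(bc)]
            )
            for bc in BackcrossType
        }
    return np.stack([blocks[d] for d in pop.direction])


@dataclass
class ScanResult:
    """LR/LOD profile over grid positions with per-position estimates."""

    chrom: np.ndarray
    position: np.ndarray
    lr: np.ndarray
    beta: np.ndarray            # (G, 8) estimates at each position
    sigma2: np.ndarray
    converged: np.ndarray
    null_loglik: float
    family: str = "F2"
    skipped: list[str] = field(default_factory=list)

    @property
    def lod(self) -> np.ndarray:
        return lod_from_lr(self.lr)

    def peak_index(self) -> int:
        """Index of the profile maximum; ties broken by the left-most position."""
        return int(np.argmax(self.lr))

    def peak(self) -> tuple[str, float]:
        """(chromosome, position cM) of the profile maximum."""
        k = self.peak_index()
        return str(self.chrom[k]), float(self.position[k])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"chromosome": self.chrom, "position_cM": self.position})
        df["LR"] = self.lr
        df["LOD"] = self.lod
        for j, name in enumerate(EFFECT_NAMES):
            df[name] = self.beta[:, j]
        df["sigma2"] = self.sigma2
        df["converged"] = self.converged
        return df


def _scan_arrays(
    y: np.ndarray,
    grid_post: np.ndarray,
    X: np.ndarray,
    null_loglik: float,
    tol: float,
    max_iter: int,
):
    G = grid_post.shape[1]
    lr = np.empty(G)
    beta = np.empty((G, 8))
    sigma2 = np.empty(G)
    conv = np.empty(G, dtype=bool)
    init = None
    for g in range(G):
        fit = em_fit(
            y, grid_post[:, g, :], X, FULL_MODEL,
            tol=tol, max_iter=max_iter, init=init,
        )
        lr[g] = max(0.0, 2.0 * (fit.loglik - null_loglik))
        beta[g] = fit.beta.as_array()
        sigma2[g] = fit.sigma2
        conv[g] = fit.converged
        # warm-start the next grid position: adjacent positions share flanking
        # markers, so the optimum moves smoothly and EM converges in few steps
        init = (beta[g], sigma2[g])
    return lr, beta, sigma2, conv


def genome_scan(
    pop: Population,
    gmap: GeneticMap,
    step: float = 2.0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> ScanResult:
    """Scan the genome on a cM grid and profile the QTL likelihood ratio.

    At each position the full model is fitted by EM against the
    marker-conditional genotype posteriors; the LR compares it with the
    closed-form no-QTL null.  The profile argmax (left-most on ties) is the
    MLE of the QTL location.
    """
    grid = posteriors_at_grid(
        pop.genotypes, pop.direction, gmap, step=step, family=pop.family
    )
    X = design_tensor(pop)
    null = fit_no_qtl(pop.phenotype, pop.m)
    lr, beta, sigma2, conv = _scan_arrays(
        pop.phenotype, grid.post, X, null.loglik, tol, max_iter
    )
    return ScanResult(
        chrom=grid.chrom,
        position=grid.position,
        lr=lr,
        beta=beta,
        sigma2=sigma2,
        converged=conv,
        null_loglik=null.loglik,
        family=pop.family,
        skipped=grid.skipped,
    )


@dataclass
class PermutationResult:
    """Null distribution of the genome-wide maximum LR under permutation."""

    null_max_stats: np.ndarray
    alpha: float
    threshold: float
    seed: int | None
    stratified: bool

    def threshold_at(self, alpha: float) -> float:
        """Empirical (1-alpha) quantile of the null maxima."""
        return float(
            np.quantile(self.null_max_stats, 1.0 - alpha, method="higher")
        )


def _permuted(y: np.ndarray, direction: np.ndarray, rng, stratified: bool):
    if not stratified:
        return rng.permutation(y)
    out = y.copy()
    for lab in np.unique(direction):
        idx = np.where(direction == lab)[0]
        out[idx] = y[idx[rng.permutation(len(idx))]]
    return out


def permutation_threshold(
    pop: Population,
    gmap: GeneticMap,
    n_perm: int,
    alpha: float = 0.05,
    seed: int | None = None,
    stratified: bool = True,
    step: float = 2.0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> PermutationResult:
    """Churchill-Doerge genome-wide LR threshold from phenotype permutations.

    Phenotypes are shuffled (within cross-direction strata by default, so
    the cytoplasm term of the null is preserved), the genome is rescanned,
    and the maximum LR per permutation is recorded; the threshold is the
    empirical (1-alpha) quantile.  Deterministic given ``seed``.
    """
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} < 100 gives an unstable threshold", stacklevel=2
        )
    rng = np.random.default_rng(seed)
    grid = posteriors_at_grid(
        pop.genotypes, pop.direction, gmap, step=step, family=pop.family
    )
    X = design_tensor(pop)
    maxima = np.empty(n_perm)
    for b in range(n_perm):
        y_perm = _permuted(pop.phenotype, pop.direction, rng, stratified)
        null = fit_no_qtl(y_perm, pop.m)
        lr, *_ = _scan_arrays(y_perm, grid.post, X, null.loglik, tol, max_iter)
        maxima[b] = lr.max()
    threshold = float(np.quantile(maxima, 1.0 - alpha, method="higher"))
    return PermutationResult(
        null_max_stats=maxima,
        alpha=alpha,
        threshold=threshold,
        seed=seed,
        stratified=stratified,
    )


@dataclass
class TestResult:
    """One LR test of a nested null against the full model at a position."""

    name: str
    zeroed: tuple[str, ...]
    lr: float
    df: int
    p_value: float
    method: str


@dataclass
class TestBattery:
    """The four-test battery at a detected QTL position."""

    chrom: str
    position: float
    full: FitResult
    cytoplasmic: TestResult
    imprinting: TestResult
    interaction: TestResult
    additive_dominance: TestResult
    converged: bool = True

    @property
    def tests(self) -> tuple[TestResult, ...]:
        return (
            self.cytoplasmic,
            self.imprinting,
            self.interaction,
            self.additive_dominance,
        )

    def to_dict(self) -> dict:
        return {
            "chromosome": self.chrom,
            "position_cM": self.position,
            "converged": self.converged,
            "full": self.full.to_dict(),
            "tests": {
                t.name: {
                    "zeroed": list(t.zeroed),
                    "LR": t.lr,
                    "df": t.df,
                    "p_value": t.p_value,
                    "method": t.method,
                }
                for t in self.tests
            },
        }


def _battery_constraints(imprinting_joint: bool) -> list[tuple[str, tuple[str, ...]]]:
    imprint = ("i", "ici") if imprinting_joint else ("i",)
    return [
        ("cytoplasmic", ("c",)),
        ("imprinting", imprint),
        ("interaction", ("ica", "icd", "ici")),
        ("additive_dominance", ("a", "d")),
    ]


def test_battery(
    pop: Population,
    gmap: GeneticMap,
    position: tuple[str, float] | float,
    imprinting_joint: bool = False,
    n_perm: int | None = None,
    seed: int | None = None,
    stratified: bool = True,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> TestBattery:
    """Run the four nested LR tests at a genome position.

    ``position`` is ``(chromosome, cM)`` (the chromosome may be omitted for
    single-chromosome maps).  P-values use the chi-square reference with df
    equal to the number of zeroed effects, or position-fixed phenotype
    permutations when ``n_perm`` is given.  ``imprinting_joint=True`` widens
    the imprinting null to {i, ici} (2 df).
    """
    if isinstance(position, (int, float)):
        if len(gmap.chromosomes) != 1:
            raise ValueError("position must be (chromosome, cM) for multi-chromosome maps")
        chrom, pos = gmap.chromosomes[0].name, float(position)
    else:
        chrom, pos = str(position[0]), float(position[1])

    post = posteriors_at_position(
        pop.genotypes, pop.direction, gmap, chrom, pos, family=pop.family
    )
    X = design_tensor(pop)
    y = pop.phenotype

    sign_un = F2_SIGN_UNIDENTIFIED if pop.family == "F2" else ()
    full = em_fit(y, post, X, FULL_MODEL, tol=tol, max_iter=max_iter)
    full.sign_unidentified = sign_un

    specs = _battery_constraints(imprinting_joint)
    nulls = {
        name: em_fit(y, post, X, Constraint(frozenset(z)), tol=tol, max_iter=max_iter)
        for name, z in specs
    }
    lrs = {name: lr_statistic(full, nulls[name]) for name, _ in specs}

    if n_perm is None:
        pvals = {
            name: float(chi2.sf(lrs[name], df=len(z))) for name, z in specs
        }
        method = "chi-square"
    else:
        rng = np.random.default_rng(seed)
        exceed = {name: 0 for name, _ in specs}
        for _ in range(n_perm):
            y_perm = _permuted(y, pop.direction, rng, stratified)
            full_p = em_fit(y_perm, post, X, FULL_MODEL, tol=tol, max_iter=max_iter)
            for name, z in specs:
                null_p = em_fit(
                    y_perm, post, X, Constraint(frozenset(z)),
                    tol=tol, max_iter=max_iter,
                )
                if lr_statistic(full_p, null_p) >= lrs[name]:
                    exceed[name] += 1
        pvals = {
            name: (1.0 + exceed[name]) / (1.0 + n_perm) for name, _ in specs
        }
        method = "permutation"

    results = {
        name: TestResult(
            name=name,
            zeroed=tuple(z),
            lr=lrs[name],
            df=len(z),
            p_value=pvals[name],
            method=method,
        )
        for name, z in specs
    }
    converged = full.converged and all(f.converged for f in nulls.values())
    if not converged:
        warnings.warn("some fits did not converge; tests flagged", stacklevel=2)
    return TestBattery(
        chrom=chrom,
        position=pos,
        full=full,
        cytoplasmic=results["cytoplasmic"],
        imprinting=results["imprinting"],
        interaction=results["interaction"],
        additive_dominance=results["additive_dominance"],
        converged=converged,
    )


def plot_profile(result: ScanResult, path: str, threshold: float | None = None) -> None:
    """Write a LOD profile plot to ``path`` (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    offset = 0.0
    for name in dict.fromkeys(result.chrom.tolist()):
        mask = result.chrom == name
        pos = result.position[mask]
        ax.plot(pos - pos[0] + offset, result.lod[mask], label=str(name))
        offset += pos[-1] - pos[0] + 5.0
    if threshold is not None:
        ax.axhline(lod_from_lr(threshold), color="red", linestyle="--")
    ax.set_xlabel("position (cM)")
    ax.set_ylabel("LOD")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
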