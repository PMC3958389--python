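"""Genetic-map arithmetic and QTL-genotype posteriors from flanking markers.

Interval mapping treats the QTL genotype of each individual as missing data
and infers it from the two markers flanking the tested position.  Because
an F2 cross cannot distinguish the two reciprocal heterozygotes from
unordered marker codes, the posteriors here are computed over *ordered*
genotypes by tracking the maternal and paternal gametes separately, with
sex-specific recombination fractions: the maternal gamete recombines at
female map distances and the paternal gamete at male distances.  A single
female:male map-expansion ratio ``lambda`` (1.25 for mouse) converts the
sex-averaged map into the two sex-specific maps.

Recombination uses the Haldane map function (no crossover interference),
which makes crossovers in adjacent intervals independent and gives the
three-point conditional probability

    P(QTL allele | left allele, right allele) = t1 * t2 / t12

with transition probabilities t = r or 1 - r per interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd



__all__ = [
    "GeneticMap",
    "ChromosomeMap",
    "ScanGrid",
    "haldane_r",
    "sex_split",
    "gamete_allele_prob",
    "qtl_genotype_posterior",
    "posteriors_at_grid",
    "posteriors_at_position",
]

# Marker genotype codes used package-wide.
HOM_A = 0   # P1/P1
HET = 1
HOM_B = 2   # P2/P2
MISSING = -1

DEFAULT_LAMBDA = 1.25  # mouse genome-wide female:male map ratio


class ImpossibleConfigurationError(ValueError):
    """A marker configuration with zero prior probability was conditioned on."""


@dataclass
class ChromosomeMap:
    """Marker names and strictly increasing sex-averaged positions (cM)."""

    name: str
    markers: list[str]
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.markers) != len(self.positions):
            raise ValueError("marker names and positions differ in length")
        if len(self.positions) < 1:
            raise ValueError(f"chromosome {self.name}: empty marker list")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError(
                f"chromosome {self.name}: positions must be strictly increasing"
            )


@dataclass
class GeneticMap:
    """A genetic map: one or more linkage groups plus the sex map ratio lambda."""

    chromosomes: list[ChromosomeMap]
    lam: float = DEFAULT_LAMBDA

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda (female:male map ratio) must be > 0")
        if not self.chromosomes:
            raise ValueError("empty genetic map")

    @property
    def marker_names(self) -> list[str]:
        """Global marker order: chromosomes in map order, markers left to right."""
        return [m for ch in self.chromosomes for m in ch.markers]

    @property
    def n_markers(self) -> int:
        return sum(len(ch.markers) for ch in self.chromosomes)

    def chrom_slices(self) -> list[tuple[ChromosomeMap, slice]]:
        """Each chromosome with its column slice into the global marker order."""
        out, start = [], 0
        for ch in self.chromosomes:
            out.append((ch, slice(start, start + len(ch.markers))))
            start += len(ch.markers)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chromosome": [ch.name for ch in self.chromosomes for _ in ch.markers],
                "marker": self.marker_names,
                "position_cM": np.concatenate(
                    [ch.positions for ch in self.chromosomes]
                ),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, lam: float = DEFAULT_LAMBDA) -> "GeneticMap":
        required = {"chromosome", "marker", "position_cM"}
        if not required.issubset(df.columns):
            raise ValueError(f"map file needs columns {sorted(required)}")
        chroms = []
        for name, grp in df.groupby("chromosome", sort=False):
            chroms.append(
                ChromosomeMap(
                    str(name),
                    [str(m) for m in grp["marker"]],
                    grp["position_cM"].to_numpy(dtype=float),
                )
            )
        return cls(chroms, lam=lam)


def haldane_r(d):
    """Haldane map function: distance d (cM) -> recombination fraction in [0, 0.5)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be nonnegative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if r.ndim == 0 else r


def sex_split(d_avg, lam: float):
    """Split a sex-averaged distance into (female, male) distances.

    d_f = 2*lam*d/(1+lam), d_m = 2*d/(1+lam); their mean is d and their
    ratio is lam.
    """
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    d_avg = np.asarray(d_avg, dtype=float)
    if np.any(d_avg < 0):
        raise ValueError("map distance must be nonnegative")
    d_f = 2.0 * lam * d_avg / (1.0 + lam)
    d_m = 2.0 * d_avg / (1.0 + lam)
    if d_f.ndim == 0:
        return float(d_f), float(d_m)
    return d_f, d_m


def gamete_allele_prob(left: int, right: int, r1: float, r2: float) -> float:
    """P(gamete carries allele A at the QTL | flanking gamete alleles).

    Alleles are coded 0 (A) / 1 (B).  ``r1`` is the recombination fraction
    between the left marker and the QTL, ``r2`` between the QTL and the
    right marker; no interference, so r12 = r1 + r2 - 2*r1*r2.
    """
    r12 = r1 + r2 - 2.0 * r1 * r2
    t1 = (1.0 - r1) if left == 0 else r1
    t2 = (1.0 - r2) if right == 0 else r2
    t12 = (1.0 - r12) if left == right else r12
    if t12 == 0.0:
        raise ImpossibleConfigurationError(
            "flanking alleles are discordant but the interval has zero "
            "recombination probability"
        )
    return t1 * t2 / t12


def _two_locus_weight(same: bool, r12: float) -> float:
    """Prior probability of an ordered two-locus F1 gamete (1/2 per first allele)."""
    return 0.5 * ((1.0 - r12) if same else r12)


def _interval_rates(d_left: float, d_right: float, lam: float):
    """Sex-specific recombination fractions for the two sub-intervals."""
    if d_left < 0 or d_right < 0:
        raise ValueError("interval distances must be nonnegative")
    dlf, dlm = sex_split(d_left, lam)
    drf, drm = sex_split(d_right, lam)
    return (haldane_r(dlf), haldane_r(drf)), (haldane_r(dlm), haldane_r(drm))


def _f2_posterior_table(d_left: float, d_right: float, lam: float) -> np.ndarray:
    """Posterior over ordered QTL genotypes for every observed flank-code pair.

    Returns a (4, 4, 4) array indexed by (left_code+1, right_code+1) with the
    convention MISSING -> slot 0, so codes -1/0/1/2 map to slots 0..3.  Cells
    whose marker configuration has zero prior mass are NaN.

    The enumeration runs over the ordered alleles carried by the maternal and
    paternal gametes at the two flanking markers (16 configurations), weights
    each by its two-locus gamete probability (female rates for the maternal
    gamete, male rates for the paternal one), multiplies in the conditional
    QTL-allele probabilities, and marginalizes onto the observed unordered
    marker codes.
    """
    (rf1, rf2), (rm1, rm2) = _interval_rates(d_left, d_right, lam)
    rf12 = rf1 + rf2 - 2.0 * rf1 * rf2
    rm12 = rm1 + rm2 - 2.0 * rm1 * rm2

    table = np.zeros((4, 4, 4))
    for ml, mr in product((0, 1), repeat=2):
        wm = _two_locus_weight(ml == mr, rf12)
        if wm == 0.0:
            continue
        p_am = gamete_allele_prob(ml, mr, rf1, rf2)
        for pl, pr in product((0, 1), repeat=2):
            wp = _two_locus_weight(pl == pr, rm12)
            if wp == 0.0:
                continue
            p_ap = gamete_allele_prob(pl, pr, rm1, rm2)
            w = wm * wp
            # ordered genotype = (maternal allele, paternal allele):
            # AmAf, AmBf, BmAf, BmBf
            v = w * np.array(
                [
                    p_am * p_ap,
                    p_am * (1.0 - p_ap),
                    (1.0 - p_am) * p_ap,
                    (1.0 - p_am) * (1.0 - p_ap),
                ]
            )
            lc = ml + pl  # unordered marker code 0/1/2
            rc = mr + pr
            for li in (0, lc + 1):  # slot 0 accumulates the MISSING marginal
                for ri in (0, rc + 1):
                    table[li, ri] += v

    sums = table.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        table = np.where(sums > 0, table / sums, np.nan)
    return table


def _bc_posterior_table(
    d_left: float, d_right: float, lam: float, paternal_allele: int
) -> np.ndarray:
    """Backcross analogue of :func:`_f2_posterior_table`.

    In a backcross only the maternal (F1) gamete segregates; the paternal
    allele is fixed by the recurrent parent.  Returns a (4, 4, 2) array over
    the two components ordered (maternal allele A, maternal allele B).
    """
    (rf1, rf2), _ = _interval_rates(d_left, d_right, lam)
    rf12 = rf1 + rf2 - 2.0 * rf1 * rf2

    table = np.zeros((4, 4, 2))
    for ml, mr in product((0, 1), repeat=2):
        wm = _two_locus_weight(ml == mr, rf12)
        if wm == 0.0:
            continue
        p_am = gamete_allele_prob(ml, mr, rf1, rf2)
        v = wm * np.array([p_am, 1.0 - p_am])
        lc = ml + paternal_allele
        rc = mr + paternal_allele
        for li in (0, lc + 1):
            for ri in (0, rc + 1):
                table[li, ri] += v

    sums = table.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        table = np.where(sums > 0, table / sums, np.nan)
    return table


def qtl_genotype_posterior(
    left_code: int,
    right_code: int,
    d_left: float,
    d_right: float,
    lam: float = DEFAULT_LAMBDA,
    direction=None,
) -> np.ndarray:
    """Posterior over the four ordered QTL genotypes for one F2 individual.

    ``left_code``/``right_code`` are the unordered flanking-marker codes
    (0=HOM_A, 1=HET, 2=HOM_B, -1=missing), ``d_left``/``d_right`` the
    sex-averaged distances (cM) from the tested position to the flanks.

    ``direction`` is accepted for interface symmetry but does not enter the
    computation: in both reciprocal F2 directions each parent is an F1
    heterozygous at every locus, so the gamete process is identical.
    """
    del direction
    table = _f2_posterior_table(d_left, d_right, lam)
    post = table[left_code + 1, right_code + 1]
    if np.any(np.isnan(post)):
        raise ImpossibleConfigurationError(
            f"marker codes ({left_code}, {right_code}) have zero prior "
            "probability at the given distances"
        )
    return post


@dataclass
class ScanGrid:
    """Per-individual QTL-genotype posteriors over a grid of genome positions."""

    chrom: np.ndarray          # (G,) chromosome name per grid position
    position: np.ndarray       # (G,) cM, map coordinates
    post: np.ndarray           # (n, G, K) posterior probabilities
    skipped: list[str] = field(default_factory=list)

    @property
    def n_positions(self) -> int:
        return len(self.position)


def _grid_positions(positions: np.ndarray, step: float) -> np.ndarray:
    """Grid from the first to the last marker inclusive."""
    if step <= 0:
        raise ValueError("step must be > 0")
    p0, p1 = positions[0], positions[-1]
    grid = np.arange(p0, p1 + 1e-9, step)
    if grid[-1] < p1 - 1e-9:
        grid = np.append(grid, p1)
    return grid


def _flank_interval(positions: np.ndarray, pos: float) -> tuple[int, float, float]:
    """Flanking-marker index pair for a position within the map span."""
    k = int(np.searchsorted(positions, pos, side="right")) - 1
    k = min(max(k, 0), len(positions) - 2)
    return k, pos - positions[k], positions[k + 1] - pos


def _bc_paternal_allele(direction: str) -> int:
    # BC1/BC2 backcross to P1 (paternal allele A); BC3/BC4 to P2 (allele B)
    return 0 if direction in ("BC1", "BC2") else 1


def _position_posteriors(
    geno: np.ndarray,
    directions: np.ndarray,
    family: str,
    k: int,
    d_left: float,
    d_right: float,
    lam: float,
) -> np.ndarray:
    """Posterior matrix (n, K) at one position given local genotype columns."""
    lcodes = geno[:, k] + 1
    rcodes = geno[:, k + 1] + 1
    if family == "F2":
        table = _f2_posterior_table(d_left, d_right, lam)
        post = table[lcodes, rcodes]
    else:
        post = np.empty((len(lcodes), 2))
        for pa in (0, 1):
            mask = np.array([_bc_paternal_allele(d) == pa for d in directions])
            if not mask.any():
                continue
            table = _bc_posterior_table(d_left, d_right, lam, pa)
            post[mask] = table[lcodes[mask], rcodes[mask]]
    if np.any(np.isnan(post)):
        bad = np.where(np.isnan(post).any(axis=1))[0][0]
        raise ImpossibleConfigurationError(
            f"individual {bad}: flanking-marker codes have zero prior "
            "probability (check genotype coding against the design)"
        )
    return post


def posteriors_at_grid(
    genotypes: np.ndarray,
    directions: np.ndarray,
    gmap: GeneticMap,
    step: float = 2.0,
    family: str = "F2",
) -> ScanGrid:
    """QTL-genotype posteriors for every individual at every grid position.

    Parameters
    ----------
    genotypes : (n, M) int array of marker codes in the map's global order.
    directions : (n,) array of cross-direction labels ("F"/"Fprime" or BC1..BC4).
    step : grid increment in cM; each chromosome is covered from its first to
        its last marker inclusive.  At a marker the flanking interval
        degenerates and the posterior is driven by that marker alone.
    family : "F2" or "BC"; determines the component space (4 ordered
        genotypes for F2, 2 for BC).

    Chromosomes whose genotypes are entirely missing are skipped with a
    warning and recorded in ``ScanGrid.skipped``.
    """
    genotypes = np.asarray(genotypes)
    chroms, poss, blocks, skipped = [], [], [], []
    for ch, sl in gmap.chrom_slices():
        sub = genotypes[:, sl]
        if np.all(sub == MISSING):
            warnings.warn(
                f"chromosome {ch.name}: all genotypes missing; skipped",
                stacklevel=2,
            )
            skipped.append(ch.name)
            continue
        if len(ch.positions) < 2:
            warnings.warn(
                f"chromosome {ch.name}: fewer than two markers; skipped",
                stacklevel=2,
            )
            skipped.append(ch.name)
            continue
        grid = _grid_positions(ch.positions, step)
        for pos in grid:
            k, d_l, d_r = _flank_interval(ch.positions, pos)
            blocks.append(
                _position_posteriors(
                    sub, directions, family, k, d_l, d_r, gmap.lam
                )
            )
            chroms.append(ch.name)
            poss.append(pos)
    if not blocks:
        raise ValueError("no scannable chromosome in the map")
    return ScanGrid(
        chrom=np.array(chroms),
        position=np.array(poss, dtype=float),
        post=np.stack(blocks, axis=1),
        skipped=skipped,
    )


def posteriors_at_position(
    genotypes: np.ndarray,
    directions: np.ndarray,
    gmap: GeneticMap,
    chrom: str,
    pos: float,
    family: str = "F2",
) -> np.ndarray:
    """Posterior matrix (n, K) at a single genome position."""
    for ch, sl in gmap.chrom_slices():
        if ch.name == str(chrom):
            if not (ch.positions[0] - 1e-9 <= pos <= ch.positions[-1] + 1e-9):
                raise ValueError(
                    f"position {pos} cM outside chromosome {chrom} "
                    f"span [{ch.positions[0]}, {ch.positions[-1]}]"
                )
            k, d_l, d_r = _flank_interval(ch.positions, pos)
            return _position_posteriors(
                np.asarray(genotypes)[:, sl], directions, family, k, d_l, d_r,
                gmap.lam,
            )
    raise ValueError(f"chromosome {chrom!r} not in map")
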