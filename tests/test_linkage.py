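"""Map arithmetic and ordered-genotype posteriors vs an enumeration oracle."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cytoqtl.linkage import (
    HET,
    HOM_A,
    HOM_B,
    MISSING,
    ChromosomeMap,
    GeneticMap,
    ImpossibleConfigurationError,
    gamete_allele_prob,
    haldane_r,
    posteriors_at_grid,
    posteriors_at_position,
    qtl_genotype_posterior,
    sex_split,
)


# ---------------------------------------------------------------- map function

def test_haldane_limits():
    assert haldane_r(0.0) == 0.0
    assert haldane_r(1e6) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        haldane_r(-1.0)


@given(st.floats(0, 200), st.floats(0, 200))
def test_haldane_additivity(d1, d2):
    r1, r2 = haldane_r(d1), haldane_r(d2)
    assert haldane_r(d1 + d2) == pytest.approx(r1 + r2 - 2 * r1 * r2, abs=1e-12)


def test_sex_split_closed_form():
    d_f, d_m = sex_split(20.0, 1.25)
    assert d_f == pytest.approx(200.0 / 9.0)
    assert d_m == pytest.approx(160.0 / 9.0)
    assert sex_split(7.0, 1.0) == (pytest.approx(7.0), pytest.approx(7.0))
    with pytest.raises(ValueError):
        sex_split(1.0, 0.0)


@given(st.floats(0, 100), st.floats(0.1, 5))
def test_sex_split_mean_and_ratio(d, lam):
    d_f, d_m = sex_split(d, lam)
    assert (d_f + d_m) / 2 == pytest.approx(d, abs=1e-9)
    if d > 1e-300:
        assert d_f / d_m == pytest.approx(lam, rel=1e-9)


# ---------------------------------------------------- three-point gamete rule

def test_gamete_allele_prob_limits():
    assert gamete_allele_prob(0, 0, 0.0, 0.0) == 1.0
    assert gamete_allele_prob(0, 1, 0.2, 0.2) == pytest.approx(0.5)
    expected = (0.92 * 0.88) / (1 - (0.08 + 0.12 - 2 * 0.08 * 0.12))
    assert gamete_allele_prob(0, 0, 0.08, 0.12) == pytest.approx(expected)
    assert expected == pytest.approx(0.98828, abs=1e-5)
    with pytest.raises(ImpossibleConfigurationError):
        gamete_allele_prob(0, 1, 0.0, 0.0)


# ------------------------------------------------------- enumeration oracle

def _transition(a, b, r):
    return (1 - r) if a == b else r


def oracle_posterior(lc, rc, d_left, d_right, lam):
    """Posterior over ordered QTL genotypes by exhaustive three-locus
    enumeration of maternal x paternal gametes; independent of the
    conditional-probability code path."""
    dlf, dlm = sex_split(d_left, lam)
    drf, drm = sex_split(d_right, lam)
    rf = (haldane_r(dlf), haldane_r(drf))
    rm = (haldane_r(dlm), haldane_r(drm))
    post = np.zeros(4)
    for mg in product((0, 1), repeat=3):
        wm = 0.5 * _transition(mg[0], mg[1], rf[0]) * _transition(mg[1], mg[2], rf[1])
        for pg in product((0, 1), repeat=3):
            wp = 0.5 * _transition(pg[0], pg[1], rm[0]) * _transition(pg[1], pg[2], rm[1])
            if lc != MISSING and mg[0] + pg[0] != lc:
                continue
            if rc != MISSING and mg[2] + pg[2] != rc:
                continue
            post[2 * mg[1] + pg[1]] += wm * wp
    return post / post.sum()


@pytest.mark.parametrize("lam", [1.0, 1.25, 2.0])
@pytest.mark.parametrize("d_left,d_right", [(2.0, 18.0), (10.0, 10.0), (0.5, 3.0)])
def test_posterior_matches_enumeration_oracle(lam, d_left, d_right):
    codes = (MISSING, HOM_A, HET, HOM_B)
    for lc in codes:
        for rc in codes:
            ours = qtl_genotype_posterior(lc, rc, d_left, d_right, lam)
            theirs = oracle_posterior(lc, rc, d_left, d_right, lam)
            np.testing.assert_allclose(ours, theirs, atol=1e-10)
            assert np.all(ours >= 0)
            assert ours.sum() == pytest.approx(1.0, abs=1e-12)


def test_tight_linkage_is_degenerate():
    post = qtl_genotype_posterior(HOM_A, HOM_A, 0.01, 0.01, 1.25)
    assert post[0] > 0.999
    assert post[1:].max() < 1e-3


def test_double_het_reciprocal_heterozygotes_equiprobable_any_lambda():
    # A<->B label swap of both gametes fixes double-HET marker data and
    # exchanges the reciprocal heterozygotes: exact symmetry at any lambda.
    for lam in (1.0, 1.25, 3.0):
        post = qtl_genotype_posterior(HET, HET, 4.0, 16.0, lam)
        assert post[1] == pytest.approx(post[2], abs=1e-12)


def test_asymmetric_flanks_split_heterozygotes_only_with_sex_difference():
    sym = qtl_genotype_posterior(HOM_A, HET, 10.0, 10.0, 1.0)
    assert sym[1] == pytest.approx(sym[2], abs=1e-12)
    asym = qtl_genotype_posterior(HOM_A, HET, 10.0, 10.0, 1.25)
    assert abs(asym[1] - asym[2]) > 1e-4


def test_both_missing_gives_mendelian_prior():
    post = qtl_genotype_posterior(MISSING, MISSING, 5.0, 15.0, 1.25)
    np.testing.assert_allclose(post, 0.25, atol=1e-12)


# ------------------------------------------------------------------ grid scan

def _single_chrom_map(positions, lam=1.25):
    return GeneticMap(
        [ChromosomeMap("1", [f"M{i}" for i in range(len(positions))],
                       np.asarray(positions, float))],
        lam=lam,
    )


def test_grid_covers_map_inclusively():
    gmap = _single_chrom_map(np.linspace(0, 100, 6))
    n = 5
    geno = np.zeros((n, 6), dtype=np.int8)
    grid = posteriors_at_grid(geno, np.array(["F"] * n, object), gmap, step=2.0)
    assert grid.n_positions == 51
    assert grid.position[0] == 0.0 and grid.position[-1] == 100.0
    np.testing.assert_allclose(grid.post.sum(axis=2), 1.0, atol=1e-12)


def test_posterior_degenerate_at_informative_marker():
    gmap = _single_chrom_map([0.0, 20.0, 40.0])
    geno = np.array([[HOM_A, HOM_B, HET]], dtype=np.int8)
    dirs = np.array(["F"], object)
    at_marker = posteriors_at_position(geno, dirs, gmap, "1", 20.0)
    # HOM_B marker: both gametes carried B -> BmBf with certainty
    np.testing.assert_allclose(at_marker[0], [0, 0, 0, 1], atol=1e-12)


def test_all_missing_chromosome_skipped_with_warning():
    gmap = GeneticMap(
        [
            ChromosomeMap("1", ["A1", "A2"], np.array([0.0, 20.0])),
            ChromosomeMap("2", ["B1", "B2"], np.array([0.0, 20.0])),
        ]
    )
    geno = np.zeros((3, 4), dtype=np.int8)
    geno[:, 2:] = MISSING
    with pytest.warns(UserWarning, match="chromosome 2"):
        grid = posteriors_at_grid(geno, np.array(["F"] * 3, object), gmap, step=5.0)
    assert set(grid.chrom) == {"1"}
    assert grid.skipped == ["2"]


def test_map_validation():
    with pytest.raises(ValueError, match="strictly increasing"):
        ChromosomeMap("1", ["a", "b"], np.array([10.0, 5.0]))
    with pytest.raises(ValueError, match="lambda"):
        GeneticMap([ChromosomeMap("1", ["a"], np.array([0.0]))], lam=-1)
    with pytest.raises(ValueError, match="empty"):
        GeneticMap([])
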