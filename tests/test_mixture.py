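"""Mixture likelihood, EM fitting, constraints and LR statistics."""

from itertools import product

import numpy as np
import pytest

from cytoqtl.design import EffectVector, OrderedGenotype, f2_design_row, CrossDirection
from cytoqtl.mixture import (
    FULL_MODEL,
    NO_QTL,
    Constraint,
    RankDeficiencyError,
    em_fit,
    fit_no_qtl,
    lod_from_lr,
    lr_statistic,
    mixture_loglik,
)


def _f2_block(direction):
    return np.vstack([f2_design_row(direction, g) for g in OrderedGenotype])


def _toy_problem(rng, n=60):
    """Small F2-style mixture with known design tensor and soft posteriors."""
    X = np.stack([_f2_block(CrossDirection.F if i % 2 else CrossDirection.FPRIME)
                  for i in range(n)])
    priors = rng.dirichlet(np.ones(4), size=n)
    beta = EffectVector(10, 1, 1, 0.8, 0, 0.6, 0.5, 0)
    comp = rng.integers(0, 4, size=n)
    means = np.einsum("nkp,p->nk", X, beta.as_array())
    y = means[np.arange(n), comp] + rng.normal(0, 1.0, n)
    return y, priors, X, beta


def test_loglik_degenerate_posterior_is_normal_density():
    X = _f2_block(CrossDirection.F)[None, :, :]
    beta = EffectVector(10, 1, 1, 0.8, 0, 0.6, 0.5, 0)
    mean1 = X[0, 1] @ beta.as_array()
    priors = np.array([[0.0, 1.0, 0.0, 0.0]])
    sigma2 = 0.7
    ll = mixture_loglik(np.array([mean1]), priors, X, beta, sigma2)
    assert ll == pytest.approx(-0.5 * np.log(2 * np.pi * sigma2))


def test_loglik_translation_invariance(rng):
    y, priors, X, beta = _toy_problem(rng)
    base = mixture_loglik(y, priors, X, beta, 1.3)
    shifted_beta = EffectVector.from_array(beta.as_array() + np.eye(8)[0] * 5.0)
    shifted = mixture_loglik(y + 5.0, priors, X, shifted_beta, 1.3)
    assert shifted == pytest.approx(base, abs=1e-9)


def test_loglik_matches_assignment_enumeration(rng):
    """Sum over all per-individual genotype assignments on 3 individuals."""
    y, priors, X, beta = _toy_problem(rng, n=3)
    sigma2 = 1.7
    means = np.einsum("nkp,p->nk", X, beta.as_array())

    def norm_pdf(x, m):
        return np.exp(-((x - m) ** 2) / (2 * sigma2)) / np.sqrt(2 * np.pi * sigma2)

    total = 0.0
    for assign in product(range(4), repeat=3):
        term = 1.0
        for i, j in enumerate(assign):
            term *= priors[i, j] * norm_pdf(y[i], means[i, j])
        total += term
    assert mixture_loglik(y, priors, X, beta, sigma2) == pytest.approx(
        np.log(total), abs=1e-10
    )


def test_loglik_rejects_nonpositive_variance(rng):
    y, priors, X, beta = _toy_problem(rng, n=5)
    with pytest.raises(ValueError):
        mixture_loglik(y, priors, X, beta, 0.0)


def test_em_with_degenerate_posteriors_equals_ols(rng):
    """A QTL at a fully informative marker reduces EM to one regression."""
    n = 120
    y, _, X, beta = _toy_problem(rng, n=n)
    comp = rng.integers(0, 4, size=n)
    priors = np.zeros((n, 4))
    priors[np.arange(n), comp] = 1.0
    rows = X[np.arange(n), comp, :]
    y = rows @ beta.as_array() + rng.normal(0, 0.8, n)

    fit = em_fit(y, priors, X)
    coef, *_ = np.linalg.lstsq(rows, y, rcond=None)
    np.testing.assert_allclose(fit.beta.as_array(), coef, atol=1e-10)
    resid = y - rows @ coef
    assert fit.sigma2 == pytest.approx(float(resid @ resid / n), abs=1e-10)
    assert fit.converged


def test_all_effects_zeroed_gives_sample_moments(rng):
    y, priors, X, _ = _toy_problem(rng, n=80)
    constraint = Constraint(frozenset({"c", "a", "d", "i", "ica", "icd", "ici"}))
    fit = em_fit(y, priors, X, constraint)
    assert fit.beta.mu == pytest.approx(y.mean(), abs=1e-9)
    assert fit.sigma2 == pytest.approx(y.var(), abs=1e-9)
    for name in constraint.zeroed:
        assert getattr(fit.beta, name) == 0.0


def test_em_loglik_monotone_ascent(rng):
    y, priors, X, _ = _toy_problem(rng, n=200)
    fit = em_fit(y, priors, X)
    increments = np.diff(fit.loglik_trace)
    assert np.all(increments >= -1e-9)
    assert fit.converged


def test_em_scale_equivariance(rng):
    y, priors, X, _ = _toy_problem(rng, n=150)
    f1 = em_fit(y, priors, X)
    f2 = em_fit(3.0 * y, priors, X)
    np.testing.assert_allclose(f2.beta.as_array(), 3.0 * f1.beta.as_array(),
                               atol=1e-5)
    assert f2.sigma2 == pytest.approx(9.0 * f1.sigma2, rel=1e-5)


def test_em_nonconvergence_flagged_not_raised(rng):
    y, priors, X, _ = _toy_problem(rng, n=100)
    fit = em_fit(y, priors, X, max_iter=2)
    assert not fit.converged
    assert fit.n_iter >= 2


def test_rank_deficiency_names_confounded_effects(rng):
    # single cross direction: cytoplasm indicator is constant -> c ~ mu
    n = 50
    X = np.stack([_f2_block(CrossDirection.F)] * n)
    priors = np.full((n, 4), 0.25)
    y = rng.normal(10, 1, n)
    with pytest.raises(RankDeficiencyError, match="confounded"):
        em_fit(y, priors, X)


def test_heterozygote_relabeling_invariance_under_no_imprinting(rng):
    """With {i, ici} zeroed the two reciprocal heterozygote components share a
    mean, so swapping their posterior columns cannot change the fit."""
    y, priors, X, _ = _toy_problem(rng, n=120)
    constraint = Constraint(frozenset({"i", "ici"}))
    swapped = priors.copy()
    swapped[:, [1, 2]] = swapped[:, [2, 1]]
    f1 = em_fit(y, priors, X, constraint)
    f2 = em_fit(y, swapped, X, constraint)
    np.testing.assert_allclose(f1.beta.as_array(), f2.beta.as_array(), atol=1e-8)
    assert f1.loglik == pytest.approx(f2.loglik, abs=1e-8)


def test_constraint_validation():
    with pytest.raises(ValueError, match="mu"):
        Constraint(frozenset({"mu"}))
    assert NO_QTL.df == 6
    assert Constraint(frozenset({"c"})).free_indices() == [0, 2, 3, 4, 5, 6, 7]


def test_lr_statistic_and_nesting(rng):
    y, priors, X, _ = _toy_problem(rng, n=100)
    full = em_fit(y, priors, X)
    null = em_fit(y, priors, X, Constraint(frozenset({"c"})))
    assert lr_statistic(full, full) == 0.0
    lr = lr_statistic(full, null)
    assert lr == pytest.approx(max(0.0, 2 * (full.loglik - null.loglik)), abs=1e-12)
    with pytest.raises(ValueError, match="nested"):
        lr_statistic(null, full)


def test_no_qtl_closed_form(rng):
    n = 200
    m = np.repeat([-1.0, 1.0], n // 2)
    y = 10 + 0.5 * m + rng.normal(0, 1, n)
    fit = fit_no_qtl(y, m)
    coef, *_ = np.linalg.lstsq(np.column_stack([np.ones(n), m]), y, rcond=None)
    assert fit.beta.mu == pytest.approx(coef[0])
    assert fit.beta.c == pytest.approx(coef[1])
    assert fit.constraint == NO_QTL


def test_lod_conversion():
    assert lod_from_lr(2 * np.log(10) * 2) == pytest.approx(2.0)
    assert lod_from_lr(4.605) == pytest.approx(1.0, abs=1e-3)
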