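"""Design-constrained Gaussian mixture likelihood and its EM maximizer.

Each individual's phenotype is a mixture over its possible ordered QTL
genotypes: component j of individual i has mean ``row_ij . beta`` (a design
row from :mod:`cytoqtl.design`) and common variance sigma^2, with mixture
proportions given by the marker-conditional posteriors from
:mod:`cytoqtl.linkage`.  Null models for hypothesis tests are expressed as
zero-constraints on subsets of the seven genetic effects; the M-step then
solves the responsibility-weighted least-squares problem in the remaining
free coefficients.

EM details: the fit is initialized deterministically from a single weighted
least-squares pass that uses the prior mixture proportions as weights, so
results do not depend on a random seed.  The log-likelihood is
nondecreasing across iterations; convergence is declared when the increment
drops below ``tol`` (default 1e-8) or after ``max_iter`` iterations
(default 500), in which case the result is flagged unconverged rather than
raising.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .design import EFFECT_NAMES, EffectVector

__all__ = [
    "Constraint",
    "FitResult",
    "RankDeficiencyError",
    "FULL_MODEL",
    "NO_QTL",
    "mixture_loglik",
    "em_fit",
    "fit_no_qtl",
    "lr_statistic",
    "lod_from_lr",
]

_LOG_2PI = float(np.log(2.0 * np.pi))
_LN10_X2 = float(2.0 * np.log(10.0))

#: effects that may be zero-constrained (mu never; sigma^2 always free)
CONSTRAINABLE = frozenset(EFFECT_NAMES[1:])


class RankDeficiencyError(np.linalg.LinAlgError):
    """The weighted normal equations are singular: some effects are confounded."""


@dataclass(frozen=True)
class Constraint:
    """A null model expressed as a set of effects constrained to zero."""

    zeroed: frozenset = frozenset()

    def __post_init__(self) -> None:
        zeroed = frozenset(self.zeroed)
        object.__setattr__(self, "zeroed", zeroed)
        bad = zeroed - CONSTRAINABLE
        if bad:
            raise ValueError(
                f"cannot constrain {sorted(bad)}; allowed: {sorted(CONSTRAINABLE)}"
            )

    def free_indices(self) -> list[int]:
        """Column indices of the free coefficients (mu is always free)."""
        return [k for k, name in enumerate(EFFECT_NAMES) if name not in self.zeroed]

    def nests(self, other: "Constraint") -> bool:
        """True when this constraint's null is nested in ``other``'s model."""
        return self.zeroed >= other.zeroed

    @property
    def df(self) -> int:
        """Number of zeroed effects (test degrees of freedom vs the full model)."""
        return len(self.zeroed)


FULL_MODEL = Constraint()
#: the no-QTL scan null: keep mu and the cytoplasmic effect, zero all QTL terms
NO_QTL = Constraint(frozenset({"a", "d", "i", "ica", "icd", "ici"}))


@dataclass
class FitResult:
    """Constrained MLEs, residual variance, log-likelihood and diagnostics."""

    beta: EffectVector
    sigma2: float
    loglik: float
    n_iter: int
    converged: bool
    constraint: Constraint
    posterior_weights: np.ndarray | None = None
    loglik_trace: np.ndarray | None = None
    #: effects whose sign is not identified under the design (F2: i, ici)
    sign_unidentified: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "beta": self.beta.to_dict(),
            "sigma2": self.sigma2,
            "loglik": self.loglik,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "zeroed": sorted(self.constraint.zeroed),
            "sign_unidentified": list(self.sign_unidentified),
        }


def _as_tensor(X: np.ndarray, n: int, K: int) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        X = np.broadcast_to(X, (n,) + X.shape)
    if X.shape != (n, K, 8):
        raise ValueError(f"design tensor shape {X.shape}, expected ({n}, {K}, 8)")
    return X


def _log_components(y, log_priors, means, sigma2):
    z = (y[:, None] - means) ** 2 / (2.0 * sigma2)
    return log_priors - 0.5 * (_LOG_2PI + np.log(sigma2)) - z


def mixture_loglik(y, priors, X, beta, sigma2: float) -> float:
    """Observed-data log-likelihood (nats) of the mixture at given parameters."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    y = np.asarray(y, dtype=float)
    priors = np.asarray(priors, dtype=float)
    n, K = priors.shape
    X = _as_tensor(X, n, K)
    beta_arr = beta.as_array() if isinstance(beta, EffectVector) else np.asarray(beta, float)
    means = np.einsum("nkp,p->nk", X, beta_arr)
    with np.errstate(divide="ignore"):
        log_priors = np.log(priors)
    return float(logsumexp(_log_components(y, log_priors, means, sigma2), axis=1).sum())


def _m_step(y, w, X2, Xf2, free, n, K):
    """Responsibility-weighted least squares in the free coefficients.

    ``X2``/``Xf2`` are the (n*K, .) flattened design tensors; flattening lets
    the normal equations run through BLAS matmuls.
    """
    wf = w.reshape(n * K)
    weighted = Xf2 * wf[:, None]
    a_mat = weighted.T @ Xf2
    b_vec = weighted.T @ np.repeat(y, K)
    try:
        coef = np.linalg.solve(a_mat, b_vec)
    except np.linalg.LinAlgError as exc:
        names = [EFFECT_NAMES[k] for k in free]
        raise RankDeficiencyError(
            f"weighted normal equations singular; confounded effects among {names}"
        ) from exc
    beta_arr = np.zeros(8)
    beta_arr[free] = coef
    means = (X2 @ beta_arr).reshape(n, K)
    sigma2 = float((w * (y[:, None] - means) ** 2).sum() / n)
    return beta_arr, max(sigma2, 1e-300), means


def em_fit(
    y,
    priors,
    X,
    constraint: Constraint = FULL_MODEL,
    tol: float = 1e-8,
    max_iter: int = 500,
    init: tuple | None = None,
) -> FitResult:
    """Maximize the mixture likelihood under zero-constraints by EM.

    Parameters
    ----------
    y : (n,) phenotypes.
    priors : (n, K) prior mixture proportions (marker-conditional posteriors).
    X : (n, K, 8) or (K, 8) design rows per individual and component.
    constraint : effects forced to zero (null models for LR tests).
    init : optional ``(beta_array, sigma2)`` warm start; by default a
        deterministic prior-weighted least-squares pass.

    Returns a :class:`FitResult`; non-convergence sets ``converged=False``
    instead of raising.
    """
    y = np.asarray(y, dtype=float)
    priors = np.asarray(priors, dtype=float)
    if priors.ndim != 2 or priors.shape[0] != len(y):
        raise ValueError("priors must be (n, K)")
    if np.any(priors < 0):
        raise ValueError("negative mixture proportions")
    row_sums = priors.sum(axis=1)
    if np.any(row_sums <= 0):
        raise ValueError("each individual needs positive total prior mass")
    priors = priors / row_sums[:, None]
    n, K = priors.shape
    X = _as_tensor(X, n, K)

    free = constraint.free_indices()
    if n < len(free) + 1:
        raise ValueError(
            f"{n} individuals cannot identify {len(free)} coefficients + sigma2"
        )
    X2 = np.ascontiguousarray(X.reshape(n * K, 8))
    Xf2 = np.ascontiguousarray(X2[:, free])

    if init is None:
        beta_arr, sigma2, means = _m_step(y, priors, X2, Xf2, free, n, K)
    else:
        beta_arr = np.zeros(8)
        beta_arr[free] = np.asarray(init[0], dtype=float)[free]
        sigma2 = float(init[1])
        means = (X2 @ beta_arr).reshape(n, K)

    trace: list[float] = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        # E-step with a per-row max shift for numerical safety
        z = (y[:, None] - means) ** 2 / (2.0 * sigma2)
        z_min = z.min(axis=1)
        scaled = priors * np.exp(z_min[:, None] - z)
        row_sum = scaled.sum(axis=1)
        ll = float(
            (np.log(row_sum) - z_min).sum() - n * 0.5 * (_LOG_2PI + np.log(sigma2))
        )
        trace.append(ll)
        if ll - prev < tol:
            converged = True
            break
        prev = ll
        w = scaled / row_sum[:, None]
        beta_arr, sigma2, means = _m_step(y, w, X2, Xf2, free, n, K)
    else:
        # max_iter exhausted: report the likelihood of the final parameters
        z = (y[:, None] - means) ** 2 / (2.0 * sigma2)
        z_min = z.min(axis=1)
        scaled = priors * np.exp(z_min[:, None] - z)
        row_sum = scaled.sum(axis=1)
        ll = float(
            (np.log(row_sum) - z_min).sum() - n * 0.5 * (_LOG_2PI + np.log(sigma2))
        )
        trace.append(ll)

    w = scaled / row_sum[:, None]
    return FitResult(
        beta=EffectVector.from_array(beta_arr),
        sigma2=float(sigma2),
        loglik=ll,
        n_iter=len(trace),
        converged=converged,
        constraint=constraint,
        posterior_weights=w,
        loglik_trace=np.array(trace),
    )


def fit_no_qtl(y, m) -> FitResult:
    """Closed-form fit of the no-QTL null ``y = mu + c*m + eps``.

    The null retains the cytoplasmic effect, which is estimable without any
    marker data; a pure maternal effect therefore cannot masquerade as a
    QTL peak in the scan.  Falls back to the intercept-only model (with a
    warning embedded in the result) when all individuals share one cross
    direction.
    """
    y = np.asarray(y, dtype=float)
    m = np.asarray(m, dtype=float)
    n = len(y)
    Z = np.column_stack([np.ones(n), m])
    coef, _, rank, _ = np.linalg.lstsq(Z, y, rcond=None)
    if rank < 2:
        coef = np.array([y.mean(), 0.0])
    resid = y - Z @ coef
    sigma2 = float(resid @ resid / n)
    sigma2 = max(sigma2, 1e-300)
    ll = -0.5 * n * (_LOG_2PI + np.log(sigma2) + 1.0)
    return FitResult(
        beta=EffectVector(mu=float(coef[0]), c=float(coef[1])),
        sigma2=sigma2,
        loglik=float(ll),
        n_iter=1,
        converged=True,
        constraint=NO_QTL,
    )


def lr_statistic(full: FitResult, null: FitResult) -> float:
    """LR = 2*(loglik_full - loglik_null), clipped at zero.

    Requires the null's constraint set to contain the full model's
    (nested models); raises otherwise.
    """
    if not null.constraint.nests(full.constraint):
        raise ValueError(
            f"models not nested: null zeroes {sorted(null.constraint.zeroed)}, "
            f"full zeroes {sorted(full.constraint.zeroed)}"
        )
    return max(0.0, 2.0 * (full.loglik - null.loglik))


def lod_from_lr(lr):
    """LOD = LR / (2 ln 10)."""
    return np.asarray(lr, dtype=float) / _LN10_X2
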