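"""Exponential-family response families and variational cumulant moments.

Each longitudinal marker is modelled through a one-parameter exponential
family with cumulant function ``b``: Gaussian (identity link, ``b(x) = x^2/2``),
Poisson (log link, ``b(x) = exp(x)``) and Bernoulli (logit link,
``b(x) = log(1 + e^x)``).  During a variational fit the linear predictor of
row ``j`` is Gaussian under ``q`` with mean ``mu_j`` and variance ``var_j``;
the coordinate updates need the expectations ``E[b'(eta)]`` and
``E[b''(eta)]`` under that Gaussian.

For the Gaussian family these are trivial; for the Poisson family they have a
lognormal closed form; for the Bernoulli family the logistic function is
replaced by a mixture of eight scaled normal CDFs (a Monahan--Stefanski
approximation), which turns both expectations into closed-form probit
integrals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable

import numpy as np
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "FamilySpec",
    "GAUSSIAN",
    "POISSON",
    "BERNOULLI",
    "FAMILIES",
    "MSBasis",
    "ms_basis",
    "fit_ms_basis",
    "PredictorMoments",
    "cumulant_moments",
]

# Floor on E[b''] entries: rows whose likelihood is locally flat would
# otherwise make the per-subject curvature matrices singular.
B2_FLOOR = 1e-12


@dataclass(frozen=True)
class FamilySpec:
    """A response family: cumulant function, link name, dispersion flag."""

    family_tag: str
    cumulant: Callable[[np.ndarray], np.ndarray]
    link: str
    has_dispersion: bool

    def validate_response(self, y: np.ndarray) -> None:
        """Raise ``ValueError`` if responses fall outside the family support."""
        y = np.asarray(y, dtype=float)
        if self.family_tag == "bernoulli":
            if not np.all(np.isin(y, (0.0, 1.0))):
                raise ValueError("bernoulli responses must lie in {0, 1}")
        elif self.family_tag == "poisson":
            if np.any(y < 0) or np.any(y != np.round(y)):
                raise ValueError("poisson responses must be non-negative integers")


def _b_gaussian(x):
    return np.square(x) / 2.0


def _b_poisson(x):
    return np.exp(x)


def _b_bernoulli(x):
    return np.logaddexp(0.0, x)


GAUSSIAN = FamilySpec("gaussian", _b_gaussian, "identity", True)
POISSON = FamilySpec("poisson", _b_poisson, "log", False)
BERNOULLI = FamilySpec("bernoulli", _b_bernoulli, "logit", False)

FAMILIES = {f.family_tag: f for f in (GAUSSIAN, POISSON, BERNOULLI)}


def get_family(tag: str) -> FamilySpec:
    try:
        return FAMILIES[tag]
    except KeyError:
        raise KeyError(f"unknown family tag {tag!r}; expected one of {sorted(FAMILIES)}")


# ---------------------------------------------------------------------------
# Monahan--Stefanski normal-scale-mixture basis for the logistic function
# ---------------------------------------------------------------------------

# Frozen coefficients of an 8-component fit of sum_k p_k * Phi(s_k x) to
# expit(x): non-negative weights constrained to sum to one, scales and
# weights obtained by nested least squares on a dense grid over [0, 12]
# (both sides are odd about 1/2, so the positive half determines the fit).
# Reproducible via fit_ms_basis(); max absolute error on [-10, 10] is 1.4e-7.
_MS_P = np.array(
    [
        0.014749921934462564,
        0.14629437264781597,
        0.35918835481183192,
        0.34984978252474497,
        0.0,
        0.0,
        0.12186362445289964,
        0.0080539436282448373,
    ]
)
_MS_S = np.array(
    [
        0.28041688668274434,
        0.38604461395064138,
        0.52642791375136744,
        0.71345403780938299,
        0.76535349570975675,
        0.94633780917113985,
        0.95945874191455094,
        1.2954886239728638,
    ]
)

_MS_ERROR_BOUND = 1e-3


@dataclass(frozen=True)
class MSBasis:
    """Weights ``p`` and scales ``s`` of the 8-term probit mixture."""

    p: np.ndarray
    s: np.ndarray

    def mixture(self, x: np.ndarray) -> np.ndarray:
        """Evaluate ``sum_k p_k Phi(s_k x)`` — the logistic surrogate."""
        x = np.asarray(x, dtype=float)
        return norm.cdf(np.multiply.outer(x, self.s)) @ self.p

    def max_error(self, lo: float = -10.0, hi: float = 10.0, n: int = 20001) -> float:
        grid = np.linspace(lo, hi, n)
        return float(np.abs(self.mixture(grid) - expit(grid)).max())


def fit_ms_basis(n_components: int = 8, grid_hi: float = 12.0, n_grid: int = 4001) -> MSBasis:
    """Refit the probit-mixture basis from scratch (slow; for reproducibility).

    Scales are optimised by Nelder--Mead with the weights profiled out by
    non-negative least squares under a sum-to-one constraint.
    """
    from scipy.optimize import minimize, nnls

    x = np.linspace(0.0, grid_hi, n_grid)
    target = expit(x)

    def best_p(s: np.ndarray) -> np.ndarray:
        a = norm.cdf(np.outer(x, s))
        lam = 1e3
        aa = np.vstack([a, lam * np.ones((1, len(s)))])
        ta = np.concatenate([target, [lam]])
        p, _ = nnls(aa, ta)
        return p

    def obj(logs: np.ndarray) -> float:
        s = np.exp(logs)
        r = norm.cdf(np.outer(x, s)) @ best_p(s) - target
        return float(np.sqrt(np.mean(r**2)))

    logs0 = np.log(np.linspace(0.4, 1.2, n_components))
    res = minimize(
        obj,
        logs0,
        method="Nelder-Mead",
        options=dict(maxiter=20000, maxfev=20000, xatol=1e-12, fatol=1e-14),
    )
    s = np.sort(np.exp(res.x))
    p = best_p(s)
    return MSBasis(p=p / p.sum(), s=s)


@lru_cache(maxsize=1)
def ms_basis() -> MSBasis:
    """Return the cached probit-mixture basis, validated against its bound."""
    basis = MSBasis(p=_MS_P.copy(), s=_MS_S.copy())
    err = basis.max_error()
    if err > _MS_ERROR_BOUND:
        raise RuntimeError(
            f"logistic mixture basis violates its error bound: {err:.2e} > {_MS_ERROR_BOUND:.0e}"
        )
    return basis


# ---------------------------------------------------------------------------
# Cumulant moments under a Gaussian variational predictor
# ---------------------------------------------------------------------------


@dataclass
class PredictorMoments:
    """Row-wise predictor moments and derived cumulant expectations.

    ``mu`` and ``var`` are the mean and variance of each row's linear
    predictor under ``q(beta, u)``; ``e_b1 = E[b'(eta)]`` and
    ``e_b2 = E[b''(eta)]`` are the derived expectations used by the
    coordinate updates.
    """

    mu: np.ndarray
    var: np.ndarray
    e_b1: np.ndarray = field(default=None)  # type: ignore[assignment]
    e_b2: np.ndarray = field(default=None)  # type: ignore[assignment]


def cumulant_moments(
    family: FamilySpec | str,
    mu: np.ndarray,
    var: np.ndarray,
    basis: MSBasis | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(E[b'(eta)], E[b''(eta)])`` for ``eta ~ N(mu, var)`` elementwise.

    Gaussian: ``(mu, 1)``.  Poisson: both equal the lognormal mean
    ``exp(mu + var/2)``.  Bernoulli: probit-mixture closed forms

        E[b']_j  = sum_k p_k Phi(s_k mu_j / omega_jk),
        E[b'']_j = sum_k p_k s_k phi(s_k mu_j / omega_jk) / omega_jk,

    with ``omega_jk = sqrt(1 + s_k^2 var_j)``.
    """
    if isinstance(family, str):
        family = get_family(family)
    mu = np.asarray(mu, dtype=float)
    var = np.asarray(var, dtype=float)
    if np.any(var < 0):
        raise ValueError("predictor variances must be non-negative")

    if family.family_tag == "gaussian":
        return mu.copy(), np.ones_like(mu)
    if family.family_tag == "poisson":
        # the lognormal mean overflows to inf for extreme predictors, which
        # is the correct limit — no warning needed
        with np.errstate(over="ignore"):
            m = np.exp(mu + 0.5 * var)
        return m, np.maximum(m, B2_FLOOR)
    if family.family_tag == "bernoulli":
        if basis is None:
            basis = ms_basis()
        s = basis.s
        omega = np.sqrt(1.0 + np.multiply.outer(var, s**2))
        z = np.multiply.outer(mu, s) / omega
        e_b1 = norm.cdf(z) @ basis.p
        e_b2 = (norm.pdf(z) / omega) @ (basis.p * s)
        return e_b1, np.maximum(e_b2, B2_FLOOR)
    raise KeyError(f"unknown family {family.family_tag!r}")
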