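"""Stage 2: Sugeno fuzzy-integral similarity between two feature vectors.

Given feature vectors v and t on the 20-simplex, the pipeline is

    evidence      rho_i = 1 - |v_i - t_i|          (agreement per state)
    densities     mu_i  = max(v_i, t_i)            (importance per state)
    lambda        the root > -1 of  1 + L = prod_i (1 + L*mu_i)
    measure chain mu(A_1) <= ... <= mu(A_m) = 1 over the prefix sets of the
                  evidence sorted descending, via the lambda-measure union
                  rule  mu(A u {x}) = mu(A) + mu_x + L*mu(A)*mu_x
    integral      I = max_i min(rho_(i), mu(A_i))  in [0, 1]
    distance      D = 1 - I

All functions accept arbitrary set size m (>= 1); the protein pipeline uses
m = 20. For feature vectors on the simplex, sum(mu) >= 1, hence lambda lies
in (-1, 0], with lambda = 0 iff v = t.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

#: residual tolerance for the solved lambda
LAMBDA_TOL = 1e-12
#: treat sum(densities) within this of 1 as the exactly-additive case
ADDITIVE_TOL = 1e-9
#: measure_chain errors when the final chain value misses 1 by more than this
CHAIN_ERROR_TOL = 1e-4


class LambdaSolveError(RuntimeError):
    """No admissible lambda root could be bracketed."""


class MeasureError(RuntimeError):
    """The built measure chain is inconsistent with mu(G) = 1."""


@dataclass(frozen=True)
class FuzzyMeasureChain:
    """Densities, solved lambda, sort order and nested prefix-set measures."""

    densities: np.ndarray
    lam: float
    order: np.ndarray       # permutation sorting the evidence descending
    chain: np.ndarray       # chain[i] = mu({x_order[0..i]})


def evidence(v: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Per-element agreement rho_i = 1 - |v_i - t_i|, in [0, 1]."""
    v = np.asarray(v, dtype=float)
    t = np.asarray(t, dtype=float)
    if v.shape != t.shape:
        raise ValueError("feature vectors must share a shape")
    return 1.0 - np.abs(v - t)


def densities(v: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Fuzzy densities mu_i = max(v_i, t_i)."""
    v = np.asarray(v, dtype=float)
    t = np.asarray(t, dtype=float)
    if v.shape != t.shape:
        raise ValueError("feature vectors must share a shape")
    mu = np.maximum(v, t)
    if not np.any(mu > 0):
        raise ValueError("all densities are zero; cannot build a measure")
    return mu


def _poly_residual(lam: float, mu: np.ndarray) -> float:
    """f(lam) = prod(1 + lam*mu_i) - (1 + lam); roots define the measure.

    Evaluated as expm1(sum(log1p(lam*mu_i))) - lam so that the residual
    keeps full relative precision for |lam| near 0.
    """
    return float(np.expm1(np.sum(np.log1p(lam * mu))) - lam)


def _deflated(lam: float, mu: np.ndarray) -> float:
    """g(lam) = f(lam)/lam with the removable singularity filled in.

    lam = 0 always solves f; the measure-defining root is the zero of g,
    which brackets cleanly: g(0) = sum(mu) - 1 while g(-1+) < 0 when all
    mu_i < 1 (and g eventually turns positive for lam > 0).
    """
    if lam == 0.0:
        return float(mu.sum() - 1.0)
    return _poly_residual(lam, mu) / lam


def solve_lambda(mu: np.ndarray, tol: float = LAMBDA_TOL) -> float:
    """Solve 1 + lambda = prod_i (1 + lambda * mu_i) for lambda > -1.

    lambda = 0 always solves the equation; the measure-defining root is the
    other one: in (-1, 0) when sum(mu) > 1, in (0, inf) when sum(mu) < 1,
    and exactly 0 when sum(mu) = 1 (the additive case). When a density
    equals 1 the non-zero root degenerates to -1 (inadmissible) and 0 is
    returned as the only root > -1.
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(mu < 0) or np.any(mu > 1):
        raise ValueError("densities must lie in [0, 1]")
    if not np.any(mu > 0):
        raise ValueError("at least one density must be positive")
    s = float(mu.sum())
    if abs(s - 1.0) < ADDITIVE_TOL:
        return 0.0

    if s > 1.0:
        # unique non-zero root in (-1, 0): g(0) = s - 1 > 0 while
        # g(-1^+) = -prod(1-mu_i)/(1-eps) < 0 when all mu_i < 1.
        if np.max(mu) >= 1.0 - 1e-12:
            # factor (1 + lam) appears inside the product: root merges
            # with the inadmissible lam = -1; only lam = 0 remains.
            return 0.0
        lo, hi = -1.0 + 1e-12, 0.0
        if _deflated(lo, mu) >= 0:
            raise LambdaSolveError(
                f"could not bracket a root in (-1, 0); sum(mu)={s:.6g}, "
                f"max(mu)={mu.max():.6g}"
            )
    else:
        # unique non-zero root in (0, inf): g(0) = s - 1 < 0 and the
        # product eventually dominates if >= 2 densities are positive.
        if np.count_nonzero(mu) < 2:
            raise LambdaSolveError(
                "sum(mu) < 1 with a single positive density: "
                "no admissible root exists"
            )
        lo, hi = 0.0, 1.0
        for _ in range(200):
            if _deflated(hi, mu) > 0:
                break
            hi *= 2.0
        else:
            raise LambdaSolveError("failed to bracket a root in (0, inf)")

    lam = float(brentq(_deflated, lo, hi, args=(mu,),
                       xtol=1e-15, rtol=8.9e-16, maxiter=200))
    # Newton polish to drive the residual below tol
    for _ in range(5):
        r = _poly_residual(lam, mu)
        if abs(r) < tol:
            break
        prod = np.prod(1.0 + lam * mu)
        dprod = prod * np.sum(mu / (1.0 + lam * mu))
        deriv = dprod - 1.0
        if deriv == 0:
            break
        lam -= r / deriv
    if abs(_poly_residual(lam, mu)) > max(tol, 1e-10):
        raise LambdaSolveError(
            f"root refinement stalled: lambda={lam!r}, "
            f"residual={_poly_residual(lam, mu):.3e}"
        )
    return lam


def sort_order(rho: np.ndarray) -> np.ndarray:
    """Permutation sorting the evidence descending, ties by ascending index."""
    rho = np.asarray(rho, dtype=float)
    return np.argsort(-rho, kind="stable")


def measure_chain(mu: np.ndarray, lam: float,
                  order: np.ndarray) -> FuzzyMeasureChain:
    """Build the nested prefix-set measures mu(A_1) .. mu(A_m).

    chain[i] accumulates via the lambda-measure rule for disjoint union:
    mu(A u {x}) = mu(A) + mu_x + lam * mu(A) * mu_x. The chain is
    non-decreasing and must end at mu(G) = 1; a final value off by more
    than 1e-4 signals a lambda inconsistent with the densities, except in
    the degenerate some-density-equals-1 case where mu(G) = 1 is
    unattainable and a warning is emitted instead.
    """
    mu = np.asarray(mu, dtype=float)
    order = np.asarray(order, dtype=int)
    if sorted(order.tolist()) != list(range(mu.size)):
        raise ValueError("order must be a permutation of 0..m-1")
    chain = np.empty(mu.size, dtype=float)
    acc = 0.0
    for i, j in enumerate(order):
        acc = acc + mu[j] + lam * acc * mu[j]
        chain[i] = acc
    degenerate = lam == 0.0 and float(np.max(mu)) >= 1.0 - 1e-12 \
        and abs(float(mu.sum()) - 1.0) >= ADDITIVE_TOL
    gap = abs(chain[-1] - 1.0)
    if degenerate:
        if gap > CHAIN_ERROR_TOL:
            warnings.warn(
                "degenerate densities (some mu_i = 1): measure cannot "
                f"normalise, mu(G) = {chain[-1]:.6g}",
                RuntimeWarning, stacklevel=2,
            )
    elif gap > CHAIN_ERROR_TOL:
        raise MeasureError(
            f"chain ends at {chain[-1]!r}, not 1: lambda={lam!r} is "
            "inconsistent with the densities"
        )
    else:
        chain[-1] = 1.0
    return FuzzyMeasureChain(densities=mu, lam=lam, order=order, chain=chain)


def sugeno_integral(rho: np.ndarray, chain: FuzzyMeasureChain) -> float:
    """I = max_i min(rho_(i), mu(A_i)) with rho sorted descending."""
    rho = np.asarray(rho, dtype=float)
    rho_sorted = rho[chain.order]
    if np.any(np.diff(rho_sorted) > 1e-12):
        raise ValueError("chain.order does not sort the evidence descending")
    return float(np.max(np.minimum(rho_sorted, chain.chain)))


def fuzzy_similarity(v: np.ndarray, t: np.ndarray) -> float:
    """Sugeno fuzzy-integral similarity I(v, t) in [0, 1]."""
    rho = evidence(v, t)
    mu = densities(v, t)
    lam = solve_lambda(mu)
    order = sort_order(rho)
    with warnings.catch_warnings():
        # disjoint-support vectors hit the degenerate measure on purpose
        warnings.simplefilter("ignore", RuntimeWarning)
        ch = measure_chain(mu, lam, order)
    return sugeno_integral(rho, ch)


def fuzzy_distance(v, t) -> float:
    """D(v, t) = 1 - I(v, t); symmetric, zero iff v = t, in [0, 1].

    Accepts bare arrays or FeatureVector-like objects with an ``x`` field.
    """
    v = getattr(v, "x", v)
    t = getattr(t, "x", t)
    d = 1.0 - fuzzy_similarity(v, t)
    return float(min(max(d, 0.0), 1.0))


# ---------------------------------------------------------------------------
# Closed-form subset measure (used by tests as the brute-force oracle target)

def subset_measure(mu: np.ndarray, lam: float, subset) -> float:
    """mu(S) from the closed form (prod_{i in S}(1+lam*mu_i) - 1)/lam.

    Falls back to plain additivity when lam = 0. Agrees with building S one
    element at a time through the union rule, in any insertion order.
    """
    mu = np.asarray(mu, dtype=float)
    idx = list(subset)
    if not idx:
        return 0.0
    if lam == 0.0:
        return float(mu[idx].sum())
    return float((np.prod(1.0 + lam * mu[idx]) - 1.0) / lam)
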