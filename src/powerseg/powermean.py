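"""Power-mean (generalized mean) machinery for robust location estimation.

The power mean ``M_p = ((1/n) Σ x_i^p)^(1/p)`` underlies a robust alternative
to the least-squares sample mean: the *generalized sample mean* is the
minimizer of ``Σ ((x_i − a)^2)^p``.  For ``p < 1`` the implied per-sample
weights ``((x_i − a)^2)^(p−1)`` shrink with the residual, so outliers pull the
estimate far less than they pull the arithmetic mean.  The minimizer is found
by an iteratively reweighted (MM) fixed-point scheme: each step replaces the
concave power of the squared residual by its tangent quadratic surrogate and
takes the resulting weighted average, which never increases the objective.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np

__all__ = [
    "power_mean",
    "pm_objective",
    "pm_weights",
    "pm_mean_iterate",
    "generalized_sample_mean",
    "GeneralizedMeanResult",
]

#: Guard under which squared residuals are clamped before raising to p−1.
#: Calibrated to intensities on the normalized [0,1] scale.
DEFAULT_EPS = 1e-8


def _as_samples(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size < 1:
        raise ValueError("sample set must contain at least one value")
    if not np.all(np.isfinite(arr)):
        raise ValueError("sample values must be finite")
    return arr


def power_mean(values, p: float) -> float:
    """Power (generalized) mean ``((1/n) Σ v_i^p)^(1/p)`` of non-negative samples.

    ``p=1`` is the arithmetic mean, ``p=-1`` the harmonic mean; ``p=0`` (the
    geometric-mean limit) is rejected.  The result always lies between the
    sample minimum and maximum.
    """
    arr = _as_samples(values)
    if p == 0:
        raise ValueError("exponent must be nonzero")
    if np.any(arr < 0):
        raise ValueError("power mean requires non-negative values")
    if p < 0 and np.any(arr == 0):
        raise ValueError("negative exponents require strictly positive values")
    # log-space evaluation avoids overflow for large |p|
    with np.errstate(divide="ignore"):
        logs = np.log(arr)
    if np.any(np.isneginf(logs)):  # zeros with p > 0
        return float(np.mean(arr**p) ** (1.0 / p))
    m = np.max(p * logs)
    return float(np.exp((m + np.log(np.mean(np.exp(p * logs - m)))) / p))


def pm_objective(values, a: float, p: float) -> float:
    """Robust location objective ``Σ ((v_i − a)^2)^p`` (``p > 0``)."""
    if p <= 0:
        raise ValueError("objective exponent p must be positive")
    arr = _as_samples(values)
    return float(np.sum(((arr - a) ** 2) ** p))


def pm_weights(values, a: float, p: float, eps: float = DEFAULT_EPS) -> np.ndarray:
    """MM weights ``(max((v_i − a)^2, eps))^(p−1)``.

    For ``p < 1`` the weights decrease with the residual (outlier damping);
    ``p = 1`` gives unit weights.  ``eps`` keeps a zero residual finite.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    arr = _as_samples(values)
    d2 = np.maximum((arr - a) ** 2, eps)
    return d2 ** (p - 1.0)


def pm_mean_iterate(values, a_current: float, p: float, eps: float = DEFAULT_EPS) -> float:
    """One reweighting step: the ``pm_weights``-weighted average of the samples.

    The output always lies in ``[min(values), max(values)]``.
    """
    arr = _as_samples(values)
    w = pm_weights(arr, a_current, p, eps)
    return float(np.sum(w * arr) / np.sum(w))


class GeneralizedMeanResult(NamedTuple):
    value: float
    iterations: int
    converged: bool


def generalized_sample_mean(
    values,
    p: float,
    eps: float = DEFAULT_EPS,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> GeneralizedMeanResult:
    """Robust location estimate minimizing ``Σ ((v_i − a)^2)^p``.

    Starts from the arithmetic mean (the exact ``p=1`` solution) and iterates
    the weighted-average fixed point until successive iterates change by at
    most ``tol``.  Non-convergence returns the last iterate with
    ``converged=False`` and a warning rather than raising.

    Parameters
    ----------
    values : array_like
        Finite sample values (scalar intensities).
    p : float
        Positive exponent; ``0 < p <= 1`` is the robust operating regime
        (the useful tuning range in practice is roughly 0.5–0.8).
    eps, tol, max_iter :
        Residual guard, convergence tolerance on successive iterates, and
        iteration cap.

    Returns
    -------
    GeneralizedMeanResult
        ``(value, iterations, converged)``.
    """
    if p <= 0:
        raise ValueError("exponent p must be positive")
    if tol <= 0 or max_iter < 1:
        raise ValueError("tol must be positive and max_iter >= 1")
    arr = _as_samples(values)
    a = float(np.mean(arr))
    for k in range(1, max_iter + 1):
        a_next = pm_mean_iterate(arr, a, p, eps)
        if abs(a_next - a) <= tol:
            return GeneralizedMeanResult(a_next, k, True)
        a = a_next
    warnings.warn(
        f"generalized_sample_mean did not converge within {max_iter} iterations",
        RuntimeWarning,
        stacklevel=2,
    )
    return GeneralizedMeanResult(a, max_iter, False)
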