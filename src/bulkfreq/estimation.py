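"""Maximum-likelihood estimation of the population allele frequency.

Fits ``(p, k, delta_T, sigma_c)`` — optionally with ``k`` or other
parameters held fixed — to the ΔCq pairs of N ≥ 2 bulk samples by
quasi-Newton minimization of the negative log-likelihood on an
unconstrained scale (logit for ``p``, log for the rest).  Asymptotic 95%
confidence intervals come from the observed information: the inverse of
the finite-difference Hessian at the optimum.  Interval estimation
*succeeds* only if every diagonal element of that inverse is positive
and finite; otherwise point estimates are still reported but the CIs are
absent, mirroring how practitioners treat an indefinite Hessian as "no
interval available".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.special import expit

from .model_core import CqQuartet, DeltaPair, conventional_freq_estimate, delta_pair_from_quartet
from .likelihood import (
    DEFAULT_QUADRATURE,
    FREE_PARAM_NAMES,
    ParamVector,
    QuadratureConfig,
    total_negloglik,
)

__all__ = [
    "FreqFitResult",
    "ParameterEstimate",
    "fit_population_frequency",
    "confidence_interval_from_hessian",
    "estimation_success",
]

#: objective value substituted when the likelihood cannot be evaluated
_PENALTY = 1e12

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class ParameterEstimate:
    """Point estimate with transformed-scale SE and natural-scale 95% CI."""

    name: str
    estimate: float
    se_transformed: float = math.nan
    ci_lower: float = math.nan
    ci_upper: float = math.nan
    fixed: bool = False


@dataclass(frozen=True)
class FreqFitResult:
    """Outcome of one bulk-sample frequency fit."""

    estimates: Mapping[str, ParameterEstimate]
    loglik: float
    converged: bool
    success: bool
    n_iter: int
    kernel: str
    fixed: tuple
    n_samples: int
    message: str = ""

    @property
    def p(self) -> float:
        return self.estimates["p"].estimate

    @property
    def p_ci(self) -> tuple:
        e = self.estimates["p"]
        return (e.ci_lower, e.ci_upper)

    def __getitem__(self, name: str) -> ParameterEstimate:
        return self.estimates[name]


def _back_transform(name: str, x: float) -> float:
    return float(expit(x)) if name == "p" else math.exp(x)


def confidence_interval_from_hessian(
    estimates: Sequence[float],
    hessian: np.ndarray,
    names: Sequence[str],
    level: float = 0.95,
    min_curvature=None,
):
    """Wald CIs from the observed information on the transformed scale.

    ``estimates`` are the free parameters on the unconstrained scale and
    ``hessian`` is the curvature of the *negative* log-likelihood there.
    ``min_curvature`` (optional, per parameter) is the resolution floor of
    the finite-difference scheme that produced the Hessian: a diagonal
    element at or below it is numerically indistinguishable from zero and
    the corresponding interval is reported as unavailable.
    Returns ``(per-parameter dict, success)`` with success True only if
    every parameter received an interval.
    """
    hessian = np.asarray(hessian, dtype=float)
    x = np.asarray(estimates, dtype=float)
    if hessian.shape != (x.size, x.size):
        raise ValueError("hessian shape does not match the number of estimates")
    if min_curvature is None:
        min_curvature = np.zeros(x.size)
    else:
        min_curvature = np.asarray(min_curvature, dtype=float)
    zq = float(-_q_normal((1.0 - level) / 2.0))
    out = {}
    try:
        cov = np.linalg.inv(hessian)
    except np.linalg.LinAlgError:
        cov = None
    success = cov is not None
    for i, name in enumerate(names):
        # interval availability is judged per parameter: an indefinite
        # information matrix can still carry usable curvature for some
        # parameters (typically p) while another (typically k) is flat
        ok_i = (
            cov is not None
            and math.isfinite(cov[i, i])
            and cov[i, i] > 0.0
            and hessian[i, i] > min_curvature[i]
        )
        if ok_i:
            se = math.sqrt(cov[i, i])
            lo = _back_transform(name, x[i] - zq * se)
            hi = _back_transform(name, x[i] + zq * se)
        else:
            se = lo = hi = math.nan
            success = False
        out[name] = ParameterEstimate(
            name=name,
            estimate=_back_transform(name, x[i]),
            se_transformed=se,
            ci_lower=lo,
            ci_upper=hi,
        )
    return out, success


def _q_normal(q: float) -> float:
    from scipy.special import ndtri

    return float(ndtri(q))


def _fd_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian of a scalar function."""
    x = np.asarray(x, dtype=float)
    d = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    hess = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h[i]
        fpp = f(x + ei)
        fmm = f(x - ei)
        hess[i, i] = (fpp - 2.0 * f0 + fmm) / h[i] ** 2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = h[j]
            fij = f(x + ei + ej)
            fi_j = f(x + ei - ej)
            f_ij = f(x - ei + ej)
            f_i_j = f(x - ei - ej)
            hess[i, j] = hess[j, i] = (fij - fi_j - f_ij + f_i_j) / (
                4.0 * h[i] * h[j]
            )
    return hess


def _as_delta_pairs(samples: Iterable) -> list:
    out = []
    for obs, n in samples:
        if isinstance(obs, CqQuartet):
            obs = delta_pair_from_quartet(obs)
        elif not isinstance(obs, DeltaPair):
            raise TypeError("samples must contain CqQuartet or DeltaPair values")
        out.append((obs, int(n)))
    return out


def fit_population_frequency(
    samples: Iterable,
    z: float,
    eta: float,
    kernel: Literal["beta", "gamma"] = "beta",
    fix_k: Optional[float] = None,
    fix_delta_T: Optional[float] = None,
    fix_sigma_c: Optional[float] = None,
    start: Optional[Mapping[str, float]] = None,
    gtol: float = 1e-6,
    maxiter: int = 200,
    config: QuadratureConfig = DEFAULT_QUADRATURE,
) -> FreqFitResult:
    """Fit ``(p, k, delta_T, sigma_c)`` to N bulk samples' Cq data.

    ``samples`` is an iterable of ``(CqQuartet | DeltaPair, n)``; ``z``
    and ``eta`` must come from a known-ratio calibration.  ``fix_k=1``
    reproduces the common exponential-yield restriction, which speeds up
    and stabilizes the fit considerably.

    Starting values: ``k`` always starts at 1 (small shape is the safe
    side — overstated yield variability — and large true ``k`` carries
    little likelihood information anyway); ``p`` starts at the simple
    ΔΔCq-average estimate clipped to [1e-3, 1−1e-3]; ``delta_T`` at 1;
    ``sigma_c`` at 0.3 cycles.
    """
    pairs = _as_delta_pairs(samples)
    if len(pairs) < 2:
        raise ValueError(
            "at least 2 bulk samples are required: a single sample "
            "provides two ΔCq values, too few to identify the parameters"
        )
    if any(n < 1 for _, n in pairs):
        raise ValueError("all pool sizes must be >= 1")

    fixed = {}
    if fix_k is not None:
        fixed["k"] = float(fix_k)
    if fix_delta_T is not None:
        fixed["delta_T"] = float(fix_delta_T)
    if fix_sigma_c is not None:
        fixed["sigma_c"] = float(fix_sigma_c)

    conv = conventional_freq_estimate([dp.dd_tau for dp, _ in pairs], eta)
    p0 = min(max(conv.estimate, 1e-3), 1.0 - 1e-3)
    defaults = {"p": p0, "k": 1.0, "delta_T": 1.0, "sigma_c": 0.3}
    if start:
        defaults.update(start)
    defaults.update(fixed)

    params0 = ParamVector(
        p=defaults["p"],
        k=defaults["k"],
        delta_T=defaults["delta_T"],
        sigma_c=defaults["sigma_c"],
        z=z,
        eta=eta,
        fixed=frozenset(fixed),
    )
    free_names = params0.free_names

    def objective(x: np.ndarray) -> float:
        try:
            val = total_negloglik(pairs, params0.with_free(x), kernel, config)
        except (ValueError, OverflowError, FloatingPointError):
            return _PENALTY
        if not math.isfinite(val):
            return _PENALTY
        return val

    x0 = params0.to_free()
    res = optimize.minimize(
        objective,
        x0,
        method="BFGS",
        options={"gtol": gtol, "maxiter": maxiter},
    )
    x_hat = np.asarray(res.x, dtype=float)
    loglik = -float(res.fun)
    converged = bool(res.success)

    hessian = _fd_hessian(objective, x_hat)
    estimates, success = confidence_interval_from_hessian(x_hat, hessian, free_names)
    # a p-interval that contains every practically distinguishable
    # frequency is no interval: this happens when the MLE runs to the
    # boundary (e.g. no carrier in the whole data set) and the curvature,
    # while formally positive, carries no information about p
    if "p" in estimates:
        e = estimates["p"]
        if (
            math.isfinite(e.ci_lower)
            and e.ci_lower < 1e-3
            and e.ci_upper > 1.0 - 1e-3
        ):
            estimates["p"] = ParameterEstimate(
                name="p", estimate=e.estimate, se_transformed=e.se_transformed
            )
            success = False
    for name, value in fixed.items():
        estimates[name] = ParameterEstimate(name=name, estimate=value, fixed=True)
    # keep canonical ordering for serialization
    ordered = {n: estimates[n] for n in FREE_PARAM_NAMES if n in estimates}

    return FreqFitResult(
        estimates=ordered,
        loglik=loglik,
        converged=converged,
        success=bool(success),
        n_iter=int(res.nit),
        kernel=kernel,
        fixed=tuple(sorted(fixed)),
        n_samples=len(pairs),
        message=str(res.message),
    )


def estimation_success(result: FreqFitResult) -> bool:
    """True iff confidence intervals were obtained for all free parameters."""
    if not result.success:
        return False
    return all(
        math.isfinite(e.ci_lower) and math.isfinite(e.ci_upper)
        for e in result.estimates.values()
        if not e.fixed
    )
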