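"""Marginal likelihood of bulk-sample ΔCq pairs.

For one bulk sample of ``n`` individuals the observables are the two ΔCq
values.  ΔτW depends only on the target/housekeeping content ratio
``delta_T`` and carries no allele information; ΔτD mixes over the latent
number ``m`` of R individuals (binomial in the population frequency
``p``) and, for interior ``m``, over the latent within-sample frequency
``y ~ Beta(mk, (n−m)k)``:

    L = N(ΔτW; −ln δT / L, 2σc²)
        · Σ_m Bin(m | n, p) · P(ΔτD | m),          L = ln(1+η)

    P(ΔτD | m) = N(−ln(z δT)/L, 2σc²)                      m = 0
               = ∫₀¹ N(−[ln δT + ln(z + y(1−z))]/L, 2σc²)
                     · Beta(y | mk, (n−m)k) dy              0 < m < n
               = N(−ln δT/L, 2σc²)                          m = n

The beta kernel ``psi_beta`` is the default; ``psi_gamma`` computes the
same marginal by double integration over the two gamma-distributed
template amounts and exists as a cross-check and compatibility path (the
ratio of independent same-scale gammas is exactly beta distributed, so
the two must agree).

Numerics: the beta integral is evaluated in ``u = ln(z + y(1−z))``
coordinates, where the measurement kernel is exactly Gaussian with
centre ``u* = −L·ΔτD − ln δT`` and SD ``s = √2 σc L``.  A tanh-sinh
(double-exponential) rule spans the full interval ``(ln z, 0)`` with a
node count scaled to resolve that Gaussian, absorbing the integrable
beta endpoint singularities; when σc is too small for that budget the
rule falls back to a window around ``u*`` outside which the integrand is
negligible.  Everything is accumulated in log space so rare-allele
binomial weights and far-tail densities never underflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import integrate, stats
from scipy.special import betaln, expit, gammaln, logit, logsumexp

from .model_core import DeltaPair

__all__ = [
    "ParamVector",
    "QuadratureConfig",
    "dtauw_logdensity",
    "psi_beta",
    "psi_gamma",
    "bulk_sample_loglik",
    "total_negloglik",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)

#: Names of the parameters estimable from ΔCq data, in canonical order.
FREE_PARAM_NAMES = ("p", "k", "delta_T", "sigma_c")


@dataclass(frozen=True)
class QuadratureConfig:
    """Tunables of the beta-kernel quadrature.

    The tanh-sinh rule normally spans the full ``u = ln(z + y(1−z))``
    interval with a node count proportional to (interval width)/(Gaussian
    SD), capped at ``max_nodes``.  When the Gaussian kernel is too narrow
    for that budget (tiny σc), the rule falls back to a window of
    ``window_sds`` Gaussian SDs around the kernel centre — outside it the
    integrand is smaller by ``exp(−window_sds²/2)`` and cannot contribute.
    """

    nodes_per_sigma: float = 3.0
    min_nodes: int = 301
    max_nodes: int = 3001
    t_max: float = 3.5
    window_sds: float = 11.0
    window_nodes: int = 351
    quad_epsrel: float = 1e-10
    quad_epsabs: float = 1e-200


DEFAULT_QUADRATURE = QuadratureConfig()

#: node-count grid reused across likelihood evaluations (cache friendly)
_NODE_SIZES = (301, 401, 601, 801, 1201, 1601, 2001, 3001)


@dataclass(frozen=True)
class ParamVector:
    """Parameters of the frequency likelihood with their fixed/free status.

    ``p`` (population R frequency), ``k`` (gamma shape of individual DNA
    yield), ``delta_T`` and ``sigma_c`` are potentially free; ``z`` and
    ``eta`` are auxiliary parameters always held at externally calibrated
    values.  Free parameters are optimized on an unconstrained scale
    (logit for ``p``, log for the rest).
    """

    p: float
    k: float
    delta_T: float
    sigma_c: float
    z: float
    eta: float
    fixed: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p must lie in [0, 1], got {self.p}")
        for name in ("k", "delta_T", "sigma_c", "z", "eta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        unknown = set(self.fixed) - set(FREE_PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown fixed-parameter names: {sorted(unknown)}")

    @property
    def free_names(self) -> tuple:
        return tuple(n for n in FREE_PARAM_NAMES if n not in self.fixed)

    def to_free(self) -> np.ndarray:
        """Pack free parameters onto the unconstrained optimization scale."""
        out = []
        for name in self.free_names:
            v = getattr(self, name)
            out.append(float(logit(v)) if name == "p" else math.log(v))
        return np.asarray(out, dtype=float)

    def with_free(self, values: Sequence[float]) -> "ParamVector":
        """Return a copy with free parameters set from the unconstrained scale."""
        names = self.free_names
        if len(values) != len(names):
            raise ValueError(f"expected {len(names)} values, got {len(values)}")
        updates = {}
        for name, v in zip(names, values):
            updates[name] = float(expit(v)) if name == "p" else math.exp(v)
        return replace(self, **updates)


def dtauw_logdensity(d_tau_W: float, delta_T: float, eta: float, sigma_c: float):
    """Log-density of ΔτW ~ N(−ln δT / ln(1+η), 2σc²)."""
    if sigma_c <= 0 or delta_T <= 0 or eta <= 0:
        raise ValueError("delta_T, eta and sigma_c must be strictly positive")
    mean = -math.log(delta_T) / math.log1p(eta)
    sd = math.sqrt(2.0) * sigma_c
    x = (np.asarray(d_tau_W, dtype=float) - mean) / sd
    out = -0.5 * x * x - math.log(sd) - _LOG_SQRT_2PI
    return float(out) if np.isscalar(d_tau_W) else out


@lru_cache(maxsize=16)
def _tanh_sinh_rule(num_nodes: int, t_max: float):
    """Tanh-sinh rule on (0, 1): nodes x, complements 1−x, log-weights.

    ``x = expit(π sinh t)`` keeps full precision at both endpoints (a
    plain ``tanh`` saturates to ±1 in float64), which matters because the
    integrands carry algebraic endpoint singularities.
    """
    t = np.linspace(-t_max, t_max, num_nodes)
    h = t[1] - t[0]
    st = 0.5 * math.pi * np.sinh(t)
    x = expit(2.0 * st)
    one_minus_x = expit(-2.0 * st)
    # dx/dt = (pi/4) cosh(t) / cosh^2((pi/2) sinh t)
    log_w = (
        math.log(h)
        + math.log(math.pi / 4.0)
        + np.log(np.cosh(t))
        - 2.0 * np.logaddexp(st, -st)
        + 2.0 * math.log(2.0)
    )
    return x, one_minus_x, log_w


@lru_cache(maxsize=64)
def _shared_u_grid(z: float, num: int, t_max: float):
    """Node geometry on the full u interval (ln z, 0), reused across calls.

    Returns ``u`` nodes, ``log y``, ``log (1−y)`` and the per-node row
    ``log(dy/du) + log w + log width`` — everything that does not depend
    on the sample or the mixture component.
    """
    x, one_minus_x, log_w = _tanh_sinh_rule(num, t_max)
    log_z = math.log(z)
    log_1mz = math.log1p(-z)
    width = -log_z
    du = width * x
    neg_u = width * one_minus_x
    u = log_z + du
    with np.errstate(divide="ignore"):
        log_y = log_z + np.log(np.expm1(du)) - log_1mz
        log_1my = np.log(-np.expm1(-neg_u)) - log_1mz
    row = (u - log_1mz) + log_w + math.log(width)
    return u, log_y, log_1my, row


def _interior_log_psi_beta(
    d_tau_D: np.ndarray,
    m: np.ndarray,
    n: int,
    k: float,
    delta_T: float,
    z: float,
    eta: float,
    sigma_c: float,
    config: QuadratureConfig = DEFAULT_QUADRATURE,
) -> np.ndarray:
    """log ψB for every observed ΔτD (axis 0) × interior m (axis 1).

    Vectorized over samples and mixture components; returns an array of
    shape ``(len(d_tau_D), len(m))``.
    """
    d = np.atleast_1d(np.asarray(d_tau_D, dtype=float))
    m = np.atleast_1d(np.asarray(m, dtype=float))
    L = math.log1p(eta)
    sd_cq = math.sqrt(2.0) * sigma_c

    if z == 1.0:
        # the digested ratio is identically 1: psi collapses to the W density
        mu = -math.log(delta_T) / L
        val = -0.5 * ((d - mu) / sd_cq) ** 2 - math.log(sd_cq) - _LOG_SQRT_2PI
        return np.broadcast_to(val[:, None], (d.size, m.size)).copy()

    if z > 1.0:
        raise ValueError("psi_beta requires z <= 1")
    a = m * k  # beta shape of the R side
    b = (n - m) * k
    log_z = math.log(z)
    log_1mz = math.log1p(-z)

    # Gaussian kernel in u = ln(z + y(1-z)); centre and SD per sample
    s_u = sd_cq * L
    u_star = -L * d - math.log(delta_T)
    full_width = -log_z
    # nodes needed to resolve the Gaussian on the full interval; the
    # tanh-sinh map thins mid-interval density by ~pi/4 per unit of t
    needed = config.nodes_per_sigma * 0.785 * 2.0 * config.t_max * full_width / s_u
    if needed <= config.max_nodes:
        num = next(nn for nn in _NODE_SIZES if nn >= max(needed, config.min_nodes))
        u, log_y, log_1my, row = _shared_u_grid(z, num, config.t_max)
        A = (
            -0.5 * ((u[None, :] - u_star[:, None]) / s_u) ** 2
            - math.log(s_u)
            - _LOG_SQRT_2PI
            + row[None, :]
        )  # (H, J)
        B = (
            (a[:, None] - 1.0) * log_y[None, :]
            + (b[:, None] - 1.0) * log_1my[None, :]
            - betaln(a, b)[:, None]
        )  # (M, J)
        amax = np.max(A, axis=1)
        bmax = np.max(B, axis=1)
        prod = np.exp(A - amax[:, None]) @ np.exp(B - bmax[:, None]).T
        with np.errstate(divide="ignore"):
            out = np.log(prod) + amax[:, None] + bmax[None, :]
        return out + math.log(L)
    else:
        # tiny-sigma regime: the Gaussian sifts the beta density; restrict
        # to its window (the remainder is exp(-window_sds^2/2) smaller)
        num = config.window_nodes
        half = config.window_sds * s_u
        lo = np.clip(u_star - half, log_z, 0.0)
        hi = np.clip(u_star + half, log_z, 0.0)
        # if the window collapsed onto a boundary, keep a boundary layer
        width = hi - lo
        collapsed = width <= 0.5 * half
        lo = np.where(collapsed & (u_star >= 0.0), np.maximum(log_z, -2.0 * half), lo)
        hi = np.where(
            collapsed & (u_star <= log_z), np.minimum(0.0, log_z + 2.0 * half), hi
        )

    x, one_minus_x, log_w = _tanh_sinh_rule(num, config.t_max)
    width = hi - lo
    # distances to the two true endpoints, each accurate where it is small
    du = (lo - log_z)[:, None] + width[:, None] * x[None, :]  # u − ln z
    neg_u = (-hi)[:, None] + width[:, None] * one_minus_x[None, :]  # −u
    u = lo[:, None] + width[:, None] * x[None, :]  # (H, J)

    # y(u) and 1−y(u) in forms exact near both endpoints
    with np.errstate(divide="ignore"):
        log_y = log_z + np.log(np.expm1(du)) - log_1mz  # y = z(e^{u−ln z}−1)/(1−z)
        log_1my = np.log(-np.expm1(-neg_u)) - log_1mz  # 1−y = (1−e^u)/(1−z)

    log_gauss = (
        -0.5 * ((u - u_star[:, None]) / s_u) ** 2 - math.log(s_u) - _LOG_SQRT_2PI
    )
    log_jac = u - log_1mz  # dy/du = e^u/(1−z)

    # per-sample windows (tiny sigma): full (H, M, J) accumulation
    log_beta = (
        (a[None, :, None] - 1.0) * log_y[:, None, :]
        + (b[None, :, None] - 1.0) * log_1my[:, None, :]
        - betaln(a, b)[None, :, None]
    )
    log_terms = (
        log_gauss[:, None, :]
        + log_beta
        + log_jac[:, None, :]
        + log_w[None, None, :]
        + np.log(width)[:, None, None]
    )
    # L·s_u factor: the Gaussian was written in ΔτD units; convert to u units
    return logsumexp(log_terms, axis=2) + math.log(L)


def psi_beta(
    d_tau_D: float,
    m: int,
    n: int,
    k: float,
    delta_T: float,
    z: float,
    eta: float,
    sigma_c: float,
    *,
    method: Literal["tanh-sinh", "quad"] = "tanh-sinh",
    config: QuadratureConfig = DEFAULT_QUADRATURE,
) -> float:
    """Marginal density of ΔτD for an interior mixture component.

    Integrates the Gaussian Cq-error kernel over the latent within-sample
    frequency ``y ~ Beta(mk, (n−m)k)``.  ``method="tanh-sinh"`` is the
    fast default; ``method="quad"`` uses adaptive QUADPACK integration in
    the y domain and serves as an independent numerical route.
    """
    if not (1 <= m <= n - 1):
        raise ValueError("psi_beta handles interior components only (1 <= m <= n-1)")
    for name, v in (("k", k), ("delta_T", delta_T), ("z", z), ("eta", eta), ("sigma_c", sigma_c)):
        if v <= 0:
            raise ValueError(f"{name} must be strictly positive")
    if method == "tanh-sinh":
        out = _interior_log_psi_beta(
            np.array([d_tau_D]), np.array([m]), n, k, delta_T, z, eta, sigma_c, config
        )
        return float(np.exp(out[0, 0]))
    if method != "quad":
        raise ValueError(f"unknown method {method!r}")

    if z == 1.0:
        return math.exp(dtauw_logdensity(d_tau_D, delta_T, eta, sigma_c))
    L = math.log1p(eta)
    sd = math.sqrt(2.0) * sigma_c
    a, b = m * k, (n - m) * k
    lbeta = betaln(a, b)

    def integrand(y: float) -> float:
        if y <= 0.0 or y >= 1.0:
            return 0.0
        mu = -(math.log(delta_T) + math.log(z + y * (1.0 - z))) / L
        lg = -0.5 * ((d_tau_D - mu) / sd) ** 2 - math.log(sd) - _LOG_SQRT_2PI
        lb = (a - 1.0) * math.log(y) + (b - 1.0) * math.log1p(-y) - lbeta
        t = lg + lb
        return math.exp(t) if t > -745.0 else 0.0

    # breakpoints: the measurement kernel's peak, the beta mode and a
    # log-spaced ladder towards each endpoint (boundary-layer cases)
    u_star = -L * d_tau_D - math.log(delta_T)
    y_star = (math.exp(u_star) - z) / (1.0 - z)
    points = {1e-12, 1e-9, 1e-6, 1e-3, 1e-1, 0.5, 0.9, 0.999, 1.0 - 1e-6}
    if 0.0 < y_star < 1.0:
        points.add(y_star)
    if a > 1.0 and b > 1.0:
        points.add((a - 1.0) / (a + b - 2.0))
    val, _ = integrate.quad(
        integrand,
        0.0,
        1.0,
        points=sorted(points),
        limit=500,
        epsabs=config.quad_epsabs,
        epsrel=config.quad_epsrel,
    )
    return val


def psi_gamma(
    d_tau_D: float,
    m: int,
    n: int,
    k: float,
    delta_T: float,
    z: float,
    eta: float,
    sigma_c: float,
    *,
    theta: float = 1.0,
    epsrel: float = 1e-10,
) -> float:
    """Marginal density of ΔτD by double integration over (X_R, X_S).

    Integrates the Gaussian kernel against ``Ga(r | mk, θ) Ga(s | (n−m)k, θ)``
    over the positive quadrant.  The scale ``θ`` cancels inside the ratio
    ``(r + z s)/(r + s)`` and must not affect the value.  Mathematically
    identical to :func:`psi_beta`; kept as an independent cross-check and
    as the gamma-model compatibility path.
    """
    if not (1 <= m <= n - 1):
        raise ValueError("psi_gamma handles interior components only (1 <= m <= n-1)")
    if theta <= 0:
        raise ValueError("theta must be strictly positive")
    if not (0.0 < z < 1.0):
        raise ValueError("psi_gamma requires 0 < z < 1")
    L = math.log1p(eta)
    sd = math.sqrt(2.0) * sigma_c
    a, b = m * k, (n - m) * k
    log_norm_a = -gammaln(a)
    log_norm_b = -gammaln(b)
    log_dT = math.log(delta_T)
    # ratio the measurement kernel centres on; r* / s = layer location
    u_star = -L * d_tau_D - log_dT
    rho = math.exp(u_star)
    layer = (rho - z) / (1.0 - rho) if z < rho < 1.0 else None

    # integrate in log coordinates (w = ln r, v = ln s): the algebraic
    # origin singularities become exponential tails of O(1) width
    tail = 1e-14
    w_lo, w_hi = (
        math.log(stats.gamma.ppf(tail, a, scale=theta)),
        math.log(stats.gamma.isf(tail, a, scale=theta)),
    )
    v_lo, v_hi = (
        math.log(stats.gamma.ppf(tail, b, scale=theta)),
        math.log(stats.gamma.isf(tail, b, scale=theta)),
    )
    # the kernel can drag s far outside the gamma bulk; under (y, t) with
    # s = (1−y)t the mass has y in hull(beta bulk, kernel window) and t in
    # the gamma(a+b) bulk, which bounds the s range
    s_u = sd * L
    u_lo_m = max(math.log(z), u_star - 30.0 * s_u)
    u_hi_m = min(0.0, u_star + 30.0 * s_u)
    if u_hi_m > math.log(z):
        y_gauss_lo = max((math.exp(u_lo_m) - z) / (1.0 - z), 0.0)
        one_minus_y_gauss_hi = -math.expm1(u_hi_m) / (1.0 - z)
        y_lo_m = min(y_gauss_lo, stats.beta.ppf(1e-18, a, b))
        one_minus_hi = max(
            min(one_minus_y_gauss_hi, float(stats.beta.ppf(1e-18, b, a))), 1e-20
        )
        t_lo = stats.gamma.ppf(tail, a + b, scale=theta)
        t_hi = stats.gamma.isf(tail, a + b, scale=theta)
        v_lo = min(v_lo, math.log(one_minus_hi * t_lo))
        v_hi = max(v_hi, math.log(max(1.0 - y_lo_m, 1e-20) * t_hi))

    def inner(s: float) -> float:
        log_gs = log_norm_b + b * (math.log(s) - math.log(theta)) - s / theta

        def f(w: float) -> float:
            r = math.exp(w)
            mu = -(log_dT + math.log((r + z * s) / (r + s))) / L
            t = (
                -0.5 * ((d_tau_D - mu) / sd) ** 2
                - math.log(sd)
                - _LOG_SQRT_2PI
                + log_norm_a
                + a * (w - math.log(theta))
                - r / theta
                + log_gs
            )
            return math.exp(t) if t > -745.0 else 0.0

        # the kernel may concentrate the mass far outside the gamma bulk,
        # where the ratio saturates at z (r << zs) or 1 (r >> s); extend
        # the bounds to cover those layers
        anchor = math.log(layer * s) if layer is not None else math.log(z * s)
        wl = min(w_lo, anchor - 50.0 / min(a, 1.0))
        wh = max(w_hi, math.log(s) + 10.0, anchor + 10.0)
        # breakpoints: the gamma bulk and the kernel layer, so the adaptive
        # rule refines both even when the extended interval is very wide
        pts = sorted({p for p in (w_lo, w_hi, anchor) if wl < p < wh})
        val, _ = integrate.quad(
            f, wl, wh, points=pts or None, limit=400, epsabs=1e-280, epsrel=epsrel
        )
        return val

    def outer(v: float) -> float:
        return inner(math.exp(v))

    bulk = (
        math.log(stats.gamma.ppf(1e-6, b, scale=theta)),
        math.log(stats.gamma.isf(1e-6, b, scale=theta)),
    )
    pts = sorted({p for p in bulk if v_lo < p < v_hi})
    val, _ = integrate.quad(
        outer,
        v_lo,
        v_hi,
        points=pts or None,
        limit=400,
        epsabs=1e-280,
        epsrel=max(epsrel, 1e-9),
    )
    return val


@lru_cache(maxsize=64)
def _log_binom_coef(n: int) -> np.ndarray:
    m = np.arange(n + 1, dtype=float)
    return gammaln(n + 1.0) - gammaln(m + 1.0) - gammaln(n - m + 1.0)


def _binom_logpmf(n: int, p: float) -> np.ndarray:
    """log Bin(m | n, p) for m = 0..n, with exact p = 0 / 1 limits."""
    m = np.arange(n + 1, dtype=float)
    out = np.full(n + 1, -np.inf)
    if p <= 0.0:
        out[0] = 0.0
        return out
    if p >= 1.0:
        out[n] = 0.0
        return out
    return _log_binom_coef(n) + m * math.log(p) + (n - m) * math.log1p(-p)


def _log_p_dtau_d(
    d: np.ndarray,
    n: int,
    params: ParamVector,
    kernel: str,
    config: QuadratureConfig,
) -> np.ndarray:
    """log P(ΔτD | m) for all samples (axis 0) and m = 0..n (axis 1)."""
    L = math.log1p(params.eta)
    sd = math.sqrt(2.0) * params.sigma_c
    out = np.empty((d.size, n + 1))
    mu0 = -(math.log(params.z) + math.log(params.delta_T)) / L
    mun = -math.log(params.delta_T) / L
    out[:, 0] = -0.5 * ((d - mu0) / sd) ** 2 - math.log(sd) - _LOG_SQRT_2PI
    out[:, n] = -0.5 * ((d - mun) / sd) ** 2 - math.log(sd) - _LOG_SQRT_2PI
    if n >= 2:
        interior = np.arange(1, n)
        if kernel == "beta":
            out[:, 1:n] = _interior_log_psi_beta(
                d,
                interior,
                n,
                params.k,
                params.delta_T,
                params.z,
                params.eta,
                params.sigma_c,
                config,
            )
        elif kernel == "gamma":
            for j, mm in enumerate(interior):
                for i, dd in enumerate(d):
                    val = psi_gamma(
                        float(dd),
                        int(mm),
                        n,
                        params.k,
                        params.delta_T,
                        params.z,
                        params.eta,
                        params.sigma_c,
                    )
                    out[i, 1 + j] = math.log(val) if val > 0.0 else -np.inf
        else:
            raise ValueError(f"unknown kernel {kernel!r}")
    return out


def bulk_sample_loglik(
    delta: DeltaPair,
    n: int,
    params: ParamVector,
    kernel: Literal["beta", "gamma"] = "beta",
    config: QuadratureConfig = DEFAULT_QUADRATURE,
) -> float:
    """Log-likelihood of one bulk sample's ΔCq pair.

    Sums the binomial mixture over the latent R count ``m = 0..n`` in log
    space, so rare-allele weights do not underflow.  ``p = 0`` and
    ``p = 1`` are accepted as degenerate limits (the mixture reduces to
    its m=0 or m=n component).
    """
    if n < 1:
        raise ValueError("pool size n must be >= 1")
    d = np.array([delta.d_tau_D], dtype=float)
    log_pd = _log_p_dtau_d(d, n, params, kernel, config)
    log_bin = _binom_logpmf(n, params.p)
    log_mix = logsumexp(log_bin[None, :] + log_pd, axis=1)[0]
    return float(
        dtauw_logdensity(delta.d_tau_W, params.delta_T, params.eta, params.sigma_c)
        + log_mix
    )


def total_negloglik(
    samples: Iterable,
    params: ParamVector,
    kernel: Literal["beta", "gamma"] = "beta",
    config: QuadratureConfig = DEFAULT_QUADRATURE,
) -> float:
    """Negative total log-likelihood over N >= 2 bulk samples.

    ``samples`` is an iterable of ``(DeltaPair, n)``.  A single bulk
    sample is rejected: two observables cannot identify the four model
    parameters.  Samples sharing a pool size are evaluated together
    through the vectorized beta kernel.
    """
    items = [(dp, int(n)) for dp, n in samples]
    if len(items) < 2:
        raise ValueError(
            "at least 2 bulk samples are required: one sample provides two "
            "ΔCq observables, which cannot identify the model parameters"
        )
    total = 0.0
    by_n: dict[int, list[DeltaPair]] = {}
    for dp, n in items:
        if n < 1:
            raise ValueError("pool size n must be >= 1")
        by_n.setdefault(n, []).append(dp)
    for n, pairs in by_n.items():
        d_w = np.array([dp.d_tau_W for dp in pairs])
        d_d = np.array([dp.d_tau_D for dp in pairs])
        log_pd = _log_p_dtau_d(d_d, n, params, kernel, config)
        log_bin = _binom_logpmf(n, params.p)
        log_mix = logsumexp(log_bin[None, :] + log_pd, axis=1)
        log_w = dtauw_logdensity(d_w, params.delta_T, params.eta, params.sigma_c)
        total += float(np.sum(log_mix) + np.sum(log_w))
    return -total
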