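"""Forward model of (RED-)ΔΔCq quantification on bulk DNA samples.

A bulk sample pools ``n`` haploid individuals, ``m`` of which carry the
allele of interest (R).  Per-individual DNA yields are gamma distributed,
so the total R and S template amounts are ``X_R ~ Ga(mk, θ)`` and
``X_S ~ Ga((n−m)k, θ)``, and the within-sample allele frequency
``Y_R = X_R/(X_R+X_S)`` is ``Beta(mk, (n−m)k)``.

qPCR reads each bulk sample four times — {housekeeping, target locus} ×
{control, test} — giving the "Cq quartet".  In the restriction-enzyme
variant the test condition digests the susceptible allele (a fraction
``z`` survives); in the allele-specific-primer variant the control is a
pure-R solution and ``z`` is the off-target amplification fraction.  The
same quartet structure and the same downstream likelihood serve both
protocols because the protocol-specific scale factors cancel in ΔΔCq.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PopulationState",
    "GammaYieldModel",
    "BulkSampleComposition",
    "QpcrParams",
    "CqQuartet",
    "DeltaPair",
    "ConventionalEstimate",
    "delta_pair_from_quartet",
    "expected_cq_quartet",
    "theoretical_ddcq",
    "conventional_freq_estimate",
]


@dataclass(frozen=True)
class PopulationState:
    """Frequency ``p`` of the R allele in the sampled population."""

    p: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"allele frequency p must lie in [0, 1], got {self.p}")


@dataclass(frozen=True)
class GammaYieldModel:
    """Gamma model of per-individual DNA yield (shape ``k``, scale ``theta``).

    ``k`` controls yield variability: ``k=1`` is exponential, large ``k``
    approaches a constant yield.  The scale is not identifiable from ΔCq
    data and is conventionally set to 1.
    """

    k: float
    theta: float = 1.0

    def __post_init__(self) -> None:
        if self.k <= 0 or self.theta <= 0:
            raise ValueError("gamma shape and scale must be strictly positive")

    @property
    def mean_yield(self) -> float:
        return self.k * self.theta


@dataclass(frozen=True)
class BulkSampleComposition:
    """Latent state of one bulk sample: counts and template amounts."""

    n: int
    m: int
    X_R: float = 0.0
    X_S: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("pool size n must be >= 1")
        if not (0 <= self.m <= self.n):
            raise ValueError(f"R count m={self.m} outside 0..n={self.n}")
        if self.m == 0 and self.X_R != 0.0:
            raise ValueError("m=0 implies X_R=0")
        if self.m == self.n and self.X_S != 0.0:
            raise ValueError("m=n implies X_S=0")
        if self.X_R < 0 or self.X_S < 0:
            raise ValueError("template amounts must be non-negative")

    @property
    def Y_R(self) -> float:
        total = self.X_R + self.X_S
        if total == 0:
            raise ValueError("Y_R undefined for an empty sample")
        return self.X_R / total


@dataclass(frozen=True)
class QpcrParams:
    """Parameters of the qPCR measurement process.

    eta
        Per-cycle amplification efficiency; the template multiplies by
        ``1 + eta`` each cycle (``eta`` near 1 means near-perfect doubling).
    X_theta
        Fluorescence termination threshold; amounts are expressed relative
        to it, so it is fixed at 1 internally.
    delta_T
        Relative content of the target locus to the housekeeping locus.
    delta_B
        Locus-independent change in template quantity caused by the test
        treatment (e.g. restriction digestion).
    z
        Residual fraction of the susceptible allele after digestion (or the
        off-target amplified fraction with an allele-specific primer).
        Strictly positive; keeps all-S samples measurable.
    sigma_c
        SD of the Cq measurement error, in cycles.
    mean_dna
        Mean per-individual template amount relative to ``X_theta``; used
        by calibration and the simulator, not by the ΔCq likelihood.
    """

    eta: float
    delta_T: float = 1.0
    delta_B: float = 1.0
    z: float = 1e-3
    sigma_c: float = 0.2
    mean_dna: float = 1e-6
    X_theta: float = 1.0

    def __post_init__(self) -> None:
        for name in ("eta", "delta_T", "delta_B", "z", "sigma_c", "mean_dna", "X_theta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.z >= 1.0:
            warnings.warn(
                f"z={self.z} >= 1: the test condition does not suppress the S "
                "allele; estimates will be uninformative",
                stacklevel=2,
            )

    @property
    def log_efficiency(self) -> float:
        """ln(1+eta) — cycles-to-log-quantity conversion factor."""
        return math.log1p(self.eta)


@dataclass(frozen=True)
class CqQuartet:
    """The four Cq values of one bulk sample.

    ``tau_HW``/``tau_TW`` are housekeeping/target Cq under the control
    condition (undigested, or the pure-R control of the allele-specific
    protocol); ``tau_HD``/``tau_TD`` are the same loci under the test
    condition (digested, or the test sample).
    """

    tau_HW: float
    tau_TW: float
    tau_HD: float
    tau_TD: float

    def __post_init__(self) -> None:
        for name in ("tau_HW", "tau_TW", "tau_HD", "tau_TD"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"Cq value {name}={v} is not finite")


@dataclass(frozen=True)
class DeltaPair:
    """ΔCq pair of one bulk sample: ΔτW, ΔτD and their difference ΔΔτ."""

    d_tau_W: float
    d_tau_D: float
    dd_tau: float = field(default=math.nan)

    def __post_init__(self) -> None:
        expected = self.d_tau_D - self.d_tau_W
        if math.isnan(self.dd_tau):
            object.__setattr__(self, "dd_tau", expected)
        elif self.dd_tau != expected:
            raise ValueError("dd_tau must equal d_tau_D - d_tau_W exactly")


def delta_pair_from_quartet(q: CqQuartet) -> DeltaPair:
    """ΔτW = τTW − τHW, ΔτD = τTD − τHD, ΔΔτ = ΔτD − ΔτW."""
    d_w = q.tau_TW - q.tau_HW
    d_d = q.tau_TD - q.tau_HD
    return DeltaPair(d_tau_W=d_w, d_tau_D=d_d)


def expected_cq_quartet(params: QpcrParams, X_R: float, X_S: float) -> CqQuartet:
    """Noise-free Cq quartet for template amounts ``(X_R, X_S)``.

    The control condition measures ``X_R + X_S`` (housekeeping) and
    ``delta_T (X_R + X_S)`` (target); the test condition scales both by
    ``delta_B`` and replaces the target amount by ``X_R + z X_S``.
    """
    if X_R < 0 or X_S < 0:
        raise ValueError("template amounts must be non-negative")
    total = X_R + X_S
    if total <= 0:
        raise ValueError("X_R + X_S must be positive")
    digested = X_R + params.z * X_S
    if digested <= 0:
        raise ValueError("X_R + z*X_S must be positive")
    L = params.log_efficiency
    ln_thresh = math.log(params.X_theta)
    ln_total = math.log(total)
    ln_dT = math.log(params.delta_T)
    ln_dB = math.log(params.delta_B)
    return CqQuartet(
        tau_HW=(ln_thresh - ln_total) / L,
        tau_TW=(ln_thresh - ln_dT - ln_total) / L,
        tau_HD=(ln_thresh - ln_dB - ln_total) / L,
        tau_TD=(ln_thresh - ln_dB - ln_dT - math.log(digested)) / L,
    )


def theoretical_ddcq(Y_R: float, z: float, eta: float) -> float:
    """Noise-free expected ΔΔτ for a sample of true frequency ``Y_R``.

    Equals ``−ln(z + Y_R (1−z)) / ln(1+eta)``: zero for a pure-R sample and
    increasing as R becomes rarer, capped by the digestion residue ``z``.
    """
    if not (0.0 <= Y_R <= 1.0):
        raise ValueError(f"Y_R must lie in [0, 1], got {Y_R}")
    if z <= 0 or eta <= 0:
        raise ValueError("z and eta must be strictly positive")
    return -math.log(z + Y_R * (1.0 - z)) / math.log1p(eta)


@dataclass(frozen=True)
class ConventionalEstimate:
    """Simple-average ΔΔCq point estimate with its naive Wald interval.

    The interval endpoints transform ``mean(ΔΔτ) ∓ 1.96 SE``; both the
    point estimate and the upper endpoint can exceed 1, which is one of
    the failure modes the likelihood-based estimator avoids.
    """

    estimate: float
    lower: float
    upper: float
    mean_ddcq: float
    se_ddcq: float
    n_obs: int


def conventional_freq_estimate(dd_taus, eta: float) -> ConventionalEstimate:
    """Frequency-scale estimate ``(1+eta)^(−mean ΔΔτ)`` with a naive CI.

    This is the classical point estimator obtained by averaging observed
    ΔΔCq values over bulk samples.  The naive interval transforms the
    normal-theory endpoints of the ΔΔτ mean and is provided only for
    comparison with the likelihood-based interval.
    """
    arr = np.asarray(list(dd_taus), dtype=float)
    if arr.size == 0:
        raise ValueError("at least one ddCq value is required")
    if eta <= 0:
        raise ValueError("eta must be strictly positive")
    if not np.all(np.isfinite(arr)):
        raise ValueError("ddCq values must be finite")
    mean = float(arr.mean())
    if arr.size > 1:
        se = float(arr.std(ddof=1) / math.sqrt(arr.size))
    else:
        se = math.nan
    base = 1.0 + eta
    est = base ** (-mean)
    if math.isnan(se):
        lo = hi = math.nan
    else:
        # a larger ddCq mean implies a smaller frequency, so endpoints swap
        lo = base ** (-(mean + 1.96 * se))
        hi = base ** (-(mean - 1.96 * se))
    return ConventionalEstimate(
        estimate=est, lower=lo, upper=hi, mean_ddcq=mean, se_ddcq=se, n_obs=int(arr.size)
    )
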