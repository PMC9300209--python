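"""Calibration of auxiliary qPCR parameters from known-ratio samples.

Mixing DNA from pure R and S lines at known ratios removes the pool
composition uncertainty: every Cq value is then a Gaussian observation
around a closed-form mean determined by six parameters — per-individual
template amount ``mean_dna`` (relative to the threshold), target-locus
content ``delta_T``, digestion change rate ``delta_B``, digestion
residue ``z``, efficiency ``eta`` and Cq error SD ``sigma_c``.  Their
joint MLE (all on log scale, Wald CIs from the observed information)
supplies the fixed ``z`` and ``eta`` the frequency likelihood needs.

The unpaired mode accepts arbitrary incomplete designs — e.g. the common
layout where undigested (control) wells are run only for the pure-R
ratio; the paired mode additionally insists on complete quartets per
(ratio, replicate).

``linearity_diagnostics`` reproduces the classical assay-validation
regressions: observed ΔΔCq (or its frequency-scale transform) against
the theoretical value, with a Breusch–Pagan heteroscedasticity test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Literal, Mapping, Optional, Sequence

import numpy as np
from scipy import optimize

from .estimation import _fd_hessian, ParameterEstimate, _Z95

__all__ = [
    "KnownRatioObservation",
    "CalibrationFitResult",
    "RegressionDiagnostics",
    "predict_known_cq",
    "fit_known_ratio",
    "linearity_diagnostics",
    "make_known_ratio_dataset",
]

GENES = ("housekeeping", "target")
CONDITIONS = ("W", "D")  # control/undigested vs test/digested

#: calibration parameters, canonical order (all strictly positive)
CAL_PARAM_NAMES = ("mean_dna", "delta_T", "delta_B", "sigma_c", "z", "eta")


@dataclass(frozen=True)
class KnownRatioObservation:
    """One Cq measurement on a sample of exactly known allele ratio."""

    ratio: float  # true Y_R = X_R / (X_R + X_S)
    gene: str  # housekeeping | target
    condition: str  # W (control/undigested) | D (test/digested)
    replicate: int
    cq: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.ratio <= 1.0):
            raise ValueError(f"ratio must lie in [0, 1], got {self.ratio}")
        if self.gene not in GENES:
            raise ValueError(f"gene must be one of {GENES}, got {self.gene!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if not math.isfinite(self.cq):
            raise ValueError("cq must be finite")


@dataclass(frozen=True)
class CalibrationFitResult:
    """Joint MLE of the six auxiliary parameters with log-scale Wald CIs."""

    estimates: Mapping[str, ParameterEstimate]
    loglik: float
    converged: bool
    success: bool
    n_obs: int
    n_iter: int
    message: str = ""

    def __getitem__(self, name: str) -> ParameterEstimate:
        return self.estimates[name]

    @property
    def z(self) -> float:
        return self.estimates["z"].estimate

    @property
    def eta(self) -> float:
        return self.estimates["eta"].estimate


def predict_known_cq(
    params: Mapping[str, float], ratio: float, gene: str, condition: str
) -> float:
    """Expected Cq for a known-ratio sample in one of the four channels.

    With L = ln(1+eta) and the template expressed relative to the
    threshold:

        housekeeping, W:  −ln(mean_dna) / L
        target,       W:  −ln(delta_T · mean_dna) / L
        housekeeping, D:  −ln(delta_B · mean_dna) / L
        target,       D:  −ln(delta_B · delta_T · (ratio + z(1−ratio)) · mean_dna) / L
    """
    if not (0.0 <= ratio <= 1.0):
        raise ValueError(f"ratio must lie in [0, 1], got {ratio}")
    if gene not in GENES or condition not in CONDITIONS:
        raise ValueError(f"unknown channel ({gene!r}, {condition!r})")
    L = math.log1p(params["eta"])
    val = math.log(params["mean_dna"])
    if gene == "target":
        val += math.log(params["delta_T"])
    if condition == "D":
        val += math.log(params["delta_B"])
        if gene == "target":
            val += math.log(ratio + params["z"] * (1.0 - ratio))
    return -val / L


def _check_identifiable(obs: Sequence[KnownRatioObservation], paired: bool) -> None:
    ratios = {o.ratio for o in obs}
    if len(ratios) < 2:
        raise ValueError(
            "calibration requires at least 2 distinct mixing ratios "
            "(a single ratio cannot separate eta from the template amount)"
        )
    if not any(o.condition == "D" and o.gene == "target" and o.ratio < 1.0 for o in obs):
        raise ValueError(
            "no digested/test target measurement with ratio < 1: "
            "the residue rate z is unidentifiable"
        )
    if not any(o.condition == "W" for o in obs):
        raise ValueError(
            "no control/undigested measurements: delta_B cannot be "
            "separated from the template amount"
        )
    if not any(o.gene == "housekeeping" for o in obs) or not any(
        o.gene == "target" for o in obs
    ):
        raise ValueError(
            "both housekeeping and target measurements are required to "
            "identify delta_T"
        )
    if paired:
        cells = {}
        for o in obs:
            cells.setdefault((o.ratio, o.replicate), set()).add((o.gene, o.condition))
        incomplete = [key for key, got in cells.items() if len(got) < 4]
        if incomplete:
            raise ValueError(
                "paired mode requires a complete Cq quartet per "
                f"(ratio, replicate); incomplete: {sorted(incomplete)[:5]}"
            )


def fit_known_ratio(
    observations: Iterable[KnownRatioObservation],
    paired: bool = False,
    start: Optional[Mapping[str, float]] = None,
    maxiter: int = 500,
) -> CalibrationFitResult:
    """Joint MLE of the six auxiliary parameters from known-ratio Cq data.

    Each observation contributes ``N(predicted Cq, sigma_c^2)`` to the
    likelihood; ``sigma_c`` is itself a free likelihood parameter rather
    than a plug-in residual SD, so it gets a CI like the others.  All six
    parameters are estimated on the log scale, which yields multiplicative
    (right-skewed) Wald intervals appropriate for positive quantities.
    """
    obs = list(observations)
    if not obs:
        raise ValueError("no observations")
    _check_identifiable(obs, paired)

    ratio = np.array([o.ratio for o in obs])
    is_target = np.array([o.gene == "target" for o in obs])
    is_digested = np.array([o.condition == "D" for o in obs])
    cq = np.array([o.cq for o in obs])
    n_obs = len(obs)

    # data-driven starting values: efficiency ~1 (near-doubling assays),
    # template amount from the overall Cq level
    mean_cq_w = (
        float(np.mean(cq[~is_digested & ~is_target]))
        if np.any(~is_digested & ~is_target)
        else float(np.mean(cq))
    )
    defaults = {
        "mean_dna": math.exp(-math.log(2.0) * mean_cq_w),
        "delta_T": 1.0,
        "delta_B": 0.5,
        "sigma_c": 0.3,
        "z": 1e-3,
        "eta": 1.0,
    }
    if start:
        defaults.update(start)

    structural = [n for n in CAL_PARAM_NAMES if n != "sigma_c"]

    def residuals(x: np.ndarray) -> np.ndarray:
        par = {name: math.exp(v) for name, v in zip(structural, x)}
        L = math.log1p(par["eta"])
        pred = -(
            math.log(par["mean_dna"])
            + is_target * math.log(par["delta_T"])
            + is_digested * math.log(par["delta_B"])
            + (is_target & is_digested)
            * np.log(ratio + par["z"] * (1.0 - ratio))
        ) / L
        return cq - pred

    def negloglik(x: np.ndarray) -> float:
        """Full 6-parameter objective (sigma_c included) for the Hessian."""
        resid = residuals(np.delete(x, CAL_PARAM_NAMES.index("sigma_c")))
        sigma = math.exp(x[CAL_PARAM_NAMES.index("sigma_c")])
        val = 0.5 * float(resid @ resid) / sigma**2 + n_obs * (
            math.log(sigma) + 0.5 * math.log(2.0 * math.pi)
        )
        return val if math.isfinite(val) else 1e12

    # sigma_c profiles out of the Gaussian likelihood: the structural MLE
    # is plain nonlinear least squares and sigma_hat^2 = SS/n afterwards
    x0 = np.array([math.log(defaults[name]) for name in structural])
    ls = optimize.least_squares(
        residuals, x0, method="lm", xtol=1e-14, ftol=1e-14, max_nfev=200 * maxiter
    )
    ss = float(ls.fun @ ls.fun)
    sigma_hat = math.sqrt(ss / n_obs) if ss > 0 else 1e-12
    x_hat = np.insert(ls.x, CAL_PARAM_NAMES.index("sigma_c"), math.log(sigma_hat))

    res = ls
    hess = _fd_hessian(negloglik, x_hat)
    success = True
    try:
        cov = np.linalg.inv(hess)
        diag = np.diag(cov)
        if not np.all(np.isfinite(diag)) or np.any(diag <= 0.0):
            success = False
    except np.linalg.LinAlgError:
        cov = None
        success = False

    estimates = {}
    for i, name in enumerate(CAL_PARAM_NAMES):
        est = math.exp(x_hat[i])
        if success:
            se = math.sqrt(cov[i, i])
            lo, hi = est * math.exp(-_Z95 * se), est * math.exp(_Z95 * se)
        else:
            se = lo = hi = math.nan
        estimates[name] = ParameterEstimate(
            name=name, estimate=est, se_transformed=se, ci_lower=lo, ci_upper=hi
        )

    return CalibrationFitResult(
        estimates=estimates,
        loglik=-negloglik(x_hat),
        converged=bool(res.success),
        success=success,
        n_obs=n_obs,
        n_iter=int(res.nfev),
        message=str(res.message),
    )


@dataclass(frozen=True)
class RegressionDiagnostics:
    """Straight-line fit of observed vs theoretical assay response."""

    intercept: float
    slope: float
    adjusted_r2: float
    bp_stat: float
    bp_df: int
    bp_pvalue: float
    n_points: int
    scale: str


def _ols_line(x: np.ndarray, y: np.ndarray):
    """Least-squares line with adjusted R^2 and residuals."""
    n = x.size
    X = np.column_stack([np.ones(n), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return coef, resid, adj


def _breusch_pagan(x: np.ndarray, resid: np.ndarray):
    """Lagrange-multiplier form: n·R² of squared residuals on the regressor."""
    n = x.size
    w = resid**2
    X = np.column_stack([np.ones(n), x])
    coef, *_ = np.linalg.lstsq(X, w, rcond=None)
    fitted = X @ coef
    ss_res = float(np.sum((w - fitted) ** 2))
    ss_tot = float(np.sum((w - w.mean()) ** 2))
    # an (up to roundoff) exact fit has no variance structure to test
    r2aux = 1.0 - ss_res / ss_tot if ss_tot > 1e-40 else 0.0
    stat = n * r2aux
    from scipy.stats import chi2

    return stat, 1, float(chi2.sf(stat, 1))


def observed_ddcq_by_replicate(
    observations: Iterable[KnownRatioObservation],
    reference_ratio: float = 1.0,
) -> List[tuple]:
    """Per (replicate, ratio) ΔΔτ using the reference-ratio ΔτW.

    Mirrors the common bench practice when control wells were run only at
    one ratio: each replicate's control ΔτW (at ``reference_ratio``) is
    reused across all its test ratios.
    """
    cells: dict = {}
    for o in observations:
        cells[(o.replicate, o.ratio, o.gene, o.condition)] = o.cq
    replicates = sorted({o.replicate for o in observations})
    ratios = sorted({o.ratio for o in observations})
    out = []
    for rep in replicates:
        try:
            d_tau_w = (
                cells[(rep, reference_ratio, "target", "W")]
                - cells[(rep, reference_ratio, "housekeeping", "W")]
            )
        except KeyError:
            continue
        for ratio in ratios:
            try:
                d_tau_d = (
                    cells[(rep, ratio, "target", "D")]
                    - cells[(rep, ratio, "housekeeping", "D")]
                )
            except KeyError:
                continue
            out.append((rep, ratio, d_tau_d - d_tau_w))
    return out


def linearity_diagnostics(
    observations: Iterable[KnownRatioObservation],
    z: float,
    eta: float,
    scale: Literal["ddcq", "linear"] = "ddcq",
    reference_ratio: float = 1.0,
) -> RegressionDiagnostics:
    """Assay linearity and homoscedasticity on the chosen response scale.

    ``scale="ddcq"`` regresses observed ΔΔτ on the theoretical
    ``−ln(z + Y(1−z))/ln(1+eta)``; ``scale="linear"`` regresses the
    back-transformed frequency ``(1+eta)^(−ΔΔτ)`` on ``z + Y(1−z)``.
    The Breusch–Pagan statistic tests whether the residual variance
    drifts with the predictor (df = 1).
    """
    triples = observed_ddcq_by_replicate(observations, reference_ratio)
    if len(triples) < 3:
        raise ValueError("at least 3 (replicate, ratio) points are required")
    ratios = np.array([t[1] for t in triples])
    ddcq = np.array([t[2] for t in triples])
    L = math.log1p(eta)
    if scale == "ddcq":
        x = -np.log(z + ratios * (1.0 - z)) / L
        y = ddcq
    elif scale == "linear":
        x = z + ratios * (1.0 - z)
        y = (1.0 + eta) ** (-ddcq)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    coef, resid, adj = _ols_line(x, y)
    stat, df, pval = _breusch_pagan(x, resid)
    return RegressionDiagnostics(
        intercept=float(coef[0]),
        slope=float(coef[1]),
        adjusted_r2=float(adj),
        bp_stat=float(stat),
        bp_df=df,
        bp_pvalue=pval,
        n_points=len(triples),
        scale=scale,
    )


MITE_LAYOUT_RATIOS = (0.0, 0.001, 0.005, 0.01, 0.05, 0.1, 0.25, 0.5, 0.75, 1.0)


def make_known_ratio_dataset(
    params: Mapping[str, float],
    ratios: Sequence[float] = MITE_LAYOUT_RATIOS,
    n_replicates: int = 4,
    undigested_ratios: Optional[Sequence[float]] = (1.0,),
    rng=None,
) -> List[KnownRatioObservation]:
    """Synthetic known-ratio Cq dataset.

    The default layout emulates a typical dilution-series validation
    experiment: 10 mixing ratios, 4 replicates, digested wells everywhere
    but undigested (control) wells only at the pure-R ratio.
    ``undigested_ratios=None`` yields the complete paired layout.  With
    ``rng=None`` the Cq values are noise-free conditional means.
    """
    if undigested_ratios is None:
        undigested_ratios = tuple(ratios)
    out = []
    for rep in range(1, n_replicates + 1):
        for ratio in ratios:
            for gene in GENES:
                for condition in CONDITIONS:
                    if condition == "W" and ratio not in undigested_ratios:
                        continue
                    cq = predict_known_cq(params, ratio, gene, condition)
                    if rng is not None:
                        cq += float(rng.normal(0.0, params["sigma_c"]))
                    out.append(
                        KnownRatioObservation(
                            ratio=ratio,
                            gene=gene,
                            condition=condition,
                            replicate=rep,
                            cq=cq,
                        )
                    )
    return out
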