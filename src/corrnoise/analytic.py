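"""Closed-form expected correlation, attenuation, and bias-regime analysis.

For measured variables following the generalized correlated error model,
the large-sample (population) correlation of the measured pair is

    rho = A * [ rho0 * (1 + pi_mc * s_mc_x * s_mc_y)
                + pi_ac * gamma_x * gamma_y
                + delta_x * delta_y * pi_mc * s_mc_x * s_mc_y ]

with attenuation coefficient

    A = 1 / sqrt(f_x * f_y),
    f = 1 + (1 + delta^2) * (var_mu + var_mc) + xi^2 + gamma^2

where per variable xi^2 = var_au / var0, gamma = sd_ac / sd0 and
delta = mu0 / sd0.  The additive, multiplicative and combined models are
the pi = +/-1, shared-variance reductions of these formulas.
"""

from __future__ import annotations

import dataclasses
import enum
import math

import numpy as np

from .models import ErrorSpec, ModelKind, TrueSignal, theoretical_var

__all__ = [
    "ErrorRatios",
    "ExpectedCorr",
    "Regime",
    "RegimeReport",
    "error_ratios",
    "attenuation_coeff",
    "expected_corr",
    "expected_corr_raw",
    "expected_corr_grid",
    "null_corr",
    "classify_regime",
    "limiting_surface",
]

#: absolute tolerance for regime comparisons
REGIME_TOL = 1e-12


@dataclasses.dataclass(frozen=True)
class ErrorRatios:
    """Dimensionless error ratios of one (signal, error) configuration.

    ``xi_*`` and ``gamma_*`` are the unsquared ratios (error SD over
    biological SD); ``delta_*`` is the signal-to-biological-variation
    ratio mu0 / sd0.
    """

    xi_x: float
    xi_y: float
    gamma_x: float
    gamma_y: float
    delta_x: float
    delta_y: float

    @property
    def xi2_x(self) -> float:
        return self.xi_x ** 2

    @property
    def xi2_y(self) -> float:
        return self.xi_y ** 2

    @property
    def gamma2_x(self) -> float:
        return self.gamma_x ** 2

    @property
    def gamma2_y(self) -> float:
        return self.gamma_y ** 2


class Regime(str, enum.Enum):
    UNBIASED = "unbiased"
    ATTENUATED = "attenuated"
    INFLATED = "inflated"
    SIGN_FLIPPED = "sign_flipped"


@dataclasses.dataclass(frozen=True)
class ExpectedCorr:
    """Population correlation of the measured pair plus its decomposition."""

    rho: float
    attenuation: float
    ratios: ErrorRatios
    model_kind: ModelKind

    def __post_init__(self) -> None:
        if abs(self.rho) > 1 + 1e-12:
            raise ValueError(f"|rho| must be <= 1, got {self.rho}")
        if not (0 < self.attenuation <= 1 + 1e-12):
            raise ValueError(f"attenuation must be in (0, 1], got {self.attenuation}")


@dataclasses.dataclass(frozen=True)
class RegimeReport:
    """Bias classification of the expected vs the true correlation."""

    regime: Regime
    surface_S: float | None
    rho: float
    rho0: float


def error_ratios(signal: TrueSignal, err: ErrorSpec) -> ErrorRatios:
    sd_x, sd_y = math.sqrt(signal.var_x), math.sqrt(signal.var_y)
    return ErrorRatios(
        xi_x=math.sqrt(err.var_au_x) / sd_x,
        xi_y=math.sqrt(err.var_au_y) / sd_y,
        gamma_x=math.sqrt(err.var_ac_x) / sd_x,
        gamma_y=math.sqrt(err.var_ac_y) / sd_y,
        delta_x=signal.mu_x / sd_x,
        delta_y=signal.mu_y / sd_y,
    )


def _variance_inflation(signal: TrueSignal, err: ErrorSpec, which: str) -> float:
    """f = var(measured) / var(signal) for one variable."""
    return theoretical_var(signal, err, which) / (signal.var_x if which == "x" else signal.var_y)


def attenuation_coeff(signal: TrueSignal, err: ErrorSpec) -> float:
    """Attenuation coefficient A in (0, 1]; 1 iff all error variances are 0."""
    if err.model_kind is ModelKind.NONE or not err.has_error:
        return 1.0
    fx = _variance_inflation(signal, err, "x")
    fy = _variance_inflation(signal, err, "y")
    return 1.0 / math.sqrt(fx * fy)


def expected_corr(signal: TrueSignal, err: ErrorSpec) -> ExpectedCorr:
    """Population correlation of the measured (x, y) pair."""
    ratios = error_ratios(signal, err)
    if err.model_kind is ModelKind.NONE or not err.has_error:
        return ExpectedCorr(
            rho=signal.rho0, attenuation=1.0, ratios=ratios, model_kind=err.model_kind
        )
    a = attenuation_coeff(signal, err)
    s_mc = err.pi_mc * math.sqrt(err.var_mc_x * err.var_mc_y)
    rho = a * (
        signal.rho0 * (1.0 + s_mc)
        + err.pi_ac * ratios.gamma_x * ratios.gamma_y
        + ratios.delta_x * ratios.delta_y * s_mc
    )
    return ExpectedCorr(rho=rho, attenuation=a, ratios=ratios, model_kind=err.model_kind)


def expected_corr_raw(signal: TrueSignal, err: ErrorSpec) -> float:
    """Same population correlation from raw moments (independent route).

    rho = [cov0 + pi_mc*s_mc_x*s_mc_y*(cov0 + mu_x*mu_y) + pi_ac*s_ac_x*s_ac_y]
          / sqrt(var(x) * var(y))
    """
    s_mc = err.pi_mc * math.sqrt(err.var_mc_x * err.var_mc_y)
    s_ac = err.pi_ac * math.sqrt(err.var_ac_x * err.var_ac_y)
    num = signal.cov + s_mc * (signal.cov + signal.mu_x * signal.mu_y) + s_ac
    den = math.sqrt(theoretical_var(signal, err, "x") * theoretical_var(signal, err, "y"))
    return num / den


def expected_corr_grid(
    mu_x, mu_y, var_x, var_y, rho0,
    var_au_x=0.0, var_au_y=0.0, var_ac=0.0,
    var_mu_x=0.0, var_mu_y=0.0, var_mc=0.0,
    pi: float = 1.0,
):
    """Vectorized expected correlation for shared-variance correlated error.

    All arguments broadcast; correlated components are shared between the
    two variables with error correlation sign ``pi``.  Used by the
    Monte-Carlo envelope experiment.
    """
    mu_x, mu_y, var_x, var_y, rho0 = map(np.asarray, (mu_x, mu_y, var_x, var_y, rho0))
    var_au_x, var_au_y, var_ac = map(np.asarray, (var_au_x, var_au_y, var_ac))
    var_mu_x, var_mu_y, var_mc = map(np.asarray, (var_mu_x, var_mu_y, var_mc))
    cov0 = rho0 * np.sqrt(var_x * var_y)
    num = cov0 + pi * var_mc * (cov0 + mu_x * mu_y) + pi * var_ac
    vx = var_x + (var_x + mu_x**2) * (var_mu_x + var_mc) + var_au_x + var_ac
    vy = var_y + (var_y + mu_y**2) * (var_mu_y + var_mc) + var_au_y + var_ac
    return num / np.sqrt(vx * vy)


def null_corr(signal: TrueSignal, err: ErrorSpec) -> float:
    """Expected correlation when the true correlation is zero."""
    return expected_corr(signal.with_rho0(0.0), err).rho


def _additive_surface(signal: TrueSignal, err: ErrorSpec) -> float | None:
    """Limiting rho0 value separating attenuation from inflation.

    Defined for additive-type error with a correlated component; the
    single expression pi_ac * A/(1-A) * gamma_x * gamma_y covers both
    error-correlation signs.
    """
    if err.has_multiplicative:
        return None
    if err.var_ac_x * err.var_ac_y == 0:
        return None
    a = attenuation_coeff(signal, err)
    if a >= 1.0 - REGIME_TOL:
        return None
    ratios = error_ratios(signal, err)
    return err.pi_ac * a / (1.0 - a) * ratios.gamma_x * ratios.gamma_y


def classify_regime(signal: TrueSignal, err: ErrorSpec) -> RegimeReport:
    """Classify the bias of rho vs rho0 by direct numeric comparison."""
    rho = expected_corr(signal, err).rho
    rho0 = signal.rho0
    surface = _additive_surface(signal, err)
    if abs(rho - rho0) <= REGIME_TOL:
        regime = Regime.UNBIASED
    elif abs(rho0) > REGIME_TOL and rho * rho0 < 0:
        regime = Regime.SIGN_FLIPPED
    elif abs(rho) < abs(rho0):
        regime = Regime.ATTENUATED
    else:
        regime = Regime.INFLATED
    return RegimeReport(regime=regime, surface_S=surface, rho=rho, rho0=rho0)


def limiting_surface(xi2: float, gamma2: float, sign: str = "pos") -> float:
    """Attenuation/inflation boundary rho0 for the symmetric additive case.

    For equal error ratios on both variables, rho is inflated
    (|rho| > moves away from rho0 towards the correlated-error term) when
    rho0 lies on one side of S = +/- gamma^2 / (xi^2 + gamma^2) and
    attenuated on the other.
    """
    if xi2 < 0 or gamma2 < 0:
        raise ValueError("error ratios must be non-negative")
    if xi2 == 0 and gamma2 == 0:
        raise ValueError("no measurement error: limiting surface undefined")
    s = gamma2 / (xi2 + gamma2)
    if sign in ("pos", "+", "positive"):
        return s
    if sign in ("neg", "-", "negative"):
        return -s
    raise ValueError(f"sign must be 'pos' or 'neg', got {sign!r}")
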