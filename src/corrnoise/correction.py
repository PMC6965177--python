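"""Disattenuation: invert the bias formulas to recover the true correlation.

Given an observed sample correlation r and known (externally supplied)
error-variance components, the corrected correlation is the exact
algebraic inverse of the expected-correlation formula:

    rho0 = r / (A * (1 + pi_mc * s_mc_x * s_mc_y))
           - (pi_ac * gamma_x * gamma_y + delta_x * delta_y * pi_mc * s_mc_x * s_mc_y)
             / (1 + pi_mc * s_mc_x * s_mc_y)

Corrected values exceeding +/-1 (possible through sampling error) are
clipped to +/-1 and flagged; the raw value is kept for diagnostics.
Estimating the error components from data is out of scope here, except
for the classical replicate-based plug-in for purely additive
uncorrelated error.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .analytic import attenuation_coeff, error_ratios
from .models import ErrorSpec, MultiTrueSignal, TrueSignal

__all__ = [
    "CorrectionResult",
    "ClipReport",
    "correct_corr",
    "correct_matrix",
    "estimate_additive_variance",
]


@dataclasses.dataclass(frozen=True)
class CorrectionResult:
    rho_corrected: float
    clipped: bool
    raw_value: float
    inputs_echo: dict

    def __post_init__(self) -> None:
        if abs(self.rho_corrected) > 1:
            raise ValueError("rho_corrected must be in [-1, 1]")
        if self.clipped != (abs(self.raw_value) > 1):
            raise ValueError("clipped flag inconsistent with raw value")


@dataclasses.dataclass
class ClipReport:
    """Count and location of clipping events in a matrix correction."""

    n_pairs: int
    events: list[tuple[int, int, float]] = dataclasses.field(default_factory=list)

    @property
    def n_clipped(self) -> int:
        return len(self.events)

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "n_clipped": self.n_clipped,
            "events": [
                {"i": i, "j": j, "raw_value": raw} for i, j, raw in self.events
            ],
        }


def correct_corr(r: float, signal: TrueSignal, err: ErrorSpec) -> CorrectionResult:
    """Invert the expected-correlation formula at observed correlation r.

    ``signal`` supplies the biological means and variances (its rho0 is
    ignored); ``err`` supplies the error-variance components.  Exact
    inverse of :func:`corrnoise.analytic.expected_corr`.
    """
    r = float(r)
    if abs(r) > 1:
        raise ValueError(f"|r| must be <= 1, got {r}")
    a = attenuation_coeff(signal, err)
    s_mc = err.pi_mc * math.sqrt(err.var_mc_x * err.var_mc_y)
    denom = 1.0 + s_mc
    if denom == 0:
        raise ValueError("pathological input: 1 + pi_mc*s_mc_x*s_mc_y = 0")
    scale = a * denom
    if scale == 0 or not math.isfinite(1.0 / scale):
        raise ValueError("attenuation coefficient is zero or undefined")
    ratios = error_ratios(signal, err)
    offset = err.pi_ac * ratios.gamma_x * ratios.gamma_y + ratios.delta_x * ratios.delta_y * s_mc
    raw = r / scale - offset / denom
    clipped = abs(raw) > 1
    value = math.copysign(1.0, raw) if clipped else raw
    return CorrectionResult(
        rho_corrected=value,
        clipped=clipped,
        raw_value=raw,
        inputs_echo={"r": r, "signal": signal.to_dict(), "err": err.to_dict()},
    )


def correct_matrix(
    R: np.ndarray,
    signal: MultiTrueSignal | tuple,
    err: ErrorSpec,
) -> tuple[np.ndarray, ClipReport]:
    """Element-wise correction of a p x p correlation matrix.

    ``signal`` is either a :class:`MultiTrueSignal` or a ``(mu, var)``
    pair of length-p arrays.  Each off-diagonal entry is corrected with
    its pair's means/variances and the shared error components; the
    output has unit diagonal and is symmetric.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if R.shape != (p, p):
        raise ValueError("R must be square")
    if not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("R must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise ValueError("R must have unit diagonal")
    if isinstance(signal, MultiTrueSignal):
        mu, var = signal.mu, signal.variances
    else:
        mu, var = (np.asarray(v, dtype=float) for v in signal)
    if mu.shape != (p,) or var.shape != (p,):
        raise ValueError(f"means/variances must have length {p}")

    out = np.eye(p)
    report = ClipReport(n_pairs=p * (p - 1) // 2)
    for i in range(p):
        for j in range(i + 1, p):
            pair = TrueSignal(
                mu_x=float(mu[i]), mu_y=float(mu[j]),
                var_x=float(var[i]), var_y=float(var[j]), rho0=0.0,
            )
            res = correct_corr(R[i, j], pair, err)
            out[i, j] = out[j, i] = res.rho_corrected
            if res.clipped:
                report.events.append((i, j, res.raw_value))
    return out, report


def estimate_additive_variance(replicates: np.ndarray) -> float:
    """Replicate-based plug-in estimate of additive uncorrelated error variance.

    ``replicates`` is an S x R matrix of R technical replicates for each
    of S samples; returns the pooled within-sample variance.  Valid only
    under the purely additive uncorrelated model, the one case the prior
    literature fully supports.
    """
    replicates = np.asarray(replicates, dtype=float)
    if replicates.ndim != 2 or replicates.shape[1] < 2:
        raise ValueError("need an S x R matrix with R >= 2 replicates")
    return float(replicates.var(axis=1, ddof=1).mean())
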