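"""True-signal and measurement-error model definitions and simulators.

The measured variables are modelled as corrupted versions of latent,
error-free signals.  The most general structural equation implemented is

    x = x0 * (1 + e_mu_x + e_mc_x) + e_au_x + e_ac_x
    y = y0 * (1 + e_mu_y + e_mc_y) + e_au_y + e_ac_y

with four kinds of zero-mean Gaussian error streams per variable:
additive uncorrelated (``au``), additive correlated (``ac``),
multiplicative uncorrelated (``mu``) and multiplicative correlated
(``mc``).  The correlated streams of x and y share a correlation
``pi_ac`` (resp. ``pi_mc``) in [-1, 1].  The classic additive,
multiplicative and combined ("realistic") models are reductions of this
generalized model with equal correlated variances and ``pi = +1`` or
``-1``.

All simulators are deterministic given ``(parameters, n, seed)``.  Each
error stream draws from its own RNG sub-stream spawned from the root
seed, so switching one component on or off does not perturb the draws of
the others.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from pathlib import Path
from typing import Union

import numpy as np

__all__ = [
    "ModelKind",
    "TrueSignal",
    "MultiTrueSignal",
    "ErrorSpec",
    "NoisySample",
    "simulate_bivariate",
    "simulate_multivariate",
    "sample_corr",
    "theoretical_var",
    "additive_spec_from_fractions",
]

SeedLike = Union[int, np.random.SeedSequence]


class ModelKind(str, enum.Enum):
    """Which structural error model a specification refers to."""

    NONE = "none"
    ADDITIVE = "additive"
    MULTIPLICATIVE = "multiplicative"
    REALISTIC = "realistic"
    GENERALIZED = "generalized"


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


@dataclasses.dataclass(frozen=True)
class TrueSignal:
    """Bivariate error-free signal law: means, variances and correlation."""

    mu_x: float
    mu_y: float
    var_x: float
    var_y: float
    rho0: float

    def __post_init__(self) -> None:
        for name in ("mu_x", "mu_y", "var_x", "var_y", "rho0"):
            object.__setattr__(self, name, _require_finite(name, getattr(self, name)))
        if self.var_x <= 0 or self.var_y <= 0:
            raise ValueError("biological variances must be strictly positive")
        if abs(self.rho0) > 1:
            raise ValueError(f"|rho0| must be <= 1, got {self.rho0}")

    @property
    def cov(self) -> float:
        """Implied covariance of the error-free pair."""
        return self.rho0 * math.sqrt(self.var_x * self.var_y)

    @property
    def sigma0(self) -> np.ndarray:
        return np.array([[self.var_x, self.cov], [self.cov, self.var_y]])

    def with_rho0(self, rho0: float) -> "TrueSignal":
        return dataclasses.replace(self, rho0=rho0)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class MultiTrueSignal:
    """p-variate error-free signal law (mean vector and SPD covariance)."""

    mu: np.ndarray
    sigma0: np.ndarray

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        sigma0 = np.asarray(self.sigma0, dtype=float)
        if mu.ndim != 1 or sigma0.shape != (mu.size, mu.size):
            raise ValueError("mu must be length p and sigma0 p x p")
        if not (np.isfinite(mu).all() and np.isfinite(sigma0).all()):
            raise ValueError("non-finite signal parameters")
        if not np.allclose(sigma0, sigma0.T, atol=1e-12, rtol=0.0):
            raise ValueError("sigma0 must be symmetric within 1e-12")
        eigmin = float(np.linalg.eigvalsh(sigma0).min())
        if eigmin <= 0:
            raise ValueError(f"sigma0 must be positive definite (min eig {eigmin:g})")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma0", 0.5 * (sigma0 + sigma0.T))

    @property
    def p(self) -> int:
        return self.mu.size

    @property
    def variances(self) -> np.ndarray:
        return np.diag(self.sigma0).copy()

    @property
    def corr(self) -> np.ndarray:
        sd = np.sqrt(self.variances)
        return self.sigma0 / np.outer(sd, sd)

    def pair_signal(self, i: int, j: int) -> TrueSignal:
        """Bivariate marginal law of variables (i, j)."""
        return TrueSignal(
            mu_x=float(self.mu[i]),
            mu_y=float(self.mu[j]),
            var_x=float(self.sigma0[i, i]),
            var_y=float(self.sigma0[j, j]),
            rho0=float(self.corr[i, j]),
        )

    def to_dict(self) -> dict:
        return {"mu": self.mu.tolist(), "sigma0": self.sigma0.tolist()}


_SPECIAL_KINDS = (ModelKind.ADDITIVE, ModelKind.MULTIPLICATIVE, ModelKind.REALISTIC)


@dataclasses.dataclass(frozen=True)
class ErrorSpec:
    """All error-variance components and error correlations for one model.

    Variances are absolute.  For the non-generalized kinds the correlated
    components must be shared (``var_ac_x == var_ac_y``,
    ``var_mc_x == var_mc_y``) and the error correlations restricted to
    +/-1, representing the sign of the perfectly correlated error term.
    """

    model_kind: ModelKind
    var_au_x: float = 0.0
    var_au_y: float = 0.0
    var_mu_x: float = 0.0
    var_mu_y: float = 0.0
    var_ac_x: float = 0.0
    var_ac_y: float = 0.0
    var_mc_x: float = 0.0
    var_mc_y: float = 0.0
    pi_ac: float = 1.0
    pi_mc: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "model_kind", ModelKind(self.model_kind))
        for name in (
            "var_au_x", "var_au_y", "var_mu_x", "var_mu_y",
            "var_ac_x", "var_ac_y", "var_mc_x", "var_mc_y",
        ):
            value = _require_finite(name, getattr(self, name))
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")
            object.__setattr__(self, name, value)
        for name in ("pi_ac", "pi_mc"):
            value = _require_finite(name, getattr(self, name))
            if abs(value) > 1:
                raise ValueError(f"|{name}| must be <= 1, got {value}")
            object.__setattr__(self, name, value)

        kind = self.model_kind
        addv = (self.var_au_x, self.var_au_y, self.var_ac_x, self.var_ac_y)
        mulv = (self.var_mu_x, self.var_mu_y, self.var_mc_x, self.var_mc_y)
        if kind is ModelKind.NONE and any(v != 0 for v in addv + mulv):
            raise ValueError("model_kind 'none' requires all error variances to be 0")
        if kind is ModelKind.ADDITIVE and any(v != 0 for v in mulv):
            raise ValueError("additive model requires all multiplicative variances to be 0")
        if kind is ModelKind.MULTIPLICATIVE and any(v != 0 for v in addv):
            raise ValueError("multiplicative model requires all additive variances to be 0")
        if kind in _SPECIAL_KINDS:
            if self.var_ac_x != self.var_ac_y or self.var_mc_x != self.var_mc_y:
                raise ValueError(
                    f"{kind.value} model requires shared correlated variances "
                    "(var_ac_x == var_ac_y, var_mc_x == var_mc_y)"
                )
            if self.pi_ac not in (-1.0, 1.0) or self.pi_mc not in (-1.0, 1.0):
                raise ValueError(f"{kind.value} model requires pi_ac, pi_mc in {{-1, +1}}")

    # ---- convenience constructors ------------------------------------

    @classmethod
    def none(cls) -> "ErrorSpec":
        return cls(model_kind=ModelKind.NONE)

    @classmethod
    def additive(
        cls,
        var_au_x: float = 0.0,
        var_au_y: float | None = None,
        var_ac: float = 0.0,
        sign: int = +1,
    ) -> "ErrorSpec":
        if var_au_y is None:
            var_au_y = var_au_x
        return cls(
            model_kind=ModelKind.ADDITIVE,
            var_au_x=var_au_x, var_au_y=var_au_y,
            var_ac_x=var_ac, var_ac_y=var_ac,
            pi_ac=float(np.sign(sign) or 1.0), pi_mc=float(np.sign(sign) or 1.0),
        )

    @classmethod
    def multiplicative(
        cls,
        var_mu_x: float = 0.0,
        var_mu_y: float | None = None,
        var_mc: float = 0.0,
        sign: int = +1,
    ) -> "ErrorSpec":
        if var_mu_y is None:
            var_mu_y = var_mu_x
        return cls(
            model_kind=ModelKind.MULTIPLICATIVE,
            var_mu_x=var_mu_x, var_mu_y=var_mu_y,
            var_mc_x=var_mc, var_mc_y=var_mc,
            pi_ac=float(np.sign(sign) or 1.0), pi_mc=float(np.sign(sign) or 1.0),
        )

    @classmethod
    def realistic(
        cls,
        var_au_x: float = 0.0,
        var_au_y: float | None = None,
        var_ac: float = 0.0,
        var_mu_x: float = 0.0,
        var_mu_y: float | None = None,
        var_mc: float = 0.0,
        sign: int = +1,
    ) -> "ErrorSpec":
        if var_au_y is None:
            var_au_y = var_au_x
        if var_mu_y is None:
            var_mu_y = var_mu_x
        s = float(np.sign(sign) or 1.0)
        return cls(
            model_kind=ModelKind.REALISTIC,
            var_au_x=var_au_x, var_au_y=var_au_y,
            var_mu_x=var_mu_x, var_mu_y=var_mu_y,
            var_ac_x=var_ac, var_ac_y=var_ac,
            var_mc_x=var_mc, var_mc_y=var_mc,
            pi_ac=s, pi_mc=s,
        )

    @classmethod
    def generalized(cls, **kwargs) -> "ErrorSpec":
        return cls(model_kind=ModelKind.GENERALIZED, **kwargs)

    # ---- helpers -----------------------------------------------------

    @property
    def has_error(self) -> bool:
        return any(
            getattr(self, f) != 0
            for f in ("var_au_x", "var_au_y", "var_mu_x", "var_mu_y",
                      "var_ac_x", "var_ac_y", "var_mc_x", "var_mc_y")
        )

    @property
    def has_multiplicative(self) -> bool:
        return any(v != 0 for v in (self.var_mu_x, self.var_mu_y, self.var_mc_x, self.var_mc_y))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["model_kind"] = self.model_kind.value
        return d


def additive_spec_from_fractions(
    signal: TrueSignal,
    frac_au_x: float,
    frac_au_y: float | None = None,
    frac_ac: float = 0.0,
    sign: int = +1,
) -> ErrorSpec:
    """Additive ErrorSpec with variances given as fractions of biological variance.

    ``frac_au_*`` scale the per-variable biological variances; ``frac_ac``
    scales the average of the two biological variances (the correlated
    component is shared between x and y).
    """
    if frac_au_y is None:
        frac_au_y = frac_au_x
    return ErrorSpec.additive(
        var_au_x=frac_au_x * signal.var_x,
        var_au_y=frac_au_y * signal.var_y,
        var_ac=frac_ac * 0.5 * (signal.var_x + signal.var_y),
        sign=sign,
    )


@dataclasses.dataclass(frozen=True)
class NoisySample:
    """A simulated N x p measured-data matrix with its full provenance."""

    data: np.ndarray
    seed: SeedLike
    signal: TrueSignal | MultiTrueSignal
    err: ErrorSpec

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
            raise ValueError("data must be an N x p matrix with N >= 2, p >= 2")
        if not np.isfinite(data).all():
            raise ValueError("data contains non-finite entries")
        object.__setattr__(self, "data", data)

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def p(self) -> int:
        return self.data.shape[1]

    def write_csv(self, path: str | Path) -> Path:
        """Write the sample as headed CSV plus a JSON sidecar for exact replay."""
        path = Path(path)
        header = ",".join(
            ["x", "y"] if self.p == 2 else [f"x{j}" for j in range(1, self.p + 1)]
        )
        np.savetxt(path, self.data, delimiter=",", header=header, comments="", fmt="%.17g")
        sidecar = path.with_suffix(".json")
        seed = self.seed
        meta = {
            "signal": self.signal.to_dict(),
            "error": self.err.to_dict(),
            "n": self.n,
            "seed": int(seed.entropy) if isinstance(seed, np.random.SeedSequence) else int(seed),
        }
        sidecar.write_text(json.dumps(meta, indent=2) + "\n")
        return path


# ---------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------

_BIVARIATE_STREAMS = ("signal", "au_x", "au_y", "mu_x", "mu_y", "ac", "mc")
_MULTIVARIATE_STREAMS = ("signal", "au", "mu", "ac", "mc")


def _spawn_rngs(seed: SeedLike, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(int(seed))
    return {name: np.random.default_rng(child) for name, child in zip(names, root.spawn(len(names)))}


def _correlated_pair(
    rng: np.random.Generator, n: int, sd_x: float, sd_y: float, pi: float
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n correlated zero-mean Gaussian pairs with correlation pi.

    Always consumes 2n deviates so that the stream layout does not depend
    on which components are switched on.
    """
    z = rng.standard_normal((n, 2))
    e_x = sd_x * z[:, 0]
    e_y = sd_y * (pi * z[:, 0] + math.sqrt(max(0.0, 1.0 - pi * pi)) * z[:, 1])
    return e_x, e_y


def _check_n(n: int) -> int:
    n = int(n)
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    return n


def simulate_bivariate(
    signal: TrueSignal,
    err: ErrorSpec,
    n: int,
    seed: SeedLike,
    return_components: bool = False,
) -> NoisySample | tuple[NoisySample, dict[str, np.ndarray]]:
    """Draw n independent measured (x, y) pairs under the given error model.

    With ``return_components=True`` also returns the latent signal and
    every injected error stream (instrumentation for independence checks).
    """
    n = _check_n(n)
    rngs = _spawn_rngs(seed, _BIVARIATE_STREAMS)

    z = rngs["signal"].standard_normal((n, 2))
    sd_x, sd_y = math.sqrt(signal.var_x), math.sqrt(signal.var_y)
    rho = signal.rho0
    x0 = signal.mu_x + sd_x * z[:, 0]
    y0 = signal.mu_y + sd_y * (rho * z[:, 0] + math.sqrt(max(0.0, 1.0 - rho * rho)) * z[:, 1])

    e_au_x = math.sqrt(err.var_au_x) * rngs["au_x"].standard_normal(n)
    e_au_y = math.sqrt(err.var_au_y) * rngs["au_y"].standard_normal(n)
    e_mu_x = math.sqrt(err.var_mu_x) * rngs["mu_x"].standard_normal(n)
    e_mu_y = math.sqrt(err.var_mu_y) * rngs["mu_y"].standard_normal(n)
    e_ac_x, e_ac_y = _correlated_pair(
        rngs["ac"], n, math.sqrt(err.var_ac_x), math.sqrt(err.var_ac_y), err.pi_ac
    )
    e_mc_x, e_mc_y = _correlated_pair(
        rngs["mc"], n, math.sqrt(err.var_mc_x), math.sqrt(err.var_mc_y), err.pi_mc
    )

    x = x0 * (1.0 + e_mu_x + e_mc_x) + e_au_x + e_ac_x
    y = y0 * (1.0 + e_mu_y + e_mc_y) + e_au_y + e_ac_y
    sample = NoisySample(data=np.column_stack([x, y]), seed=seed, signal=signal, err=err)
    if not return_components:
        return sample
    components = {
        "x0": x0, "y0": y0,
        "e_au_x": e_au_x, "e_au_y": e_au_y,
        "e_mu_x": e_mu_x, "e_mu_y": e_mu_y,
        "e_ac_x": e_ac_x, "e_ac_y": e_ac_y,
        "e_mc_x": e_mc_x, "e_mc_y": e_mc_y,
    }
    return sample, components


def _as_length_p(value, p: int, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        arr = np.full(p, float(arr[0]))
    if arr.shape != (p,):
        raise ValueError(f"{name} must be scalar or length {p}, got shape {arr.shape}")
    if (arr < 0).any() or not np.isfinite(arr).all():
        raise ValueError(f"{name} entries must be finite and non-negative")
    return arr


def simulate_multivariate(
    signal: MultiTrueSignal,
    err: ErrorSpec,
    n: int,
    seed: SeedLike,
    var_au=None,
    var_mu=None,
) -> NoisySample:
    """Draw n measured p-vectors; correlated error terms are shared scalars.

    Each draw uses one scalar additive-correlated and one scalar
    multiplicative-correlated deviate common to all p variables
    (positively correlated error); the uncorrelated terms are drawn
    independently per variable.  ``var_au`` / ``var_mu`` optionally give
    per-variable uncorrelated variances (scalar or length-p vectors);
    they default to the spec's x-components, which must then equal the
    y-components.
    """
    n = _check_n(n)
    if err.model_kind is ModelKind.GENERALIZED:
        raise ValueError("multivariate simulation requires a non-generalized error model")
    if err.has_error and (err.pi_ac != 1.0 or err.pi_mc != 1.0):
        raise ValueError("multivariate simulation supports only positively correlated error")
    p = signal.p
    if var_au is None:
        if err.var_au_x != err.var_au_y:
            raise ValueError("var_au_x != var_au_y: pass an explicit var_au vector")
        var_au = err.var_au_x
    if var_mu is None:
        if err.var_mu_x != err.var_mu_y:
            raise ValueError("var_mu_x != var_mu_y: pass an explicit var_mu vector")
        var_mu = err.var_mu_x
    var_au = _as_length_p(var_au, p, "var_au")
    var_mu = _as_length_p(var_mu, p, "var_mu")

    rngs = _spawn_rngs(seed, _MULTIVARIATE_STREAMS)
    chol = np.linalg.cholesky(signal.sigma0)
    x0 = signal.mu + rngs["signal"].standard_normal((n, p)) @ chol.T

    e_au = rngs["au"].standard_normal((n, p)) * np.sqrt(var_au)
    e_mu = rngs["mu"].standard_normal((n, p)) * np.sqrt(var_mu)
    e_ac = math.sqrt(err.var_ac_x) * rngs["ac"].standard_normal(n)
    e_mc = math.sqrt(err.var_mc_x) * rngs["mc"].standard_normal(n)

    data = x0 * (1.0 + e_mu + e_mc[:, None]) + e_au + e_ac[:, None]
    return NoisySample(data=data, seed=seed, signal=signal, err=err)


# ---------------------------------------------------------------------
# Moments and estimators
# ---------------------------------------------------------------------

def sample_corr(data: np.ndarray) -> float:
    """Product-moment (Pearson) correlation of the two columns of data."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError("data must be an N x 2 matrix")
    if data.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    if not np.isfinite(data).all():
        raise ValueError("data contains non-finite entries")
    sd = data.std(axis=0)
    if (sd == 0).any():
        raise ValueError("undefined correlation: a column has zero variance")
    return float(np.corrcoef(data[:, 0], data[:, 1])[0, 1])


def theoretical_var(signal: TrueSignal, err: ErrorSpec, which: str = "x") -> float:
    """Model-implied variance of the measured variable x or y.

    var = s0^2 + (s0^2 + mu0^2)(var_mu + var_mc) + var_au + var_ac,
    which covers every model kind (absent components are zero).
    """
    if which == "x":
        mu, var0 = signal.mu_x, signal.var_x
        v_mu, v_mc, v_au, v_ac = err.var_mu_x, err.var_mc_x, err.var_au_x, err.var_ac_x
    elif which == "y":
        mu, var0 = signal.mu_y, signal.var_y
        v_mu, v_mc, v_au, v_ac = err.var_mu_y, err.var_mc_y, err.var_au_y, err.var_ac_y
    else:
        raise ValueError("which must be 'x' or 'y'")
    return var0 + (var0 + mu * mu) * (v_mu + v_mc) + v_au + v_ac
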