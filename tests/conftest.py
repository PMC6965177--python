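"""Shared fixtures and random parameter-set generators."""

from __future__ import annotations

import numpy as np
import pytest

from corrnoise import ErrorSpec, ModelKind, TrueSignal

MODEL_KINDS = ["none", "additive", "multiplicative", "realistic", "generalized"]


def random_signal(rng: np.random.Generator, mu_max: float = 3.0) -> TrueSignal:
    return TrueSignal(
        mu_x=rng.uniform(-mu_max, mu_max),
        mu_y=rng.uniform(-mu_max, mu_max),
        var_x=rng.uniform(0.5, 2.0),
        var_y=rng.uniform(0.5, 2.0),
        rho0=rng.uniform(-0.9, 0.9),
    )


def random_error(rng: np.random.Generator, kind: str, scale: float = 0.3) -> ErrorSpec:
    """Random ErrorSpec of the given kind with moderate error magnitudes.

    Additive variances are drawn up to ``scale``; multiplicative
    (relative) variances up to ``scale / 2`` to keep the measured
    distribution well-behaved.
    """
    kind = ModelKind(kind)
    sign = int(rng.choice([-1, 1]))
    add = lambda: float(rng.uniform(0.0, scale))          # noqa: E731
    mul = lambda: float(rng.uniform(0.0, scale / 2.0))    # noqa: E731
    if kind is ModelKind.NONE:
        return ErrorSpec.none()
    if kind is ModelKind.ADDITIVE:
        return ErrorSpec.additive(add(), add(), var_ac=add(), sign=sign)
    if kind is ModelKind.MULTIPLICATIVE:
        return ErrorSpec.multiplicative(mul(), mul(), var_mc=mul(), sign=sign)
    if kind is ModelKind.REALISTIC:
        return ErrorSpec.realistic(
            var_au_x=add(), var_au_y=add(), var_ac=add(),
            var_mu_x=mul(), var_mu_y=mul(), var_mc=mul(), sign=sign,
        )
    return ErrorSpec.generalized(
        var_au_x=add(), var_au_y=add(),
        var_mu_x=mul(), var_mu_y=mul(),
        var_ac_x=add(), var_ac_y=add(),
        var_mc_x=mul(), var_mc_y=mul(),
        pi_ac=float(rng.uniform(-1, 1)),
        pi_mc=float(rng.uniform(-1, 1)),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def unit_signal() -> TrueSignal:
    """The classic unit-variance configuration with rho0 = 0.8."""
    return TrueSignal(mu_x=100.0, mu_y=100.0, var_x=1.0, var_y=1.0, rho0=0.8)
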