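"""Numerical reference for the continuous colony-size transport model.

In the continuous formulation, a primary tumour of size ``G(t)`` (Gompertz,
grown from one cell) seeds metastatic colonies at the rate

    beta(x) = gamma * x**alpha,

and every colony itself grows by the same Gompertz law from one cell.  The
expected number of first-order colonies of at least ``x_min`` cells at time
``t`` is then the renewal integral

    N1(t, x_min) = int_0^{t - a(x_min)} gamma * G(tau)**alpha dtau,

with ``a(x)`` the Gompertz time from one cell to ``x`` (a colony seeded at
``tau`` has reached ``x_min`` by ``t`` iff ``t - tau >= a(x_min)``).  Second
order colonies follow from a second convolution with the same kernel.  This
module evaluates those integrals by adaptive quadrature and serves as the
calibration target and independent oracle for the generation engines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .growth import GompertzParams, gompertz_size, gompertz_time_to_size

__all__ = ["IksParams", "iks_colony_count"]


@dataclass(frozen=True)
class IksParams:
    """Colonization coefficient gamma (1/day/cells^alpha) and fractal exponent."""

    gamma: float
    alpha: float

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")


def _g_alpha(tau, iks: IksParams, p: GompertzParams):
    return np.power(p.b, iks.alpha * (1.0 - np.exp(-p.mu * tau)))


def iks_colony_count(
    t: float,
    x_min: float,
    iks: IksParams,
    p: GompertzParams,
    order: int = 1,
    rtol: float = 1e-9,
) -> float:
    """Expected colonies of order 1 or 2 with >= ``x_min`` cells at time ``t``."""
    if t < 0:
        raise ValueError("t must be non-negative")
    if not 1.0 <= x_min < p.b:
        raise ValueError("x_min must satisfy 1 <= x_min < b")
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    a = 0.0 if x_min <= 1.0 else gompertz_time_to_size(x_min, p)
    t_seed = t - a  # latest seeding time that still reaches x_min by t
    if t_seed <= 0:
        return 0.0
    if order == 1:
        val, _ = integrate.quad(
            lambda tau: iks.gamma * _g_alpha(tau, iks, p),
            0.0,
            t_seed,
            epsrel=rtol,
            limit=200,
        )
        return float(val)

    # order 2: colonies seeded at rate r2(s) = int_0^s beta(G(u)) beta(G(s-u)) du
    def r2(s: float) -> float:
        if s <= 0:
            return 0.0
        inner, _ = integrate.quad(
            lambda u: _g_alpha(u, iks, p) * _g_alpha(s - u, iks, p),
            0.0,
            s,
            epsrel=max(rtol, 1e-8),
            limit=200,
        )
        return iks.gamma**2 * inner

    val, _ = integrate.quad(r2, 0.0, t_seed, epsrel=max(rtol, 1e-7), limit=200)
    return float(val)
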