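"""Shared fixtures and independent Monte Carlo oracles.

The oracles deliberately re-derive everything they check from first
principles (explicit per-cell event simulation, direct series summation,
ODE integration) instead of calling the library's own machinery.
"""

from __future__ import annotations

import numpy as np
import pytest

from metasim.cascade import CirculationParams
from metasim.growth import (
    GenerationConfig,
    GompertzParams,
    generation_time,
    initial_doubling_time,
)

HEPATO = GompertzParams(b=7.3e10, mu=0.00286)


@pytest.fixture(scope="session")
def hepato_params() -> GompertzParams:
    return HEPATO


@pytest.fixture(scope="session")
def hepato_T_G0() -> float:
    return generation_time(initial_doubling_time(HEPATO), 2.0 / 3.0)


@pytest.fixture(scope="session")
def hepato_circ() -> CirculationParams:
    return CirculationParams(T_env=1.0, c_frac=1e-4)


# ---------------------------------------------------------------------------
# Event-driven Monte Carlo oracle for the cascade (small GDR instance)
# ---------------------------------------------------------------------------


def gdr_sizes(d_i: float, epsilon: float, n_gen: int) -> np.ndarray:
    """Deterministic GDR population sizes x_0..x_{n_gen-1}, from first principles."""
    x = np.empty(n_gen)
    x[0] = 1.0
    for n in range(1, n_gen):
        excess = (2.0 * d_i - 1.0) * (1.0 - epsilon) ** (n - 1)
        x[n] = x[n - 1] * (1.0 + excess)
    return x


def event_mc_cascade(
    cfg: GenerationConfig,
    circ: CirculationParams,
    horizon: float,
    n_rep: int,
    seed: int,
    max_order: int = 2,
):
    """Per-cell event simulation of a GDR cascade; returns per-order counts
    (n_rep x max_order) of colonizations occurring by ``horizon``.

    Every disseminated cell is drawn individually: Poisson number per
    generation (expected m * x^alpha), uniform entry time within the step,
    exponential circulation lifetime, Bernoulli colonization at elimination.
    Colonies grow deterministically by the same generation law, restarted at
    one cell, and disseminate the same way (expected values per their own
    generations, drawn Poisson).
    """
    assert cfg.engine == "GDR"
    rng = np.random.default_rng(seed)
    n_gen = int(np.ceil(horizon / cfg.T_G0))
    x = gdr_sizes(cfg.d_i, cfg.epsilon, n_gen)
    counts = np.zeros((n_rep, max_order), dtype=float)
    for rep in range(n_rep):
        # (time, order) of colonization events yet to spawn offspring
        frontier = _mc_disseminate_and_settle(
            rng, cfg, circ, x, 0.0, horizon
        )
        counts[rep, 0] = len(frontier)
        for order in range(2, max_order + 1):
            new_frontier = []
            for s in frontier:
                n_gen_col = int(np.ceil((horizon - s) / cfg.T_G0))
                if n_gen_col <= 0:
                    continue
                z = gdr_sizes(cfg.d_i, cfg.epsilon, n_gen_col)
                new_frontier.extend(
                    _mc_disseminate_and_settle(rng, cfg, circ, z, s, horizon)
                )
            counts[rep, order - 1] = len(new_frontier)
            frontier = new_frontier
    return counts


def _mc_disseminate_and_settle(rng, cfg, circ, sizes, t0, horizon):
    """Colonization times of cells shed by one tumour whose generation n spans
    [t0 + n T_G0, t0 + (n+1) T_G0) with ``sizes[n]`` cells at step start."""
    out = []
    for n, xn in enumerate(sizes):
        start = t0 + n * cfg.T_G0
        if start >= horizon:
            break
        k = rng.poisson(cfg.m * xn**cfg.alpha_d)
        if k == 0:
            continue
        entry = start + rng.random(k) * cfg.T_G0
        death = entry + rng.exponential(circ.T_env, size=k)
        colonized = rng.random(k) < circ.c_frac
        ok = colonized & (death <= horizon)
        out.extend(death[ok])
    return out
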