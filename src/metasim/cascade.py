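"""Circulation survival, colonization and expected-value colony bookkeeping.

Disseminated cells survive in the circulation for an exponentially distributed
time with mean ``T_env`` (the combined decay of immune kill and colonization,
rate ``lambda_env = 1/T_env``).  Of the cells leaving the circulation, only the
fraction ``c_frac = lambda_c / lambda_env`` colonizes a distant organ; each
colonizing cell founds a colony of one cell that then grows by the same
generation engine as the primary (or by an inherited, reduced variant).

Everything here is expected-value arithmetic: intensities are expected numbers
of colonizing cells per time bin, registries hold fractional colony cohorts.
Integer, per-patient randomness lives in :mod:`metasim.courses`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .growth import (
    GenerationConfig,
    GompertzParams,
    Trajectory,
    gdr_doubling_fractions,
    gdr_trajectory,
    ms_trajectory,
)

__all__ = [
    "CirculationParams",
    "CirculationStepResult",
    "ColonizationIntensity",
    "GrowthVariant",
    "ColonyRegistry",
    "circulation_step",
    "first_order_intensity",
    "build_colony_registry",
    "higher_order_intensity",
    "full_cascade",
    "colonies_above",
    "metastatic_mass",
    "mass_parity_time",
]

_POOL_CUTOFF = 1e-12  # stop tracking the circulating pool below this fraction


@dataclass(frozen=True)
class CirculationParams:
    """Mean circulation lifetime ``T_env`` (days) and colonization fraction."""

    T_env: float = 1.0
    c_frac: float = 1e-4

    def __post_init__(self) -> None:
        if not self.T_env > 0:
            raise ValueError(f"T_env must be positive, got {self.T_env}")
        if not 0.0 <= self.c_frac <= 1.0:
            raise ValueError(f"c_frac must lie in [0, 1], got {self.c_frac}")

    @property
    def lam(self) -> float:
        return 1.0 / self.T_env


@dataclass(frozen=True)
class CirculationStepResult:
    surviving_pool: float
    surviving_new: float
    colonizers: float
    mean_colonization_time: float  # days since step start; nan if no colonizers


def _pool_mass(pool: float, lam: float, t1, t2):
    """Deaths in (t1, t2] of an existing pool decaying at rate lam."""
    return pool * (np.exp(-lam * t1) - np.exp(-lam * t2))


def _pool_moment(pool: float, lam: float, t1, t2):
    """First moment of death times in (t1, t2] of an existing pool."""
    return pool * (
        (t1 + 1.0 / lam) * np.exp(-lam * t1) - (t2 + 1.0 / lam) * np.exp(-lam * t2)
    )


def _influx_mass(influx: float, lam: float, T: float, t1, t2):
    """Deaths in (t1, t2] of cells entering uniformly over a step of length T.

    Death-time density: f(tau) = (1 - exp(-lam tau)) / T on [0, T].
    """
    return influx * ((t2 - t1) / T - (np.exp(-lam * t1) - np.exp(-lam * t2)) / (lam * T))


def _influx_moment(influx: float, lam: float, T: float, t1, t2):
    g1 = (t1 / lam + 1.0 / lam**2) * np.exp(-lam * t1)
    g2 = (t2 / lam + 1.0 / lam**2) * np.exp(-lam * t2)
    return influx * ((t2**2 - t1**2) / 2.0 - (g1 - g2)) / T


def circulation_step(
    pool: float, influx: float, circ: CirculationParams, T: float
) -> CirculationStepResult:
    """Resolve one generation step of the circulating compartment.

    The old pool decays by ``F = exp(-T/T_env)``; the ``influx`` cells enter
    uniformly over the step and may already be eliminated within it.  Of all
    eliminated cells the fraction ``c_frac`` colonizes; the mean colonization
    time (relative to the step start) combines the truncated-exponential
    distribution of the old pool and the uniform(x)exponential convolution of
    the new arrivals.
    """
    if pool < 0 or influx < 0:
        raise ValueError("pool and influx must be non-negative")
    if not T > 0:
        raise ValueError("step length T must be positive")
    lam = circ.lam
    F = float(np.exp(-lam * T))
    surviving_pool = pool * F
    eliminated_old = pool - surviving_pool
    A = (1.0 - F) / lam  # integral of exp(-lam tau) over the step
    surviving_new = influx * A / T
    eliminated_new = influx - surviving_new
    eliminated = eliminated_old + eliminated_new
    colonizers = circ.c_frac * eliminated
    if eliminated > 0:
        moment = _pool_moment(pool, lam, 0.0, T) + _influx_moment(influx, lam, T, 0.0, T)
        mean_t = float(moment / eliminated)
    else:
        mean_t = float("nan")
    return CirculationStepResult(surviving_pool, surviving_new, colonizers, mean_t)


@dataclass
class ColonizationIntensity:
    """Expected colonizing cells per uniform time bin for one metastatic order.

    Bin ``j`` covers ``[j*dt, (j+1)*dt)`` days since tumour initiation;
    ``lambda_j[j]`` is the expected number of cells colonizing in that bin and
    ``mean_t_j[j]`` their mean colonization time (absolute days).
    """

    order: int
    dt: float
    lambda_j: np.ndarray
    mean_t_j: np.ndarray
    total_disseminated: float
    circ: CirculationParams
    residual_pool: float = 0.0

    @property
    def edges(self) -> np.ndarray:
        return np.arange(len(self.lambda_j) + 1) * self.dt

    @property
    def t_end(self) -> float:
        return len(self.lambda_j) * self.dt

    def total(self) -> float:
        return float(self.lambda_j.sum())

    def cumulative(self, t):
        """Expected colonizers up to time ``t`` (linear within a bin)."""
        t = np.asarray(t, dtype=float)
        cum = np.concatenate(([0.0], np.cumsum(self.lambda_j)))
        out = np.interp(t, self.edges, cum)
        return out if out.ndim else float(out)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t_bin_start_days": self.edges[:-1],
                "order": self.order,
                "expected_colonizers": self.lambda_j,
                "mean_colonization_time_days": self.mean_t_j,
            }
        )


class _Accumulator:
    """Bins colonizer mass and first moments onto a uniform grid."""

    def __init__(self, dt: float, n_bins_hint: int):
        self.dt = dt
        self.mass = np.zeros(max(n_bins_hint, 1))
        self.moment = np.zeros(max(n_bins_hint, 1))

    def _grow(self, n: int) -> None:
        if n > len(self.mass):
            extra = max(n - len(self.mass), len(self.mass) // 2 + 1)
            self.mass = np.append(self.mass, np.zeros(extra))
            self.moment = np.append(self.moment, np.zeros(extra))

    def deposit(self, t0: float, T: float, pool: float, influx: float, lam: float) -> None:
        """Deposit the deaths occurring during step [t0, t0+T)."""
        j0 = int(np.floor(t0 / self.dt))
        j1 = int(np.ceil((t0 + T) / self.dt))
        self._grow(j1)
        # local step coordinates of the bin boundaries clipped to the step
        bounds = np.clip(np.arange(j0, j1 + 1) * self.dt, t0, t0 + T) - t0
        t1, t2 = bounds[:-1], bounds[1:]
        m = _pool_mass(pool, lam, t1, t2) + _influx_mass(influx, lam, T, t1, t2)
        mo = _pool_moment(pool, lam, t1, t2) + _influx_moment(influx, lam, T, t1, t2)
        self.mass[j0:j1] += m
        self.moment[j0:j1] += mo + t0 * m  # shift moments to absolute time

    def finish(self, order, circ, total_diss, residual_pool) -> ColonizationIntensity:
        mass = self.mass * circ.c_frac
        moment = self.moment * circ.c_frac
        centers = (np.arange(len(mass)) + 0.5) * self.dt
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_t = np.where(mass > 0, moment / np.maximum(mass, 1e-300), centers)
        return ColonizationIntensity(
            order=order,
            dt=self.dt,
            lambda_j=mass,
            mean_t_j=mean_t,
            total_disseminated=total_diss,
            circ=circ,
            residual_pool=residual_pool,
        )


def first_order_intensity(
    traj: Trajectory,
    circ: CirculationParams,
    grid_dt: float = 1.0,
    excision_time: float | None = None,
) -> ColonizationIntensity:
    """Chain the circulating compartment across a primary trajectory.

    Each generation step feeds ``disseminated_n`` cells uniformly into the
    circulation; colonizers are binned onto a uniform reporting grid of
    spacing ``grid_dt``.  With ``excision_time`` set, dissemination stops at
    that instant (the step containing it contributes pro rata) while the
    residual circulating pool still resolves.
    """
    if grid_dt <= 0:
        raise ValueError("grid_dt must be positive")
    lam = circ.lam
    horizon = max(traj.t_end, traj.horizon)
    acc = _Accumulator(grid_dt, int(np.ceil(horizon / grid_dt)) + 1)
    pool = 0.0
    total_influx = 0.0
    for t0, T, diss in zip(traj.t_start, traj.T_G, traj.disseminated):
        segments = [(t0, T, diss)]
        if excision_time is not None:
            if t0 >= excision_time:
                segments = [(t0, T, 0.0)]
            elif t0 + T > excision_time:
                frac = (excision_time - t0) / T
                segments = [
                    (t0, excision_time - t0, diss * frac),
                    (excision_time, t0 + T - excision_time, 0.0),
                ]
        for s0, sT, sin in segments:
            acc.deposit(s0, sT, pool, sin, lam)
            F = np.exp(-lam * sT)
            pool = pool * F + sin * (1.0 - F) / (lam * sT)
            total_influx += sin
    # let the residual pool resolve after the last generation step
    t_tail = traj.t_end
    cutoff = _POOL_CUTOFF * max(total_influx, 1.0)
    while pool > cutoff:
        acc.deposit(t_tail, grid_dt, pool, 0.0, lam)
        pool *= np.exp(-lam * grid_dt)
        t_tail += grid_dt
    return acc.finish(1, circ, total_influx, pool)


# ---------------------------------------------------------------------------
# Colony registries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrowthVariant:
    """How a metastatic colony grows once founded.

    ``primary_like``: restarted at one cell with the primary's own engine and
    parameters.  ``gdr_inherited_d``: GDR colony starting with the (already
    decayed) doubling fraction of the generation in which its founder cell was
    disseminated — a reduced maximal colony size.  ``ms_inherited_TG``: MS
    colony starting with the prolonged generation time of that generation —
    same maximal size, proportionally slower growth (dormancy).
    """

    kind: str = "primary_like"

    def __post_init__(self) -> None:
        if self.kind not in ("primary_like", "gdr_inherited_d", "ms_inherited_TG"):
            raise ValueError(f"unknown growth variant {self.kind!r}")


class ColonyRegistry:
    """Expected colony cohorts of one metastatic order.

    Cohort ``i`` holds ``counts[i]`` expected colonies seeded at ``seed_t[i]``
    days (the mean colonization time of its grid bin), growing from one cell
    under the configured variant.  ``seed_gen[i]`` is the primary generation
    active at seeding, used by the inherited variants.
    """

    def __init__(
        self,
        intensity: ColonizationIntensity,
        variant: GrowthVariant,
        p: GompertzParams,
        cfg: GenerationConfig,
        traj: Trajectory | None = None,
        min_count: float = 0.0,
    ):
        self.intensity = intensity
        self.variant = variant
        self.params = p
        self.config = cfg
        self.order = intensity.order
        mask = intensity.lambda_j > min_count
        self.seed_t = intensity.mean_t_j[mask]
        self.counts = intensity.lambda_j[mask]
        self.seed_bin = np.nonzero(mask)[0]
        horizon = max(intensity.t_end, traj.t_end if traj is not None else 0.0)
        self._horizon = horizon
        if variant.kind != "primary_like":
            if traj is None:
                traj = _rebuild_primary(p, cfg, horizon)
            self.seed_gen = np.asarray(traj.generation_at(self.seed_t))
        else:
            self.seed_gen = np.zeros(len(self.seed_t), dtype=int)
        self._primary = traj
        self._init_size_model()

    # -- size model --------------------------------------------------------------

    def _init_size_model(self) -> None:
        p, cfg = self.params, self.config
        horizon = self._horizon
        if self.variant.kind in ("primary_like", "ms_inherited_TG"):
            base = _rebuild_primary(p, cfg, horizon)
            t_kn = np.append(base.t_start, base.t_end)
            logx_kn = np.append(np.log(base.x), base._log_x_end[-1])
            self._base_t, self._base_logx = t_kn, logx_kn
            cum = np.concatenate(([0.0], np.cumsum(base.disseminated)))
            self._base_cumdiss_t = t_kn
            self._base_cumdiss = cum
            if self.variant.kind == "ms_inherited_TG":
                if cfg.engine != "MS":
                    raise ValueError("ms_inherited_TG requires an MS engine")
                x_seed = self._primary.x[self.seed_gen]
                self._stretch = np.log(p.b) / (np.log(p.b) - np.log(x_seed))
            else:
                self._stretch = np.ones(len(self.seed_t))
        else:  # gdr_inherited_d
            if cfg.engine != "GDR":
                raise ValueError("gdr_inherited_d requires a GDR engine")
            n_extra = int(np.ceil(horizon / cfg.T_G0)) + 2
            k_max = int(self.seed_gen.max()) if len(self.seed_gen) else 0
            d_seq = gdr_doubling_fractions(cfg, k_max + n_extra)
            self._L = np.concatenate(([0.0], np.cumsum(np.log(2.0 * d_seq))))
            self._stretch = np.ones(len(self.seed_t))

    def _log_sizes(self, ages: np.ndarray) -> np.ndarray:
        """ln colony size per cohort at the given ages (same length arrays)."""
        cfg = self.config
        if self.variant.kind in ("primary_like", "ms_inherited_TG"):
            eff = ages / self._stretch
            return np.interp(eff, self._base_t, self._base_logx)
        gen = self.seed_gen + ages / cfg.T_G0
        idx = np.arange(len(self._L), dtype=float)
        return np.interp(gen, idx, self._L) - self._L[self.seed_gen]

    def sizes_at(self, t: float) -> np.ndarray:
        """Cells per cohort colony at absolute time ``t`` (0 before seeding)."""
        ages = np.maximum(t - self.seed_t, 0.0)
        sizes = np.exp(self._log_sizes(ages))
        return np.where(t >= self.seed_t, sizes, 0.0)

    def mass(self, t) -> np.ndarray | float:
        """Total metastatic cells of this order at time(s) ``t``."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty(len(t_arr))
        for i, ti in enumerate(t_arr):
            out[i] = float(np.sum(self.counts * self.sizes_at(ti)))
        return out if np.ndim(t) else float(out[0])

    def visible_count(self, t: float, threshold: float) -> float:
        """Expected number of colonies with at least ``threshold`` cells at ``t``.

        A cohort whose seeding deadline (t minus the colony's crossing age)
        falls inside its grid bin is counted fractionally, so the count varies
        smoothly with t and is stable under grid refinement.
        """
        if threshold < 1:
            raise ValueError("threshold must be at least one cell")
        if len(self.seed_t) == 0:
            return 0.0
        cross_t = self.threshold_crossing_times(threshold)
        deadline = t - (cross_t - self.seed_t)
        edge_lo = self.seed_bin * self.intensity.dt
        with np.errstate(invalid="ignore"):
            w = np.clip((deadline - edge_lo) / self.intensity.dt, 0.0, 1.0)
        w = np.where(np.isfinite(deadline), w, 0.0)
        return float(np.sum(self.counts * w))

    def cumulative_dissemination(self, edges: np.ndarray) -> np.ndarray:
        """Total cells disseminated by this order's colonies, at grid ``edges``."""
        cfg = self.config
        out = np.zeros(len(edges))
        if self.variant.kind in ("primary_like", "ms_inherited_TG"):
            # a time-stretched colony sheds proportionally more per (longer)
            # generation: dissemination is a per-day leak (see GenerationConfig)
            for s, c, stretch in zip(self.seed_t, self.counts, self._stretch):
                ages = np.maximum(edges - s, 0.0) / stretch
                out += (
                    c
                    * stretch
                    * np.interp(ages, self._base_cumdiss_t, self._base_cumdiss)
                )
        else:
            for s, c, k in zip(self.seed_t, self.counts, self.seed_gen):
                n_gen = int(np.ceil(max(edges[-1] - s, 0.0) / cfg.T_G0)) + 1
                lsz = self._L[k : k + n_gen] - self._L[k]
                diss = cfg.m * np.exp(cfg.alpha_d * lsz)
                cum = np.concatenate(([0.0], np.cumsum(diss)))
                t_kn = s + np.arange(n_gen + 1) * cfg.T_G0
                out += c * np.interp(edges, t_kn, cum)
        return out

    def threshold_crossing_times(self, threshold: float) -> np.ndarray:
        """Absolute time each cohort's colony reaches ``threshold`` cells (inf if never)."""
        target = np.log(threshold)
        if self.variant.kind in ("primary_like", "ms_inherited_TG"):
            logx = self._base_logx
            if target > logx[-1]:
                age = np.full(len(self.seed_t), np.inf)
            else:
                base_age = float(np.interp(target, logx, self._base_t))
                age = base_age * self._stretch
        else:
            age = np.empty(len(self.seed_t))
            idx = np.arange(len(self._L), dtype=float)
            for i, k in enumerate(self.seed_gen):
                tail = self._L - self._L[k]
                if target > tail[-1]:
                    age[i] = np.inf
                else:
                    gen_cross = float(np.interp(target + self._L[k], self._L, idx))
                    age[i] = (gen_cross - k) * self.config.T_G0
        return self.seed_t + age

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "seed_time_days": self.seed_t,
                "order": self.order,
                "expected_colonies": self.counts,
                "seed_generation": self.seed_gen,
                "growth_variant": self.variant.kind,
            }
        )


def _rebuild_primary(p: GompertzParams, cfg: GenerationConfig, horizon: float) -> Trajectory:
    builder = ms_trajectory if cfg.engine == "MS" else gdr_trajectory
    return builder(p, cfg, horizon)


def build_colony_registry(
    intensity: ColonizationIntensity,
    variant: GrowthVariant,
    p: GompertzParams,
    cfg: GenerationConfig,
    traj: Trajectory | None = None,
) -> ColonyRegistry:
    """Turn a colonization intensity into expected colony cohorts."""
    return ColonyRegistry(intensity, variant, p, cfg, traj=traj)


def higher_order_intensity(
    registry: ColonyRegistry,
    circ: CirculationParams,
    cfg: GenerationConfig,
    max_order: int = 3,
) -> list[ColonizationIntensity]:
    """Recursive metastasis-from-metastasis intensities up to ``max_order``.

    Colonies of order ``k`` disseminate ``m * size**alpha_d`` per generation;
    that influx is pushed through the circulating compartment on the uniform
    reporting grid, yielding the order ``k+1`` intensity, and so on.
    """
    if max_order < 1:
        raise ValueError("max_order must be at least 1")
    out: list[ColonizationIntensity] = []
    reg = registry
    for order in range(registry.order + 1, max_order + 1):
        intensity = _intensity_from_registry(reg, circ)
        out.append(intensity)
        if order < max_order:
            reg = ColonyRegistry(
                intensity, reg.variant, reg.params, reg.config, traj=reg._primary
            )
    return out


def _intensity_from_registry(
    reg: ColonyRegistry, circ: CirculationParams
) -> ColonizationIntensity:
    dt = reg.intensity.dt
    edges = reg.intensity.edges
    cum_diss = reg.cumulative_dissemination(edges)
    influx = np.diff(cum_diss)
    lam = circ.lam
    acc = _Accumulator(dt, len(influx))
    pool = 0.0
    F = float(np.exp(-lam * dt))
    gain = (1.0 - F) / (lam * dt)
    for j, inj in enumerate(influx):
        if pool > 0 or inj > 0:
            acc.deposit(j * dt, dt, pool, inj, lam)
        pool = pool * F + inj * gain
    return acc.finish(reg.order + 1, circ, float(cum_diss[-1]), pool)


def full_cascade(
    traj: Trajectory,
    circ: CirculationParams,
    variant: GrowthVariant = GrowthVariant(),
    grid_dt: float = 1.0,
    max_order: int = 1,
    excision_time: float | None = None,
) -> tuple[list[ColonizationIntensity], list[ColonyRegistry]]:
    """Convenience: first-order intensity plus registries up to ``max_order``."""
    intensity = first_order_intensity(traj, circ, grid_dt, excision_time)
    registry = build_colony_registry(intensity, variant, traj.params, traj.config, traj)
    intensities = [intensity]
    registries = [registry]
    reg = registry
    for order in range(2, max_order + 1):
        intensity = _intensity_from_registry(reg, circ)
        intensities.append(intensity)
        reg = ColonyRegistry(intensity, variant, traj.params, traj.config, traj=traj)
        registries.append(reg)
    return intensities, registries


# ---------------------------------------------------------------------------
# Registry queries
# ---------------------------------------------------------------------------


def _as_registry_list(registries) -> list[ColonyRegistry]:
    return [registries] if isinstance(registries, ColonyRegistry) else list(registries)


def colonies_above(registries, threshold: float, t: float) -> float:
    """Expected number of colonies of at least ``threshold`` cells at time ``t``."""
    return float(
        sum(reg.visible_count(t, threshold) for reg in _as_registry_list(registries))
    )


def metastatic_mass(registries, t):
    """Total metastatic cells over all supplied registries at time(s) ``t``."""
    regs = _as_registry_list(registries)
    total = regs[0].mass(t)
    for reg in regs[1:]:
        total = total + reg.mass(t)
    return total


def mass_parity_time(registry, traj: Trajectory, grid_dt: float = 1.0) -> float | None:
    """First time the metastatic cell mass reaches the primary's size.

    Scans the reporting grid and refines the crossing by bisection; returns
    ``None`` if parity is never reached within the registry horizon.
    """
    regs = _as_registry_list(registry)
    t_end = max(max(r.intensity.t_end for r in regs), traj.t_end)
    t_grid = np.arange(0.0, t_end, grid_dt)
    mass = metastatic_mass(regs, t_grid)
    primary = traj.size_at(t_grid)
    above = mass >= primary
    if not above.any():
        return None
    j = int(np.argmax(above))
    if j == 0:
        return float(t_grid[0])
    lo, hi = t_grid[j - 1], t_grid[j]
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if metastatic_mass(regs, mid) >= traj.size_at(mid):
            hi = mid
        else:
            lo = mid
        if hi - lo < 1e-6:
            break
    return float(hi)
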