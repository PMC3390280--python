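"""Randomized integer courses of disease and first-metastasis statistics.

The expected-value cascade yields an intensity: expected colonizing cells per
time bin.  A patient's course of disease is a realization with integer events;
bins receive independent Poisson counts (each bin aggregates many independent,
individually tiny per-cell colonization probabilities).  From an ensemble of
such courses one obtains the probability that metastasis formation occurs at
all and the distribution of the time of the first colonizing cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .cascade import ColonizationIntensity, ColonyRegistry, colonies_above

__all__ = [
    "DAYS_PER_MONTH",
    "DAYS_PER_YEAR",
    "CourseEnsemble",
    "FirstMetFit",
    "sample_courses",
    "formation_probability",
    "first_colonization_stats",
    "first_met_scan",
]

DAYS_PER_MONTH = 30.4375
DAYS_PER_YEAR = 365.25


@dataclass
class CourseEnsemble:
    """Ensemble of randomized disease courses drawn from one intensity.

    ``first_times[i]`` is the time (days) of course *i*'s first colonizing
    cell, NaN if the course never colonizes within the horizon.  ``totals``
    are integer colonizer counts per course; the full per-bin count matrix is
    kept only when requested at sampling time.
    """

    n_courses: int
    first_times: np.ndarray
    totals: np.ndarray
    seed: int
    dt: float
    counts: np.ndarray | None = None

    @property
    def event_fraction(self) -> float:
        return float(np.mean(~np.isnan(self.first_times)))

    def event_times(self) -> np.ndarray:
        return self.first_times[~np.isnan(self.first_times)]


def sample_courses(
    intensity: ColonizationIntensity,
    n: int,
    seed: int,
    rate_scale: float = 1.0,
    keep_counts: bool = False,
) -> CourseEnsemble:
    """Draw ``n`` independent integer courses from a colonization intensity.

    Per course and per bin the number of colonizing cells is Poisson with mean
    ``rate_scale * lambda_j``; the first colonization time is the earliest bin
    with a positive draw, jittered uniformly within the bin.
    """
    if n < 1:
        raise ValueError("need at least one course")
    if rate_scale < 0:
        raise ValueError("rate_scale must be non-negative")
    rng = np.random.default_rng(seed)
    lam = intensity.lambda_j * rate_scale
    nz = np.nonzero(lam)[0]
    first = np.full(n, np.nan)
    totals = np.zeros(n, dtype=np.int64)
    counts_full = np.zeros((n, len(lam)), dtype=np.int64) if keep_counts else None
    if len(nz):
        chunk = max(1, int(5e7) // max(len(nz), 1))
        for lo in range(0, n, chunk):
            hi = min(lo + chunk, n)
            draws = rng.poisson(lam[nz], size=(hi - lo, len(nz)))
            totals[lo:hi] = draws.sum(axis=1)
            any_event = totals[lo:hi] > 0
            if any_event.any():
                first_idx = np.argmax(draws > 0, axis=1)
                rows = np.nonzero(any_event)[0]
                bins = nz[first_idx[rows]]
                jitter = rng.random(len(rows))
                first[lo + rows] = (bins + jitter) * intensity.dt
            if keep_counts:
                counts_full[lo:hi, nz] = draws
    return CourseEnsemble(
        n_courses=n,
        first_times=first,
        totals=totals,
        seed=seed,
        dt=intensity.dt,
        counts=counts_full,
    )


def formation_probability(
    source,
    t_eval: float,
    visibility_threshold: float | None = None,
    rate_scale: float = 1.0,
) -> float:
    """Probability that at least one (visible) metastasis exists at ``t_eval``.

    With a :class:`ColonyRegistry` source and a threshold, the expected number
    of colonies at or above the visibility threshold at ``t_eval`` is Lambda,
    and the probability of at least one is ``1 - exp(-Lambda)`` (Poisson
    counts).  With a plain intensity (or ``visibility_threshold=None``) every
    colonizing cell counts, whatever its colony size.
    """
    if isinstance(source, ColonizationIntensity):
        if visibility_threshold is not None:
            raise ValueError("a visibility threshold requires a ColonyRegistry")
        lam = source.cumulative(t_eval)
    elif isinstance(source, (ColonyRegistry, list, tuple)):
        if visibility_threshold is None:
            regs = source if isinstance(source, (list, tuple)) else [source]
            lam = sum(r.intensity.cumulative(t_eval) for r in regs)
        else:
            lam = colonies_above(source, visibility_threshold, t_eval)
    else:
        raise TypeError(f"unsupported source {type(source)!r}")
    return float(-np.expm1(-rate_scale * lam))


def first_colonization_stats(
    ensemble: CourseEnsemble, hist_bins: int = 40
) -> dict:
    """Mean (months) and relative FWHM of the first-colonization time.

    The mean is over courses that colonize at all; the full width at half
    maximum is read off a histogram of those event times and reported as a
    fraction of the mean.
    """
    times = ensemble.event_times()
    if len(times) == 0:
        raise ValueError("no course produced a colonization event")
    mean_days = float(np.mean(times))
    hist, edges = np.histogram(times, bins=hist_bins)
    half = hist.max() / 2.0
    above = np.nonzero(hist >= half)[0]
    fwhm_days = float(edges[above[-1] + 1] - edges[above[0]])
    return {
        "mean_months": mean_days / DAYS_PER_MONTH,
        "mean_days": mean_days,
        "fwhm_fraction": fwhm_days / mean_days,
        "n_events": int(len(times)),
        "histogram": hist,
        "bin_edges_days": edges,
    }


# ---------------------------------------------------------------------------
# First-metastasis-time scan over the maximal tumour size
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FirstMetFit:
    """Fit of mean first-metastasis time vs maximal size b.

    f(b) = -(fm_scale / mu_ref) * ln(1 - ln(fm_beta) / ln(b)), in days; the
    same functional shape as the initial-doubling-time formula.
    """

    fm_scale: float
    fm_beta: float
    mu_ref: float

    def __call__(self, b):
        b = np.asarray(b, dtype=float)
        return -(self.fm_scale / self.mu_ref) * np.log(
            1.0 - np.log(self.fm_beta) / np.log(b)
        )


def first_met_scan(
    b_grid,
    engine: str = "MS",
    T_D_ref: float = 10.0,
    b_ref: float = 1e11,
    d_i: float = 2.0 / 3.0,
    m: float = 2.554e-6,
    alpha_d: float = 1.0,
    circ=None,
    horizon: float = 25.0 * DAYS_PER_YEAR,
    n_courses: int = 2000,
    seed: int = 0,
    grid_dt: float = 1.0,
):
    """Mean first-colonization time and formation probability versus ``b``.

    The growth constant mu is fixed by requiring the initial doubling time at
    the reference size ``b_ref`` to equal ``T_D_ref`` (so the actual T_D
    varies slightly with b).  For each b the trajectory and first-order
    intensity are rebuilt, ``n_courses`` integer courses are sampled over a
    ~25 year follow-up, and the mean time of the first colonizing cell is
    recorded.  The decreasing branch is fitted with the doubling-time-like
    law of :class:`FirstMetFit`.

    Returns a ``(pandas.DataFrame, FirstMetFit | None)`` pair.
    """
    import pandas as pd

    from .cascade import CirculationParams, first_order_intensity
    from .growth import (
        GenerationConfig,
        GompertzParams,
        fit_gdr_decrement,
        gdr_trajectory,
        generation_time,
        initial_doubling_time,
        ms_trajectory,
    )

    if circ is None:
        circ = CirculationParams()
    mu_ref = -float(np.log(1.0 - np.log(2.0) / np.log(b_ref))) / T_D_ref
    rows = []
    rng_seeds = np.random.SeedSequence(seed).spawn(len(list(b_grid)))
    for b, ss in zip(b_grid, rng_seeds):
        p = GompertzParams(b=float(b), mu=mu_ref)
        T_D = initial_doubling_time(p)
        T_G0 = generation_time(T_D, d_i)
        if engine == "MS":
            cfg = GenerationConfig(engine="MS", T_G0=T_G0, d_i=d_i, m=m, alpha_d=alpha_d)
            traj = ms_trajectory(p, cfg, horizon)
        else:
            eps = fit_gdr_decrement(p, d_i=d_i)
            cfg = GenerationConfig(
                engine="GDR", T_G0=T_G0, d_i=d_i, m=m, alpha_d=alpha_d, epsilon=eps
            )
            traj = gdr_trajectory(p, cfg, horizon)
        intensity = first_order_intensity(traj, circ, grid_dt=grid_dt)
        sub_seed = int(ss.generate_state(1)[0] % (2**31 - 1))
        ens = sample_courses(intensity, n_courses, seed=sub_seed)
        times = ens.event_times()
        rows.append(
            {
                "b": float(b),
                "mu": mu_ref,
                "T_D_days": T_D,
                "mean_T1stM_months": (
                    float(np.mean(times)) / DAYS_PER_MONTH if len(times) else np.nan
                ),
                "P_formation": ens.event_fraction,
                "n_courses": n_courses,
                "seed": sub_seed,
            }
        )
    df = pd.DataFrame(rows)
    fit = _fit_first_met_curve(df, mu_ref)
    return df, fit


def _fit_first_met_curve(df, mu_ref: float) -> FirstMetFit | None:
    """Fit f(b) to the monotone-decreasing tail of the scan."""
    ok = df.dropna(subset=["mean_T1stM_months"])
    if len(ok) < 4:
        return None
    b = ok["b"].to_numpy()
    y_days = ok["mean_T1stM_months"].to_numpy() * DAYS_PER_MONTH
    # longest strictly-decreasing suffix
    start = len(y_days) - 1
    while start > 0 and y_days[start - 1] > y_days[start]:
        start -= 1
    b_fit, y_fit = b[start:], y_days[start:]
    if len(b_fit) < 4:
        return None

    def model(b, scale, log_beta):
        return -(scale / mu_ref) * np.log(1.0 - log_beta / np.log(b))

    log_b_min = np.log(b_fit.min())
    try:
        popt, _ = optimize.curve_fit(
            model,
            b_fit,
            y_fit,
            p0=(1.0, 0.5 * log_b_min),
            bounds=([1e-6, 1e-6], [np.inf, 0.999 * log_b_min]),
            maxfev=20000,
        )
    except RuntimeError:
        return None
    return FirstMetFit(
        fm_scale=float(popt[0]), fm_beta=float(np.exp(popt[1])), mu_ref=mu_ref
    )
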