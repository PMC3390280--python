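# Methods

## Model

A primary tumour starts from a single malignant cell at t = 0 and develops in
discrete generations. In a generation, each of the x cells present resolves
into one of three fates — doubling (fraction d), apoptosis (a) or
dissemination into the circulation (m) — with a + d + m = 1, so a generation
multiplies the population by 2d. The target growth law is Gompertzian,

    dx/dt = mu * x * ln(b/x),   G(t) = b^(1 - exp(-mu * t)),

with maximal size b (cells) and growth constant mu (1/day). The initial
doubling time follows as T_D = -(1/mu) ln(1 - ln2/ln b) and the base
generation time as T_G0 = T_D ln(2d)/ln 2 (a population multiplying by 2d
every T_G0 grows exactly as fast as one doubling every T_D).

Two engines realize the saturating law:

* **MS (metabolic stagnation).** Fate fractions stay constant; the
  generation time stretches as T_G(x) = T_G0 * ln(b)/ln(b/x). Because every
  step still multiplies the population by 2d, the engine stops stepping when
  the next doubling would exceed b and the size is clamped there; the
  diverging step length makes the regime near b effectively stationary.
* **GDR (generation-dependent rates).** The generation time stays T_G0 while
  the doubling excess decays geometrically, 2 d_n - 1 = (2 d_i - 1)(1-eps)^n,
  the loss absorbed by apoptosis (a_n = 1 - d_n - m_n). The asymptotic
  log-size is the series sum_n ln(1 + (2 d_i - 1)(1-eps)^n), evaluated
  through the geometrically convergent alternating form
  sum_k (-1)^(k+1) e0^k / (k (1-(1-eps)^k)); `fit_gdr_decrement` root-finds
  eps so the asymptote equals b (Brent, xtol 1e-14). For b = 7.3e10 and
  d_i = 2/3 this gives eps = 1.235 % per generation.

**Dissemination convention.** Dissemination is treated as a constant per-day
leak normalised to the base step: a generation of length T_G_n sheds
m * x^alpha_d * (T_G_n / T_G0) cells, with x the step-start size and
alpha_d in {1, 2/3, 1/3} selecting volume-, surface- or diameter-
proportional spread. For the GDR engine (constant T_G) this coincides with a
plain per-generation fraction; for the MS engine the stretched late
generations shed proportionally more. This convention reproduces the
published hepatocellular calibration of the MS engine to 2 % (see
Calibration below), where a strict per-generation fraction is a factor ~6
off; it is applied uniformly to primaries and metastatic colonies.

**Circulation and colonization.** Disseminated cells die or colonize after an
exponential lifetime with mean T_env (default 1 day); the fraction
c_frac = lambda_c/lambda_env (default 1e-4) of the cells leaving the
circulation founds a colony of one cell. Within a generation step of length
T, cells already in the pool are eliminated with density ~ exp(-t/T_env)
(survival factor F = exp(-T/T_env)), while the step's own influx enters
uniformly over the step, giving the uniform(x)exponential convolution: the
surviving fraction of new arrivals is (T_env/T)(1-F) and the elimination-time
density is (1 - exp(-t/T_env))/T. Colonizer mass and first moments are
deposited analytically, bin by bin, onto a uniform 1-day reporting grid (the
grid makes MS cascades with variable step lengths and GDR cascades
comparable); after the last generation the residual pool drains until it
falls below 1e-12 of everything disseminated. Halving the grid spacing
changes visible-colony counts by well under 1 % (tested); expected visible
counts use fractional (sub-bin) counting of the cohort whose seeding deadline
falls inside a bin, which is what makes that stability possible.

**Colony growth variants.** Each colonization founds a cohort at its bin's
mean colonization time. `primary_like` colonies rerun the engine from one
cell (the primary's own curve). The slowed variants inherit the state of the
generation in which the founder cell left the primary: `ms_inherited_TG`
starts with that generation's prolonged T_G — the whole colony clock is
stretched by ln(b)/ln(b/x_seed), same asymptote b, much later visibility
(dormancy); `gdr_inherited_d` starts from the already decayed doubling
fraction d_k and keeps decaying, so the colony saturates below b and may
never reach visibility. Colony sizes are interpolated log-linearly between
generation knots.

**Higher orders.** Order-k colonies disseminate by the same rule; their
summed influx per grid bin is pushed through the circulation recursion to
give the order-(k+1) intensity (expected, fractional colonies), by default up
to third order. For the calibrated hepatocellular case the second order is
negligible at the calibration day (~6e-4 visible colonies at day 1110) and
overtakes the first order only in the very late, 100-fold-mass regime.

**Randomized courses.** A patient course draws an independent Poisson count
per grid bin (each bin aggregates many tiny per-cell colonization
probabilities); the first colonization time is the first positive bin,
jittered uniformly inside it. The probability of at least one (visible)
metastasis is 1 - exp(-Lambda) with Lambda the expected (visible) colony
count — verified against ensembles within binomial error. Months are
30.4375 days, years 365.25 days.

## Reference model and calibration

The continuous benchmark seeds colonies at rate beta(x) = gamma * x^alpha
(gamma = 5.3e-8/day, alpha = 0.663) from a Gompertz primary, each colony
growing by the same Gompertz law. Expected counts above a size threshold are
renewal integrals, N1(t, x_min) = integral of gamma G(tau)^alpha over
tau < t - a(x_min) with a(x) the one-cell-to-x Gompertz time; the second
order adds one convolution. Both are evaluated by adaptive quadrature
(relative tolerance 1e-9 / 1e-7) and cross-checked in the tests against
direct Poisson-process simulation. The closed-form residue series of the
original transport model is deliberately not used: the quadrature computes
identical observables and is far easier to verify.

Calibration of the dissemination coefficient m matches the expected number
of visible (>= 4.6e7 cells) first-order colonies at day 1110 (432 days after
the day-678 diagnosis) to N1: counts are exactly linear in m, so one probe
run solves it. Results: m = 2.54e-6 for MS (dissemination ~ volume) and
m = 1.66e-3 for GDR (~ surface). The fitted-Gompertz growth constant
recovered from the MS curve is 0.00291/day (time-uniform log-size fit; the
generation-knot fit gives 0.00282/day — the difference is pure fit
weighting, and both are exposed).

Known residual: with the calibrated GDR configuration the model's total
first-order count at day 1110 (threshold one cell) is ~92 % of the
reference first-order total; the corresponding published comparison is ~70 %.
The gap traces one-to-one to the visible-count-per-m ratio (our calibrated m
is 1.42x the published one); no documented growth/colony convention removes
it, so the number is reported as computed.

## Breast-registry workflow

Cell counts come from spherical volumes: N = (pi/6) D^3 * 1e9 / v_cell with
D in mm and v_cell in um^3 (4.57 mm at 1000 um^3 is the 5e7-cell visibility
threshold; halving the metastatic cell volume raises it to 1e8). For a given
b, mu solves t(N_pT2) - t(N_pT1) = 1.1 years in closed form. Stage times are
read off the generation engine's own clock (the engine that also seeds the
metastases); they differ from the Gompertz closed form by well under 1 %.
The pT4 evaluation uses the 60 mm size, not the pT4 mean age. Normalization
multiplies the combined rate by -ln(1 - 0.011)/Lambda_vis(t_pT1), per
maximal size b (each b gets its own scale); table values average three b
values spanning [7.5e11, 1.25e12] cells geometrically, with 2000 courses per
b for the time statistics. Course sampling runs to the pT4-size time — the
clinical window of the table; first-colonization means for the slowest
(diameter-proportional) configurations are therefore mildly truncated.

Mean times of the first colonizing cell are reported from tumour initiation.
The first-colonization time distributions have FWHM/mean of ~0.2 (volume
dissemination) to ~0.45 (diameter); the published account quotes ~0.7 for
all configurations, which we could not reproduce under any documented
convention — the statistic is exposed but not asserted. Jointly scaling both
cell volumes shifts normalized probabilities by up to ~20 % relative (the
mu refit reacts to the changed log-count ratios); the pT1 normalization
absorbs what would otherwise be an orders-of-magnitude shift.

## Problem sizes and determinism

The hepatocellular cascades run 2200 simulated days (86 MS generations, 540
GDR generations, 1-day grid); breast scenarios run to 1.6x the pT4-size time
(~260 generations at b = 1e12); the first-metastasis scan follows each b for
25 years and samples 2000 courses per point. The expected-value pipeline is
fully deterministic; all sampling flows from explicit integer seeds
(`numpy.random.default_rng`, seeds spawned per grid point), and repeated runs
of a scenario are byte-identical.

## Limitations

No spatial structure, vasculature or immune dynamics beyond the single
circulation lifetime; primary growth is deterministic expected-value (no
birth-death noise in the primary itself); excision is modelled as a
dissemination cutoff only (existing colonies keep growing); no treatment
effects beyond excision; survival outcomes are out of scope.
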