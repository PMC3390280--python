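"""Breast-registry application: visible-metastasis probabilities by stage.

For a maximal size of 1e12 cells, fits the Gompertz timing from the stage
summaries (14 mm pT1 at mean age 57 y, 28 mm pT2 at 58.1 y), normalizes the
combined dissemination*colonization rate to the registry's 1.1 % visible
metastases at pT1, and evaluates the probability of a visible metastasis at
the pT2 time and at the 60 mm (pT4) size, plus the time of the first
colonizing cell from 2000 randomized courses.
"""

from metasim import BreastConfig, breast_row, fit_breast_gompertz
from metasim.courses import DAYS_PER_MONTH

cfg = BreastConfig()  # 1000-um^3 cells, visibility at 4.57 mm (~5e7 cells)
fit = fit_breast_gompertz(cfg, b=1e12)
print(f"fitted growth constant mu = {fit['mu']:.3g}/day for b = 1e12 cells")
print(f"pT1 reached {fit['t_pT1'] / DAYS_PER_MONTH:.1f} months after initiation (closed form)")

for alpha_d, label in ((1.0, "V"), (2 / 3, "V^2/3"), (1 / 3, "V^1/3")):
    for variant, vlabel in (("P", "primary-like"), ("A", "inherited/slowed")):
        row = breast_row(cfg, 1e12, "MS", alpha_d, variant, n_courses=2000, seed=1)
        print(
            f"MS, dissemination ~ {label:6s}, metastases {vlabel:16s}: "
            f"P(visible at pT2) = {100 * row['P_pT2']:5.1f} %, "
            f"P(visible at pT4 size) = {100 * row['P_pT4']:5.1f} %, "
            f"1st colonization at {row['mean_t1st_months']:.1f} months"
        )

# The first colonizing cell typically precedes the pT1 detection time (~50
# months) by years: metastasis formation starts long before the primary is
# clinically visible.
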