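"""Mean time of first metastasis versus the maximal tumour size b.

For each b, the growth constant is fixed by requiring a 10-day initial
doubling time at the reference size 1e11 cells; 2000 randomized courses give
the mean time of the first colonizing cell and the probability that
metastasis formation happens at all within ~25 years.
"""

from metasim import first_met_scan

b_grid = [1e5, 1e6, 1e7, 1e8, 1e9, 1e10, 1e11, 1e12, 1e13]
df, fit = first_met_scan(b_grid, engine="MS", T_D_ref=10.0, n_courses=2000, seed=1)

print(df[["b", "T_D_days", "mean_T1stM_months", "P_formation"]].to_string(index=False))
if fit is not None:
    print(
        f"\ndecreasing branch fitted by f(b) = -(gamma/mu) ln(1 - ln(beta)/ln(b)): "
        f"gamma = {fit.fm_scale:.3g}, beta = {fit.fm_beta:.3g}"
    )

# Below ~1e8 cells the mean first-metastasis time is flat (it tracks the
# bending of the growth curve, not b); formation probability reaches 1 around
# b = 1e9 cells; above that, larger tumours seed their first metastasis sooner.
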