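"""The hepatocellular training case: calibration, cascade, parity, excision.

Calibrates the dissemination coefficient m of the MS engine so that the
expected number of visible (>= 4.6e7-cell) first-order colonies at day 1110
(432 days after the day-678 diagnosis) matches the continuous colony-size
reference, then queries the expected-value cascade.
"""

from metasim import (
    GrowthVariant,
    build_colony_registry,
    calibrate_m_to_iks,
    first_order_intensity,
    full_cascade,
    hepatocellular_config,
    mass_parity_time,
    metastatic_mass,
    ms_trajectory,
)
from metasim.calibration import HEPATO_CIRCULATION, HEPATO_GOMPERTZ

cal = calibrate_m_to_iks("MS")
print(f"calibrated m = {cal['m']:.3g}  (target: {cal['target']:.2f} visible colonies)")

cfg = hepatocellular_config("MS", m=cal["m"])
traj = ms_trajectory(HEPATO_GOMPERTZ, cfg, horizon=2200.0)
intensities, registries = full_cascade(
    traj, HEPATO_CIRCULATION, GrowthVariant("primary_like"), max_order=2
)
reg1 = registries[0]

vis = reg1.visible_count(1110.0, 4.6e7)
print(f"visible 1st-order colonies at day 1110: {vis:.2f} (reference {cal['target']:.2f})")
print(f"2nd-order visible colonies at day 1110: {registries[1].visible_count(1110.0, 4.6e7):.2e}")

parity = mass_parity_time(reg1, traj)
print(f"metastatic mass equals the primary on day {parity:.0f} since initiation")
mass_2030 = metastatic_mass(reg1, 2030.0)
print(f"on day 2030 the 1st-order metastatic mass is {mass_2030 / traj.size_at(2030.0):.0f}x the primary")

# excision at diagnosis: dissemination stops, existing colonies keep growing
cut = first_order_intensity(traj, HEPATO_CIRCULATION, excision_time=678.0)
reg_cut = build_colony_registry(cut, GrowthVariant(), HEPATO_GOMPERTZ, cfg, traj)
drop = metastatic_mass(reg1, 2100.0) / metastatic_mass(reg_cut, 2100.0)
print(f"excision at diagnosis reduces late 1st-order metastatic mass {drop:.0f}-fold")
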