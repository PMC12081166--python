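"""Simulate pulsed-saturation Z-spectra and show their pH sensitivity.

Builds a white-matter-like tissue (water + amide + MT + NOE pools) and
runs the 3-T protocol schedule (B1 = 1 uT, 250 ms pulses, 49 offsets).
The amide exchange rate follows the base-catalyzed law
k(pH) = 30 /s * 10^(pH-7), so the +3.5 ppm label effect and the
APT-weighted MTR_asym grow with intracellular pH.
"""

import numpy as np

from deepcestph import (TissueParams, default_pools, mtr_asym, normalize,
                        protocol_3t_schedule, simulate_zspectrum)

schedule = protocol_3t_schedule()
offsets = np.asarray(schedule.offsets)
print(f"schedule: {offsets.size} offsets, B1 = {schedule.B1} uT, "
      f"tp = td = {schedule.tp*1e3:.0f} ms, {schedule.n_startup_pulses} startup pulses")

base = TissueParams(water_R1=1 / 1.1, water_R2=1 / 0.07,
                    pools=default_pools(), pH=7.0)
for ph in (6.9, 7.0, 7.1, 7.2, 7.3):
    z = simulate_zspectrum(base.with_ph(ph), schedule)
    zvol = normalize(z[None, None, None, :], np.ones((1, 1, 1)),
                     offsets=offsets)
    asym = mtr_asym(zvol, 3.5).values[0, 0, 0]
    i35 = np.argmin(np.abs(offsets - 3.5))
    print(f"pH {ph:.1f}:  Z(+3.5 ppm) = {z[i35]:.4f}   "
          f"label effect 1-Z = {1 - z[i35]:.4f}   MTR_asym(3.5) = {asym:+.4f}")

print("\nThe label effect rises monotonically with pH (faster amide exchange);")
print("MTR_asym is slightly negative overall because the NOE and semi-solid MT")
print("pools depress the negative side of the spectrum - the realistic 3-T baseline.")
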