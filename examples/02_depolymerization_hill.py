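"""Microtubule depolymerization rates and a Hill concentration-response fit.

Ground-truth per-end shrinkage rates follow a Hill curve over motor
concentration; each concentration is simulated as a set of shrinking-
microtubule kymographs (30 frames/min), ends are traced and slope-fitted,
and the measured rates are refitted with the same baseline-offset Hill
model. Printed parameters should match the generating curve.
"""

import numpy as np

from kymoxl import fit_hill, hill_curve
from kymoxl.pipelines import measure_depoly_rate

V0, VMAX, K, H = 0.0, 0.95, 30.0, 1.5  # um/min, nM
concentrations = np.array([5.0, 15.0, 40.0, 62.5, 125.0, 250.0])

measured = []
for i, conc in enumerate(concentrations):
    true_rate = hill_curve(conc, V0, VMAX, K, H)
    est = measure_depoly_rate(float(true_rate), frame_interval=2.0,
                              n_kymographs=8, duration=600.0, seed=100 + i)
    measured.append(est)
    print(f"{conc:6.1f} nM: true {true_rate:.3f}, measured {est:.3f} um/min")

fit = fit_hill(concentrations, measured)
print(f"\nHill fit: v0={fit.v0:.3f}, v_max={fit.v_max:.3f} um/min, "
      f"K={fit.K:.1f} nM, h={fit.h:.2f}  (truth v_max={VMAX}, K={K}, h={H})")
# K is the half-maximal motor concentration; h > 1 indicates cooperative
# concentration dependence of the depolymerization activity.
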