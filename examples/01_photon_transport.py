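"""Photon transport in a layered head model, checked against diffusion theory.

Runs a small Monte-Carlo simulation (isotropic scattering, absorption applied
at detection), histograms the detected photon times-of-flight, and compares
the mean time-of-flight with the closed-form diffusion solution for a
homogeneous half-space with an index-matched boundary.
"""

import numpy as np

from trbci import Geometry, OpticalLayer, default_head_medium, run_photon_mc
from trbci.diffusion import diffusion_mean_tof

medium = default_head_medium()                       # 10 x 2 mm, mu_a=0.017, mu_s'=1.0
geometry = Geometry(external_refractive_index=1.4)   # index-matched for the comparison
records = run_photon_mc(medium, geometry, n_photons=300_000, seed=1)

w = records.weights_for(medium.mu_a)
t = records.arrival_time_ps
t_mean = (t * w).sum() / w.sum()
ess = w.sum() ** 2 / (w**2).sum()
se = np.sqrt(((w * (t - t_mean) ** 2).sum() / w.sum()) / ess)

props = OpticalLayer(1e9, 0.017, 1.0, 1.4, semi_infinite=True)
t_diffusion = diffusion_mean_tof(geometry, props, max_time_ps=12500.0)

print(f"detected photons:        {records.n_detected}")
print(f"effective sample size:   {ess:.0f}  (absorption weights)")
print(f"MC <t>:                  {t_mean:.1f} +- {se:.1f} ps")
print(f"diffusion-theory <t>:    {t_diffusion:.1f} ps")
print(f"difference:              {abs(t_mean - t_diffusion) / se:.2f} MC standard errors")
# <t> ~ 800 ps at 30 mm: the average detected photon spends ~0.8 ns in tissue.
# Agreement within a few SE confirms the transport engine against the
# analytic half-space solution.
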