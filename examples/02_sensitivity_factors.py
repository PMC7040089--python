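"""Depth sensitivity of the mean time-of-flight.

Computes the per-layer MTSF (the derivative of <t> with respect to each
layer's absorption, ps mm) from a photon ensemble and shows why <t> is a
depth-sensitive observable: deep layers, reached only by late photons, carry
most of the sensitivity per unit pathlength, while the superficial scalp
layer contributes almost nothing.
"""

from trbci import Geometry, compute_mtsf, default_head_medium, run_photon_mc

medium = default_head_medium()
records = run_photon_mc(medium, Geometry(), n_photons=500_000, seed=2)
sens = compute_mtsf(records, medium, delta_mua=0.001)

print("layer  depth(mm)   MTSF (ps mm)    MC SE")
for k, (value, se) in enumerate(
    zip(sens.per_layer_mtsf[830.0], sens.per_layer_error[830.0]), start=1
):
    tag = " <- brain" if k in medium.brain_layer_indices else ""
    print(f"  {k:2d}   {2*k-2:2d}-{2*k:2d}     {value:10.1f}   {se:7.1f}{tag}")

print(
    f"\nbrain MTSF (sum of layers 5-10): {sens.mtsf[830.0]:.0f} "
    f"+- {sens.mc_error[830.0]:.0f} ps mm"
)
# A brain absorption increase of 1e-4 mm^-1 (a ~0.5 uM oxyhemoglobin rise)
# therefore shortens <t> by ~|MTSF|*1e-4 ~ 1 ps - the signal the BCI decodes.
# The negative sign: extra absorption preferentially removes late,
# deep-travelling photons.
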