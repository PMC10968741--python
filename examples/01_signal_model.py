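"""Evaluate the bi-exponential IVIM model on the whole-brain protocol.

Builds the 35-measurement acquisition scheme (5 b0 + 10 nonzero b-values in
3 directions), evaluates the noiseless signal for a grey-matter-like voxel,
and shows how the perfusion component dominates the low-b decay.
"""

import numpy as np

import ivimsim as iv

scheme = iv.default_acquisition_scheme()
params = iv.IVIMParameters(s0=1.0, f=0.12, d_star=0.01, d=0.001)
signal = iv.ivim_signal(params, scheme)

print(f"scheme: {scheme.total_measurements} measurements, "
      f"{scheme.n_b0} b0, nonzero b = {scheme.nonzero_b}")
print(f"ground truth: S0={params.s0}, f={params.f}, D*={params.d_star}, D={params.d} [mm^2/s]\n")

print(" b [s/mm^2]   signal   slow-only   perfusion share")
slow_only = iv.monoexp_signal((1 - params.f) * params.s0, params.d, scheme)
for b in [0.0, 10.0, 50.0, 200.0, 500.0, 1200.0]:
    i = int(np.flatnonzero(scheme.b_values == b)[0])
    share = (signal[i] - slow_only[i]) / signal[i]
    print(f"{b:10.0f}  {signal[i]:8.4f}  {slow_only[i]:9.4f}  {share:14.1%}")

print(
    "\nThe perfusion (fast) component carries ~12% of the signal at b=0 and is"
    "\nessentially gone above b=250 s/mm^2 -- the separation the segmented"
    "\nestimators exploit."
)
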