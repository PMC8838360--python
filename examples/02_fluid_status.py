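"""Fluid-status marker K = R5k/R150k from bioimpedance spectroscopy.

Simulates one minute of spectroscopy (30 sweeps of 32 log-spaced frequencies,
5-150 kHz) from a Cole tissue model, averages the sweeps, and reads off the
low/high-frequency resistances and their ratio.
"""

import numpy as np

import pulmosense as ps

# tissue whose noiseless ratio is the admission-regime K = 1.27
cole = ps.cole_params_for_k(1.27, rinf=25.0)
print(f"Cole model: R0 = {cole.r0:.2f} ohm, Rinf = {cole.rinf:.2f} ohm, "
      f"tau_c = {cole.tau_c:.2e} s, alpha = {cole.alpha}")

sweeps = ps.make_bis_sweeps(cole, n_sweeps=30, noise_sd=0.5, seed=7)
curve = ps.average_sweeps(sweeps)
markers = ps.compute_k_ratio(curve)

z = ps.cole_impedance(cole, np.array([5000.0, 150000.0]))
print(f"averaged {curve.n_sweeps} sweeps")
print(f"R5k   = {markers.r5k:.2f} ohm   (noiseless {z[0].real:.2f})")
print(f"R150k = {markers.r150k:.2f} ohm   (noiseless {z[1].real:.2f})")
print(f"K     = {markers.k:.4f}        (noiseless "
      f"{z[0].real / z[1].real:.4f})")

# K > 1 because low-frequency current is confined to extracellular paths
# (higher resistance); with 0.5 ohm sweep noise and 30 sweeps the estimate
# lands within ~1 % of the model's true ratio.
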