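"""Second-stage dilution: power-law fit to centerline concentrations.

Generates noisy receptor samples of an inert tracer decaying as a*x^-b
downwind of the stack (emulating dispersion-model output along the plume
centerline) and recovers the dilution parameters by a log-log least-squares
fit.
"""

import numpy as np

from shipplume import fit_power_law, make_dilution_samples

true_a, true_b = 5000.0, 1.26  # b = 1.26 is the typical fitted exponent
distances = np.geomspace(40.0, 3600.0, 50)
samples = make_dilution_samples(true_a, true_b, distances, noise_sd=0.1, seed=7)

fit = fit_power_law(samples[:, 0], samples[:, 1])
print(f"true      a = {true_a:8.1f}   b = {true_b:.3f}")
print(f"recovered a = {fit['a']:8.1f}   b = {fit['b']:.3f}   r^2 = {fit['r2']:.4f}")
print(
    "\nParameter b controls how fast the plume dilutes toward background"
    "\n(fits for real harbor events span roughly 0.99-1.47); it feeds the"
    "\nper-species mixing term dN/dt = -(b/t)(N - N_background)."
)
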