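"""Invert resonance frequencies to corneal elasticity (flap version).

Generates noiseless resonance peaks from a forward model at a "posterior
flap" elasticity, then fits the modulus by iterative matching against the
anterior reference.  The stiffness factor between the two fits quantifies
the relative stiffness of the two tissues -- the same procedure used to
quantify cross-linking-induced stiffening in whole globes.
"""

from ocuvib import FlapConfig
from ocuvib.fitting import fit_elasticity, forward_peaks, stiffness_factor, with_corneal_E

cfg = FlapConfig()
window = dict(f_min=50.0, f_max=750.0, step=5.0, refine_step=1.0)

obs_anterior = forward_peaks(with_corneal_E(cfg, 14.58), **window)
obs_posterior = forward_peaks(with_corneal_E(cfg, 11.6), **window)
print("anterior peaks (Hz):", [round(f, 1) for f in obs_anterior])
print("posterior peaks (Hz):", [round(f, 1) for f in obs_posterior])

fit_ant = fit_elasticity(cfg, obs_anterior, f_resolution=40.0, bounds_kpa=(5, 30), **window)
fit_post = fit_elasticity(cfg, obs_posterior, f_resolution=40.0, bounds_kpa=(5, 30), **window)
ratio, sigma = stiffness_factor(fit_ant, fit_post)

print(f"\nfitted anterior  E = {fit_ant.E_kpa:.2f} +/- {fit_ant.uncertainty_kpa:.2f} kPa")
print(f"fitted posterior E = {fit_post.E_kpa:.2f} +/- {fit_post.uncertainty_kpa:.2f} kPa")
print(f"stiffness factor posterior/anterior = {ratio:.3f} +/- {sigma:.3f}")
print(
    "\nThe uncertainty comes from the 40 Hz frequency resolution of the"
    " emulated\nmeasurement, propagated through the local sensitivity of the"
    " most responsive mode."
)
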