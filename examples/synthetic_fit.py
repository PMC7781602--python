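"""Fit the relay model to a synthetic chemotactic-index map.

Generates a noisy <cos theta>(r, t) map from known relay parameters,
extracts information-front points by thresholding each time bin, fits
(Cth/a rho, D) by weighted least squares and reports the recovery error.
"""

import numpy as np

from relaywave.swarming import fit_front, synth_front_map

Q_TRUE, D_TRUE, RI = 3.66e5, 1.25e-10, 100e-6

cmap, obs = synth_front_map(cth_over_arho=Q_TRUE, D=D_TRUE, ri=RI,
                            noise=0.05, seed=42)
print(f"synthetic map: {cmap.values.shape[0]} time bins x "
      f"{cmap.values.shape[1]} radial bins, 5% index noise")
print(f"extracted {obs.times.size} front points, e.g. "
      f"t={obs.times[0]:.0f} s -> r={obs.radii[0] * 1e6:.0f} µm, "
      f"t={obs.times[-1]:.0f} s -> r={obs.radii[-1] * 1e6:.0f} µm")

fit = fit_front(obs, RI)
print(f"\nfitted Cth/(a rho) = {fit.cth_over_arho:.3g} s/m "
      f"(truth {Q_TRUE:.3g}, {fit.cth_over_arho / Q_TRUE - 1:+.1%})")
print(f"fitted D           = {fit.D:.3g} m^2/s "
      f"(truth {D_TRUE:.3g}, {fit.D / D_TRUE - 1:+.1%})")
print(f"implied wave speed = {fit.implied_v * 1e6:.2f} µm/s; "
      f"rms front residual = {fit.residual * 1e6:.1f} µm")
print("\nBoth parameters come back within a few percent at this noise "
      "level; the residual\nreflects the 25 µm radial binning of the map.")
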