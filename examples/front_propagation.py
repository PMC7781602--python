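"""Self-consistent information-front propagation, relay vs simple diffusion.

Propagates the relay front for the thin-film benchmark (v = 2 µm/s) with
the Green's-function solver, measures its late-time slope, and contrasts
it with the decelerating front of a target that never recruits its
neighbours.
"""

import numpy as np

from relaywave import (Geometry, PhysicalParams, estimate_speed,
                       natural_scales, propagate_front,
                       simple_diffusion_front, wave_speed)

geom = Geometry(2, 2)
params = PhysicalParams(D=1e-10, a=1.0, rho=1.0, Cth=25 / 1e-4, h=1e-4)
L, T = natural_scales(params, geom)
v_theory = wave_speed(params, geom)

relay = propagate_front(params, geom, ri=4 * L, t_end=40 * T)
diffusion = simple_diffusion_front(params, geom, ri=4 * L, t_end=40 * T)

print(f"theory: v = {v_theory * 1e6:.3f} µm/s; D/v = {L * 1e6:.0f} µm; "
      f"D/v^2 = {T:.0f} s")
print(f"\n{'t (D/v^2)':>10} {'relay r_c (D/v)':>16} {'diffusion r_c (D/v)':>20}")
for t_nd in (5, 10, 20, 30, 40):
    t = t_nd * T
    print(f"{t_nd:>10d} {relay.radius_at(t) / L:>16.2f} "
          f"{diffusion.radius_at(t) / L:>20.2f}")

v_meas = estimate_speed(relay, (32 * T, 40 * T))
print(f"\nmeasured relay slope over [32, 40] D/v^2: {v_meas * 1e6:.3f} µm/s "
      f"({v_meas / v_theory:.1%} of the asymptote; the residual is the "
      f"curvature transient)")
print("The relay front advances linearly while the diffusion-only front "
      "creeps diffusively —\nby 40 D/v^2 the relay has signalled more than "
      "twice as far.")
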