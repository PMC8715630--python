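"""Macro kinematic metrics of a single reach.

A noise-free minimum-jerk reach is the canonical smooth movement: its
speed-shape ratio is 8/15 ~ 0.533 and its dimensionless discrete jerk is
720.  Higher jerk / lower speed shape indicate less smooth movement.
"""

import numpy as np

from robokin import reach_macro_metrics

duration, amplitude = 1.2, 0.14  # s, m
t = np.linspace(0.0, duration, 2000)
tau = t / duration
x = amplitude * (10 * tau**3 - 15 * tau**4 + 6 * tau**5)
q = np.stack([x, np.zeros_like(x)], axis=1)

m = reach_macro_metrics(t, q, target=(amplitude, 0.0), target_radius=0.01)
print(f"duration      {m.duration:.3f} s")
print(f"mean speed    {m.mean_speed * 100:.2f} cm/s")
print(f"peak speed    {m.peak_speed * 100:.2f} cm/s")
print(f"speed shape   {m.speed_shape:.4f}   (minimum-jerk value 8/15 = {8 / 15:.4f})")
print(f"jerk (disc.)  {m.jerk_discrete:.1f}    (minimum-jerk value 720)")
print(f"aim           {m.aim:.2e} rad, deviation {m.deviation:.2e} m (straight reach)")
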