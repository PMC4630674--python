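"""Generate a synthetic trot and segment it into strides.

Builds 2 s of a mouse trotting at 0.25 m/s, segments each paw's forward
trajectory into stance and swing, and prints the per-stride parameters.
The printed medians should sit on the generator's stride laws: at 0.25 m/s
the cadence is ~4.2 strides/s, so strides are ~59 mm long, and walking
speed = stride length x cadence recovers the requested 0.25 m/s.
"""

import locogait as lg
from locogait.synth import SyntheticSpec, gen_gait

tracks, truth = gen_gait(SyntheticSpec(speed=0.25, seed=1), duration_s=2.0)
table = lg.build_strides(tracks)

d = table.data
print(f"strides found: {len(d)} (ground truth: {len(truth.data)})")
print(f"median walking speed : {d.walking_speed.median():.3f} m/s")
print(f"median cadence       : {d.cadence.median():.2f} strides/s")
print(f"median stride length : {d.stride_length.median():.1f} mm")
print(f"median swing velocity: {d.swing_velocity.median():.3f} m/s")
print(f"median duty factor   : "
      f"{(d.stance_duration / d.stride_duration).median():.2f}")
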