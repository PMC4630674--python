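"""Interlimb coordination of a symmetric trot.

Computes stance phases relative to the front-right paw, support-pattern
fractions and signed double support for a clean synthetic trot.  In a trot
the diagonal partner touches down together with the reference paw (phase
~0) and the contralateral partner half a cycle later (phase ~0.5); at a
duty factor near 0.5 the animal spends nearly the whole stride on the two
diagonal pairs and double support is near zero.
"""

import numpy as np

import locogait as lg
from locogait.coordination import (circular_mean, double_support,
                                   stance_phase, support_fractions)
from locogait.synth import SyntheticSpec, gen_gait

tracks, _ = gen_gait(SyntheticSpec(speed=0.25, seed=2), duration_s=2.0)
table = lg.build_strides(tracks)
fps = tracks.fps

onsets = {p: table.for_paw(p).stance_onset.to_numpy() / fps
          for p in ("FR", "FL", "HR", "HL")}
liftoffs = {p: table.for_paw(p).swing_onset.to_numpy() / fps
            for p in ("FR", "FL", "HR", "HL")}
intervals = {p: list(zip(onsets[p], liftoffs[p]))
             for p in ("FR", "FL", "HR", "HL")}

phases = {p: [] for p in ("FL", "HR", "HL")}
ds, supports = [], []
for _, rec in table.for_paw("FR").iterrows():
    t0 = rec.stance_onset / fps
    for p in phases:
        phases[p].append(stance_phase(t0, rec.stride_duration, onsets[p]))
    ds.append(double_support(t0, rec.stride_duration, liftoffs["FL"]))
    supports.append(support_fractions(intervals, t0,
                                      rec.next_stance_onset / fps))

for p, vals in phases.items():
    print(f"stance phase {p} vs FR: {circular_mean(np.array(vals)):.3f}")
print(f"double support (FR vs FL): {np.nanmedian(ds):+.1f}% of the cycle")
for cat in ("four", "three", "two_diagonal", "two_other", "one", "zero"):
    frac = np.median([s[cat] for s in supports])
    if frac > 0.005:
        print(f"support {cat:13s}: {frac:.1%} of the stride")
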