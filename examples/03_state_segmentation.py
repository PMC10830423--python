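"""Segment a long trajectory into latent diffusive states with the SLDS.

A 5000-step trajectory switches between free (0.5 um^2/s) and
contact-associated (0.1 um^2/s) diffusion with mean state dwell of 100
steps; the sticky HDP-SLDS recovers the per-step state and the per-state
diffusion tensor, separating true motion from the 25 nm localization error.
"""

import numpy as np

from ermcs_spt.simkit import simulate_switching_diffusion
from ermcs_spt.statedyn import SLDSConfig, match_labels, segment_trajectory_slds

traj = simulate_switching_diffusion(5000, D_states=(5e5, 1e5),
                                    mean_dwell_steps=100, seed=7)
seg = segment_trajectory_slds(traj, SLDSConfig(seed=0))

truth = traj["state"].to_numpy()[:-1]
_, accuracy = match_labels(seg.labels, truth)
print(f"{seg.n_steps} steps segmented into {len(seg.states)} occupied states; "
      f"per-step accuracy vs ground truth: {accuracy*100:.1f}%")
for k, sp in sorted(seg.states.items()):
    D = sp.diffusion_eigenvalues_nm2_s / 1e6
    print(f"  state {k}: occupancy {sp.occupancy:.2f}, "
          f"D eigenvalues ({D[0]:.3f}, {D[1]:.3f}) um^2/s, "
          f"relaxation ({sp.relaxation_eigenvalues_per_s[0]:.1f}, "
          f"{sp.relaxation_eigenvalues_per_s[1]:.1f}) 1/s")
# The two occupied states recover ~0.5 and ~0.1 um^2/s despite every
# observed displacement carrying ~2*(25 nm)^2 of measurement variance -- a
# noise-blind estimator would report an extra sigma^2/dt ~ 0.059 um^2/s.
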