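"""Directed movement influence from a coupled pair of bees.

A follower whose velocity tracks its leader's previous displacement (c = 0.6)
is simulated for a 30-frame window, the length the pipeline uses.  A VAR is
fitted per coordinate axis, the squared information partial directed
coherence (iPDC) is computed in both directions, and each spectrum is
integrated into information flow in bits.  The leader->follower direction
should dominate.
"""

import numpy as np

from hiveflow import (simulate_coupled_pair, fit_var, ipdc_spectrum,
                      information_flow)

leader, follower = simulate_coupled_pair(n_frames=30, c=0.6, seed=3)

flows = {"leader->follower": [], "follower->leader": []}
for axis, name in ((0, "X"), (1, "Y")):
    model = fit_var((leader[:, axis], follower[:, axis]), order="aic", p_max=3)
    spec = ipdc_spectrum(model, n_freqs=128)
    fwd = information_flow(spec, direction=(0, 1))
    rev = information_flow(spec, direction=(1, 0))
    flows["leader->follower"].append(fwd)
    flows["follower->leader"].append(rev)
    print(f"axis {name}: VAR({model.order}), "
          f"I_flow leader->follower {fwd:.4f} bits, follower->leader {rev:.4f} bits")

print(f"averaged over axes: leader->follower {np.mean(flows['leader->follower']):.4f} bits, "
      f"follower->leader {np.mean(flows['follower->leader']):.4f} bits")
# A positive gap between the two directions is the signature of directed
# influence: the leader's past positions carry information about the
# follower's present position, beyond the follower's own history.
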