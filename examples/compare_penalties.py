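"""How the penalty multiplier lambda(N) controls the number of clusters.

On one tight-scenario dataset of 200 points (10 true clusters), sweep the
penalty from a weak constant (lambda = 1) through the AIC (lambda = 2) to
the N-dependent criteria, and report the cluster count each returns.
"""

import numpy as np

from bgmix import PenaltySpec
from bgmix.experiments import penalty_sweep

penalties = [
    PenaltySpec("constant", 1.0),
    PenaltySpec("constant", 2.0),
    PenaltySpec("hannan_quinn"),
    PenaltySpec("bic"),
    PenaltySpec("caic"),
]
counts = penalty_sweep(
    n_points=200, cluster_size=20, penalties=penalties,
    seeds=[0, 1, 2],
    schedule_kwargs=dict(t_init=5.0, cooling=0.9, moves_per_temperature=20,
                         max_no_improve=8),
)
print("true number of clusters: 10")
for name, vals in counts.items():
    print(f"{name:30s} -> clusters found per seed: {vals}, "
          f"median {np.median(vals):g}")
print("Counts can only shrink as the per-parameter penalty grows; strong "
      "N-dependent penalties flatten the search surface and may stop short "
      "of the true solution.")
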