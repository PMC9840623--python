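"""Track slow molecules across consecutive frames and fit the step sizes.

Long-exposure tracking (30 ms frames): localizations are linked only when
the match within 800 nm is unambiguous in both directions, 5-30 frame
tracks are kept, and the pooled step-size distribution is fit with a
two-component 2D random-walk mixture — the membrane-bound vs clustered
decomposition.
"""

import numpy as np
import pandas as pd

from smdmap import fit_trajectory_displacements, link_trajectories

rng = np.random.default_rng(4)
rows = []
for m in range(200):
    d_true = 0.15 if m < 120 else 0.03         # 60% mobile, 40% clustered
    origin = np.array([(m % 15) * 20_000.0, (m // 15) * 20_000.0])
    sd = np.sqrt(2 * d_true * 1e3 * 30.0)
    steps = rng.normal(scale=sd, size=(24, 2))
    pos = origin + np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    rows.extend((f + 1, x, y) for f, (x, y) in enumerate(pos))
table = pd.DataFrame(rows, columns=["frame", "x_nm", "y_nm"])

trajs = link_trajectories(table, link_radius_nm=800.0, min_len=5, max_len=30)
fit = fit_trajectory_displacements(trajs, dt_ms=30.0, n_components=2)

print(f"trajectories: {len(trajs)}, pooled steps: {fit.n_displacements}")
for name, (d, f) in zip(("mobile", "clustered"), fit.components):
    print(f"{name}: D = {d:.3f} um^2/s, fraction = {f:.2f}")
print("True values: 0.15 / 0.03 um^2/s at fractions 0.60 / 0.40. No")
print("background term is needed: ambiguous pairings were discarded at")
print("the linking stage.")
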