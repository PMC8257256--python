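"""Per-pixel entropy of one group and symmetrized KL between two groups.

Both maps use k-nearest-neighbor estimators on the aligned disc pixels
after dequantization; they localize where a wing ensemble varies and where
two ensembles differ (vein corridors, in this synthetic anatomy).
"""

import numpy as np

from discmorph import (
    PipelineConfig, VariationSpec, WingTemplate, entropy_map, generate_ensemble,
    process_ensemble, symmetrized_kl_map,
)
from discmorph.alignment import SearchGrid

cfg = PipelineConfig(disc_diameter=100, n_vertices=32, radon_step_deg=2.0,
                     search=SearchGrid(n_refine=3))
spec = VariationSpec(group_offsets={"b": (3.0, 0.0)})
ens_a, _ = process_ensemble(
    generate_ensemble(WingTemplate(), spec, 20, ["a"], seed=21, shape=(240, 320)),
    cfg, reference_id="a_0000")
ens_b, _ = process_ensemble(
    generate_ensemble(WingTemplate(), spec, 20, ["b"], seed=22, shape=(240, 320)),
    cfg, reference_id="b_0000")

em = entropy_map(ens_a.images, k=3, seed=0)
print(f"per-pixel entropy over {em.n} wings: median {np.median(em.values):.2f} nats, "
      f"95th pct {np.quantile(em.values, 0.95):.2f} nats, "
      f"{int(em.minimal.sum())} constant pixels")

A = np.vstack([im.values() for im in ens_a.images])
B = np.vstack([im.values() for im in ens_b.images])
kl = symmetrized_kl_map(A, B, k=2, seed=0)
print(f"symmetrized KL map: median {np.median(kl):.3f} nats, "
      f"99th pct {np.quantile(kl, 0.99):.2f} nats")
# High-entropy and high-KL pixels trace the moving vein positions; flat
# intervein tissue sits near the estimator's noise floor.
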