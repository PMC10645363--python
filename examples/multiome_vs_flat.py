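"""Multiome (shared assignment) versus flat (independent) integration.

On a paired assay, where both modalities measure the same physical
cells, the multiome model gives each cell one clone assignment driving
both its RNA and ATAC counts; the flat model treats the two measurement
sets as independent cells that only share the copy-number tensor. On
well-behaved data the two agree.
"""

import numpy as np

from cnaclone import (
    CloneTree,
    FitConfig,
    SimulationTruth,
    adjusted_rand_index,
    default_prior,
    sample_segment_rates,
    select_model,
    simulate_counts,
)

# tumour (trisomy on segment 2, LOH on segment 7) vs normal, 60/40
cn = np.full((2, 12), 2)
cn[1, 2], cn[1, 7] = 3, 1
truth = SimulationTruth(
    tree=CloneTree([-1, 0], [{}, {2: 3, 7: 1}]),
    cn_matrix=cn,
    proportions=np.array([0.4, 0.6]),
)
rng = np.random.default_rng(42)
theta, over = {}, {}
for name in ("RNA", "ATAC"):
    theta[name], over[name] = sample_segment_rates(12, name, seed=rng)
sim = simulate_counts(truth, 250, theta, over, paired=True, seed=rng)
prior = default_prior(np.full(12, 2), H=4)

cfg_multi = FitConfig(K_range=range(1, 4), mode="multiome", steps=400,
                      restarts=2, seed=3)
multi, _ = select_model(sim.rna, sim.atac, prior, cfg_multi)

cfg_flat = FitConfig(K_range=range(1, 4), mode="flat", steps=400,
                     restarts=2, seed=3)
flat, _ = select_model(sim.rna, sim.atac, prior, cfg_flat)

# the multiome model assigns each physical cell once; replicate that
# assignment for both measurement sets to compare against the flat model
multi_labels = np.concatenate([multi.assignments["cells"]] * 2)
flat_labels = np.concatenate(
    [flat.assignments["RNA"], flat.assignments["ATAC"]]
)
agreement = adjusted_rand_index(multi_labels, flat_labels)
truth = np.concatenate([sim.labels_rna, sim.labels_atac])

print(f"multiome: K={multi.K}, ARI vs truth = "
      f"{adjusted_rand_index(truth, multi_labels):.3f}")
print(f"flat:     K={flat.K}, ARI vs truth = "
      f"{adjusted_rand_index(truth, flat_labels):.3f}")
print(f"agreement between the two models (ARI) = {agreement:.3f}")
print("\nAgreement near 1 mirrors the observation that treating paired "
      "cells as unpaired still recovers the same clones.")
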