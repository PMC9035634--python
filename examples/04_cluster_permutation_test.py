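"""Sensor-level cluster-based permutation test for a group difference.

Subjects x electrodes mean-amplitude matrices are compared with
per-electrode t tests; neighboring supra-threshold electrodes of common
sign form clusters whose summed-t mass is referred to the permutation
distribution of the maximum cluster mass under group-label shuffling.
"""

import numpy as np

from heplpp import Montage, build_adjacency, cluster_permutation_test

labels = ("F3", "Fz", "F4", "FC1", "FCz", "FC2", "C3", "Cz", "C4", "Pz")
adjacency = build_adjacency(Montage.standard(labels))
print(f"adjacency: {len(adjacency)} electrodes, {adjacency.n_edges} edges (Delaunay)")

rng = np.random.default_rng(3)
controls = rng.normal(0.0, 1.0, size=(14, len(labels)))
patients = rng.normal(0.0, 1.0, size=(14, len(labels)))
# attenuate the frontocentral electrodes in the patient group by 1.5 units
target = [i for i, lab in enumerate(labels) if lab in ("FC1", "FCz", "FC2")]
patients[:, target] -= 1.5

result = cluster_permutation_test(patients, controls, adjacency, n_perm=2000, seed=0)
print(f"cluster-forming |t| threshold: {result.forming_threshold:.2f}")
for c in result.clusters:
    tag = "attenuated in patients" if c.sign < 0 else "enhanced in patients"
    print(f"  cluster {c.electrodes}: mass={c.mass:.1f} ({tag}), p={c.p_value:.4f}")
print("\nA small Monte-Carlo p on the frontocentral cluster means the injected")
print("attenuation is unlikely under random group relabeling.")
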