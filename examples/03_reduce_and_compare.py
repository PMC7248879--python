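"""The full reduction pipeline: featurize, cluster, select, compare.

Keeps one structure per (cluster, 0.01-REU energy level) and reports how
the reduced ensemble compares to the source in size, energies and lRMSD
to the native.
"""

from decoyreduce import (
    SynthSpec,
    compare,
    gmx_cluster_usr,
    make_ensemble,
    select_reduced,
    usr_score_matrix,
)

ensemble, _ = make_ensemble(SynthSpec(sizes=[250] * 4, seed=3))
clusters = gmx_cluster_usr(usr_score_matrix(ensemble, "ca_only"), cutoff=0.1)
selection = select_reduced(ensemble, clusters, width=0.01, seed=3)
report = compare(ensemble, selection.selected_ids, with_correlation=False)

print(f"clusters found: {clusters.k}")
print(report.to_frame().to_string(index=False, float_format=lambda v: f"{v:.3f}"))
# The min-energy diff is below the 0.01 REU bin width by construction and
# the lRMSD min diff is small: the reduced ensemble keeps the best decoys
# while discarding energy-level duplicates within each structural cluster.
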