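"""Cluster an ensemble in USR shape space, four ways.

Each algorithm picks its own number of clusters: k-means at the knee of
the SSE curve, the Gaussian mixture at the BIC minimum, single-linkage
at the Davies-Bouldin minimum, and the greedy USR-cutoff method directly
from its 0.1 neighbor cutoff.
"""

from sklearn.metrics import adjusted_rand_score

from decoyreduce import (
    SynthSpec,
    feature_matrix,
    gmm_cluster,
    gmx_cluster_usr,
    hierarchical_cluster,
    kmeans_cluster,
    make_ensemble,
    usr_score_matrix,
)

ensemble, truth = make_ensemble(SynthSpec(sizes=[50] * 4, seed=0))
X = feature_matrix(ensemble, "ca_only")

results = {
    "kmeans (SSE knee)": kmeans_cluster(X, (2, 8), seed=0),
    "gmm (BIC)": gmm_cluster(X, (2, 8), seed=0),
    "hierarchical (DB)": hierarchical_cluster(X, list(range(2, 9))),
    "gmx-usr (cutoff 0.1)": gmx_cluster_usr(usr_score_matrix(ensemble, "ca_only")),
}
print("4 planted basins; agreement with the planted labels as ARI:")
for name, res in results.items():
    ari = adjusted_rand_score(truth, res.labels)
    print(f"  {name:22s} k={res.k:2d}  ARI={ari:.2f}")
# ARI = 1 means the planted partition was recovered exactly; USR is a
# lossy shape summary, so basins with similar overall shape can merge.
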