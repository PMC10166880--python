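"""Gate-free grouping with a Gaussian mixture on two marker genes.

Fits a 2-component full-covariance Gaussian mixture (EM, k-means++
initialization) to the normalized expression of two transcription-factor-like
markers, writes the hard assignments as an annotation, and checks how well
the groups align with the ground-truth clusters.
"""

import numpy as np

import cellgate as cg

spec = cg.SimSpec(
    n_cells=2000,
    n_genes=40,
    n_clusters=2,
    marker_table=[
        cg.MarkerSpec("TBX21", frozenset({0}), 30.0),
        cg.MarkerSpec("RORC", frozenset({1}), 30.0),
    ],
    seed=6,
)
ds = cg.simulate(spec)

model = cg.fit_gmm(ds, "TBX21", "RORC", K=2, seed=0, layer="normalized")
cg.assign_groups(model, ds, key="gmm_groups")

print("mixture weights:", np.round(model.weights, 3))
print("component means (normalized TBX21, RORC):")
print(np.round(model.means, 2))
print(f"EM iterations: {len(model.loglik_trace)}, "
      f"final mean log-likelihood: {model.loglik_trace[-1]:.4f}")

truth = ds.annotations["true_cluster"].to_numpy()
groups = ds.annotations["gmm_groups"].to_numpy()
agree = max(
    (groups == truth).mean(),
    (np.where(groups == "0", "1", "0") == truth).mean(),
)
print(f"agreement with true clusters (best label matching): {100 * agree:.1f}%")

for g in ("TBX21", "RORC"):
    e = {lab: cg.enrichment(ds, "gmm_groups", lab, g) for lab in ("0", "1")}
    print(f"{g} enrichment per group: " +
          ", ".join(f"{k}={v:.1f}" for k, v in e.items()))
print()
print(
    "With well-separated marker-high populations the mixture recovers the\n"
    "true grouping; each group is strongly enriched for exactly one marker,\n"
    "matching what polygon gates on the same axes would select."
)
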