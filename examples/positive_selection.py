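"""Positive selection: a polygon gate can beat cluster-level selection.

Simulates a dataset in which a marker's high-expression zone straddles two
block clusters of the embedding, so neither cluster is a good proxy for the
marker-high population.  A tight polygon gate around the zone isolates the
population directly, yielding a higher fold-enrichment than either cluster.
"""

import cellgate as cg

ds, zone_gate = cg.straddling_marker_dataset(seed=11, n_cells=2000, n_genes=60)

session = cg.PolygonSet(
    axes=cg.AxesContext(kind="embedding", embedding_name="umap"),
    polygons=[zone_gate],
)
result = cg.select_on_embedding(ds, "umap", session, key="selection")
cg.rename_labels(ds, "selection", {"zone": "MARKER_high"})

table = cg.region_stats(ds, "selection", genes=["MARKER"])
print(table.round(2))
print()
for label in sorted(set(ds.annotations["true_cluster"])):
    e = cg.enrichment(ds, "true_cluster", label, "MARKER")
    print(f"block cluster {label}: MARKER enrichment {e:6.2f}-fold")
e_gate = cg.enrichment(ds, "selection", "MARKER_high", "MARKER")
print(f"polygon gate:    MARKER enrichment {e_gate:6.2f}-fold")
print()
print(
    "Enrichment is the ratio of the gene's transcripts-per-million inside a\n"
    "region to its TPM among all other cells.  Because the marker-high zone\n"
    "spans both clusters, each cluster dilutes the signal with flanking\n"
    "cells; the hand-drawn gate around the zone is far more specific."
)
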