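"""Rank features with SVM-RFE and assemble hybrid group vectors.

Extracts the GDC block from a planted-signal dataset, ranks its 128
features, keeps the top 5, and prints the nine cataloged hybrid group
dimensions plus a concrete G4 hybrid matrix.
"""

import recspot as rs
from recspot.pipeline import PipelineSpec, extract_needed_blocks, rank_blocks
from recspot.hybrid import HybridSpec, build_hybrid

ds = rs.generate_synthetic_dataset(
    rs.SimulationSpec(n_pos=30, n_neg=30, length_low=300, length_high=400,
                      effect=0.2, seed=3)
)

gdc = rs.extract_block(ds, "gdc")
ranking = rs.svm_rfe_rank(gdc)
top5 = rs.select_top(ranking, 5)
print("top-5 GDC features by SVM-RFE:", top5)
# AAA/TTT-planted data should push A/T-pair compositions up the ranking.

print("\nnine hybrid groups (a, lam -> dimension):")
for name, spec in rs.catalog_groups().specs.items():
    print(f"  {name}: a={spec.a}, lam={spec.lam_mix} -> {spec.dimension}")

pipeline = PipelineSpec(hybrid=HybridSpec.for_group("G4"))
blocks = extract_needed_blocks(ds, pipeline)
selected = rank_blocks(blocks, ds.numeric_labels(), pipeline)
hybrid = build_hybrid(selected, pipeline.hybrid)
print(f"\nG4 hybrid matrix: {hybrid.shape[0]} x {hybrid.shape[1]} "
      "(5 GDC + 12 RCC + 66 PseTNC)")
print("first columns:", hybrid.feature_names[:3], "...")
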