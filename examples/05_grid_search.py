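"""Small learning-rate x activation grid search.

Evaluates a 2 x 2 grid by cross-validated pooled accuracy and prints the
winning cell under the deterministic tie rule (lowest rate, then tanh <
relu < sigmoid).  The published protocol sweeps 11 rates x 3 activations
the same way; shrink or grow the lists to taste.
"""

import recspot as rs
from recspot.hybrid import HybridSpec
from recspot.model import DnnConfig
from recspot.pipeline import PipelineSpec

ds = rs.generate_synthetic_dataset(rs.SimulationSpec(
    n_pos=40, n_neg=40, length_low=300, length_high=400, effect=0.2, seed=4))

spec = PipelineSpec(hybrid=HybridSpec.for_group("G4"),
                    classifier=DnnConfig.small(iterations=150, seed=6))
result = rs.grid_search(
    ds, rates=[0.1, 0.5], activations=["tanh", "relu"],
    base_config=spec.classifier, pipeline_spec=spec, k=4, seed=4)

print("cell accuracies:")
for (rate, act), acc in sorted(result.cells.items()):
    print(f"  lr={rate:<4} {act:<8} ACC {acc:.4f}")
rate, act = result.best_cell
print(f"best cell: learning rate {rate}, activation {act} "
      "(highest pooled CV accuracy; ties go to the lower rate)")
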