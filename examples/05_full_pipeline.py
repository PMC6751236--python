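"""Run the whole study end to end and inspect the artifacts it writes.

Equivalent to `recurmap run-all`, scaled to a small cohort so it runs in
about a minute: synthetic cohort -> registration + QC -> volume labeling ->
regional statistics -> voxel features -> leave-one-out forest -> elimination.
"""

import json
from pathlib import Path

from recurmap import PipelineConfig, run_all

out = Path("scratch/example_run")
cfg = PipelineConfig(seed=7, out_dir=str(out), n_patients=5, n_trees=150,
                     voxel_cap=400, elimination_trees=80, elimination_voxel_cap=200)
manifest = run_all(cfg)

print(json.dumps(manifest.summary, indent=2, sort_keys=True, default=str))
print("\nartifacts:")
for key, path in manifest.outputs.items():
    print(f"  {key:18s} {path}")
print()
print("Every run writes its config snapshot beside the outputs; re-running with")
print("the same seed reproduces all tabular outputs byte for byte.")
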