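"""Run the full study replica end to end on a scaled-down configuration.

Simulate -> composites -> per-network cross-validated prediction ->
bootstrap inference + mediation -> vertex-wise BSR maps with permutation
enrichment.  All outputs land in ./pipeline_out with a checksummed manifest;
rerunning with the same config reproduces identical checksums.
"""

from netcog.pipeline import run_study

config = {
    "seed": 1,
    "simulate": "default",
    "measures": ["thickness", "area"],
    "abilities": ["executive_function", "episodic_memory"],
    "networks": [1, 2, 3, 4, 5, 6, 7, "whole"],
    "cv": {"k": 5, "iterations": 10, "alphas": [0.05, 0.01, 0.001, 0.0005, 0.0001]},
    "bootstrap": {"B": 200},
    "vertexwise": {"B": 200, "n_perm": 500, "thresholds": [1.96, 2.58, 3.3, 3.9],
                   "sign": "positive"},
}

manifest = run_study(config, "pipeline_out")
for stage in manifest.stages:
    print(f"stage {stage['stage']:12s} {stage['status']}  {stage['elapsed_s']:.1f}s")
print(f"{len(manifest.outputs)} output files; see pipeline_out/manifest.json")
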