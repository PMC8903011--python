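"""Run the whole pipeline end to end and print the manifest tallies.

Equivalent to `fetalsplice run --outdir <dir> --seed 0` from a shell.
"""

import json

from fetalsplice.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(outdir="scratch/example_run", seed=0, n_events=500)
manifest = run_pipeline(config)

cd = manifest["stages"]["cross_dataset"]
print(json.dumps(cd, indent=2))
print("empirical FDR:", manifest["stages"]["differential"]["empirical_fdr"])
# The manifest records, for any dataset, the same tally types a splicing
# atlas reports: significant events per dataset, their overlap with a Fisher
# enrichment p, the direction histogram, and the shuffling FDR of the rule.
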