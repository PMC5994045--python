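"""Run every stage end to end on seeded synthetic inputs and print the report.

The pipeline chains simulate -> panel -> popstats -> demog -> range and
writes filter_ladder.tsv, range_scenarios.tsv and report.json under out/.
Re-running with the same seed reproduces the report byte for byte.
"""

import json

from declinomics import PipelineConfig, run_pipeline

config = PipelineConfig(
    mu=1.2e-8,
    n_sites=1_000,
    n_per_deme=20,
    pos_stride=20_000,
    n_dropout_variants=200_000,
    seed=5,
)
report = run_pipeline(config, outdir="out")
print(json.dumps({k: v for k, v in report.to_dict().items() if k != "config"}, indent=1))
# fst_weighted should sit near fst_target; fnr_percent near the planted 12;
# the decline percentages come from the scaled synthetic Ne trajectory.
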