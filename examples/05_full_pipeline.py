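"""Run every stage end to end on one simulated study and print the report.

Equivalent to `holosplit run --seed 17 --out report.json` from a shell.
"""

import json

from holosplit.pipeline import PipelineConfig, run, write_report

report = run(PipelineConfig(seed=17))
write_report(report, "report.json")

public = {k: v for k, v in report.items() if not k.startswith("_")}
print(json.dumps(public["ledger"], indent=2))
print("GC modes:", public["gc_modes"])
print("dedup:", public["dedup"])
print("overlap:", public["expression"]["overlap"])
for sex, res in public["expression"]["per_sex"].items():
    print(sex, {k: res[k] for k in ("n_de", "high_fc_sizes", "outliers")})
print("enrichment:", {s: v["passing_terms"] for s, v in public["enrichment"].items()})
print("\nfull report written to report.json")
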