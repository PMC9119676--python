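"""One-command run: simulate -> preprocess -> epoch -> analyze -> report.

The same orchestration the `photoseek run` CLI exposes, driven from
Python.  The JSON report carries event counts before/after exclusion,
traces per response type, and every significant window, plus a full
parameter echo so the run is reproducible from the report alone.
"""

import json
import tempfile

import photoseek as ps

config = ps.RunConfig(
    out_dir=tempfile.mkdtemp(prefix="photoseek_"),
    seed=5,
    phase="PUN",
    fr=3,
    synthetic={"duration": 3600.0, "rate_active": 0.05, "rate_inactive": 0.02},
)
report = ps.run_pipeline(config)

print(f"artifacts in {config.out_dir}")
print("events:", report["epochs"]["n_events"],
      "retained:", report["epochs"]["n_retained_events"])
print("traces per type:", report["epochs"]["traces_per_type"])
print("alpha:", round(report["alpha"], 4))
for rt, b in report["bootstrap"].items():
    print(f"  {rt}: positive windows {b['positive_windows'] or 'none'}")
print(json.dumps(report["permutation"], indent=2)[:400], "...")
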