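"""Simulate a punishment session and summarize its behavior.

Builds one hour of free-operant responding on an FR3 schedule where half
of the reinforced active nose-pokes are paired with footshock, then
prints the session totals a behavioral analysis would start from.
"""

import json

import photoseek as ps

cfg = ps.SyntheticConfig(phase=ps.Phase.PUN, fr=3, punish_prob=0.5, seed=42)
log = ps.simulate_behavior(cfg)
print(json.dumps(ps.session_summary(log), indent=2))

# infusions = rewarded + punished pokes (both deliver nicotine);
# nonrewarded active pokes are sub-ratio or time-out responses, which the
# schedule records but never reinforces.
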