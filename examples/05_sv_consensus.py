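"""Multi-caller deletion consolidation and novelty classification.

Four simulated callers each detect ~80% of planted deletions with ±10 bp
boundary jitter plus a few false positives.  Calls are size-filtered
(50 bp – 10 Mb), chained into union-boundary consensus deletions, and
classified as novel when under half of their span is covered by a
known-deletions catalog (here: half of the truth set).
"""

import tempfile
from pathlib import Path

from popdiv import simulate, sv

cfg = simulate.SvSimConfig(n_true_deletions=40, detection_prob=0.8,
                           boundary_jitter_sd=10.0, fp_per_caller=3, seed=9)
calls, truth = simulate.simulate_sv_calls(cfg)
print(f"{len(truth)} planted deletions, {len(calls)} caller-level calls")

consensuses = sv.merge_union(sv.size_filter(calls))
print(f"consolidated into {len(consensuses)} consensus deletions")
multi = sum(1 for c in consensuses if c.n_callers >= 2)
print(f"{multi} supported by ≥2 callers")

# pretend only the first half of the truth set was previously catalogued
catalog = truth[: len(truth) // 2]
novelty = [sv.classify_sv_novelty(c, catalog) for c in consensuses]
print(f"against a catalog of {len(catalog)} known deletions: "
      f"{novelty.count('known')} known, {novelty.count('novel')} novel")
print("\n(novel = under 50% of the consensus span covered by catalogued deletions)")
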