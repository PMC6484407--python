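"""Differential alternative splicing between genotypes.

Simulates junction counts for 300 events (one third with a true
inclusion shift of +-20 PSI points), applies the coverage filters,
scores each event with the Beta-posterior dPSI test (|dPSI| >= 10 and
directional posterior >= 0.95), and tabulates UP/DOWN calls by class.
"""
import numpy as np

from polwave import splicing as sp
from polwave import synthetic as syn

rng = np.random.default_rng(5)
dpsi_true = np.where(rng.random(300) < 1 / 3, rng.choice([-20.0, 20.0], 300), 0.0)
events = syn.simulate_junction_counts(300, dpsi_true=dpsi_true, depth=200,
                                      replicates=3, seed=6)
results = sp.diff_splice_all(events, "WT", "slow", n_mc=5_000, seed=7)
print(sp.summarize_calls(results).to_string())

truth = {ev.event_id: ev.true_dpsi for ev in events}
called = {r.event_id for r in results if r.call in ("UP", "DOWN")}
true_changed = {eid for eid, d in truth.items() if d != 0}
recall = len(called & true_changed) / len(true_changed)
false = len(called - true_changed)
print(f"\nrecall of true +-20-point events: {recall:.2f}; false calls: {false}")
print("UP means higher inclusion in the slow condition; with 3 replicates at")
print("depth 200 the double criterion keeps the null call rate near zero.")
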