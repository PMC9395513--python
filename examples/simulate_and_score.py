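"""Simulate a reduced session with the synthetic agent and score it.

A 12-trial session (6 A, 6 B, strictly alternating) is generated by an
agent with a 3-item memory span, then scored from the mouse data alone:
per-trial completion under the 12-item criterion, response time, and the
percentage-of-completion (PC) summary with B/A ratios.
"""

from ctmt.agent import AgentParameters, simulate_session
from ctmt.performance import aggregate_performance
from ctmt.pipeline import analyze_session
from ctmt.stimuli import GridSpec, generate_layout_set

grid = GridSpec()
layouts, _ = generate_layout_set(grid, 12, seed=3)
sess = simulate_session(AgentParameters(), layouts, seed=42, trials_per_block=4)

out = analyze_session(sess.trials)
results = [an.result for an in out["analyses"]]
for r in results[:4]:
    rt = f"{r.rt_s:.2f} s" if r.rt_s is not None else "--"
    print(f"type {r.trial_type}: completed={r.completed} correct={r.correct} "
          f"rt={rt} items={r.n_concatenated}")
print("...")

agg = aggregate_performance(results)
print(f"\nPC-A = {agg['A']['pc']:.0f}%   PC-B = {agg['B']['pc']:.0f}%")
print(f"median RT-A = {agg['A']['rt_median_s']:.2f} s   "
      f"median RT-B = {agg['B']['rt_median_s']:.2f} s")
if agg.get("completion_ratio") is not None:
    print(f"Completion Ratio (PC-B/PC-A) = {agg['completion_ratio']:.2f}")
if agg.get("rt_ratio") is not None:
    print(f"RT Ratio (RT-B/RT-A)         = {agg['rt_ratio']:.2f}")
# Ratios near 1 are expected here: the synthetic agent treats A and B
# trails identically, unlike human participants.
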