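"""Operant sessions: FR1 with a 10-s stimulation pause, then progressive ratio.

Scores Poisson poking agents through both schedules: each active-port poke
during stimulation earns a 10-s pause (FR1), or an exponentially growing
number of pokes is required per pause (progressive ratio,
round(5 e^{0.2 j} - 5)).
"""

import fiberphot as fp
from fiberphot.operant import progressive_ratio_schedule

print("progressive-ratio schedule (rewards 1-12):", progressive_ratio_schedule(12))
print(f"maximum rewards in a 10-min FR1 session:  {fp.max_rewards(600.0, 10.0)}")

# an engaged agent: 1 active poke/s, occasional inactive pokes
events = fp.generate_operant_events(1.0, 0.1, 600.0, seed=5)
fr1 = fp.score_session(events, "FR1_pause", 600.0)
print(f"\nFR1, 10 min, eager agent: {fr1.rewards} pauses earned "
      f"({fr1.active_count} active / {fr1.inactive_count} inactive pokes, "
      f"first poke at {fr1.latency_first_active_s:.1f} s)")

pr_events = fp.generate_operant_events(0.5, 0.05, 1800.0, seed=5)
pr = fp.score_session(pr_events, "progressive_ratio", 1800.0)
print(f"PR, 30 min, same agent:   {pr.rewards} pauses, "
      f"breakpoint {pr.breakpoint}, next requirement {pr.next_requirement}")
# Cumulative records (pr.cumulative_active, pr.cumulative_rewards) are
# per-second step functions ready for cumulative-record plots.
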