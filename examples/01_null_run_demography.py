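"""Run the bare (NULL) model and read off its female demography.

Simulates 20,000 steps without any care interactions, estimates the female
period life table over the last 2,000 steps, and prints survivorship-derived
statistics.  PrR (post-reproduction representation) near zero means females
die soon after their last birth — no post-reproductive lifespan.
"""

import pprls

config = pprls.make_config(pprls.ConditionPreset.from_name("NULL"))
result = pprls.run(config, n_steps=20_000, rng=0, windows=[(18_000, 20_000)])
print(f"status: {result.status}; mean census {result.n.mean():.0f}; "
      f"famine on {100 * result.famine.mean():.0f}% of steps")

table = pprls.life_table_from_tally(result.tallies[0])
metrics = pprls.pprls_metrics(table)
print(f"infant survival l_2 = {table.l[2]:.3f} "
      f"(drop of {100 * (1 - table.l[2]):.0f}% across the dependent stages)")
print(f"lifetime fecundity m_tot = {metrics.m_tot:.2f}; "
      f"m_tot * l_2 = {metrics.product:.2f}")
print(f"reproduction spans stages B={metrics.B} to E={metrics.E}")
print(f"PrT = {metrics.PrT:.2f} steps; PrR = {metrics.PrR:.3f} "
      f"(PPRLS requires PrR > {metrics.cutoff})")
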