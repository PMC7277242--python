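"""Compare the bare model against a PPRLS-generating care condition.

Runs NULL (no care) and LTs+GM (survival-enhancing long-term care plus
grandmother-care) for a single 100,000-step replicate each — just past the
relaxation period, about 3 minutes per condition — and prints the PrR of
the three final sampling windows.

Under the full protocol (5 replicates x 200,000 steps) LTs+GM is one of
the two conditions whose mean PrR clears the 0.20 PPRLS cut-off while
NULL stays near 0.05; at this single-replicate scale the divergence is
just emerging, so expect LTs+GM to sit above NULL without yet reaching
the cut-off.
"""

import pprls

windows = [(t - 10_000, t) for t in (60_000, 80_000, 100_000)]

for name in ("NULL", "LTs+GM"):
    config = pprls.make_config(pprls.ConditionPreset.from_name(name))
    result = pprls.run(config, n_steps=100_000, rng=13, windows=windows)
    prrs = []
    for window, tally in zip(result.windows, result.tallies):
        table = pprls.life_table_from_tally(tally, window)
        prrs.append(pprls.pprls_metrics(table).PrR)
    shown = ", ".join(f"t={w[1]}: {p:.3f}" for w, p in zip(windows, prrs))
    print(f"{name:8s} PrR {shown}")
print("\nPrR is the share of adult female life lived beyond the last "
      "birth; > 0.20 would indicate PPRLS.")
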