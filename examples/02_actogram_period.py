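"""Estimate a free-running period from a simulated locomotor actogram.

Generates beam-break counts (1-min bins) for a mouse entrained 7 days to
a 12:12 light-dark cycle and then released into constant darkness with an
intrinsic period of 23.96 h, and recovers that period with the
chi-squared periodogram applied to the first week of darkness.
"""

from chronosim import estimate_free_running_period, gen_actogram

acto = gen_actogram(period=23.96, days_LD=7, days_DD=10,
                    mean_rate=2.0, nocturnality=5.0, seed=42)
print(f"actogram: {acto.days} days, {len(acto.counts)} one-minute bins, "
      f"{int(acto.counts.sum())} total beam breaks")

est = estimate_free_running_period(acto, window_days=7)
print(f"estimated free-running period: {est.period:.2f} h "
      f"(true 23.96 h; grid resolution 0.1 h)")
print(f"folded-profile relative amplitude: {est.relative_amplitude:.2f}")
# The periodogram tests every candidate period on a 0.1-h grid between 20
# and 28 h; the estimate is the significant period with the largest excess
# over its chi-square threshold, so agreement within one grid step is the
# best achievable.
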