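"""Calibrate the demand process from survey proportions.

Loads the packaged eight-wave CLHLS series (share of the oldest-old
living in nursing homes, 1998-2018), computes the period-on-period
relative changes, and calibrates the GBM drift and volatility that the
valuation scenarios use.
"""

from careoptions import clhls_waves, estimate_gbm, round_half_up

series = clhls_waves()
result = estimate_gbm(series, delta_y=3.0)

print("wave   proportion (%)   omega     (omega - mean)^2")
table = result.summary()
for i, year in enumerate(series.years):
    prop = round_half_up(series.proportions[i], 2)
    if i == 0:
        print(f"{year}   {prop:10.2f}")
    else:
        row = table.iloc[i - 1]
        print(f"{year}   {prop:10.2f}   {round_half_up(row['omega'], 2):6.2f}   {round_half_up(row['sq_deviation'], 2):10.2f}")

print()
print(f"mean omega = {result.omega_mean:.6f} over {result.n - 1} intervals of {result.delta_y:.0f} years")
print(f"drift  alpha = {result.drift:.6f} per year  -> {round_half_up(result.drift, 3):.3f}")
print(f"volatility sigma = {result.volatility:.6f} per year  -> {round_half_up(result.volatility, 2):.2f}")
print()
print("These are the (alpha, sigma) = (0.005, 0.12) of the baseline scenario.")
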