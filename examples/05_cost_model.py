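"""Cost of periodic cohort-wide data collection for a community.

A district of 150,000 people with a crude birth rate of 1% sees about
1,500 children enter school each year; at 20 per child (mostly teacher
time buy-out) a triennial assessment wave costs 30,000, i.e. 10,000 a year.
"""

from sedi import cost_model

est = cost_model(population=150_000, crude_birth_rate=0.01,
                 per_child_cost=20.0, wave_interval_years=3)
print(f"entry cohort per wave : {est.cohort_size_per_wave:,.0f} children")
print(f"cost per wave         : {est.per_wave_cost:,.0f} {est.currency}")
print(f"annualized cost       : {est.annualized_cost:,.0f} {est.currency}")
print("The annualized figure spreads one wave's cost over the interval")
print("between waves, for comparison with yearly programme budgets.")
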