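# Baseline ECSP scenario: a 300-bed project under the standard numerical
# example. Keys are the conventional symbols; units: CNY, years, beds.
I_t: 60000000     # investment cost
P: 36000          # price per elder-year
T: 30             # project lifetime, years
N_s: 300          # beds
S_cs: 12000       # construction subsidy per bed (one-time)
S_ps: 4800        # operating subsidy per elder-year
rho: 0.9          # construction pass-through under quality supervision
theta: 0.9        # operating pass-through
mu: 1.2           # premium cost coefficient (care intensity)
r: 0.1            # risk-free rate
alpha: 0.005      # demand drift per year
sigma: 0.12       # demand volatility per year
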