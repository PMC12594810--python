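"""Map nozzle flow conditions to the average in-jet shear rate.

Evaluates the Hagen-Poiseuille relation gamma = 4Q/(2*pi*R^3) for a
100 um-diameter HVE nozzle at typical flow rates, and inverts it to
find the flow rate that reproduces the jet-testing shear rate.
"""

from rheojet import flow_rate_for_shear, order_of_magnitude, shear_rate_hp

R = 50.0  # inner radius in um (100 um nozzle diameter)
for q in (0.5, 1.0, 1.5):  # uL/min, the jet-testing flow rates
    gamma = shear_rate_hp(q, R)
    print(f"Q = {q:.1f} uL/min -> gamma = {gamma:6.1f} 1/s "
          f"(~10^{order_of_magnitude(gamma)})")

q = flow_rate_for_shear(47.5, R)
print(f"gamma = 47.5 1/s (jet-shear reference) -> Q = {q:.2f} uL/min")

# at the stable 0.5 uL/min condition the jet runs near 42 1/s, i.e.
# order 10^2: the jet-shear reference viscosity (75.4 1/s) probes the
# right regime
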