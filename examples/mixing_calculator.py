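"""Program an in-channel concentration with two co-flowing inlets.

A two-inlet laminar-flow reactor mixes a subcritical and a supercritical
monomer solution; the downstream concentration is the flow-weighted mean of
the inlet concentrations. This script reproduces the two experimental
mixtures (the cycloFF critical-concentration determination and the FF
critical hold) and then solves the inverse problem: which flow split hits
the FF critical concentration exactly.
"""

from peptube.units import (
    CYCLOFF,
    FF,
    InletStream,
    MixingSpec,
    flow_rates_for_target,
    mixed_concentration,
    round_half_up,
    to_millimolar,
)

# cycloFF in DMSO: 0.5 mg/ml at 1.9 ul/h against 4.0 mg/ml at 2.1 ul/h.
spec = MixingSpec([InletStream(0.5, 1.9, "mg/ml"), InletStream(4.0, 2.1, "mg/ml")])
c_mg = mixed_concentration(spec)
print(
    f"cycloFF mixture: {round_half_up(c_mg)} mg/ml "
    f"({round_half_up(to_millimolar(c_mg, CYCLOFF))} mM)"
)
# -> 2.34 mg/ml: the length-holding (critical) concentration of cycloFF.

# FF in water: 3.20 mM at 2.2 ul/h against 1.60 mM at 1.7 ul/h.
spec = MixingSpec([InletStream(3.20, 2.2), InletStream(1.60, 1.7)])
print(f"FF mixture of printed flow rates: {round_half_up(mixed_concentration(spec))} mM")
# -> 2.50 mM: slightly above the targeted 2.43 mM critical concentration,
#    because the printed flow rates are rounded.

# Inverse problem: exact flow split for the FF critical concentration
# (2.43 mM == 0.76 mg/ml) at the same 3.9 ul/h total flow.
q_low, q_high = flow_rates_for_target(1.60, 3.20, to_millimolar(0.76, FF), 3.9)
print(f"exact split for 2.43 mM: low {q_low:.3f} ul/h, high {q_high:.3f} ul/h")
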