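"""Simulate single filaments in an open (flowing) monomer bath.

Under continuous flow the free-monomer concentration is fixed, so a
filament drifts at the net rate k_on*c - k_off forever (no equilibrium).
The FF-like preset puts all kinetics on one face: growth and shrinkage are
unidirectional. Three runs reproduce the three flow regimes: supercritical
(growth), critical (length hold), subcritical (shrinkage to dissolution).
"""

from peptube.kinetics import FF_KINETICS, critical_concentration, net_growth_rate
from peptube.simulator import BathConfig, ff_filament, simulate

cs = critical_concentration(FF_KINETICS)
for label, c in (("supercritical", 3.20), ("critical", cs), ("subcritical", 1.60)):
    fil = ff_filament(initial_length_um=20.0)
    trace = simulate(fil, BathConfig(mode="open", c0=c, t_max_min=8.0, seed=1))
    L0 = trace.pos_B0 - trace.pos_A0
    L1 = trace.length_um[-1] if trace.n_events else L0
    print(
        f"{label:13s} c={c:.2f} mM: {trace.n_events:6d} events, "
        f"length {L0:.1f} -> {L1:5.1f} um in {trace.t_final:.1f} min "
        f"({trace.status}); analytic rate {net_growth_rate(c, FF_KINETICS):+.2f} um/min"
    )
# Growth at one face only: every event in these traces happens at the O end
# (terminus B); the N end is silent under the FF preset.
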