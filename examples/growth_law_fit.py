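"""Fit the linear growth law R = k_on*c - k_off to a rate table.

Net filament growth rates measured at several monomer concentrations fall
on a line whose slope is the elongation rate constant k_on, whose negated
intercept is the dissociation rate k_off, and whose zero crossing is the
critical concentration c_s = k_off/k_on.
"""

import numpy as np

from peptube.kinetics import FF_KINETICS, critical_concentration, fit_growth_law, net_growth_rate
from peptube.units import round_half_up

rng = np.random.default_rng(7)
conc = np.linspace(1.6, 3.2, 5)  # mM, sub- to supercritical
rates = [net_growth_rate(c, FF_KINETICS) + rng.normal(0, 0.1) for c in conc]

fit = fit_growth_law(conc, rates)
print(f"k_on  = {fit.params.k_on:.3f} +/- {fit.se_k_on:.3f} um/min/mM")
print(f"k_off = {fit.params.k_off:.3f} +/- {fit.se_k_off:.3f} um/min")
print(f"R^2   = {fit.r_squared:.4f}")
print(f"critical concentration = {round_half_up(critical_concentration(fit.params), 2)} mM")
# The estimates should sit near the generating values (3.36, 7.4), and the
# zero crossing near 7.4/3.36 = 2.2 mM: below that concentration tubes
# shrink, above it they grow.
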