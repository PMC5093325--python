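"""Shared test utilities."""

import numpy as np

from peptube.simulator import BathConfig, simulate


def ensemble_net_rates(filament, c, n_seeds, t_max, seed_base):
    """Per-seed net growth rates (μm/min) of an open-bath ensemble."""
    L0 = filament.initial_layers * filament.layer_um
    out = np.empty(n_seeds)
    for i in range(n_seeds):
        tr = simulate(filament, BathConfig("open", c, t_max, seed_base + i))
        L_end = tr.length_um[-1] if tr.n_events else L0
        out[i] = (L_end - L0) / t_max
    return out


def recompute_concentration(trace):
    """Free concentration recomputed from the event list (mass bookkeeping)."""
    net = np.cumsum(
        np.where(trace.etypes == 0, 1, np.where(trace.etypes == 1, -1, 0))
    )
    return trace.bath.c0 - trace.bath.depletion_quantum_mM * net
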