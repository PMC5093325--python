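"""Concentration units and laminar co-flow mixing arithmetic.

Peptide concentrations are quoted interchangeably in mg/ml and mM in the
supramolecular-assembly literature; this module holds the conversion factor
(the monomer molar mass) and the flow-weighted mixing rule used to program
the in-channel monomer concentration of a two-inlet microfluidic reactor.

Two conventions apply throughout:

* every concentration value carries an explicit unit tag (``"mg/ml"`` or
  ``"mM"``); combining values with different tags raises
  :class:`~peptube.errors.UnitMismatchError` instead of silently converting;
* rounding (half-up, matching how concentrations are printed in reports)
  happens only at presentation boundaries via :func:`round_half_up` — all
  arithmetic is done at full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from .errors import ConfigError, UnitMismatchError, UnreachableTargetError

__all__ = [
    "MG_PER_ML",
    "MILLIMOLAR",
    "Compound",
    "FF",
    "CYCLOFF",
    "InletStream",
    "MixingSpec",
    "round_half_up",
    "to_millimolar",
    "to_mass_concentration",
    "mixed_concentration",
    "flow_rates_for_target",
    "compound_from_dict",
    "mixing_spec_from_dict",
]

#: Unit tag for mass concentration (mg per ml).
MG_PER_ML = "mg/ml"
#: Unit tag for molar concentration (millimolar).
MILLIMOLAR = "mM"

_UNITS = (MG_PER_ML, MILLIMOLAR)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round ``x`` half-up to ``ndigits`` decimals (2.435 -> 2.44).

    Python's builtin ``round`` uses banker's rounding; printed concentration
    values follow the half-up convention instead, so reported numbers use
    this helper. Only for presentation — never applied inside computations.
    """
    if not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Compound:
    """A monomeric building block identified by its molar mass.

    Parameters
    ----------
    name
        Short label, e.g. ``"FF"``.
    molar_mass
        Molar mass in g/mol; must be strictly positive.
    """

    name: str
    molar_mass: float

    def __post_init__(self) -> None:
        if not (self.molar_mass > 0):
            raise ConfigError(
                f"molar_mass must be > 0 g/mol, got {self.molar_mass!r}"
            )


#: Diphenylalanine (H-Phe-Phe-OH), assembles into nanotubes in water.
FF = Compound("FF", 312.4)
#: Cyclo-(Phe-Phe), assembles into needle-like crystals in DMSO.
CYCLOFF = Compound("cycloFF", 294.3)


def to_millimolar(c_mass: float, compound: Compound) -> float:
    """Convert a mass concentration (mg/ml) to millimolar.

    mg/ml divided by g/mol gives mol/l after the factor 1000; e.g. FF at
    0.76 mg/ml is 2.43 mM once rounded for presentation.
    """
    if c_mass < 0:
        raise ConfigError(f"mass concentration must be >= 0, got {c_mass!r}")
    return c_mass / compound.molar_mass * 1000.0


def to_mass_concentration(c_molar: float, compound: Compound) -> float:
    """Convert a molar concentration (mM) to mg/ml (inverse of
    :func:`to_millimolar`, exact before rounding)."""
    if c_molar < 0:
        raise ConfigError(f"molar concentration must be >= 0, got {c_molar!r}")
    return c_molar * compound.molar_mass / 1000.0


@dataclass(frozen=True)
class InletStream:
    """One inlet of the flow reactor.

    Parameters
    ----------
    concentration
        Monomer concentration of the injected solution (non-negative), in
        the unit given by ``unit``.
    flow_rate
        Volumetric flow rate in μl/h, non-negative.
    unit
        Concentration unit tag, ``"mM"`` or ``"mg/ml"``.
    """

    concentration: float
    flow_rate: float
    unit: str = MILLIMOLAR

    def __post_init__(self) -> None:
        if self.unit not in _UNITS:
            raise UnitMismatchError(
                f"unknown concentration unit {self.unit!r}; expected one of {_UNITS}"
            )
        if self.concentration < 0:
            raise ConfigError(
                f"stream concentration must be >= 0, got {self.concentration!r}"
            )
        if self.flow_rate < 0:
            raise ConfigError(f"flow rate must be >= 0, got {self.flow_rate!r}")


@dataclass(frozen=True)
class MixingSpec:
    """An ordered collection of inlet streams sharing one concentration unit.

    The downstream (fully mixed) concentration is the flow-weighted mean of
    the stream concentrations — complete mixing in the laminar channel is
    assumed, as established empirically with dye co-injection in the device
    this models. At least one stream must carry flow.
    """

    streams: tuple[InletStream, ...]

    def __init__(self, streams: Iterable[InletStream]) -> None:
        object.__setattr__(self, "streams", tuple(streams))
        if not self.streams:
            raise ConfigError("MixingSpec needs at least one stream")
        units = {s.unit for s in self.streams}
        if len(units) > 1:
            raise UnitMismatchError(
                f"all streams must share one unit, got {sorted(units)}"
            )
        if not any(s.flow_rate > 0 for s in self.streams):
            raise ConfigError("at least one stream must have flow_rate > 0")

    @property
    def unit(self) -> str:
        return self.streams[0].unit

    @property
    def total_flow(self) -> float:
        return sum(s.flow_rate for s in self.streams)


def mixed_concentration(spec: MixingSpec) -> float:
    """Flow-weighted mean concentration Σ(cᵢqᵢ)/Σqᵢ of a mixing spec.

    The result is in the shared unit of the streams, bounded by the extreme
    stream concentrations, and invariant under stream permutation and under
    uniform scaling of all flow rates.
    """
    q = spec.total_flow
    return sum(s.concentration * s.flow_rate for s in spec.streams) / q


def flow_rates_for_target(
    c_low: float, c_high: float, c_target: float, q_total: float
) -> tuple[float, float]:
    """Split ``q_total`` between two inlets to hit a target concentration.

    Solves the inverse mixing problem for two streams at concentrations
    ``c_low < c_high``: returns ``(q_low, q_high)`` with
    ``q_low + q_high = q_total`` such that the flow-weighted mean equals
    ``c_target``. The target must lie in ``[c_low, c_high]``.
    """
    if not c_low < c_high:
        raise ConfigError(f"need c_low < c_high, got {c_low!r} >= {c_high!r}")
    if not q_total > 0:
        raise ConfigError(f"q_total must be > 0, got {q_total!r}")
    if not (c_low <= c_target <= c_high):
        raise UnreachableTargetError(
            f"target {c_target!r} outside the reachable band "
            f"[{c_low!r}, {c_high!r}]"
        )
    frac_high = (c_target - c_low) / (c_high - c_low)
    q_high = q_total * frac_high
    return q_total - q_high, q_high


# ---------------------------------------------------------------------------
# YAML-facing constructors (plain dicts; loading the file is the caller's job)

def compound_from_dict(d: dict) -> Compound:
    """Build a :class:`Compound` from ``{"name": ..., "molar_mass_g_per_mol": ...}``.

    ``name`` may also be one of the built-ins (``"FF"``/``"cycloFF"``,
    case-insensitive), in which case the molar mass key is optional.
    """
    name = d.get("name")
    if "molar_mass_g_per_mol" in d:
        return Compound(name, float(d["molar_mass_g_per_mol"]))
    builtin = {"ff": FF, "cycloff": CYCLOFF}.get(str(name).lower())
    if builtin is None:
        raise ConfigError(
            f"unknown compound {name!r} and no molar_mass_g_per_mol given"
        )
    return builtin


def mixing_spec_from_dict(d: dict | Sequence[dict]) -> MixingSpec:
    """Build a :class:`MixingSpec` from config-style stream dicts.

    Accepts either ``{"streams": [...]}`` or the bare stream list; each
    stream is ``{"conc": float, "unit": "mM"|"mg/ml", "flow_ul_per_h": float}``.
    """
    raw = d["streams"] if isinstance(d, dict) else d
    streams = [
        InletStream(
            concentration=float(s["conc"]),
            flow_rate=float(s["flow_ul_per_h"]),
            unit=s.get("unit", MILLIMOLAR),
        )
        for s in raw
    ]
    return MixingSpec(streams)
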