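"""Synthetic observation-level datasets emulating the imaging protocol.

Real data for this problem are time-lapse micrographs of individual
filaments whose end positions are measured by hand: each terminus is
measured five times per time point and the five reads are averaged. This
module reproduces that statistical structure on top of simulated event
traces:

* frames are sampled at a fixed interval by zero-order hold on the event
  trace (lengths are constant between discrete attach/detach events), with
  the left-closed convention that a frame falling exactly on an event time
  reports the post-event position;
* each reported frame position is the mean of ``n_repeats`` independent
  Gaussian reads of SD ``sigma_um``, so the reported position has SD
  ``sigma_um/sqrt(n_repeats)``, and the replicate SD is reported alongside;
* an experiment is a grid of concentration conditions with a fixed number
  of filaments (tubes) per condition, each simulated in an open bath and
  observed, mirroring rate-versus-concentration experiments that average
  the growth rates of ten termini per concentration.

The on-disk format is one fixed CSV dialect shared by all modules:
comma-separated, UTF-8, '.' decimal, header row required, columns
``tube_id, terminus (A|B), time_min, position_um, replicate_sd_um, conc_mM``
(an optional ``seed`` column preserves per-tube observation seeds).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, SchemaError, TraceValidationError
from .kinetics import CYCLOFF_KINETICS, FF_KINETICS, KineticParameters
from .simulator import (
    BathConfig,
    EndKinetics,
    FilamentConfig,
    SimTrace,
    simulate,
)

__all__ = [
    "REQUIRED_COLUMNS",
    "MeasurementModel",
    "ExperimentDesign",
    "observe",
    "filament_for_design",
    "generate_experiment",
    "write_traces",
    "read_traces",
    "validate_traces",
    "design_to_dict",
    "design_from_dict",
    "design_from_yaml",
    "design_to_yaml",
]

REQUIRED_COLUMNS = (
    "tube_id",
    "terminus",
    "time_min",
    "position_um",
    "replicate_sd_um",
    "conc_mM",
)


@dataclass(frozen=True)
class MeasurementModel:
    """Observation-noise model of the manual length measurement.

    ``sigma_um`` is the SD of a single measurement read (Gaussian, iid);
    ``n_repeats`` reads are averaged per terminus per time point (default 5,
    matching the imaging protocol); frames are ``frame_interval_min``
    minutes apart.
    """

    sigma_um: float = 0.25
    n_repeats: int = 5
    frame_interval_min: float = 0.5

    def __post_init__(self) -> None:
        if self.sigma_um < 0:
            raise ConfigError(f"sigma_um must be >= 0, got {self.sigma_um!r}")
        if self.n_repeats < 1:
            raise ConfigError(f"n_repeats must be >= 1, got {self.n_repeats!r}")
        if not self.frame_interval_min > 0:
            raise ConfigError(
                f"frame_interval_min must be > 0, got {self.frame_interval_min!r}"
            )


def _frame_positions(trace: SimTrace, frame_times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """True terminus positions at frame times (zero-order hold, left-closed)."""
    if trace.n_events == 0:
        return (
            np.full(frame_times.shape, trace.pos_A0),
            np.full(frame_times.shape, trace.pos_B0),
        )
    idx = np.searchsorted(trace.times, frame_times, side="right") - 1
    pA = np.where(idx >= 0, trace.pos_A[np.clip(idx, 0, None)], trace.pos_A0)
    pB = np.where(idx >= 0, trace.pos_B[np.clip(idx, 0, None)], trace.pos_B0)
    return pA, pB


def observe(
    trace: SimTrace,
    model: MeasurementModel,
    seed: int | np.random.SeedSequence,
    tube_id: str = "tube-0",
) -> pd.DataFrame:
    """Frame-sample and noise-average one event trace.

    Returns a DataFrame in the shared CSV dialect with one row per
    (frame, terminus). Per-terminus noise streams are spawned from ``seed``
    so terminus A and B reads are independent.
    """
    n_frames = int(np.floor(trace.t_final / model.frame_interval_min + 1e-9)) + 1
    frame_times = np.arange(n_frames) * model.frame_interval_min
    pA, pB = _frame_positions(trace, frame_times)

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss_A, ss_B = ss.spawn(2)
    rows = []
    for terminus, truth, sub in (("A", pA, ss_A), ("B", pB, ss_B)):
        if model.sigma_um > 0:
            rng = np.random.default_rng(sub)
            reads = truth[:, None] + rng.normal(
                0.0, model.sigma_um, size=(n_frames, model.n_repeats)
            )
            mean = reads.mean(axis=1)
            sd = reads.std(axis=1, ddof=1) if model.n_repeats > 1 else np.zeros(n_frames)
        else:
            mean = truth.copy()
            sd = np.zeros(n_frames)
        rows.append(
            pd.DataFrame(
                {
                    "tube_id": tube_id,
                    "terminus": terminus,
                    "time_min": frame_times,
                    "position_um": mean,
                    "replicate_sd_um": sd,
                    "conc_mM": trace.bath.c0,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class ExperimentDesign:
    """A rate-versus-concentration experiment on synthetic filaments.

    For each concentration, ``termini_per_condition`` filaments are
    simulated in an open bath for ``duration_min`` minutes and observed
    under ``measurement``. ``params`` is the ground-truth growth law;
    ``preset`` decides how it splits across the two faces: ``"ff"`` puts
    all rates on the fast O face (strongly asymmetric, unidirectional
    growth), ``"cycloff"`` splits them equally (symmetric, bidirectional).

    Per-tube sub-seeds are derived from ``master_seed`` with
    ``numpy.random.SeedSequence((master_seed, condition_index, tube_index,
    stream))`` (stream 0 = simulation, 1 = observation, whose per-terminus
    children are spawned inside :func:`observe`), so datasets are
    reproducible independent of iteration order.
    """

    concentrations_mM: tuple[float, ...]
    termini_per_condition: int = 10
    duration_min: float = 10.0
    params: KineticParameters = FF_KINETICS
    preset: str = "ff"
    measurement: MeasurementModel = field(default_factory=MeasurementModel)
    master_seed: int = 0
    layer_um: float = 0.05
    initial_length_um: float = 60.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "concentrations_mM", tuple(float(c) for c in self.concentrations_mM)
        )
        if not self.concentrations_mM:
            raise ConfigError("concentration list must not be empty")
        if self.preset not in ("ff", "cycloff"):
            raise ConfigError(f"preset must be 'ff' or 'cycloff', got {self.preset!r}")
        if self.termini_per_condition < 1:
            raise ConfigError("termini_per_condition must be >= 1")
        if self.master_seed < 0:
            raise ConfigError("master_seed must be >= 0")

    @classmethod
    def ff_default(cls, master_seed: int = 0) -> "ExperimentDesign":
        """Default FF-like design: five concentrations spanning the
        1.60–3.20 mM band used experimentally (sub- to supercritical around
        c_s ≈ 2.2 mM), ten tubes each, 10 min at 30 s frames."""
        return cls(
            concentrations_mM=tuple(np.linspace(1.60, 3.20, 5)),
            duration_min=10.0,
            params=FF_KINETICS,
            preset="ff",
            measurement=MeasurementModel(frame_interval_min=0.5),
            master_seed=master_seed,
            initial_length_um=60.0,
        )

    @classmethod
    def cycloff_default(cls, master_seed: int = 0) -> "ExperimentDesign":
        """Default cycloFF-like design: five concentrations spanning the
        1.70–13.59 mM band (c_s ≈ 8 mM), slower frames over a longer run to
        match the slower kinetics."""
        return cls(
            concentrations_mM=tuple(np.linspace(1.70, 13.59, 5)),
            duration_min=60.0,
            params=CYCLOFF_KINETICS,
            preset="cycloff",
            measurement=MeasurementModel(frame_interval_min=4.0),
            master_seed=master_seed,
            initial_length_um=80.0,
        )


def filament_for_design(design: ExperimentDesign) -> FilamentConfig:
    """Filament configuration realizing the design's truth under its preset."""
    p = design.params
    if design.preset == "ff":
        end_O = EndKinetics(p.k_on, p.k_off)
        end_N = EndKinetics(0.0, 0.0)
    else:
        end_O = end_N = EndKinetics(p.k_on / 2, p.k_off / 2)
    return FilamentConfig(
        end_O=end_O,
        end_N=end_N,
        layer_um=design.layer_um,
        initial_length_um=design.initial_length_um,
    )


def _subseed(design: ExperimentDesign, ci: int, ti: int, stream: int):
    return np.random.SeedSequence(
        (design.master_seed, ci, ti, stream)
    )


def generate_experiment(design: ExperimentDesign) -> pd.DataFrame:
    """Simulate and observe every tube of the design.

    Returns one DataFrame in the shared dialect (plus a ``seed`` column
    with each tube's observation sub-seed entropy) containing
    ``len(concentrations) * termini_per_condition`` observed traces.
    Deterministic under the master seed.
    """
    fil = filament_for_design(design)
    parts = []
    for ci, c in enumerate(design.concentrations_mM):
        for ti in range(design.termini_per_condition):
            sim_seed = int(_subseed(design, ci, ti, 0).generate_state(1)[0])
            bath = BathConfig(
                mode="open", c0=c, t_max_min=design.duration_min, seed=sim_seed
            )
            trace = simulate(fil, bath)
            obs = observe(
                trace,
                design.measurement,
                _subseed(design, ci, ti, 1),
                tube_id=f"c{ci}_t{ti}",
            )
            obs["seed"] = int(_subseed(design, ci, ti, 1).generate_state(1)[0])
            parts.append(obs)
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# CSV dialect I/O

def validate_traces(df: pd.DataFrame) -> None:
    """Validate a trace table against the shared dialect.

    Raises :class:`SchemaError` for missing required columns and
    :class:`TraceValidationError` for duplicated or non-monotone time stamps
    within a (tube, terminus) series.
    """
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    if df.empty:
        raise SchemaError("trace table has no rows")
    bad = set(df["terminus"].unique()) - {"A", "B"}
    if bad:
        raise TraceValidationError(f"terminus labels must be A or B, got {sorted(bad)}")
    for (tube, term), grp in df.groupby(["tube_id", "terminus"], sort=False):
        t = grp["time_min"].to_numpy(dtype=float)
        if np.any(np.diff(t) == 0):
            raise TraceValidationError(
                f"duplicated time stamps in tube {tube!r} terminus {term}"
            )
        if np.any(np.diff(t) < 0):
            raise TraceValidationError(
                f"non-monotone times in tube {tube!r} terminus {term}"
            )


def write_traces(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a validated trace table to CSV (shared dialect)."""
    validate_traces(df)
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_traces(path: str | Path) -> pd.DataFrame:
    """Read and validate a trace table from CSV (shared dialect)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty trace file: {path}") from exc
    validate_traces(df)
    return df


# ---------------------------------------------------------------------------
# design (de)serialization

def design_to_dict(design: ExperimentDesign) -> dict:
    return {
        "concentrations_mM": list(design.concentrations_mM),
        "termini_per_condition": design.termini_per_condition,
        "duration_min": design.duration_min,
        "k_on": design.params.k_on,
        "k_off": design.params.k_off,
        "preset": design.preset,
        "sigma_um": design.measurement.sigma_um,
        "n_repeats": design.measurement.n_repeats,
        "frame_interval_min": design.measurement.frame_interval_min,
        "master_seed": design.master_seed,
        "layer_um": design.layer_um,
        "initial_length_um": design.initial_length_um,
    }


def design_from_dict(d: Mapping) -> ExperimentDesign:
    base: ExperimentDesign | None = None
    if "preset" in d and "concentrations_mM" not in d:
        base = (
            ExperimentDesign.ff_default()
            if d["preset"] == "ff"
            else ExperimentDesign.cycloff_default()
        )
    if base is not None:
        kwargs = {}
        mm_kwargs = {}
        for key in ("sigma_um", "n_repeats", "frame_interval_min"):
            if key in d:
                mm_kwargs[key] = d[key]
        if mm_kwargs:
            kwargs["measurement"] = replace(base.measurement, **mm_kwargs)
        for key in (
            "termini_per_condition", "duration_min", "master_seed",
            "layer_um", "initial_length_um",
        ):
            if key in d:
                kwargs[key] = d[key]
        return replace(base, **kwargs)
    params = KineticParameters(float(d["k_on"]), float(d["k_off"]))
    measurement = MeasurementModel(
        sigma_um=float(d.get("sigma_um", 0.25)),
        n_repeats=int(d.get("n_repeats", 5)),
        frame_interval_min=float(d.get("frame_interval_min", 0.5)),
    )
    return ExperimentDesign(
        concentrations_mM=tuple(d["concentrations_mM"]),
        termini_per_condition=int(d.get("termini_per_condition", 10)),
        duration_min=float(d.get("duration_min", 10.0)),
        params=params,
        preset=d.get("preset", "ff"),
        measurement=measurement,
        master_seed=int(d.get("master_seed", 0)),
        layer_um=float(d.get("layer_um", 0.05)),
        initial_length_um=float(d.get("initial_length_um", 60.0)),
    )


def design_from_yaml(path: str | Path) -> ExperimentDesign:
    with open(path) as fh:
        return design_from_dict(yaml.safe_load(fh))


def design_to_yaml(design: ExperimentDesign, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(design_to_dict(design), sort_keys=False))
    return path
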