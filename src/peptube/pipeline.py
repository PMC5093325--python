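"""End-to-end parameter-recovery pipeline and reporting.

``run_recovery`` ties the modules together: generate a synthetic
concentration-series experiment, estimate each terminus rate, average tube
growth rates per condition, fit the linear growth law, derive the critical
concentration with a delta-method confidence interval, and classify each
tube's growth directionality. Every number in the resulting
:class:`RecoveryReport` is recomputable from the design alone (the master
seed is part of the design), and the report round-trips losslessly through
JSON.

Statistical conventions
-----------------------
* The tube growth rate is the sum of the two outward terminus rates, i.e.
  the rate of change of the tube length; under either face-splitting preset
  its expectation is the design's growth law ``k_on·c − k_off``.
* The per-condition rate is the unweighted mean over tubes, its SE the
  sample SD over tubes divided by √n; those SEs feed the weighted fit as
  inverse variances (an unweighted option is exposed).
* Directionality is tallied across the whole experiment, so by default the
  per-end activity tests are Bonferroni-corrected to a family-wise level
  across all 2·n_tubes tests. An ensemble statement like "every tube grew
  unidirectionally" is a family-wise claim: at a fixed per-end level a
  fraction alpha of silent termini would be falsely called active no matter
  how good the data are. Pass ``multiplicity="none"`` for the uncorrected
  per-tube behaviour.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .kinetics import (
    EndRateEstimate,
    KineticParameters,
    RateFit,
    classify_directionality,
    critical_concentration,
    estimate_terminus_rate,
    fit_growth_law,
)
from .synthetic import ExperimentDesign, design_to_dict, design_from_dict, generate_experiment

logger = logging.getLogger(__name__)

__all__ = [
    "terminus_rate_table",
    "tube_rate_table",
    "delta_ci_critical_concentration",
    "RecoveryReport",
    "run_recovery",
]

_ORIENTATION = {"A": -1, "B": 1}


def terminus_rate_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per-(tube, terminus) outward rate estimates from an observed dataset.

    Expects the shared CSV dialect; returns columns
    ``tube_id, conc_mM, terminus, rate, se, n_frames``.
    """
    rows = []
    for (tube, term), grp in df.groupby(["tube_id", "terminus"], sort=False):
        est = estimate_terminus_rate(
            grp["time_min"].to_numpy(dtype=float),
            grp["position_um"].to_numpy(dtype=float),
            orientation=_ORIENTATION[term],
        )
        rows.append(
            {
                "tube_id": tube,
                "conc_mM": float(grp["conc_mM"].iloc[0]),
                "terminus": term,
                "rate": est.rate,
                "se": est.se,
                "n_frames": est.n_frames,
            }
        )
    return pd.DataFrame(rows)


def tube_rate_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per-tube rates: both terminus estimates plus the total growth rate.

    ``total_rate`` (= rate_A + rate_B, both outward-positive) is the length
    rate of the tube; ``se_total`` combines the two slope SEs in
    quadrature.
    """
    per_term = terminus_rate_table(df)
    wide = per_term.pivot_table(
        index=["tube_id", "conc_mM"],
        columns="terminus",
        values=["rate", "se", "n_frames"],
    )
    out = pd.DataFrame(
        {
            "rate_A": wide[("rate", "A")],
            "se_A": wide[("se", "A")],
            "rate_B": wide[("rate", "B")],
            "se_B": wide[("se", "B")],
        }
    ).reset_index()
    out["total_rate"] = out["rate_A"] + out["rate_B"]
    out["se_total"] = np.hypot(out["se_A"], out["se_B"])
    return out


def delta_ci_critical_concentration(
    fit: RateFit, level: float = 0.95
) -> tuple[float, float]:
    """First-order (delta-method) confidence interval for c_s = k_off/k_on.

    Propagates the fit covariance through the ratio; the interval is
    symmetric around the point estimate and approximate by construction
    (documented as such — the ratio is not normal for poorly determined
    k_on). Uses a Student-t quantile with the fit's residual degrees of
    freedom when available, the normal quantile otherwise. If k_on is
    within two SEs of zero, the interval is still returned but a warning is
    logged because the linearization is unreliable there.
    """
    if not 0 < level < 1:
        raise ConfigError(f"level must be in (0, 1), got {level!r}")
    k_on, k_off = fit.params.k_on, fit.params.k_off
    cs = critical_concentration(fit.params)
    if k_on <= 2 * fit.se_k_on:
        logger.warning(
            "k_on=%.4g is within 2 SE (%.4g) of zero; the delta-method "
            "interval for the critical concentration is unreliable",
            k_on,
            fit.se_k_on,
        )
        warnings.warn(
            "k_on within 2 SE of zero; critical-concentration CI is unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    var = (
        (k_off**2 / k_on**4) * fit.se_k_on**2
        + fit.se_k_off**2 / k_on**2
        - 2.0 * (k_off / k_on**3) * fit.cov_on_off
    )
    se = math.sqrt(max(var, 0.0))
    alpha = 1.0 - level
    if fit.df_resid is not None and fit.df_resid > 0:
        q = float(stats.t.ppf(1 - alpha / 2, fit.df_resid))
    else:
        q = float(stats.norm.ppf(1 - alpha / 2))
    return cs - q * se, cs + q * se


@dataclass
class RecoveryReport:
    """Everything the recovery experiment computed, JSON-serializable."""

    design: dict
    conditions: list[dict]
    fit: RateFit
    critical_concentration_mM: float
    critical_concentration_ci: tuple[float, float]
    ci_level: float
    directionality: dict[str, int]
    per_tube: list[dict]
    alpha: float
    per_end_alpha: float

    def to_dict(self) -> dict:
        return {
            "design": self.design,
            "conditions": self.conditions,
            "fit": {
                "k_on": self.fit.params.k_on,
                "k_off": self.fit.params.k_off,
                "se_k_on": self.fit.se_k_on,
                "se_k_off": self.fit.se_k_off,
                "r_squared": self.fit.r_squared,
                "n_points": self.fit.n_points,
                "cov_on_off": self.fit.cov_on_off,
                "df_resid": self.fit.df_resid,
            },
            "critical_concentration_mM": self.critical_concentration_mM,
            "critical_concentration_ci": list(self.critical_concentration_ci),
            "ci_level": self.ci_level,
            "directionality": self.directionality,
            "per_tube": self.per_tube,
            "alpha": self.alpha,
            "per_end_alpha": self.per_end_alpha,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RecoveryReport":
        f = d["fit"]
        fit = RateFit(
            params=KineticParameters(f["k_on"], f["k_off"]),
            se_k_on=f["se_k_on"],
            se_k_off=f["se_k_off"],
            r_squared=f["r_squared"],
            n_points=f["n_points"],
            cov_on_off=f["cov_on_off"],
            df_resid=f["df_resid"],
        )
        return cls(
            design=d["design"],
            conditions=d["conditions"],
            fit=fit,
            critical_concentration_mM=d["critical_concentration_mM"],
            critical_concentration_ci=tuple(d["critical_concentration_ci"]),
            ci_level=d["ci_level"],
            directionality=d["directionality"],
            per_tube=d["per_tube"],
            alpha=d["alpha"],
            per_end_alpha=d["per_end_alpha"],
        )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "RecoveryReport":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def summary(self) -> str:
        """Human-readable plain-text summary."""
        lines = [
            "Growth-law recovery report",
            "--------------------------",
            f"conditions: {len(self.conditions)}  tubes: {len(self.per_tube)}",
            (
                f"k_on  = {self.fit.params.k_on:.4g} +/- {self.fit.se_k_on:.2g} "
                "um/min/mM"
            ),
            f"k_off = {self.fit.params.k_off:.4g} +/- {self.fit.se_k_off:.2g} um/min",
            f"R^2 = {self.fit.r_squared:.4f}",
            (
                f"critical concentration = {self.critical_concentration_mM:.3g} mM "
                f"({self.ci_level:.0%} CI "
                f"{self.critical_concentration_ci[0]:.3g}"
                f"-{self.critical_concentration_ci[1]:.3g})"
            ),
            f"directionality tally: {self.directionality}",
        ]
        return "\n".join(lines)


def run_recovery(
    design: ExperimentDesign,
    alpha: float = 0.05,
    multiplicity: str = "bonferroni",
    weighted: bool = True,
    ci_level: float = 0.95,
) -> RecoveryReport:
    """Run the full synthetic recovery experiment for one design.

    Parameters
    ----------
    design
        Experiment design (includes the master seed: the report is a
        deterministic function of the design).
    alpha
        Significance level for directionality. With
        ``multiplicity="bonferroni"`` (default) this is the family-wise
        level across all per-end activity tests in the experiment;
        ``"none"`` applies it per end.
    weighted
        Weight the growth-law fit by inverse variance of the condition
        means (falls back to unweighted if any condition SE is zero).
    """
    if multiplicity not in ("bonferroni", "none"):
        raise ConfigError(f"multiplicity must be 'bonferroni' or 'none', got {multiplicity!r}")
    design_dict = design_to_dict(design)
    cfg_hash = hashlib.sha256(
        json.dumps(design_dict, sort_keys=True).encode()
    ).hexdigest()[:12]
    logger.info(
        "recovery run: master_seed=%d design_hash=%s", design.master_seed, cfg_hash
    )

    dataset = generate_experiment(design)
    tubes = tube_rate_table(dataset)
    n_tubes = len(tubes)

    conditions = []
    for c, grp in tubes.groupby("conc_mM", sort=True):
        rates = grp["total_rate"].to_numpy()
        n = rates.size
        se = float(rates.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        conditions.append(
            {
                "conc_mM": float(c),
                "mean_rate_um_per_min": float(rates.mean()),
                "se_rate_um_per_min": se,
                "n_tubes": int(n),
            }
        )
    cond_df = pd.DataFrame(conditions)
    weights = None
    if weighted and (cond_df["se_rate_um_per_min"] > 0).all():
        weights = 1.0 / cond_df["se_rate_um_per_min"] ** 2
    fit = fit_growth_law(
        cond_df["conc_mM"], cond_df["mean_rate_um_per_min"], weights=weights
    )
    cs = critical_concentration(fit.params)
    ci = delta_ci_critical_concentration(fit, level=ci_level)

    per_end_alpha = alpha / (2 * n_tubes) if multiplicity == "bonferroni" else alpha
    tally = {"unidirectional": 0, "bidirectional": 0, "stalled": 0, "indeterminate": 0}
    per_tube = []
    for row in tubes.itertuples(index=False):
        call = classify_directionality(
            EndRateEstimate(row.rate_A, row.se_A, 2),
            EndRateEstimate(row.rate_B, row.se_B, 2),
            alpha=per_end_alpha,
        )
        tally[call.label] += 1
        per_tube.append(
            {
                "tube_id": row.tube_id,
                "conc_mM": float(row.conc_mM),
                "rate_A": float(row.rate_A),
                "se_A": float(row.se_A),
                "rate_B": float(row.rate_B),
                "se_B": float(row.se_B),
                "total_rate": float(row.total_rate),
                "label": call.label,
                "z_statistic": float(call.z_statistic),
            }
        )

    return RecoveryReport(
        design=design_dict,
        conditions=conditions,
        fit=fit,
        critical_concentration_mM=cs,
        critical_concentration_ci=ci,
        ci_level=ci_level,
        directionality=tally,
        per_tube=per_tube,
        alpha=alpha,
        per_end_alpha=per_end_alpha,
    )
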