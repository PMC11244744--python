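"""Synthetic cohorts with known ground truth.

The generator emulates the joint structure the imbalance model assumes:

* a bimodal amyloid-burden distribution along the curve (a two-component
  truncated-normal mixture of arc positions on the Centiloid axis, mimicking
  the characteristic amyloid-negative / amyloid-positive clusters);
* a strictly decreasing hyperbolic CSF–PET relationship (the truth curve,
  defaulting to a mass-spectrometry-scale configuration: CSF in pg/mL falling
  from ≈3,700 at 0 CL toward ≈750 at high burden);
* covariate-driven orthogonal displacement: each subject's raw displacement
  d_i = Σ_k β_k·covariate_ik + ε_i is applied along the curve's local unit
  normal, so d_i is exactly the quantity the scoring stage estimates;
* CSF tau and Aβ38/Aβ40 with positive coupling to displacement and position;
* longitudinal cognition whose slope couples to the true aggregation score,
  with correlated per-subject random intercepts and slopes.

Ground truth (arc positions, displacements, standardized true scores, random
effects) is returned alongside the observable table and is never consumed by
the analysis path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .curves import HyperbolaParams, evaluate_curve, curve_derivative
from .model import _signed_chord

__all__ = [
    "CurveConfig",
    "MixtureConfig",
    "CovariateConfig",
    "CognitionConfig",
    "SimulationConfig",
    "simulate_cohort",
    "simulate_longitudinal",
]


class CurveConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    form: str = "rational"
    a: float = 3673.1
    b: float = -2924.9
    c: float = -0.3
    domain: tuple[float, float] = (0.0, 180.0)

    def to_params(self) -> HyperbolaParams:
        return HyperbolaParams(self.form, self.a, self.b, self.c, tuple(self.domain))


class MixtureConfig(BaseModel):
    """Two-component normal mixture of arc positions, truncated to the domain."""

    model_config = ConfigDict(extra="forbid")
    weights: tuple[float, float] = (0.55, 0.45)
    means: tuple[float, float] = (5.0, 60.0)
    sds: tuple[float, float] = (8.0, 30.0)

    @model_validator(mode="after")
    def _check(self):
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if any(s < 0 for s in self.sds):
            raise ValueError("mixture SDs must be nonnegative")
        return self


class CovariateConfig(BaseModel):
    """Covariate marginals and their effects on orthogonal displacement.

    ``effect_*`` coefficients are expressed as multiples of the orthogonal
    noise SD (i.e. in the same SD units the association tables use); they
    are converted to plane units by multiplying with ``noise_sd``.  The
    ``*_d_coef`` couplings of downstream CSF biomarkers are per displacement
    SD (positive: more aggregated-than-soluble subjects have higher tau /
    higher amyloid production).
    """

    model_config = ConfigDict(extra="forbid")
    age_mean: float = 73.0
    age_sd: float = 7.4
    p_female: float = 0.467
    apoe_probs: tuple[float, float, float] = (0.549, 0.356, 0.095)
    education_mean: float = 16.3
    education_sd: float = 2.6
    # displacement effects, in noise-SD multiples
    effect_apoe_hom: float = -0.56
    effect_apoe_het: float = 0.0
    effect_female: float = 0.18
    effect_vv_z: float = -0.13
    # couplings of downstream CSF biomarkers (pg/mL per displacement SD,
    # and pg/mL per Centiloid of arc position)
    ttau_base: float = 80.0
    ttau_t_coef: float = 0.9
    ttau_d_coef: float = 12.0
    ttau_sd: float = 25.0
    ptau_base: float = 20.0
    ptau_t_coef: float = 0.25
    ptau_d_coef: float = 3.0
    ptau_sd: float = 8.0
    ab40_base: float = 14000.0
    ab40_d_coef: float = 1500.0
    ab40_sd: float = 2500.0
    ab38_base: float = 2200.0
    ab38_d_coef: float = 250.0
    ab38_sd: float = 450.0


class CognitionConfig(BaseModel):
    """Longitudinal cognition model (default outcome in z-units)."""

    model_config = ConfigDict(extra="forbid")
    test_name: str = "mmse_z"
    intercept: float = 0.0
    sev_coef: float = -0.30
    agg_coef: float = 0.10
    time_slope: float = -0.15
    agg_time_coef: float = 0.14
    sev_time_coef: float = -0.10
    random_intercept_sd: float = 0.70
    random_slope_sd: float = 0.15
    random_corr: float = -0.20
    residual_sd: float = 0.40
    visit_times: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0)
    visit_jitter_sd: float = 0.0

    @model_validator(mode="after")
    def _check(self):
        if any(t < 0 for t in self.visit_times):
            raise ValueError("visit times must be nonnegative (years)")
        if min(self.random_intercept_sd, self.random_slope_sd, self.residual_sd) < 0:
            raise ValueError("variance components must be nonnegative")
        if not -1.0 <= self.random_corr <= 1.0:
            raise ValueError("random_corr must be in [-1, 1]")
        return self


class SimulationConfig(BaseModel):
    """Study conditions of one synthetic cohort.

    ``displacement_scaling="standardized"`` (default) measures orthogonal
    displacement in standardized plane units — each axis divided by the SD
    of the noiseless curve points — so a displacement SD of ~0.05 mirrors
    noise of about 2% of the (standardized) CSF range; the matching fit uses
    ``scaling="zscore"``.  ``"raw"`` works in the supplied units instead.
    """

    model_config = ConfigDict(extra="forbid")
    n: int = Field(default=800, ge=10)
    curve: CurveConfig = CurveConfig()
    mixture: MixtureConfig = MixtureConfig()
    noise_sd: float = Field(default=0.05, ge=0.0)
    displacement_scaling: str = "standardized"
    covariates: CovariateConfig = CovariateConfig()
    cognition: CognitionConfig = CognitionConfig()
    seed: int = 20240611

    @model_validator(mode="after")
    def _check_support(self):
        lo, hi = self.curve.domain
        for m in self.mixture.means:
            if not lo <= m <= hi:
                raise ValueError(
                    f"mixture mean {m} outside curve domain [{lo}, {hi}]"
                )
        return self


def _sample_truncated_mixture(mix: MixtureConfig, domain, n, rng) -> np.ndarray:
    lo, hi = domain
    comp = rng.choice(2, size=n, p=list(mix.weights))
    out = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        draw = rng.normal(
            np.asarray(mix.means)[comp[todo]], np.asarray(mix.sds)[comp[todo]]
        )
        ok = (draw >= lo) & (draw <= hi)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def simulate_cohort(config: SimulationConfig | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one baseline cohort; returns (cohort table, ground truth).

    Deterministic given ``config.seed``; all draws flow from one seeded
    generator.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng([cfg.seed, 0])
    n = cfg.n
    cov = cfg.covariates
    params = cfg.curve.to_params()

    # covariates
    age = rng.normal(cov.age_mean, cov.age_sd, n)
    female = rng.random(n) < cov.p_female
    apoe = rng.choice(3, size=n, p=list(cov.apoe_probs))
    educ = np.clip(rng.normal(cov.education_mean, cov.education_sd, n), 6, 24)
    icv = rng.normal(1.5e6, 1.5e5, n)
    vv_ratio = np.clip(rng.normal(0.03, 0.01, n), 0.005, None)
    vv_z = (vv_ratio - vv_ratio.mean()) / vv_ratio.std(ddof=1)

    # arc position and covariate-driven orthogonal displacement (plane units
    # follow cfg.displacement_scaling; effects are noise-SD multiples)
    t = _sample_truncated_mixture(cfg.mixture, cfg.curve.domain, n, rng)
    eps = rng.normal(0.0, cfg.noise_sd, n)
    d = (
        cfg.noise_sd
        * (
            cov.effect_apoe_hom * (apoe == 2)
            + cov.effect_apoe_het * (apoe == 1)
            + cov.effect_female * female
            + cov.effect_vv_z * vv_z
        )
        + eps
    )

    # observed point: curve(t) displaced along the local upward unit normal
    # of the (possibly standardized) plane, so positive d lands above the
    # curve (the +1 side of the scorer)
    y_curve = evaluate_curve(params, t)
    if cfg.displacement_scaling == "standardized":
        sx = float(np.std(t, ddof=1)) or 1.0
        sy = float(np.std(y_curve, ddof=1)) or 1.0
    elif cfg.displacement_scaling == "raw":
        sx = sy = 1.0
    else:
        raise ValueError(
            f"unknown displacement_scaling {cfg.displacement_scaling!r}"
        )
    slope_sc = curve_derivative(params, t) * sx / sy
    norm = np.hypot(1.0, slope_sc)
    x_obs = t + d * (-slope_sc) / norm * sx
    y_obs = y_curve + d / norm * sy

    # downstream CSF biomarkers, positively coupled to displacement/position
    d_z = d / cfg.noise_sd if cfg.noise_sd > 0 else d
    ttau = np.clip(
        cov.ttau_base + cov.ttau_t_coef * t + cov.ttau_d_coef * d_z
        + rng.normal(0, cov.ttau_sd, n),
        5.0,
        None,
    )
    ptau = np.clip(
        cov.ptau_base + cov.ptau_t_coef * t + cov.ptau_d_coef * d_z
        + rng.normal(0, cov.ptau_sd, n),
        2.0,
        None,
    )
    ab40 = np.clip(
        cov.ab40_base + cov.ab40_d_coef * d_z + rng.normal(0, cov.ab40_sd, n), 500.0, None
    )
    ab38 = np.clip(
        cov.ab38_base + cov.ab38_d_coef * d_z + rng.normal(0, cov.ab38_sd, n), 100.0, None
    )

    # vascular burden and clinical descriptors
    wmh = np.exp(rng.normal(7.5, 1.0, n)) * (1 + 0.02 * np.clip(age - 70, 0, None))
    fazekas = np.digitize(wmh, np.quantile(wmh, [0.5, 0.85, 0.97]))
    p_ci = 1.0 / (1.0 + np.exp(-(t - 40.0) / 15.0))
    ci = rng.random(n) < p_ci
    cdr = np.where(ci, rng.choice([0.5, 1.0], size=n, p=[0.8, 0.2]), 0.0)
    mmse = np.clip(
        np.round(30 - 0.02 * t - 2.5 * ci - np.abs(rng.normal(0, 1.2, n))), 10, 30
    )
    interval = np.abs(rng.normal(10.0, 14.0, n))

    subject_id = np.array([f"S{i:04d}" for i in range(n)])
    cohort = pd.DataFrame(
        {
            "subject_id": subject_id,
            "visit": "baseline",
            "age": age,
            "sex": np.where(female, "F", "M"),
            "education_years": educ,
            "apoe_e4_copies": apoe,
            "diagnosis": np.where(ci, "CI", "CU"),
            "cdr": cdr,
            "mmse": mmse,
            "centiloid": x_obs,
            "csf_ab42": y_obs,
            "csf_ab40": ab40,
            "csf_ab38": ab38,
            "csf_ptau": ptau,
            "csf_ttau": ttau,
            "icv_mm3": icv,
            "ventricle_volume_mm3": vv_ratio * icv,
            "ventricular_volume": vv_ratio,
            "wmh_volume_mm3": wmh,
            "fazekas": fazekas,
            "csf_pet_interval_days": interval,
        }
    )

    # ground truth, on the same standardization convention as the scorer
    # (an all-on-curve cohort has no displacement spread to standardize)
    d_sd = d.std(ddof=1)
    agg_z = (d - d.mean()) / d_sd if d_sd > 0 else np.zeros(n)
    raw_sev = _signed_chord(params, t, float(np.median(t)), (sx, sy))
    sev_z = (raw_sev - raw_sev.mean()) / raw_sev.std(ddof=1)
    truth = pd.DataFrame(
        {
            "subject_id": subject_id,
            "true_t": t,
            "true_d": d,
            "true_aggregation": agg_z,
            "true_severity": sev_z,
        }
    )
    return cohort, truth


def simulate_longitudinal(
    cohort: pd.DataFrame,
    truth: pd.DataFrame,
    config: SimulationConfig | None = None,
) -> pd.DataFrame:
    """Longitudinal cognition visits for a simulated cohort.

    The per-visit score is
    ``z_ij = α + λ_sev·sev_i + λ_agg·agg_i + (θ_t + θ_agg·agg_i +
    θ_sev·sev_i + u1_i)·t_ij + u0_i + ε_ij`` with correlated normal random
    effects (u0, u1) and normal residuals.  Deterministic given the seed.
    """
    cfg = config or SimulationConfig()
    cg = cfg.cognition
    if truth is None or not {"true_aggregation", "true_severity"} <= set(truth.columns):
        raise ValueError("ground truth with true scores is required")
    rng = np.random.default_rng([cfg.seed, 1])
    n = len(truth)
    agg = truth["true_aggregation"].to_numpy()
    sev = truth["true_severity"].to_numpy()

    cov_u = cg.random_corr * cg.random_intercept_sd * cg.random_slope_sd
    cov_mat = np.array(
        [[cg.random_intercept_sd**2, cov_u], [cov_u, cg.random_slope_sd**2]]
    )
    # "eigh" tolerates the PSD-singular case of zero variance components
    u = rng.multivariate_normal([0.0, 0.0], cov_mat, size=n, method="eigh")
    u0, u1 = u[:, 0], u[:, 1]

    times = np.asarray(cg.visit_times, dtype=float)
    rows = []
    sid = truth["subject_id"].to_numpy()
    for j, t0 in enumerate(times):
        tt = np.full(n, t0)
        if cg.visit_jitter_sd > 0 and t0 > 0:
            tt = np.clip(tt + rng.normal(0, cg.visit_jitter_sd, n), 0.0, None)
        eps = rng.normal(0, cg.residual_sd, n)
        z = (
            cg.intercept
            + cg.sev_coef * sev
            + cg.agg_coef * agg
            + (cg.time_slope + cg.agg_time_coef * agg + cg.sev_time_coef * sev + u1)
            * tt
            + u0
            + eps
        )
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": sid,
                    "test": cg.test_name,
                    "time_years": tt,
                    "score": z,
                }
            )
        )
    visits = pd.concat(rows, ignore_index=True)
    visits["_subject_order"] = np.tile(np.arange(n), len(times))
    visits = (
        visits.sort_values(["_subject_order", "time_years"], kind="stable")
        .drop(columns="_subject_order")
        .reset_index(drop=True)
    )
    truth_re = truth.copy()
    truth_re["u0"] = u0
    truth_re["u1"] = u1
    visits.attrs["random_effects"] = truth_re[["subject_id", "u0", "u1"]]
    return visits
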