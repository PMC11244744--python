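"""Per-subject amyloid-imbalance scores from a fitted curve.

Two standardized measures are derived from the fitted geometry:

* **Aggregation score** — signed orthogonal distance of the observed
  (Centiloid, CSF) point from the curve, z-standardized against the fitting
  cohort.  Positive values mean a higher PET burden than expected for the
  observed CSF level (more aggregated relative to soluble amyloid); negative
  values the reverse.
* **Severity score** — signed straight-line (chord) distance between the
  subject's projection and the cohort's reference point (the curve point at
  the median arc position), z-standardized against the fitting cohort.
  Positive values mean more advanced amyloid pathology.

Both use the sample (n-1) standard deviation, so within the fitting cohort
each score has mean 0 and SD 1 exactly.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .geometry import _points_to_arrays, project_points
from .model import HyperbolicImbalanceModel, _signed_chord

__all__ = [
    "DegenerateCohortError",
    "aggregation_scores",
    "severity_scores",
    "score_table",
    "score_new_subjects",
]


class DegenerateCohortError(ValueError):
    """Standardization impossible: zero spread in the raw scores."""


def _degenerate(model, sd: float) -> bool:
    # spreads below 0.01% of the cohort's plane scale are indistinguishable
    # from an all-on-curve cohort at the fitter's convergence tolerance;
    # real CSF/PET scatter sits orders of magnitude above this
    return sd <= 1e-4 * getattr(model, "plane_scale_", 1.0)


def _check_fitted(model: HyperbolicImbalanceModel) -> None:
    if not hasattr(model, "agg_sd_"):
        raise ValueError("model has no stored standardization moments; fit it first")


def aggregation_scores(model: HyperbolicImbalanceModel) -> np.ndarray:
    """Standardized aggregation scores of the fitting cohort."""
    _check_fitted(model)
    if not hasattr(model, "projections_"):
        raise ValueError("model carries no fit projections (deserialized model?)")
    if _degenerate(model, model.agg_sd_):
        raise DegenerateCohortError("all subjects lie on the curve (SD of raw scores is 0)")
    raw = model.projections_["side"] * model.projections_["distance"]
    return (raw - model.agg_mean_) / model.agg_sd_


def severity_scores(model: HyperbolicImbalanceModel) -> np.ndarray:
    """Standardized severity scores of the fitting cohort."""
    _check_fitted(model)
    if not hasattr(model, "projections_"):
        raise ValueError("model carries no fit projections (deserialized model?)")
    if _degenerate(model, model.sev_sd_):
        raise DegenerateCohortError("zero spread in arc positions")
    raw = _signed_chord(
        model.params_, model.projections_["t"], model.sev_ref_t_, model.scaling_
    )
    return (raw - model.sev_mean_) / model.sev_sd_


def _score_arrays(model: HyperbolicImbalanceModel, x, y):
    proj = project_points(
        model.params_, x, y, model.scaling_, grid_size=model.grid_size, tol=model.proj_tol
    )
    raw_agg = proj["side"] * proj["distance"]
    raw_sev = _signed_chord(model.params_, proj["t"], model.sev_ref_t_, model.scaling_)
    agg = (raw_agg - model.agg_mean_) / model.agg_sd_
    sev = (raw_sev - model.sev_mean_) / model.sev_sd_
    return proj, raw_agg, raw_sev, agg, sev


def score_new_subjects(model: HyperbolicImbalanceModel, points, subject_ids=None) -> pd.DataFrame:
    """Score arbitrary points with the model's frozen moments.

    No re-centering happens: the fitting cohort's mean/SD are applied, so
    re-scoring the fitting cohort reproduces its stored scores.  Points whose
    Centiloid lies outside the curve domain are scored against the nearest
    domain endpoint and flagged ``out_of_domain`` with a warning.
    """
    _check_fitted(model)
    if _degenerate(model, model.agg_sd_) or _degenerate(model, model.sev_sd_):
        raise DegenerateCohortError("model moments are degenerate (zero SD)")
    x, y = _points_to_arrays(points)
    proj, raw_agg, raw_sev, agg, sev = _score_arrays(model, x, y)
    if proj["out_of_domain"].any():
        n_out = int(proj["out_of_domain"].sum())
        warnings.warn(
            f"{n_out} point(s) outside the curve domain {model.params_.domain}; "
            "projection clamped to the domain endpoint",
            stacklevel=2,
        )
    if subject_ids is None:
        subject_ids = np.arange(x.size)
    return pd.DataFrame(
        {
            "subject_id": np.asarray(subject_ids),
            "aggregation": agg,
            "severity": sev,
            "raw_aggregation": raw_agg,
            "raw_severity": raw_sev,
            "distance": proj["distance"],
            "side": proj["side"],
            "arc_position": proj["t"],
            "out_of_domain": proj["out_of_domain"],
        }
    )


def score_table(model: HyperbolicImbalanceModel, subject_ids=None) -> pd.DataFrame:
    """Full score table for the fitting cohort (spec'd CSV layout)."""
    _check_fitted(model)
    if not hasattr(model, "projections_"):
        raise ValueError("model carries no fit projections (deserialized model?)")
    proj = model.projections_
    agg = aggregation_scores(model)
    sev = severity_scores(model)
    raw_agg = proj["side"] * proj["distance"]
    raw_sev = _signed_chord(model.params_, proj["t"], model.sev_ref_t_, model.scaling_)
    if subject_ids is None:
        subject_ids = np.arange(agg.size)
    return pd.DataFrame(
        {
            "subject_id": np.asarray(subject_ids),
            "aggregation": agg,
            "severity": sev,
            "raw_aggregation": raw_agg,
            "raw_severity": raw_sev,
            "distance": proj["distance"],
            "side": proj["side"],
            "arc_position": proj["t"],
            "out_of_domain": proj["out_of_domain"],
        }
    )
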