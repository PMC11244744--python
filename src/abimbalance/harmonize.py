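"""Pre-model harmonization: Centiloid calibration, reference-group
z-standardization of CSF measures, intracranial-volume normalization, and the
Aβ42/40 sensitivity ratio.

All operations are deterministic and row-independent apart from the reference
moments; excluded or missing subjects are reported in machine-readable
exclusion logs rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "CentiloidCalibration",
    "suvr_to_centiloid",
    "ReferenceCriteria",
    "select_reference_group",
    "ReferenceZScorer",
    "zscore_by_reference",
    "icv_normalize",
    "csf_ratio",
]


@dataclass(frozen=True)
class CentiloidCalibration:
    """Linear SUVr → Centiloid map for one tracer/pipeline.

    Centiloid calibrations are pipeline-specific; entries are configuration
    data, typically loaded from the run config, never hard-coded.
    """

    tracer: str
    slope: float
    intercept: float
    reference_region: str = "whole_cerebellum"
    target_region: str = "GAAIN_cortical"

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError(f"calibration slope must be > 0, got {self.slope}")


def suvr_to_centiloid(suvr, calib: CentiloidCalibration):
    """CL = slope * SUVr + intercept (linear, order-preserving)."""
    suvr_arr = np.asarray(suvr, dtype=float)
    if np.any(suvr_arr <= 0):
        raise ValueError("SUVr must be positive")
    out = calib.slope * suvr_arr + calib.intercept
    return float(out) if np.ndim(suvr) == 0 else out


@dataclass(frozen=True)
class ReferenceCriteria:
    """Inclusion criteria for a cognitively-unimpaired reference group.

    Defaults encode the conventional amyloid-negative CU reference:
    baseline visit, CDR = 0, MMSE > 27 (strict), APOE-ε4 noncarrier,
    age ≤ 70 (inclusive), Centiloid < 12 (strict).
    """

    max_cdr: float = 0.0
    min_mmse_exclusive: float = 27.0
    exclude_apoe_e4_carriers: bool = True
    max_age: float = 70.0
    max_centiloid_exclusive: float = 12.0
    visit: str | None = "baseline"

    columns: dict = field(
        default_factory=lambda: {
            "cdr": "cdr",
            "mmse": "mmse",
            "apoe": "apoe_e4_copies",
            "age": "age",
            "centiloid": "centiloid",
            "visit": "visit",
        }
    )


def select_reference_group(
    table: pd.DataFrame, criteria: ReferenceCriteria | None = None
) -> tuple[pd.DataFrame, dict]:
    """Rows satisfying every reference criterion, plus an exclusion log.

    Returns ``(subset, log)`` where ``log`` maps criterion name to the number
    of subjects it excluded (a subject failing several criteria is counted
    under each).  Rows with a missing value on an active criterion are
    excluded and counted under ``missing_<criterion>``.
    """
    crit = criteria or ReferenceCriteria()
    cols = crit.columns
    keep = pd.Series(True, index=table.index)
    log: dict[str, int] = {}

    def apply(name: str, col_key: str, fn) -> None:
        nonlocal keep
        col = cols[col_key]
        if col not in table.columns:
            raise KeyError(f"reference criteria need column {col!r}")
        vals = table[col]
        missing = vals.isna()
        ok = fn(vals).fillna(False) & ~missing
        log[name] = int((~ok & ~missing & keep).sum())
        log[f"missing_{name}"] = int((missing & keep).sum())
        keep &= ok

    if crit.visit is not None and cols["visit"] in table.columns:
        ok = table[cols["visit"]] == crit.visit
        log["visit"] = int((~ok & keep).sum())
        keep &= ok
    if np.isfinite(crit.max_cdr):
        apply("max_cdr", "cdr", lambda v: v <= crit.max_cdr)
    if np.isfinite(crit.min_mmse_exclusive):
        apply("min_mmse_exclusive", "mmse", lambda v: v > crit.min_mmse_exclusive)
    if crit.exclude_apoe_e4_carriers:
        apply("exclude_apoe_e4_carriers", "apoe", lambda v: v == 0)
    if np.isfinite(crit.max_age):
        apply("max_age", "age", lambda v: v <= crit.max_age)
    if np.isfinite(crit.max_centiloid_exclusive):
        apply(
            "max_centiloid_exclusive",
            "centiloid",
            lambda v: v < crit.max_centiloid_exclusive,
        )

    subset = table.loc[keep]
    if subset.empty:
        raise ValueError(
            f"reference group is empty; per-criterion exclusion counts: {log}"
        )
    return subset, log


class ReferenceZScorer(BaseEstimator, TransformerMixin):
    """Z-standardization against a (reference-group) sample.

    ``fit`` learns the reference mean and sample SD (n-1 denominator);
    ``transform`` maps arbitrary values to z-scores on that scale, so the
    reference members themselves have mean 0 and SD 1.
    """

    def fit(self, X, y=None):
        vals = np.asarray(X, dtype=float).ravel()
        vals = vals[np.isfinite(vals)]
        if vals.size < 2:
            raise ValueError("reference group needs at least 2 finite values")
        self.mean_ = float(np.mean(vals))
        self.sd_ = float(np.std(vals, ddof=1))
        if self.sd_ <= 0:
            raise ValueError("reference SD is zero; cannot standardize")
        self.n_reference_ = int(vals.size)
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        arr = np.asarray(X, dtype=float)
        return (arr - self.mean_) / self.sd_


def zscore_by_reference(values, reference):
    """(v - mean_ref) / SD_ref with the sample (n-1) SD convention."""
    scorer = ReferenceZScorer().fit(reference)
    out = scorer.transform(np.asarray(values, dtype=float))
    return float(out) if np.ndim(values) == 0 else out


def icv_normalize(volume, icv):
    """Volume as a dimensionless fraction of total intracranial volume."""
    icv_arr = np.asarray(icv, dtype=float)
    if np.any(icv_arr <= 0):
        raise ValueError("intracranial volume must be positive")
    out = np.asarray(volume, dtype=float) / icv_arr
    return float(out) if np.ndim(volume) == 0 and np.ndim(icv) == 0 else out


def csf_ratio(ab42, ab40, log=None):
    """CSF Aβ42/Aβ40 ratio; nonpositive/missing Aβ40 propagates as NaN.

    ``log``, if given, is a list collecting row indices whose denominator was
    unusable.
    """
    a42 = np.asarray(ab42, dtype=float)
    a40 = np.asarray(ab40, dtype=float)
    bad = ~np.isfinite(a40) | (a40 <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bad, np.nan, a42 / np.where(bad, 1.0, a40))
    if log is not None:
        log.extend(np.nonzero(np.atleast_1d(bad))[0].tolist())
    return float(out) if np.ndim(ab42) == 0 and np.ndim(ab40) == 0 else out
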