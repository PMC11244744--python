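"""Statistical battery around the imbalance scores.

Cross-sectional ordinary least squares on the aggregation score, optional
predictor × severity interactions, longitudinal linear mixed models on
cognition with participant-specific correlated random intercept and slope,
two-group comparisons computable from printed summary statistics, and
Benjamini–Hochberg FDR within model families.

Coefficients are reported as standardized betas: continuous outcome and
continuous predictors are z-scored within the analyzed (complete-case)
sample; categorical predictors enter as treatment-coded dummies against
fixed references (male sex, 0 APOE-ε4 copies, Fazekas 0) and are NOT
rescaled, so a dummy's beta reads as an outcome-SD shift.  Time is coded in
years from baseline and never standardized, so slope terms read as SD/year.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ModelSpecification",
    "AssociationResult",
    "standardize_for_regression",
    "fit_cross_sectional",
    "fit_longitudinal",
    "fdr_adjust",
    "t_test_from_summary",
    "chi_square_2x2",
    "wilcoxon_rank_sum",
    "compare_groups",
    "ab42_40_rescore",
    "run_analysis_suite",
    "SuiteReport",
]

#: categorical encodings: column -> (reference level, {level: dummy suffix})
CATEGORICAL_CODING = {
    "sex": ("M", {"F": "F"}),
    "apoe_e4_copies": (0, {1: "1", 2: "2"}),
    "fazekas": (0, {1: "1", 2: "2_3", 3: "2_3"}),
    "diagnosis": ("CU", {"CI": "CI"}),
}

#: variables never rescaled even though numeric
_NEVER_SCALE = {"time_years"}


@dataclass
class ModelSpecification:
    """One regression model: outcome, predictors, covariates, interactions."""

    outcome: str
    predictors: list = dc_field(default_factory=list)
    covariates: list = dc_field(default_factory=list)
    interactions: list = dc_field(default_factory=list)  # tuples of columns
    family: str = "custom"
    stratum: str = "all"
    categorical: dict | None = None  # overrides for CATEGORICAL_CODING

    def all_columns(self) -> list:
        cols = [self.outcome] + list(self.predictors) + list(self.covariates)
        for terms in self.interactions:
            cols.extend(terms)
        seen, out = set(), []
        for c in cols:
            if c not in seen:
                seen.add(c)
                out.append(c)
        return out


@dataclass(frozen=True)
class AssociationResult:
    """One term of one fitted model (standardized scale)."""

    model: str
    family: str
    stratum: str
    outcome: str
    term: str
    beta: float
    se: float
    p: float
    p_adj: float | None
    r2: float
    n: int
    converged: bool = True

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"SE must be > 0 (term {self.term})")
        if not 0.0 < self.p <= 1.0:
            raise ValueError(f"p out of (0, 1] (term {self.term}: {self.p})")
        if self.p_adj is not None and self.p_adj < self.p - 1e-12:
            raise ValueError("adjusted p below raw p")


def _coding_for(col: str, overrides: dict | None):
    table = dict(CATEGORICAL_CODING)
    if overrides:
        table.update(overrides)
    return table.get(col)


def _encode_column(df: pd.DataFrame, col: str, overrides: dict | None):
    """Return (encoded frame, list of produced columns, is_categorical)."""
    coding = _coding_for(col, overrides)
    if coding is None and df[col].dtype == object:
        # unseen string column: treatment-code against the first sorted level
        levels = sorted(df[col].dropna().unique())
        coding = (levels[0], {lv: str(lv) for lv in levels[1:]})
    if coding is None:
        return df[[col]].astype(float), [col], False
    ref, mapping = coding
    known = {ref} | set(mapping)
    bad = set(df[col].dropna().unique()) - known
    if bad:
        raise ValueError(f"unknown level(s) {sorted(map(str, bad))!r} in column {col!r}")
    out = {}
    for level, suffix in mapping.items():
        name = f"{col}_{suffix}"
        if name in out:
            out[name] = out[name] | (df[col] == level)
        else:
            out[name] = df[col] == level
    enc = pd.DataFrame({k: v.astype(float) for k, v in out.items()}, index=df.index)
    return enc, list(enc.columns), True


def standardize_for_regression(
    table: pd.DataFrame, spec: ModelSpecification, no_scale: set | None = None
) -> tuple[pd.DataFrame, dict]:
    """Complete-case, treatment-coded, z-standardized analysis table.

    Returns ``(df, info)``: ``df`` holds the standardized outcome, the
    standardized continuous predictors/covariates, unscaled dummies, and
    interaction product columns.  ``info`` records term lists, the n used,
    and the scaling moments.
    """
    cols = spec.all_columns()
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"columns missing from table: {missing}")
    data = table[cols].copy()
    data = data.dropna()
    n = len(data)

    out = pd.DataFrame(index=data.index)
    term_map: dict[str, list] = {}
    moments: dict[str, tuple] = {}
    skip = _NEVER_SCALE | (no_scale or set())
    for col in cols:
        enc, names, is_cat = _encode_column(data, col, spec.categorical)
        if not is_cat and col not in skip:
            sd = float(enc[col].std(ddof=1))
            if not sd > 0:
                raise ValueError(f"zero variance in continuous variable {col!r}")
            mean = float(enc[col].mean())
            moments[col] = (mean, sd)
            enc = (enc - mean) / sd
        out[names] = enc
        term_map[col] = names

    inter_terms = []
    for terms in spec.interactions:
        combos = [[t] for t in term_map[terms[0]]]
        for t in terms[1:]:
            combos = [c + [u] for c in combos for u in term_map[t]]
        for combo in combos:
            name = ":".join(combo)
            out[name] = np.prod([out[c].to_numpy() for c in combo], axis=0)
            inter_terms.append(name)

    info = {
        "n": n,
        "outcome": term_map[spec.outcome][0],
        "predictor_terms": [t for c in spec.predictors for t in term_map[c]],
        "covariate_terms": [t for c in spec.covariates for t in term_map[c]],
        "interaction_terms": inter_terms,
        "term_map": term_map,
        "moments": moments,
    }
    return out, info


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # identify offending columns by greedy QR elimination
        bad = []
        keep: list[int] = []
        for j in range(arr.shape[1]):
            cand = arr[:, keep + [j]]
            if np.linalg.matrix_rank(cand) == len(keep) + 1:
                keep.append(j)
            else:
                bad.append(X.columns[j])
        raise ValueError(f"rank-deficient design; collinear terms: {bad}")


def fit_cross_sectional(
    table: pd.DataFrame, spec: ModelSpecification, model_name: str | None = None
) -> list[AssociationResult]:
    """OLS of the (standardized) outcome on predictors + covariates.

    Two-sided t-distribution p-values; the model R² is attached to every
    term row.
    """
    df, info = standardize_for_regression(table, spec)
    terms = info["predictor_terms"] + info["covariate_terms"] + info["interaction_terms"]
    n = info["n"]
    if n < len(terms) + 10:
        raise ValueError(
            f"too few complete cases (n={n}) for {len(terms)} terms"
        )
    X = df[terms]
    _check_rank(sm.add_constant(X, has_constant="add"))
    fit = sm.OLS(df[info["outcome"]], sm.add_constant(X, has_constant="add")).fit()
    name = model_name or f"{spec.family}:{spec.outcome}"
    rows = []
    for t in terms:
        rows.append(
            AssociationResult(
                model=name,
                family=spec.family,
                stratum=spec.stratum,
                outcome=spec.outcome,
                term=t,
                beta=float(fit.params[t]),
                se=float(fit.bse[t]),
                p=float(np.clip(fit.pvalues[t], np.finfo(float).tiny, 1.0)),
                p_adj=None,
                r2=float(fit.rsquared),
                n=n,
            )
        )
    return rows


def fit_longitudinal(
    visits: pd.DataFrame,
    table: pd.DataFrame,
    spec: ModelSpecification,
    *,
    test: str | None = None,
    three_way: bool = False,
    standardize_outcome: bool = True,
    model_name: str | None = None,
) -> list[AssociationResult]:
    """Linear mixed model of a repeated cognitive score.

    Fixed effects: aggregation, time, aggregation × time, severity, the
    spec's covariates, and optionally the aggregation × severity × time
    three-way interaction with all lower-order terms.  Random effects:
    correlated per-subject intercept and slope, fitted by REML.  Wald
    p-values use the normal approximation.  The reported R² is the marginal
    (fixed-effects) variance fraction.
    """
    v = visits
    if test is not None:
        v = v[v["test"] == test]
    if v.empty:
        raise ValueError(f"no visits for test {test!r}")
    merged = v.merge(table, on="subject_id", how="inner")

    base_cols = ["aggregation", "severity"] + list(spec.covariates)
    cols = ["subject_id", "time_years", "score"] + base_cols
    missing = [c for c in cols if c not in merged.columns]
    if missing:
        raise KeyError(f"columns missing from merged table: {missing}")
    data = merged[cols].dropna()
    counts = data.groupby("subject_id")["time_years"].count()
    if (counts >= 2).mean() < 0.2:
        raise ValueError("too few subjects with repeated visits for a mixed model")

    sub_spec = ModelSpecification(
        outcome="score",
        predictors=["aggregation"],
        covariates=["severity"] + list(spec.covariates) + ["time_years"],
        interactions=[("aggregation", "time_years")]
        + (
            [
                ("severity", "time_years"),
                ("aggregation", "severity"),
                ("aggregation", "severity", "time_years"),
            ]
            if three_way
            else []
        ),
        family=spec.family,
        stratum=spec.stratum,
        categorical=spec.categorical,
    )
    no_scale = None if standardize_outcome else {"score", "aggregation", "severity"}
    df, info = standardize_for_regression(data, sub_spec, no_scale=no_scale)
    terms = info["predictor_terms"] + info["covariate_terms"] + info["interaction_terms"]
    X = sm.add_constant(df[terms], has_constant="add")
    _check_rank(X)
    groups = data.loc[df.index, "subject_id"].to_numpy()
    exog_re = np.column_stack(
        [np.ones(len(df)), data.loc[df.index, "time_years"].to_numpy()]
    )

    endog = df[info["outcome"]].to_numpy()
    mod = sm.MixedLM(endog, X.to_numpy(), groups=groups, exog_re=exog_re)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = mod.fit(reml=True)
        except Exception:
            fit = None
        if fit is None or not np.all(np.isfinite(fit.bse_fe)):
            # fallback: independent random effects
            from statsmodels.regression.mixed_linear_model import MixedLMParams

            free = MixedLMParams.from_components(
                fe_params=np.ones(X.shape[1]), cov_re=np.eye(2)
            )
            fit = mod.fit(reml=True, free=free)
            converged = False
    if not getattr(fit, "converged", True):
        converged = False

    # marginal R^2: fixed-effect variance over total variance
    fe_pred = X.to_numpy() @ fit.fe_params
    var_f = float(np.var(fe_pred))
    try:
        cov_re = np.asarray(fit.cov_re)
        zbar = exog_re
        var_re = float(np.mean(np.einsum("ij,jk,ik->i", zbar, cov_re, zbar)))
    except Exception:
        var_re = 0.0
    var_e = float(fit.scale)
    r2_marg = var_f / (var_f + var_re + var_e)

    name = model_name or f"{spec.family}:{test or 'score'}"
    n_sub = int(pd.Series(groups).nunique())
    rows = []
    for j, t in enumerate(X.columns):
        if t == "const":
            continue
        se = float(fit.bse_fe[j])
        if not np.isfinite(se) or se <= 0:
            continue
        z = float(fit.fe_params[j]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append(
            AssociationResult(
                model=name,
                family=spec.family,
                stratum=spec.stratum,
                outcome=test or "score",
                term=t,
                beta=float(fit.fe_params[j]),
                se=se,
                p=float(np.clip(p, np.finfo(float).tiny, 1.0)),
                p_adj=None,
                r2=r2_marg,
                n=n_sub,
                converged=converged,
            )
        )
    return rows


def fdr_adjust(pvalues, family: str | None = None) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment within one family."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# -- two-group comparisons -------------------------------------------------

def t_test_from_summary(mean1, sd1, n1, mean2, sd2, n2) -> tuple[float, float]:
    """Pooled-variance two-sample t test from printed summary statistics."""
    if min(n1, n2) < 2:
        raise ValueError("each group needs n >= 2")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if se == 0:
        return 0.0, 1.0
    t = (mean1 - mean2) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def chi_square_2x2(counts, correction: bool = True) -> tuple[float, float]:
    """Chi-square test on a 2×2 table (Yates continuity correction default)."""
    arr = np.asarray(counts, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("counts must form a 2x2 table")
    res = stats.chi2_contingency(arr, correction=correction)
    return float(res[0]), float(res[1])


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann–Whitney) test; W follows the R convention."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if min(x.size, y.size) < 2:
        raise ValueError("each group needs n >= 2")
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    *,
    summary=None,
    counts=None,
    values=None,
    groups=None,
    kind: str = "t",
    correction: bool = True,
) -> tuple[float, float]:
    """Dispatch to the appropriate two-group comparison.

    ``summary=(m1, s1, n1, m2, s2, n2)`` → pooled t;
    ``counts=[[a, b], [c, d]]`` → chi-square (continuity-corrected);
    ``values, groups`` → pooled t on raw data (``kind="t"``) or Wilcoxon
    rank-sum (``kind="wilcoxon"``).
    """
    if summary is not None:
        return t_test_from_summary(*summary)
    if counts is not None:
        return chi_square_2x2(counts, correction=correction)
    if values is None or groups is None:
        raise ValueError("supply summary=, counts=, or values= and groups=")
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {len(levels)}")
    a = values[groups == levels[0]]
    b = values[groups == levels[1]]
    if kind == "wilcoxon":
        return wilcoxon_rank_sum(a, b)
    return t_test_from_summary(
        a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
    )


# -- the full battery ------------------------------------------------------

@dataclass
class SuiteReport:
    """Tidy results of :func:`run_analysis_suite` plus the run log."""

    results: pd.DataFrame
    log: list

    def to_csv(self, path) -> None:
        self.results.to_csv(path, index=False)


_CSF_PREDICTORS = ["csf_ab38", "csf_ab40", "csf_ptau", "csf_ttau"]


def _rows_to_frame(rows) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


def ab42_40_rescore(cohort: pd.DataFrame, fit_kwargs: dict | None = None) -> pd.DataFrame:
    """Refit the imbalance curve on CSF-Aβ42/40 and replace the scores.

    The CSF-dynamics sensitivity variant: the ordinate becomes the
    Aβ42/Aβ40 ratio, the curve is refitted, and the cohort's aggregation and
    severity columns are replaced by ratio-derived scores (missing where the
    ratio is unavailable).
    """
    from .harmonize import csf_ratio
    from .model import HyperbolicImbalanceModel
    from .scoring import score_table

    ratio = csf_ratio(cohort["csf_ab42"].to_numpy(), cohort["csf_ab40"].to_numpy())
    ok = np.isfinite(ratio) & cohort["centiloid"].notna().to_numpy()
    pts = np.column_stack([cohort.loc[ok, "centiloid"].to_numpy(), ratio[ok]])
    kwargs = {"scaling": "zscore", "n_restarts": 3, "maxfev": 800}
    kwargs.update(fit_kwargs or {})
    model = HyperbolicImbalanceModel(**kwargs).fit(pts)
    tab = score_table(model)
    out = cohort.copy()
    out["aggregation"] = np.nan
    out["severity"] = np.nan
    out.loc[ok, "aggregation"] = tab["aggregation"].to_numpy()
    out.loc[ok, "severity"] = tab["severity"].to_numpy()
    return out


def run_analysis_suite(
    cohort: pd.DataFrame,
    visits: pd.DataFrame | None = None,
    *,
    strata: tuple = ("all", "CU", "CI"),
    interactions: bool = True,
    apply_fdr: bool = True,
    min_n: int = 50,
    sensitivity_ab42_40: bool = False,
    fit_kwargs: dict | None = None,
) -> SuiteReport:
    """Run the full cross-sectional + longitudinal battery on a scored cohort.

    Families: methodological (interval + ventricular volume, plus CSF kit /
    PET tracer when such columns are present), demographics (age, sex,
    education, APOE copies, concurrently), CSF biomarkers (each individually,
    raw and divided by Aβ40, adjusted for age/sex/APOE), vascular burden (WMH
    volume or Fazekas), and cognition (one mixed model per test, baseline and
    slope terms).  Every model is additionally adjusted for severity and
    ventricular volume.  BH-FDR is applied within the CSF family and within
    the baseline/longitudinal cognition families.  Missing columns disable
    the affected family with a logged warning.
    """
    log: list[str] = []
    all_rows: list[AssociationResult] = []

    def have(cols) -> bool:
        return all(c in cohort.columns for c in cols)

    if not have(["aggregation", "severity"]):
        raise KeyError("cohort must be scored (aggregation/severity columns)")

    for stratum in strata:
        if stratum == "all":
            sub = cohort
        else:
            if "diagnosis" not in cohort.columns:
                log.append(f"WARNING stratum {stratum}: no diagnosis column; skipped")
                continue
            sub = cohort[cohort["diagnosis"] == stratum]
        if len(sub) < min_n:
            log.append(f"WARNING stratum {stratum}: n={len(sub)} < {min_n}; skipped")
            continue

        adj = ["severity", "ventricular_volume"]

        # 1) methodological
        meth_preds = ["csf_pet_interval_days", "ventricular_volume"]
        for extra in ("csf_kit", "pet_tracer"):
            if extra in sub.columns and sub[extra].nunique() > 1:
                meth_preds.append(extra)
        if have(meth_preds[:2]):
            spec = ModelSpecification(
                outcome="aggregation",
                predictors=meth_preds,
                covariates=["severity"],
                family="methodological",
                stratum=stratum,
            )
            all_rows += _family_with_interactions(sub, spec, interactions, log)
        else:
            log.append(f"WARNING methodological family disabled in {stratum}: missing columns")

        # 2) demographics (concurrent)
        demo = ["age", "sex", "education_years", "apoe_e4_copies"]
        if have(demo):
            spec = ModelSpecification(
                outcome="aggregation",
                predictors=demo,
                covariates=adj,
                family="demographics",
                stratum=stratum,
            )
            all_rows += _family_with_interactions(sub, spec, interactions, log)
        else:
            log.append(f"WARNING demographics family disabled in {stratum}: missing columns")

        # 3) CSF biomarkers (individual, raw and /Aβ40)
        csf_rows: list[AssociationResult] = []
        csf_covs = ["age", "sex", "apoe_e4_copies"] + adj
        for pred in _CSF_PREDICTORS:
            if pred not in sub.columns:
                log.append(f"WARNING csf predictor {pred} absent in {stratum}")
                continue
            variants = [(pred, sub)]
            if pred != "csf_ab40" and "csf_ab40" in sub.columns:
                ratio_col = f"{pred}_over_ab40"
                tmp = sub.copy()
                with np.errstate(divide="ignore", invalid="ignore"):
                    tmp[ratio_col] = np.where(
                        tmp["csf_ab40"] > 0, tmp[pred] / tmp["csf_ab40"], np.nan
                    )
                variants.append((ratio_col, tmp))
            for col, frame in variants:
                spec = ModelSpecification(
                    outcome="aggregation",
                    predictors=[col],
                    covariates=csf_covs,
                    family="csf",
                    stratum=stratum,
                )
                csf_rows += _family_with_interactions(frame, spec, interactions, log)
        all_rows += _apply_family_fdr(csf_rows, apply_fdr)

        # 4) vascular burden
        vasc_pred = None
        if "wmh_volume_mm3" in sub.columns:
            vasc_pred = "wmh_volume_mm3"
        elif "fazekas" in sub.columns:
            vasc_pred = "fazekas"
        if vasc_pred:
            spec = ModelSpecification(
                outcome="aggregation",
                predictors=[vasc_pred],
                covariates=csf_covs,
                family="vascular",
                stratum=stratum,
            )
            all_rows += _family_with_interactions(sub, spec, interactions, log)
        else:
            log.append(f"WARNING vascular family disabled in {stratum}: no WMH/Fazekas column")

        # 5) cognition mixed models
        if visits is not None and len(visits):
            cog_covs = ["ventricular_volume", "age", "sex", "education_years", "apoe_e4_copies"]
            if not have(cog_covs):
                log.append(f"WARNING cognition family disabled in {stratum}: missing covariates")
            else:
                base_rows: list[AssociationResult] = []
                slope_rows: list[AssociationResult] = []
                other_rows: list[AssociationResult] = []
                for test in sorted(visits["test"].unique()):
                    spec = ModelSpecification(
                        outcome="score",
                        covariates=cog_covs,
                        family="cognition",
                        stratum=stratum,
                    )
                    try:
                        rows = fit_longitudinal(
                            visits,
                            sub,
                            spec,
                            test=test,
                            three_way=interactions,
                            model_name=f"cognition:{test}",
                        )
                    except ValueError as exc:
                        log.append(f"WARNING cognition model {test} in {stratum}: {exc}")
                        continue
                    for r in rows:
                        if r.term == "aggregation":
                            base_rows.append(_with_family(r, "cognition_baseline"))
                        elif r.term == "aggregation:time_years":
                            slope_rows.append(_with_family(r, "cognition_longitudinal"))
                        else:
                            other_rows.append(r)
                all_rows += _apply_family_fdr(base_rows, apply_fdr)
                all_rows += _apply_family_fdr(slope_rows, apply_fdr)
                all_rows += other_rows
        elif visits is not None:
            log.append(f"WARNING cognition family disabled in {stratum}: empty visit table")

    results = _rows_to_frame(all_rows)
    if len(results):
        results.insert(0, "score_source", "ab42")

    if sensitivity_ab42_40:
        if {"csf_ab42", "csf_ab40", "centiloid"} <= set(cohort.columns):
            rescored = ab42_40_rescore(cohort, fit_kwargs)
            sens = run_analysis_suite(
                rescored,
                visits,
                strata=strata,
                interactions=interactions,
                apply_fdr=apply_fdr,
                min_n=min_n,
                sensitivity_ab42_40=False,
            )
            sres = sens.results
            if len(sres):
                sres = sres.assign(score_source="ab42_40")
            results = pd.concat([results, sres], ignore_index=True)
            log.extend(f"[ab42_40] {line}" for line in sens.log)
        else:
            log.append(
                "WARNING ab42/40 sensitivity rerun disabled: missing csf_ab40 "
                "or centiloid columns"
            )
    return SuiteReport(results=results, log=log)


def _with_family(r: AssociationResult, family: str) -> AssociationResult:
    return AssociationResult(**{**r.__dict__, "family": family})


def _apply_family_fdr(rows, apply: bool):
    if not rows or not apply:
        return rows
    adj = fdr_adjust([r.p for r in rows])
    return [
        AssociationResult(**{**r.__dict__, "p_adj": float(a)})
        for r, a in zip(rows, adj)
    ]


def _family_with_interactions(frame, spec: ModelSpecification, interactions, log):
    rows = []
    try:
        rows += fit_cross_sectional(frame, spec)
    except (ValueError, KeyError) as exc:
        log.append(f"WARNING {spec.family} in {spec.stratum}: {exc}")
        return rows
    if interactions:
        for pred in spec.predictors:
            ispec = ModelSpecification(
                outcome=spec.outcome,
                predictors=list(spec.predictors),
                covariates=list(spec.covariates),
                interactions=[(pred, "severity")],
                family=spec.family,
                stratum=spec.stratum,
                categorical=spec.categorical,
            )
            try:
                irows = fit_cross_sectional(
                    frame, ispec, model_name=f"{spec.family}:{pred}_x_severity"
                )
                rows += [r for r in irows if ":" in r.term]
            except (ValueError, KeyError) as exc:
                log.append(
                    f"WARNING {spec.family} interaction {pred}xseverity in {spec.stratum}: {exc}"
                )
    return rows
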