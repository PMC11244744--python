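"""Orthogonal-distance fitting of the CSF/PET imbalance curve.

The central object is :class:`HyperbolicImbalanceModel`, a scikit-learn style
estimator.  ``fit`` performs multi-start derivative-free minimization of the
sum of orthogonal Euclidean distances between the cohort's (Centiloid,
CSF-Aβ42) points and a strictly decreasing hyperbolic curve; ``transform``
converts points into the two standardized per-subject measures (the
aggregation score, off-curve displacement, and the severity score, along-curve
position) using the moments frozen at fit time.

The objective is the plain sum of distances (L1 over orthogonal residuals);
a sum-of-squares variant is available via ``objective="l2"``.  The
monotone-decreasing constraint is enforced by a large smooth penalty so the
search can traverse infeasible parameter regions.
"""

from __future__ import annotations

import json

import numpy as np
from scipy import optimize
from scipy.stats import qmc
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import __version__ as _pkg_version
from .curves import (
    HyperbolaParams,
    auto_domain,
    evaluate_curve,
    is_strictly_decreasing,
    monotonicity_violation,
)
from .geometry import _points_to_arrays, project_points

__all__ = [
    "HyperbolicImbalanceModel",
    "FitError",
    "fit_imbalance_model",
    "pseudo_r_squared",
]

_PENALTY = 1e6


class FitError(RuntimeError):
    """All restarts of the curve fit failed or the constraint was infeasible."""


def _vertical_lsq(form, x, y, c):
    """Closed-form (a, b) and vertical SSE for fixed c; None if infeasible."""
    if form == "reciprocal":
        basis = 1.0 / (x - c)
    elif form == "rational":
        basis = x / (x - c)
    else:
        arg = x - c
        if np.any(arg <= 0):
            return None
        basis = np.log10(arg)
    if not np.all(np.isfinite(basis)):
        return None
    design = np.column_stack([np.ones_like(x), basis])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return float(coef[0]), float(coef[1]), float(resid @ resid)


def _initial_candidates(form, x, y, domain_override, n_side=24):
    """Vertical (y-on-x) least-squares initializations of (a, b, c).

    For fixed c every family is linear in (a, b), so c is scanned on a
    geometric grid on both admissible sides of the data range, (a, b) solved
    in closed form, and the best scan points refined by 1-D bounded
    minimization of the SSE profile over c (the profile has a sharp minimum
    that a coarse grid misses).  Candidates are ranked by vertical SSE with
    monotone-decreasing candidates preferred.
    """
    lo_d, hi_d = float(np.min(x)), float(np.max(x))
    width = max(hi_d - lo_d, 1e-6)
    offsets = width * np.geomspace(1e-3, 10.0, n_side)
    c_cands = list(lo_d - offsets)
    if form != "log10":  # pole may also sit right of the data
        c_cands += list(hi_d + offsets)

    scan = []
    for c in c_cands:
        sol = _vertical_lsq(form, x, y, float(c))
        if sol is not None:
            scan.append((sol[2], float(c), sol[0], sol[1]))
    if not scan:
        raise FitError(f"no feasible initialization found for form {form!r}")
    scan.sort()

    # refine c around the best scan points (profile SSE is cheap)
    refined = []
    for sse, c0, a0, b0 in scan[:4]:
        side_left = c0 < lo_d
        off0 = (lo_d - c0) if side_left else (c0 - hi_d)
        lo_off, hi_off = off0 / 1.6, off0 * 1.6

        def profile(log_off):
            off = np.exp(log_off)
            c = lo_d - off if side_left else hi_d + off
            sol = _vertical_lsq(form, x, y, c)
            return sol[2] if sol is not None else np.inf

        res = optimize.minimize_scalar(
            profile,
            bounds=(np.log(lo_off), np.log(hi_off)),
            method="bounded",
            options={"xatol": 1e-10},
        )
        off = float(np.exp(res.x))
        c = lo_d - off if side_left else hi_d + off
        sol = _vertical_lsq(form, x, y, c)
        if sol is not None and sol[2] <= sse:
            refined.append((sol[2], c, sol[0], sol[1]))
        refined.append((sse, c0, a0, b0))

    out = []
    for sse, c, a, b in refined + scan[4:]:
        dom = domain_override or auto_domain(form, c, x)
        params = HyperbolaParams(form, a, b, c, dom)
        mono = is_strictly_decreasing(params)
        out.append((not mono, sse, (a, b, c)))
    out.sort(key=lambda t: (t[0], t[1]))
    return [cand for *_, cand in out]


class HyperbolicImbalanceModel(BaseEstimator, TransformerMixin):
    """Continuous CSF/PET amyloid-imbalance model.

    Parameters
    ----------
    form : {"rational", "reciprocal", "log10"}
        Curve family; see :mod:`abimbalance.curves`.
    scaling : None, "zscore" or (sx, sy)
        Axis scaling applied before distances are measured.  ``None`` fits in
        the supplied units; ``"zscore"`` divides each axis by its cohort SD
        (resolved factors are frozen into the model).
    objective : {"l1", "l2"}
        Sum of distances (default) or sum of squared distances.
    n_restarts : int
        Multi-start count: the first start is a vertical least-squares
        initialization, the rest Latin-hypercube perturbations of it.
    random_state : int
        Seed for the restart perturbations (the fit is otherwise
        deterministic).
    domain : (lo, hi) or None
        Curve domain override.  Default: data range padded by 5 Centiloid,
        clamped a small margin away from the family's pole.
    grid_size : int
        Projection bracketing resolution.
    proj_tol : float
        Projection refinement tolerance, relative to the domain width, for
        the final stored projections.
    fit_proj_tol : float
        Looser projection tolerance used inside the optimization loop.
    maxfev : int
        Function-evaluation budget per restart (Nelder-Mead).

    Attributes
    ----------
    params_ : HyperbolaParams
    projections_ : dict of arrays (t, px, py, distance, side, out_of_domain)
    objective_value_ : float
        Sum of orthogonal distances at the optimum (fitting scale).
    pseudo_r2_ : float
        1 - sum(d_i^2) / sum(||p_i - centroid||^2), computed in the fitting
        scale.
    agg_mean_, agg_sd_ : float
        Moments of the raw signed distances (aggregation standardization).
    sev_ref_t_, sev_mean_, sev_sd_ : float
        Median arc position (reference point) and moments of the raw signed
        chord distances (severity standardization).
    converged_ : bool
    n_restarts_used_ : int
    """

    def __init__(
        self,
        form: str = "rational",
        scaling=None,
        objective: str = "l1",
        n_restarts: int = 20,
        random_state: int = 20240611,
        domain: tuple[float, float] | None = None,
        grid_size: int = 512,
        proj_tol: float = 1e-8,
        fit_proj_tol: float = 1e-4,
        maxfev: int = 3000,
    ):
        self.form = form
        self.scaling = scaling
        self.objective = objective
        self.n_restarts = n_restarts
        self.random_state = random_state
        self.domain = domain
        self.grid_size = grid_size
        self.proj_tol = proj_tol
        self.fit_proj_tol = fit_proj_tol
        self.maxfev = maxfev

    # -- helpers -----------------------------------------------------------
    def _validate_points(self, X) -> tuple[np.ndarray, np.ndarray]:
        x, y = _points_to_arrays(X)
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("input points contain non-finite coordinates")
        return x, y

    def _resolve_scaling(self, x, y) -> tuple[float, float]:
        if self.scaling is None or self.scaling == "none":
            return 1.0, 1.0
        if self.scaling == "zscore":
            sx, sy = float(np.std(x, ddof=1)), float(np.std(y, ddof=1))
            if sx <= 0 or sy <= 0:
                raise ValueError("zscore scaling needs spread on both axes")
            return sx, sy
        sx, sy = float(self.scaling[0]), float(self.scaling[1])
        if sx <= 0 or sy <= 0:
            raise ValueError("scaling factors must be positive")
        return sx, sy

    def _penalized_objective(self, theta, scales, x, y, sxy, data_scale):
        a, b, c = theta * scales
        try:
            dom = self.domain or auto_domain(self.form, c, x)
            params = HyperbolaParams(self.form, a, b, c, dom)
        except ValueError:
            return _PENALTY * 2.0 * data_scale
        viol = monotonicity_violation(params)
        if viol > 0:
            return _PENALTY * viol * data_scale
        try:
            res = project_points(
                params,
                x,
                y,
                sxy,
                grid_size=self.grid_size,
                tol=self.fit_proj_tol,
            )
        except ValueError:
            return _PENALTY * 2.0 * data_scale
        d = res["distance"]
        val = float(np.sum(d**2) if self.objective == "l2" else np.sum(d))
        if not np.isfinite(val):
            return _PENALTY * 2.0 * data_scale
        return val

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y=None):
        """Fit the curve to a cohort of (Centiloid, CSF) points."""
        xx, yy = self._validate_points(X)
        n = xx.size
        if n < 10:
            raise ValueError(f"need at least 10 points to fit, got {n}")
        if np.std(xx) == 0 or np.std(yy) == 0:
            raise ValueError("x and y must each have nonzero spread")
        if self.objective not in ("l1", "l2"):
            raise ValueError(f"unknown objective {self.objective!r}")
        sx, sy = self._resolve_scaling(xx, yy)
        sxy = (sx, sy)
        data_scale = n * float(
            np.hypot(np.ptp(xx) / sx, np.ptp(yy) / sy) + 1.0
        )

        cands = _initial_candidates(self.form, xx, yy, self.domain)
        seeds = [np.array(c, dtype=float) for c in cands[:3]]
        base = seeds[0]
        # optimize in units of the initial guess so Nelder-Mead tolerances
        # are relative; floor guards against near-zero components (e.g. c)
        scales = np.maximum(np.abs(base), 1e-3)

        rng = np.random.default_rng(self.random_state)
        n_extra = max(self.n_restarts - len(seeds), 0)
        if n_extra:
            sampler = qmc.LatinHypercube(d=3, seed=rng)
            u = sampler.random(n_extra)  # in [0,1]^3
            for row in u:
                fac = np.exp((row - 0.5) * 1.5)  # multiplicative in [~0.47, ~2.1]
                seeds.append(base * fac)
        seeds = seeds[: max(self.n_restarts, 1)]

        # two-stage multistart: short coarse runs from every seed, then one
        # tight Nelder-Mead polish of the best coarse optimum
        best = None
        log = []
        coarse_budget = min(300, self.maxfev)
        for k, s0 in enumerate(seeds):
            theta0 = s0 / scales
            res = optimize.minimize(
                self._penalized_objective,
                theta0,
                args=(scales, xx, yy, sxy, data_scale),
                method="Nelder-Mead",
                options={
                    "maxfev": coarse_budget,
                    "maxiter": coarse_budget,
                    "xatol": 1e-3,
                    "fatol": 1e-6 * data_scale,
                    "adaptive": True,
                },
            )
            log.append(
                {
                    "restart": k,
                    "fun": float(res.fun),
                    "nfev": int(res.nfev),
                    "success": bool(res.success),
                    "theta": list(map(float, res.x * scales)),
                }
            )
            if best is None or res.fun < best.fun:
                best = res
        assert best is not None
        polish = optimize.minimize(
            self._penalized_objective,
            best.x,
            args=(scales, xx, yy, sxy, data_scale),
            method="Nelder-Mead",
            options={
                "maxfev": self.maxfev,
                "maxiter": self.maxfev,
                "xatol": 1e-5,
                "fatol": 1e-9 * data_scale,
                "adaptive": True,
            },
        )
        if polish.fun <= best.fun:
            best = polish
        log.append(
            {
                "restart": "polish",
                "fun": float(best.fun),
                "nfev": int(polish.nfev),
                "success": bool(polish.success),
                "theta": list(map(float, best.x * scales)),
            }
        )
        a, b, c = best.x * scales
        dom = self.domain or auto_domain(self.form, c, xx)
        params = HyperbolaParams(self.form, float(a), float(b), float(c), dom)
        if monotonicity_violation(params) > 0 or best.fun >= _PENALTY:
            raise FitError(
                "curve fit did not reach a feasible monotone-decreasing "
                f"solution; restart log: {log}"
            )

        proj = project_points(
            params, xx, yy, sxy, grid_size=self.grid_size, tol=self.proj_tol
        )
        d = proj["distance"]
        self.params_ = params
        self.scaling_ = sxy
        # characteristic plane scale (scaled units); spreads below ~1e-10 of
        # it are numerically indistinguishable from an all-on-curve cohort
        self.plane_scale_ = float(np.hypot(np.ptp(xx) / sx, np.ptp(yy) / sy))
        self.projections_ = proj
        self.objective_value_ = float(np.sum(d))
        self.pseudo_r2_ = _pseudo_r2(xx, yy, d, sxy)
        raw = proj["side"] * d
        self.agg_mean_ = float(np.mean(raw))
        self.agg_sd_ = float(np.std(raw, ddof=1))
        t = proj["t"]
        t_ref = float(np.median(t))
        raw_sev = _signed_chord(params, t, t_ref, sxy)
        self.sev_ref_t_ = t_ref
        self.sev_mean_ = float(np.mean(raw_sev))
        self.sev_sd_ = float(np.std(raw_sev, ddof=1))
        self.converged_ = bool(best.success)
        self.n_restarts_used_ = len(seeds)
        self.restart_log_ = log
        self.n_points_ = n
        return self

    def predict(self, x):
        """Curve value (expected CSF level) at PET burden ``x``."""
        check_is_fitted(self, "params_")
        return evaluate_curve(self.params_, x)

    def transform(self, X):
        """Standardized (aggregation, severity) scores for points ``X``.

        Uses the standardization moments frozen at fit time, so new subjects
        are scored on the fitting cohort's scale.  Returns an (n, 2) array.
        """
        check_is_fitted(self, "params_")
        from .scoring import score_new_subjects  # local import, avoids cycle

        table = score_new_subjects(self, X)
        return table[["aggregation", "severity"]].to_numpy()

    # -- serialization -----------------------------------------------------
    def to_json_dict(self) -> dict:
        check_is_fitted(self, "params_")
        return {
            "software": {"package": "abimbalance", "version": _pkg_version},
            "curve": self.params_.to_dict(),
            "scaling_spec": self.scaling if not isinstance(self.scaling, tuple) else list(self.scaling),
            "scaling": [self.scaling_[0], self.scaling_[1]],
            "objective": self.objective,
            "moments": {
                "aggregation": {"mean": self.agg_mean_, "sd": self.agg_sd_},
                "severity": {
                    "ref_t": self.sev_ref_t_,
                    "mean": self.sev_mean_,
                    "sd": self.sev_sd_,
                },
            },
            "pseudo_r2": self.pseudo_r2_,
            "objective_value": self.objective_value_,
            "plane_scale": self.plane_scale_,
            "converged": self.converged_,
            "n_points": self.n_points_,
            "grid_size": self.grid_size,
            "proj_tol": self.proj_tol,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)

    @classmethod
    def from_json_dict(cls, d: dict) -> "HyperbolicImbalanceModel":
        """Rebuild a scoring-capable model from its JSON document.

        The reconstructed object carries the frozen curve and moments and can
        score new subjects bit-identically; it does not carry the per-subject
        fit projections.
        """
        curve = HyperbolaParams.from_dict(d["curve"])
        spec = d.get("scaling_spec")
        obj = cls(
            form=curve.form,
            scaling=tuple(spec) if isinstance(spec, list) else spec,
            objective=d.get("objective", "l1"),
            domain=curve.domain,
            grid_size=int(d.get("grid_size", 512)),
            proj_tol=float(d.get("proj_tol", 1e-8)),
        )
        obj.params_ = curve
        obj.scaling_ = (float(d["scaling"][0]), float(d["scaling"][1]))
        m = d["moments"]
        obj.agg_mean_ = float(m["aggregation"]["mean"])
        obj.agg_sd_ = float(m["aggregation"]["sd"])
        obj.sev_ref_t_ = float(m["severity"]["ref_t"])
        obj.sev_mean_ = float(m["severity"]["mean"])
        obj.sev_sd_ = float(m["severity"]["sd"])
        obj.pseudo_r2_ = float(d["pseudo_r2"])
        obj.objective_value_ = float(d["objective_value"])
        obj.plane_scale_ = float(d.get("plane_scale", 1.0))
        obj.converged_ = bool(d["converged"])
        obj.n_points_ = int(d["n_points"])
        obj.n_restarts_used_ = 0
        return obj

    @classmethod
    def from_json(cls, path) -> "HyperbolicImbalanceModel":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))


def _signed_chord(params, t, t_ref, sxy) -> np.ndarray:
    """Signed straight-line distance along the curve from the reference point.

    Positive for arc positions at higher Centiloid than the reference
    ("more advanced amyloid pathology").
    """
    sx, sy = sxy
    y = evaluate_curve(params, t, check_domain=False)
    y_ref = evaluate_curve(params, t_ref)
    chord = np.hypot((t - t_ref) / sx, (y - y_ref) / sy)
    return np.sign(t - t_ref) * chord


def _pseudo_r2(x, y, d, sxy) -> float:
    sx, sy = sxy
    u, v = x / sx, y / sy
    tot = float(np.sum((u - u.mean()) ** 2 + (v - v.mean()) ** 2))
    if tot <= 0:
        raise ValueError("pseudo-R2 undefined: all points identical")
    return 1.0 - float(np.sum(d**2)) / tot


def pseudo_r_squared(model: HyperbolicImbalanceModel, points) -> float:
    """1 - sum(d^2) / sum(||p - centroid||^2) in the fitting scale.

    Recomputes projections of ``points`` under the fitted curve; for the
    fitting cohort this reproduces ``model.pseudo_r2_``.
    """
    check_is_fitted(model, "params_")
    x, y = _points_to_arrays(points)
    res = project_points(
        model.params_, x, y, model.scaling_, grid_size=model.grid_size, tol=model.proj_tol
    )
    return _pseudo_r2(x, y, res["distance"], model.scaling_)


def fit_imbalance_model(cohort, fit_config: dict | None = None) -> HyperbolicImbalanceModel:
    """Functional wrapper: fit :class:`HyperbolicImbalanceModel` to a cohort.

    ``cohort`` may be a list of :class:`~abimbalance.geometry.BiomarkerPoint`,
    an (n, 2) array, or an (x, y) pair of arrays.  ``fit_config`` keys map to
    the estimator's constructor parameters (``seed`` is accepted as an alias
    for ``random_state``).
    """
    cfg = dict(fit_config or {})
    if "seed" in cfg:
        cfg["random_state"] = cfg.pop("seed")
    return HyperbolicImbalanceModel(**cfg).fit(cohort)
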