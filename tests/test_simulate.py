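"""Synthetic-cohort generator: determinism, geometry, couplings, cognition."""

import numpy as np
import pandas as pd
import pytest

from abimbalance.curves import evaluate_curve
from abimbalance.geometry import project_points
from abimbalance.model import HyperbolicImbalanceModel
from abimbalance.scoring import score_table
from abimbalance.simulate import (
    CognitionConfig,
    MixtureConfig,
    SimulationConfig,
    simulate_cohort,
    simulate_longitudinal,
)


def test_same_seed_gives_identical_bytes(tmp_path):
    cfg = SimulationConfig(n=60, seed=123)
    a, ta = simulate_cohort(cfg)
    b, tb = simulate_cohort(cfg)
    pd.testing.assert_frame_equal(a, b)
    pd.testing.assert_frame_equal(ta, tb)
    pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
    a.to_csv(pa, index=False)
    b.to_csv(pb, index=False)
    assert pa.read_bytes() == pb.read_bytes()
    va = simulate_longitudinal(a, ta, cfg)
    vb = simulate_longitudinal(b, tb, cfg)
    pd.testing.assert_frame_equal(va, vb)


def test_zero_noise_zero_effects_lies_on_curve():
    cov = dict(effect_apoe_hom=0.0, effect_apoe_het=0.0, effect_female=0.0, effect_vv_z=0.0)
    cfg = SimulationConfig(n=200, noise_sd=0.0, covariates=cov, seed=3)
    cohort, truth = simulate_cohort(cfg)
    params = cfg.curve.to_params()
    x = cohort["centiloid"].to_numpy()
    y = cohort["csf_ab42"].to_numpy()
    assert np.allclose(x, truth["true_t"])
    assert np.allclose(y, evaluate_curve(params, x))
    d = project_points(params, x, y)["distance"]
    assert d.max() < 1e-6
    # and the fitter recovers the generating curve to optimizer tolerance
    m = HyperbolicImbalanceModel(scaling="zscore", n_restarts=2).fit(
        np.column_stack([x, y])
    )
    assert abs(m.params_.a - params.a) / params.a < 1e-3
    assert abs(m.params_.b - params.b) / abs(params.b) < 1e-3
    assert abs(m.params_.c - params.c) / abs(params.c) < 1e-3


def test_generator_displacement_matches_scorer_geometry():
    """Fitting + scoring a simulated cohort recovers the generator's true
    standardized scores (displacement along the scaled normal is exactly the
    quantity the scorer estimates)."""
    cfg = SimulationConfig(n=400, seed=11)
    cohort, truth = simulate_cohort(cfg)
    m = HyperbolicImbalanceModel(scaling="zscore", n_restarts=2, maxfev=800).fit(
        cohort[["centiloid", "csf_ab42"]].to_numpy()
    )
    tab = score_table(m)
    r_agg = np.corrcoef(tab["aggregation"], truth["true_aggregation"])[0, 1]
    r_sev = np.corrcoef(tab["severity"], truth["true_severity"])[0, 1]
    assert r_agg > 0.99
    assert r_sev > 0.999


def test_round_trip_score_recovery_across_seeds():
    """Fit + score on full-size simulated cohorts recovers the generator's
    true standardized aggregation scores with correlation >= 0.99 in every
    one of 20 seeded replicates (noise dominating covariate effects)."""
    zero_eff = dict(
        effect_apoe_hom=0.0, effect_apoe_het=0.0, effect_female=0.0, effect_vv_z=0.0
    )
    for seed in range(20):
        cfg = SimulationConfig(n=800, seed=3000 + seed, covariates=zero_eff)
        cohort, truth = simulate_cohort(cfg)
        m = HyperbolicImbalanceModel(scaling="zscore", n_restarts=1, maxfev=600).fit(
            cohort[["centiloid", "csf_ab42"]].to_numpy()
        )
        tab = score_table(m)
        r = np.corrcoef(tab["aggregation"], truth["true_aggregation"])[0, 1]
        assert r >= 0.99, f"seed {seed}: r={r:.4f}"


def test_apoe_homozygotes_shift_toward_soluble():
    """A negative homozygote coefficient lowers mean aggregation of
    APOE-e4 homozygotes relative to noncarriers in nearly every replicate."""
    diffs = []
    for seed in range(50):
        cfg = SimulationConfig(n=300, seed=seed)
        _, truth = simulate_cohort(cfg)
        cohort, _ = simulate_cohort(cfg)
        agg = truth["true_aggregation"].to_numpy()
        apoe = cohort["apoe_e4_copies"].to_numpy()
        if (apoe == 2).sum() >= 5:
            diffs.append(agg[apoe == 2].mean() - agg[apoe == 0].mean())
    assert len(diffs) > 30
    assert np.mean(np.array(diffs) < 0) >= 0.9


def test_tau_couples_positively_to_displacement_and_position():
    cfg = SimulationConfig(n=2000, seed=21)
    cohort, truth = simulate_cohort(cfg)
    r_d = np.corrcoef(cohort["csf_ttau"], truth["true_d"])[0, 1]
    r_t = np.corrcoef(cohort["csf_ttau"], truth["true_t"])[0, 1]
    assert r_d > 0.05
    assert r_t > 0.3


def test_mixture_outside_domain_rejected():
    with pytest.raises(ValueError, match="outside curve domain"):
        SimulationConfig(mixture=MixtureConfig(means=(5.0, 500.0)))
    with pytest.raises(ValueError, match="sum to 1"):
        MixtureConfig(weights=(0.7, 0.6))


def test_deterministic_limit_of_longitudinal():
    cog = CognitionConfig(
        random_intercept_sd=0.0,
        random_slope_sd=0.0,
        residual_sd=0.0,
        agg_time_coef=0.0,
        agg_coef=0.0,
        sev_coef=0.0,
        sev_time_coef=0.0,
        time_slope=-0.2,
        intercept=1.0,
    )
    cfg = SimulationConfig(n=30, seed=5, cognition=cog)
    cohort, truth = simulate_cohort(cfg)
    visits = simulate_longitudinal(cohort, truth, cfg)
    # identical, perfectly linear trajectories for every subject
    for t in (0.0, 1.0, 2.0, 3.0):
        vals = visits.loc[visits["time_years"] == t, "score"]
        assert np.allclose(vals, 1.0 - 0.2 * t, atol=1e-12)


def test_slope_couples_to_aggregation():
    """With a positive aggregation-by-time coefficient, per-subject OLS
    slopes correlate positively with the true aggregation score."""
    hits = 0
    n_rep = 40
    for seed in range(n_rep):
        cfg = SimulationConfig(n=150, seed=1000 + seed)
        cohort, truth = simulate_cohort(cfg)
        visits = simulate_longitudinal(cohort, truth, cfg)
        piv = visits.pivot_table(index="subject_id", columns="time_years", values="score")
        times = piv.columns.to_numpy(dtype=float)
        tc = times - times.mean()
        slopes = (piv.to_numpy() * tc).sum(axis=1) / (tc**2).sum()
        order = truth.set_index("subject_id").loc[piv.index, "true_aggregation"]
        hits += np.corrcoef(slopes, order)[0, 1] > 0
    assert hits >= 0.95 * n_rep


def test_visit_schedule_and_baseline():
    cfg = SimulationConfig(n=20, seed=2)
    cohort, truth = simulate_cohort(cfg)
    visits = simulate_longitudinal(cohort, truth, cfg)
    assert (visits["time_years"] >= 0).all()
    assert set(visits["time_years"].unique()) == {0.0, 1.0, 2.0, 3.0}
    assert visits.groupby("subject_id")["time_years"].min().eq(0.0).all()
    with pytest.raises(ValueError, match="ground truth"):
        simulate_longitudinal(cohort, truth.drop(columns=["true_aggregation"]), cfg)


def test_unknown_config_keys_rejected():
    with pytest.raises(Exception, match="typo_key"):
        SimulationConfig(typo_key=1)
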