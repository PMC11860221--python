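"""Design fits, attenuation ratios, the assortative-mating expectation and
the additive decomposition of the population effect."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

import statusgen as sg
import statusgen.decomposition as dec
from statusgen.errors import DegenerateInputError, InvalidParameterError


def _toy_frame(n=4000, r=0.3, seed=0):
    rng = np.random.default_rng(seed)
    s = rng.standard_normal(n)
    y = r * s + np.sqrt(1 - r**2) * rng.standard_normal(n)
    return pd.DataFrame(
        {
            "phenotype": y,
            "observed_pgs": s,
            "family_id": np.arange(n) // 2,
            "is_adoptee": np.zeros(n, dtype=bool),
        }
    )


# ---------------------------------------------------------------------------
# population fit
# ---------------------------------------------------------------------------


def test_population_beta_equals_correlation():
    df = _toy_frame(n=20_000, r=0.3)
    res = dec.fit_population(df)
    assert res.beta_pgs == pytest.approx(0.3, abs=0.02)
    assert res.incremental_r2 == pytest.approx(0.09, abs=0.01)
    assert res.design == "population"


def test_population_null_effect_is_flat():
    df = _toy_frame(n=5000, r=0.0, seed=1)
    res = dec.fit_population(df)
    assert res.incremental_r2 < 0.005
    assert abs(res.beta_pgs) < 3 * res.se


def test_orthogonal_covariate_leaves_beta_unchanged():
    """Frisch-Waugh: residualizing on a covariate orthogonal to outcome and
    PGS cannot move the coefficient."""
    df = _toy_frame(n=2000, seed=2)
    rng = np.random.default_rng(3)
    z = rng.standard_normal(len(df))
    X = np.column_stack([np.ones(len(df)), df["phenotype"], df["observed_pgs"]])
    df["cov"] = z - X @ np.linalg.lstsq(X, z, rcond=None)[0]
    base = dec.fit_population(df)
    with_cov = dec.fit_population(df, covariates=("cov",))
    assert with_cov.beta_pgs == pytest.approx(base.beta_pgs, abs=1e-6)


def test_zero_variance_pgs_is_degenerate():
    df = _toy_frame(n=100)
    df["observed_pgs"] = 1.0
    with pytest.raises(DegenerateInputError):
        dec.fit_population(df)


# ---------------------------------------------------------------------------
# within-sibship fit
# ---------------------------------------------------------------------------


def test_within_sibship_equals_dummy_variable_regression():
    """Family demeaning must reproduce the family-indicator OLS coefficient
    to 1e-8 (fixed-effects algebra) on a small instance."""
    cfg = sg.nurture_scenario(0.25, n_families=20, total_effect=1.0,
                              n_generations=2, seed=5)
    last = sg.simulate_population(cfg).final_generation.copy()
    last["observed_pgs"] = last["additive_score"]
    ours = dec.fit_within_sibship(last)
    z = lambda x: (x - x.mean()) / x.std(ddof=0)
    df = pd.DataFrame(
        {
            "y": z(last["phenotype"]),
            "s": z(last["observed_pgs"]),
            "fam": last["family_id"].astype(str),
        }
    )
    oracle = smf.ols("y ~ s + C(fam)", data=df).fit().params["s"]
    assert ours.beta_pgs == pytest.approx(oracle, abs=1e-8)


def test_direct_effects_only_gives_ratio_one(nurture_children):
    cfg = sg.null_scenario(n_families=8000, n_generations=2, seed=6)
    last = sg.simulate_population(cfg).final_generation.copy()
    last["observed_pgs"] = last["additive_score"]
    pop = dec.fit_population(last)
    sib = dec.fit_within_sibship(last)
    assert sib.beta_pgs / pop.beta_pgs == pytest.approx(1.0, abs=0.04)


def test_nurture_attenuates_within_sibship_by_its_share(nurture_children):
    pop = dec.fit_population(nurture_children)
    sib = dec.fit_within_sibship(nurture_children)
    assert sib.beta_pgs / pop.beta_pgs == pytest.approx(0.75, abs=0.03)


def test_singleton_families_are_dropped():
    df = _toy_frame(n=101)
    df.loc[df.index[-1], "family_id"] = 999_999
    res = dec.fit_within_sibship(df)
    assert res.n == 100


def test_no_multi_sibling_family_raises():
    df = _toy_frame(n=50)
    df["family_id"] = np.arange(50)
    with pytest.raises(DegenerateInputError):
        dec.fit_within_sibship(df)


# ---------------------------------------------------------------------------
# adoption fit
# ---------------------------------------------------------------------------


def test_adoption_recovers_direct_effect_share():
    cfg = sg.nurture_scenario(0.25, n_families=40_000, total_effect=0.3,
                              n_generations=2, adoptee_fraction=0.5, seed=7)
    last = sg.simulate_population(cfg).final_generation.copy()
    last["observed_pgs"] = last["additive_score"]
    pop = dec.fit_population(last[~last["is_adoptee"]])
    ado = dec.fit_adoption(last)
    assert ado.beta_pgs / pop.beta_pgs == pytest.approx(0.75, abs=0.04)


def test_no_nurture_adoption_ratio_is_one():
    cfg = sg.null_scenario(n_families=10_000, n_generations=2, seed=8)
    last = sg.simulate_population(cfg).final_generation.copy()
    last["observed_pgs"] = last["additive_score"]
    pop = dec.fit_population(last)
    ado = dec.fit_adoption(last)
    assert ado.beta_pgs / pop.beta_pgs == pytest.approx(1.0, abs=0.03)


def test_adoption_errors_and_warnings():
    df = _toy_frame(n=200)
    with pytest.raises(DegenerateInputError):
        dec.fit_adoption(df)
    df.loc[df.index[:20], "is_adoptee"] = True
    with pytest.warns(UserWarning, match="adoptees"):
        res = dec.fit_adoption(df)
    assert res.design == "adoption" and res.n == 20


# ---------------------------------------------------------------------------
# parental-control fit
# ---------------------------------------------------------------------------


def test_parental_control_absorbs_phenotypic_transmission():
    """When transmission is mediated by the parental phenotype itself, the
    parental-status control absorbs it: beta matches the path-tracing
    oracle (direct effect over population slope)."""
    cfg = sg.transmission_scenario(n_families=30_000, seed=9)
    ped = sg.simulate_population(cfg)
    last = ped.final_generation.copy()
    last["observed_pgs"] = last["additive_score"]
    pop = dec.fit_population(last)
    pc = dec.fit_parental_control(last)
    assert pc.beta_pgs < pop.beta_pgs
    # path-tracing oracle: conditioning on the midparent phenotype leaves
    # only the direct path plus the segregation-uncorrelated remainder
    y = last["phenotype"].to_numpy()
    s = last["additive_score"].to_numpy()
    p = last["parental_status"].to_numpy()
    zy = (y - y.mean()) / y.std()
    zs = (s - s.mean()) / s.std()
    zp = (p - p.mean()) / p.std()
    beta_oracle = (
        np.linalg.lstsq(np.column_stack([np.ones_like(zs), zp, zs]), zy,
                        rcond=None)[0][2]
    )
    assert pc.beta_pgs == pytest.approx(beta_oracle, abs=1e-8)


def test_pure_noise_parental_status_changes_nothing():
    df = _toy_frame(n=20_000, seed=10)
    rng = np.random.default_rng(11)
    df["parental_status"] = rng.standard_normal(len(df))
    base = dec.fit_population(df)
    pc = dec.fit_parental_control(df)
    assert pc.beta_pgs == pytest.approx(base.beta_pgs, abs=0.01)


def test_collinear_parental_status_is_degenerate():
    df = _toy_frame(n=500)
    df["parental_status"] = df["observed_pgs"]
    with pytest.raises(DegenerateInputError):
        dec.fit_parental_control(df)


# ---------------------------------------------------------------------------
# attenuation ratio bootstrap
# ---------------------------------------------------------------------------


def test_identical_designs_give_ratio_one_with_ci(rng):
    df = _toy_frame(n=2000, seed=12)
    pop = dec.fit_population(df)
    est = dec.attenuation_ratio(pop, pop, df, n_boot=100, rng=rng)
    assert est.ratio == 1.0
    assert est.ci_low <= 1.0 <= est.ci_high
    assert est.attenuation_pct == 0.0


def test_ratio_recovers_nurture_share_with_sane_ci(nurture_children, rng):
    """Point ratio near the generative 0.75; the percentile CI brackets the
    point estimate and respects the attenuation identity. (Coverage of the
    generative truth is checked distributionally in the acceptance suite.)"""
    pop = dec.fit_population(nurture_children)
    sib = dec.fit_within_sibship(nurture_children)
    est = dec.attenuation_ratio(sib, pop, nurture_children, n_boot=200, rng=rng)
    assert est.ratio == pytest.approx(0.75, abs=0.04)
    assert est.ci_low <= est.ratio <= est.ci_high
    assert est.ci_high - est.ci_low < 0.1
    assert est.attenuation_pct == pytest.approx(100 * (1 - est.ratio), abs=1e-12)


def test_ci_width_shrinks_with_sample_size(rng):
    widths = []
    for n_fam in (400, 1600):
        cfg = sg.nurture_scenario(0.25, n_families=n_fam, total_effect=1.0,
                                  n_generations=2, seed=13)
        last = sg.simulate_population(cfg).final_generation.copy()
        last["observed_pgs"] = last["additive_score"]
        pop = dec.fit_population(last)
        sib = dec.fit_within_sibship(last)
        est = dec.attenuation_ratio(sib, pop, last, n_boot=300, rng=rng)
        widths.append(est.ci_high - est.ci_low)
    # quadrupling families should halve the width, within bootstrap noise
    assert widths[0] / widths[1] == pytest.approx(2.0, rel=0.35)


def test_unstable_ratio_warns(rng):
    df = _toy_frame(n=300, r=0.0, seed=14)
    pop = dec.fit_population(df)
    sib = dec.fit_within_sibship(df)
    with pytest.warns(UserWarning, match="unstable"):
        dec.attenuation_ratio(sib, pop, df, n_boot=50, rng=rng)


# ---------------------------------------------------------------------------
# expected AM attenuation
# ---------------------------------------------------------------------------


def test_am_attenuation_no_mating_is_exactly_one():
    assert dec.expected_am_attenuation(0.5, 0.0, 0.6) == 1.0


def test_am_attenuation_full_capture_is_one_for_any_r():
    for r in (0.1, 0.5, 0.8):
        assert dec.expected_am_attenuation(1.0, r, 0.6) == pytest.approx(
            1.0, abs=1e-12
        )


def test_am_attenuation_monotone_in_r_and_capture_share():
    vals = [dec.expected_am_attenuation(0.3, r, 0.6) for r in (0.2, 0.4, 0.6)]
    assert vals[0] > vals[1] > vals[2]
    vals = [dec.expected_am_attenuation(k, 0.5, 0.6) for k in (0.2, 0.5, 0.9)]
    assert vals[0] < vals[1] < vals[2]


def test_am_attenuation_band_under_strong_latent_matching():
    """Partner matching around r = 0.5-0.7 on a highly heritable latent
    status factor puts the expected within-family attenuation in the
    twenties of percent."""
    att = [
        100 * (1 - dec.expected_am_attenuation(k, r, 0.6))
        for k, r in [(0.5, 0.6), (0.35, 0.6), (0.5, 0.7)]
    ]
    assert all(15.0 < a < 35.0 for a in att)


def test_am_closed_form_matches_simulation_oracle():
    for k, r in [(0.3, 0.6), (0.6, 0.3)]:
        closed = dec.expected_am_attenuation(k, r, 0.6)
        sim = dec.simulate_am_attenuation(k, r, 0.6, n_pairs=150_000,
                                          n_generations=18, seed=15)
        assert sim == pytest.approx(closed, abs=0.01)


def test_am_attenuation_rejects_bad_parameters():
    with pytest.raises(InvalidParameterError):
        dec.expected_am_attenuation(0.0, 0.5)
    with pytest.raises(InvalidParameterError):
        dec.expected_am_attenuation(0.5, 1.0)


# ---------------------------------------------------------------------------
# spousal PGS correlation
# ---------------------------------------------------------------------------


def test_spousal_pgs_matches_phenotypic_benchmark_single_round(rng):
    cfg = sg.SimulationConfig(
        n_families=20_000, n_generations=2, beta_direct=0.76, beta_nurture=0.0,
        var_env=1.0, r_mate=0.5, pgs_target_r2=None, adoptee_fraction=0.0,
        seed=16,
    )
    ped = sg.simulate_population(cfg)
    parents = ped.persons[ped.persons["generation"] == 0].copy()
    parents["observed_pgs"] = parents["additive_score"]
    res = dec.spousal_pgs_correlation(parents, n_boot=100, rng=rng)
    assert res.expected_ci[0] <= res.observed <= res.expected_ci[1] or (
        abs(res.observed - res.expected) < 0.02
    )
    assert res.r_phenotype == pytest.approx(0.5, abs=0.02)


def test_spousal_pgs_zero_under_random_mating(rng):
    cfg = sg.null_scenario(n_families=5000, n_generations=2, seed=17)
    ped = sg.simulate_population(cfg)
    parents = ped.persons[ped.persons["generation"] == 0].copy()
    parents["observed_pgs"] = parents["additive_score"]
    res = dec.spousal_pgs_correlation(parents, n_boot=50, rng=rng)
    assert abs(res.observed) < 0.05
    assert abs(res.expected) < 0.05


def test_spousal_pgs_needs_thirty_couples(rng):
    cfg = sg.null_scenario(n_families=20, n_generations=2, seed=18)
    ped = sg.simulate_population(cfg)
    parents = ped.persons[ped.persons["generation"] == 0].copy()
    parents["observed_pgs"] = parents["additive_score"]
    with pytest.raises(DegenerateInputError):
        dec.spousal_pgs_correlation(parents, n_boot=10, rng=rng)


# ---------------------------------------------------------------------------
# additive decomposition
# ---------------------------------------------------------------------------


def test_printed_attenuations_imply_direct_share_range():
    res = dec.decompose_population_effect([23, 22, 27, 21])
    assert res.direct_shares == (77.0, 78.0, 73.0, 79.0)
    assert res.direct_range == (73.0, 79.0)


def test_zero_attenuations_give_full_direct_share():
    res = dec.decompose_population_effect([0.0], am_attenuation_range=(0.0, 0.0))
    assert res.direct_range == (100.0, 100.0)
    assert res.decompositions[0].direct_pct == 100.0


def test_residual_gap_identity():
    res = dec.decompose_population_effect(
        [27.0], am_attenuation_range=(27.0, 27.0), within_family_attenuation=54.0
    )
    assert res.residual_gap_range == (0.0, 0.0)


def test_effect_decomposition_must_sum_to_hundred():
    with pytest.raises(InvalidParameterError):
        dec.EffectDecomposition(indirect_pct=30, am_pct=30, direct_pct=30)
    with pytest.raises(InvalidParameterError):
        dec.decompose_population_effect([120.0])
    with pytest.raises(InvalidParameterError):
        dec.decompose_population_effect([60.0], am_attenuation_range=(50.0, 50.0))
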