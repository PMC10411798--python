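import math

import numpy as np
import pytest
from scipy import integrate, stats

from trioscan.inference import (
    InferenceResult,
    McmcConfig,
    PosteriorSummary,
    bayes_factor,
    bayes_factor_quadrature,
    compute_dic,
    run_mcmc,
    select_pattern,
)
from trioscan.models import null_loglik
from trioscan.transmission import TransmissionSummary


def _counts(kA, kB):
    return TransmissionSummary("x", sire_counts=(kA, kB))


DESK = McmcConfig.desk


def test_mcmc_determinism():
    s = _counts(14, 6)
    a = run_mcmc(s, "allelic_overall", DESK(seed=7))
    b = run_mcmc(s, "allelic_overall", DESK(seed=7))
    assert np.array_equal(a.draws, b.draws)
    c = run_mcmc(s, "allelic_overall", DESK(seed=8))
    assert not np.array_equal(a.draws, c.draws)


def test_mcmc_conjugate_oracle_spot_checks():
    """Overall-allelic posterior is the shifted Beta(kA+1, kB+1)."""
    rng = np.random.default_rng(0)
    for _ in range(5):
        n = int(rng.integers(10, 200))
        k = int(rng.binomial(n, 0.5))
        post = run_mcmc(_counts(k, n - k), "allelic_overall", DESK(seed=int(rng.integers(2**16))))
        exact = stats.beta(k + 1, n - k + 1)
        se = post.mc_se()[0]
        assert post.mean[0] == pytest.approx(exact.mean() - 0.5, abs=3 * se)
        assert post.sd[0] == pytest.approx(exact.std(), abs=3 * exact.std() / math.sqrt(2 * post.ess[0]) + 1e-3)


def test_mcmc_symmetric_data_centred():
    post = run_mcmc(_counts(50, 50), "allelic_overall", DESK(seed=1))
    assert abs(post.mean[0]) < 3 * post.mc_se()[0] + 0.01


def test_mcmc_no_data_errors():
    with pytest.raises(ValueError, match="no informative data"):
        run_mcmc(TransmissionSummary("x"), "allelic_overall", DESK())


def test_mcmc_posterior_within_space():
    for tag in ("allelic_overall", "allelic_parent_specific", "genotypic"):
        s = TransmissionSummary("x", sire_counts=(18, 2), dam_counts=(5, 5), hethet_cells=(12, 20, 3))
        post = run_mcmc(s, tag, DESK(seed=3))
        assert (post.ci_low <= post.median).all() and (post.median <= post.ci_high).all()
        if tag != "genotypic":
            assert (post.draws >= -0.5).all() and (post.draws <= 0.5).all()


# --- Bayes factors -----------------------------------------------------------


@pytest.mark.parametrize(
    "kA, kB, expected_bf",
    [(10, 10, 0.27026), (20, 0, 4.9932e4), (0, 0, 1.0)],
)
def test_bf_closed_form_examples(kA, kB, expected_bf):
    log10bf = bayes_factor(_counts(kA, kB), "allelic_overall")
    assert 10**log10bf == pytest.approx(expected_bf, rel=1e-4)


def test_bf_closed_form_vs_quadrature():
    rng = np.random.default_rng(2)
    for _ in range(10):
        n = int(rng.integers(1, 500))
        k = int(rng.integers(0, n + 1))
        s = _counts(k, n - k)
        assert bayes_factor(s, "allelic_overall") == pytest.approx(
            bayes_factor_quadrature(s), rel=1e-6, abs=1e-6
        )


def test_bf_monotone_in_distortion():
    n = 60
    bfs = [bayes_factor(_counts(k, n - k), "allelic_overall") for k in range(30, 61)]
    assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))


def test_bf_parent_specific_factorises_without_coupling():
    s = TransmissionSummary("x", sire_counts=(15, 5), dam_counts=(8, 12))
    expected = bayes_factor(_counts(15, 5), "allelic_overall") + bayes_factor(
        _counts(8, 12), "allelic_overall"
    )
    assert bayes_factor(s, "allelic_parent_specific") == pytest.approx(expected, rel=1e-9)


def test_bf_parent_specific_with_coupling_matches_numeric_integral():
    """het x het AB offspring couple the two parents' likelihoods."""
    s = TransmissionSummary("x", sire_counts=(9, 3), dam_counts=(6, 2), hethet_cells=(4, 7, 1))
    ll0 = null_loglik(s, "allelic_parent_specific")

    def integrand(ad, as_):
        ps, pd = 0.5 + as_, 0.5 + ad
        ll = (
            9 * math.log(ps) + 3 * math.log(1 - ps) + 6 * math.log(pd) + 2 * math.log(1 - pd)
            + 7 * math.log(ps * (1 - pd) + (1 - ps) * pd)
        )
        return math.exp(ll - ll0)

    marg, _ = integrate.dblquad(integrand, -0.5, 0.5, -0.5, 0.5, epsabs=1e-12, epsrel=1e-10)
    assert bayes_factor(s, "allelic_parent_specific", grid_size=401) == pytest.approx(
        math.log10(marg), abs=5e-3
    )


@pytest.mark.filterwarnings("ignore::scipy.integrate.IntegrationWarning")
def test_bf_genotypic_matches_numeric_integral():
    from trioscan.models import genotypic_loglik, GenotypicParams, prior_density

    s = TransmissionSummary("x", hethet_cells=(10, 14, 4), hethom_aa_cells=(6, 3))
    ll0 = null_loglik(s, "genotypic")

    def f(dg, ag):
        p = GenotypicParams(ag, dg)
        pr = prior_density(p)
        if pr == 0.0:
            return 0.0
        return math.exp(genotypic_loglik(p=p, s=s) - ll0) * pr

    def prior_only(dg, ag):
        return prior_density(GenotypicParams(ag, dg))

    num, _ = integrate.dblquad(f, -1, 1, -1, 1, epsabs=1e-11, epsrel=1e-9)
    z, _ = integrate.dblquad(prior_only, -1, 1, -1, 1, epsabs=1e-11, epsrel=1e-9)
    assert bayes_factor(s, "genotypic", grid_size=401) == pytest.approx(
        math.log10(num / z), abs=2e-2
    )


# --- DIC ---------------------------------------------------------------------


def test_dic_degenerate_chain():
    s = _counts(12, 8)
    draws = np.zeros((500, 1))
    expected = -2 * null_loglik(s, "allelic_overall")
    assert compute_dic(s, draws, "allelic_overall") == pytest.approx(expected)


def test_dic_needs_enough_draws():
    with pytest.raises(ValueError, match="100"):
        compute_dic(_counts(5, 5), np.zeros((50, 1)), "allelic_overall")


def test_dic_prefers_distortion_when_present():
    s = _counts(70, 30)
    post = run_mcmc(s, "allelic_overall", DESK(seed=5))
    dic = compute_dic(s, post.draws, "allelic_overall")
    dic_null = -2 * null_loglik(s, "allelic_overall")  # zero-parameter reference
    assert dic < dic_null


# --- pattern selection -------------------------------------------------------


def _fake_result(tag, dic, means, ci_lo, ci_hi):
    names = {
        "allelic_overall": ("alpha",),
        "allelic_parent_specific": ("alpha_s", "alpha_d"),
        "genotypic": ("alpha_g", "delta_g"),
    }[tag]
    k = len(names)
    post = PosteriorSummary(
        params=names,
        mean=np.array(means, dtype=float),
        median=np.array(means, dtype=float),
        sd=np.full(k, 0.05),
        ci_low=np.array(ci_lo, dtype=float),
        ci_high=np.array(ci_hi, dtype=float),
        ess=np.full(k, 1000.0),
    )
    return InferenceResult(model_tag=tag, posterior=post, log10_bf=3.0, dic=dic)


def test_select_pattern_clear_allelic_winner():
    call = select_pattern(
        _fake_result("allelic_overall", 100.0, [0.3], [0.2], [0.4]),
        _fake_result("allelic_parent_specific", 104.0, [0.3, 0.3], [0.1, 0.1], [0.5, 0.5]),
        _fake_result("genotypic", 110.0, [0.0, 0.0], [-0.1, -0.1], [0.1, 0.1]),
        dic_margin=3.0,
    )
    assert call.label == "overall" and call.family == "allelic"
    assert not call.tie
    assert call.magnitude == pytest.approx(0.3)


def test_select_pattern_tie_defaults_to_simplest():
    call = select_pattern(
        _fake_result("allelic_overall", 100.0, [0.25], [0.1], [0.4]),
        _fake_result("allelic_parent_specific", 101.5, [0.3, 0.0], [0.1, -0.2], [0.5, 0.2]),
        _fake_result("genotypic", 102.0, [0.1, 0.0], [-0.1, -0.1], [0.3, 0.1]),
        dic_margin=3.0,
    )
    assert call.family == "allelic" and call.label == "overall"
    assert call.tie
    assert "tie-default" in call.display


def test_select_pattern_stallion_and_mare():
    ps = _fake_result("allelic_parent_specific", 95.0, [0.35, 0.02], [0.2, -0.15], [0.5, 0.19])
    call = select_pattern(
        _fake_result("allelic_overall", 100.0, [0.2], [0.1], [0.3]),
        ps,
        _fake_result("genotypic", 110.0, [0.0, 0.0], [-0.1, -0.1], [0.1, 0.1]),
    )
    assert call.label == "stallion"
    assert call.magnitude == pytest.approx(0.35)
    mare = _fake_result("allelic_parent_specific", 95.0, [0.02, -0.35], [-0.15, -0.5], [0.19, -0.2])
    call2 = select_pattern(
        _fake_result("allelic_overall", 100.0, [0.2], [0.1], [0.3]),
        mare,
        _fake_result("genotypic", 110.0, [0.0, 0.0], [-0.1, -0.1], [0.1, 0.1]),
    )
    assert call2.label == "mare"


def test_select_pattern_heterosis():
    call = select_pattern(
        _fake_result("allelic_overall", 100.0, [0.0], [-0.1], [0.1]),
        _fake_result("allelic_parent_specific", 101.0, [0.0, 0.0], [-0.1, -0.1], [0.1, 0.1]),
        _fake_result("genotypic", 90.0, [0.1, 0.4], [-0.05, 0.2], [0.25, 0.6]),
    )
    assert call.label == "heterosis" and call.family == "genotypic"
    assert call.magnitude == pytest.approx(0.4)
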