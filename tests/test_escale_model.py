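import numpy as np
import pytest

from psibound.escale_model import (
    EModel,
    EpsilonRecord,
    classify_records,
    epsilon,
    fit_E_model,
    predict_E,
)


def make_records(beta, n=60, noise=0.0, seed=0, source="RE"):
    """Synthetic records whose E_true follows the linear model exactly."""
    rng = np.random.default_rng(seed)
    eps = rng.uniform(0.1, 3.0, n)
    tau = rng.uniform(0.0, 1.0, n)
    E = (beta[0] + beta[1] * eps + beta[2] * tau + beta[3] * eps * tau
         + (rng.normal(0, noise, n) if noise else 0.0))
    recs = []
    for e, t, Ev in zip(eps, tau, E):
        # choose mean|psi| and fst so that epsilon = e and E_true = Ev
        fst = 0.1
        recs.append(EpsilonRecord(
            mean_abs_psi=e * fst, fst_censored=fst, tau=t,
            epsilon_eq=e / Ev, source=source))
    return recs


def test_epsilon_basic_and_censor():
    assert epsilon(0.05, 0.25) == pytest.approx(0.2)
    # censored denominator when FST <= 0
    assert epsilon(0.0134, -0.3) == pytest.approx(13.4)
    with pytest.raises(ValueError):
        epsilon(np.nan, 0.1)
    with pytest.raises(ValueError):
        epsilon(-0.1, 0.1)


def test_record_properties():
    r = EpsilonRecord(mean_abs_psi=0.02, fst_censored=0.1, tau=0.5,
                      epsilon_eq=0.1)
    assert r.epsilon == pytest.approx(0.2)
    assert r.E_true == pytest.approx(2.0)
    assert EpsilonRecord(0.02, 0.1, 0.5).E_true is None


def test_fit_recovers_coefficients_noiseless():
    beta = np.array([1.0, 0.09, -0.9, 3.4])
    model = fit_E_model(make_records(beta, n=80))
    np.testing.assert_allclose(model.beta, beta, atol=1e-8)
    assert model.r2 > 1 - 1e-10


def test_fit_reduced_designs():
    beta = np.array([0.5, 2.0, 0.0, 0.0])
    recs = make_records(beta, n=50)
    m_eps = fit_E_model(recs, terms="eps")
    np.testing.assert_allclose(m_eps.beta[:2], beta[:2], atol=1e-8)
    assert m_eps.beta[2] == 0.0 and m_eps.beta[3] == 0.0
    m_tau = fit_E_model(recs, terms="tau")
    assert m_tau.r2 < m_eps.r2  # tau carries no signal here
    with pytest.raises(ValueError, match="unknown terms"):
        fit_E_model(recs, terms="bogus")


def test_fit_requires_enough_records():
    beta = np.array([1.0, 0.1, -0.9, 3.4])
    with pytest.raises(ValueError, match="at least 10"):
        fit_E_model(make_records(beta, n=5))


def test_fit_rank_deficiency_names_columns():
    rng = np.random.default_rng(3)
    recs = []
    for _ in range(20):
        e = rng.uniform(0.5, 2.0)
        recs.append(EpsilonRecord(mean_abs_psi=e * 0.1, fst_censored=0.1,
                                  tau=0.0, epsilon_eq=e, source="RE"))
    # tau identically zero -> tau and interaction columns are collinear
    with pytest.raises(ValueError, match="collinear"):
        fit_E_model(recs)


def test_prediction_interval_covers_noise():
    beta = np.array([1.0, 0.1, -0.5, 2.0])
    model = fit_E_model(make_records(beta, n=200, noise=0.2, seed=2))
    # lower bound must sit below the point prediction, further out for small n
    for eps_v, tau_v in [(0.5, 0.2), (1.5, 0.8)]:
        assert model.lower_bound(eps_v, tau_v) < model.predict(eps_v, tau_v)
    # stricter alpha pushes the bound lower
    assert (model.lower_bound(1.0, 0.5, alpha=1e-4)
            < model.lower_bound(1.0, 0.5, alpha=0.05))


def test_predict_E_decision_and_extrapolation():
    beta = np.array([1.0, 0.0914, -0.894, 3.38])
    model = EModel.from_coefficients(beta)
    out = predict_E(model, 1.05, 0.58)
    assert out["E_hat"] == pytest.approx(1.0 + 0.0914 * 1.05 - 0.894 * 0.58
                                         + 3.38 * 1.05 * 0.58)
    # exact arithmetic gives 2.6359; reported elsewhere at two decimals
    assert out["E_hat"] == pytest.approx(2.63587, abs=1e-5)
    assert out["re_supported"]  # zero-variance fixed-coefficient model
    fitted = fit_E_model(make_records(beta, n=60))
    assert fitted.extrapolates(100.0, 0.5)
    assert not fitted.extrapolates(1.0, 0.5)


def test_model_json_roundtrip(tmp_path):
    beta = np.array([1.0, 0.1, -0.5, 2.0])
    model = fit_E_model(make_records(beta, n=60, noise=0.1))
    path = tmp_path / "model.json"
    model.to_json(path)
    back = EModel.from_json(path)
    np.testing.assert_allclose(back.beta, model.beta)
    np.testing.assert_allclose(back.cov_beta, model.cov_beta)
    assert back.lower_bound(1.0, 0.5) == pytest.approx(model.lower_bound(1.0, 0.5))
    # also accepts a raw JSON string
    again = EModel.from_json(model.to_json())
    np.testing.assert_allclose(again.beta, model.beta)


def test_zero_epsilon_records_excluded():
    beta = np.array([1.0, 0.1, -0.5, 2.0])
    recs = make_records(beta, n=40)
    recs.append(EpsilonRecord(mean_abs_psi=0.0, fst_censored=0.1, tau=0.5,
                              epsilon_eq=1.0, source="RE"))
    model = fit_E_model(recs)
    assert model.n_excluded_zero_eps == 1
    assert model.n_obs == 40


def test_classify_records_and_summary():
    model = EModel.from_coefficients([0.0, 1.0, 0.0, 0.0])  # E_hat = eps
    recs = [
        EpsilonRecord(0.3, 0.1, 0.5, epsilon_eq=1.0, source="RE"),    # E=3
        EpsilonRecord(0.11, 0.1, 0.5, epsilon_eq=1.0, source="RE"),   # E=1.1
        EpsilonRecord(0.3, 0.1, 0.5, epsilon_eq=3.0, source="panmictic"),
        EpsilonRecord(0.05, 0.1, 0.5, source="DE"),                   # unknown
    ]
    labeled, summary = classify_records(recs, model=model)
    assert [r.label for r in labeled] == [
        "nonequilibrium", "equilibrium", "equilibrium", "unknown"]
    assert summary["n_nonequilibrium"] == 1
    assert summary["n_equilibrium"] == 2
    assert summary["n_unknown"] == 1
    # zero-variance model: decision is E_hat > 1
    assert summary["power"] == 1.0   # eps = 3 -> E_hat = 3 > 1
    assert summary["fpr"] == 1.0     # eps 1.1 and 3 both exceed 1
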