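"""Laplace marginal likelihood, fitting, shrinkage, covariate stepping."""

import copy

import numpy as np
import pandas as pd
import pytest

from conftest import deterministic_params
from dmer import estimation as est
from dmer import workflows as wf
from dmer.synthetic_trial import Arm, TrialDesign, generate_trial


@pytest.fixture(scope="module")
def small_fit_problem():
    """Tiny two-arm dataset over a two-endpoint panel with its template."""
    from dmer.params import default_parameters
    p = default_parameters().subset(["cdasi_a", "ptga"])
    design = TrialDesign("small", "SPDM",
                         [Arm("placebo", 0.0, 15), Arm("600mg", 600.0, 15)],
                         visits=(0.0, 4.0, 8.0, 12.0),
                         panel=("cdasi_a", "ptga"), doses_per_period=3)
    data = generate_trial(design, p, seed=101)
    prepared = est.EstimationData.from_tidy(data, p,
                                            panel=["cdasi_a", "ptga"])
    return p, data, prepared


class _LinearModel:
    """Linear-Gaussian toy: f(eta) = a + B eta, one subject.

    The Laplace approximation is exact here, so the objective must equal
    the closed-form normal marginal -2 log likelihood.
    """

    def __init__(self, a, B, sigma, omega, y):
        n_obs = len(a)
        self.a, self.B = a, B
        self._sigma = sigma
        self._omega = omega
        self.d = B.shape[1]
        self.eta_names = [f"eta{i}" for i in range(self.d)]

        class D:
            pass

        self.data = D()
        self.data.y = y.reshape(1, n_obs, 1)
        self.data.mask = np.ones_like(self.data.y, dtype=bool)
        self.data.n_sub = 1

    def sigma(self, params):
        return np.array([self._sigma])

    def omega(self, params):
        return self._omega

    def predict(self, params, etas):
        return (self.a + etas @ self.B.T).reshape(1, -1, 1)

    def predict_with_jacobian(self, params, etas):
        f = self.predict(params, etas)
        J = self.B.reshape(1, -1, 1, self.d).repeat(1, axis=0)
        return f, J


class TestLaplaceObjective:
    def test_linear_gaussian_marginal_is_exact(self):
        rng = np.random.default_rng(3)
        a = rng.normal(10, 1, 6)
        B = rng.normal(0, 1, (6, 2))
        omega = np.array([[0.5, 0.1], [0.1, 0.3]])
        sigma = 0.7
        y = rng.normal(10, 2, 6)
        model = _LinearModel(a, B, sigma, omega, y)
        ofv, _, _, _ = est._laplace_terms(model, None,
                                          np.zeros((1, 2)))
        # closed form: y ~ N(a, B Omega B' + sigma^2 I)
        cov = B @ omega @ B.T + sigma**2 * np.eye(6)
        resid = y - a
        ref = (np.linalg.slogdet(2 * np.pi * cov)[1]
               + resid @ np.linalg.solve(cov, resid))
        assert ofv == pytest.approx(ref, rel=1e-8)

    def test_objective_minimized_at_truth_without_noise(self, params):
        p = deterministic_params(params).subset(["cdasi_a", "ptga"])
        design = TrialDesign("z", "SPDM",
                             [Arm("placebo", 0.0, 5),
                              Arm("600mg", 600.0, 5)],
                             visits=(0.0, 4.0, 8.0, 12.0),
                             panel=("cdasi_a", "ptga"), doses_per_period=3)
        data = generate_trial(design, p, seed=1, include_ruv=False)
        ofv0 = est.objective(p, data, panel=["cdasi_a", "ptga"])
        for name, fac in [("kout", 1.3), ("kout", 0.7), ("emax_norm", 0.8),
                          ("base_cdasi_a", 1.1), ("ruv_cdasi_a", 2.0)]:
            z = est.pack(p, [name]) + np.log(fac)
            assert est.objective(est.unpack(p, [name], z), data,
                                 panel=["cdasi_a", "ptga"]) > ofv0

    def test_duplicating_subjects_doubles_ofv(self, small_fit_problem):
        p, data, prepared = small_fit_problem
        ofv = est.objective(p, prepared)
        doubled = data.copy()
        doubled["subject"] += data["subject"].max()
        both = pd.concat([data, doubled], ignore_index=True)
        ofv2 = est.objective(p, both, panel=["cdasi_a", "ptga"])
        assert ofv2 == pytest.approx(2 * ofv, rel=1e-6)

    def test_record_order_invariance(self, small_fit_problem):
        p, data, _ = small_fit_problem
        shuffled = data.sample(frac=1.0, random_state=0)
        assert est.objective(p, shuffled, panel=["cdasi_a", "ptga"]) == \
            pytest.approx(est.objective(p, data, panel=["cdasi_a", "ptga"]),
                          rel=1e-9)


class TestFit:
    def test_all_fixed_returns_start_and_objective(self, small_fit_problem):
        p, _, prepared = small_fit_problem
        res = est.fit(prepared, p, free=[])
        assert res.converged
        assert res.ofv == pytest.approx(est.objective(p, prepared), rel=1e-9)
        assert res.estimates == {}
        assert res.fixed["kout"] == p.shared.k_out

    def test_fixed_mask_honored(self, small_fit_problem):
        p, _, prepared = small_fit_problem
        start = copy.deepcopy(p)
        start.endpoints["cdasi_a"].ruv_sd = 8.0
        res = est.fit(prepared, start, free=["base_cdasi_a"], maxiter=20)
        # everything outside the free list is untouched
        assert res.params.endpoints["cdasi_a"].ruv_sd == 8.0
        assert res.params.shared.k_out == p.shared.k_out
        assert "base_cdasi_a" in res.estimates

    def test_transforms_round_trip(self, params):
        names = ["kout", "emax_norm", "e_plac", "base_cdasi_a",
                 "emax_ptga", "ruv_ptga", "omega_cdasi_a"]
        z = est.pack(params, names)
        back = est.unpack(params, names, z)
        for n in names:
            assert est._get_param(back, n) == pytest.approx(
                est._get_param(params, n), rel=1e-12)

    def test_small_panel_recovery(self, small_fit_problem):
        p, _, prepared = small_fit_problem
        start = copy.deepcopy(p)
        start.shared.emax_norm = 0.35
        start.endpoints["ptga"].emax = -0.3
        res = est.fit(prepared, start,
                      free=["emax_norm", "emax_ptga"], maxiter=60)
        # n=30 subjects: coarse but unambiguous recovery
        assert res.estimates["emax_norm"] == pytest.approx(0.564, abs=0.2)
        assert res.estimates["emax_ptga"] == pytest.approx(-0.797, abs=0.25)

    def test_omega_estimation_supported(self, small_fit_problem):
        p, _, prepared = small_fit_problem
        start = copy.deepcopy(p)
        start.endpoints["cdasi_a"].iiv_baseline = 0.5
        res = est.fit(prepared, start, free=["omega_cdasi_a"], maxiter=40)
        assert res.estimates["omega_cdasi_a"] == pytest.approx(0.147,
                                                               rel=0.6)


class TestEbesAndShrinkage:
    def test_rich_data_low_shrinkage(self, params):
        p = params.subset(["cdasi_a"])
        design = TrialDesign("r", "SPDM", [Arm("placebo", 0.0, 60)],
                             visits=tuple(np.arange(0.0, 25.0, 2.0)),
                             panel=("cdasi_a",))
        data = generate_trial(design, p, seed=21)
        res = est.fit(data, p, free=[], panel=["cdasi_a"])
        ebes, eta_tab, eps_tab = est.ebes_and_shrinkage(res)
        shr = eta_tab.set_index("eta").loc["cdasi_a", "shrinkage_pct"]
        assert shr < 25.0
        assert len(ebes) == 60
        assert np.isfinite(eps_tab["eps_shrinkage_pct"]).all()

    def test_uninformed_eta_shrinks_to_100(self, params):
        # placebo-only data carry no information on the drug-effect eta
        p = params.subset(["cdasi_a"])
        design = TrialDesign("u", "SPDM", [Arm("placebo", 0.0, 40)],
                             visits=(0.0, 4.0, 8.0), panel=("cdasi_a",))
        data = generate_trial(design, p, seed=22)
        res = est.fit(data, p, free=[], panel=["cdasi_a"])
        _, eta_tab, _ = est.ebes_and_shrinkage(res)
        shr = eta_tab.set_index("eta").loc["emax_norm", "shrinkage_pct"]
        assert shr > 90.0


class TestCovariateStep:
    def test_null_candidates_return_base_model(self):
        gen, base, design, free, cands = wf.covariate_null_fixture(0.0)
        data = generate_trial(design, gen, seed=404)
        included, final = est.covariate_step(data, base, free, cands,
                                             panel=["cdasi_a"], maxiter=60)
        assert included == []
        assert final.converged

    def test_strong_effect_selected(self):
        assert wf.covariate_step_replicate(777, effect_percent=-51.8)


class TestUncertaintyDraws:
    @pytest.fixture(scope="module")
    def unc_fit(self, small_fit_problem):
        p, _, prepared = small_fit_problem
        return est.fit(prepared, p, free=["kout", "emax_ptga"],
                       maxiter=30, compute_uncertainty=True)

    def test_zero_draws_empty(self, unc_fit):
        assert est.uncertainty_draws(unc_fit, 0, seed=1) == []

    def test_draw_mean_matches_estimates(self, unc_fit):
        draws = est.uncertainty_draws(unc_fit, 4000, seed=2)
        kouts = np.log([d.shared.k_out for d in draws])
        assert kouts.mean() == pytest.approx(np.log(unc_fit.params.shared.k_out),
                                             abs=0.02)

    def test_draws_respect_constraints(self, unc_fit):
        draws = est.uncertainty_draws(unc_fit, 500, seed=3)
        emaxes = np.array([d.endpoints["ptga"].emax for d in draws])
        assert np.all((emaxes > -1) & (emaxes < 1))
        assert all(d.shared.k_out > 0 for d in draws)

    def test_condition_number_reported(self, unc_fit):
        assert unc_fit.condition_number is not None
        assert unc_fit.condition_number >= 1.0
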