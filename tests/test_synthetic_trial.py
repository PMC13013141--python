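"""Virtual trial generation: panels, crossover, noise structure, truth."""

import numpy as np
import pytest

from conftest import deterministic_params
from dmer.synthetic_trial import (DEFAULT_VISITS, FULL_PANEL, SPDM_PANEL, Arm,
                                  TrialDesign, cts_design, generate_trial,
                                  study_stage_designs, truth_record)
from dmer.population import draw_subjects


class TestDesigns:
    def test_stage_panels_follow_study_rules(self):
        designs = study_stage_designs()
        assert "mmt8" not in designs["stage1"].panel
        assert "tis_phga" not in designs["stage2"].panel
        assert "cdasi_a" in designs["stage1"].panel
        assert set(designs["stage3"].panel) == set(FULL_PANEL)

    def test_crossover_must_be_scheduled_visit(self):
        with pytest.raises(ValueError, match="crossover"):
            TrialDesign("x", "SPDM", [Arm("a", 600, 5, "AP")],
                        visits=(0.0, 4.0), crossover_week=12.0)

    def test_unknown_endpoint_rejected(self):
        with pytest.raises(ValueError, match="panel"):
            TrialDesign("x", "SPDM", [Arm("a", 0, 5)], panel=("nope",))

    def test_crossover_sequences_dose_schedules(self):
        d = study_stage_designs()["stage3"]
        ap = next(a for a in d.arms if a.sequence == "AP")
        pa = next(a for a in d.arms if a.sequence == "PA")
        reg_ap = d.regimen_for(ap, 1.0)
        reg_pa = d.regimen_for(pa, 1.0)
        assert list(reg_ap.dose_times) == [0.0, 4.0, 8.0]
        assert list(reg_pa.dose_times) == [12.0, 16.0, 20.0]


class TestGenerateTrial:
    def test_deterministic_steady_state(self, params):
        # no IIV, no noise, placebo, no placebo drift: every observation
        # sits exactly at its endpoint's typical baseline
        p = deterministic_params(params)
        design = TrialDesign("t", "SPDM", [Arm("placebo", 0.0, 3)],
                             visits=(0.0, 4.0, 8.0), panel=("cdasi_a",
                                                            "ptga", "mmt8"))
        data = generate_trial(design, p, seed=0, include_ruv=False)
        obs = data[data["record"] == "obs"]
        for e in ("cdasi_a", "ptga", "mmt8"):
            vals = obs[obs["endpoint"] == e]["value"]
            assert np.allclose(vals, p.endpoints[e].baseline, rtol=1e-9)

    def test_stage_panel_rules_in_dataset(self, params):
        designs = study_stage_designs()
        d1 = generate_trial(designs["stage1"], params, seed=1)
        d3 = generate_trial(designs["stage3"], params, seed=1)
        assert "mmt8" not in set(d1["endpoint"])
        assert "mmt8" in set(d3["endpoint"])

    def test_seed_reproducibility(self, params):
        design = study_stage_designs()["stage2"]
        a = generate_trial(design, params, seed=5)
        b = generate_trial(design, params, seed=5)
        c = generate_trial(design, params, seed=6)
        assert a.equals(b)
        assert not a.equals(c)

    def test_crossover_dose_records(self, params):
        design = study_stage_designs()["stage3"]
        data = generate_trial(design, params, seed=2)
        doses = data[data["record"] == "dose"]
        pa = doses[doses["sequence"] == "PA"]
        ap = doses[doses["sequence"] == "AP"]
        assert pa["time"].min() == 12.0       # no active dose before the switch
        assert ap["time"].max() == 8.0        # active only before the switch
        assert (doses["amount"] > 0).all()

    def test_enzyme_rows_denormalized_by_uln(self, params):
        p = deterministic_params(params)
        design = TrialDesign("t", "SPDM", [Arm("placebo", 0.0, 4)],
                             visits=(0.0, 4.0), panel=("enzyme",))
        data = generate_trial(design, p, seed=0, include_ruv=False)
        obs = data[(data["record"] == "obs")]
        assert np.allclose(obs["value"], 1.19 * obs["uln"], rtol=1e-9)
        assert set(obs["uln"]).issubset(set(p.uln_catalogue))

    def test_one_baseline_per_subject_endpoint(self, params):
        data = generate_trial(study_stage_designs()["stage1"], params, seed=3)
        obs = data[(data["record"] == "obs") & (data["time"] == 0.0)]
        counts = obs.groupby(["subject", "endpoint"]).size()
        assert (counts == 1).all()
        assert data[data["record"] == "obs"]["time"].min() == 0.0


class TestTruthRecord:
    def test_latent_baseline_and_etas(self, params):
        design = TrialDesign("t", "SPDM", [Arm("placebo", 0.0, 10)],
                             visits=DEFAULT_VISITS, panel=SPDM_PANEL)
        data, truth = generate_trial(design, params, seed=7,
                                     return_truth=True)
        lat = truth["latent"]
        t0 = lat[lat["time"] == 0.0].set_index(["subject", "endpoint"])
        for _, row in truth["subjects"].iterrows():
            for e in ("cdasi_a", "ptga"):
                assert t0.loc[(row["subject"], e), "latent"] == \
                    pytest.approx(row[f"base_{e}"])

    def test_observed_minus_latent_is_ruv(self, params):
        design = TrialDesign("t", "SPDM", [Arm("placebo", 0.0, 150)],
                             visits=DEFAULT_VISITS, panel=("cdasi_a",))
        data, truth = generate_trial(design, params, seed=8,
                                     return_truth=True)
        obs = data[data["record"] == "obs"].reset_index()
        lat = truth["latent"]
        resid = obs["value"].to_numpy() - lat["latent"].to_numpy()
        sd = params.endpoints["cdasi_a"].ruv_sd
        assert abs(resid.mean()) < 0.4
        assert resid.std(ddof=1) == pytest.approx(sd, rel=0.08)

    def test_truth_record_matches_generation(self, params):
        design = study_stage_designs()["stage1"]
        truth = truth_record(design, params, seed=9)
        _, truth2 = generate_trial(design, params, seed=9, return_truth=True)
        assert truth["subjects"].equals(truth2["subjects"])


class TestMarginalMoments:
    def test_baseline_medians_match_typicals(self, params):
        subs = draw_subjects(params, ["SPDM"] * 2000, seed=123)
        for e in ("cdasi_a", "ptga", "mmt8", "enzyme", "haq"):
            med = np.median([s.baselines[e] for s in subs])
            assert med == pytest.approx(params.endpoints[e].baseline,
                                        rel=0.03)

    def test_enzyme_ratio_centered_at_baseline(self, params):
        design = TrialDesign("t", "SPDM", [Arm("placebo", 0.0, 400)],
                             visits=(0.0,), panel=("enzyme",))
        data = generate_trial(design, params, seed=44)
        obs = data[data["record"] == "obs"]
        ratios = obs["value"] / obs["uln"]
        assert np.median(ratios) == pytest.approx(1.19, rel=0.05)
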