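"""Synthetic cohort generator: log-normal fits, sampling, trajectories."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from asphyxomics.cohort import (default_concentration_model, default_design,
                                default_panel, ratio_to_signed_fc,
                                sample_cohort, sample_concentrations,
                                signed_fc_to_ratio, simple_design)
from asphyxomics.reference import Z75, fit_lognormal_from_median_iqr


class TestLognormalFit:
    def test_degenerate_iqr(self):
        assert fit_lognormal_from_median_iqr(1, 1, 1) == (0.0, 0.0)

    def test_closed_form_sigma(self):
        # verified against a brute-force quantile search over a sigma grid
        mu, sigma = fit_lognormal_from_median_iqr(10, 5, 20)
        assert mu == pytest.approx(math.log(10))
        assert sigma == pytest.approx(math.log(4) / (2 * Z75))
        grid = np.linspace(0.01, 3, 3000)
        iqr_ratio = np.exp(2 * Z75 * grid)  # q3/q1 of lognormal(mu, s)
        best = grid[np.argmin(np.abs(iqr_ratio - 4.0))]
        assert sigma == pytest.approx(best, abs=2e-3)

    def test_monte_carlo_reproduces_printed_lactate_quartiles(self):
        # plasma lactate baseline: median 2.9, IQR 1.5-5.3
        mu, sigma = fit_lognormal_from_median_iqr(2.9, 1.5, 5.3)
        draws = np.exp(mu + sigma * np.random.default_rng(1).standard_normal(100_000))
        q1, med, q3 = np.percentile(draws, [25, 50, 75])
        assert med == pytest.approx(2.9, rel=0.03)
        assert q1 == pytest.approx(1.5, rel=0.03)
        assert q3 == pytest.approx(5.3, rel=0.03)

    def test_zero_q1_uses_upper_spread(self):
        mu, sigma = fit_lognormal_from_median_iqr(2.0, 0.0, 8.0)
        assert sigma == pytest.approx(math.log(4) / Z75)

    @pytest.mark.parametrize("bad", [(0, 1, 2), (1, 2, 0.5), (1, -1, 2),
                                     (2, 1, 1.5)])
    def test_invalid_quantiles_rejected(self, bad):
        with pytest.raises(ValueError):
            fit_lognormal_from_median_iqr(*bad)

    @given(med=st.floats(0.01, 100), ratio=st.floats(1.01, 50))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_quartiles(self, med, ratio):
        q1 = med / math.sqrt(ratio)
        q3 = med * math.sqrt(ratio)
        mu, sigma = fit_lognormal_from_median_iqr(med, q1, q3)
        assert math.exp(mu) == pytest.approx(med, rel=1e-9)
        # analytic quartiles of the fitted distribution
        assert math.exp(mu + sigma * norm.ppf(0.75)) == pytest.approx(q3, rel=1e-9)


class TestFoldChangeConvention:
    @pytest.mark.parametrize("fc,ratio", [(2.0, 2.0), (-2.0, 0.5),
                                          (1.0, 1.0), (-1.38, 1 / 1.38)])
    def test_signed_to_ratio(self, fc, ratio):
        assert signed_fc_to_ratio(fc) == pytest.approx(ratio)

    @given(st.floats(0.01, 100))
    @settings(max_examples=50, deadline=None)
    def test_ratio_round_trip(self, r):
        assert signed_fc_to_ratio(ratio_to_signed_fc(r)) == pytest.approx(r)


class TestSampleCohort:
    def test_published_group_sizes_full_availability(self):
        design = default_design(survival_prob=1.0)
        design = dataclasses.replace(
            design, availability={k: 1.0 for k in design.availability})
        animals, manifest = sample_cohort(design, 1)
        assert len(animals) == 110
        counts = animals.groupby("group").size()
        assert counts.to_dict() == {1: 21, 2: 32, 3: 21, 4: 8, 5: 16, 6: 12}
        # all samples present: 110 animals x 2 materials x 3 timepoints
        assert len(manifest) == 110 * 2 * 3

    def test_zero_availability_removes_timepoint(self):
        design = simple_design(10, timepoints=("t1", "t2"))
        design = dataclasses.replace(
            design, availability={(1, "plasma", "t2"): 0.0})
        _, manifest = sample_cohort(design, 2)
        assert (manifest["timepoint"] == "t2").sum() == 0

    def test_fixed_seed_is_deterministic(self):
        design = default_design()
        a1, m1 = sample_cohort(design, 33)
        a2, m2 = sample_cohort(design, 33)
        assert a1.equals(a2) and m1.equals(m2)

    def test_non_survivors_lack_later_samples(self):
        design = simple_design(200, survival_prob=0.5)
        animals, manifest = sample_cohort(design, 3)
        dead = animals.index[~animals["survived"]]
        later = manifest[manifest["timepoint"] != "t1"]
        assert not set(later["animal_id"]) & set(dead)

    def test_positive_durations(self):
        animals, _ = sample_cohort(default_design(), 4)
        assert (animals["time_to_asystole"] > 0).all()
        assert (animals["time_to_rosc_s"] > 0).all()


class TestSampleConcentrations:
    def test_deterministic_trajectory_when_noise_free(self, plasma_model):
        model = dataclasses.replace(plasma_model, noise_sd=0.0, clusters=(),
                                    endpoint_correlations={})
        mets = {}
        for name, mm in model.metabolites.items():
            mets[name] = dataclasses.replace(
                mm, lognormal={tp: (ms[0], 0.0) for tp, ms in mm.lognormal.items()},
                fold_changes={("t1", "t2"): 2.0, ("t2", "t3"): -2.0})
        model = dataclasses.replace(model, metabolites=mets)
        design = simple_design(5)
        animals, manifest = sample_cohort(design, 5)
        table, _ = sample_concentrations(model, animals, manifest, 6)
        v = table.values.join(table.meta[["animal_id", "timepoint"]])
        wide = v.pivot(index="animal_id", columns="timepoint", values="Lactate")
        assert np.allclose(wide["t2"], 2.0 * wide["t1"])
        # signed FC -2 means a halving
        assert np.allclose(wide["t3"], 0.5 * wide["t2"])

    def test_succinate_median_ratio_matches_fold_change(self, plasma_model):
        design = simple_design(400, timepoints=("t1", "t2"))
        animals, manifest = sample_cohort(design, 8)
        table, _ = sample_concentrations(plasma_model, animals, manifest, 9)
        v = table.values.join(table.meta[["timepoint"]])
        med = v.groupby("timepoint")["Succinate"].median()
        assert med["t2"] / med["t1"] == pytest.approx(7.67, rel=0.15)

    def test_marginal_quantile_fidelity(self, plasma_model):
        # large-sample quartiles match the fitted log-normal exactly, and
        # the printed values wherever a log-normal can represent them (the
        # median always; the individual quartile positions only when the
        # printed IQR is log-symmetric around the median, e.g. lactate and
        # glucose -- succinate's printed IQR is not)
        design = simple_design(100_000, timepoints=("t1",))
        animals, manifest = sample_cohort(design, 10)
        table, _ = sample_concentrations(
            plasma_model, animals, manifest, 11,
            default_panel("plasma").subset(["Lactate", "Glucose", "Succinate"]))
        printed = {"Lactate": (2.9, 1.5, 5.3), "Glucose": (6.0, 4.1, 8.6),
                   "Succinate": (0.015, 0.0054, 0.035)}
        for name, (med, q1, q3) in printed.items():
            got = np.percentile(table.values[name], [25, 50, 75])
            mu, sigma = plasma_model[name].lognormal["t1"]
            assert got[1] == pytest.approx(med, rel=0.03)
            assert got[0] == pytest.approx(math.exp(mu - Z75 * sigma), rel=0.03)
            assert got[2] == pytest.approx(math.exp(mu + Z75 * sigma), rel=0.03)
            # the IQR *ratio* always matches the printed spread
            assert got[2] / got[0] == pytest.approx(q3 / q1, rel=0.06)
        for name in ("Lactate", "Glucose"):
            med, q1, q3 = printed[name]
            got = np.percentile(table.values[name], [25, 50, 75])
            assert got[0] == pytest.approx(q1, rel=0.05)
            assert got[2] == pytest.approx(q3, rel=0.05)

    def test_missing_transition_raises_with_name(self, plasma_model):
        mets = dict(plasma_model.metabolites)
        broken = dataclasses.replace(mets["Lactate"], fold_changes={})
        mets["Lactate"] = broken
        model = dataclasses.replace(plasma_model, metabolites=mets)
        design = simple_design(3, timepoints=("t1", "t2"))
        animals, manifest = sample_cohort(design, 12)
        with pytest.raises(KeyError, match="Lactate"):
            sample_concentrations(model, animals, manifest, 13)

    def test_endpoint_correlation_configured(self, plasma_model):
        design = simple_design(4000, timepoints=("t1",))
        animals, manifest = sample_cohort(design, 14)
        table, _ = sample_concentrations(plasma_model, animals, manifest, 15)
        logh = np.log(table.values["Hypoxanthine"])
        asys = np.log(animals.loc[table.meta["animal_id"], "time_to_asystole"])
        r = np.corrcoef(logh, asys)[0, 1]
        assert r == pytest.approx(-0.23, abs=0.03)


class TestPanelValidation:
    def test_default_panels_valid(self):
        for material in ("plasma", "urine"):
            panel = default_panel(material)
            assert len(panel.signals) > 20
            assert all(-0.5 <= s.ppm <= 9.0 for s in panel.signals)

    def test_duplicate_names_rejected(self, plasma_panel):
        from asphyxomics.cohort import MetabolitePanel
        sig = plasma_panel.signals[0]
        with pytest.raises(ValueError):
            MetabolitePanel("plasma", (sig, sig))
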