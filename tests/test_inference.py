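import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

import methylselect as ms
from helpers import brute_force_select
from methylselect.bayes import ModelFitPerCpG, PriorConfig
from methylselect.inference import (
    RANGE_BIN_LABELS,
    differential_posterior,
    select_markers,
    sex_effect_posterior,
    validate_panel,
)
from methylselect.lineage import model_from_groups


class TestSelectMarkers:
    def test_worked_example(self):
        panel = select_markers(list("abcd"), [0.99, 0.98, 0.90, 0.50], 0.05, "m")
        assert panel.probe_ids == ["a", "b", "c"]
        assert panel.realized_bayes_fdr == pytest.approx((0.01 + 0.02 + 0.10) / 3)

    def test_all_certain_selects_everything(self):
        panel = select_markers(list("abc"), [1.0, 1.0, 1.0], 0.05)
        assert len(panel) == 3
        assert panel.realized_bayes_fdr == 0.0

    def test_weak_probabilities_give_empty_panel(self):
        panel = select_markers(list("abc"), [0.5, 0.4, 0.2], 0.05)
        assert len(panel) == 0
        assert panel.realized_bayes_fdr == 0.0

    def test_tie_group_all_in_or_all_out(self):
        # the tied pair at 0.97 can only enter together
        probs = [0.99, 0.97, 0.97, 0.2]
        panel = select_markers(list("abcd"), probs, 0.025)
        assert panel.probe_ids == ["a", "b", "c"]
        panel2 = select_markers(list("abcd"), probs, 0.015)
        assert panel2.probe_ids == ["a"]

    def test_panel_is_maximal(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            probs = rng.beta(0.5, 0.5, size=rng.integers(5, 60))
            panel = select_markers([f"p{i}" for i in range(probs.size)], probs, 0.05)
            order = np.argsort(-probs, kind="stable")
            r = len(panel)
            # extend past the next tie group: estimate must exceed the level
            nxt = r + 1
            while nxt < probs.size and probs[order[nxt]] == probs[order[nxt - 1]]:
                nxt += 1
            if r < probs.size:
                assert np.mean(1.0 - probs[order[:nxt]]) > 0.05

    @given(
        probs=st.lists(
            st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=200
        ),
        level=st.sampled_from([0.01, 0.05, 0.1, 0.25]),
    )
    def test_matches_brute_force_enumeration(self, probs, level):
        panel = select_markers([f"p{i}" for i in range(len(probs))], probs, level)
        expected = brute_force_select(probs, level)
        assert panel.probe_ids == [f"p{i}" for i in expected]

    def test_out_of_range_probabilities_rejected(self):
        with pytest.raises(ValueError):
            select_markers(["a"], [1.2], 0.05)


class TestCommonMarkers:
    def test_intersection(self):
        pf = ms.MarkerPanel("m", 0.05, [("a", 1.0), ("b", 1.0), ("c", 1.0)], 0.0)
        pm = ms.MarkerPanel("m", 0.05, [("b", 1.0), ("c", 1.0), ("d", 1.0)], 0.0)
        assert ms.common_markers(pf, pm) == {"b", "c"}

    def test_disjoint_and_identical(self):
        pf = ms.MarkerPanel("m", 0.05, [("a", 1.0)], 0.0)
        pm = ms.MarkerPanel("m", 0.05, [("b", 1.0)], 0.0)
        assert ms.common_markers(pf, pm) == set()
        assert ms.common_markers(pf, pf) == {"a"}

    def test_model_mismatch_rejected(self):
        pf = ms.MarkerPanel("m1", 0.05, [], 0.0)
        pm = ms.MarkerPanel("m2", 0.05, [], 0.0)
        with pytest.raises(ValueError, match="different models"):
            ms.common_markers(pf, pm)


def _fit_for(model, mu, sigma2, probe="cg1"):
    return ModelFitPerCpG(
        probe_id=probe,
        model_names=(model.name,),
        log_marginal=np.array([0.0]),
        posterior_prob=np.array([1.0]),
        mu_hat={model.name: np.asarray(mu, dtype=float)},
        sigma2_hat={model.name: float(sigma2)},
    )


@pytest.fixture()
def single_cell_model():
    cts = ("A", "B", "C", "D", "E", "F")
    return model_from_groups("Aonly", [("A",), tuple(cts[1:])], cts, 1)


class TestDifferentialPosterior:
    def test_variance_closed_form_instance(self, single_cell_model):
        # ghat=9, sigma2=0.01, n_s=5, c_p=1, c_ref=5, posterior mean diff 0.45
        fit = _fit_for(single_cell_model, [0.95, 0.50], 0.01)
        prior = PriorConfig(b0=0.5, g=9.0)
        (summ,) = differential_posterior(fit, single_cell_model, prior, n_s=5)
        assert summ.posterior_mean == pytest.approx(0.45)
        assert summ.posterior_sd**2 == pytest.approx(0.9 * 0.002 * 1.2)
        assert summ.posterior_sd**2 == pytest.approx(0.00216)
        assert summ.state == "hypermethylated"
        lo, hi = summ.ci95
        assert (lo, hi) == pytest.approx(
            (0.45 - 1.959964 * np.sqrt(0.00216), 0.45 + 1.959964 * np.sqrt(0.00216))
        )

    def test_zero_difference_is_unclassified(self, single_cell_model):
        fit = _fit_for(single_cell_model, [0.5, 0.5], 0.01)
        (summ,) = differential_posterior(
            fit, single_cell_model, PriorConfig(b0=0.5, g=9.0), n_s=5
        )
        assert summ.posterior_mean == 0.0
        assert summ.state is None

    def test_range_probs_sum_to_one_and_degenerate_limit(self, single_cell_model):
        fit = _fit_for(single_cell_model, [0.52, 0.50], 1e-18)
        (summ,) = differential_posterior(
            fit, single_cell_model, PriorConfig(b0=0.5, g=9.0), n_s=5
        )
        assert sum(summ.range_probs.values()) == pytest.approx(1.0, abs=1e-10)
        assert summ.range_probs["<0.10"] == pytest.approx(1.0)

    def test_bins_left_closed_on_absolute_difference(self, single_cell_model):
        fit = _fit_for(single_cell_model, [0.25, 0.50], 1e-18)  # |diff| = 0.25
        (summ,) = differential_posterior(
            fit, single_cell_model, PriorConfig(b0=0.5, g=9.0), n_s=5
        )
        assert summ.range_probs["0.20-0.30"] == pytest.approx(1.0)
        assert summ.state == "hypomethylated"

    def test_null_model_rejected(self):
        null = model_from_groups("Null", [("A", "B")], ("A", "B"), None)
        fit = _fit_for(null, [0.5], 0.01)
        with pytest.raises(ValueError, match="null"):
            differential_posterior(fit, null, PriorConfig(b0=0.5, g=1.0), n_s=5)

    def test_saturated_requires_baseline(self):
        sat = model_from_groups("All", [("A",), ("B",)], ("A", "B"), None)
        fit = _fit_for(sat, [0.3, 0.7], 0.01)
        prior = PriorConfig(b0=0.5, g=1.0)
        with pytest.raises(ValueError, match="baseline"):
            differential_posterior(fit, sat, prior, n_s=5)
        summs = differential_posterior(fit, sat, prior, n_s=5, baseline_index=0)
        assert len(summs) == 1 and summs[0].posterior_mean == pytest.approx(0.4)


class TestSexEffectPosterior:
    def _pair(self, model, mu_f, mu_m, s2=0.0025):
        return (
            _fit_for(model, mu_f, s2),
            _fit_for(model, mu_m, s2),
        )

    def test_declaration_example(self, single_cell_model):
        # mean diff 0.2, per-sex sigma2 chosen so total sd = 0.03
        fit_f, fit_m = self._pair(single_cell_model, [0.70, 0.5], [0.50, 0.5])
        prior = PriorConfig(b0=0.5, g=9.0)
        res = sex_effect_posterior(
            fit_f, fit_m, single_cell_model, prior, prior, n_f=5, n_m=5
        )
        total_var = 2 * 0.0025 * 0.9 / 5
        assert res.variances[0] == pytest.approx(total_var)
        sd = np.sqrt(total_var)
        expected = norm.cdf((-0.1 - 0.2) / sd) + 1 - norm.cdf((0.1 - 0.2) / sd)
        assert res.prob_exceeds[0] == pytest.approx(expected)
        assert res.prob_exceeds[0] == pytest.approx(0.99957, abs=5e-5)
        assert res.declared

    def test_no_difference_not_declared(self, single_cell_model):
        fit_f, fit_m = self._pair(single_cell_model, [0.6, 0.5], [0.6, 0.5])
        prior = PriorConfig(b0=0.5, g=9.0)
        res = sex_effect_posterior(
            fit_f, fit_m, single_cell_model, prior, prior, n_f=5, n_m=5
        )
        sd = np.sqrt(res.variances[0])
        assert res.prob_exceeds[0] == pytest.approx(2 * (1 - norm.cdf(0.10 / sd)))
        assert not res.declared

    def test_delta_zero_gives_probability_one(self, single_cell_model):
        fit_f, fit_m = self._pair(single_cell_model, [0.6, 0.5], [0.55, 0.5])
        prior = PriorConfig(b0=0.5, g=9.0)
        res = sex_effect_posterior(
            fit_f, fit_m, single_cell_model, prior, prior, 5, 5, delta=0.0
        )
        assert res.prob_exceeds[0] == pytest.approx(1.0)

    def test_swapping_sexes_negates_mean_and_preserves_declaration(self, single_cell_model):
        fit_f, fit_m = self._pair(single_cell_model, [0.72, 0.5], [0.50, 0.5])
        prior = PriorConfig(b0=0.5, g=9.0)
        a = sex_effect_posterior(fit_f, fit_m, single_cell_model, prior, prior, 5, 6)
        b = sex_effect_posterior(fit_m, fit_f, single_cell_model, prior, prior, 6, 5)
        assert a.means[0] == pytest.approx(-b.means[0])
        assert a.declared == b.declared
        assert a.prob_exceeds[0] == pytest.approx(b.prob_exceeds[0])

    def test_partition_mismatch_rejected(self, single_cell_model):
        other = model_from_groups(
            "Aonly", [("A",), ("B",), ("C", "D", "E", "F")],
            ("A", "B", "C", "D", "E", "F"), 2,
        )
        fit_f = _fit_for(single_cell_model, [0.6, 0.5], 0.0025)
        fit_m = _fit_for(other, [0.6, 0.5, 0.5], 0.0025)
        with pytest.raises(ValueError, match="partition"):
            sex_effect_posterior(
                fit_f, fit_m, single_cell_model,
                PriorConfig(b0=0.5, g=9.0), PriorConfig(b0=0.5, g=9.0), 5, 5,
            )


def _validation_dataset(probe_means: dict, cell_types, n=3, seed=0):
    rng = np.random.default_rng(seed)
    probes = list(probe_means)
    K, J = len(probes), len(cell_types)
    beta = np.empty((K, n, J))
    for k, p in enumerate(probes):
        beta[k] = np.asarray(probe_means[p])[None, :]
    return ms.MethylationDataset(
        probe_ids=probes, cell_types=tuple(cell_types),
        subjects=[f"v{i}" for i in range(n)], beta=np.clip(beta, 0, 1), sex="F",
    )


class TestValidatePanel:
    def _summary(self, probe, partition, mean, lo, hi, state):
        return ms.DifferentialSummary(
            probe_id=probe, model_name="m", partition_label=partition,
            posterior_mean=mean, posterior_sd=0.01, ci95=(lo, hi),
            range_probs={lab: 0.0 for lab in RANGE_BIN_LABELS}, state=state,
        )

    def test_validation_at_training_mean_is_covered_and_concordant(self):
        cts = ("A", "B", "C")
        model = model_from_groups("m", [("A",), ("B", "C")], cts, 1)
        # validation difference A - mean(B,C) = 0.2, matching training
        vdata = _validation_dataset({"cg1": [0.6, 0.4, 0.4]}, cts)
        report = validate_panel(
            [self._summary("cg1", "A", 0.2, 0.1, 0.3, "hypermethylated")],
            vdata, model,
        )
        row = report.per_probe.iloc[0]
        assert row.covered and row.state_concordant
        assert report.summary["coverage_pct"] == 100.0

    def test_discordant_difference_fails_both_checks(self):
        cts = ("A", "B", "C")
        model = model_from_groups("m", [("A",), ("B", "C")], cts, 1)
        vdata = _validation_dataset({"cg1": [0.35, 0.4, 0.4]}, cts)  # diff -0.05
        report = validate_panel(
            [self._summary("cg1", "A", 0.15, 0.10, 0.20, "hypermethylated")],
            vdata, model,
        )
        row = report.per_probe.iloc[0]
        assert not row.covered and not row.state_concordant

    def test_joint_coverage_bounded_by_per_partition_rates(self):
        cts = ("A", "B", "C", "D")
        model = model_from_groups("pan", [("A",), ("B",), ("C", "D")], cts, 2)
        vdata = _validation_dataset(
            {"cg1": [0.6, 0.4, 0.4, 0.4], "cg2": [0.9, 0.45, 0.4, 0.4]}, cts
        )
        training = [
            self._summary("cg1", "A", 0.2, 0.1, 0.3, "hypermethylated"),
            self._summary("cg1", "B", 0.0, -0.1, 0.1, "hypomethylated"),
            self._summary("cg2", "A", 0.2, 0.1, 0.3, "hypermethylated"),  # val 0.5
            self._summary("cg2", "B", 0.0, -0.1, 0.1, "hypomethylated"),
        ]
        report = validate_panel(training, vdata, model)
        s = report.summary
        assert s["joint_coverage_pct"] <= min(
            s["coverage_pct[A]"], s["coverage_pct[B]"]
        )

    def test_marginalises_to_available_cell_types(self):
        cts = ("A", "B", "C")
        model = model_from_groups("m", [("A",), ("B", "C")], cts, 1)
        # validation lacks cell type C: reference restricted to B
        vdata = _validation_dataset({"cg1": [0.6, 0.4]}, ("A", "B"))
        report = validate_panel(
            [self._summary("cg1", "A", 0.2, 0.1, 0.3, "hypermethylated")],
            vdata, model,
        )
        assert report.per_probe.iloc[0].validation_diff == pytest.approx(0.2)

    def test_no_overlap_gives_empty_report(self):
        cts = ("A", "B", "C")
        model = model_from_groups("m", [("A",), ("B", "C")], cts, 1)
        vdata = _validation_dataset({"cgX": [0.5, 0.5, 0.5]}, cts)
        report = validate_panel(
            [self._summary("cg1", "A", 0.2, 0.1, 0.3, "hypermethylated")],
            vdata, model,
        )
        assert report.per_probe.empty


class TestPipelineProperties:
    def test_panels_recover_signal(self, strong_signal_run):
        _, _, truth, fit, panels = strong_signal_run
        truth_by_probe = dict(zip(truth.probe_ids, truth.model_names))
        tp = sum(
            sum(truth_by_probe[q] == name for q in panel.probe_ids)
            for name, panel in panels.items() if name != "Null"
        )
        n_signal = int((truth.model_names != "Null").sum())
        assert tp / n_signal >= 0.90

    def test_pure_null_data_yields_almost_no_markers(self, model_set6):
        cfg = ms.SimulationConfig(
            K=1000, n_per_sex={"F": 5}, sigma=0.02,
            model_mixture={"Null": 1.0}, sex_shift=None, seed=77,
        )
        datasets, _ = ms.simulate_dataset(cfg)
        fit = ms.fit(datasets["F"], cfg.models)
        n_sel = sum(
            len(ms.select_markers(fit.probe_ids, fit.prob_for(n), 0.05, n))
            for n in fit.model_names if n != "Null"
        )
        assert n_sel <= 0.01 * cfg.K
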