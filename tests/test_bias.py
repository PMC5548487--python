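import datetime as dt
import math

import numpy as np
import pytest

from faerspv import synth
from faerspv.bias import (
    exposure_margin,
    find_conflations,
    irls_logit,
    logistic_model,
    outcome_distribution,
    reporter_composition,
)
from faerspv.model import Corpus, DrugEntry, Report

from conftest import make_report


def _report_with_indication(rid, indication, reactions, role="PS"):
    return Report(
        report_id=rid, case_id=rid,
        drugs=[DrugEntry("rosiglitazone", role=role, indication=indication)
               .with_mapping({"ING-RSG"}, 1.0)],
        reactions=list(reactions),
        event_date=dt.date(2006, 5, 1), receipt_date=dt.date(2006, 6, 1),
        patient_age=60.0, patient_sex="F",
    )


class TestFindConflations:
    def test_worked_rows(self):
        # three canonical cases: indication repeated as the ADR (twice,
        # different terms) and a correctly reported pair
        corpus = Corpus(reports=[
            _report_with_indication("R1", "Diabetes mellitus", ["Diabetes mellitus"]),
            _report_with_indication("R2", "Cardiac failure congestive", ["Cardiac failure congestive"]),
            _report_with_indication("R3", "Diabetes mellitus", ["Cardiac failure congestive"]),
        ])
        records, _ = find_conflations(corpus)
        assert sorted(r.report_id for r in records) == ["R1", "R2"]

    def test_no_indication_not_flagged(self):
        corpus = Corpus(reports=[_report_with_indication("R1", None, ["Headache"])])
        records, series = find_conflations(corpus)
        assert records == [] and series.empty

    def test_non_ps_drug_not_flagged(self):
        corpus = Corpus(reports=[
            _report_with_indication("R1", "Diabetes mellitus", ["Diabetes mellitus"], role="C"),
        ])
        records, _ = find_conflations(corpus)
        assert records == []

    def test_case_insensitive_match(self):
        corpus = Corpus(reports=[
            _report_with_indication("R1", "DIABETES MELLITUS", ["Diabetes mellitus"]),
        ])
        records, _ = find_conflations(corpus)
        assert len(records) == 1

    def test_configured_fraction_recovered(self):
        frac = 0.08
        corpus, truth = synth.generate(
            synth.SyntheticConfig(n_reports=10_000, conflation_fraction=frac, seed=29)
        )
        records, series = find_conflations(corpus)
        flagged = {r.report_id for r in records}
        assert flagged == truth.conflated_report_ids
        half_width = 1.96 * math.sqrt(frac * (1 - frac) / 10_000)
        observed = len(flagged & {f"R{i:07d}" for i in range(10_000)}) / 10_000
        assert abs(observed - frac) <= half_width + 1e-12 or abs(observed - frac) < 0.01


class TestReporterComposition:
    def test_fractions_sum_to_one(self):
        corpus, _ = synth.generate(synth.SyntheticConfig(n_reports=2000, seed=1))
        comp = reporter_composition(corpus, [dt.date(2005, 1, 1)])
        assert np.allclose(comp.sum(axis=1), 1.0)

    def test_single_occupation(self):
        corpus = Corpus(reports=[make_report("R1", occupation="lawyer")])
        comp = reporter_composition(corpus, [dt.date(2000, 1, 1)])
        assert comp.iloc[0]["lawyer"] == 1.0

    def test_shifting_mixture_recovered(self):
        mix = {
            "2004-01": [0.8, 0.0, 0.0, 0.2, 0.0, 0.0],
            "2005-01": [0.3, 0.0, 0.0, 0.3, 0.4, 0.0],
        }
        corpus, _ = synth.generate(
            synth.SyntheticConfig(n_reports=40_000, occupation_mixture=mix, seed=41)
        )
        comp = reporter_composition(corpus, [dt.date(2005, 1, 1)])
        early = comp.iloc[0]
        late = comp.loc["2005-01-01"]
        assert early["physician"] == pytest.approx(0.8, abs=0.03)
        assert early["consumer"] == pytest.approx(0.2, abs=0.03)
        assert late["lawyer"] == pytest.approx(0.4, abs=0.03)


class TestOutcomeDistribution:
    def test_all_other(self):
        corpus = Corpus(reports=[make_report(f"R{i}", age=float(20 + i)) for i in range(5)])
        dist = outcome_distribution(corpus)
        assert dist["Other"] == 1.0

    def test_mentions_conservation(self):
        corpus, _ = synth.generate(synth.SyntheticConfig(n_reports=1000, seed=2))
        dist = outcome_distribution(corpus)
        assert dist.sum() == pytest.approx(1.0)

    def test_planted_mixture_recovered(self):
        weights = [0.05, 0.05, 0.05, 0.05, 0.10, 0.30, 0.40]
        corpus, _ = synth.generate(
            synth.SyntheticConfig(n_reports=50_000, outcome_weights=weights, seed=37)
        )
        dist = outcome_distribution(corpus)
        for w, (_, frac) in zip(weights, dist.items()):
            assert frac == pytest.approx(w, abs=0.02)

    def test_worst_mode(self):
        r = make_report("R1", outcomes=frozenset({"Death", "Other"}))
        dist = outcome_distribution(Corpus(reports=[r]), mode="worst")
        assert dist["Death"] == 1.0 and dist["Other"] == 0.0

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            outcome_distribution(Corpus(reports=[make_report("R1")]), mode="median")


class TestLogisticRegression:
    def test_coefficient_recovery(self):
        rng = np.random.default_rng(0)
        n = 100_000
        X = np.column_stack([
            np.ones(n),
            rng.random(n) < 0.1,
            rng.random(n) < 0.05,
            rng.random(n) < 0.5,
        ]).astype(float)
        beta = np.array([-3.0, 1.2, 0.8, 0.5])
        y = (rng.random(n) < 1.0 / (1.0 + np.exp(-X @ beta))).astype(float)
        fit = irls_logit(X, y)
        assert fit.converged
        assert np.max(np.abs(fit.params - beta)) <= 0.1

    def test_matches_statsmodels_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(500), rng.normal(size=500), rng.random(500) < 0.3])
        y = (rng.random(500) < 0.3).astype(float)
        fit = irls_logit(X, y)
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert np.max(np.abs(fit.params - res.params)) < 1e-6
        assert np.max(np.abs(fit.bse - res.bse)) < 1e-6

    def test_intercept_only_closed_form(self):
        y = np.array([1.0] * 30 + [0.0] * 70)
        fit = irls_logit(np.ones((100, 1)), y)
        assert fit.params[0] == pytest.approx(math.log(0.3 / 0.7), abs=1e-8)

    def test_null_covariates_rarely_significant(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = np.column_stack([np.ones(2000), rng.random(2000) < 0.2])
            y = (rng.random(2000) < 0.1).astype(float)
            fit = irls_logit(X, y)
            if abs(fit.zvalues[1]) < 2:
                hits += 1
        assert hits >= 18  # >= 90% of seeds

    def test_perfect_separation_flagged(self):
        X = np.column_stack([np.ones(20), np.r_[np.zeros(10), np.ones(10)]])
        y = np.r_[np.zeros(10), np.ones(10)]
        fit = irls_logit(X, y)
        assert not fit.converged

    def test_corpus_model_wiring(self):
        rng = np.random.default_rng(9)
        reports = []
        for i in range(4000):
            has_drug = rng.random() < 0.5
            p = 0.4 if has_drug else 0.1
            reactions = ["Myocardial infarction"] if rng.random() < p else ["Headache"]
            reports.append(
                make_report(
                    f"R{i}",
                    drug="celecoxib" if has_drug else "placebo",
                    ingredient_keys={"ING-CXB"} if has_drug else {"ING-PLB"},
                    reactions=tuple(reactions),
                )
            )
        fit = logistic_model(
            Corpus(reports=reports), "Myocardial infarction", "ING-CXB",
            covariates=("suspect",),
        )
        assert fit.converged
        true_beta = math.log(0.4 / 0.6) - math.log(0.1 / 0.9)
        assert fit.params[1] == pytest.approx(true_beta, abs=0.2)
        assert fit.names == ["intercept", "suspect"]

    def test_pre_cutoff_requires_date(self, tiny_corpus):
        with pytest.raises(ValueError, match="cutoff_date"):
            logistic_model(tiny_corpus, "Headache", "ING-A", covariates=("pre_cutoff",))


class TestExposureMargin:
    def test_unit_margin_flagged(self):
        em, flag = exposure_margin(2.0, 2.0)
        assert em == 1.0 and flag

    def test_threshold_13_dichotomy(self):
        # EM below vs above the working threshold used for the target class
        assert exposure_margin(12.0, 1.0, threshold=13.0)[1]
        assert not exposure_margin(14.0, 1.0, threshold=13.0)[1]

    def test_default_threshold_ten(self):
        assert not exposure_margin(11.0, 1.0)[1]
        assert exposure_margin(9.9, 1.0)[1]

    @pytest.mark.parametrize("ic50,cmax", [(0.0, 1.0), (1.0, 0.0), (-1.0, 2.0)])
    def test_nonpositive_error(self, ic50, cmax):
        with pytest.raises(ValueError):
            exposure_margin(ic50, cmax)
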