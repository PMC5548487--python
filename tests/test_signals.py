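import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faerspv import synth
from faerspv.ingredients import SynonymTable, map_corpus
from faerspv.model import Corpus
from faerspv.signals import (
    ContingencyTable,
    EBPrior,
    build_contingency,
    detect_signals,
    eb_prior_marginal_loglik,
    eb_scores,
    fit_eb_prior,
    holm_adjust,
    rrr,
    stratified_expected,
    yates_chi2_p,
)

from conftest import make_report
from oracles import holm_oracle, posterior_ebgm_quadrature, yates_p_oracle


def _random_tables(rng, n):
    t = rng.integers(50, 5000, size=n)
    r = (rng.random(n) * t * 0.5).astype(int) + 1
    c = (rng.random(n) * t * 0.5).astype(int) + 1
    lo = np.maximum(0, r + c - t)
    hi = np.minimum(r, c)
    n11 = (lo + rng.random(n) * (hi - lo + 1)).astype(int)
    n11 = np.minimum(n11, hi)
    return n11, r, c, t


def _mapped(corpus, truth):
    out, _ = map_corpus(corpus, SynonymTable.from_mapping(truth.synonym_map))
    return out


class TestContingencyTable:
    def test_expected_value(self):
        t = ContingencyTable(n11=20, row_total=100, col_total=50, grand_total=1000)
        assert t.expected == 5.0

    def test_margin_invariant(self):
        with pytest.raises(ValueError):
            ContingencyTable(n11=60, row_total=50, col_total=100, grand_total=1000)


class TestBuildContingency:
    def test_counts_and_role_filter(self):
        reports = [
            make_report("R1", role="PS", ingredient_keys={"K"}, reactions=("A",)),
            make_report("R2", role="C", ingredient_keys={"K"}, reactions=("A",)),
            make_report("R3", role="PS", ingredient_keys={"J"}, reactions=("B",)),
        ]
        corpus = Corpus(reports=reports)
        ps = build_contingency(corpus, "K", "A", role_filter="PS")
        assert (ps.n11, ps.row_total, ps.col_total, ps.grand_total) == (1, 1, 2, 3)
        allr = build_contingency(corpus, "K", "A", role_filter="ALL")
        assert (allr.n11, allr.row_total) == (2, 2)

    def test_absent_ingredient(self, tiny_corpus):
        t = build_contingency(tiny_corpus, "NOPE", "Headache")
        assert t.row_total == 0 and t.n11 == 0

    def test_unmapped_corpus_error(self):
        corpus = Corpus(reports=[make_report("R1")])
        with pytest.raises(ValueError, match="mapping"):
            build_contingency(corpus, "K", "A")


class TestRRR:
    def test_ratio(self):
        assert rrr(ContingencyTable(20, 100, 50, 1000)) == 4.0

    def test_n_equal_e(self):
        assert rrr(ContingencyTable(5, 100, 50, 1000)) == 1.0

    def test_zero_when_no_observations(self):
        assert rrr(ContingencyTable(0, 0, 50, 1000)) == 0.0

    def test_zero_margin_forces_n_zero(self):
        # E = 0 with N > 0 cannot be represented: the margins invariant
        # rejects the table before rrr ever sees it
        with pytest.raises(ValueError):
            ContingencyTable(3, 0, 50, 1000)


class TestYatesChi2:
    def test_proportional_table_p_one(self):
        assert yates_chi2_p(ContingencyTable(5, 100, 50, 1000)) == 1.0

    def test_against_scipy_oracle(self):
        p = yates_chi2_p(ContingencyTable(20, 100, 50, 1000))
        assert p == pytest.approx(yates_p_oracle(20, 100, 50, 1000), abs=1e-10)

    def test_transpose_symmetry(self):
        a = yates_chi2_p(ContingencyTable(20, 100, 50, 1000))
        b = yates_chi2_p(ContingencyTable(20, 50, 100, 1000))
        assert a == pytest.approx(b, abs=1e-12)

    def test_degenerate_margin(self):
        assert yates_chi2_p(ContingencyTable(0, 0, 50, 1000)) == 1.0

    def test_many_random_tables_match_oracle(self):
        rng = np.random.default_rng(0)
        n11, r, c, t = _random_tables(rng, 2000)
        for args in zip(n11, r, c, t):
            assert yates_chi2_p(ContingencyTable(*map(int, args))) == pytest.approx(
                yates_p_oracle(*map(int, args)), abs=1e-10
            )

    def test_monotone_in_n11_above_expectation(self):
        r, c, t = 100, 50, 1000
        e = r * c / t
        ps = [yates_chi2_p(ContingencyTable(n, r, c, t)) for n in range(int(np.ceil(e)), 50)]
        rs = [rrr(ContingencyTable(n, r, c, t)) for n in range(int(np.ceil(e)), 50)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))
        assert all(a <= b for a, b in zip(rs, rs[1:]))


class TestHolm:
    def test_worked_example(self):
        assert holm_adjust([0.01, 0.04]).tolist() == pytest.approx([0.02, 0.04])

    def test_all_ones(self):
        assert holm_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_out_of_range_error(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.5])

    def test_empty(self):
        assert holm_adjust([]).size == 0

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_matches_statsmodels_oracle(self, ps):
        assert holm_adjust(ps) == pytest.approx(holm_oracle(ps), abs=1e-12)

    def test_q_at_least_p(self):
        rng = np.random.default_rng(1)
        p = rng.random(500)
        assert (holm_adjust(p) >= p - 1e-15).all()


class TestDetectSignals:
    def test_empty_corpus(self):
        assert detect_signals(Corpus(reports=[])) == []

    def test_small_n_fails_gate(self):
        reports = [
            make_report(f"R{i}", ingredient_keys={"K"}, reactions=("A",)) for i in range(4)
        ] + [make_report(f"S{i}", ingredient_keys={"J"}, reactions=("B",)) for i in range(50)]
        results = {(s.ingredient_key, s.adr_pt): s for s in detect_signals(Corpus(reports=reports))}
        target = results[("K", "A")]
        assert target.N == 4 and not target.passes_filter

    def test_permutation_invariance(self):
        corpus, truth = synth.generate(synth.SyntheticConfig(n_reports=1000, seed=2))
        mapped = _mapped(corpus, truth)
        shuffled = Corpus(reports=list(reversed(mapped.reports)))
        a = {(s.ingredient_key, s.adr_pt): (s.N, s.q, s.passes_filter) for s in detect_signals(mapped)}
        b = {(s.ingredient_key, s.adr_pt): (s.N, s.q, s.passes_filter) for s in detect_signals(shuffled)}
        assert a == b

    def test_planted_signal_flagged(self):
        cfg = synth.SyntheticConfig(
            n_reports=20_000, n_ingredients=50, n_adrs=50, adr_count_weights={1: 1.0},
            planted_associations=[synth.PlantedAssociation(1, 2, 8.0)], seed=6,
        )
        corpus, truth = synth.generate(cfg)
        results = {(s.ingredient_key, s.adr_pt): s for s in detect_signals(_mapped(corpus, truth))}
        assert results[(synth.ingredient_key(1), synth.adr_term(2))].passes_filter


class TestStratifiedExpected:
    def test_single_stratum_reduces_to_pooled(self):
        reports = [
            make_report(f"R{i}", ingredient_keys={"K"} if i < 10 else {"J"},
                        reactions=("A",) if i % 2 else ("B",), age=30.0, sex="F")
            for i in range(40)
        ]
        corpus = Corpus(reports=reports)
        pooled = build_contingency(corpus, "K", "A").expected
        assert stratified_expected(corpus, "K", "A") == pytest.approx(pooled)

    def test_constructed_confounding(self):
        # drug only in the young stratum, ADR only in the old one
        young = [make_report(f"Y{i}", ingredient_keys={"K"}, reactions=("B",), age=20.0)
                 for i in range(20)]
        old = [make_report(f"O{i}", ingredient_keys={"J"}, reactions=("A",), age=80.0)
               for i in range(20)]
        corpus = Corpus(reports=young + old)
        assert stratified_expected(corpus, "K", "A") == 0.0
        assert build_contingency(corpus, "K", "A").expected > 0


@pytest.fixture(scope="module")
def simulated():
    rng = np.random.default_rng(7)
    true = EBPrior(w=0.9, alpha1=2.0, beta1=2.0, alpha2=2.0, beta2=0.2)
    e = rng.uniform(0.5, 20.0, 5000)
    comp = rng.random(5000) < true.w
    lam = np.where(comp, rng.gamma(2.0, 0.5, 5000), rng.gamma(2.0, 5.0, 5000))
    n = rng.poisson(lam * e)
    return true, list(zip(n.tolist(), e.tolist())), lam


class TestEmpiricalBayes:
    def _unused(self):
        rng = np.random.default_rng(7)
        true = EBPrior(w=0.9, alpha1=2.0, beta1=2.0, alpha2=2.0, beta2=0.2)
        e = rng.uniform(0.5, 20.0, 5000)
        comp = rng.random(5000) < true.w
        lam = np.where(comp, rng.gamma(2.0, 0.5, 5000), rng.gamma(2.0, 5.0, 5000))
        n = rng.poisson(lam * e)
        return true, list(zip(n.tolist(), e.tolist())), lam

    def test_parameter_recovery_by_likelihood(self, simulated):
        true, pairs, _ = simulated
        fit = fit_eb_prior(pairs, seed=0)
        assert eb_prior_marginal_loglik(fit, pairs) >= eb_prior_marginal_loglik(true, pairs) - 1.0

    def test_deterministic(self, simulated):
        _, pairs, _ = simulated
        assert fit_eb_prior(pairs[:500], seed=3) == fit_eb_prior(pairs[:500], seed=3)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="50"):
            fit_eb_prior([(1, 1.0)] * 10)

    def test_all_zero_counts_push_prior_down(self):
        rng = np.random.default_rng(11)
        pairs = [(0, float(e)) for e in rng.uniform(1.0, 5.0, 300)]
        prior = fit_eb_prior(pairs, seed=0)
        mean = prior.w * prior.alpha1 / prior.beta1 + (1 - prior.w) * prior.alpha2 / prior.beta2
        assert mean < 0.5

    def test_ordering(self, simulated):
        true, pairs, _ = simulated
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(0, 60))
            e = float(rng.uniform(0.1, 30.0))
            ebgm, eb05, eb95 = eb_scores(n, e, true)
            assert eb05 <= ebgm + 1e-10 <= eb95 + 1e-9

    def test_shrinkage_strictly_between_prior_and_data(self):
        prior = EBPrior(w=0.5, alpha1=10.0, beta1=10.0, alpha2=10.0, beta2=10.0)
        ebgm, _, _ = eb_scores(20, 2.0, prior)  # N/E = 10, prior centered at 1
        assert 1.0 < ebgm < 10.0

    def test_matches_quadrature_oracle(self):
        prior = EBPrior(w=0.7, alpha1=1.5, beta1=1.2, alpha2=3.0, beta2=0.5)
        for n, e in [(3, 1.0), (20, 2.0), (0, 4.0), (50, 55.0)]:
            ebgm, _, _ = eb_scores(n, e, prior)
            assert ebgm == pytest.approx(posterior_ebgm_quadrature(n, e, prior), rel=1e-6)

    def test_large_count_limit(self):
        prior = EBPrior(w=0.9, alpha1=2.0, beta1=2.0, alpha2=2.0, beta2=0.2)
        ebgm, _, _ = eb_scores(10_000, 1000.0, prior)
        assert abs(ebgm - 10.0) / 10.0 < 0.01

    def test_e_zero_error(self):
        with pytest.raises(ValueError):
            eb_scores(3, 0.0, EBPrior(0.5, 1, 1, 1, 1))

    def test_shrinkage_dominance(self, simulated):
        _, pairs, lam = simulated
        fit = fit_eb_prior(pairs, seed=0)
        sub = slice(0, 1000)
        ebgm = np.array([eb_scores(int(n), float(e), fit)[0] for n, e in pairs[sub]])
        raw = np.array([n / e for n, e in pairs[sub]])
        truth = lam[sub]
        assert np.sqrt(np.mean((ebgm - truth) ** 2)) <= np.sqrt(np.mean((raw - truth) ** 2))
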