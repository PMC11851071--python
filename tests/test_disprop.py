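"""Fourfold tables, the four estimators, criteria and ranking."""

import math
import random

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvdisprop import (
    Cohort,
    ContingencyTable,
    SignalCriteria,
    SignalScores,
    build_contingency,
    compute_scores,
    ebgm_stat,
    evaluate_signal,
    ic_stat,
    prr_stat,
    rank_signals,
    ror_stat,
    signal_table,
    subgroup_analysis,
)
from support import mk_case, oracle_scores, relerr


def tab(a, b, c, d, term="X"):
    return ContingencyTable(term=term, level="PT", a=a, b=b, c=c, d=d)


class TestBuildContingency:
    def _cohort(self):
        target = [mk_case("1", {"AcneX"}, target=True), mk_case("2", {"AcneX", "Rash"}, target=True)]
        background = [mk_case("3", {"Rash"})]
        return Cohort(target, background, "upadacitinib", frozenset({"Ulcerative colitis"}))

    def test_pair_counting_enumeration(self):
        tables = {t.term: t for t in build_contingency(self._cohort(), min_a=1)}
        acne = tables["AcneX"]
        assert (acne.a, acne.b, acne.c, acne.d) == (2, 1, 0, 1)
        rash = tables["Rash"]
        assert (rash.a, rash.b, rash.c, rash.d) == (1, 2, 1, 0)

    def test_min_a_filters_rare_terms(self):
        terms = {t.term for t in build_contingency(self._cohort(), min_a=3)}
        assert terms == set()
        terms1 = {t.term for t in build_contingency(self._cohort(), min_a=1)}
        assert terms1 == {"AcneX", "Rash"}

    def test_margins_consistent(self, ibd_cohort):
        tables = build_contingency(ibd_cohort, min_a=3)
        assert tables, "expected at least one analyzable term"
        n_target_pairs = tables[0].a + tables[0].b
        for t in tables:
            assert t.a + t.b == n_target_pairs
            assert t.a >= 3 and min(t.a, t.b, t.c, t.d) >= 0

    def test_counts_match_generator_truth(self, ibd_cohort, assembled):
        _, _, manifest = assembled
        got = {t.term: (t.a, t.b, t.c, t.d) for t in build_contingency(ibd_cohort, min_a=1)}
        for pt, truth in manifest.per_pt.items():
            if truth["a"] >= 1:
                assert got[pt] == (truth["a"], truth["b"], truth["c"], truth["d"])

    def test_same_indication_background_shrinks_cd(self, ibd_cohort):
        rest = {t.term: t for t in build_contingency(ibd_cohort, min_a=3)}
        same = {t.term: t for t in
                build_contingency(ibd_cohort, min_a=3, background_mode="same_indication")}
        for term, t in same.items():
            assert t.c <= rest[term].c and t.d <= rest[term].d
            assert t.a == rest[term].a


# Frozen expected values, recomputed by hand from the printed formulas.
FOURFOLD_EXAMPLES = [
    # (cells, ror, prr, chi2, ic, ebgm)
    ((1917, 35905, 232598, 6766584), 1.553212, 1.525172, 355.68229, 0.604906, 1.520879),
    ((5, 5, 5, 5), 1.0, 1.0, 0.0, 0.0, 1.0),
    ((10, 90, 100, 9800), 10.888889, 9.9, 73.545455, 3.184425, 9.090909),
]


class TestEstimators:
    @pytest.mark.parametrize("cells,ror,prr,chi2,ic,ebgm", FOURFOLD_EXAMPLES)
    def test_frozen_examples(self, cells, ror, prr, chi2, ic, ebgm):
        t = tab(*cells)
        assert ror_stat(t)[0] == pytest.approx(ror, rel=1e-6)
        got_prr, _, _, got_chi2 = prr_stat(t)
        assert got_prr == pytest.approx(prr, rel=1e-6)
        assert got_chi2 == pytest.approx(chi2, rel=1e-6)
        assert ic_stat(t)[0] == pytest.approx(ic, abs=1e-6)
        assert ebgm_stat(t)[0] == pytest.approx(ebgm, rel=1e-6)

    def test_fourfold_ci_bounds_bracket_points(self):
        for cells in [c for c, *_ in FOURFOLD_EXAMPLES]:
            s = compute_scores(tab(*cells))
            assert s.ror_lo95 <= s.ror <= s.ror_hi95
            assert s.prr_lo95 <= s.prr <= s.prr_hi95
            assert s.ic025 <= s.ic
            assert s.ebgm05 <= s.ebgm

    def test_matches_rational_oracle(self):
        rng = random.Random(12345)
        for _ in range(200):
            a = rng.randint(3, 50)
            b, c, d = (rng.randint(1, 1000) for _ in range(3))
            s = compute_scores(tab(a, b, c, d))
            want = oracle_scores(a, b, c, d)
            for key, expected in want.items():
                assert relerr(getattr(s, key), expected) < 1e-10, (key, (a, b, c, d))

    @given(
        a=st.integers(3, 200),
        b=st.integers(1, 2000),
        c=st.integers(1, 2000),
        d=st.integers(1, 20000),
    )
    @settings(max_examples=100, derandomize=True)
    def test_ic_identity_with_ebgm(self, a, b, c, d):
        t = tab(a, b, c, d)
        ic, _ = ic_stat(t)
        ebgm, _ = ebgm_stat(t)
        assert abs(ic - math.log2(ebgm)) < 1e-12

    @given(
        a=st.integers(3, 100),
        b=st.integers(1, 1000),
        c=st.integers(1, 1000),
        d=st.integers(1, 10000),
    )
    @settings(max_examples=60, derandomize=True)
    def test_ror_prr_strictly_monotone_in_a(self, a, b, c, d):
        lo, hi = tab(a, b, c, d), tab(a + 1, b, c, d)
        assert ror_stat(hi)[0] > ror_stat(lo)[0]
        assert prr_stat(hi)[0] > prr_stat(lo)[0]

    @given(
        a=st.integers(3, 50),
        b=st.integers(2600, 5000),
        c=st.integers(2600, 5000),
        d=st.integers(1, 50000),
    )
    @settings(max_examples=60, derandomize=True)
    def test_ic_ebgm_monotone_in_a_for_sparse_signals(self, a, b, c, d):
        # the relative reporting ratio rises in a only while the term stays a
        # small share of both margins (a^2 < b*c); outside that regime the
        # count feeds back into its own expected value and the ratio can fall
        lo, hi = tab(a, b, c, d), tab(a + 1, b, c, d)
        assert ic_stat(hi)[0] > ic_stat(lo)[0]
        assert ebgm_stat(hi)[0] > ebgm_stat(lo)[0]

    def test_zero_background_cell_gets_continuity_correction(self):
        s = compute_scores(tab(4, 10, 0, 100))
        assert s.corrected
        assert math.isfinite(s.ror) and math.isfinite(s.ic025) and math.isfinite(s.ebgm05)

    def test_bate_posterior_mode_shrinks_toward_null(self):
        t = tab(10, 90, 100, 9800)
        ic_delta, lo_delta = ic_stat(t, mode="delta")
        ic_bate, lo_bate = ic_stat(t, mode="bate1998")
        assert lo_bate <= ic_bate
        assert 0 < ic_bate < ic_delta  # posterior mean pulled toward 0
        big = tab(10000, 90000, 100000, 9_800_000)
        assert ic_stat(big, mode="bate1998")[0] == pytest.approx(ic_stat(big)[0], abs=0.01)


class TestCriteria:
    def _scores(self, **kw):
        base = dict(
            term="X", n=5, ror=1.5, ror_lo95=0.8, ror_hi95=2.0,
            prr=1.5, prr_lo95=0.8, prr_hi95=2.0, chi2=1.0,
            ic=0.2, ic025=-0.5, ebgm=1.2, ebgm05=0.8,
        )
        base.update(kw)
        return SignalScores(**base)

    def test_any_single_rule_fires_combined_flag(self):
        s = self._scores(ror_lo95=1.2)
        rules = evaluate_signal(s)
        assert rules["ror_rule"] and rules["signal"]
        assert not (rules["prr_rule"] or rules["ic_rule"] or rules["ebgm_rule"])

    def test_min_n_gates_ror_and_prr_rules(self):
        s = self._scores(n=2, ror_lo95=50.0, prr=99.0, chi2=500.0, ic025=-1.0, ebgm05=0.5)
        rules = evaluate_signal(s)
        assert not rules["signal"]

    def test_null_table_scores_trigger_nothing(self):
        s = compute_scores(tab(5, 5, 5, 5))
        assert not evaluate_signal(s)["signal"]

    def test_prr_threshold_inclusive_by_default_configurable_strict(self):
        s = self._scores(prr=2.0, chi2=10.0)
        assert evaluate_signal(s)["prr_rule"]
        strict = SignalCriteria(prr_inclusive=False)
        assert not evaluate_signal(s, strict)["prr_rule"]

    def test_combine_all_requires_every_rule(self):
        s = self._scores(ror_lo95=1.2)
        assert not evaluate_signal(s, SignalCriteria(combine="all"))["signal"]


class TestRanking:
    def _frame(self):
        rows = [
            {"SOC": "", "PT": "A", "n": 5, "ROR": 5.0},
            {"SOC": "", "PT": "B", "n": 9, "ROR": 3.0},
            {"SOC": "", "PT": "C", "n": 2, "ROR": 9.0},
            {"SOC": "", "PT": "D", "n": 7, "ROR": 3.0},
        ]
        return pd.DataFrame(rows)

    def test_descending_with_top_k(self):
        out = rank_signals(self._frame(), by="ror", top_k=2)
        assert list(out["PT"]) == ["C", "A"]

    def test_tie_breaks_by_n_then_term(self):
        # B and D tie on ROR 3.0; B has the larger n so it ranks first
        out = rank_signals(self._frame(), by="ror")
        assert list(out["PT"]) == ["C", "A", "B", "D"]


class TestSubgroups:
    def test_age_groups_partition_and_empty_group_warns(self, vocab):
        target = [
            mk_case("1", {"Acne"}, target=True, age=30),
            mk_case("2", {"Acne"}, target=True, age=40),
            mk_case("3", {"Acne"}, target=True, age=50),
            mk_case("4", {"Acne"}, target=True, age=70),
        ]
        background = [mk_case(str(10 + i), {"Acne", "Rash"}, age=30 + i) for i in range(20)]
        cohort = Cohort(target, background, "upadacitinib", frozenset())
        tables = subgroup_analysis(cohort, min_a=3, vocab=vocab)
        assert set(tables) == {"under18", "a18to65", "over65"}
        assert tables["under18"].empty
        assert len(tables["a18to65"]) >= 1
        # within-group background: three 18-65 target cases vs 18-65 background
        row = tables["a18to65"].iloc[0]
        assert row["n"] == 3

    def test_signal_table_runs_at_soc_level(self, ibd_cohort, vocab):
        df = signal_table(ibd_cohort, level="SOC", min_a=3, vocab=vocab)
        assert len(df) > 0
        assert (df["SOC"] == df["PT"]).all() or (df["PT"].notna()).all()
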