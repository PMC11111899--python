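"""Disproportionality statistics: hand values, identities, oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

from pvsignal import ingest
from pvsignal.ingest import PtDictionary, case_pt_pairs, deduplicate
from pvsignal.signals import (BcpnnHyperparams, ContingencyTable,
                              EmptyUniverseError, SignalThresholds,
                              aggregate_soc, bcpnn_stat, build_contingency,
                              ebgm_stat, evaluate_thresholds, prr_stat,
                              ror_stat, score_pairs)
from pvsignal.simulate import drug_name, generate_pt_dictionary

TABLE = ContingencyTable(10, 20, 30, 40)
INDEP = ContingencyTable(1, 9, 9, 81)

cells = st.integers(min_value=1, max_value=500)


class TestHandValues:
    def test_ror_example(self):
        ror, lo, hi = ror_stat(TABLE)
        assert ror == pytest.approx(2 / 3, rel=1e-12)
        assert (lo, hi) == pytest.approx((0.2725, 1.6309), abs=1e-3)

    def test_prr_example(self):
        prr, chi2 = prr_stat(TABLE)
        assert prr == pytest.approx(7 / 9, rel=1e-12)
        assert chi2 == pytest.approx(0.794, abs=1e-3)

    def test_ebgm_example(self):
        ebgm, lo, hi = ebgm_stat(TABLE)
        assert ebgm == pytest.approx(5 / 6, rel=1e-12)
        assert lo == pytest.approx(0.341, abs=1e-3)

    def test_bcpnn_example(self):
        ic, e_ic, v_ic, ic2sd = bcpnn_stat(TABLE)
        assert ic == pytest.approx(-0.263, abs=1e-3)
        assert e_ic == pytest.approx(-0.2648, abs=1e-4)
        assert v_ic == pytest.approx(0.2448, abs=1e-4)
        assert ic2sd == pytest.approx(-1.254, abs=1e-3)

    def test_independence_table_is_neutral(self):
        assert ror_stat(INDEP)[0] == pytest.approx(1.0)
        prr, chi2 = prr_stat(INDEP)
        assert (prr, chi2) == pytest.approx((1.0, 0.0))
        assert ebgm_stat(INDEP)[0] == pytest.approx(1.0)
        assert bcpnn_stat(INDEP)[0] == pytest.approx(0.0)

    def test_bcpnn_default_hyperparameters(self):
        h = BcpnnHyperparams()
        assert (h.alpha1, h.beta1, h.alpha, h.beta, h.gamma11) == (1, 1, 2, 2, 1)


class TestSymmetriesAndOracles:
    def test_ror_and_chi2_invariant_under_transpose(self):
        t = ContingencyTable(10, 20, 30, 40)
        tt = ContingencyTable(10, 30, 20, 40)
        assert ror_stat(t)[0] == pytest.approx(ror_stat(tt)[0])
        assert prr_stat(t)[1] == pytest.approx(prr_stat(tt)[1])

    @pytest.mark.parametrize("t", [TABLE, ContingencyTable(3, 97, 50, 850),
                                   ContingencyTable(12, 5, 40, 900)])
    def test_chi2_matches_scipy_pearson(self, t):
        _, chi2 = prr_stat(t)
        expect = chi2_contingency([[t.a, t.b], [t.c, t.d]], correction=False)[0]
        assert chi2 == pytest.approx(expect, rel=1e-12)

    @pytest.mark.parametrize("t", [TABLE, ContingencyTable(3, 97, 50, 850)])
    def test_ror_matches_statsmodels(self, t):
        sm2 = pytest.importorskip("statsmodels.stats.contingency_tables")
        tab = sm2.Table2x2(np.array([[t.a, t.b], [t.c, t.d]]))
        ror, lo, hi = ror_stat(t)
        assert ror == pytest.approx(tab.oddsratio, rel=1e-12)
        # we use z = 1.96 exactly; statsmodels uses the exact normal quantile
        assert (lo, hi) == pytest.approx(tab.oddsratio_confint(0.05), rel=1e-4)

    @settings(max_examples=200, derandomize=True)
    @given(a=cells, b=cells, c=cells, d=cells)
    def test_ebgm_equals_two_to_the_ic(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        ebgm = ebgm_stat(t)[0]
        ic = bcpnn_stat(t)[0]
        assert 2.0 ** ic == pytest.approx(ebgm, rel=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(a=st.integers(1, 30), b=st.integers(40, 400),
           c=st.integers(40, 400), d=st.integers(100, 5000))
    def test_statistics_increase_in_a_when_margins_dominate(self, a, b, c, d):
        # monotone regime: bc > a^2 (holds throughout this strategy)
        t0, t1 = ContingencyTable(a, b, c, d), ContingencyTable(a + 1, b, c, d)
        assert ror_stat(t1)[0] > ror_stat(t0)[0]
        assert prr_stat(t1)[0] > prr_stat(t0)[0]
        assert ebgm_stat(t1)[0] > ebgm_stat(t0)[0]
        assert bcpnn_stat(t1)[0] > bcpnn_stat(t0)[0]

    def test_zero_cell_policy(self):
        t = ContingencyTable(5, 0, 3, 100)
        ror, lo, hi = ror_stat(t)  # Haldane on all four cells
        assert ror == pytest.approx((5.5 * 100.5) / (0.5 * 3.5), rel=1e-12)
        assert math.isnan(prr_stat(ContingencyTable(5, 5, 0, 100))[0])
        assert math.isnan(ebgm_stat(ContingencyTable(0, 0, 3, 100))[0])

    def test_empty_universe_rejected(self):
        with pytest.raises(EmptyUniverseError):
            ContingencyTable(0, 0, 0, 0).validate()


class TestBuildContingency:
    def _pairs(self, rows):
        return pd.DataFrame(rows, columns=["primaryid", "pt", "exposed"])

    def test_four_unit_universe_partitions(self):
        pairs = self._pairs([(1, "PT1", True), (2, "PT2", True),
                             (3, "PT1", False), (4, "PT2", False)])
        assert build_contingency(pairs, "PT1") == ContingencyTable(1, 1, 1, 1)

    def test_no_exposed_cases(self):
        pairs = self._pairs([(1, "PT1", False), (2, "PT2", False)])
        t = build_contingency(pairs, "PT1")
        assert (t.a, t.b) == (0, 0) and t.n == 2

    def test_counts_match_bruteforce_on_planted_quarter(self, small_quarter):
        cfg, bundle = small_quarter
        demo_dd = deduplicate(ingest.assemble_demo(bundle.demo))
        kept = set(demo_dd["primaryid"])
        ps = bundle.drug[(bundle.drug["role_cod"] == "PS")
                         & (bundle.drug["drugname"] == drug_name(0))]
        exposed = set(ps["primaryid"]) & kept
        pairs = case_pt_pairs(bundle.reac, kept, exposed)
        t = build_contingency(pairs, "PT0001")
        brute = {(int(p), str(pt)) for p, pt in
                 zip(bundle.reac["primaryid"], bundle.reac["pt"])
                 if int(p) in kept}
        a = sum(1 for (p, pt) in brute if pt == "PT0001" and p in exposed)
        assert t.a == a
        assert t.n == len(brute)


class TestThresholdsAndConsensus:
    def _score(self, **kw):
        base = dict(a=10, ror_lo95=2.0, prr=3.0, chi2=30.0, ebgm05=2.5,
                    ic_minus_2sd=0.5)
        base.update(kw)
        return base

    def test_small_count_gate_beats_large_ror(self):
        flags = evaluate_thresholds(self._score(a=2, ror_lo95=50.0))
        assert not flags["flag_ror"] and not flags["consensus"]

    def test_independence_flags_all_false(self):
        flags = evaluate_thresholds(self._score(a=1, ror_lo95=0.2, prr=1.0,
                                                chi2=0.0, ebgm05=0.9,
                                                ic_minus_2sd=-1.0))
        assert not any(flags.values())

    def test_undefined_statistic_cannot_vote(self):
        flags = evaluate_thresholds(self._score(ebgm05=float("nan")))
        assert not flags["flag_mgps"] and not flags["consensus"]

    def test_consensus_requires_all_four(self):
        flags = evaluate_thresholds(self._score())
        assert flags["consensus"]
        for key in ("flag_ror", "flag_prr", "flag_mgps", "flag_bcpnn"):
            down = evaluate_thresholds(self._score(**{
                "flag_ror": dict(a=2), "flag_prr": dict(prr=1.5),
                "flag_mgps": dict(ebgm05=1.0), "flag_bcpnn": dict(ic_minus_2sd=-0.1),
            }[key]))
            assert not down[key] and not down["consensus"]


class TestScorePairs:
    def test_matches_scalar_bruteforce_per_pt(self, small_quarter):
        cfg, bundle = small_quarter
        demo_dd = deduplicate(ingest.assemble_demo(bundle.demo))
        kept = set(demo_dd["primaryid"])
        ps = bundle.drug[(bundle.drug["role_cod"] == "PS")
                         & (bundle.drug["drugname"] == drug_name(0))]
        exposed = set(ps["primaryid"]) & kept
        pairs = case_pt_pairs(bundle.reac, kept, exposed)
        frame = score_pairs(pairs).set_index("pt")
        for pt in frame.index:
            t = build_contingency(pairs, pt)
            row = frame.loc[pt]
            assert (row["a"], row["b"], row["c"], row["d"]) == tuple(t)
            ror, lo, hi = ror_stat(t)
            prr, chi2 = prr_stat(t)
            ebgm, e05, _ = ebgm_stat(t)
            ic, e_ic, v_ic, ic2 = bcpnn_stat(t)
            for name, val in [("ror", ror), ("ror_lo95", lo), ("prr", prr),
                              ("chi2", chi2), ("ebgm", ebgm), ("ebgm05", e05),
                              ("ic", ic), ("e_ic", e_ic), ("ic_minus_2sd", ic2)]:
                if math.isnan(val):
                    assert math.isnan(row[name]), (pt, name)
                else:
                    assert row[name] == pytest.approx(val, rel=1e-10), (pt, name)
            assert bool(row["consensus"]) == evaluate_thresholds(row)["consensus"]

    def test_consensus_subset_of_each_method(self, small_quarter):
        cfg, bundle = small_quarter
        demo_dd = deduplicate(ingest.assemble_demo(bundle.demo))
        kept = set(demo_dd["primaryid"])
        ps = bundle.drug[(bundle.drug["role_cod"] == "PS")
                         & (bundle.drug["drugname"] == drug_name(0))]
        pairs = case_pt_pairs(bundle.reac, kept, set(ps["primaryid"]) & kept)
        frame = score_pairs(pairs)
        consensus = frame[frame["consensus"]]
        for flag in ("flag_ror", "flag_prr", "flag_mgps", "flag_bcpnn"):
            assert consensus[flag].all()
        assert frame.loc[0, "a"] == frame["a"].max()  # sorted by a desc

    def test_planted_signal_reaches_consensus(self, small_quarter):
        cfg, bundle = small_quarter
        demo_dd = deduplicate(ingest.assemble_demo(bundle.demo))
        kept = set(demo_dd["primaryid"])
        ps = bundle.drug[(bundle.drug["role_cod"] == "PS")
                         & (bundle.drug["drugname"] == drug_name(0))]
        pairs = case_pt_pairs(bundle.reac, kept, set(ps["primaryid"]) & kept)
        frame = score_pairs(pairs).set_index("pt")
        assert bool(frame.loc["PT0001", "consensus"])


class TestAggregateSoc:
    def _pairs(self, rows):
        return pd.DataFrame(rows, columns=["primaryid", "pt", "exposed"])

    def _dict(self, mapping):
        return PtDictionary.from_frame(pd.DataFrame(
            {"pt": list(mapping), "soc": list(mapping.values())}))

    def test_single_soc_equals_summed_pt_table_without_case_dedup(self):
        pairs = self._pairs([(1, "A", True), (2, "B", True), (3, "A", False)])
        d = self._dict({"A": "S1", "B": "S1"})
        out = aggregate_soc(pairs, d, dedup_within_case=False)
        assert out.loc[0, "n"] == 2
        assert out.loc[0, ["a", "b", "c", "d"]].tolist() == [2, 0, 1, 0]

    def test_case_with_two_pts_in_soc_counts_once(self):
        # oracle: set-based recount of (case, SOC) units
        pairs = self._pairs([(1, "A", True), (1, "B", True), (2, "A", False)])
        d = self._dict({"A": "S1", "B": "S1"})
        out = aggregate_soc(pairs, d).set_index("soc")
        units = {(p, "S1") for p, pt, _ in pairs.itertuples(index=False)}
        assert out.loc["S1", "n"] == 1
        assert out.loc["S1", ["a", "c"]].sum() == len(units)

    def test_empty_input_gives_empty_table(self):
        out = aggregate_soc(self._pairs([]), self._dict({"A": "S1"}))
        assert out.empty
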