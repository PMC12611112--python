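"""Disproportionality formulas, positivity criteria, Fisher/Bonferroni and
the end-to-end screen, each checked against independent arithmetic."""

import math
from fractions import Fraction

import numpy as np
import pytest

from conftest import make_record
from pvsignal.contingency import ContingencyTable, PtSocMap
from pvsignal.dpa_stats import (BcpnnPriors, ExclusionList, SignalCriteria,
                                bcpnn_ic, bonferroni, estimate_all,
                                evaluate_criteria, fisher_exact,
                                intersect_signals, prr, ror, screen_signals,
                                volcano_table)

# ---------------------------------------------------------------------------
# independent oracles (straight transcriptions of the published formulas)


def oracle_ror(a, b, c, d):
    if 0 in (a, b, c, d):
        return None, (None, None)
    est = a * d / (b * c)
    half = 1.96 * math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return est, (math.exp(math.log(est) - half), math.exp(math.log(est) + half))


def oracle_prr(a, b, c, d):
    est = None if (c == 0 or a + b == 0) else (a * (c + d)) / (c * (a + b))
    n = a + b + c + d
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    chi2 = None if margins == 0 else (a * d - b * c) ** 2 * n / margins
    return est, chi2


def oracle_ic(a, b, c, d, priors=BcpnnPriors()):
    n = a + b + c + d
    if a == 0:
        return None, None, None
    ic = math.log2(a * n / ((a + c) * (a + b)))
    p = priors
    ab, ac = a + b, a + c
    gamma = p.gamma11 * (n + p.alpha) * (n + p.beta) / (
        (ab + p.alpha1) * (ac + p.beta1))
    v = (1 / math.log(2)) ** 2 * (
        (n - a + gamma - p.gamma11) / ((a + p.gamma11) * (1 + n + gamma))
        + (n - ab + p.alpha - p.alpha1) / ((ab + p.alpha1) * (1 + n + p.alpha))
        + (n - ac + p.beta - p.beta1) / ((ac + p.beta1) * (1 + n + p.beta)))
    half = p.z * math.sqrt(v)
    return ic, ic - half, ic + half


def oracle_fisher(a, b, c, d):
    """Two-sided p by full hypergeometric enumeration (exact rationals)."""
    r1, c1, n = a + b, a + c, a + b + c + d
    denom = math.comb(n, c1)
    p_obs = Fraction(math.comb(r1, a) * math.comb(n - r1, c1 - a), denom)
    total = Fraction(0)
    for aa in range(max(0, c1 - (n - r1)), min(r1, c1) + 1):
        p = Fraction(math.comb(r1, aa) * math.comb(n - r1, c1 - aa), denom)
        if p <= p_obs:
            total += p
    return total


# ---------------------------------------------------------------------------


class TestRor:
    def test_hand_arithmetic(self):
        est, (lo, hi) = ror(ContingencyTable(10, 90, 100, 9900))
        assert est == pytest.approx(11.0)
        assert lo == pytest.approx(5.5595, abs=1e-3)
        assert hi == pytest.approx(21.7645, abs=1e-3)

    def test_independence_table(self):
        assert ror(ContingencyTable(5, 5, 5, 5))[0] == pytest.approx(1.0)

    def test_zero_cell_not_evaluable(self):
        assert ror(ContingencyTable(3, 10, 0, 100)) == (None, (None, None))

    def test_haldane_correction_makes_zero_cell_evaluable(self):
        est, (lo, hi) = ror(ContingencyTable(3, 10, 0, 100), correction=True)
        assert est == pytest.approx((3.5 * 100.5) / (10.5 * 0.5))


class TestPrr:
    def test_hand_arithmetic(self):
        est, chi2 = prr(ContingencyTable(10, 90, 100, 9900))
        assert est == pytest.approx(10.0)
        assert chi2 == pytest.approx(74.4472, abs=1e-3)

    def test_independence(self):
        est, chi2 = prr(ContingencyTable(5, 5, 5, 5))
        assert est == pytest.approx(1.0) and chi2 == pytest.approx(0.0)

    def test_a_zero_gives_prr_zero(self):
        est, _ = prr(ContingencyTable(0, 100, 10, 9990))
        assert est == pytest.approx(0.0)

    def test_c_zero_not_evaluable(self):
        assert prr(ContingencyTable(3, 10, 0, 100))[0] is None


class TestBcpnnIc:
    def test_point_estimate(self):
        ic, ic025, ic975 = bcpnn_ic(ContingencyTable(10, 90, 100, 9900))
        assert ic == pytest.approx(math.log2(101000 / 11000), rel=1e-12)
        # hand evaluation of the closed-form variance for this table
        assert ic025 == pytest.approx(2.24371, abs=1e-4)
        assert ic975 == pytest.approx(4.15385, abs=1e-4)

    def test_independence_ci_below_point(self):
        ic, ic025, _ = bcpnn_ic(ContingencyTable(5, 5, 5, 5))
        assert ic == pytest.approx(0.0)
        assert ic025 < 0

    def test_a_zero_not_evaluable(self):
        assert bcpnn_ic(ContingencyTable(0, 5, 5, 5)) == (None, None, None)


class TestOracleEquivalence:
    def test_thousand_random_tables(self):
        rng = np.random.default_rng(20240917)
        cells = rng.integers(0, 10_001, size=(1000, 4))
        cells = cells[cells.sum(axis=1) > 0]
        for row in cells:
            a, b, c, d = (int(v) for v in row)
            t = ContingencyTable(a, b, c, d)
            for got, want in [(ror(t), oracle_ror(a, b, c, d)),
                              (prr(t), oracle_prr(a, b, c, d))]:
                np.testing.assert_allclose(
                    [x for x in _flat(got)], [x for x in _flat(want)],
                    rtol=1e-10)
            np.testing.assert_allclose(
                _flat(bcpnn_ic(t)), _flat(oracle_ic(a, b, c, d)), rtol=1e-10,
                atol=1e-12)

    def test_sign_coherence_across_methods(self):
        rng = np.random.default_rng(7)
        for a, b, c, d in rng.integers(1, 500, size=(200, 4)):
            t = ContingencyTable(int(a), int(b), int(c), int(d))
            r = ror(t)[0]
            p = prr(t)[0]
            ic = bcpnn_ic(t)[0]
            assert np.sign(r - 1) == np.sign(p - 1) == np.sign(ic) \
                or min(abs(r - 1), abs(p - 1), abs(ic)) < 1e-9

    def test_ror_dominates_prr_above_one(self):
        rng = np.random.default_rng(8)
        for a, b, c, d in rng.integers(1, 500, size=(200, 4)):
            t = ContingencyTable(int(a), int(b), int(c), int(d))
            r, p = ror(t)[0], prr(t)[0]
            if r > 1:
                assert r >= p - 1e-12
                assert p >= 1 - 1e-12


def _flat(result):
    out = []
    for part in result:
        if isinstance(part, tuple):
            out.extend(part)
        else:
            out.append(part)
    return [math.nan if x is None else x for x in out]


class TestCriteria:
    def test_case_count_gate_blocks_huge_ror(self):
        t = ContingencyTable(2, 1, 1, 10000)
        flags = evaluate_criteria(t, estimate_all(t))
        assert not flags.ror and not flags.combined

    def test_independence_table_all_negative(self):
        t = ContingencyTable(5, 5, 5, 5)
        flags = evaluate_criteria(t, estimate_all(t))
        assert not (flags.ror or flags.prr or flags.bcpnn)

    def test_strong_signal_table(self):
        t = ContingencyTable(10, 90, 100, 9900)
        e = estimate_all(t)
        flags = evaluate_criteria(t, e)
        assert flags.ror and flags.prr and flags.bcpnn and flags.combined

    def test_combined_is_conjunction(self):
        t = ContingencyTable(10, 90, 100, 9900)
        flags = evaluate_criteria(t, estimate_all(t),
                                  SignalCriteria(ic025_min=10.0))
        assert flags.ror and flags.prr and not flags.bcpnn
        assert not flags.combined


class TestFisherBonferroni:
    def test_exact_value_3113(self):
        p = fisher_exact(ContingencyTable(3, 1, 1, 3))
        assert p == pytest.approx(34 / 70, rel=1e-12)

    def test_most_probable_table_p_one(self):
        assert fisher_exact(ContingencyTable(2, 2, 2, 2)) == pytest.approx(1.0)

    def test_row_swap_symmetry(self):
        p1 = fisher_exact(ContingencyTable(7, 2, 5, 11))
        p2 = fisher_exact(ContingencyTable(5, 11, 7, 2))
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_matches_enumeration_on_small_margins(self):
        rng = np.random.default_rng(99)
        for a, b, c, d in rng.integers(0, 16, size=(150, 4)):
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            t = ContingencyTable(int(a), int(b), int(c), int(d))
            want = float(oracle_fisher(int(a), int(b), int(c), int(d)))
            assert fisher_exact(t) == pytest.approx(want, rel=1e-7)

    @pytest.mark.parametrize("p, m, expected", [
        (0.01, 50, 0.5), (0.5, 3, 1.0), (0.0, 1000, 0.0)])
    def test_bonferroni(self, p, m, expected):
        assert bonferroni([p], m) == [pytest.approx(expected)]

    def test_bonferroni_rejects_bad_family(self):
        with pytest.raises(ValueError):
            bonferroni([0.1], 0)
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2], 1)


def _screen_records(planted_pt="hot", n_target=60, n_background=600):
    records = []
    pid = 0
    for i in range(n_target):
        pid += 1
        events = {planted_pt} if i < 30 else {f"mild{i % 5}"}
        records.append(make_record(str(pid), str(pid),
                                   drugs=[("t", "PS")], events=events))
    for i in range(n_background):
        pid += 1
        events = {f"mild{i % 5}", f"bg{i % 11}"}
        if i < 5:  # rare background occurrence of the planted term
            events.add(planted_pt)
        records.append(make_record(str(pid), str(pid), events=events))
    return records


class TestScreen:
    def _soc_map(self, records):
        pts = {pt for r in records for pt in r.events}
        return PtSocMap({pt: "Some SOC" for pt in pts})

    def test_overrepresented_pt_is_combined_signal(self):
        records = _screen_records()
        result = screen_signals(records, "t", self._soc_map(records))
        by_pt = {s.pt: s for s in result.signals}
        assert by_pt["hot"].combined_signal
        assert by_pt["hot"].a == 30

    def test_results_ranked_by_count_then_ror(self):
        records = _screen_records()
        result = screen_signals(records, "t", self._soc_map(records))
        counts = [s.a for s in result.signals]
        assert counts == sorted(counts, reverse=True)

    def test_bonferroni_family_is_pts_tested(self):
        records = _screen_records()
        result = screen_signals(records, "t", self._soc_map(records))
        m = result.n_pts_tested
        for s in result.signals:
            assert s.p_adjust == pytest.approx(min(1.0, m * s.fisher_p))

    def test_exclusion_list_drops_and_annotates(self):
        records = _screen_records(planted_pt="Off label use")
        result = screen_signals(records, "t", self._soc_map(records),
                                exclusions=ExclusionList(["off label use"]))
        assert all(s.pt != "Off label use" for s in result.signals)
        assert any(s.pt == "Off label use" and s.excluded
                   for s in result.excluded)

    def test_all_pts_excluded_gives_empty_output(self):
        records = _screen_records()
        pts = {pt for r in records for pt in r.events}
        result = screen_signals(records, "t", self._soc_map(records),
                                exclusions=ExclusionList(list(pts)))
        assert result.signals == []


class TestIntersectVolcano:
    def _sig(self, pt, combined=True, ror_est=10.0, p_adj=0.01, a=5):
        from pvsignal.dpa_stats import DpaEstimates, SignalResult
        est = DpaEstimates(ror_est, None, None, None, None, None, None, None)
        return SignalResult(drug="t", pt=pt, a=a,
                            table=ContingencyTable(a, 1, 1, 1),
                            estimates=est, flag_ror=combined,
                            flag_prr=combined, flag_bcpnn=combined,
                            combined_signal=combined, soc="s",
                            fisher_p=p_adj, p_adjust=p_adj)

    def test_intersection_of_shared_pts(self):
        a = [self._sig("x"), self._sig("y"), self._sig("z", combined=False)]
        b = [self._sig("x"), self._sig("y"), self._sig("w")]
        assert intersect_signals(a, b) == {"x", "y"}

    def test_disjoint_and_identical(self):
        a, b = [self._sig("x")], [self._sig("y")]
        assert intersect_signals(a, b) == set()
        assert intersect_signals(a, a) == {"x"}

    def test_volcano_coordinates(self):
        table = volcano_table([
            self._sig("origin", ror_est=1.0, p_adj=1.0),
            self._sig("corner", ror_est=10.0, p_adj=0.01),
            self._sig("gone", ror_est=None),
        ])
        rows = table.set_index("pt")
        assert rows.loc["origin", "log_ror"] == 0.0
        assert rows.loc["origin", "neg_log10_p_adjust"] == 0.0
        assert rows.loc["corner", "log_ror"] == pytest.approx(1.0)
        assert rows.loc["corner", "neg_log10_p_adjust"] == pytest.approx(2.0)
        assert "gone" not in rows.index
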