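"""Fourfold-table construction, pair counting and SOC rollups."""

import pytest

from conftest import make_record
from pvsignal.contingency import (BACKGROUND, ContingencyTable, PtSocMap,
                                  UnmappedPtError, build_2x2,
                                  count_drug_event_pairs,
                                  soc_distribution_from_counts)


class TestPairCounting:
    def test_counting_unit_is_report_pt_pair(self):
        rec = make_record(drugs=[("penicillamine", "PS")], events={"x", "y"})
        counts = count_drug_event_pairs([rec], {"penicillamine"})
        assert counts.group_counts["penicillamine"] == {"x": 1, "y": 1}
        assert counts.total("penicillamine") == 2

    def test_set_semantics_collapse_repeated_pt(self):
        # a PT listed twice in REAC is one event on the record
        rec = make_record(events={"x"})
        counts = count_drug_event_pairs([rec], {"penicillamine"})
        assert counts.group_counts[BACKGROUND]["x"] == 1

    def test_non_ps_report_counts_as_background(self):
        rec = make_record(drugs=[("penicillamine", "C")], events={"x"})
        counts = count_drug_event_pairs([rec], {"penicillamine"})
        assert counts.group_counts["penicillamine"]["x"] == 0
        assert counts.group_counts[BACKGROUND]["x"] == 1

    def test_conservation_over_groups(self):
        records = [
            make_record("1", "1", drugs=[("penicillamine", "PS")],
                        events={"x", "y"}),
            make_record("2", "2", drugs=[("trientine", "PS")], events={"x"}),
            make_record("3", "3", events={"y", "z"}),
        ]
        counts = count_drug_event_pairs(records,
                                        {"penicillamine", "trientine"})
        for pt in "xyz":
            total = sum(counts.group_counts[g][pt]
                        for g in counts.group_counts)
            assert total == counts.overall[pt]
        assert counts.overall_total == 5


class TestBuild2x2:
    def _counts(self, a, total_t, c, total_b):
        records = []
        pid = 0
        for i in range(a):
            pid += 1
            records.append(make_record(str(pid), str(pid),
                                       drugs=[("t", "PS")], events={"pt"}))
        for i in range(total_t - a):
            pid += 1
            records.append(make_record(str(pid), str(pid),
                                       drugs=[("t", "PS")],
                                       events={f"other{i}"}))
        for i in range(c):
            pid += 1
            records.append(make_record(str(pid), str(pid), events={"pt"}))
        for i in range(total_b - c):
            pid += 1
            records.append(make_record(str(pid), str(pid),
                                       events={f"bg{i}"}))
        return count_drug_event_pairs(records, {"t"})

    def test_forced_arithmetic(self):
        counts = self._counts(a=10, total_t=100, c=100, total_b=10000)
        assert build_2x2(counts, "t", "pt").cells == (10, 90, 100, 9900)

    def test_pt_absent_from_both_groups(self):
        counts = self._counts(a=0, total_t=5, c=0, total_b=7)
        assert build_2x2(counts, "t", "nowhere").cells == (0, 5, 0, 7)

    def test_pt_only_in_target(self):
        counts = self._counts(a=2, total_t=5, c=0, total_b=7)
        assert build_2x2(counts, "t", "pt").cells == (2, 3, 0, 7)

    def test_cells_invariant_to_record_order(self):
        records = [
            make_record("1", "1", drugs=[("t", "PS")], events={"pt", "o"}),
            make_record("2", "2", events={"pt"}),
            make_record("3", "3", events={"o"}),
        ]
        fwd = build_2x2(count_drug_event_pairs(records, {"t"}), "t", "pt")
        rev = build_2x2(count_drug_event_pairs(records[::-1], {"t"}), "t", "pt")
        assert fwd.cells == rev.cells

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(1, -1, 0, 3)


class TestSocDistribution:
    # Case counts per SOC as printed for the penicillamine signal set
    PENICILLAMINE = {
        "Immune system disorders": 74,
        "Skin and subcutaneous tissue disorders": 62,
        "Nervous system disorders": 45,
        "Renal and urinary disorders": 30,
        "Injury, poisoning and procedural complications": 30,
        "Hepatobiliary disorders": 28,
        "General disorders and administration site conditions": 25,
        "Gastrointestinal disorders": 20,
        "Respiratory, thoracic and mediastinal disorders": 17,
        "Congenital, familial and genetic disorders": 12,
        "Blood and lymphatic system disorders": 11,
        "Musculoskeletal and connective tissue disorders": 10,
        "Investigations": 9,
        "Surgical and medical procedures": 7,
        "Vascular disorders": 6,
        "Metabolism and nutrition disorders": 6,
        "Cardiac disorders": 4,
        "Pregnancy, puerperium and perinatal conditions": 3,
        "Infections and infestations": 3,
    }
    TRIENTINE = {
        "Nervous system disorders": 46,
        "Renal and urinary disorders": 5,
        "Hepatobiliary disorders": 17,
        "General disorders and administration site conditions": 13,
        "Gastrointestinal disorders": 56,
        "Musculoskeletal and connective tissue disorders": 3,
        "Investigations": 3,
        "Metabolism and nutrition disorders": 3,
        "Psychiatric disorders": 24,
    }

    def test_immune_share_of_penicillamine_counts(self):
        assert sum(self.PENICILLAMINE.values()) == 402
        table = soc_distribution_from_counts(self.PENICILLAMINE)
        immune = table.set_index("soc").loc["Immune system disorders"]
        assert immune["percent"] == pytest.approx(18.41, abs=0.005)

    def test_gastrointestinal_share_of_trientine_counts(self):
        assert sum(self.TRIENTINE.values()) == 170
        table = soc_distribution_from_counts(self.TRIENTINE)
        gi = table.set_index("soc").loc["Gastrointestinal disorders"]
        assert gi["percent"] == pytest.approx(32.94, abs=0.005)

    def test_single_soc_is_hundred_percent(self):
        table = soc_distribution_from_counts({"Hepatobiliary disorders": 5})
        assert table["percent"].tolist() == [100.0]

    @pytest.mark.parametrize("counts", [PENICILLAMINE, TRIENTINE])
    def test_percents_sum_to_hundred(self, counts):
        table = soc_distribution_from_counts(counts)
        assert round(table["percent"], 2).sum() == pytest.approx(100, abs=0.05)

    def test_signal_based_rollup_uses_case_counts(self, record_factory):
        # two positive signals in one SOC with a=2 and a=3, one in another
        from pvsignal.contingency import soc_distribution
        from pvsignal.dpa_stats import screen_signals
        soc_map = PtSocMap({"x": "SOC A", "y": "SOC A", "z": "SOC B"})
        records = []
        pid = 0
        for events in [{"x", "y"}, {"x"}, {"z"}] * 4:
            pid += 1
            records.append(record_factory(str(pid), str(pid),
                                          drugs=[("t", "PS")], events=events))
        for i in range(200):
            pid += 1
            events = {f"bg{i % 7}"}
            if i < 2:  # rare background occurrence keeps cells positive
                events = {"x", "y", "z"}
            records.append(record_factory(str(pid), str(pid), events=events))
        result = screen_signals(records, "t", soc_map)
        table = soc_distribution(result.signals, soc_map)
        by_soc = dict(zip(table["soc"], table["n"]))
        # every screened PT is strongly disproportionate here
        assert by_soc["SOC A"] == 12  # a(x)=8 + a(y)=4
        assert by_soc["SOC B"] == 4

    def test_unmapped_pt_is_named_in_error(self):
        with pytest.raises(UnmappedPtError, match="mystery"):
            PtSocMap({}).lookup("mystery")
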