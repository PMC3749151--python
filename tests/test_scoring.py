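"""Blind-test scoring against brute-force tallies and the published tables."""

import numpy as np
import pandas as pd
import pytest

from taphomark.io import load_fixture, table3_values
from taphomark.scoring import (confidence_success_correlation,
                               correspondence_table, diagnose_success,
                               exclusion_effect, experience_correlation,
                               instrument_comparison, locate_success,
                               pedagogy_comparison, size_success_correlation,
                               subset_excluding, two_way_correspondence)
from taphomark.stats import kendall_tau


def tiny_test():
    """Hand-built 2-participant, 4-specimen blind test with known tallies."""
    key = pd.DataFrame({
        "specimen": ["s1", "s2", "s3", "s4"],
        "category": ["cut/scrape", "trampling", "none", "percussion"],
        "size_um": [120.0, 80.0, None, 200.0],
    })
    responses = pd.DataFrame([
        # pA: correct on s1, s3; wrong diagnosis s2; missed s4
        ("pA", "s1", True, "cut/scrape", 5),
        ("pA", "s2", True, "cut/scrape", 2),
        ("pA", "s3", False, "none", 4),
        ("pA", "s4", False, "none", 1),
        # pB: correct everywhere except a false positive on s3
        ("pB", "s1", True, "cut/scrape", 4),
        ("pB", "s2", True, "trampling", 3),
        ("pB", "s3", True, "cut/scrape", 1),
        ("pB", "s4", True, "percussion", 5),
    ], columns=["participant", "specimen", "present", "diagnosis", "confidence"])
    participants = pd.DataFrame({
        "participant": ["pA", "pB"],
        "instrument": ["hand_lens", "hand_lens"],
        "pedagogy": ["TT1", "TT1"],
        "years": [5, 10],
    })
    return responses, key, participants


class TestSuccess:
    def test_locate_tallies(self):
        responses, key, _ = tiny_test()
        s = locate_success(responses, key)
        assert s["pA"] == pytest.approx(100 * 3 / 4)  # missed s4
        assert s["pB"] == pytest.approx(100 * 3 / 4)  # false positive on s3

    def test_diagnose_tallies(self):
        responses, key, _ = tiny_test()
        s = diagnose_success(responses, key)
        assert s["pA"] == pytest.approx(100 * 2 / 4)  # s1 and the "none" call
        assert s["pB"] == pytest.approx(100 * 3 / 4)

    def test_always_present_caller_scores_modified_fraction(self):
        responses, key, _ = tiny_test()
        r = responses[responses["participant"] == "pB"].copy()
        r["present"] = True
        assert locate_success(r, key)["pB"] == pytest.approx(100 * 3 / 4)

    def test_subset_restriction(self):
        responses, key, _ = tiny_test()
        s = locate_success(responses, key, subset=["s1", "s2"])
        assert s["pA"] == 100.0

    def test_unanswered_participant_missing_not_zero(self):
        responses, key, _ = tiny_test()
        s = locate_success(responses, key, subset=["s2"])
        r2 = responses[~((responses.participant == "pA")
                         & (responses.specimen == "s2"))]
        s2 = locate_success(r2, key, subset=["s2"])
        assert "pA" not in s2.index
        assert "pA" in s.index


class TestCorrespondence:
    def test_both_correct_tally(self):
        responses, key, _ = tiny_test()
        # locating: both correct on s1, s2; pA wrong on s4, pB wrong on s3
        val = two_way_correspondence(responses, key, ("pA", "pB"), "locate")
        assert val == pytest.approx(100 * 2 / 4)
        # diagnosing: both correct only on s1
        val = two_way_correspondence(responses, key, ("pA", "pB"), "diagnose")
        assert val == pytest.approx(100 * 1 / 4)

    def test_perfect_pair(self):
        responses, key, _ = tiny_test()
        perfect = responses.copy()
        truth = key.set_index("specimen")["category"]
        perfect["present"] = perfect["specimen"].map(truth) != "none"
        perfect["diagnosis"] = perfect["specimen"].map(truth)
        for task in ("locate", "diagnose"):
            assert two_way_correspondence(perfect, key, ("pA", "pB"),
                                          task) == 100.0

    def test_denominator_is_jointly_answered(self):
        responses, key, _ = tiny_test()
        r = responses[~((responses.participant == "pA")
                        & (responses.specimen.isin(["s2", "s4"])))]
        # joint specimens: s1, s3 -> locating both correct on s1 only
        val = two_way_correspondence(r, key, ("pA", "pB"), "locate")
        assert val == pytest.approx(100 * 1 / 2)

    def test_correspondence_bounded_by_success(self, blind_test_data):
        responses, participants, key = blind_test_data
        for task, success_fn in (("locate", locate_success),
                                 ("diagnose", diagnose_success)):
            succ = success_fn(responses, key)
            tab = correspondence_table(responses, key, participants, task=task,
                                       within=None)
            for row in tab.itertuples():
                assert row.value <= min(succ[row.p1], succ[row.p2]) + 1e-9


class TestSubsets:
    def test_exclude_trampling(self, blind_test_data):
        _, _, key = blind_test_data
        subset = subset_excluding(key, "trampling")
        assert len(subset) == 36 - 7

    def test_exclude_absent_category_is_identity(self):
        _, key, _ = tiny_test()
        assert len(subset_excluding(key, "human-tooth")) == 4

    def test_complements_cover_key(self):
        _, key, _ = tiny_test()
        union = set()
        for cat in ("cut/scrape", "percussion", "human-tooth", "trampling",
                    "none"):
            union |= set(key["specimen"]) - set(subset_excluding(key, cat))
        assert union == set(key["specimen"])

    def test_subset_consistency(self, blind_test_data):
        # scores on the complement subset are unchanged by exclusion
        responses, _, key = blind_test_data
        subset = subset_excluding(key, "trampling")
        direct = locate_success(responses, key, subset=subset)
        r2 = responses[responses["specimen"].isin(subset)]
        again = locate_success(r2, key, subset=subset)
        pd.testing.assert_series_equal(direct, again)

    def test_unknown_category_rejected(self):
        _, key, _ = tiny_test()
        with pytest.raises(ValueError):
            subset_excluding(key, "gnawing")


class TestGroupComparisons:
    @staticmethod
    def _table3_as_corr(task, abrasion):
        rows = []
        for block in ("hand_lens", "microscope"):
            vals = table3_values(task, abrasion, block)
            for i, v in enumerate(vals):
                rows.append({"p1": f"{block}{i}a", "p2": f"{block}{i}b",
                             "group": block, "value": float(v)})
        return pd.DataFrame(rows)

    def test_instrument_comparison_on_published_table(self):
        res = instrument_comparison(self._table3_as_corr("locating", "included"))
        assert res.statistic == 12.0
        assert res.z == pytest.approx(-1.921, abs=5e-4)
        res = instrument_comparison(self._table3_as_corr("locating", "excluded"))
        assert res.statistic == 4.5
        assert res.z == pytest.approx(-2.740, abs=5e-4)

    def test_exclusion_effect_on_published_table(self):
        inc = self._table3_as_corr("diagnosing", "included")
        exc = self._table3_as_corr("diagnosing", "excluded")
        res = exclusion_effect(inc, exc, "hand_lens")
        assert res.statistic == 55.0
        assert res.z == pytest.approx(2.848, abs=5e-4)
        res = exclusion_effect(inc, exc, "microscope")
        assert res.statistic == 21.0
        assert res.z == pytest.approx(2.207, abs=5e-4)

    def test_exclusion_identity_degenerate(self):
        inc = self._table3_as_corr("locating", "included")
        res = exclusion_effect(inc, inc.copy(), "hand_lens")
        assert res.degenerate

    def test_pedagogy_comparison_on_published_table(self):
        t6 = load_fixture("table6")
        tab = pd.DataFrame({"p1": t6["pair"], "p2": t6["pair"] + "x",
                            "group": t6["group"],
                            "value": t6["value"].astype(float)})
        res = pedagogy_comparison(tab)
        assert res.statistic == 17.0
        assert res.z == pytest.approx(-1.367, abs=5e-4)

    def test_identical_groups_not_significant(self):
        vals = [50.0, 55, 60, 65]
        rows = ([{"p1": f"a{i}", "p2": f"b{i}", "group": "hand_lens", "value": v}
                 for i, v in enumerate(vals)]
                + [{"p1": f"c{i}", "p2": f"d{i}", "group": "microscope",
                    "value": v} for i, v in enumerate(vals)])
        res = instrument_comparison(pd.DataFrame(rows))
        assert res.p > 0.9

    def test_missing_group_rejected(self):
        rows = [{"p1": "a", "p2": "b", "group": "hand_lens", "value": 50.0}]
        with pytest.raises(ValueError):
            instrument_comparison(pd.DataFrame(rows))


class TestCorrelations:
    def test_two_participants_rejected(self):
        _, _, participants = tiny_test()
        success = pd.Series([40.0, 60.0], index=["pA", "pB"])
        with pytest.raises(ValueError):
            experience_correlation(success, participants)

    def test_experience_strictly_increasing(self, blind_test_data):
        responses, participants, key = blind_test_data
        succ = diagnose_success(responses, key)
        meta = participants.set_index("participant")
        rigged = pd.Series(np.argsort(np.argsort(
            meta.loc[succ.index, "years"].to_numpy())).astype(float),
            index=succ.index)
        tau, _ = experience_correlation(rigged, participants)
        assert tau == pytest.approx(1.0)

    def test_size_success_positive_when_detection_monotone(self, aquatic_marks):
        # construction: detection rises steeply through the size range and
        # diagnosis is near-faithful, so success must track mark size
        from taphomark.synthetic import (CATEGORIES, BlindTestSpec,
                                         _logistic_detection,
                                         simulate_blind_test)
        steep = _logistic_detection(0.02, 0.98,
                                    float(np.log(aquatic_marks
                                                 ["max_dimension_um"]).median()),
                                    k=8.0)
        confusion = {c: {k: (0.9 if k == c else 0.025) for k in CATEGORIES}
                     for c in CATEGORIES[:4]}
        spec = BlindTestSpec(
            detection={"hand_lens": steep, "microscope": steep},
            confusion=confusion, n_skipped=0, seed=2)
        responses, _, key = simulate_blind_test(spec, aquatic_marks)
        tau, p, dropped = size_success_correlation(responses, key)
        assert dropped == 0
        assert tau > 0
        assert p < 0.05

    def test_size_success_null_calibration(self, aquatic_marks):
        from taphomark.synthetic import BlindTestSpec, simulate_blind_test
        taus = []
        flat = {"hand_lens": lambda s: 0.6, "microscope": lambda s: 0.6}
        for rep in range(30):
            spec = BlindTestSpec(seed=1000 + rep, detection=flat)
            responses, _, key = simulate_blind_test(spec, aquatic_marks)
            try:
                tau, _, _ = size_success_correlation(responses, key)
                taus.append(tau)
            except ValueError:
                pass
        assert abs(np.mean(taus)) < 0.15

    def test_confidence_success_trivial_directions(self):
        key = pd.DataFrame({"specimen": [f"s{i}" for i in range(5)],
                            "category": ["cut/scrape", "percussion",
                                         "human-tooth", "trampling", "none"]})
        rows = []
        for i, (cat, conf, correct) in enumerate(zip(
                key["category"], [1, 2, 3, 4, 5], [False, False, True, True, True])):
            diagnosis = cat if correct else "none"
            present = cat != "none" if correct else not (cat != "none")
            rows.append(("p1", f"s{i}", bool(present), diagnosis, conf))
        responses = pd.DataFrame(rows, columns=["participant", "specimen",
                                                "present", "diagnosis",
                                                "confidence"])
        tau, _ = confidence_success_correlation(responses, key)
        assert tau > 0
        anti = responses.assign(confidence=[5, 4, 3, 2, 1])
        tau2, _ = confidence_success_correlation(anti, key)
        assert tau2 == pytest.approx(-tau)

    def test_five_points_one_swap(self):
        # {1..5} vs {1,2,4,3,5}: 9 concordant, 1 discordant -> tau = 0.8
        tau, p = kendall_tau([1, 2, 3, 4, 5], [1, 2, 4, 3, 5])
        assert tau == pytest.approx(0.8)
        assert p == pytest.approx(0.050, abs=0.005)


class TestFixtureTables:
    def test_table4_diagnosing_column(self):
        t4 = load_fixture("table4")
        dia = t4.loc[t4["task"] == "diagnosing", "score"].tolist()
        assert dia == [44, 42, 39, 47, 36]

    def test_table6_tt1_column(self):
        t6 = load_fixture("table6")
        assert t6.loc[t6["group"] == "TT1", "value"].tolist() == \
            [33, 30, 30, 25, 22, 22]

    def test_table3_block_sizes(self):
        for task in ("locating", "diagnosing"):
            for abrasion in ("included", "excluded"):
                assert len(table3_values(task, abrasion, "hand_lens")) == 10
                assert len(table3_values(task, abrasion, "microscope")) == 6
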