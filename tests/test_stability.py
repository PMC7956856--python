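"""Reference shortlist, M-value exclusion and normalization, checked
against exhaustive brute-force oracles."""

import statistics

import numpy as np
import pandas as pd
import pytest

from proteokinetics.io import ratio_to_baseline
from proteokinetics.simulate import simulate, stable_pool_config
from proteokinetics.stability import (
    CandidateShortlist,
    iterate_exclusion,
    m_value,
    normalize,
    shortlist_candidates,
)

from conftest import random_ratio_matrix


# -- independent brute-force oracle (pure-python, no shared code path) --

def brute_m(candidate, candidates, logratios):
    sds = []
    for other in candidates:
        if other == candidate:
            continue
        diffs = [
            logratios.loc[candidate, s] - logratios.loc[other, s]
            for s in logratios.columns
        ]
        sds.append(statistics.stdev(diffs))
    return statistics.mean(sds)


def brute_exclusion(candidates, logratios, stop_size):
    current = list(candidates)
    order = []
    while len(current) > stop_size:
        ms = {c: brute_m(c, current, logratios) for c in current}
        worst = max(current, key=lambda c: (ms[c], c))
        order.append(worst)
        current.remove(worst)
    return order, current


class TestShortlist:
    def test_only_fully_detected_proteins_eligible(self):
        rng = np.random.default_rng(0)
        r = random_ratio_matrix(rng, 12, 6)
        r.iloc[0, 0] = np.nan
        r.iloc[1, 3] = np.nan
        sl = shortlist_candidates(r, k=10)
        assert len(sl) == 10
        assert r.index[0] not in sl.protein_ids
        assert r.index[1] not in sl.protein_ids
        assert list(sl.cv_values) == sorted(sl.cv_values)

    def test_zero_noise_protein_ranked_first(self):
        rng = np.random.default_rng(1)
        r = random_ratio_matrix(rng, 10, 6)
        r.loc["CONST"] = 1.0
        sl = shortlist_candidates(r, k=5)
        assert sl.protein_ids[0] == "CONST"
        assert sl.cv_values[0] == pytest.approx(0.0, abs=1e-15)

    def test_tie_broken_by_protein_id(self):
        rng = np.random.default_rng(2)
        r = random_ratio_matrix(rng, 6, 5)
        r.loc["ZZB"] = r.iloc[0].to_numpy()  # duplicate profile of row 0
        r.loc["AAB"] = r.iloc[0].to_numpy()
        sl = shortlist_candidates(r, k=8)
        ids = list(sl.protein_ids)
        assert ids.index("AAB") < ids.index("ZZB")

    def test_too_few_candidates_reports_attainable_count(self):
        rng = np.random.default_rng(3)
        r = random_ratio_matrix(rng, 5, 4)
        r.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="4"):
            shortlist_candidates(r, k=5)


class TestMValue:
    def test_identical_profiles_give_zero(self):
        r = pd.DataFrame(
            {"s1": [1.0, 1.0], "s2": [2.0, 2.0], "s3": [0.5, 0.5]},
            index=["A", "B"],
        )
        assert m_value("A", {"B"}, np.log2(r)) == pytest.approx(0.0)

    def test_matches_brute_force_on_hand_listed_values(self):
        rng = np.random.default_rng(5)
        logr = pd.DataFrame(
            rng.normal(0, 1, size=(3, 4)),
            index=["A", "B", "C"],
            columns=list("wxyz"),
        )
        for c in "ABC":
            assert m_value(c, {"A", "B", "C"}, logr) == pytest.approx(
                brute_m(c, ["A", "B", "C"], logr), abs=1e-12
            )

    def test_shift_invariance(self):
        rng = np.random.default_rng(6)
        logr = pd.DataFrame(
            rng.normal(0, 1, size=(3, 5)), index=["A", "B", "C"]
        )
        before = [m_value(c, {"A", "B", "C"}, logr) for c in "ABC"]
        logr.loc["B"] += 3.7  # constant offset in log space
        after = [m_value(c, {"A", "B", "C"}, logr) for c in "ABC"]
        np.testing.assert_allclose(before, after, atol=1e-12)

    def test_needs_a_partner(self):
        logr = pd.DataFrame({"s": [1.0]}, index=["A"])
        with pytest.raises(ValueError):
            m_value("A", {"A"}, logr)

    def test_masked_cells_rejected(self):
        logr = pd.DataFrame(
            {"s1": [1.0, np.nan], "s2": [2.0, 1.0]}, index=["A", "B"]
        )
        with pytest.raises(ValueError, match="masked"):
            m_value("A", {"B"}, logr)


class TestIterateExclusion:
    def test_counting_and_conservation(self):
        rng = np.random.default_rng(7)
        r = random_ratio_matrix(rng, 10, 6)
        sl = shortlist_candidates(r, k=10)
        rep = iterate_exclusion(sl, r, stop_size=2)
        assert len(rep.exclusion_order) == 8
        assert len(rep.iterations) == 8
        assert len(rep.reference_set) == 2
        # each iteration's set is the previous minus its excluded member
        for i in range(1, len(rep.iterations)):
            prev = set(rep.iterations[i - 1].index)
            cur = set(rep.iterations[i].index)
            assert cur == prev - {rep.exclusion_order[i - 1]}

    def test_single_iteration_for_size_3_stop_2(self):
        rng = np.random.default_rng(8)
        r = random_ratio_matrix(rng, 3, 5)
        sl = shortlist_candidates(r, k=3)
        rep = iterate_exclusion(sl, r, stop_size=2)
        assert len(rep.iterations) == 1

    def test_zero_noise_references_recovered(self):
        # 2 exactly constant proteins among 8 noisy: must win for any seed
        for seed in range(5):
            rng = np.random.default_rng(seed)
            r = random_ratio_matrix(rng, 8, 7)
            r.loc["REFA"] = 1.0
            r.loc["REFB"] = 2.0
            sl = shortlist_candidates(r, k=10)
            rep = iterate_exclusion(sl, r, stop_size=2)
            assert set(rep.reference_set) == {"REFA", "REFB"}

    def test_m_ranking_invariant_to_log_base(self):
        rng = np.random.default_rng(9)
        r = random_ratio_matrix(rng, 6, 5)
        ids = list(r.index)
        m2 = {c: m_value(c, ids, np.log2(r)) for c in ids}
        mn = {c: m_value(c, ids, np.log(r)) for c in ids}
        assert sorted(ids, key=m2.get) == sorted(ids, key=mn.get)
        ratio = np.array([mn[c] / m2[c] for c in ids])
        np.testing.assert_allclose(ratio, np.log(2), rtol=1e-9)

    def test_oracle_equivalence_small_sets(self):
        # exhaustive brute force on random 5-sample matrices
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n = int(rng.integers(4, 7))
            r = random_ratio_matrix(rng, n, 5)
            sl = shortlist_candidates(r, k=n)
            rep = iterate_exclusion(sl, r, stop_size=2)
            logr = np.log2(r)
            for c in sl.protein_ids:
                assert m_value(c, set(sl.protein_ids), logr) == pytest.approx(
                    brute_m(c, list(sl.protein_ids), logr), abs=1e-12
                )
            order, final = brute_exclusion(sl.protein_ids, logr, 2)
            assert rep.exclusion_order == order
            assert set(rep.reference_set) == set(final)


class TestNormalize:
    def test_unit_references_leave_log_ratio(self):
        r = pd.DataFrame(
            {"s1": [3.0, 1.0, 1.0], "s2": [0.5, 1.0, 1.0]},
            index=["P", "R1", "R2"],
        )
        nm = normalize(r, ["R1", "R2"])
        assert nm.loc["P", "s1"] == pytest.approx(np.log10(3.0))
        assert nm.loc["P", "s2"] == pytest.approx(np.log10(0.5))

    def test_geometric_mean_hand_case(self):
        # refs at 2 and 0.5 -> geomean 1 -> value log10(2)
        r = pd.DataFrame(
            {"s1": [2.0, 2.0, 0.5]}, index=["P", "R1", "R2"]
        )
        nm = normalize(r, ["R1", "R2"])
        assert nm.loc["P", "s1"] == pytest.approx(np.log10(2.0), abs=1e-12)

    def test_reference_log_values_center_to_zero(self):
        rng = np.random.default_rng(10)
        r = random_ratio_matrix(rng, 6, 7)
        refs = list(r.index[:2])
        nm = normalize(r, refs)
        np.testing.assert_allclose(
            nm.loc[refs].mean(axis=0).to_numpy(), 0.0, atol=1e-12
        )

    def test_column_scaling_invariance(self):
        rng = np.random.default_rng(11)
        r = random_ratio_matrix(rng, 8, 6)
        refs = list(r.index[:3])
        nm1 = normalize(r, refs)
        r2 = r.copy()
        r2.iloc[:, 2] *= 13.7
        nm2 = normalize(r2, refs)
        pd.testing.assert_frame_equal(nm1, nm2, atol=1e-12, rtol=0)

    def test_arithmetic_mean_option_differs(self):
        rng = np.random.default_rng(12)
        r = random_ratio_matrix(rng, 5, 4)
        refs = list(r.index[:2])
        g = normalize(r, refs, ref_mean="geometric")
        a = normalize(r, refs, ref_mean="arithmetic")
        assert not np.allclose(g.to_numpy(), a.to_numpy())

    def test_masked_source_stays_masked(self):
        r = pd.DataFrame(
            {"s1": [np.nan, 1.0, 1.0], "s2": [2.0, 1.0, 1.0]},
            index=["P", "R1", "R2"],
        )
        nm = normalize(r, ["R1", "R2"])
        assert np.isnan(nm.loc["P", "s1"]) and np.isfinite(nm.loc["P", "s2"])

    def test_empty_or_masked_reference_rejected(self):
        r = pd.DataFrame({"s1": [1.0, np.nan]}, index=["A", "B"])
        with pytest.raises(ValueError):
            normalize(r, [])
        with pytest.raises(ValueError):
            normalize(r, ["B"])


class TestReferenceRecovery:
    def test_planted_ultra_stable_pair_recovered(self):
        # smaller rehearsal of the seeded benchmark (full run lives in
        # the acceptance suite)
        hits = 0
        for seed in range(20):
            cfg = stable_pool_config(n_noisy=8, seed=seed)
            intens, truth, _ = simulate(cfg)
            ratios, _ = ratio_to_baseline(intens, cfg.design)
            sl = shortlist_candidates(ratios, k=10)
            rep = iterate_exclusion(sl, ratios, stop_size=2)
            hits += set(rep.reference_set) == set(truth.ultra_stable)
        assert hits >= 19
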