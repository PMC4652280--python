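import numpy as np
import pytest
from scipy import stats

from macscreen.allele_content import (
    all_content_scores,
    build_hac_set,
    build_mac2_set,
    build_minor_allele_set,
    compute_allele_frequencies,
    compute_content,
    content_scores,
    maf_departure_test,
)
from macscreen.panel_io import MISSING, P1, P2

from conftest import make_panel


class TestAlleleFrequencies:
    @pytest.mark.parametrize(
        "column, maf, minor, informative",
        [
            ([P1, P1, P2, P2], 0.5, None, False),   # exact tie: excluded
            ([P2, P2, P2, P2], 0.0, None, False),   # monomorphic
            ([P1, P2, P2, P2], 0.25, "P1", True),
        ],
    )
    def test_single_marker_cases(self, column, maf, minor, informative):
        freqs = compute_allele_frequencies(make_panel([[c] for c in column]))
        row = freqs.iloc[0]
        assert row["maf"] == maf
        assert row["minor_allele"] == minor
        assert bool(row["informative"]) is informative

    def test_missing_calls_shrink_the_denominator(self):
        # hand count: 6 strains, one missing -> n=5, one P1 among 5
        panel = make_panel([[c] for c in [P1, P2, P2, P2, MISSING, P2]])
        row = compute_allele_frequencies(panel).iloc[0]
        assert row["n_nonmissing"] == 5
        assert row["maf"] == pytest.approx(1 / 5)
        assert row["minor_allele"] == "P1"

    def test_all_missing_marker_flagged_uninformative(self):
        panel = make_panel([[MISSING], [MISSING]])
        row = compute_allele_frequencies(panel).iloc[0]
        assert np.isnan(row["maf"]) and not row["informative"]

    def test_frequencies_invariant_under_strain_duplication(self, toy_panel):
        doubled = make_panel(np.vstack([toy_panel.calls, toy_panel.calls]))
        a = compute_allele_frequencies(toy_panel)
        b = compute_allele_frequencies(doubled)
        assert build_minor_allele_set(a) == build_minor_allele_set(b)
        np.testing.assert_allclose(a["maf"], b["maf"])


class TestMafDepartureTest:
    def test_skewed_count_is_significant_and_matches_binomial_oracle(self):
        # 59 minor alleles among 237 strains: far from an even split
        p_chi = maf_departure_test(59, 237)
        p_exact = stats.binomtest(59, 237, 0.5).pvalue
        assert p_chi < 0.05 and p_exact < 0.05
        assert np.isclose(p_chi, maf_departure_test(59, 237), rtol=0)
        # chi-square approximation tracks the exact tail at this n
        assert abs(np.log10(p_chi) - np.log10(p_exact)) < 1.0

    def test_near_even_split_not_significant(self):
        assert maf_departure_test(118, 237) > 0.9

    def test_threshold_scan_at_panel_size(self):
        # brute force over every possible minor count at n=237: the largest
        # count still significant at 0.05 defines the MAC2 marker rule
        sig = [k for k in range(119) if maf_departure_test(k, 237) < 0.05]
        assert max(sig) == 103
        assert all(maf_departure_test(k, 237) >= 0.05 for k in range(104, 119))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            maf_departure_test(0, 0)
        with pytest.raises(ValueError):
            maf_departure_test(5, 8)  # 5 of 8 is not a minor count


class TestAlleleSets:
    def test_all_ties_give_empty_set(self):
        panel = make_panel([[P1, P1], [P1, P2], [P2, P1], [P2, P2]])
        assert build_minor_allele_set(compute_allele_frequencies(panel)) == {}

    def test_minor_allele_set_from_hand_example(self):
        panel = make_panel([[c] for c in [P1, P2, P2, P2, MISSING, P2]])
        assert build_minor_allele_set(compute_allele_frequencies(panel)) == {
            "mk1": P1
        }

    def test_mac2_alpha_limits(self, rng):
        calls = (rng.random((40, 30)) < 0.3).astype(np.int8)
        freqs = compute_allele_frequencies(make_panel(calls))
        ma = build_minor_allele_set(freqs)
        assert build_mac2_set(freqs, alpha=1.0) == ma  # ties already excluded
        assert build_mac2_set(freqs, alpha=0.0) == {}

    def test_mac2_subset_of_ma_set_on_skewed_panel(self, rng):
        calls = (rng.random((237, 200)) < rng.uniform(0.3, 0.5, 200)).astype(np.int8)
        freqs = compute_allele_frequencies(make_panel(calls))
        ma = build_minor_allele_set(freqs)
        mac2 = build_mac2_set(freqs)
        assert set(mac2) <= set(ma)
        assert len(mac2) < len(ma)
        # spot-check membership against the departure test directly
        for marker in list(ma)[:20]:
            row = freqs.loc[marker]
            k = int(min(row["count_p1"], row["count_p2"]))
            expected = maf_departure_test(k, int(row["n_nonmissing"])) < 0.05
            assert (marker in mac2) == expected


class TestContentScores:
    def test_extreme_strains(self):
        # strain 1 matches no minor allele, strain 4 matches all of them
        panel = make_panel(
            [
                [P2, P2, P2],
                [P2, P2, P2],
                [P2, P1, P2],
                [P1, P1, P1],
            ]
        )
        freqs = compute_allele_frequencies(panel)
        scores = compute_content(panel, build_minor_allele_set(freqs), "MAC")
        assert scores.loc[0, "score"] == 0.0
        assert scores.loc[3, "score"] == 1.0

    def test_scores_match_per_cell_hand_count(self, toy_panel):
        freqs = compute_allele_frequencies(toy_panel)
        aset = build_minor_allele_set(freqs)
        scores = compute_content(toy_panel, aset, "MAC")
        for i in range(toy_panel.n_strains):
            num = den = 0
            for marker, allele in aset.items():
                call = toy_panel.calls[i, toy_panel.marker_index(marker)]
                if call != MISSING:
                    den += 1
                    num += int(call == allele)
            assert scores.loc[i, "numerator"] == num
            assert scores.loc[i, "denominator"] == den
            assert scores.loc[i, "score"] == pytest.approx(num / den)

    def test_hac_plus_p1_content_is_one_without_missing(self, rng):
        calls = (rng.random((30, 50)) < 0.4).astype(np.int8)
        panel = make_panel(calls)
        freqs = compute_allele_frequencies(panel)
        hac_set = build_hac_set(freqs)
        hac = compute_content(panel, hac_set, "HAC")["score"]
        p1_set = {m: P1 for m in hac_set}
        p1c = compute_content(panel, p1_set, "P1C")["score"]
        np.testing.assert_allclose(hac + p1c, 1.0)

    def test_strain_with_no_calls_over_set_is_flagged(self):
        panel = make_panel([[P1, P1], [P2, P2], [MISSING, MISSING]])
        freqs = compute_allele_frequencies(panel)
        scores = compute_content(panel, build_minor_allele_set(freqs), "MAC")
        assert not scores.loc[2, "defined"]
        assert np.isnan(scores.loc[2, "score"])

    def test_mac_invariant_under_duplication_and_changes_with_new_strain(self):
        base = [[P1, P2, P2], [P2, P2, P1], [P2, P1, P2], [P2, P2, P2]]
        panel = make_panel(base)
        doubled = make_panel(base + base)
        a = content_scores(panel, "mac")["score"].to_numpy()
        b = content_scores(doubled, "mac")["score"].to_numpy()
        np.testing.assert_allclose(np.concatenate([a, a]), b)
        # adding a strain changes frequencies; recompute oracle from scratch
        grown = make_panel(base + [[P1, P1, P1]])
        c = content_scores(grown, "mac")
        freqs = compute_allele_frequencies(grown)
        aset = build_minor_allele_set(freqs)
        expected = compute_content(grown, aset, "MAC")["score"]
        np.testing.assert_allclose(c["score"], expected)

    def test_mean_mac_tracks_mean_maf_on_symmetric_panel(self, rng):
        # with no selection skew, strains and markers are exchangeable draws:
        # E[MAC] over strains equals E[MAF] over markers up to Monte Carlo error
        calls = (rng.random((400, 300)) < 0.5).astype(np.int8)
        panel = make_panel(calls)
        freqs = compute_allele_frequencies(panel)
        inf = freqs[freqs["informative"]]
        mac = content_scores(panel, "mac")["score"]
        assert abs(mac.mean() - inf["maf"].mean()) < 0.01

    def test_all_content_scores_wide_table(self, toy_panel):
        wide = all_content_scores(toy_panel)
        assert {"mac", "mac2", "hac"} <= set(wide.columns)
        assert len(wide) == toy_panel.n_strains
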