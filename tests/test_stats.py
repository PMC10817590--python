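import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from oculotex.constants import FEATURES
from oculotex.errors import ConfigurationError, DataError
from oculotex.stats import (CorrelationSet, benjamini_hochberg, bonferroni,
                            normality_gate, paired_test,
                            pairwise_correlations, run_group_analysis,
                            select_uncorrelated, storey)


def frame(cols: dict) -> pd.DataFrame:
    return pd.DataFrame(cols, index=[f"P{i}" for i in
                                     range(len(next(iter(cols.values()))))])


# ---------------------------------------------------------------------------
# Correlation filter
# ---------------------------------------------------------------------------

class TestPairwiseCorrelations:
    def test_duplicated_feature_is_correlated(self, rng):
        x = rng.random(20)
        od = frame({"RNFL/Q1/Entropy": x, "RNFL/Q1/Energy": x.copy()})
        corr = pairwise_correlations(od, od.copy())
        assert corr.correlated[0, 1]
        rec = corr.records()
        assert rec.iloc[0]["r_od"] == pytest.approx(1.0)

    def test_negated_feature_is_correlated(self, rng):
        x = rng.random(20)
        od = frame({"RNFL/Q1/Entropy": x, "RNFL/Q1/Energy": -x})
        corr = pairwise_correlations(od, od.copy())
        assert corr.correlated[0, 1]
        assert corr.records().iloc[0]["r_od"] == pytest.approx(-1.0)

    def test_both_eyes_rule(self, rng):
        x = rng.random(30)
        od = frame({"A/Q1/Entropy": x, "A/Q1/Energy": x + 0.001 * rng.random(30)})
        os_ = frame({"A/Q1/Entropy": rng.random(30),
                     "A/Q1/Energy": rng.random(30)})
        corr = pairwise_correlations(od, os_)
        assert abs(corr.r_od[0, 1]) >= 0.5
        assert not corr.correlated[0, 1]  # OS decorrelates the pair

    def test_independent_features_not_correlated(self, rng):
        od = frame({f"A/Q1/{f}": rng.standard_normal(49)
                    for f in ("Entropy", "Energy", "Contrast")})
        os_ = frame({c: rng.standard_normal(49) for c in od.columns})
        corr = pairwise_correlations(od, os_)
        assert not corr.correlated.any()

    def test_constant_feature_flagged_not_correlated(self, rng):
        od = frame({"A/Q1/Entropy": np.ones(10),
                    "A/Q1/Energy": rng.random(10)})
        corr = pairwise_correlations(od, od.copy())
        assert "A/Q1/Entropy" in corr.undefined
        assert not corr.correlated.any()

    def test_missing_values_rejected(self, rng):
        od = frame({"A/Q1/Entropy": rng.random(10)})
        od.iloc[0, 0] = np.nan
        with pytest.raises(DataError):
            pairwise_correlations(od, od.copy())


def make_corrset(ids, pairs):
    """CorrelationSet from a dict {(i, j): (r_od, r_os)}."""
    m = len(ids)
    r_od, r_os = np.eye(m), np.eye(m)
    for (i, j), (a, b) in pairs.items():
        r_od[i, j] = r_od[j, i] = a
        r_os[i, j] = r_os[j, i] = b
    correlated = (np.abs(r_od) >= 0.5) & (np.abs(r_os) >= 0.5)
    np.fill_diagonal(correlated, False)
    return CorrelationSet(feature_ids=ids, r_od=r_od, r_os=r_os,
                          correlated=correlated, threshold=0.5)


IDS3 = ["RNFL/Q1/Entropy", "RNFL/Q1/Energy", "RNFL/Q1/Contrast"]  # A, B, C


class TestSelection:
    def test_hand_traced_triple(self):
        # (A,B) strongly correlated, (A,C) correlated, (B,C) not:
        # n(A)=2 > n(B)=n(C)=1, so A is kept and discards both.
        corr = make_corrset(IDS3, {(0, 1): (0.9, 0.9), (0, 2): (0.6, 0.7),
                                   (1, 2): (0.1, 0.1)})
        sel = select_uncorrelated(corr)
        assert sel.kept == [IDS3[0]]
        assert set(sel.discarded) == {IDS3[1], IDS3[2]}
        assert sel.discarded[IDS3[1]] == IDS3[0]
        assert sel.n_correlations[IDS3[0]] == 2

    def test_no_correlated_pairs_keeps_everything(self):
        corr = make_corrset(IDS3, {})
        sel = select_uncorrelated(corr)
        assert sel.kept == IDS3 and not sel.discarded

    def test_single_eye_correlation_keeps_both(self):
        corr = make_corrset(IDS3[:2], {(0, 1): (0.9, 0.1)})
        sel = select_uncorrelated(corr)
        assert sel.kept == IDS3[:2]

    def test_ev_sum_breaks_ties(self):
        # B and C both have n=1 via A... make a 4-cycle: (A,B), (C,D),
        # where the (C,D) link is stronger; every feature has n=1, ev
        # decides who keeps within each pair; ordering is deterministic.
        ids = IDS3 + ["RNFL/Q1/Dissimilarity"]
        corr = make_corrset(ids, {(0, 1): (0.6, 0.6), (2, 3): (0.9, 0.9)})
        sel = select_uncorrelated(corr)
        # each pair contributes exactly one keeper
        assert len(sel.kept) == 2
        assert (ids[0] in sel.kept) != (ids[1] in sel.kept)
        assert (ids[2] in sel.kept) != (ids[3] in sel.kept)

    def test_kept_set_pairwise_uncorrelated_on_random_structures(self, rng):
        feats = [f"RNFL/Q1/{f}" for f in FEATURES]
        for _ in range(20):
            m = len(feats)
            a = rng.uniform(-1, 1, (m, m))
            r_od = (a + a.T) / 2
            b = rng.uniform(-1, 1, (m, m))
            r_os = (b + b.T) / 2
            np.fill_diagonal(r_od, 1.0)
            np.fill_diagonal(r_os, 1.0)
            correlated = (np.abs(r_od) >= 0.5) & (np.abs(r_os) >= 0.5)
            np.fill_diagonal(correlated, False)
            corr = CorrelationSet(feature_ids=feats, r_od=r_od, r_os=r_os,
                                  correlated=correlated, threshold=0.5)
            for recompute in (False, True):
                sel = select_uncorrelated(corr, recompute_after_discard=recompute)
                kept_idx = [feats.index(f) for f in sel.kept]
                assert not correlated[np.ix_(kept_idx, kept_idx)].any()
                assert set(sel.kept) | set(sel.discarded) == set(feats)


# ---------------------------------------------------------------------------
# Normality gate and paired tests
# ---------------------------------------------------------------------------

class TestNormalityGate:
    def test_normal_samples_pass_at_ten_percent(self, rng):
        od = rng.standard_normal(49)
        os_ = rng.standard_normal(49)
        assert normality_gate(od, os_) == (True, True)

    def test_exponential_samples_fail(self, rng):
        od = rng.exponential(1.0, 49)
        os_ = rng.exponential(1.0, 49)
        assert normality_gate(od, os_) == (False, False)

    def test_undersized_sample_rejected(self):
        with pytest.raises(DataError):
            normality_gate([1.0, 2.0], [1.0, 2.0])


class TestPairedTest:
    def test_identical_samples_degenerate(self, rng):
        x = rng.random(20)
        res = paired_test(x, x.copy(), (True, True))
        assert res.degenerate and res.p == 1.0

    def test_swap_symmetry(self, rng):
        od = rng.standard_normal(30)
        os_ = od + 0.4 + rng.standard_normal(30)
        for gate in ((True, True), (False, True)):
            a = paired_test(od, os_, gate)
            b = paired_test(os_, od, gate)
            assert a.p == pytest.approx(b.p, rel=1e-12)
            assert a.statistic == pytest.approx(
                -b.statistic if a.test == "paired-t" else b.statistic, rel=1e-9)

    def test_gate_routes_to_t_or_wilcoxon(self, rng):
        od, os_ = rng.standard_normal(30), rng.standard_normal(30)
        assert paired_test(od, os_, (True, True)).test == "paired-t"
        assert paired_test(od, os_, (True, False)).test == "wilcoxon"

    def test_paired_t_matches_closed_form(self, rng):
        """Shifted sample: scipy's paired t equals the textbook statistic
    d_bar / (s_d / sqrt(n)) with a Student-t two-sided p."""
        od = rng.standard_normal(49) + 1.0
        os_ = rng.standard_normal(49)
        res = paired_test(od, os_, (True, True))
        d = od - os_
        t_stat = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p = 2 * sps.t.sf(abs(t_stat), len(d) - 1)
        assert res.p < 0.05
        assert res.statistic == pytest.approx(t_stat, abs=1e-10)
        assert res.p == pytest.approx(p, abs=1e-8)

    def test_wilcoxon_detects_shift(self, rng):
        od = rng.standard_normal(49) + 1.0
        os_ = rng.standard_normal(49)
        res = paired_test(od, os_, (False, False))
        assert res.test == "wilcoxon" and res.p < 0.05

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(DataError):
            paired_test(rng.random(5), rng.random(6), (True, True))


# ---------------------------------------------------------------------------
# Corrections
# ---------------------------------------------------------------------------

class TestBonferroni:
    def test_single_test_is_identity(self):
        res = bonferroni([0.03], alpha=0.05)
        assert res.significant[0]
        assert res.adjusted[0] == pytest.approx(0.03)

    def test_large_family_threshold(self):
        # alpha/m = 0.05/146 ~ 3.42e-4
        p = [0.04] + [0.5] * 145
        res = bonferroni(p, alpha=0.05)
        assert not res.significant.any()
        p[0] = 3e-4
        assert bonferroni(p, alpha=0.05).significant[0]

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(DataError):
            bonferroni([0.5, 1.2])


class TestBenjaminiHochberg:
    def test_step_up_example(self):
        res = benjamini_hochberg([0.001, 0.013, 0.04], alpha=0.05)
        assert res.significant.all()  # 0.04 < 3 * 0.05 / 3

    def test_all_ones_nothing_significant(self):
        res = benjamini_hochberg([1.0, 1.0, 1.0])
        assert not res.significant.any()

    def test_matches_sorted_rule_on_random_vectors(self, rng):
        """Step-up selection equals the rule `largest k with
    p_(k) < k*alpha/m` applied literally to the sorted p-values."""
        for _ in range(50):
            m = int(rng.integers(1, 40))
            p = rng.random(m) ** rng.uniform(0.5, 3)
            res = benjamini_hochberg(p, alpha=0.05)
            sp = np.sort(p)
            k = 0
            for i in range(m, 0, -1):
                if sp[i - 1] < i * 0.05 / m:
                    k = i
                    break
            assert res.significant.sum() == k
            if k:
                assert np.all(np.sort(p[res.significant]) == sp[:k])

    def test_adjusted_match_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(25)
        res = benjamini_hochberg(p)
        np.testing.assert_allclose(
            res.adjusted, multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_bonferroni_subset_of_bh(self, rng):
        for _ in range(30):
            p = rng.random(int(rng.integers(1, 60))) ** 2
            bon = bonferroni(p).significant
            bh = benjamini_hochberg(p).significant
            assert np.all(bh[bon])


class TestStorey:
    def test_pi0_direct_count(self):
        res = storey([0.01, 0.2, 0.6, 0.8], lam=0.5)
        assert res.pi0 == pytest.approx(2 / (4 * 0.5))

    def test_lambda_zero_reduces_to_bh(self, rng):
        p = rng.random(30)
        q = storey(p, lam=0.0)
        bh = benjamini_hochberg(p)
        np.testing.assert_allclose(q.adjusted, bh.adjusted, atol=1e-12)
        assert q.pi0 == 1.0

    def test_qvalues_monotone_in_p(self, rng):
        p = rng.random(50)
        res = storey(p)
        order = np.argsort(p)
        assert np.all(np.diff(res.adjusted[order]) >= -1e-15)

    def test_fdr_estimate_formula(self):
        p = [0.01, 0.02, 0.2, 0.6, 0.9]
        res = storey(p, lam=0.5, t=0.05)
        pi0 = 2 / (5 * 0.5)  # two of the five p-values exceed lambda
        assert res.fdr_estimate == pytest.approx(min(1.0, pi0 * 5 * 0.05 / 2))

    def test_invalid_lambda_rejected(self):
        with pytest.raises(ConfigurationError):
            storey([0.5], lam=1.0)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_qvalues_within_unit_interval(self, pvals):
        res = storey(np.asarray(pvals))
        assert np.all((res.adjusted >= 0) & (res.adjusted <= 1))


# ---------------------------------------------------------------------------
# Group analysis
# ---------------------------------------------------------------------------

def synthetic_feature_table(rng, n=12, delta=0.0):
    """Small tidy table: 2 layers x 4 quadrants x 3 features, both sexes.
    ``delta`` shifts RNFL/Q1/Entropy in female OS eyes."""
    rows = []
    for sex in ("female", "male"):
        for i in range(n):
            pid = f"{sex[0].upper()}{i:02d}"
            for eye in ("OD", "OS"):
                for layer in ("RNFL", "IPL"):
                    for quad in ("Q1", "Q2", "Q3", "Q4"):
                        for feat in ("Entropy", "Energy", "Contrast"):
                            val = rng.standard_normal()
                            if (sex == "female" and eye == "OS"
                                    and layer == "RNFL" and quad == "Q1"
                                    and feat == "Entropy"):
                                val += delta
                            rows.append(dict(participant_id=pid, sex=sex,
                                             age=40.0, eye=eye, layer=layer,
                                             quadrant=quad, feature=feat,
                                             value=val))
    return pd.DataFrame(rows)


class TestGroupAnalysis:
    def test_grid_covers_all_features_with_valid_states(self, rng):
        table = synthetic_feature_table(rng)
        ga = run_group_analysis(table, "female")
        assert ga.grid.size == 24  # 3 features x 2 layers x 4 quadrants
        states = {str(s).split(":")[0] for s in ga.grid.to_numpy().ravel()}
        assert states <= {"correlated-out", "non-significant",
                          "significant-uncorrected", "significant-corrected"}
        assert ga.counts["n_features"] == 24

    def test_identical_groups_give_identical_results(self, rng):
        table = synthetic_feature_table(rng)
        male = table[table.sex == "female"].copy()
        male["sex"] = "male"
        male["participant_id"] = male["participant_id"].str.replace("F", "M")
        both = pd.concat([table[table.sex == "female"], male])
        ga_f = run_group_analysis(both, "female")
        ga_m = run_group_analysis(both, "male")
        pd.testing.assert_frame_equal(
            ga_f.tests.reset_index(drop=True),
            ga_m.tests.reset_index(drop=True))
        assert ga_f.counts["storey"] == ga_m.counts["storey"]

    def test_strong_shift_detected_in_target_group_only(self, rng):
        table = synthetic_feature_table(rng, n=30, delta=3.0)
        ga_f = run_group_analysis(table, "female")
        ga_m = run_group_analysis(table, "male")
        sig_f = [f for f, s in zip(ga_f.selection.kept,
                                   ga_f.corrections["storey"].significant) if s]
        assert "RNFL/Q1/Entropy" in sig_f
        assert not any(r.significant.any() for r in ga_m.corrections.values())

    def test_unpaired_participants_rejected(self, rng):
        table = synthetic_feature_table(rng)
        broken = table[~((table.participant_id == "F00") & (table.eye == "OS"))]
        with pytest.raises(DataError):
            run_group_analysis(broken, "female")
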