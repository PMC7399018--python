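import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nirsretest import (frequency_map, group_betas, pair_scores, physio_change,
                        subject_repro, summarize_medians,
                        variability_regression)
from nirsretest.datasets import reference_subject_scores
from nirsretest.glm import ActivationVector, GLMChannelResult


def _vec(values, session="s"):
    values = np.asarray(values, dtype=int)
    return ActivationVector(session=session,
                            channel_ids=np.arange(len(values)),
                            values=values)


def _brute_force(vi, vj):
    """Set-based recomputation of both indices."""
    si = {k for k, v in enumerate(vi) if v}
    sj = {k for k, v in enumerate(vj) if v}
    tot = len(si) + len(sj)
    if tot == 0:
        return 0.0, 0.0
    return 1 - abs(len(si) - len(sj)) / tot, 2 * len(si & sj) / tot


class TestPairScores:
    def test_identical_vectors(self):
        s = pair_scores(_vec([1, 0, 1]), _vec([1, 0, 1]))
        assert s.r_q == 1.0 and s.r_o == 1.0

    def test_hand_computed_example(self):
        vi = _vec([1, 1, 1, 0, 0])
        vj = _vec([1, 0, 0, 0, 0])
        s = pair_scores(vi, vj)
        assert (s.a_i, s.a_j, s.a_overlap) == (3, 1, 1)
        assert s.r_q == pytest.approx(0.5)
        assert s.r_o == pytest.approx(0.5)

    def test_degenerate_all_zero(self):
        s = pair_scores(_vec([0, 0, 0]), _vec([0, 0, 0]))
        assert s.r_q == 0.0 and s.r_o == 0.0

    def test_roi_restriction(self):
        vi = _vec([1, 1, 0, 0])
        vj = _vec([1, 0, 1, 0])
        s = pair_scores(vi, vj, roi_channels=[0, 3])
        assert (s.a_i, s.a_j, s.a_overlap) == (1, 1, 1)
        assert s.r_o == 1.0

    def test_mismatched_channels_raise(self):
        a = _vec([1, 0])
        b = ActivationVector("s", np.array([5, 6]), np.array([1, 0]))
        with pytest.raises(ValueError):
            pair_scores(a, b)

    def test_oracle_equivalence_random_vectors(self, rng):
        for _ in range(1000):
            vi = rng.integers(0, 2, 64)
            vj = rng.integers(0, 2, 64)
            s = pair_scores(_vec(vi), _vec(vj))
            rq, ro = _brute_force(vi, vj)
            assert s.r_q == rq and s.r_o == ro

    @given(st.lists(st.booleans(), min_size=1, max_size=64),
           st.data())
    @settings(max_examples=100, deadline=None)
    def test_reorder_invariance(self, vals, data):
        vj = data.draw(st.lists(st.booleans(), min_size=len(vals),
                                max_size=len(vals)))
        vi = np.array(vals, dtype=int)
        vj = np.array(vj, dtype=int)
        perm = np.random.default_rng(0).permutation(len(vi))
        s1 = pair_scores(_vec(vi), _vec(vj))
        s2 = pair_scores(_vec(vi[perm]), _vec(vj[perm]))
        assert s1.r_q == s2.r_q and s1.r_o == s2.r_o

    def test_overlap_monotone_in_common_channel(self, rng):
        for _ in range(200):
            vi = rng.integers(0, 2, 32)
            vj = rng.integers(0, 2, 32)
            off = np.where((vi == 0) & (vj == 0))[0]
            if len(off) == 0:
                continue
            s0 = pair_scores(_vec(vi), _vec(vj))
            vi2, vj2 = vi.copy(), vj.copy()
            vi2[off[0]] = vj2[off[0]] = 1
            s1 = pair_scores(_vec(vi2), _vec(vj2))
            assert s1.r_o >= s0.r_o

    def test_overlap_bound(self, rng):
        for _ in range(200):
            vi = rng.integers(0, 2, 16)
            vj = rng.integers(0, 2, 16)
            s = pair_scores(_vec(vi), _vec(vj))
            if s.a_i + s.a_j:
                assert s.r_o <= 2 * min(s.a_i, s.a_j) / (s.a_i + s.a_j)
            assert 0 <= s.r_o <= 1 and 0 <= s.r_q <= 1


class TestSubjectRepro:
    def test_identical_sessions(self):
        vecs = [_vec([1, 1, 0], f"s{i}") for i in range(3)]
        r = subject_repro(vecs)
        assert r.r_q_mean == 1.0 and r.r_o_mean == 1.0
        assert r.r_q_se == 0.0 and r.v_q == 0.0

    def test_single_pair(self):
        r = subject_repro([_vec([1, 1, 1, 0, 0]), _vec([1, 0, 0, 0, 0])])
        assert r.r_q_mean == pytest.approx(0.5)
        assert r.n_pairs == 1

    def test_mean_over_all_pairs_brute_force(self):
        vecs = [_vec([1, 1, 0, 0], "a"), _vec([1, 0, 1, 0], "b"),
                _vec([0, 1, 1, 1], "c")]
        r = subject_repro(vecs)
        pairs = [(0, 1), (0, 2), (1, 2)]
        rqs = [_brute_force(vecs[i].values, vecs[j].values)[0]
               for i, j in pairs]
        ros = [_brute_force(vecs[i].values, vecs[j].values)[1]
               for i, j in pairs]
        assert r.r_q_mean == pytest.approx(np.mean(rqs))
        assert r.r_o_mean == pytest.approx(np.mean(ros))
        assert r.v_q == pytest.approx(1 - np.mean(rqs))

    def test_too_few_sessions(self):
        with pytest.raises(ValueError):
            subject_repro([_vec([1])])


class TestFrequencyMap:
    def test_counts(self):
        vecs = [_vec([1, 0, 1]), _vec([1, 0, 0]), _vec([0, 0, 1])]
        f = frequency_map(vecs)
        assert f.counts.tolist() == [2, 0, 2]
        assert np.allclose(f.frequency, [2 / 3, 0, 2 / 3])

    def test_all_zero(self):
        f = frequency_map([_vec([0, 0]), _vec([0, 0])])
        assert np.all(f.counts == 0)

    def test_union_identity(self, rng):
        vecs = [_vec(rng.integers(0, 2, 16), f"s{i}") for i in range(4)]
        f = frequency_map(vecs)
        union = np.any([v.values for v in vecs], axis=0)
        assert np.array_equal(f.counts > 0, union)


class TestMedians:
    def test_reference_study_medians(self):
        """Every published group median is reproduced exactly."""
        df = reference_subject_scores()
        med = summarize_medians(df)
        expect = {
            ("standard_same_day", "whole"): (0.73, 0.36, 11.8, 5.5),
            ("standard_across_days", "whole"): (0.66, 0.04, 8.9, 8.3),
            ("guided_across_days", "whole"): (0.71, 0.36, None, None),
            ("standard_across_days", "left"): (0.13, 0.00, None, None),
            ("guided_across_days", "left"): (0.69, 0.43, None, None),
            ("standard_across_days", "navigated"): (0.17, 0.00, None, None),
            ("guided_across_days", "navigated"): (0.70, 0.59, None, None),
        }
        for (cond, roi), (rq, ro, hr, mp) in expect.items():
            row = med[(med.condition == cond) & (med.roi == roi)].iloc[0]
            assert row.r_q_mean == pytest.approx(rq)
            assert row.r_o_mean == pytest.approx(ro)
            if hr is not None:
                assert row.d_hr_pct == pytest.approx(hr)
                assert row.d_map_pct == pytest.approx(mp)

    def test_single_subject_median_is_value(self):
        df = pd.DataFrame({"condition": ["a"], "roi": ["whole"],
                           "r_q_mean": [0.42], "r_o_mean": [0.1]})
        med = summarize_medians(df)
        assert med.r_q_mean.iloc[0] == 0.42

    def test_even_group_midpoint(self):
        df = pd.DataFrame({"condition": ["a"] * 4, "roi": ["whole"] * 4,
                           "r_q_mean": [0.1, 0.2, 0.6, 0.9],
                           "r_o_mean": [0.0] * 4})
        med = summarize_medians(df)
        assert med.r_q_mean.iloc[0] == pytest.approx(0.4)


class TestVariabilityRegression:
    def test_constant_response(self):
        df = pd.DataFrame({"v_q": [0.3] * 6,
                           "d_hr_pct": [5, 8, 10, 3, 7, 9.0],
                           "d_map_pct": [2, 9, 4, 6, 8, 1.0]})
        fit = variability_regression(df)
        assert fit.estimate.iloc[0] == pytest.approx(0.3, abs=1e-10)
        assert fit.estimate.iloc[1:].abs().max() < 1e-10

    def test_exact_linear_recovery(self):
        hr = np.array([5, 8, 10, 3, 7, 9.0])
        mp = np.array([2, 9, 4, 6, 8, 1.0])
        df = pd.DataFrame({"v_q": 0.2 + 1.0 * hr / 100,
                           "d_hr_pct": hr, "d_map_pct": mp})
        fit = variability_regression(df, covariates_as="fraction")
        assert fit.estimate.iloc[0] == pytest.approx(0.2, abs=1e-10)
        assert fit.estimate.iloc[1] == pytest.approx(1.0, abs=1e-10)
        assert fit.estimate.iloc[2] == pytest.approx(0.0, abs=1e-10)

    def test_reference_table_consistency_check(self):
        """Documented comparison against the published fit (alpha 0.62,
        beta -0.37, gamma -1.6); covariate-scale ambiguity means this is
        a sanity check of magnitude, not an exact assertion."""
        df = reference_subject_scores()
        rows = df[(df.roi == "whole")
                  & df.condition.isin(["standard_same_day",
                                       "standard_across_days"])]
        for conv in ("fraction", "percent"):
            fit = variability_regression(rows, covariates_as=conv)
            assert np.all(np.isfinite(fit.estimate))
            assert 0.0 < fit.estimate.iloc[0] < 1.2  # intercept plausible

    def test_collinear_covariates_raise(self):
        df = pd.DataFrame({"v_q": [0.1, 0.2, 0.3, 0.4, 0.5],
                           "d_hr_pct": [1, 2, 3, 4, 5.0],
                           "d_map_pct": [2, 4, 6, 8, 10.0]})
        with pytest.raises(ValueError):
            variability_regression(df)

    def test_too_few_rows(self):
        df = pd.DataFrame({"v_q": [0.1, 0.2], "d_hr_pct": [1, 2.0],
                           "d_map_pct": [2, 1.0]})
        with pytest.raises(ValueError):
            variability_regression(df)


class TestPhysioChange:
    def test_range_over_mean(self):
        assert physio_change([60, 66]) == pytest.approx(100 * 6 / 63)

    def test_single_value(self):
        assert physio_change([70]) == 0.0


def _glm_result(beta, se):
    t = beta / se if se > 0 else np.inf
    return GLMChannelResult(beta=beta, se=se, t=t, p=0.01,
                            ar_order=0, converged=True, n_iter=1,
                            weight_mean=1.0, dof=100)


class TestGroupBetas:
    def test_equal_se_is_unweighted_mean(self):
        tabs = [{0: {"hbo": _glm_result(1.0, 0.5),
                     "hbr": _glm_result(-0.5, 0.5)}},
                {0: {"hbo": _glm_result(3.0, 0.5),
                     "hbr": _glm_result(-1.5, 0.5)}}]
        table, _ = group_betas(tabs, np.array([0]))
        hbo = table[(table.channel == 0) & (table.chromophore == "hbo")]
        assert hbo.beta.iloc[0] == pytest.approx(2.0)

    def test_single_measurement_passthrough(self):
        tabs = [{0: {"hbo": _glm_result(1.3, 0.2),
                     "hbr": _glm_result(-0.2, 0.1)}}]
        table, _ = group_betas(tabs, np.array([0]))
        hbo = table[table.chromophore == "hbo"]
        assert hbo.beta.iloc[0] == pytest.approx(1.3)
        assert hbo.se.iloc[0] == pytest.approx(0.2)

    def test_hand_computed_weighted_mean(self):
        tabs = [{0: {"hbo": _glm_result(1.0, 0.1),
                     "hbr": _glm_result(-1.0, 0.1)}},
                {0: {"hbo": _glm_result(0.0, 1.0),
                     "hbr": _glm_result(0.0, 1.0)}}]
        table, _ = group_betas(tabs, np.array([0]))
        hbo = table[table.chromophore == "hbo"]
        assert hbo.beta.iloc[0] == pytest.approx(100.0 / 101.0)

    def test_zero_se_raises(self):
        tabs = [{0: {"hbo": _glm_result(1.0, 0.0),
                     "hbr": _glm_result(-1.0, 0.1)}}]
        with pytest.raises(ValueError):
            group_betas(tabs, np.array([0]))
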