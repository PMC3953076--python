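"""Egger and Begg bias tests, leave-one-out sensitivity, Bonferroni, funnel data."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from snpmeta import (
    begg_test,
    bonferroni,
    egger_test,
    funnel_data,
    leave_one_out,
    pool_dl,
)
from snpmeta.bias import InsufficientStudiesError
from conftest import make_effect

SES = [0.1, 0.2, 0.3, 0.4]


class TestEgger:
    def test_affine_small_study_construction(self):
        # y = 0.1 + 1.0*se  =>  y/se = 1.0 + 0.1*(1/se): intercept 1, slope 0.1
        effs = [make_effect(0.1 + 1.0 * se, se, f"s{i}") for i, se in enumerate(SES)]
        r = egger_test(effs)
        assert r.intercept == pytest.approx(1.0, abs=1e-10)
        assert r.slope == pytest.approx(0.1, abs=1e-10)
        assert r.df == 2

    def test_pure_proportionality_gives_exact_intercept(self):
        effs = [make_effect(0.7 * se, se, f"s{i}") for i, se in enumerate(SES)]
        r = egger_test(effs)
        assert r.intercept == pytest.approx(0.7, abs=1e-10)
        assert r.slope == pytest.approx(0.0, abs=1e-10)

    def test_constant_effect_shows_no_asymmetry(self):
        effs = [make_effect(0.25, se, f"s{i}") for i, se in enumerate(SES)]
        r = egger_test(effs)
        assert r.intercept == pytest.approx(0.0, abs=1e-10)
        assert r.t == pytest.approx(0.0, abs=1e-8)
        assert r.p == pytest.approx(1.0, abs=1e-8)

    def test_reordering_invariance_and_linearity(self):
        rng = np.random.default_rng(3)
        effs = [
            make_effect(rng.normal(0.2, 0.3), rng.uniform(0.05, 0.6), f"s{i}")
            for i in range(8)
        ]
        base = egger_test(effs)
        shuffled = [effs[i] for i in rng.permutation(8)]
        assert egger_test(shuffled).intercept == pytest.approx(base.intercept, abs=1e-10)
        doubled = [make_effect(2 * e.log_or, e.se, e.study_id) for e in effs]
        assert egger_test(doubled).intercept == pytest.approx(2 * base.intercept, abs=1e-8)

    def test_too_few_studies_and_low_dispersion(self):
        with pytest.raises(InsufficientStudiesError):
            egger_test([make_effect(0.1, 0.2, "a"), make_effect(0.2, 0.2, "b")])
        equal = [make_effect(0.1 * i, 0.2, f"s{i}") for i in range(4)]
        assert egger_test(equal).low_dispersion


class TestBegg:
    def test_perfect_concordance_and_discordance(self):
        # this (y, se) layout makes the variance-stabilized deviates strictly
        # increasing with the variances, so every pair is concordant
        inc = [make_effect(y, se, f"s{i}") for i, (y, se) in enumerate(
            [(0.0, 0.1), (1.0, 0.2), (3.0, 0.4), (7.0, 0.8)]
        )]
        assert begg_test(inc).kendall_tau == pytest.approx(1.0)
        dec = [make_effect(-y, se, f"s{i}") for i, (y, se) in enumerate(
            [(0.0, 0.1), (1.0, 0.2), (3.0, 0.4), (7.0, 0.8)]
        )]
        assert begg_test(dec).kendall_tau == pytest.approx(-1.0)

    def test_matches_exhaustive_pair_counting(self):
        """Implementation tau equals an O(k^2) double-loop pair count."""
        rng = np.random.default_rng(17)
        from snpmeta.pooling import pool_fixed

        for _ in range(20):
            k = int(rng.integers(3, 31))
            effs = [
                make_effect(rng.normal(0, 0.5), rng.uniform(0.05, 1.0), f"s{i}")
                for i in range(k)
            ]
            r = begg_test(effs)
            fixed = pool_fixed(effs)
            v = np.array([e.se**2 for e in effs])
            u = (np.array([e.log_or for e in effs]) - fixed.pooled_log_or) / np.sqrt(
                v - 1.0 / np.sum(1.0 / v)
            )
            s = 0
            for i in range(k):
                for j in range(i + 1, k):
                    s += int(np.sign(u[i] - u[j]) * np.sign(v[i] - v[j]))
            assert r.kendall_tau == s / (k * (k - 1) / 2)

    def test_continuity_correction_reduces_z(self):
        rng = np.random.default_rng(2)
        effs = [
            make_effect(rng.normal(0, 0.5), rng.uniform(0.05, 1.0), f"s{i}")
            for i in range(10)
        ]
        with_cc = begg_test(effs, continuity=True)
        without = begg_test(effs, continuity=False)
        assert abs(with_cc.z) <= abs(without.z) + 1e-12

    def test_degenerate_rankings_flagged(self):
        effs = [make_effect(0.2, 0.3, f"s{i}") for i in range(5)]
        r = begg_test(effs)
        assert r.degenerate
        assert r.p == 1.0


class TestLeaveOneOut:
    def test_identical_studies_give_zero_shift(self):
        effs = [make_effect(0.4, 0.2, f"s{i}") for i in range(5)]
        rep = leave_one_out(effs)
        assert len(rep.rows) == 5
        assert rep.max_abs_shift == pytest.approx(0.0, abs=1e-12)
        assert all(r.k == 4 for _, r in rep.rows)

    def test_omitting_the_outlier_minimizes_tau2(self):
        effs = [make_effect(0.2, 0.15, f"s{i}") for i in range(6)]
        effs.append(make_effect(2.5, 0.15, "outlier"))
        rep = leave_one_out(effs)
        tau2_by_omitted = {sid: r.tau2 for sid, r in rep.rows}
        assert min(tau2_by_omitted, key=tau2_by_omitted.get) == "outlier"

    def test_negligible_weight_study_barely_shifts_pool(self):
        effs = [make_effect(0.3, 0.1, f"s{i}") for i in range(4)]
        effs.append(make_effect(5.0, 200.0, "tiny_weight"))
        rep = leave_one_out(effs)
        row = dict(rep.rows)["tiny_weight"]
        full = pool_dl(effs)
        assert abs(row.pooled_log_or - full.pooled_log_or) < 1e-6

    def test_requires_three_studies(self):
        with pytest.raises(InsufficientStudiesError):
            leave_one_out([make_effect(0.1, 0.2, "a"), make_effect(0.2, 0.2, "b")])


class TestBonferroni:
    def test_examples_and_cap(self):
        assert bonferroni([0.01], m=3) == [pytest.approx(0.03)]
        assert bonferroni([0.5], m=3) == [1.0]
        assert bonferroni([0.01, 0.5, 0.2]) == [
            pytest.approx(0.03),
            1.0,
            pytest.approx(0.6),
        ]

    @given(
        ps=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=6),
        m=st.integers(6, 20),
    )
    def test_monotone_and_order_preserving(self, ps, m):
        adj = bonferroni(ps, m=m)
        assert len(adj) == len(ps)
        order = np.argsort(ps)
        assert all(
            adj[order[i]] <= adj[order[i + 1]] + 1e-15 for i in range(len(ps) - 1)
        )

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2], m=1)
        with pytest.raises(ValueError):
            bonferroni([0.1], m=0)


class TestFunnelData:
    def test_structure_and_symmetry(self):
        effs = [make_effect(y, 0.2, f"s{i}") for i, y in enumerate([-0.2, -0.1, 0.1, 0.2])]
        pooled = pool_dl(effs)
        fd = funnel_data(effs, pooled)
        points = fd["points"]
        assert len(points) == 4
        left = (points["log_or"] < pooled.pooled_log_or).sum()
        right = (points["log_or"] > pooled.pooled_log_or).sum()
        assert left == right

    def test_guides_converge_at_zero_se(self):
        effs = [make_effect(0.1 * i, 0.1 + 0.1 * i, f"s{i}") for i in range(4)]
        pooled = pool_dl(effs)
        guides = funnel_data(effs, pooled)["guides"]
        at_zero = guides.iloc[0]
        assert at_zero["se"] == 0.0
        assert at_zero["lower"] == pytest.approx(pooled.pooled_log_or)
        assert at_zero["upper"] == pytest.approx(pooled.pooled_log_or)
        assert guides["se"].max() == pytest.approx(max(e.se for e in effs))
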