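"""Fixed-effect and DerSimonian-Laird pooling, Q/I^2, and the Z-test."""

from __future__ import annotations

import json
import math
import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given, strategies as st

from snpmeta import PoolMethod, pool_dl, pool_fixed, z_test
from conftest import make_effect

effect_lists = st.lists(
    st.tuples(
        st.floats(-1.5, 1.5, allow_nan=False),
        st.floats(0.05, 1.0, allow_nan=False),
    ),
    min_size=2,
    max_size=10,
).map(lambda tl: [make_effect(y, se, f"s{i}") for i, (y, se) in enumerate(tl)])


class TestPoolFixed:
    def test_single_study_is_identity(self):
        r = pool_fixed([make_effect(0.3, 0.1)])
        assert r.pooled_log_or == pytest.approx(0.3)
        assert r.pooled_se == pytest.approx(0.1)
        assert r.q == 0.0
        assert r.q_p == 1.0  # defined as 1 for k = 1

    def test_two_equal_weight_studies(self):
        effs = [make_effect(0.0, math.sqrt(0.1), "a"), make_effect(1.0, math.sqrt(0.1), "b")]
        r = pool_fixed(effs)
        assert r.pooled_log_or == pytest.approx(0.5)
        assert r.q == pytest.approx(5.0)
        assert r.q_df == 1

    def test_replicated_study_shrinks_se(self):
        effs = [make_effect(0.4, 0.2, f"s{i}") for i in range(4)]
        r = pool_fixed(effs)
        assert r.pooled_log_or == pytest.approx(0.4)
        assert r.pooled_se == pytest.approx(0.2 / 2)
        assert r.q == pytest.approx(0.0, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pool_fixed([])


class TestPoolDL:
    def test_homogeneous_pair_reduces_to_fixed(self):
        effs = [make_effect(0.5, 0.2, "a"), make_effect(0.5, 0.2, "b")]
        r = pool_dl(effs)
        assert r.tau2 == 0.0
        assert r.pooled_log_or == pytest.approx(0.5)
        assert r.pooled_se == pytest.approx(0.2 / math.sqrt(2))

    def test_hand_evaluated_heterogeneous_pair(self):
        effs = [make_effect(0.0, math.sqrt(0.1), "a"), make_effect(1.0, math.sqrt(0.1), "b")]
        r = pool_dl(effs)
        # w = 10 each: C = 20 - 200/20 = 10, tau2 = (5-1)/10 = 0.4,
        # w* = 1/(0.1+0.4) = 2 each -> pooled = 0.5, se = 1/2, I2 = 80%
        assert r.q == pytest.approx(5.0)
        assert r.tau2 == pytest.approx(0.4)
        assert r.pooled_log_or == pytest.approx(0.5)
        assert r.pooled_se == pytest.approx(0.5)
        assert r.i2_pct == pytest.approx(80.0)

    @given(effects=effect_lists)
    def test_truncation_rule_matches_fixed_when_homogeneous(self, effects):
        fixed = pool_fixed(effects)
        dl = pool_dl(effects)
        if fixed.q <= fixed.q_df:
            assert dl.tau2 == 0.0
            assert dl.pooled_log_or == pytest.approx(fixed.pooled_log_or, abs=1e-12)

    @given(effects=effect_lists)
    def test_convexity_and_se_ordering(self, effects):
        ys = [e.log_or for e in effects]
        fixed = pool_fixed(effects)
        dl = pool_dl(effects)
        for r in (fixed, dl):
            assert min(ys) - 1e-12 <= r.pooled_log_or <= max(ys) + 1e-12
        assert dl.pooled_se >= fixed.pooled_se - 1e-12
        if dl.tau2 == 0.0:
            assert dl.pooled_se == pytest.approx(fixed.pooled_se, abs=1e-12)

    @given(effects=effect_lists, shift=st.floats(-2, 2, allow_nan=False))
    def test_q_and_tau2_shift_invariant(self, effects, shift):
        shifted = [
            make_effect(e.log_or + shift, e.se, e.study_id) for e in effects
        ]
        assert pool_dl(effects).q == pytest.approx(pool_dl(shifted).q, abs=1e-8)
        assert pool_dl(effects).tau2 == pytest.approx(
            pool_dl(shifted).tau2, abs=1e-10
        )

    def test_single_study_falls_back_to_fixed(self):
        r = pool_dl([make_effect(0.3, 0.1)])
        assert r.method is PoolMethod.DL_RANDOM
        assert r.pooled_log_or == pytest.approx(0.3)
        assert r.tau2 == 0.0


class TestZTest:
    def test_null_gives_p_one(self):
        assert z_test(0.0, 0.37) == (0.0, 1.0)

    def test_unit_z(self):
        z, p = z_test(0.5, 0.5)
        assert z == pytest.approx(1.0)
        assert p == pytest.approx(0.3173, abs=1e-4)

    def test_strong_effect_is_highly_significant(self):
        z, p = z_test(0.10436, 0.018397)
        assert z == pytest.approx(5.67, abs=0.01)
        assert p < 1e-5

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            z_test(0.1, 0.0)


class TestAgainstMetafor:
    def test_dl_matches_r_metafor(self, tmp_path):
        """Independent cross-check of the DL chain against R's metafor."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not on PATH; cannot run the metafor cross-check")
        y = [0.12, -0.05, 0.30, 0.08, 0.22]
        v = [0.01, 0.04, 0.09, 0.02, 0.05]
        effs = [
            make_effect(yi, math.sqrt(vi), f"s{i}") for i, (yi, vi) in enumerate(zip(y, v))
        ]
        ours = pool_dl(effs)
        script = tmp_path / "dl.R"
        script.write_text(
            "suppressMessages(library(metafor))\n"
            f"yi <- c({','.join(map(str, y))}); vi <- c({','.join(map(str, v))})\n"
            "f <- rma(yi, vi, method='DL')\n"
            "cat(sprintf('{\"b\": %.12f, \"se\": %.12f, \"tau2\": %.12f, \"QE\": %.12f}',\n"
            "    as.numeric(f$b), f$se, f$tau2, f$QE))\n"
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        ref = json.loads(out.stdout)
        assert ours.pooled_log_or == pytest.approx(ref["b"], abs=1e-9)
        assert ours.pooled_se == pytest.approx(ref["se"], abs=1e-9)
        assert ours.tau2 == pytest.approx(ref["tau2"], abs=1e-9)
        assert ours.q == pytest.approx(ref["QE"], abs=1e-9)
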