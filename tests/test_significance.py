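"""Ratio computation, Significance A/B, BH adjustment and set algebra."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import erfc

from phosphosig import significance as sg
from phosphosig.errors import ConfigurationError, StatisticError
from phosphosig.phosphodata import ExperimentDesign, PhosphoSiteRecord
from phosphosig.synthetic_data import default_design


def _record(site_id, gene, residue, intensities):
    return PhosphoSiteRecord(site_id, "P", gene, residue, intensities=intensities)


class TestComputeRatios:
    def test_direct_log2(self, design):
        rec = _record("s1", "A", "S10", {(1, "light"): 1000.0, (1, "medium"): 250.0})
        df = sg.compute_ratios([rec], design, "smarcb1_high", center=False)
        assert df.loc[0, "log2_ratio"] == pytest.approx(2.0)
        assert df.loc[0, "summed_intensity"] == pytest.approx(1250.0)

    def test_chained_cancels_equal_anchor(self):
        design = ExperimentDesign(
            conditions={
                (1, "light"): "anchor",
                (1, "medium"): "def10",
                (2, "light"): "anchor",
                (2, "medium"): "def01",
            },
            anchor="anchor",
            comparisons={"c": ("def10", "def01")},
        )
        rec = _record(
            "s1",
            "A",
            "S10",
            {
                (1, "light"): 500.0,
                (1, "medium"): 2000.0,
                (2, "light"): 500.0,
                (2, "medium"): 250.0,
            },
        )
        df = sg.compute_ratios([rec], design, "c", center=False)
        # equal anchors cancel: log2(2000/250) = 3
        assert df.loc[0, "log2_ratio"] == pytest.approx(3.0)
        # conservative weight: min of the two legs' summed intensities
        assert df.loc[0, "summed_intensity"] == pytest.approx(750.0)

    def test_site_without_required_channel_is_skipped(self, design):
        rec = _record("s1", "A", "S10", {(1, "light"): 1000.0})
        df = sg.compute_ratios([rec], design, "smarcb1_high")
        assert len(df) == 0

    def test_unknown_comparison_is_config_error(self, design, small_bundle):
        _, records, _ = small_bundle
        with pytest.raises(ConfigurationError):
            sg.compute_ratios(records, design, "nope")

    def test_median_centering(self, small_bundle, design):
        _, records, _ = small_bundle
        df = sg.compute_ratios(records, design, "smarcb1_high")
        assert abs(np.median(df["log2_ratio"])) < 1e-12

    def test_noiseless_recovery_of_planted_effects(self, noiseless_bundle, design):
        _, records, truth = noiseless_bundle
        df = sg.compute_ratios(records, design, "smarcb1_high")
        raw = df["log2_ratio"] + df.attrs["center_offset"]
        planted = truth.set_index("site_id").loc[df["site_id"], "d_high"].to_numpy()
        assert np.allclose(raw, planted, atol=1e-6)


class TestSignificanceA:
    def test_median_gets_p_half(self):
        r = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        p = sg.significance_A(r)
        assert p[2] == pytest.approx(0.5)

    def test_one_sigma_closed_form(self, rng):
        # a value sitting at the 84.13th percentile scores z = 1
        r = rng.standard_normal(20001)
        v = np.percentile(r, 84.13)
        p = sg.significance_A(np.append(r, v))[-1]
        assert p == pytest.approx(0.5 * erfc(1 / math.sqrt(2)), abs=2e-3)

    def test_null_calibration_per_tail(self, rng):
        # p is the one-sided tail probability (p = 1 - Phi(z) on each side of
        # the median), so under a Gaussian null each tail flags ~5% at
        # p < 0.05 and the two tails together flag ~10%
        r = rng.standard_normal(10000)
        p = sg.significance_A(r)
        med = np.median(r)
        assert 0.04 <= ((r > med) & (p < 0.05)).mean() <= 0.06
        assert 0.04 <= ((r < med) & (p < 0.05)).mean() <= 0.06
        assert 0.09 <= (p < 0.05).mean() <= 0.11

    def test_shift_and_scale_invariance(self, rng):
        r = rng.standard_normal(500)
        p = sg.significance_A(r)
        assert np.allclose(p, sg.significance_A(r + 3.7), atol=1e-9)
        assert np.allclose(p, sg.significance_A(r * 12.5), atol=1e-9)

    def test_monotone_in_distance_from_median(self, rng):
        r = rng.standard_normal(1000)
        p = sg.significance_A(r)
        med = np.median(r)
        upper = np.argsort(r[r > med])
        p_upper = p[r > med][upper]
        assert np.all(np.diff(p_upper) <= 1e-12)

    def test_degenerate_scale_raises(self):
        with pytest.raises(StatisticError):
            sg.significance_A([1.0, 1.0, 1.0, 1.0, 5.0])

    def test_too_few_ratios(self):
        with pytest.raises(StatisticError):
            sg.significance_A([0.0, 1.0])


class TestSignificanceB:
    def test_single_bin_equals_A(self, rng):
        r = rng.standard_normal(100)
        inten = rng.uniform(1e5, 1e8, 100)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p_b = sg.significance_B(r, inten, min_bin=300)
        assert np.array_equal(p_b, sg.significance_A(r))

    def test_two_regime_advantage(self, rng):
        """A clear shift at high intensity is invisible to the pooled statistic
        but obvious against the tight high-intensity null."""
        n = 2000
        low = rng.normal(0, 2.0, n)
        high = rng.normal(0, 0.5, n)
        r = np.concatenate([low, high, [1.5]])
        inten = np.concatenate([np.full(n, 1e5), np.full(n, 1e8), [1e8]])
        p_a = sg.significance_A(r)[-1]
        p_b = sg.significance_B(r, inten, min_bin=500)[-1]
        assert p_b < 0.01
        assert p_a > 0.05

    def test_homoscedastic_B_close_to_A(self, rng):
        r = rng.standard_normal(3000)
        inten = rng.uniform(1e5, 1e8, 3000)
        p_a = sg.significance_A(r)
        p_b = sg.significance_B(r, inten, min_bin=300)
        # per-bin percentile scales are estimated from ~300 sites, so B
        # wobbles around A but stays close and keeps the same null rate
        # (~5% per tail, see test_null_calibration_per_tail)
        assert np.quantile(np.abs(p_a - p_b), 0.95) < 0.1
        assert 0.09 <= (p_b < 0.05).mean() <= 0.11

    def test_output_aligned_to_input_order(self, rng):
        r = rng.standard_normal(900)
        inten = rng.uniform(1e5, 1e8, 900)
        p = sg.significance_B(r, inten, min_bin=300)
        perm = rng.permutation(900)
        p_perm = sg.significance_B(r[perm], inten[perm], min_bin=300)
        assert np.allclose(p[perm], p_perm)

    def test_misaligned_inputs_raise(self):
        with pytest.raises(StatisticError):
            sg.significance_B([0.1, 0.2, 0.3], [1.0, 2.0])


class TestBH:
    def test_single_p(self):
        assert sg.bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_step_up(self):
        # step-up: q_i = min over j>=i of p_j * m / j -> all 0.04 here
        q = sg.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_ties_stay_equal(self):
        q = sg.bh_adjust([0.2, 0.2, 0.2])
        assert np.allclose(q, 0.2)

    def test_empty(self):
        assert sg.bh_adjust([]).size == 0

    def test_monotone_in_p_rank(self, rng):
        p = rng.uniform(0.001, 1.0, 200)
        q = sg.bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q <= 1.0)


class TestVenn:
    def test_disjoint(self):
        v = sg.venn_counts({("A", "S1")}, {("B", "S2")})
        assert v.both == 0 and v.only_a == 1 and v.only_b == 1

    def test_identical(self):
        s = {("A", "S1"), ("B", "S2")}
        v = sg.venn_counts(s, set(s))
        assert v.only_a == v.only_b == 0 and v.both == 2

    @settings(deadline=None, max_examples=50)
    @given(
        st.sets(st.integers(0, 50)),
        st.sets(st.integers(0, 50)),
    )
    def test_conservation(self, a, b):
        ka = {("G", f"S{i+1}") for i in a}
        kb = {("G", f"S{i+1}") for i in b}
        v = sg.venn_counts(ka, kb)
        assert len(ka) + len(kb) == v.only_a + v.only_b + 2 * v.both
        assert v.size_a == len(ka) and v.size_b == len(kb)

    def test_sign_split(self):
        a = {("A", "S1"), ("B", "S2")}
        signs = {("A", "S1"): 1, ("B", "S2"): -1}
        v = sg.venn_counts(a, set(), signs_a=signs)
        assert v.up_a == 1 and v.down_a == 1


class TestVolcano:
    def test_flags_match_significant_sites(self, small_bundle, design):
        _, records, _ = small_bundle
        df = sg.compute_ratios(records, design, "smarcb1_high")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scored = sg.add_significance(df, min_bin=300)
        vol = sg.volcano_table(scored)
        assert len(vol) == len(scored)
        flagged = {
            (g.upper(), r)
            for g, r, f in zip(vol["gene"], vol["residue"], vol["significant"])
            if f
        }
        assert flagged == sg.significant_sites(scored)
        # -log10 threshold behavior
        assert np.all(vol.loc[vol["significant"], "neg_log10_p"] > -math.log10(0.05))

    def test_p_of_one_maps_to_zero(self):
        import pandas as pd

        scored = pd.DataFrame(
            {
                "gene": ["A"],
                "residue": ["S1"],
                "log2_ratio": [0.0],
                "p_value": [1.0],
                "significant": [False],
            }
        )
        assert sg.volcano_table(scored)["neg_log10_p"].iloc[0] == 0.0
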