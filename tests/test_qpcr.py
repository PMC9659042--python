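"""Copy-number phenotyping: dCt arithmetic, 2^-ddCt identities,
elongation calling, log-normal outlier screening, in-silico PCR."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from telmap import (
    CtMeasurement,
    call_elongation,
    delta_ct,
    fit_panel_distribution,
    flag_outliers,
    in_silico_pcr,
    relative_copy_number,
)
from telmap.qpcr import _revcomp


def ct(sample, gene, reps, generation=None):
    return CtMeasurement(sample_id=sample, gene=gene, replicates=reps,
                         generation=generation)


class TestDeltaCt:
    @pytest.mark.parametrize(
        "target,reference,expected",
        [
            ((20.0, 20.2, 19.8), (15.0, 15.1, 14.9), 5.0),
            ((21.0, 21.0), (21.0, 21.0), 0.0),
            ((30.0,), (25.5,), 4.5),
        ],
    )
    def test_mean_difference(self, target, reference, expected):
        d = delta_ct(ct("s", "target", target), ct("s", "ref", reference))
        assert d.value == pytest.approx(expected)

    def test_mismatched_samples_rejected(self):
        with pytest.raises(ValueError, match="sample"):
            delta_ct(ct("a", "t", (20.0,)), ct("b", "r", (15.0,)))

    def test_replicate_sd_propagates_in_quadrature(self):
        t = ct("s", "t", (20.0, 21.0, 22.0))
        r = ct("s", "r", (15.0, 16.0, 17.0))
        assert delta_ct(t, r).sd == pytest.approx(math.hypot(t.sd, r.sd))

    def test_ct_range_validated(self):
        with pytest.raises(ValueError):
            ct("s", "t", (0.0,))
        with pytest.raises(ValueError):
            ct("s", "t", (46.0,))


class TestRelativeCopyNumber:
    @pytest.mark.parametrize("s,c,expected", [(4.0, 5.0, 2.0), (5.0, 5.0, 1.0),
                                              (7.0, 5.0, 0.25)])
    def test_closed_form(self, s, c, expected):
        assert relative_copy_number(s, c) == pytest.approx(expected)

    def test_reciprocal_identity_on_grid(self):
        grid = np.linspace(-6, 12, 13)
        for a in grid:
            for b in grid:
                prod = relative_copy_number(a, b) * relative_copy_number(b, a)
                assert prod == pytest.approx(1.0)

    def test_one_extra_cycle_halves_copy_number(self):
        for dct in np.linspace(-4, 10, 15):
            ratio = relative_copy_number(dct + 1.0, 0.0) / relative_copy_number(dct, 0.0)
            assert ratio == pytest.approx(0.5)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            relative_copy_number(float("nan"), 0.0)


class TestCallElongation:
    def test_two_cycle_drop_is_fourfold(self):
        c = call_elongation("r", [(0, 6.0), (12, 4.0)])
        assert c.fold_change == pytest.approx(4.0)
        assert c.elongated

    def test_flat_series_not_elongated(self):
        c = call_elongation("r", [(0, 5.0), (6, 5.0), (9, 5.0), (12, 5.0)])
        assert c.fold_change == pytest.approx(1.0)
        assert not c.elongated
        assert c.slope == pytest.approx(0.0)

    def test_generator_drift_closed_form(self):
        # drift 0.25 dCt/generation over generations 0..12 -> ddCt = 3
        traj = [(g, 5.0 - 0.25 * g) for g in (0, 6, 9, 12)]
        c = call_elongation("r", traj)
        assert c.fold_change == pytest.approx(2.0 ** 3)
        assert c.elongated
        assert c.slope == pytest.approx(-0.25)

    def test_missing_generation_zero_rejected(self):
        with pytest.raises(ValueError, match="generation 0"):
            call_elongation("r", [(6, 5.0), (12, 4.0)])

    def test_regression_gate_vetoes_rising_then_dropping_series(self):
        # big terminal drop but overall positive slope should fail the
        # slope requirement when enabled
        traj = [(0, 5.0), (6, 9.0), (9, 9.0), (12, 3.5)]
        assert call_elongation("r", traj, use_regression=False).elongated
        loose_slope = call_elongation("r", traj, use_regression=True)
        assert loose_slope.elongated == (loose_slope.slope < 0)


class TestPanelDistribution:
    def test_constant_values(self):
        mu, sd = fit_panel_distribution([7.0] * 10)
        assert mu == pytest.approx(math.log10(7.0))
        assert sd == pytest.approx(0.0)

    def test_decade_spaced_values(self):
        mu, sd = fit_panel_distribution([1.0, 10.0, 100.0])
        assert mu == pytest.approx(1.0)
        assert sd == pytest.approx(1.0)

    def test_moment_recovery_within_three_se(self):
        rng = np.random.default_rng(11)
        mu, sigma, n = 0.3, 0.2, 4000
        values = 10.0 ** (mu + sigma * rng.standard_normal(n))
        mu_hat, sd_hat = fit_panel_distribution(values.tolist())
        assert abs(mu_hat - mu) < 3 * sigma / math.sqrt(n)
        assert abs(sd_hat - sigma) < 3 * sigma / math.sqrt(2 * (n - 1))

    def test_nonpositive_value_named(self):
        with pytest.raises(ValueError, match="index 1"):
            fit_panel_distribution([1.0, -2.0, 3.0])


class TestFlagOutliers:
    def test_planted_high_outliers_flagged_exactly(self):
        rng = np.random.default_rng(5)
        values = {f"l{i}": float(10.0 ** (0.15 * rng.standard_normal()))
                  for i in range(159)}
        for i in range(3):
            values[f"out{i}"] = float(10.0 ** (5 * 0.15 + 0.015 * rng.standard_normal()))
        res = flag_outliers(values, k=3.0)
        assert sorted(res.flagged) == ["out0", "out1", "out2"]

    def test_false_flag_rate_near_expectation(self):
        # with no planted outliers, E[# flags] = n * P(Z > 3) ~ 0.2 at n=162
        n_flagged = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            values = {f"l{i}": float(10.0 ** (0.15 * rng.standard_normal()))
                      for i in range(162)}
            n_flagged += len(flag_outliers(values, k=3.0).flagged)
        # Poisson(mean 0.2*40=8.7ish upper bound); loose sanity bound
        assert n_flagged <= 25

    def test_identical_values_none_flagged(self):
        res = flag_outliers({f"l{i}": 3.3 for i in range(10)})
        assert res.flagged == ()
        assert res.log_sd == pytest.approx(0.0)

    @settings(max_examples=30, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3),
           seed=st.integers(0, 50))
    def test_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        values = {f"l{i}": float(10.0 ** (0.2 * rng.standard_normal()))
                  for i in range(30)}
        values["hot"] = 10.0 ** 1.5
        base = flag_outliers(values, k=3.0).flagged
        scaled = flag_outliers({k: v * scale for k, v in values.items()}, k=3.0).flagged
        assert base == scaled

    def test_low_tail_only_with_both(self):
        rng = np.random.default_rng(3)
        values = {f"l{i}": float(10.0 ** (0.1 * rng.standard_normal()))
                  for i in range(50)}
        values["cold"] = 10.0 ** -2.0
        assert "cold" not in flag_outliers(values, k=3.0, tail="high").flagged
        assert "cold" in flag_outliers(values, k=3.0, tail="both").flagged


class TestInSilicoPcr:
    F = "TTGTCTTCTCCTCCGTCCACC"
    R = "GAGCTGAGATTTTTCTCTATGCTACTG"

    def test_constructed_amplicon_length(self):
        rng = np.random.default_rng(0)
        mid = "".join(rng.choice(list("ACGT"), size=50))
        f, r = "ACGTACGTACGTACGTACGT", "TTGGCCAATTGGCCAATTGG"
        template = f + mid + _revcomp(r)
        products = in_silico_pcr(template, f, r)
        assert len(products) == 1
        assert products[0].length == 90
        assert products[0].start == 1
        assert products[0].end == 90

    def test_absent_primers_no_product(self):
        assert in_silico_pcr("ACGT" * 50, self.F, self.R) == []

    def test_short_primers_rejected(self):
        with pytest.raises(ValueError, match="10"):
            in_silico_pcr("ACGT" * 50, "ACGTACG", "ACGTACGTA")

    def test_length_cap_drops_long_products(self):
        f, r = "ACGTACGTACGTACGTACGT", "TTGGCCAATTGGCCAATTGG"
        template = f + "A" * 6000 + _revcomp(r)
        assert in_silico_pcr(template, f, r, max_length=5000) == []
        assert len(in_silico_pcr(template, f, r, max_length=7000)) == 1

    @settings(max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_agrees_with_bruteforce_scan(self, seed):
        rng = np.random.default_rng(seed)
        template = "".join(rng.choice(list("AC"), size=300))  # repeat-prone
        f = "".join(rng.choice(list("AC"), size=10))
        r = "".join(rng.choice(list("AC"), size=10))
        rc = _revcomp(r)
        expected = []
        for i in range(len(template) - len(f) + 1):
            if template[i:i + len(f)] != f:
                continue
            for j in range(i, len(template) - len(rc) + 1):
                if template[j:j + len(rc)] != rc:
                    continue
                length = j + len(rc) - i
                if length <= 5000 and length >= max(len(f), len(r)):
                    expected.append((i + 1, j + len(rc), length))
        got = [(a.start, a.end, a.length) for a in in_silico_pcr(template, f, r)]
        assert got == sorted(expected)
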