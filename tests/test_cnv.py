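"""Bin normalization, CNV likelihoods, segmentation and size-shift channel."""

import numpy as np
import pandas as pd
import pytest

from plasmakit.cnv import (
    CNVCaller,
    CNVCallerConfig,
    DegenerateReferenceError,
    DIPLOID,
    FETAL_DEL,
    FETAL_DUP,
    ReferenceBinSet,
    call_cnvs,
    calls_to_frame,
    expected_ratio,
    expected_short_fraction,
    flag_gross_deviations,
    normalize_bins,
    segment_log_likelihood,
    size_shift_statistic,
    write_calls_vcf,
)
from plasmakit.simulate import (
    CNVEvent,
    SimConfig,
    nominal_size_distribution,
    simulate_cohort,
    simulate_ratio_bins,
)

from _oracles import gaussian_log_density


def _bins(ratios, chrom="chr2", bin_size=100_000, short_fractions=None):
    starts = np.arange(len(ratios)) * bin_size
    frame = pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": starts + bin_size, "ratio": ratios}
    )
    if short_fractions is not None:
        frame["short_fraction"] = short_fractions
    return frame


def _reference(n_bins, sigma=0.05, count=500.0):
    starts = np.arange(n_bins) * 100_000
    return ReferenceBinSet(
        bins=pd.DataFrame(
            {"chrom": "chr2", "start": starts, "end": starts + 100_000, "count": count}
        ),
        ratio_sigma=sigma,
    )


class TestExpectedRatio:
    @pytest.mark.parametrize("state,f,expected", [
        (FETAL_DEL, 0.10, 0.95),
        (FETAL_DUP, 0.20, 1.10),
        (DIPLOID, 0.07, 1.00),
        (DIPLOID, 0.9, 1.00),
    ])
    def test_formula(self, state, f, expected):
        assert expected_ratio(state, f) == pytest.approx(expected)

    @pytest.mark.parametrize("f", [0.01, 0.05, 0.2, 1.0])
    def test_ordering_for_positive_f(self, f):
        assert expected_ratio(FETAL_DEL, f) < 1 < expected_ratio(FETAL_DUP, f)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            expected_ratio("triploid", 0.1)
        with pytest.raises(ValueError):
            expected_ratio(FETAL_DEL, 1.5)


class TestNormalizeBins:
    def test_identity_when_counts_match_reference(self):
        ref = _reference(10, count=500.0)
        raw = ref.bins.copy()
        out = normalize_bins(raw, ref)
        np.testing.assert_allclose(out["ratio"], 1.0)

    def test_doubled_bin_has_ratio_two(self):
        ref = _reference(11, count=500.0)
        raw = ref.bins.copy()
        raw.loc[5, "count"] = 1000.0
        out = normalize_bins(raw, ref)
        # median renormalization is unaffected by a single outlier bin
        assert out.loc[5, "ratio"] == pytest.approx(2.0)
        np.testing.assert_allclose(out.drop(index=5)["ratio"], 1.0)

    def test_missing_reference_bin_raises(self):
        ref = _reference(5)
        raw = ref.bins.copy()
        raw.loc[0, "start"] = 999_999_999
        with pytest.raises(KeyError):
            normalize_bins(raw, ref)

    def test_zero_reference_count_masks_bin(self):
        ref = _reference(5)
        ref.bins.loc[2, "count"] = 0.0
        raw = _reference(5).bins.copy()
        out = normalize_bins(raw, ref)
        assert np.isnan(out.loc[2, "ratio"])
        assert out["ratio"].drop(index=2).notna().all()

    def test_simulated_fetal_deletion_depresses_ratio_by_half_f(self):
        # event bins expect ratio 1 - f/2 = 0.95
        event = CNVEvent("chr2", 1_000_000, 2_000_000, FETAL_DEL)
        means = []
        for seed in range(5):
            config = SimConfig(
                seed=seed, cnv_events=(event,), fragments_per_bin=2000,
                n_sites=10, fragments_per_site=0,
            )
            cohort = simulate_cohort(config)
            out = normalize_bins(cohort.bins, cohort.reference)
            means.append(out.iloc[10:20]["ratio"].mean())
        assert np.mean(means) == pytest.approx(0.95, abs=0.01)

    def test_diploid_median_ratio_is_one(self, small_cohort):
        out = normalize_bins(small_cohort.bins, small_cohort.reference)
        assert out["ratio"].median() == pytest.approx(1.0, abs=0.05)


class TestSegmentLogLikelihood:
    def test_zero_residual_equals_density_at_mode(self):
        ref = _reference(4, sigma=0.04)
        bins = _bins([0.95] * 4)
        ll = segment_log_likelihood(bins, FETAL_DEL, 0.10, ref)
        per_bin = gaussian_log_density(np.log2(0.95), np.log2(0.95), 0.04)
        assert ll == pytest.approx(4 * per_bin, abs=1e-9)

    def test_matches_independent_summation(self, rng):
        ref = _reference(8, sigma=0.05)
        ratios = 2.0 ** rng.normal(0, 0.05, 8)
        bins = _bins(ratios)
        for state in (FETAL_DEL, DIPLOID, FETAL_DUP):
            mu = np.log2(expected_ratio(state, 0.12))
            expected = sum(
                gaussian_log_density(np.log2(r), mu, 0.05) for r in ratios
            )
            assert segment_log_likelihood(bins, state, 0.12, ref) == pytest.approx(
                expected, abs=1e-9
            )

    def test_wrong_model_penalty(self):
        ref = _reference(6, sigma=0.03)
        bins = _bins([1.0] * 6)
        ll_diploid = segment_log_likelihood(bins, DIPLOID, 0.1, ref)
        ll_del = segment_log_likelihood(bins, FETAL_DEL, 0.1, ref)
        assert ll_del < ll_diploid

    def test_zero_ratio_floored_not_infinite(self):
        ref = _reference(1)
        bins = _bins([0.0])
        assert np.isfinite(segment_log_likelihood(bins, DIPLOID, 0.1, ref))

    def test_empty_segment_raises(self):
        with pytest.raises(ValueError):
            segment_log_likelihood(_bins([]), DIPLOID, 0.1, _reference(1))


class TestSizeShift:
    def _size_ref(self, mean=0.25, sd=0.02):
        ref = _reference(5)
        ref.short_fraction_mean = mean
        ref.short_fraction_sd = sd
        return ref

    def test_zero_at_reference_mean(self):
        assert size_shift_statistic(0.25, self._size_ref()) == pytest.approx(0.0)

    def test_one_sd_above_mean(self):
        assert size_shift_statistic(0.27, self._size_ref()) == pytest.approx(1.0)

    def test_degenerate_reference_raises(self):
        with pytest.raises(DegenerateReferenceError):
            size_shift_statistic(0.25, self._size_ref(sd=0.0))
        with pytest.raises(DegenerateReferenceError):
            size_shift_statistic(0.25, _reference(3))

    def test_expected_short_fraction_ordering(self):
        fetal = nominal_size_distribution(143, 20)
        maternal = nominal_size_distribution(166, 20)
        sfs = {
            state: expected_short_fraction(state, 0.1, fetal, maternal, 150)
            for state in (FETAL_DEL, DIPLOID, FETAL_DUP)
        }
        assert sfs[FETAL_DEL] < sfs[DIPLOID] < sfs[FETAL_DUP]

    def test_duplication_bins_shift_positive_over_seeds(self):
        event = CNVEvent("chr2", 1_000_000, 2_000_000, FETAL_DUP)
        mean_z = []
        for seed in range(20):
            config = SimConfig(
                seed=seed, cnv_events=(event,), n_sites=10,
                fragments_per_site=0, fragments_per_bin=1000,
            )
            cohort = simulate_cohort(config)
            z = [
                size_shift_statistic(sf, cohort.reference)
                for sf in cohort.bins.iloc[10:20]["short_fraction"]
            ]
            mean_z.append(np.mean(z))
        assert np.mean(mean_z) > 0


class TestCallCNVs:
    def test_noise_free_diploid_emits_nothing(self):
        ref = _reference(20, sigma=0.01)
        calls = call_cnvs(_bins([1.0] * 20), 0.10, ref)
        assert calls == []

    def test_ten_bin_deletion_called_exactly(self):
        ratios = [1.0] * 20 + [0.95] * 10 + [1.0] * 20
        ref = _reference(50, sigma=0.01)
        calls = call_cnvs(_bins(ratios), 0.10, ref)
        assert len(calls) == 1
        call = calls[0]
        assert call.copy_state == FETAL_DEL
        assert (call.start, call.end) == (20 * 100_000, 30 * 100_000)
        assert call.n_bins == 10
        assert call.log_lr > 10

    def test_f_zero_warns_and_returns_empty(self):
        ref = _reference(10, sigma=0.01)
        with pytest.warns(UserWarning, match="indistinguishable"):
            assert call_cnvs(_bins([0.9] * 10), 0.0, ref) == []

    def test_deterministic_given_input(self, rng):
        bins, ref = simulate_ratio_bins(50, 0.03, 0.10, rng, event_bins=(10, 20))
        first = calls_to_frame(call_cnvs(bins, 0.10, ref))
        second = calls_to_frame(call_cnvs(bins, 0.10, ref))
        pd.testing.assert_frame_equal(first, second)

    def test_calls_do_not_overlap(self, rng):
        ratios = [1.0] * 5 + [0.95] * 8 + [1.0] * 5 + [1.05] * 8 + [1.0] * 5
        ref = _reference(31, sigma=0.01)
        calls = call_cnvs(_bins(ratios), 0.10, ref)
        assert [c.copy_state for c in calls] == [FETAL_DEL, FETAL_DUP]
        assert calls[0].end <= calls[1].start

    def test_estimator_wrapper_and_vcf_output(self, tmp_path, rng):
        bins, ref = simulate_ratio_bins(
            50, 0.02, 0.10, rng, event_bins=(30, 40), event_state=FETAL_DUP
        )
        caller = CNVCaller(fetal_fraction=0.10).fit(ref)
        calls = caller.predict(bins)
        assert any(c.copy_state == FETAL_DUP for c in calls)
        out = tmp_path / "calls.vcf"
        write_calls_vcf(calls, out)
        body = [l for l in out.read_text().splitlines() if not l.startswith("#")]
        assert len(body) == len(calls)
        assert "<DUP>" in body[0] and "SVTYPE=DUP" in body[0]

    def test_gross_deviation_guard_flags_maternal_scale_shift(self):
        bins = _bins([1.0, 0.5, 1.0, 1.6])
        flags = flag_gross_deviations(bins)
        assert list(flags) == [False, True, False, False]
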