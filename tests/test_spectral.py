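"""Spectrum computation, RR peak picking, harmonic rejection, HR voting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from uwbvitals import (
    AlgorithmConfig,
    NoHeartRateError,
    NoRespirationError,
    PeakCandidate,
    Spectrum,
    VitalSignal,
    VoteTally,
    compute_spectrum,
    conventional_hr,
    estimate_rr,
    find_hr_candidates,
    reject_harmonics,
    select_hr,
    update_tally,
)

FPS = 92.71


def tone_signal(freqs_cpm, amps, duration_s=40.0, fps=FPS):
    t = np.arange(int(duration_s * fps)) / fps
    x = sum(
        a * np.sin(2 * np.pi * (f / 60.0) * t) for f, a in zip(freqs_cpm, amps)
    )
    return VitalSignal(values=x, frame_rate_hz=fps)


def spectrum_from_peaks(peak_locs, peak_mags, lo=40, hi=130):
    """Triangular peaks on an integer-bpm frequency grid."""
    freqs = np.arange(lo, hi, 1.0)
    mags = np.zeros_like(freqs)
    for loc, mag in zip(peak_locs, peak_mags):
        i = int(loc - lo)
        mags[i] = mag
        mags[i - 1] = max(mags[i - 1], 0.3 * mag)
        mags[i + 1] = max(mags[i + 1], 0.3 * mag)
    return Spectrum(freqs_cpm=freqs, mags=mags)


class TestComputeSpectrum:
    def test_pure_tone_argmax_within_resolution(self):
        spec = compute_spectrum(tone_signal([18], [1.0]))
        peak = spec.freqs_cpm[np.argmax(spec.mags)]
        assert abs(peak - 18.0) <= spec.resolution_cpm

    def test_two_tones_give_two_local_maxima(self):
        spec = compute_spectrum(tone_signal([18, 70], [1.0, 0.5]))
        for target in (18.0, 70.0):
            idx = np.argmin(np.abs(spec.freqs_cpm - target))
            window = spec.mags[idx - 40 : idx + 40]
            peak = spec.freqs_cpm[idx - 40 + np.argmax(window)]
            assert abs(peak - target) <= 1.0

    def test_parseval_identity_unpadded(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=1024)
        x -= x.mean()
        sig = VitalSignal(values=x, frame_rate_hz=FPS)
        spec = compute_spectrum(sig, AlgorithmConfig(pad_factor=1))
        # one-sided accounting: double every bin except DC and Nyquist
        power = (
            np.sum(2 * spec.mags**2) - spec.mags[0] ** 2 - spec.mags[-1] ** 2
        )
        assert np.sum(x**2) == pytest.approx(power / x.size, rel=1e-6)

    def test_constant_signal_gives_zero_spectrum_off_dc(self):
        sig = VitalSignal(values=np.full(512, 2.0), frame_rate_hz=FPS)
        spec = compute_spectrum(sig)
        off_dc = spec.freqs_cpm > 5.0
        assert np.allclose(spec.mags[off_dc], 0.0, atol=1e-8)


class TestEstimateRR:
    def test_in_band_tone_recovered(self):
        spec = compute_spectrum(tone_signal([18], [1.0]))
        assert estimate_rr(spec) == 18

    def test_out_of_band_tone_raises(self):
        spec = compute_spectrum(tone_signal([40], [1.0]))
        # the 40-cpm tone leaks only sidelobes into 10-30; a pure tone
        # elsewhere must not produce a confident in-band answer equal to it
        rr = None
        try:
            rr = estimate_rr(spec)
        except NoRespirationError:
            pass
        assert rr != 40

    def test_zero_spectrum_raises(self):
        spec = Spectrum(freqs_cpm=np.arange(5, 40, 1.0), mags=np.zeros(35))
        with pytest.raises(NoRespirationError):
            estimate_rr(spec)


class TestFindCandidates:
    def test_three_strongest_of_six_peaks(self):
        spec = spectrum_from_peaks(
            [54, 62, 70, 72, 82, 90], [5.0, 2.0, 4.0, 4.5, 3.0, 1.0]
        )
        cands = find_hr_candidates(spec)
        assert [c.loc_bpm for c in cands] == [54, 72, 70]

    def test_brute_force_local_maxima_agreement(self):
        rng = np.random.default_rng(7)
        config = AlgorithmConfig(k_peaks=100)
        for _ in range(20):
            freqs = np.arange(40.0, 130.0)
            mags = rng.random(freqs.size)
            spec = Spectrum(freqs_cpm=freqs, mags=mags)
            got = sorted(c.loc_bpm for c in find_hr_candidates(spec, config))
            expected = sorted(
                int(freqs[i])
                for i in range(1, freqs.size - 1)
                if mags[i] > mags[i - 1]
                and mags[i] > mags[i + 1]
                and 48 <= freqs[i] <= 120
            )
            assert got == expected

    def test_flat_spectrum_gives_empty_list(self):
        spec = Spectrum(freqs_cpm=np.arange(40, 130, 1.0), mags=np.ones(90))
        assert find_hr_candidates(spec) == []

    def test_single_in_band_peak(self):
        spec = spectrum_from_peaks([66], [2.0])
        cands = find_hr_candidates(spec)
        assert [c.loc_bpm for c in cands] == [66]


class TestRejectHarmonics:
    def test_integer_multiples_of_18_discarded(self):
        cands = [PeakCandidate(loc, 1.0) for loc in (54, 72, 90)]
        assert reject_harmonics(cands, rr_cpm=18, tol_bpm=1.0) == []

    def test_heartbeat_two_away_from_multiple_survives(self):
        cands = [PeakCandidate(70, 1.0)]
        assert reject_harmonics(cands, rr_cpm=18, tol_bpm=1.0) == cands

    def test_zero_tolerance_keeps_near_multiple(self):
        cands = [PeakCandidate(71, 1.0)]
        assert reject_harmonics(cands, rr_cpm=18, tol_bpm=0.0) == cands

    def test_nonpositive_rr_rejected(self):
        with pytest.raises(ValueError):
            reject_harmonics([PeakCandidate(70, 1.0)], rr_cpm=0.0)

    @settings(max_examples=200, deadline=None)
    @given(
        rr=st.integers(min_value=10, max_value=30),
        locs=st.lists(st.integers(min_value=48, max_value=120), max_size=6),
        tol=st.floats(min_value=0.0, max_value=3.0),
    )
    def test_matches_exhaustive_multiple_scan(self, rr, locs, tol):
        cands = [PeakCandidate(loc, 1.0) for loc in locs]
        got = {c.loc_bpm for c in reject_harmonics(cands, rr, tol)}
        expected = {
            loc
            for loc in locs
            if all(abs(loc - k * rr) > tol for k in range(2, 14))
        }
        assert got == expected


class TestVoteTally:
    def test_empty_survivors_only_advance_iteration(self):
        tally = VoteTally(n_iterations=20)
        out = update_tally(tally, [])
        assert out.counts == {}
        assert out.iterations_done == 1

    def test_repeated_location_reaches_full_count(self):
        tally = VoteTally(n_iterations=20)
        for _ in range(20):
            tally = update_tally(tally, [PeakCandidate(70, 2.0)])
        assert tally.counts == {70: 20}
        assert tally.mag_sums[70] == pytest.approx(40.0)

    def test_sliding_window_retires_oldest_iteration(self):
        tally = VoteTally(n_iterations=3)
        tally = update_tally(tally, [PeakCandidate(60, 1.0)])
        for _ in range(3):
            tally = update_tally(tally, [PeakCandidate(70, 1.0)])
        assert tally.counts == {70: 3}  # the 60-vote retired
        assert tally.iterations_done == 4

    def test_counts_bounded_by_window(self):
        tally = VoteTally(n_iterations=5)
        for _ in range(12):
            tally = update_tally(tally, [PeakCandidate(70, 1.0)])
        assert max(tally.counts.values()) <= 5


class TestSelectHR:
    def test_highest_occurrence_wins(self):
        tally = VoteTally.from_counts({57: 12, 62: 8, 70: 19, 82: 13})
        assert select_hr(tally) == 70
        assert max(tally.counts.values()) == 19

    def test_tie_breaks_on_mean_magnitude(self):
        tally = VoteTally.from_counts(
            {60: 5, 80: 5}, mag_means={60: 1.0, 80: 2.0}
        )
        assert select_hr(tally) == 80

    def test_single_entry(self):
        tally = VoteTally.from_counts({66: 1})
        assert select_hr(tally) == 66

    def test_empty_tally_raises(self):
        with pytest.raises(NoHeartRateError):
            select_hr(VoteTally())

    def test_adjacent_bins_merge_into_stronger(self):
        # jittered votes at 70/71 must not lose to a clean 62
        tally = VoteTally.from_counts(
            {70: 8, 71: 6, 62: 10}, mag_means={70: 3.0, 71: 2.0, 62: 1.0}
        )
        assert select_hr(tally) == 70


class TestConventionalBaseline:
    def test_argmax_follows_strongest_in_band_peak(self):
        spec = spectrum_from_peaks([54, 70], [5.0, 1.0])
        assert conventional_hr(spec) == 54
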