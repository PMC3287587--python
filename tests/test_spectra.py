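"""Power spectra, Parseval/symmetry invariants and windowed tracks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqspectra import (
    RepeatUnitSpec,
    SymbolicSequence,
    channel_dft_power,
    combined_power_spectrum,
    encode_binary,
    encode_flexibility,
    flexibility_power_spectrum,
    generate_repeat_sequence,
    rect_train_power_oracle,
    windowed_power_track,
)

nucleotide_text = st.text(alphabet="ACGT", min_size=1, max_size=300)


class TestChannelDftPower:
    def test_delta_has_flat_spectrum(self):
        spec = channel_dft_power([1, 0, 0, 0])
        np.testing.assert_allclose(spec.combined_power, [1, 1, 1])
        np.testing.assert_allclose(spec.frequencies, [0, 0.25, 0.5])

    def test_delta_train_comb(self):
        """80 repeats of a 21-nt unit with one C: power R^2 on the comb, 0 off it."""
        seq = generate_repeat_sequence(RepeatUnitSpec(21, "C", 1, "A", 80))
        power = channel_dft_power(encode_binary(seq).channel("C")).combined_power
        comb_bins = 80 * np.arange(1, 11)
        np.testing.assert_allclose(power[comb_bins], 6400.0, rtol=1e-9)
        off = np.ones(len(power), dtype=bool)
        off[comb_bins] = False
        off[0] = False
        np.testing.assert_allclose(power[off], 0.0, atol=1e-6)

    def test_centered_constant_is_dc_only(self):
        x = np.full(64, 3.0)
        spec = channel_dft_power(x - x.mean())
        np.testing.assert_allclose(spec.combined_power[1:], 0.0, atol=1e-9)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            channel_dft_power([])


class TestCombinedSpectrum:
    def test_acgt_flat_combined(self):
        spec = combined_power_spectrum(encode_binary(SymbolicSequence("ACGT", "nucleotide")))
        np.testing.assert_allclose(spec.combined_power, [4, 4, 4])

    @given(nucleotide_text)
    def test_parseval_per_channel_and_combined(self, symbols):
        """Full-grid power sums: N per channel count, N^2 combined."""
        channels = encode_binary(SymbolicSequence(symbols, "nucleotide"))
        spec = combined_power_spectrum(channels)
        n = len(symbols)
        for label in "ACGT":
            count = symbols.count(label)
            assert spec.total_power(label) == pytest.approx(n * count, rel=1e-9, abs=1e-6)
        assert spec.total_power() == pytest.approx(n * n, rel=1e-9)

    @given(st.text(alphabet="ACGT", min_size=2, max_size=200), st.integers(0, 199))
    def test_cyclic_shift_invariance(self, symbols, shift):
        shift %= len(symbols)
        rotated = symbols[shift:] + symbols[:shift]
        a = combined_power_spectrum(encode_binary(SymbolicSequence(symbols, "nucleotide")))
        b = combined_power_spectrum(encode_binary(SymbolicSequence(rotated, "nucleotide")))
        np.testing.assert_allclose(a.combined_power, b.combined_power, rtol=1e-9, atol=1e-6)

    @given(nucleotide_text)
    def test_reverse_complement_invariance(self, symbols):
        """Reversal conjugates the transform; complementation swaps A<->T, C<->G."""
        seq = SymbolicSequence(symbols, "nucleotide", "s")
        a = combined_power_spectrum(encode_binary(seq))
        b = combined_power_spectrum(encode_binary(seq.reverse_complement()))
        np.testing.assert_allclose(a.combined_power, b.combined_power, rtol=1e-9, atol=1e-6)

    def test_mismatched_channel_lengths_rejected(self):
        from seqspectra import IndicatorChannels

        with pytest.raises(ValueError):
            IndicatorChannels(labels=("A", "C"), data=np.zeros((3, 4)))


class TestFlexibilitySpectrum:
    def test_constant_profile_centered_is_silent(self):
        profile = encode_flexibility(SymbolicSequence("A" * 40, "nucleotide"))
        spec = flexibility_power_spectrum(profile)
        np.testing.assert_allclose(spec.combined_power, 0.0, atol=1e-9)

    def test_alternating_profile_peaks_at_half(self):
        # ATAT... alternates ApT (1.83) / TpA (2.42): one peak at f = 1/2
        profile = encode_flexibility(SymbolicSequence("AT" * 32, "nucleotide"))
        spec = flexibility_power_spectrum(profile)
        nondc = spec.combined_power[1:]
        assert spec.frequencies[1 + int(np.argmax(nondc))] == pytest.approx(0.5, abs=0.01)

    def test_masked_profile_rejected(self):
        profile = encode_flexibility(SymbolicSequence("ACNGT", "nucleotide"))
        with pytest.raises(ValueError, match="split"):
            flexibility_power_spectrum(profile)

    def test_overtones_weaker_than_binary_comb(self, example_seq):
        """Re-encoding the repeat with the smooth mapping weakens the comb:
        fewer overtones clear the detection threshold than under binary."""
        from seqspectra import comb_powers, detect_overtones, repeated_consensus

        seq = repeated_consensus(example_seq, 80)
        p = len(example_seq)
        binary = detect_overtones(
            comb_powers(combined_power_spectrum(encode_binary(seq)), p)
        )
        flex = detect_overtones(
            comb_powers(flexibility_power_spectrum(encode_flexibility(seq)), p)
        )
        assert binary.n_detected == p // 2  # the spike train carries the full comb
        assert flex.n_detected < binary.n_detected


@settings(max_examples=20)
@given(st.integers(2, 12), st.integers(1, 12), st.sampled_from([5, 80]))
def test_rect_train_matches_oracle(p, m, r):
    """FFT comb powers equal the geometric-sum closed form."""
    m = min(m, p)
    seq = generate_repeat_sequence(RepeatUnitSpec(p, "C", m, "A", r))
    power = channel_dft_power(encode_binary(seq).channel("C")).combined_power
    for k in range(1, p // 2 + 1):
        expected = rect_train_power_oracle(p, m, r, k)
        assert power[r * k] == pytest.approx(expected, rel=1e-9, abs=1e-6)


class TestWindowedTrack:
    def test_all_zero_window(self):
        track = windowed_power_track(np.zeros(100), 50, 1 / 21)
        np.testing.assert_allclose(track.powers, 0.0, atol=1e-12)

    def test_pure_periodic_region_closed_form(self):
        """Single-C 21-periodic signal, w a multiple of 21: power (w/21)^2."""
        seq = generate_repeat_sequence(RepeatUnitSpec(21, "C", 1, "A", 100))
        series = encode_binary(seq).channel("C")
        track = windowed_power_track(series, 21 * 20, 1 / 21)
        np.testing.assert_allclose(track.powers, 400.0, rtol=1e-9)

    def test_integer_bin_equals_window_fft(self, rng):
        series = rng.normal(size=500)
        w, l = 100, 7
        track = windowed_power_track(series, w, l / w)
        for i, start in enumerate(track.starts):
            bin_power = np.abs(np.fft.fft(series[start : start + w])[l]) ** 2
            assert track.powers[i] == pytest.approx(bin_power, rel=1e-9)

    def test_step_and_bounds(self):
        track = windowed_power_track(np.zeros(105), 50, 0.25, step=10)
        assert track.starts.tolist() == [0, 10, 20, 30, 40, 50]

    def test_snap_to_bin(self):
        track = windowed_power_track(np.zeros(100), 100, 1 / 21, snap_to_bin=True)
        assert track.frequency == pytest.approx(5 / 100)

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError):
            windowed_power_track(np.zeros(10), 11, 0.25)

    def test_localizes_planted_block(self):
        """Track maximum at f = 1/21 lands on a planted repeat block."""
        from seqspectra import PlantedBlock, PlantedGenomeSpec, generate_planted_genome

        unit = "CTTAACTAACATAGGTCTTAA"
        spec = PlantedGenomeSpec(
            length=50_000, blocks=(PlantedBlock(unit, 50, 1000),), seed=7
        )
        seq, truth = generate_planted_genome(spec)
        channels = encode_binary(seq)
        powers = None
        for row in channels.data:
            t = windowed_power_track(row, 1000, 1 / 21)
            powers = t.powers if powers is None else powers + t.powers
        start = t.starts[int(np.argmax(powers))]
        assert truth[0].start - 1000 <= start <= truth[0].end + 1000
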