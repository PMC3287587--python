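"""Discrete Fourier power spectra and position-dependent power tracks.

Conventions
-----------
The forward transform is the unnormalized sum
``U(j) = sum_n x_n exp(-2*pi*i*j*n/L)`` and power is ``|U(j)|**2`` with no
1/L scaling; published spectra of this kind are in arbitrary units, and
the unnormalized choice keeps closed forms integer-valued for binary
inputs (e.g. a train of R isolated ones has comb power exactly R**2).
Frequencies are reported in cycles per position on the half grid
``j = 0 .. floor(L/2)``; full-grid conjugate symmetry is asserted before
truncation.  The DC bin (j = 0) is computed but excluded from peak
detection downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mappings import FlexibilityProfile, IndicatorChannels


@dataclass(frozen=True)
class PowerSpectrum:
    """Half-grid power spectrum with per-channel and combined powers.

    ``frequencies[j] = j / n_points`` for ``j = 0 .. floor(n_points/2)``;
    ``combined_power`` is the sum of the per-channel powers (equal to the
    single channel's power for one-channel spectra).
    """

    n_points: int
    frequencies: np.ndarray
    channel_powers: dict  # label -> power array on the half grid
    combined_power: np.ndarray
    name: str = ""

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.channel_powers)

    def total_power(self, label: str | None = None) -> float:
        """Full-grid power sum (for Parseval checks), from the half grid.

        Interior bins count twice (conjugate pair); DC and, for even
        lengths, the Nyquist bin count once.
        """
        p = self.combined_power if label is None else self.channel_powers[label]
        total = 2.0 * p.sum() - p[0]
        if self.n_points % 2 == 0 and self.n_points > 0:
            total -= p[-1]
        return float(total)


def _half_grid_power(series: np.ndarray) -> tuple[int, np.ndarray, np.ndarray]:
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("series must be a non-empty 1-D array")
    if np.isnan(x).any():
        raise ValueError(
            "series contains NaN (masked ambiguity); split the sequence into "
            "unambiguous segments before computing a spectrum"
        )
    n = x.size
    power_full = np.abs(np.fft.fft(x)) ** 2
    # conjugate symmetry of the transform of a real series
    if not np.allclose(power_full[1:], power_full[:0:-1], rtol=1e-9, atol=1e-6):
        raise AssertionError("full-grid power spectrum lost conjugate symmetry")
    half = power_full[: n // 2 + 1]
    freqs = np.arange(n // 2 + 1) / n
    return n, freqs, half


def channel_dft_power(series: np.ndarray, label: str = "x", name: str = "") -> PowerSpectrum:
    """Power spectrum of a single binary or numeric series."""
    n, freqs, power = _half_grid_power(series)
    return PowerSpectrum(
        n_points=n,
        frequencies=freqs,
        channel_powers={label: power},
        combined_power=power,
        name=name,
    )


def combined_power_spectrum(channels: IndicatorChannels) -> PowerSpectrum:
    """Sum of per-channel indicator power spectra.

    Each channel is transformed independently and the powers are added;
    per-channel powers are retained so individual symbols' contributions
    to a comb can be inspected.
    """
    if channels.n == 0:
        raise ValueError("cannot compute a spectrum of an empty sequence")
    per_channel: dict[str, np.ndarray] = {}
    combined: np.ndarray | None = None
    n_points = freqs = None
    for label, row in zip(channels.labels, channels.data):
        n_points, freqs, power = _half_grid_power(row)
        per_channel[label] = power
        combined = power if combined is None else combined + power
    return PowerSpectrum(
        n_points=n_points,
        frequencies=freqs,
        channel_powers=per_channel,
        combined_power=combined,
        name=channels.name,
    )


def flexibility_power_spectrum(
    profile: FlexibilityProfile, center: bool = True
) -> PowerSpectrum:
    """Single-channel power spectrum of a flexibility profile.

    The profile mean (~2.4 eV/nm^2) is subtracted by default: its spectral
    leakage would otherwise swamp the low-frequency bins of interest.
    """
    if profile.m == 0:
        raise ValueError("empty flexibility profile")
    values = profile.values
    if np.isnan(values).any():
        raise ValueError(
            "profile contains masked (NaN) steps; split at ambiguity first"
        )
    if center:
        values = values - values.mean()
    return channel_dft_power(values, label="flexibility", name=profile.name)


@dataclass(frozen=True)
class WindowedTrack:
    """Power at one fixed frequency in windows along a series."""

    window_size: int
    step: int
    frequency: float
    starts: np.ndarray
    powers: np.ndarray
    name: str = ""

    def argmax_start(self) -> int:
        return int(self.starts[int(np.argmax(self.powers))])


def windowed_power_track(
    series: np.ndarray,
    w: int,
    f: float,
    step: int | None = None,
    snap_to_bin: bool = False,
    name: str = "",
) -> WindowedTrack:
    """Position-dependent power at frequency ``f`` in windows of size ``w``.

    For each window start ``p`` (``p = 0, step, 2*step, ...`` while
    ``p + w <= len(series)``) the power is
    ``|sum_{n=p}^{p+w-1} x_n exp(-2*pi*i*f*(n-p))|**2``.  The phase is
    referenced to the window start so values are translation-comparable.
    By default the *exact* requested frequency is evaluated by direct
    summation (Goertzel-style) — monitored comb frequencies like k/21 are
    generally not bins of a w = 1000 window — while ``snap_to_bin=True``
    rounds ``f`` to the nearest window bin ``l/w`` for comparison.
    """
    x = np.asarray(series, dtype=float)
    if not 1 <= w <= x.size:
        raise ValueError(f"window size {w} must be in [1, {x.size}]")
    if not 0 < f <= 0.5:
        raise ValueError("frequency must be in (0, 1/2] cycles per position")
    if step is None:
        step = w
    if step < 1:
        raise ValueError("step must be >= 1")
    if snap_to_bin:
        f = round(f * w) / w
    phasor = np.exp(-2j * np.pi * f * np.arange(w))
    windows = np.lib.stride_tricks.sliding_window_view(x, w)[::step]
    amplitudes = windows @ phasor
    starts = np.arange(windows.shape[0]) * step
    return WindowedTrack(
        window_size=w,
        step=step,
        frequency=f,
        starts=starts,
        powers=np.abs(amplitudes) ** 2,
        name=name,
    )


def write_spectrum_tsv(spectrum: PowerSpectrum, path, comments: list[str] | None = None) -> None:
    """Write a spectrum as TSV: frequency, combined, then one column per channel."""
    with open(path, "w") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        fh.write("frequency\tcombined\t" + "\t".join(spectrum.labels) + "\n")
        cols = [spectrum.channel_powers[l] for l in spectrum.labels]
        for i, freq in enumerate(spectrum.frequencies):
            row = [f"{freq:.10g}", f"{spectrum.combined_power[i]:.10g}"]
            row += [f"{c[i]:.10g}" for c in cols]
            fh.write("\t".join(row) + "\n")


def write_track_tsv(track: WindowedTrack, path, comments: list[str] | None = None) -> None:
    """Write a windowed track as TSV: window_start, power."""
    with open(path, "w") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        fh.write("window_start\tpower\n")
        for start, power in zip(track.starts, track.powers):
            fh.write(f"{start}\t{power:.10g}\n")
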