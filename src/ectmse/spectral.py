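"""Hanning-windowed FFT power spectra and the alpha-dominance wakefulness check.

The conventional comparison analysis: each 30 s segment is split into 15
consecutive non-overlapping 2 s epochs, each epoch is Hann-tapered and
Fourier transformed, absolute power is averaged across epochs, and the
average is log10-transformed for reporting.  The 2 s epoch gives 0.5 Hz
frequency resolution.  Window power loss is compensated (division by the
mean squared window) so that white noise yields a flat spectrum at the
signal's variance level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import TimeSeriesSegment

__all__ = [
    "DEFAULT_BANDS",
    "PowerSpectrum",
    "power_spectrum",
    "band_power",
    "alpha_dominance_check",
]

#: Clinical EEG band edges in Hz, [lo, hi).
DEFAULT_BANDS = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 60.0),
}


@dataclass
class PowerSpectrum:
    """Epoch-averaged power spectrum of one segment.

    ``power`` is the absolute (pre-log) power per frequency bin;
    ``log_power`` its log10.  Frequencies ascend from 0 to the Nyquist.
    """

    freqs_hz: np.ndarray
    power: np.ndarray
    channel: str
    n_epochs: int
    log_base: float = 10.0

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs_hz.shape != self.power.shape:
            raise ValueError("freqs and power must have equal length")
        if np.any(np.diff(self.freqs_hz) <= 0) or self.freqs_hz[0] < 0:
            raise ValueError("frequencies must be non-negative and ascending")

    @property
    def log_power(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            if self.log_base == 10.0:
                return np.log10(self.power)
            return np.log(self.power) / np.log(self.log_base)

    @property
    def resolution_hz(self) -> float:
        return float(self.freqs_hz[1] - self.freqs_hz[0])


def power_spectrum(
    seg: TimeSeriesSegment, epoch_s: float = 2.0, log_base: float = 10.0
) -> PowerSpectrum:
    """Epoch-averaged Hann-windowed power spectrum of a segment.

    The segment must partition exactly into whole ``epoch_s`` epochs (the
    canonical 30 s segment gives 15).  Per epoch the Hann taper is applied,
    the squared magnitude of the real FFT is normalized by the window's
    power (sum of squared window values) so a white-noise input is flat at
    its variance, one-sided bins are doubled, and powers are averaged over
    epochs.
    """
    x = np.asarray(seg.samples, dtype=float)
    n_ep = int(round(epoch_s * seg.sampling_rate_hz))
    if n_ep < 2:
        raise ValueError("epoch too short")
    if len(x) % n_ep != 0:
        raise ValueError(
            f"segment of {len(x)} samples does not partition into "
            f"{epoch_s} s epochs of {n_ep} samples"
        )
    n_epochs = len(x) // n_ep
    epochs = x.reshape(n_epochs, n_ep)
    window = np.hanning(n_ep)
    w2 = float(np.sum(window**2))
    spec = np.fft.rfft(epochs * window, axis=1)
    power = np.abs(spec) ** 2 / w2
    # one-sided: double all bins except DC (and Nyquist for even epoch length)
    power[:, 1:] *= 2.0
    if n_ep % 2 == 0:
        power[:, -1] /= 2.0
    freqs = np.fft.rfftfreq(n_ep, d=1.0 / seg.sampling_rate_hz)
    return PowerSpectrum(
        freqs_hz=freqs,
        power=power.mean(axis=0),
        channel=seg.channel,
        n_epochs=n_epochs,
        log_base=log_base,
    )


def band_power(ps: PowerSpectrum, band: tuple[float, float]) -> float:
    """Mean absolute (pre-log) power over bins with lo <= f < hi."""
    lo, hi = band
    if not lo < hi:
        raise ValueError(f"invalid band ({lo}, {hi})")
    mask = (ps.freqs_hz >= lo) & (ps.freqs_hz < hi)
    if not mask.any():
        raise ValueError(f"band ({lo}, {hi}) Hz contains no spectral bins")
    return float(ps.power[mask].mean())


def alpha_dominance_check(
    ps_o1: PowerSpectrum,
    ps_o2: PowerSpectrum,
    ratio_threshold: float = 1.0,
    bands: dict[str, tuple[float, float]] = DEFAULT_BANDS,
) -> bool:
    """Eyes-closed wakefulness check: posterior alpha dominance.

    True iff, in both occipital spectra, mean alpha-band power exceeds
    ``ratio_threshold`` times the mean of the flanking theta- and beta-band
    powers.  An automated stand-in for visual confirmation of a posterior
    dominant rhythm.
    """
    for ps in (ps_o1, ps_o2):
        alpha = band_power(ps, bands["alpha"])
        flank = 0.5 * (band_power(ps, bands["theta"]) + band_power(ps, bands["beta"]))
        if not alpha > ratio_threshold * flank:
            return False
    return True
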