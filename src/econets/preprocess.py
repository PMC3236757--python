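"""Preprocessing and Morlet band decomposition of multichannel recordings.

The chain mirrors standard resting/task EEG practice: re-reference to
digitally linked earlobes, linear detrend per epoch, anti-aliased
downsampling, extraction of fixed-length artifact-free epochs, and a
continuous Morlet wavelet decomposition summed over in-band scales to give a
band-limited time series per channel (alpha, beta, gamma by default).

Every step is linear, so the whole chain is linear in the input signal.
"""

from __future__ import annotations

import numpy as np
import scipy.signal

from .signals import Band, BandSeries, EpochSet, MultichannelRecording

__all__ = [
    "rereference_linked_earlobes",
    "detrend_linear",
    "downsample",
    "extract_epochs",
    "morlet_center_frequencies",
    "morlet_band_series",
]


def rereference_linked_earlobes(
    rec: MultichannelRecording, a1_label: str = "A1"
) -> MultichannelRecording:
    """Re-reference an A2-referenced recording to digitally linked earlobes.

    With A2 as the (implicit, zero) recording reference, referencing to the
    average (A1+A2)/2 amounts to subtracting half of the recorded A1 channel
    from every scalp channel.  The A1 channel is dropped from the output.

    Parameters
    ----------
    rec : recording referenced to A2, containing an ``a1_label`` channel.
    a1_label : name of the recorded left-earlobe channel.
    """
    if a1_label not in rec.labels:
        raise KeyError(f"channel {a1_label!r} not found in recording")
    idx = rec.labels.index(a1_label)
    a1 = rec.data[idx]
    keep = [i for i in range(rec.n_channels) if i != idx]
    data = rec.data[keep] - a1 / 2.0
    labels = tuple(rec.labels[i] for i in keep)
    return MultichannelRecording(data=data, fs=rec.fs, labels=labels, reference="linked-earlobes")


def detrend_linear(epochs: EpochSet) -> EpochSet:
    """Remove the per-epoch, per-channel least-squares linear trend.

    After detrending each epoch/channel has zero mean and zero least-squares
    slope (to numerical precision).
    """
    if epochs.n_samples < 2:
        raise ValueError("detrending requires at least 2 samples per epoch")
    data = scipy.signal.detrend(epochs.data, axis=-1, type="linear")
    return EpochSet(data=data, fs=epochs.fs, labels=epochs.labels)


def downsample(rec: MultichannelRecording, factor: int) -> MultichannelRecording:
    """Anti-alias low-pass filter then keep every ``factor``-th sample.

    Uses a zero-phase FIR decimator (cutoff below the new Nyquist).  The
    output length is ``floor(n_samples / factor)`` and the sampling rate is
    divided by ``factor``.  ``factor == 1`` is the identity.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError(f"downsampling factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return rec.copy_with(data=rec.data.copy())
    data = scipy.signal.decimate(rec.data, factor, ftype="fir", zero_phase=True, axis=-1)
    data = data[:, : rec.n_samples // factor]
    return MultichannelRecording(
        data=data, fs=rec.fs / factor, labels=rec.labels, reference=rec.reference
    )


def extract_epochs(rec: MultichannelRecording, n_epochs: int, epoch_len: float) -> EpochSet:
    """Cut the first ``n_epochs`` consecutive non-overlapping windows.

    ``epoch_len`` is in seconds and must correspond to an integer number of
    samples.  ``n_epochs == 0`` yields a valid empty EpochSet.
    """
    if n_epochs < 0:
        raise ValueError("n_epochs must be non-negative")
    n_samp = epoch_len * rec.fs
    if abs(n_samp - round(n_samp)) > 1e-9:
        raise ValueError(f"epoch_len {epoch_len} s is not an integer number of samples at {rec.fs} Hz")
    n_samp = int(round(n_samp))
    needed = n_epochs * n_samp
    if rec.n_samples < needed:
        raise ValueError(
            f"insufficient data: need {needed} samples for {n_epochs} epochs of "
            f"{epoch_len} s, recording has {rec.n_samples}"
        )
    data = rec.data[:, :needed].reshape(rec.n_channels, n_epochs, n_samp).transpose(1, 0, 2)
    return EpochSet(data=data.copy(), fs=rec.fs, labels=rec.labels)


def morlet_center_frequencies(band: Band, voices_per_octave: int = 4) -> np.ndarray:
    """Logarithmically spaced wavelet center frequencies covering [low, high).

    Frequencies are ``low * 2**(k / voices_per_octave)`` for k = 0, 1, ...
    while below ``high``.
    """
    if voices_per_octave < 1:
        raise ValueError("voices_per_octave must be >= 1")
    freqs = []
    k = 0
    while True:
        f = band.low * 2.0 ** (k / voices_per_octave)
        if f >= band.high:
            break
        freqs.append(f)
        k += 1
    return np.asarray(freqs)


def morlet_band_series(
    epochs: EpochSet,
    band: Band,
    omega0: float = 6.0,
    voices_per_octave: int = 4,
    mode: str = "real",
) -> BandSeries:
    """Morlet wavelet decomposition summed over in-band scales.

    The continuous Morlet transform (dimensionless center frequency
    ``omega0``, i.e. ``n_cycles = omega0`` in the mne parameterization) is
    evaluated at log-spaced center frequencies covering ``[low, high)`` and
    the coefficients are summed across scales.  ``mode="real"`` (default)
    returns the sum of real parts — a band-limited reconstruction of the
    signal; ``mode="magnitude"`` returns the summed coefficient magnitudes
    (an amplitude envelope).

    Edge effects are mitigated by symmetric padding of five Gaussian
    standard deviations of the longest (lowest-frequency) wavelet, cropped
    after the transform.
    """
    band.validate_against(epochs.fs)
    if omega0 <= 0:
        raise ValueError("omega0 must be positive")
    if mode not in ("real", "magnitude"):
        raise ValueError(f"unknown mode {mode!r}")
    if epochs.n_epochs == 0:
        return BandSeries(data=epochs.data.copy(), band=band, fs=epochs.fs, labels=epochs.labels)

    from mne.time_frequency import tfr_array_morlet

    freqs = morlet_center_frequencies(band, voices_per_octave)
    # half-support of the longest wavelet: 5 * sigma_t at the lowest frequency
    sigma_t = omega0 / (2.0 * np.pi * freqs[0])
    pad = int(np.ceil(5.0 * sigma_t * epochs.fs))
    pad = min(pad, epochs.n_samples - 1)
    padded = np.pad(epochs.data, ((0, 0), (0, 0), (pad, pad)), mode="symmetric")

    coef = tfr_array_morlet(
        padded, sfreq=epochs.fs, freqs=freqs, n_cycles=omega0, output="complex", verbose="error"
    )
    coef = coef[..., pad : pad + epochs.n_samples]
    if mode == "real":
        out = coef.real.sum(axis=2)
    else:
        out = np.abs(coef).sum(axis=2)
    return BandSeries(data=out, band=band, fs=epochs.fs, labels=epochs.labels)
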