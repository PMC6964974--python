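"""Spectral predictor extraction: Hann-tapered FFT power in 1 Hz steps.

Each trial and channel is demeaned and linearly detrended, multiplied by a
single Hann taper, and Fourier transformed.  Power (squared magnitude) at the
requested integer frequencies forms the predictor matrix: one column per
(channel, frequency) pair, channel-major.  With the conventional 122-channel
montage and frequencies 1-40 Hz this yields 4880 predictors.

A 3 s epoch has native resolution 1/3 Hz, so integer-Hz values must be reduced
from several native bins.  The default mode ``"bin_average"`` averages native
bin power over ``[f - 0.5, f + 0.5)`` Hz; ``"nearest_bin"`` takes the single
closest bin instead.  The taper is not amplitude-compensated — power values
are in arbitrary units, which leaves cross-condition contrasts unaffected.

Band and ROI groupings of the resulting predictors are built by
:func:`band_groups` and :func:`roi_groups`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .types import (
    ChannelLayout,
    FeatureMatrix,
    GroupSpec,
    PredictorMeta,
    TrialEpochs,
    ValidationError,
)

__all__ = [
    "BandDefinition",
    "DEFAULT_BANDS",
    "detrend_demean",
    "power_spectrum",
    "band_groups",
    "roi_groups",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with inclusive integer bounds in Hz."""

    name: str
    lo_hz: int
    hi_hz: int

    def __post_init__(self) -> None:
        if not (1 <= self.lo_hz <= self.hi_hz <= 40):
            raise ValidationError(
                f"band {self.name!r}: bounds [{self.lo_hz}, {self.hi_hz}] "
                "must satisfy 1 <= lo <= hi <= 40"
            )

    def contains(self, f_hz: int) -> bool:
        return self.lo_hz <= f_hz <= self.hi_hz


#: Conventional EEG band partition of 1-40 Hz.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1, 4),
    BandDefinition("theta", 5, 7),
    BandDefinition("alpha", 8, 12),
    BandDefinition("beta", 13, 20),
    BandDefinition("gamma", 21, 40),
)


def detrend_demean(signal: np.ndarray) -> np.ndarray:
    """Remove the least-squares linear trend (and hence the mean).

    Operates on the last axis.  The output has zero mean and zero fitted
    slope on every series.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.shape[-1] < 2:
        raise ValidationError(
            f"signal: need at least 2 samples to detrend, got {signal.shape[-1]}"
        )
    return scipy.signal.detrend(signal, axis=-1, type="linear")


def power_spectrum(
    epochs: TrialEpochs,
    freqs_hz: list[int] | range = range(1, 41),
    mode: str = "bin_average",
    log10: bool = False,
    chunk_trials: int = 64,
) -> FeatureMatrix:
    """Per-trial, per-channel Hann-taper FFT power at integer frequencies.

    Parameters
    ----------
    epochs
        Epoched recordings; epoch duration must be >= 1 s so that 1 Hz is
        resolvable.
    freqs_hz
        Requested integer frequencies (Hz); all must lie at or below Nyquist.
    mode
        ``"bin_average"`` (default): mean native-bin power over
        ``[f - 0.5, f + 0.5)``; ``"nearest_bin"``: the single closest bin.
    log10
        If true, return ``log10(power + tiny)`` instead of raw power.
    chunk_trials
        Trials processed per FFT block (memory control only).

    Returns
    -------
    FeatureMatrix
        Columns ordered channel-major, frequency-minor; metadata carries
        (channel name, frequency).
    """
    freqs = [int(f) for f in freqs_hz]
    if any(f <= 0 for f in freqs):
        raise ValidationError(f"freqs_hz: frequencies must be positive, got {freqs}")
    nyquist = epochs.srate / 2.0
    too_high = [f for f in freqs if f > nyquist]
    if too_high:
        raise ValidationError(
            f"freqs_hz: {too_high} exceed the Nyquist frequency {nyquist:g} Hz"
        )
    if epochs.duration_s < 1.0:
        raise ValidationError(
            f"epochs: duration {epochs.duration_s:g} s < 1 s; 1 Hz not resolvable"
        )
    if mode not in ("bin_average", "nearest_bin"):
        raise ValidationError(f"mode: expected bin_average|nearest_bin, got {mode!r}")

    n_samples = epochs.n_samples
    taper = scipy.signal.windows.hann(n_samples, sym=False)
    native = np.fft.rfftfreq(n_samples, d=1.0 / epochs.srate)

    # Map each requested integer frequency to the native bins it reduces over.
    bin_sets: list[np.ndarray] = []
    for f in freqs:
        if mode == "bin_average":
            sel = np.flatnonzero((native >= f - 0.5) & (native < f + 0.5))
        else:
            sel = np.array([int(np.argmin(np.abs(native - f)))])
        if sel.size == 0:
            raise ValidationError(f"freqs_hz: no native FFT bin near {f} Hz")
        bin_sets.append(sel)

    n_trials, n_channels = epochs.n_trials, epochs.n_channels
    out = np.empty((n_trials, n_channels, len(freqs)), dtype=float)
    for start in range(0, n_trials, chunk_trials):
        block = slice(start, min(start + chunk_trials, n_trials))
        seg = detrend_demean(epochs.data[block]) * taper
        power = np.abs(np.fft.rfft(seg, axis=-1)) ** 2
        for k, sel in enumerate(bin_sets):
            out[block, :, k] = power[..., sel].mean(axis=-1)

    if log10:
        out = np.log10(out + np.finfo(float).tiny)

    X = out.reshape(n_trials, n_channels * len(freqs))
    meta = [
        PredictorMeta(channel_name=ch, frequency_hz=f)
        for ch in epochs.channel_names
        for f in freqs
    ]
    return FeatureMatrix(X=X, y=epochs.labels.copy(), meta=meta)


def band_groups(
    meta: list[PredictorMeta], bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
) -> GroupSpec:
    """Group predictor columns by frequency band (kind ``band``)."""
    freqs = np.array([m.frequency_hz if m.frequency_hz is not None else -1
                      for m in meta])
    groups, kinds = {}, {}
    for band in bands:
        idx = np.flatnonzero((freqs >= band.lo_hz) & (freqs <= band.hi_hz))
        if idx.size == 0:
            raise ValidationError(
                f"band {band.name!r}: no predictor in [{band.lo_hz}, {band.hi_hz}] Hz"
            )
        groups[band.name] = idx
        kinds[band.name] = "band"
    return GroupSpec(groups=groups, kinds=kinds, n_predictors=len(meta))


def roi_groups(meta: list[PredictorMeta], layout: ChannelLayout) -> GroupSpec:
    """Group predictor columns by the ROI of their source channel (kind ``roi``).

    Every channel appearing in the metadata must carry an ROI assignment in
    the layout; a missing assignment is an error naming the channel.
    """
    if layout.roi is None:
        raise ValidationError("layout: carries no ROI assignment")
    roi_of = dict(zip(layout.names, layout.roi))
    missing = sorted({m.channel_name for m in meta} - set(roi_of))
    if missing:
        raise ValidationError(f"layout: channels without ROI assignment: {missing}")
    groups: dict[str, list[int]] = {}
    for j, m in enumerate(meta):
        groups.setdefault(roi_of[m.channel_name], []).append(j)
    return GroupSpec(
        groups={k: np.asarray(v) for k, v in groups.items()},
        kinds={k: "roi" for k in groups},
        n_predictors=len(meta),
    )
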