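"""Resampling, band-pass decomposition, epoching and amplitude-based
artifact rejection.

All filtering is zero-phase (forward-backward FIR), which matters here
because a phase-lagged connectivity measure downstream would be biased by
any filter phase distortion. Filters are applied to the *continuous* record
before epoching so filter edge transients never fall inside the 1-s epochs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .containers import EpochSet, EventSchedule, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with inclusive corner frequencies in Hz."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0 < self.low_hz < self.high_hz):
            raise ValidationError(
                f"band {self.name}: need 0 < low < high, got "
                f"({self.low_hz}, {self.high_hz})"
            )

    @property
    def center_hz(self) -> float:
        return 0.5 * (self.low_hz + self.high_hz)


#: Conventional EEG bands. The wide band spans the union of the named bands.
BANDS: dict[str, BandDefinition] = {
    "wide": BandDefinition("wide", 1.0, 45.0),
    "delta": BandDefinition("delta", 1.0, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 13.0),
    "beta": BandDefinition("beta", 13.0, 30.0),
    "gamma": BandDefinition("gamma", 30.0, 45.0),
}


def resample(record: np.ndarray, orig_rate: float, target_rate: float) -> np.ndarray:
    """Anti-aliased polyphase down-sampling of a (channels, samples) record.

    Up-sampling is refused: the pipeline only ever reduces rate (e.g.
    1000 Hz acquisition down to 250 Hz analysis).
    """
    if target_rate > orig_rate:
        raise ValidationError(
            f"refusing to upsample from {orig_rate} to {target_rate} Hz"
        )
    if target_rate == orig_rate:
        return np.asarray(record, dtype=np.float64)
    frac = Fraction(target_rate / orig_rate).limit_denominator(10000)
    return sps.resample_poly(
        np.asarray(record, dtype=np.float64), frac.numerator, frac.denominator,
        axis=-1,
    )


def _design_fir(band: BandDefinition, sampling_rate: float) -> np.ndarray:
    nyq = sampling_rate / 2.0
    if band.high_hz >= nyq:
        raise ValidationError(
            f"band {band.name} upper edge {band.high_hz} Hz >= Nyquist {nyq} Hz"
        )
    # Transition width 25% of the low edge; Hamming window FIR.
    transition = 0.25 * band.low_hz
    numtaps = int(math.ceil(3.3 * sampling_rate / transition))
    numtaps += 1 - numtaps % 2  # odd length, linear phase type I
    return sps.firwin(
        numtaps, [band.low_hz, band.high_hz], pass_zero=False, fs=sampling_rate,
        window="hamming",
    )


def bandpass(x: np.ndarray, band: BandDefinition, sampling_rate: float) -> np.ndarray:
    """Zero-phase band-pass along the last axis; output length = input length."""
    x = np.asarray(x, dtype=np.float64)
    taps = _design_fir(band, sampling_rate)
    padlen = min(3 * len(taps), x.shape[-1] - 1)
    return sps.filtfilt(taps, [1.0], x, axis=-1, padlen=padlen)


def epoch(
    record: np.ndarray,
    schedule: EventSchedule,
    channel_names,
    sampling_rate: float,
    window: tuple[float, float] = (-0.2, 0.8),
    subject_id: str = "",
    group_label: str = "",
    band: str = "wide",
) -> EpochSet:
    """Cut target-locked epochs out of a (channels, samples) record.

    The window is half-open [start, stop): 1.0 s at 250 Hz gives exactly 250
    samples. The per-channel pre-stimulus mean is subtracted (baseline
    correction). Events whose window exceeds the record are dropped with a
    logged warning.
    """
    record = np.asarray(record, dtype=np.float64)
    n_ch, n_samp = record.shape
    w0, w1 = window
    n_win = int(round((w1 - w0) * sampling_rate))
    n_pre = int(round(-w0 * sampling_rate))
    trials = []
    dropped = 0
    for onset in schedule.target_onsets:
        start = int(onset) - n_pre
        stop = start + n_win
        if start < 0 or stop > n_samp:
            dropped += 1
            continue
        seg = record[:, start:stop].copy()
        if n_pre > 0:
            seg -= seg[:, :n_pre].mean(axis=1, keepdims=True)
        trials.append(seg)
    if dropped:
        logger.warning("dropped %d/%d target events outside record bounds",
                       dropped, schedule.n_targets)
    data = np.stack(trials) if trials else np.empty((0, n_ch, n_win))
    return EpochSet(
        data=data, channel_names=tuple(channel_names),
        sampling_rate=sampling_rate, subject_id=subject_id,
        group_label=group_label, window=window, band=band,
    )


def reject_artifacts(epochs: EpochSet, peak_to_peak_limit: float) -> EpochSet:
    """Drop trials whose any-channel peak-to-peak amplitude exceeds the limit (uV)."""
    if not peak_to_peak_limit > 0:
        raise ValidationError("peak_to_peak_limit must be positive")
    ptp = epochs.data.max(axis=2) - epochs.data.min(axis=2)  # trials x channels
    keep = (ptp <= peak_to_peak_limit).all(axis=1)
    if not keep.any():
        raise ValidationError(
            f"all {epochs.n_trials} trials exceed the {peak_to_peak_limit} uV "
            "peak-to-peak limit"
        )
    n_rej = int((~keep).sum())
    if n_rej:
        logger.info("rejected %d/%d trials above %g uV peak-to-peak",
                    n_rej, epochs.n_trials, peak_to_peak_limit)
    out = epochs.copy_with(data=epochs.data[keep],
                           trial_labels=epochs.trial_labels[keep])
    return out
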