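"""Phase-lag-index (PLI) network construction.

PLI between channels x and y is |<sign(dphi)>| where dphi is the
instantaneous phase difference wrapped to (-pi, pi] and <.> averages over
time samples within a trial. A value of 1 means the lag sign is perfectly
consistent (genuine lagged synchronization); 0 means no consistent lag.
Zero-lag coupling — the signature of volume conduction — contributes
sign(0)=0 and is therefore invisible to PLI, which is the reason it is used
for scalp-level networks.

Per-trial matrices are averaged to a subject matrix, subject matrices to a
group matrix; sparsification keeps the strongest fixed fraction of edges
(proportional / consistency threshold, default 30%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .containers import EpochSet, ValidationError


@dataclass
class PhaseSeries:
    """Instantaneous phase, trials x channels x samples, radians in (-pi, pi]."""

    phase: np.ndarray
    channel_names: tuple[str, ...]
    band: str = "wide"

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=np.float64)
        if self.phase.ndim != 3:
            raise ValidationError("phase must be trials x channels x samples")


@dataclass
class ConnectivityMatrix:
    """Symmetric channel x channel PLI matrix with provenance tags."""

    values: np.ndarray
    channel_names: tuple[str, ...]
    band: str = "wide"
    level: str = "subject"  # trial | subject | group
    subject_id: str = ""
    group_label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("connectivity values must be square")
        if not np.allclose(v, v.T):
            raise ValidationError("connectivity matrix must be symmetric")
        self.values = v

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def instantaneous_phase(epochs: EpochSet) -> PhaseSeries:
    """Analytic-signal (Hilbert transform) phase of band-filtered epochs."""
    data = epochs.data
    flat_ch = np.all(data == 0, axis=(0, 2))
    if flat_ch.any():
        bad = [epochs.channel_names[i] for i in np.flatnonzero(flat_ch)]
        raise ValidationError(f"phase undefined for all-zero channels: {bad}")
    analytic = hilbert(data, axis=-1)
    return PhaseSeries(phase=np.angle(analytic),
                       channel_names=epochs.channel_names, band=epochs.band)


def continuous_phase(record: np.ndarray) -> np.ndarray:
    """Analytic-signal phase of a continuous (channels, samples) record.

    Computing the Hilbert transform on the continuous record instead of on
    1-s epochs keeps its FFT edge distortion out of every epoch (the same
    reasoning as filtering before epoching).
    """
    record = np.asarray(record, dtype=np.float64)
    if np.all(record == 0, axis=-1).any():
        raise ValidationError("phase undefined for all-zero channels")
    return np.angle(hilbert(record, axis=-1))


def epoch_phase(phase: np.ndarray, target_onsets: np.ndarray,
                channel_names, sampling_rate: float,
                window: tuple[float, float] = (-0.2, 0.8),
                band: str = "wide") -> PhaseSeries:
    """Cut target-locked phase epochs (no baseline correction — phase is
    circular). Events whose window exceeds the record are dropped."""
    n_ch, n_samp = phase.shape
    w0, w1 = window
    n_win = int(round((w1 - w0) * sampling_rate))
    n_pre = int(round(-w0 * sampling_rate))
    trials = []
    for onset in np.asarray(target_onsets):
        start = int(onset) - n_pre
        if start < 0 or start + n_win > n_samp:
            continue
        trials.append(phase[:, start:start + n_win])
    stack = np.stack(trials) if trials else np.empty((0, n_ch, n_win))
    return PhaseSeries(phase=stack, channel_names=tuple(channel_names),
                       band=band)


def _wrapped_diff(phase_x: np.ndarray, phase_y: np.ndarray) -> np.ndarray:
    # wrap to (-pi, pi]; the raw difference of wrapped phases flips sign at
    # the +-pi branch cut, which would destroy a perfectly consistent lag
    d = np.angle(np.exp(1j * (phase_x - phase_y)))
    # np.angle returns [-pi, pi); map -pi to +pi for the (-pi, pi] convention
    return np.where(d == -np.pi, np.pi, d)


def pli_pair(phase_x: np.ndarray, phase_y: np.ndarray) -> float:
    """PLI of two equal-length phase series; sign(0) counts as 0."""
    phase_x = np.asarray(phase_x, dtype=np.float64)
    phase_y = np.asarray(phase_y, dtype=np.float64)
    if phase_x.shape != phase_y.shape:
        raise ValidationError("phase series must have equal length")
    if phase_x.size < 2:
        raise ValidationError("need at least 2 samples")
    return float(np.abs(np.mean(np.sign(_wrapped_diff(phase_x, phase_y)))))


def pli_matrix(phases: PhaseSeries, level: str = "subject",
               subject_id: str = "", group_label: str = "") -> ConnectivityMatrix:
    """Subject-level PLI matrix: per-trial matrices averaged over trials."""
    trials = trial_pli_matrices(phases)
    values = trials.mean(axis=0)
    return ConnectivityMatrix(values=values, channel_names=phases.channel_names,
                              band=phases.band, level=level,
                              subject_id=subject_id, group_label=group_label)


def trial_pli_matrices(phases: PhaseSeries) -> np.ndarray:
    """Stack of per-trial PLI matrices, shape (trials, C, C)."""
    p = phases.phase
    if p.shape[0] < 1:
        raise ValidationError("need at least one trial")
    if p.shape[2] < 2:
        raise ValidationError("single-sample trials have no defined PLI")
    out = np.empty((p.shape[0], p.shape[1], p.shape[1]))
    for t in range(p.shape[0]):
        d = _wrapped_diff(p[t, :, None, :], p[t, None, :, :])
        m = np.abs(np.sign(d).mean(axis=-1))
        np.fill_diagonal(m, 0.0)
        out[t] = m
    return out


def group_mean_matrix(matrices: list[ConnectivityMatrix],
                      group_label: str = "") -> ConnectivityMatrix:
    """Group-level matrix: arithmetic mean of subject matrices."""
    if not matrices:
        raise ValidationError("no matrices to average")
    names = matrices[0].channel_names
    for m in matrices:
        if m.channel_names != names:
            raise ValidationError("montage mismatch across matrices")
    values = np.mean([m.values for m in matrices], axis=0)
    return ConnectivityMatrix(values=values, channel_names=names,
                              band=matrices[0].band, level="group",
                              group_label=group_label)


def _top_fraction_mask(weights: np.ndarray, fraction: float) -> np.ndarray:
    """Boolean (C, C) symmetric mask of the top `fraction` off-diagonal pairs.

    Ranking is by descending weight; exact ties broken by ascending
    (row, column) index, deterministically.
    """
    n = weights.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = weights[iu, ju]
    k = int(np.floor(fraction * w.size))
    # stable sort on (-w, row, col): lexsort keys are last-key-dominant
    order = np.lexsort((ju, iu, -w))
    keep = order[:k]
    mask = np.zeros((n, n), dtype=bool)
    mask[iu[keep], ju[keep]] = True
    return mask | mask.T


def proportional_threshold(C: ConnectivityMatrix,
                           density: float = 0.30) -> ConnectivityMatrix:
    """Keep the strongest `density` fraction of connections, zero the rest.

    For 22 nodes at density 0.30 this retains floor(0.30 * 231) = 69 edges.
    """
    if not (0 < density <= 1):
        raise ValidationError(f"density {density} outside (0, 1]")
    mask = _top_fraction_mask(C.values, density)
    values = np.where(mask, C.values, 0.0)
    return ConnectivityMatrix(values=values, channel_names=C.channel_names,
                              band=C.band, level=C.level,
                              subject_id=C.subject_id,
                              group_label=C.group_label)


def difference_matrix(Ca: ConnectivityMatrix, Cb: ConnectivityMatrix,
                      retain: float = 0.30) -> np.ndarray:
    """Signed group difference Ca - Cb, keeping the `retain` fraction of
    largest-magnitude connections (the rest zeroed)."""
    if Ca.channel_names != Cb.channel_names:
        raise ValidationError("montage mismatch between groups")
    if Ca.band != Cb.band:
        raise ValidationError("band mismatch between groups")
    if not (0 < retain <= 1):
        raise ValidationError(f"retain {retain} outside (0, 1]")
    D = Ca.values - Cb.values
    mask = _top_fraction_mask(np.abs(D), retain)
    return np.where(mask, D, 0.0)
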