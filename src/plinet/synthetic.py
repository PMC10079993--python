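"""Synthetic three-group auditory-oddball EEG cohorts.

The generator emulates the structure the analysis is sensitive to — band-
specific, lagged phase coupling between channel pairs — without pretending
to be a biophysical forward model:

* background: per-channel 1/f (pink) noise;
* rhythms: per band, each channel carries a narrow-band oscillator
  cos(2*pi*f0*t + random phase walk) with f0 drawn inside the band, so
  uncoupled channel pairs have drifting relative phase;
* coupling: a rule (pair, band, mean_lag, jitter_concentration) makes both
  channels share ONE oscillator, the second channel's phase offset by
  mean_lag plus slowly-varying von Mises jitter of the given concentration.
  Large concentration => near-constant nonzero lag => phase-lag index -> 1;
  concentration -> 0 => uniform jitter => PLI -> 0;
* evoked response: a parietal-maximal, Gaussian-windowed half-sine peaking
  ~300 ms after each target tone (P300-like), for waveform realism only.

Three default group profiles mimic the reported contrast pattern: a chronic-
primary-pain-like group with strongly enhanced theta frontoparietal coupling
(FP1-P3, FP2-O2), a control group with moderate CP5-O2 / FC2-F4 coupling,
and a depression-like group in which the same couplings are suppressed.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import (DEFAULT_SFREQ, MONTAGE_22, EpochSet, EventSchedule,
                         ValidationError)
from .preprocessing import BANDS, epoch

#: Phase random-walk innovation (radians/sample at 250 Hz). Together with a
#: per-oscillator centre frequency drawn inside the band, this decorrelates
#: uncoupled channel pairs within a 1-s epoch while keeping each oscillator
#: narrow-band enough that zero-phase filtering preserves imposed lags.
PHASE_WALK_SD = 0.08

#: Oscillator amplitude (uV) used for a coupled band absent from band_powers.
DEFAULT_BAND_AMPLITUDE = 5.0

#: von Mises jitter is piecewise-smooth with this block length (seconds).
JITTER_BLOCK_S = 0.25

#: Evoked-response scalp weighting, parietal-maximal.
_P300_TOPOGRAPHY = {
    "Pz": 1.0, "P3": 0.9, "P4": 0.9, "CP1": 0.8, "CP2": 0.8,
    "CP5": 0.6, "CP6": 0.6, "Oz": 0.7, "O1": 0.6, "O2": 0.6,
    "C3": 0.5, "C4": 0.5, "FC1": 0.35, "FC2": 0.35, "FC5": 0.3,
    "FC6": 0.3, "F3": 0.2, "F4": 0.2, "F7": 0.15, "F8": 0.15,
    "FP1": 0.1, "FP2": 0.1,
}


@dataclass(frozen=True)
class CouplingRule:
    """Shared-oscillator phase coupling between one channel pair in one band."""

    pair: tuple[str, str]
    band: str
    mean_lag: float  # radians, in (-pi, pi]
    jitter_concentration: float  # von Mises kappa, >= 0; inf = deterministic lag

    def __post_init__(self) -> None:
        if not (-np.pi < self.mean_lag <= np.pi):
            raise ValidationError(f"mean_lag {self.mean_lag} outside (-pi, pi]")
        if self.jitter_concentration < 0 or np.isnan(self.jitter_concentration):
            raise ValidationError("jitter_concentration must be >= 0")
        if self.band not in BANDS:
            raise ValidationError(f"unknown band {self.band!r}")


def _default_band_powers() -> dict[str, float]:
    # uV amplitudes of the per-band background rhythms
    return {"delta": 6.0, "theta": 6.0, "alpha": 8.0, "beta": 3.0, "gamma": 2.0}


@dataclass
class GroupProfile:
    """Generative parameters of one synthetic group."""

    label: str
    coupling_rules: list[CouplingRule] = field(default_factory=list)
    erp_amplitude: float = 8.0  # uV at the Pz peak
    noise_sd: float = 10.0  # uV, pink background
    band_powers: dict[str, float] = field(default_factory=_default_band_powers)


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort; everything derives from `seed`."""

    groups: list[GroupProfile]
    n_subjects_per_group: int = 22
    montage: tuple[str, ...] = MONTAGE_22
    sampling_rate: float = DEFAULT_SFREQ
    seed: int = 0
    n_target: int = 30
    n_standard: int = 200
    isi_bounds: tuple[float, float] = (1000.0, 1500.0)
    window: tuple[float, float] = (-0.2, 0.8)

    def __post_init__(self) -> None:
        self.montage = tuple(self.montage)
        if len(set(self.montage)) != len(self.montage) or len(self.montage) != 22:
            raise ValidationError("montage must list exactly 22 unique channels")
        if self.n_subjects_per_group < 1:
            raise ValidationError("n_subjects_per_group must be >= 1")
        for g in self.groups:
            for rule in g.coupling_rules:
                for ch in rule.pair:
                    if ch not in self.montage:
                        raise ValidationError(
                            f"group {g.label!r}: coupling channel {ch!r} "
                            "not in montage"
                        )


def default_group_profiles() -> list[GroupProfile]:
    """The three study-condition profiles (pain-like, depression-like, control)."""
    cpp = GroupProfile(
        label="cpp",
        coupling_rules=[
            CouplingRule(("FP1", "P3"), "theta", 1.0, 10.0),
            CouplingRule(("FP2", "O2"), "theta", 1.0, 10.0),
            CouplingRule(("FC2", "F4"), "theta", 1.0, 2.0),
        ],
    )
    hc = GroupProfile(
        label="hc",
        coupling_rules=[
            CouplingRule(("CP5", "O2"), "theta", 1.0, 6.0),
            CouplingRule(("FC2", "F4"), "theta", 1.0, 6.0),
        ],
    )
    dd = GroupProfile(
        label="dd",
        coupling_rules=[
            CouplingRule(("CP5", "O2"), "theta", 1.0, 0.5),
            CouplingRule(("FC2", "F4"), "theta", 1.0, 0.5),
        ],
        band_powers={"delta": 6.0, "theta": 4.0, "alpha": 8.0,
                     "beta": 3.0, "gamma": 2.0},
    )
    return [cpp, dd, hc]


def default_cohort_spec(n_subjects_per_group: int = 22, seed: int = 0) -> CohortSpec:
    return CohortSpec(groups=default_group_profiles(),
                      n_subjects_per_group=n_subjects_per_group, seed=seed)


def separable_cohort_spec(n_subjects_per_group: int = 8,
                          seed: int = 0) -> CohortSpec:
    """A deliberately easy benchmark cohort for classifier validation.

    Each group carries a disjoint set of near-deterministic theta couplings
    (high concentration, high oscillator-to-noise ratio), so the three
    connectivity fingerprints are linearly separable by construction. Use
    it to check that a classifier can learn at all — not as a model of
    realistic effect sizes (see ``default_group_profiles`` for those).
    """
    kappa = 32.0
    powers = {"theta": 15.0, "alpha": 6.0}

    def rules(pairs):
        return [CouplingRule(p, "theta", 1.0, kappa) for p in pairs]

    groups = [
        GroupProfile("g1", rules([("FP1", "P3"), ("FP2", "O2"),
                                  ("F3", "P4"), ("F4", "Pz")]),
                     noise_sd=5.0, band_powers=dict(powers)),
        GroupProfile("g2", rules([("CP5", "O2"), ("FC2", "F7"),
                                  ("C3", "O1"), ("CP6", "F8")]),
                     noise_sd=5.0, band_powers=dict(powers)),
        GroupProfile("g3", [], noise_sd=5.0, band_powers=dict(powers)),
    ]
    return CohortSpec(groups=groups,
                      n_subjects_per_group=n_subjects_per_group, seed=seed)


def make_oddball_schedule(
    n_target: int,
    n_standard: int,
    isi_bounds: tuple[float, float] = (1000.0, 1500.0),
    seed: int = 0,
    sampling_rate: float = DEFAULT_SFREQ,
    lead_in_s: float = 2.0,
) -> EventSchedule:
    """Pseudo-random target/standard order with uniform inter-stimulus intervals."""
    if n_target < 0 or n_standard < 0:
        raise ValidationError("stimulus counts must be >= 0")
    lo, hi = isi_bounds
    if not (0 < lo <= hi):
        raise ValidationError(f"invalid isi_bounds {isi_bounds}")
    rng = np.random.default_rng(seed)
    labels = np.array(["target"] * n_target + ["standard"] * n_standard)
    rng.shuffle(labels)
    n = n_target + n_standard
    gaps_ms = rng.uniform(lo, hi, size=n)
    onset_s = lead_in_s + np.cumsum(gaps_ms) / 1000.0 - gaps_ms[0] / 1000.0 \
        if n else np.empty(0)
    onsets = np.round(onset_s * sampling_rate).astype(np.int64)
    return EventSchedule(onsets=onsets, labels=labels, isi_bounds=(lo, hi))


def _pink_noise(rng: np.random.Generator, n_ch: int, n: int, sd: float) -> np.ndarray:
    """1/f-amplitude noise, per channel, scaled to the requested SD."""
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    pink = np.fft.irfft(spec * scale, n=n, axis=-1)
    pink /= pink.std(axis=-1, keepdims=True)
    return sd * pink


#: Oscillator centre frequency is re-drawn inside the band on this time
#: scale (seconds) and interpolated, emulating the slow wandering of EEG
#: peak frequencies; without it two independent oscillators that draw
#: nearly equal frequencies would stay spuriously phase-locked all session.
FREQ_DRIFT_BLOCK_S = 4.0


def _oscillator_phase(rng: np.random.Generator, n: int, fs: float,
                      low_hz: float, high_hz: float) -> np.ndarray:
    block = max(1, int(round(FREQ_DRIFT_BLOCK_S * fs)))
    n_blocks = max(2, int(np.ceil(n / block)) + 1)
    f_nodes = rng.uniform(low_hz, high_hz, n_blocks)
    freq = np.interp(np.arange(n), np.arange(n_blocks) * block, f_nodes)
    return (2 * np.pi * np.cumsum(freq) / fs
            + np.cumsum(rng.normal(0.0, PHASE_WALK_SD, n)))


def _jitter_series(rng: np.random.Generator, n: int, fs: float,
                   kappa: float) -> np.ndarray:
    """Slowly varying von Mises phase jitter (piecewise blocks, interpolated)."""
    if np.isinf(kappa):
        return np.zeros(n)
    block = max(1, int(round(JITTER_BLOCK_S * fs)))
    n_blocks = max(2, int(np.ceil(n / block)) + 1)
    if kappa == 0:
        vals = rng.uniform(-np.pi, np.pi, n_blocks)
    else:
        vals = rng.vonmises(0.0, kappa, n_blocks)
    centers = (np.arange(n_blocks) + 0.5) * block
    return np.interp(np.arange(n), centers, vals)


def _p300_kernel(fs: float, amplitude: float) -> np.ndarray:
    """Gaussian-windowed half-sine, peak ~300 ms post stimulus, 600 ms support."""
    t = np.arange(int(round(0.6 * fs))) / fs
    halfsine = np.sin(np.pi * t / 0.6)
    gauss = np.exp(-0.5 * ((t - 0.3) / 0.1) ** 2)
    kern = halfsine * gauss
    return amplitude * kern / kern.max()


def synthesize_continuous(
    profile: GroupProfile,
    schedule: EventSchedule,
    spec: CohortSpec,
    subject_seed: int,
) -> np.ndarray:
    """Continuous (22, n_samples) record for one subject, in microvolts."""
    for rule in profile.coupling_rules:
        for ch in rule.pair:
            if ch not in spec.montage:
                raise ValidationError(f"coupling channel {ch!r} not in montage")
    fs = spec.sampling_rate
    rng = np.random.default_rng(subject_seed)
    n_ch = len(spec.montage)
    tail = int(round(2.0 * fs))
    n = int(schedule.onsets[-1]) + tail if schedule.onsets.size else tail
    idx = {ch: i for i, ch in enumerate(spec.montage)}

    x = _pink_noise(rng, n_ch, n, profile.noise_sd)

    # channels whose band rhythm is supplied by a coupling rule
    coupled = {(idx[ch], rule.band)
               for rule in profile.coupling_rules for ch in rule.pair}

    for band_name, amp in profile.band_powers.items():
        band = BANDS[band_name]
        for ci in range(n_ch):
            if (ci, band_name) in coupled:
                continue
            phase = _oscillator_phase(rng, n, fs, band.low_hz, band.high_hz)
            x[ci] += amp * np.cos(phase)

    for rule in profile.coupling_rules:
        band = BANDS[rule.band]
        amp = profile.band_powers.get(rule.band, DEFAULT_BAND_AMPLITUDE)
        phase = _oscillator_phase(rng, n, fs, band.low_hz, band.high_hz)
        jitter = _jitter_series(rng, n, fs, rule.jitter_concentration)
        a, b = (idx[ch] for ch in rule.pair)
        x[a] += amp * np.cos(phase)
        x[b] += amp * np.cos(phase - rule.mean_lag - jitter)

    kern = _p300_kernel(fs, profile.erp_amplitude)
    topo = np.array([_P300_TOPOGRAPHY.get(ch, 0.3) for ch in spec.montage])
    for onset in schedule.target_onsets:
        stop = min(n, onset + kern.size)
        x[:, onset:stop] += topo[:, None] * kern[: stop - onset]
    return x


def synthesize_subject(
    profile: GroupProfile,
    schedule: EventSchedule,
    spec: CohortSpec,
    subject_seed: int,
    subject_id: str = "",
) -> EpochSet:
    """Wide-band target-locked epochs for one synthetic subject."""
    record = synthesize_continuous(profile, schedule, spec, subject_seed)
    return epoch(record, schedule, spec.montage, spec.sampling_rate,
                 window=spec.window, subject_id=subject_id,
                 group_label=profile.label)


def _subject_seed(spec_seed: int, group_idx: int, subj_idx: int) -> int:
    ss = np.random.SeedSequence([spec_seed, group_idx, subj_idx])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def generate_cohort(spec: CohortSpec, out_dir, overwrite: bool = False) -> Path:
    """Write a full cohort to disk; returns the cohort directory.

    Layout: ``manifest.json`` plus, per subject, a float32 little-endian
    epochs blob (trial-major, then channel, then sample) with a JSON sidecar,
    a continuous-record blob, and the event schedule.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()):
        if not overwrite:
            raise FileExistsError(
                f"{out} exists and is not empty (pass overwrite=True)")
        shutil.rmtree(out)
    out.mkdir(parents=True, exist_ok=True)

    manifest = {
        "montage": list(spec.montage),
        "sampling_rate": spec.sampling_rate,
        "seed": spec.seed,
        "window": list(spec.window),
        "n_target": spec.n_target,
        "n_standard": spec.n_standard,
        "isi_bounds": list(spec.isi_bounds),
        "subjects": [],
    }
    for gi, profile in enumerate(spec.groups):
        for si in range(spec.n_subjects_per_group):
            sid = f"{profile.label}_{si:03d}"
            seed = _subject_seed(spec.seed, gi, si)
            schedule = make_oddball_schedule(
                spec.n_target, spec.n_standard, spec.isi_bounds,
                seed=seed, sampling_rate=spec.sampling_rate)
            record = synthesize_continuous(profile, schedule, spec, seed)
            epochs = epoch(record, schedule, spec.montage, spec.sampling_rate,
                           window=spec.window, subject_id=sid,
                           group_label=profile.label)
            _write_blob(out / f"{sid}_epochs.f32", epochs.data)
            _write_sidecar(out / f"{sid}_epochs.json", epochs.data.shape,
                           ["trial", "channel", "sample"])
            _write_blob(out / f"{sid}_continuous.f32", record)
            _write_sidecar(out / f"{sid}_continuous.json", record.shape,
                           ["channel", "sample"])
            (out / f"{sid}_events.json").write_text(
                json.dumps(schedule.to_dict()))
            manifest["subjects"].append(
                {"subject_id": sid, "group": profile.label, "seed": seed})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def _write_blob(path: Path, arr: np.ndarray) -> None:
    np.asarray(arr, dtype="<f4").tofile(path)


def _write_sidecar(path: Path, shape, order) -> None:
    path.write_text(json.dumps(
        {"shape": list(shape), "dtype": "<f4", "order": order}))


def _read_blob(path: Path) -> np.ndarray:
    sidecar = json.loads(path.with_suffix(".json").read_text())
    arr = np.fromfile(path, dtype="<f4").reshape(sidecar["shape"])
    return arr.astype(np.float64)


class Cohort:
    """Read access to an on-disk cohort directory."""

    def __init__(self, path):
        self.path = Path(path)
        self.manifest = json.loads((self.path / "manifest.json").read_text())
        self.montage = tuple(self.manifest["montage"])
        self.sampling_rate = float(self.manifest["sampling_rate"])
        self.window = tuple(self.manifest["window"])

    @property
    def subjects(self) -> list[dict]:
        return self.manifest["subjects"]

    def load_epochs(self, subject_id: str) -> EpochSet:
        entry = self._entry(subject_id)
        data = _read_blob(self.path / f"{subject_id}_epochs.f32")
        return EpochSet(data=data, channel_names=self.montage,
                        sampling_rate=self.sampling_rate,
                        subject_id=subject_id, group_label=entry["group"],
                        window=self.window)

    def load_continuous(self, subject_id: str) -> np.ndarray:
        return _read_blob(self.path / f"{subject_id}_continuous.f32")

    def load_schedule(self, subject_id: str) -> EventSchedule:
        d = json.loads((self.path / f"{subject_id}_events.json").read_text())
        return EventSchedule.from_dict(d)

    def _entry(self, subject_id: str) -> dict:
        for s in self.subjects:
            if s["subject_id"] == subject_id:
                return s
        raise KeyError(subject_id)


def load_cohort(path) -> Cohort:
    return Cohort(path)
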