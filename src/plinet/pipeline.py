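"""End-to-end orchestration: cohort -> band networks -> graphs -> statistics
-> CNN classification, with all file I/O.

Every artifact written under the output directory is regenerable from the
configuration plus the global seed alone: the seed fans out to per-stage
seeds through a counter-based SeedSequence derivation, so stages can be
rerun independently yet reproducibly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import (ConnectivityMatrix, PhaseSeries, continuous_phase,
                           difference_matrix, epoch_phase, group_mean_matrix,
                           pli_matrix, proportional_threshold,
                           trial_pli_matrices)
from .containers import MONTAGE_22, EpochSet, ValidationError
from .graph import binarize, node_metric_table
from .nn import (ArchitectureSpec, ClassifiedDataset, TrainConfig,
                 assign_folds, train)
from .preprocessing import BANDS, bandpass, epoch, reject_artifacts
from .stats import anova_with_posthoc, node_strength_table
from .synthetic import Cohort, default_cohort_spec, generate_cohort, load_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything needed for one reproducible run."""

    out_dir: str = "results"
    dataset_dir: str | None = None  # reuse an existing cohort if set
    n_subjects_per_group: int = 10
    bands: list[str] = field(default_factory=lambda: ["theta"])
    density: float = 0.30
    reject_limit: float = 300.0  # uV peak-to-peak
    cv_folds: int = 10
    test_fold: int = 0
    cnn_variants: list[str] = field(default_factory=lambda: ["pli"])
    epochs: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.bands) - set(BANDS)
        if unknown:
            raise ValidationError(f"unknown bands: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


def _stage_seed(global_seed: int, stage: int) -> int:
    ss = np.random.SeedSequence([global_seed, stage])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def band_epochs(cohort: Cohort, subject_id: str, band_name: str,
                reject_limit: float | None = None) -> EpochSet:
    """Band-pass the continuous record, epoch around targets, reject trials."""
    record = cohort.load_continuous(subject_id)
    schedule = cohort.load_schedule(subject_id)
    band = BANDS[band_name]
    filtered = bandpass(record, band, cohort.sampling_rate)
    entry = cohort._entry(subject_id)
    ep = epoch(filtered, schedule, cohort.montage, cohort.sampling_rate,
               window=cohort.window, subject_id=subject_id,
               group_label=entry["group"], band=band_name)
    if reject_limit is not None and np.isfinite(reject_limit):
        ep = reject_artifacts(ep, reject_limit)
    return ep


def subject_connectivity(cohort: Cohort, subject_id: str, band_name: str,
                         reject_limit: float | None = None
                         ) -> tuple[ConnectivityMatrix, np.ndarray]:
    """(subject-level PLI matrix, per-trial matrix stack) for one band.

    The analytic-signal phase is taken on the continuous band-filtered
    record and then epoched, so Hilbert edge distortion never falls inside
    a trial; amplitude-based artifact rejection is applied to the matching
    amplitude epochs and the same trials are removed from the phase stack.
    """
    record = cohort.load_continuous(subject_id)
    schedule = cohort.load_schedule(subject_id)
    band = BANDS[band_name]
    filtered = bandpass(record, band, cohort.sampling_rate)
    entry = cohort._entry(subject_id)
    ep = epoch(filtered, schedule, cohort.montage, cohort.sampling_rate,
               window=cohort.window, subject_id=subject_id,
               group_label=entry["group"], band=band_name)
    phases = epoch_phase(continuous_phase(filtered), schedule.target_onsets,
                         cohort.montage, cohort.sampling_rate,
                         window=cohort.window, band=band_name)
    if reject_limit is not None and np.isfinite(reject_limit):
        ptp = ep.data.max(axis=2) - ep.data.min(axis=2)
        keep = (ptp <= reject_limit).all(axis=1)
        if not keep.any():
            raise ValidationError(
                f"all trials of {subject_id} exceed the {reject_limit} uV "
                "peak-to-peak limit")
        phases = PhaseSeries(phase=phases.phase[keep],
                             channel_names=phases.channel_names,
                             band=phases.band)
    trials = trial_pli_matrices(phases)
    subj = pli_matrix(phases, subject_id=subject_id,
                      group_label=entry["group"])
    return subj, trials


def matrix_to_tsv(values: np.ndarray, channel_names, path) -> None:
    pd.DataFrame(values, index=list(channel_names),
                 columns=list(channel_names)).to_csv(path, sep="\t")


def plot_training_curves(curves: pd.DataFrame, path) -> None:
    """Accuracy and loss of training/validation sets over epochs."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_acc, ax_loss) = plt.subplots(1, 2, figsize=(9, 3.5))
    ax_acc.plot(curves["epoch"], curves["train_accuracy"], label="training")
    ax_acc.plot(curves["epoch"], curves["val_accuracy"], label="validation")
    ax_acc.set_xlabel("epoch"), ax_acc.set_ylabel("accuracy"), ax_acc.legend()
    ax_loss.plot(curves["epoch"], curves["train_loss"], label="training")
    ax_loss.plot(curves["epoch"], curves["val_loss"], label="validation")
    ax_loss.set_xlabel("epoch"), ax_loss.set_ylabel("loss"), ax_loss.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage; returns the output directory.

    Writes per band: group connectivity matrices and signed difference
    matrices (TSV), per-subject and group graph-metric tables (TSV), the
    ANOVA/Tukey summary (TSV), and CNN training curves (TSV), curve plots
    (PNG) and evaluation reports (JSON). A run manifest records seeds,
    package version and the config.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": config.seed,
                "config": dataclasses.asdict(config), "artifacts": []}

    def record(path: Path) -> Path:
        manifest["artifacts"].append(str(path.relative_to(out)))
        return path

    # stage 0: cohort
    if config.dataset_dir is not None:
        cohort = load_cohort(config.dataset_dir)
    else:
        spec = default_cohort_spec(config.n_subjects_per_group,
                                   seed=_stage_seed(config.seed, 0))
        cohort_dir = out / "cohort"
        generate_cohort(spec, cohort_dir, overwrite=True)
        cohort = load_cohort(cohort_dir)
        manifest["cohort"] = str(cohort_dir)
    subject_ids = [s["subject_id"] for s in cohort.subjects]
    groups = sorted({s["group"] for s in cohort.subjects})

    stats_rows = []
    for band_name in config.bands:
        logger.info("band %s: connectivity", band_name)
        band_dir = out / band_name
        band_dir.mkdir(exist_ok=True)
        subj_mats, trial_stacks = {}, {}
        for sid in subject_ids:
            subj, trials = subject_connectivity(cohort, sid, band_name,
                                                config.reject_limit)
            subj_mats[sid] = subj
            trial_stacks[sid] = trials

        by_group = {g: [m for m in subj_mats.values() if m.group_label == g]
                    for g in groups}
        group_mats = {g: group_mean_matrix(ms, group_label=g)
                      for g, ms in by_group.items()}
        for g, gm in group_mats.items():
            thr = proportional_threshold(gm, config.density)
            matrix_to_tsv(gm.values, cohort.montage,
                          record(band_dir / f"connectivity_{g}.tsv"))
            matrix_to_tsv(thr.values, cohort.montage,
                          record(band_dir / f"connectivity_{g}_thresholded.tsv"))
        for i, ga in enumerate(groups):
            for gb in groups[i + 1:]:
                D = difference_matrix(group_mats[ga], group_mats[gb],
                                      config.density)
                matrix_to_tsv(D, cohort.montage,
                              record(band_dir / f"difference_{ga}-{gb}.tsv"))

        # graph metrics: per-subject thresholded graphs, then group averages
        tables = []
        for sid, m in subj_mats.items():
            g = binarize(proportional_threshold(m, config.density))
            tables.append(node_metric_table(g, band=band_name,
                                            group=m.group_label,
                                            subject_id=sid))
        metrics = pd.concat(tables, ignore_index=True)
        metrics.to_csv(record(band_dir / "node_metrics_subject.tsv"),
                       sep="\t", index=False)
        metric_cols = [c for c in metrics.columns
                       if c not in ("subject_id", "group", "band", "channel")]
        group_avg = (metrics.groupby(["group", "channel"], sort=False,
                                     as_index=False)[metric_cols].mean())
        group_avg.to_csv(record(band_dir / "node_metrics_group.tsv"),
                         sep="\t", index=False)

        # group statistics
        obs = node_strength_table(list(subj_mats.values()), band=band_name)
        res = anova_with_posthoc(obs)
        stats_rows.append({
            "band": band_name, "ss_between": res.ss_between,
            "mean_square": res.ms_between, "F": res.F, "p": res.p,
            **{f"tukey_{a}_vs_{b}": p for (a, b), p in res.tukey_p.items()},
        })

        # CNN classification
        label_names = tuple(groups)
        label_of = {g: i for i, g in enumerate(label_names)}
        for variant in config.cnn_variants:
            X, y, owners = [], [], []
            for sid in subject_ids:
                grp = cohort._entry(sid)["group"]
                if variant == "pli":
                    samples = trial_stacks[sid][:, None, :, :]
                else:
                    ep = band_epochs(cohort, sid, band_name,
                                     config.reject_limit)
                    samples = ep.data[:, None, :, :]
                X.append(samples)
                y.extend([label_of[grp]] * len(samples))
                owners.extend([sid] * len(samples))
            dataset = ClassifiedDataset(np.concatenate(X), np.array(y),
                                        np.array(owners), label_names)
            arch = ArchitectureSpec(
                variant=variant, n_classes=len(label_names),
                input_width=dataset.X.shape[-1])
            cfg = TrainConfig(epochs=config.epochs,
                              seed=_stage_seed(config.seed, 1))
            folds = assign_folds(dataset.subject_groups, k=config.cv_folds,
                                 seed=_stage_seed(config.seed, 2))
            result = train(dataset, folds, arch, cfg,
                           test_fold=config.test_fold)
            result.curves.to_csv(
                record(band_dir / f"cnn_{variant}_curves.tsv"),
                sep="\t", index=False)
            plot_training_curves(
                result.curves, record(band_dir / f"cnn_{variant}_curves.png"))
            report = result.test_report.to_dict()
            report["best_epoch"] = result.best_epoch
            report["best_val_accuracy"] = result.best_val_accuracy
            record(band_dir / f"cnn_{variant}_report.json").write_text(
                json.dumps(report, indent=1))

    pd.DataFrame(stats_rows).to_csv(record(out / "anova.tsv"), sep="\t",
                                    index=False)
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def import_external(path, fmt: str = "cohort") -> Cohort:
    """Validate and open an external dataset as a cohort container.

    Only the package's own on-disk container format is supported; the
    montage must match the 22-channel analysis montage (channel mismatches
    are reported by name).
    """
    if fmt != "cohort":
        raise ValidationError(f"unsupported format {fmt!r}")
    cohort = load_cohort(path)
    missing = [ch for ch in MONTAGE_22 if ch not in cohort.montage]
    if missing:
        raise ValidationError(
            f"dataset montage is missing {len(missing)} required channels: "
            f"{missing}")
    extra = [ch for ch in cohort.montage if ch not in MONTAGE_22]
    if extra:
        raise ValidationError(f"dataset montage has unknown channels: {extra}")
    return cohort
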