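"""Group statistics on network strength.

The dependent variable follows the connectivity analysis: for each subject
matrix, the channel-mean connection strength (row mean excluding the
diagonal) yields one observation per subject x channel. Group membership is
the single factor of a classical one-way ANOVA (between/within sum-of-
squares decomposition, F test at the 95% confidence framing), with Tukey's
honestly-significant-difference method for pairwise post-hoc comparisons.

A per-subject-mean variant (`per_subject=True`) collapses the 22 channel
observations of a subject to their mean first; use it when independence of
observations matters (channel means within a subject are correlated).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .connectivity import ConnectivityMatrix
from .containers import ValidationError


@dataclass
class AnovaResult:
    """One-way ANOVA decomposition plus Tukey post-hoc p-values."""

    ss_between: float
    ss_within: float
    df_between: int
    df_within: int
    F: float
    p: float
    tukey_p: dict[tuple[str, str], float] = field(default_factory=dict)
    degenerate: bool = False  # zero within-group variance

    @property
    def ms_between(self) -> float:
        return self.ss_between / self.df_between

    @property
    def ms_within(self) -> float:
        return self.ss_within / self.df_within


def node_strength_table(subject_matrices: list[ConnectivityMatrix],
                        band: str = "") -> pd.DataFrame:
    """One row per subject x channel: channel-mean PLI (diagonal excluded)."""
    groups = {m.group_label for m in subject_matrices}
    if len(groups) < 2:
        raise ValidationError("need matrices from at least 2 groups")
    rows = []
    for m in subject_matrices:
        n = m.n_channels
        strength = (m.values.sum(axis=1)) / (n - 1)  # diagonal is zero
        for ch, v in zip(m.channel_names, strength):
            rows.append({"subject_id": m.subject_id, "group": m.group_label,
                         "channel": ch, "value": float(v),
                         "band": band or m.band})
    return pd.DataFrame(rows)


def _group_arrays(observations: pd.DataFrame, per_subject: bool) -> dict[str, np.ndarray]:
    df = observations
    if per_subject:
        df = (df.groupby(["group", "subject_id"], as_index=False)["value"]
              .mean())
    out = {}
    for g, sub in df.groupby("group"):
        vals = np.asarray(sub["value"], dtype=np.float64)
        if vals.size < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 observations")
        out[str(g)] = vals
    if len(out) < 2:
        raise ValidationError("need at least 2 groups")
    return out


def one_way_anova(observations: pd.DataFrame,
                  per_subject: bool = False) -> AnovaResult:
    """Classical one-way ANOVA of `value` on `group`.

    With zero within-group variance the F statistic is unbounded; the result
    is flagged `degenerate` and p is reported as 0.0.
    """
    groups = _group_arrays(observations, per_subject)
    arrays = list(groups.values())
    grand = np.concatenate(arrays)
    ss_between = sum(a.size * (a.mean() - grand.mean()) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between = len(arrays) - 1
    df_within = grand.size - len(arrays)
    if ss_within <= np.finfo(float).tiny * grand.size:
        return AnovaResult(ss_between=float(ss_between), ss_within=0.0,
                           df_between=df_between, df_within=df_within,
                           F=np.inf if ss_between > 0 else 0.0,
                           p=0.0 if ss_between > 0 else 1.0, degenerate=True)
    F, p = sstats.f_oneway(*arrays)
    return AnovaResult(ss_between=float(ss_between), ss_within=float(ss_within),
                       df_between=df_between, df_within=df_within,
                       F=float(F), p=float(p))


def tukey_hsd(observations: pd.DataFrame,
              per_subject: bool = False) -> dict[tuple[str, str], float]:
    """Tukey HSD adjusted p-values for every group pair (studentized range)."""
    groups = _group_arrays(observations, per_subject)
    labels = sorted(groups)
    res = sstats.tukey_hsd(*(groups[g] for g in labels))
    out = {}
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            out[(labels[i], labels[j])] = float(res.pvalue[i, j])
    return out


def anova_with_posthoc(observations: pd.DataFrame,
                       per_subject: bool = False) -> AnovaResult:
    res = one_way_anova(observations, per_subject=per_subject)
    if not res.degenerate:
        res.tukey_p = tukey_hsd(observations, per_subject=per_subject)
    return res


def null_rejection_rate(n_sims: int = 1000, n_groups: int = 3,
                        n_per_group: int = 15, alpha: float = 0.05,
                        seed: int = 0) -> float:
    """Empirical type-I error of the ANOVA under an exchangeable null.

    Per-subject strengths are drawn i.i.d. from one common Gaussian for all
    groups (one observation per subject, so the F-test's independence
    assumption holds); returns the fraction of simulations with p < alpha.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        arrays = [rng.normal(0.5, 0.05, n_per_group) for _ in range(n_groups)]
        _, p = sstats.f_oneway(*arrays)
        rejections += p < alpha
    return rejections / n_sims
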