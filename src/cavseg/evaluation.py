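"""Segmentation metrics and the statistical comparison workflow.

Metrics follow the standard definitions used to evaluate delineation
quality in radiotherapy:

* Dice coefficient  DC = 2|A∩B| / (|A| + |B|), in [0, 1];
* relative volume error  (V_auto − V_ref) / V_ref, signed (negative means
  the automatic contour underestimates the reference);
* absolute volume in cm³.

Group comparison mirrors the usual non-parametric chain: per-group
Shapiro-Wilk normality check, Kruskal-Wallis omnibus test, and — only when
the omnibus test is significant at level α — pairwise unpaired Wilcoxon
rank-sum tests.  The tests themselves come from scipy.stats; this module
contributes the gated workflow and the report shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ConformanceError, LabelMap, volume_cm3

__all__ = [
    "MetricsRecord",
    "StatReport",
    "UndefinedMetricError",
    "dice",
    "relative_volume_error",
    "evaluate_cohort",
    "summarize_pairings",
    "compare_groups",
    "plot_metric_boxplots",
]


class UndefinedMetricError(ValueError):
    """The metric is undefined for this input (e.g. empty reference volume)."""


@dataclass(frozen=True)
class MetricsRecord:
    """One (case, pairing) row: Dice, relative volume error, volumes in cm³."""

    case_id: str
    pairing: str
    dice: float
    rel_vol_err: float  # NaN when the reference side is empty
    vol_a: float
    vol_b: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.dice <= 1.0:
            raise ValueError(f"dice out of [0,1]: {self.dice}")
        if self.vol_a < 0 or self.vol_b < 0:
            raise ValueError("volumes must be non-negative")


@dataclass
class StatReport:
    """Result of the gated group-comparison chain for one metric."""

    alpha: float
    group_medians: dict[str, float]
    group_iqrs: dict[str, float]
    shapiro_p: dict[str, float]
    omnibus_stat: float
    omnibus_p: float
    pairwise_p: dict[tuple[str, str], float] = field(default_factory=dict)
    pairwise_performed: bool = False

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "group_medians": self.group_medians,
            "group_iqrs": self.group_iqrs,
            "shapiro_p": self.shapiro_p,
            "omnibus_stat": self.omnibus_stat,
            "omnibus_p": self.omnibus_p,
            "pairwise_performed": self.pairwise_performed,
            "pairwise_p": {f"{a} vs {b}": p for (a, b), p in self.pairwise_p.items()},
        }


def _check_same_grid(a: LabelMap, b: LabelMap) -> None:
    if not a.geometry.matches(b.geometry):
        raise ConformanceError(
            f"masks on different grids: {a.geometry.shape} vs {b.geometry.shape}"
        )


def dice(a: LabelMap, b: LabelMap) -> float:
    """Dice coefficient 2|A∩B|/(|A|+|B|); two empty masks agree perfectly (1)."""
    _check_same_grid(a, b)
    na, nb = a.num_foreground, b.num_foreground
    if na == 0 and nb == 0:
        return 1.0
    inter = int(np.count_nonzero(a.values & b.values))
    return 2.0 * inter / (na + nb)


def relative_volume_error(auto: LabelMap, ref: LabelMap) -> float:
    """Signed fractional volume difference (V_auto − V_ref) / V_ref."""
    _check_same_grid(auto, ref)
    v_ref = volume_cm3(ref)
    if v_ref == 0.0:
        raise UndefinedMetricError("relative volume error undefined for empty reference")
    return (volume_cm3(auto) - v_ref) / v_ref


def _record(case_id: str, pairing: str, a: LabelMap, b: LabelMap) -> MetricsRecord:
    v_b = volume_cm3(b)
    rve = (volume_cm3(a) - v_b) / v_b if v_b > 0 else float("nan")
    return MetricsRecord(
        case_id=case_id,
        pairing=pairing,
        dice=dice(a, b),
        rel_vol_err=rve,
        vol_a=volume_cm3(a),
        vol_b=v_b,
    )


def evaluate_cohort(
    predictions: Mapping[str, LabelMap],
    raters: Mapping[str, "RaterSet"],
    reference: Mapping[str, LabelMap],
) -> pd.DataFrame:
    """Per-case metrics for every pairing, one row per (case, pairing).

    Pairings per case: automatic vs each rater, every rater-rater pair, and
    automatic vs the fused reference.  Raises a completeness error naming
    cases missing from any of the three maps.
    """
    cases = sorted(predictions)
    missing = {
        "raters": [c for c in cases if c not in raters],
        "reference": [c for c in cases if c not in reference],
    }
    extra = [c for c in sorted(set(raters) | set(reference)) if c not in predictions]
    problems = {k: v for k, v in missing.items() if v}
    if extra:
        problems["predictions"] = extra
    if problems:
        raise KeyError(f"case sets not aligned; missing from: {problems}")

    rows: list[MetricsRecord] = []
    for case in cases:
        pred = predictions[case]
        rs = raters[case]
        for label, mask in zip(rs.rater_labels, rs.masks):
            rows.append(_record(case, f"auto-{label}", pred, mask))
        for i in range(len(rs)):
            for j in range(i + 1, len(rs)):
                rows.append(
                    _record(case, f"{rs.rater_labels[i]}-{rs.rater_labels[j]}",
                            rs.masks[i], rs.masks[j])
                )
        rows.append(_record(case, "auto-reference", pred, reference[case]))
    return pd.DataFrame([r.__dict__ for r in rows])


def summarize_pairings(records: pd.DataFrame) -> pd.DataFrame:
    """Median and IQR (Q3−Q1, linear-interpolation quantiles) per pairing."""

    def iqr(x: pd.Series) -> float:
        return float(np.nanquantile(x, 0.75) - np.nanquantile(x, 0.25))

    return records.groupby("pairing").agg(
        dice_median=("dice", "median"),
        dice_iqr=("dice", iqr),
        rel_vol_err_median=("rel_vol_err", "median"),
        rel_vol_err_iqr=("rel_vol_err", iqr),
        n=("case_id", "count"),
    )


def compare_groups(
    metric_values: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> StatReport:
    """Shapiro → Kruskal-Wallis → (if significant) pairwise rank-sum chain."""
    groups = {k: np.asarray(v, dtype=float) for k, v in metric_values.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    small = [k for k, v in groups.items() if v.size < 3]
    if small:
        raise ValueError(f"groups too small (<3 values): {small}")

    shapiro_p: dict[str, float] = {}
    for name, vals in groups.items():
        if np.ptp(vals) == 0:
            shapiro_p[name] = float("nan")  # constant sample: W undefined
        else:
            shapiro_p[name] = float(stats.shapiro(vals).pvalue)

    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0:
        stat, p = 0.0, 1.0  # no rank variation anywhere
    else:
        kw = stats.kruskal(*groups.values())
        stat, p = float(kw.statistic), float(kw.pvalue)

    medians = {k: float(np.median(v)) for k, v in groups.items()}
    iqrs = {k: float(np.quantile(v, 0.75) - np.quantile(v, 0.25)) for k, v in groups.items()}
    report = StatReport(
        alpha=alpha,
        group_medians=medians,
        group_iqrs=iqrs,
        shapiro_p=shapiro_p,
        omnibus_stat=stat,
        omnibus_p=p,
    )
    if p < alpha:
        report.pairwise_performed = True
        names = list(groups)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                rs = stats.ranksums(groups[names[i]], groups[names[j]])
                report.pairwise_p[(names[i], names[j])] = float(rs.pvalue)
    return report


def plot_metric_boxplots(
    records: pd.DataFrame, metric: str, path: str, pairings: Iterable[str] | None = None
) -> None:
    """Box plots of one metric per pairing (automatic vs inter-rater groups)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if pairings is None:
        pairings = sorted(records["pairing"].unique())
    data = [records.loc[records["pairing"] == p, metric].dropna().values for p in pairings]
    fig, ax = plt.subplots(figsize=(1.2 * len(data) + 2, 4))
    ax.boxplot(data, tick_labels=list(pairings))
    ax.set_ylabel(metric)
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
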