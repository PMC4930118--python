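"""Protein-level phenotype summaries and group comparisons.

Covers total-protein normalization (per cell, per constitutive renilla
reporter), HPG/flow-cytometry protein-synthesis readouts (median
fluorescent intensity and percent positive relative to a no-label
control), forward-scatter size estimates, reference-based batch
normalization, Box-Cox variance stabilization and the group-comparison
statistics (Student's t, Tukey-Kramer HSD, patient-nested analysis).

Every comparison reports an effect size (fold of group means) alongside
its p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

WELL_COLUMNS = ("well", "group", "patient", "protein_mass", "cell_count",
                "renilla_lum")


@dataclass
class GroupComparison:
    """Two-or-more-group comparison with effect size and p-value."""

    method: str
    group_means: dict[str, float]
    fold: float
    statistic: float
    p_value: float
    n_per_group: dict[str, int] = field(default_factory=dict)
    boxcox_lambda: float | None = None
    normality_flag: bool | None = None  # advisory Shapiro-Wilk on residuals
    pairwise: pd.DataFrame | None = None

    def summary(self) -> str:
        groups = ", ".join(f"{g}={m:.4g}" for g, m in self.group_means.items())
        return (
            f"{self.method}: means [{groups}], fold={self.fold:.3f}, "
            f"stat={self.statistic:.3f}, p={self.p_value:.3g}"
        )


def signed_fold(ratio: float) -> float:
    """Fold-change sign convention: ratios below 1 become -1/ratio."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    return ratio if ratio >= 1 else -1.0 / ratio


# ---------------------------------------------------------------------
# total-protein normalization


def _well_comparison(values: pd.Series, wells: pd.DataFrame,
                     method: str = "t_test") -> GroupComparison:
    return group_compare(
        values.to_numpy(),
        wells["group"].to_numpy(),
        wells.get("patient"),
        method=method,
    )


def protein_per_cell(wells: pd.DataFrame) -> tuple[pd.Series, GroupComparison]:
    """Protein mass per cell for each well, plus a case/control comparison."""
    zero = wells[wells["cell_count"] <= 0]
    if len(zero):
        raise ValueError(f"zero cell count in well {zero['well'].iloc[0]!r}")
    values = wells["protein_mass"] / wells["cell_count"]
    values.name = "protein_per_cell"
    return values, _well_comparison(values, wells)


def protein_per_renilla(wells: pd.DataFrame) -> tuple[pd.Series, GroupComparison]:
    """Protein mass per unit renilla luminescence, plus group comparison."""
    zero = wells[wells["renilla_lum"] <= 0]
    if len(zero):
        raise ValueError(f"nonpositive luminescence in well {zero['well'].iloc[0]!r}")
    values = wells["protein_mass"] / wells["renilla_lum"]
    values.name = "protein_per_renilla"
    return values, _well_comparison(values, wells)


def bradford_calibration(standards_conc: Sequence[float],
                         standards_abs: Sequence[float]) -> tuple[float, float]:
    """Linear fit (slope, intercept) of absorbance against the BSA series."""
    slope, intercept, *_ = stats.linregress(standards_conc, standards_abs)
    return float(slope), float(intercept)


# ---------------------------------------------------------------------
# FACS readouts


def _split_negative(events: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    if "is_negative_control" in events.columns:
        neg = events[events["is_negative_control"]]
        sample = events[~events["is_negative_control"]]
    else:
        neg = events[events["condition"] == "negative"]
        sample = events[events["condition"] != "negative"]
    if len(neg) == 0:
        raise ValueError("no negative-control (no-label) events present")
    return sample, neg


def hpg_summary(events: pd.DataFrame, q: float = 99.0,
                min_events: int = 100) -> pd.DataFrame:
    """Median fluorescent intensity and percent positive per condition.

    The positivity threshold is the ``q``-th percentile of the pooled
    negative-control fluorescence; percent_positive is the share of a
    condition's events above it.
    """
    sample, neg = _split_negative(events)
    if len(neg) < min_events:
        raise ValueError(f"negative control has fewer than {min_events} events")
    threshold = float(np.percentile(neg["fluorescence"], q))
    rows = []
    for cond, sub in sample.groupby("condition", sort=True):
        if len(sub) < min_events:
            raise ValueError(f"condition {cond!r} has fewer than {min_events} events")
        rows.append(
            {
                "condition": cond,
                "n": len(sub),
                "mfi": float(sub["fluorescence"].median()),
                "percent_positive": float(
                    100.0 * (sub["fluorescence"] > threshold).mean()
                ),
                "threshold": threshold,
            }
        )
    return pd.DataFrame(rows).set_index("condition")


def median_fsc(events: pd.DataFrame, min_events: int = 100) -> pd.DataFrame:
    """Median forward scatter (cell-size estimate) per condition."""
    sample = events[events["condition"] != "negative"] \
        if "condition" in events.columns else events
    rows = []
    for cond, sub in sample.groupby("condition", sort=True):
        if len(sub) < min_events:
            raise ValueError(f"condition {cond!r} has fewer than {min_events} events")
        rows.append({"condition": cond, "n": len(sub),
                     "median_fsc": float(sub["fsc"].median())})
    return pd.DataFrame(rows).set_index("condition")


def batch_normalize(values: pd.DataFrame, reference_condition: str = "control",
                    value_col: str = "value") -> pd.Series:
    """Divide each value by its batch's mean reference-condition value.

    After normalization the reference condition averages 1 in every
    batch, making values comparable across independently scaled runs.
    Idempotent: normalizing twice equals normalizing once.
    """
    required = {value_col, "batch", "condition"}
    missing = required - set(values.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = values[value_col].astype(float).copy()
    for batch, sub in values.groupby("batch"):
        ref = sub[sub["condition"] == reference_condition][value_col]
        if len(ref) == 0:
            raise ValueError(f"batch {batch!r} lacks reference condition "
                             f"{reference_condition!r}")
        out.loc[sub.index] = sub[value_col] / ref.mean()
    out.name = f"{value_col}_normalized"
    return out


# ---------------------------------------------------------------------
# transforms and comparisons


def boxcox(values: Sequence[float]) -> tuple[float, np.ndarray]:
    """Box-Cox transform at the profile-likelihood-maximizing lambda."""
    values = np.asarray(values, dtype=float)
    if (values <= 0).any():
        raise ValueError("Box-Cox requires strictly positive values")
    transformed, lam = stats.boxcox(values)
    return float(lam), transformed


def group_compare(
    values: Sequence[float],
    groups: Sequence[str],
    patients: Sequence[str] | None = None,
    method: str = "t_test",
    apply_boxcox: bool = False,
    reference: str | None = None,
) -> GroupComparison:
    """Compare group means by Student's t, Tukey-Kramer HSD or nested t.

    ``nested`` collapses replicate values to one mean per patient before
    a two-sample t-test across patients, so degrees of freedom depend on
    patients, not replicates.  With ``apply_boxcox`` the test runs on
    Box-Cox-transformed values (fold is still computed on the raw scale).
    An advisory Shapiro-Wilk flag on the (transformed) residuals is
    reported; it never alters the analysis.

    The fold and t statistic are oriented as effect-over-reference; the
    reference group is ``reference`` when given, else ``control`` if
    present, else the alphabetically first label.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if reference is None and "control" in labels:
        reference = "control"
    if reference is not None:
        if reference not in labels:
            raise ValueError(f"reference group {reference!r} not present")
        labels = [reference] + [lab for lab in labels if lab != reference]
    for lab in labels:
        if (groups == lab).sum() < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 values")

    raw_means = {lab: float(values[groups == lab].mean()) for lab in labels}
    fold = raw_means[labels[-1]] / raw_means[labels[0]] \
        if raw_means[labels[0]] != 0 else np.inf

    lam = None
    tvals = values
    if apply_boxcox:
        lam, tvals = boxcox(values)

    residuals = np.concatenate(
        [tvals[groups == lab] - tvals[groups == lab].mean() for lab in labels]
    )
    try:
        normal_ok = bool(stats.shapiro(residuals).pvalue > 0.05)
    except ValueError:
        normal_ok = None

    n_per_group = {lab: int((groups == lab).sum()) for lab in labels}
    pairwise = None

    if method == "t_test":
        if len(labels) != 2:
            raise ValueError("t_test requires exactly 2 groups")
        res = stats.ttest_ind(tvals[groups == labels[1]], tvals[groups == labels[0]])
        statistic, p = float(res.statistic), float(res.pvalue)
    elif method == "tukey_kramer":
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        tk = pairwise_tukeyhsd(tvals, groups)
        pairwise = pd.DataFrame(
            tk.summary().data[1:], columns=tk.summary().data[0]
        )
        # headline: the first/last-group pair
        mask = (
            (pairwise["group1"] == labels[0]) & (pairwise["group2"] == labels[-1])
        ) | (
            (pairwise["group1"] == labels[-1]) & (pairwise["group2"] == labels[0])
        )
        row = pairwise[mask].iloc[0]
        statistic, p = float(row["meandiff"]), float(row["p-adj"])
    elif method == "nested":
        if patients is None:
            raise ValueError("nested analysis requires patient labels")
        if len(labels) != 2:
            raise ValueError("nested analysis requires exactly 2 groups")
        frame = pd.DataFrame({"v": tvals, "g": groups,
                              "patient": np.asarray(patients)})
        per_patient = frame.groupby(["g", "patient"], sort=True)["v"].mean()
        a = per_patient[labels[0]].to_numpy()
        b = per_patient[labels[1]].to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ValueError("nested analysis needs >= 2 patients per group")
        res = stats.ttest_ind(b, a)
        statistic, p = float(res.statistic), float(res.pvalue)
        n_per_group = {labels[0]: len(a), labels[1]: len(b)}
    else:
        raise ValueError(f"unsupported method {method!r}")

    return GroupComparison(
        method=method,
        group_means=raw_means,
        fold=float(fold),
        statistic=statistic,
        p_value=p,
        n_per_group=n_per_group,
        boxcox_lambda=lam,
        normality_flag=normal_ok,
        pairwise=pairwise,
    )
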