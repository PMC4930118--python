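"""Label-free differential-abundance pipeline.

The processing order follows the standard label-free workflow: filter
identifications by peptide evidence, log2-transform intensities, impute
left-censored missing values from a downshifted normal distribution,
median-center each sample, test each protein with a two-sample Student's
t-test across NPC lines, and control discoveries with a permutation-based
false discovery rate.

The model front end is statsmodels-like: build a
:class:`DifferentialAbundanceModel` from an :class:`AbundanceMatrix` and
call :meth:`~DifferentialAbundanceModel.fit` to obtain a results object
with the per-protein table, discovery counts and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from npcquant.diffabund.containers import AbundanceMatrix, ProteinRecord
from npcquant.diffabund.families import classify_family


def filter_identifications(records: Iterable[ProteinRecord]) -> list[str]:
    """Retain proteins with >= 2 peptides, at least one uniquely assigned."""
    records = list(records)
    if not records:
        raise ValueError("no protein records supplied")
    return [
        r.protein_id
        for r in records
        if r.peptide_count >= 2 and r.unique_peptide_count >= 1
    ]


def log2_transform(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """log2-transform raw intensities; missing entries stay missing."""
    vals = matrix.values.to_numpy()
    bad = (vals <= 0) & ~np.isnan(vals)
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValueError(
            "nonpositive intensity at protein "
            f"{matrix.values.index[i]!r}, sample {matrix.values.columns[j]!r}"
        )
    return matrix.with_values(np.log2(matrix.values))


def impute_missing(
    matrix: AbundanceMatrix,
    width_frac: float = 0.3,
    downshift_sd: float = 1.8,
    seed: int = 0,
) -> AbundanceMatrix:
    """Replace missing values by draws from a downshifted normal.

    Per sample ``s`` with observed mean ``m_s`` and s.d. ``sd_s``, each
    missing entry is drawn from ``Normal(m_s - downshift_sd * sd_s,
    (width_frac * sd_s)^2)``.  This is the de facto convention for
    left-censored proteomics data: imputed values land in the low tail of
    the observed distribution.  Observed values are untouched.
    """
    rng = np.random.default_rng(seed)
    out = matrix.values.copy()
    for col in out.columns:
        observed = out[col].dropna()
        n_miss = out[col].isna().sum()
        if n_miss == 0:
            continue
        if len(observed) < 2:
            raise ValueError(
                f"sample {col!r} has {len(observed)} observed values; "
                "standard deviation undefined"
            )
        m, sd = observed.mean(), observed.std(ddof=1)
        draws = rng.normal(m - downshift_sd * sd, width_frac * sd, size=n_miss)
        out.loc[out[col].isna(), col] = draws
    return matrix.with_values(out)


def median_normalize(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Subtract each sample's median so every column is centered at 0."""
    if matrix.n_missing:
        raise ValueError("median_normalize requires a fully imputed matrix")
    return matrix.with_values(matrix.values - matrix.values.median(axis=0))


# ---------------------------------------------------------------------
# testing


def _pooled_t(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pooled-variance two-sided t-test over matrix rows."""
    n1, n2 = x.shape[1], y.shape[1]
    m1, m2 = x.mean(axis=1), y.mean(axis=1)
    v1 = x.var(axis=1, ddof=1)
    v2 = y.var(axis=1, ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m2 - m1) / denom
    t = np.where((denom == 0) & (m1 == m2), 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isinf(t), 0.0, p)
    return t, p


def two_sample_test(
    matrix: AbundanceMatrix, alpha: float = 0.05, equal_var: bool = True
) -> pd.DataFrame:
    """Per-protein two-sided t-test of case vs control columns.

    Returns a frame with means, log2 fold change (case - control), the t
    statistic, the p-value, a pre-FDR ``significant`` flag at ``alpha``
    and the direction of change.
    """
    groups = matrix.groups
    x = matrix.values.loc[:, groups == "control"].to_numpy()
    y = matrix.values.loc[:, groups == "case"].to_numpy()
    if x.shape[1] < 2 or y.shape[1] < 2:
        raise ValueError("both groups need at least 2 samples")
    if equal_var:
        t, p = _pooled_t(x, y)
    else:
        t, p = stats.ttest_ind(y, x, axis=1, equal_var=False)
    log2fc = y.mean(axis=1) - x.mean(axis=1)
    return pd.DataFrame(
        {
            "gene_symbol": matrix.gene_symbols.to_numpy(),
            "mean_control": x.mean(axis=1),
            "mean_case": y.mean(axis=1),
            "log2fc": log2fc,
            "t": t,
            "p": p,
            "significant": p < alpha,
            "direction": np.where(log2fc > 0, "up", "down"),
        },
        index=matrix.protein_ids,
    )


def permutation_fdr(
    matrix: AbundanceMatrix,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    equal_var: bool = True,
) -> pd.Series:
    """Permutation-based FDR flags at level ``alpha``.

    Group labels are permuted ``n_perm`` times.  For the threshold set at
    the k-th smallest observed p-value, the estimated FDR is the mean
    permuted count of proteins at or below that p divided by k; proteins
    in the largest p-ordered set with estimated FDR <= ``alpha`` are
    flagged.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a stable FDR estimate")
    rng = np.random.default_rng(seed)
    groups = matrix.groups.to_numpy()
    data = matrix.values.to_numpy()
    n_control = int((groups == "control").sum())
    n_samples = data.shape[1]
    if n_control < 2 or n_samples - n_control < 2:
        raise ValueError("both groups need at least 2 samples")

    def pvals(labels: np.ndarray) -> np.ndarray:
        x = data[:, labels == "control"]
        y = data[:, labels == "case"]
        if equal_var:
            return _pooled_t(x, y)[1]
        return stats.ttest_ind(y, x, axis=1, equal_var=False)[1]

    observed = pvals(groups)
    order = np.argsort(observed, kind="stable")
    sorted_p = observed[order]

    perm_counts = np.zeros(len(sorted_p))
    for _ in range(n_perm):
        labels = rng.permutation(groups)
        perm_p = np.sort(pvals(labels))
        # permuted discoveries at each observed threshold
        perm_counts += np.searchsorted(perm_p, sorted_p, side="right")
    mean_perm = perm_counts / n_perm
    k = np.arange(1, len(sorted_p) + 1)
    fdr_hat = mean_perm / k
    passing = np.nonzero(fdr_hat <= alpha)[0]
    flags = np.zeros(len(sorted_p), dtype=bool)
    if passing.size:
        flags[order[: passing.max() + 1]] = True
    return pd.Series(flags, index=matrix.protein_ids, name="fdr_flag")


# ---------------------------------------------------------------------
# model / results front end


@dataclass
class DifferentialAbundanceResults:
    """Fitted per-protein differential-abundance results."""

    table: pd.DataFrame
    alpha: float
    n_perm: int
    n_control: int
    n_case: int

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    @property
    def n_discoveries(self) -> int:
        return int(self.table["fdr_flag"].sum())

    def discoveries(self) -> pd.DataFrame:
        return self.table[self.table["fdr_flag"]]

    def summary(self) -> str:
        t = self.table
        up = int((t["significant"] & (t["direction"] == "up")).sum())
        lines = [
            "Differential protein abundance (two-sided Student's t, "
            "pooled variance)",
            f"  proteins tested:            {len(t)}",
            f"  control / case lines:       {self.n_control} / {self.n_case}",
            f"  significant at p<{self.alpha:g}:     {self.n_significant} "
            f"({up} up, {self.n_significant - up} down)",
            f"  passing permutation FDR:    {self.n_discoveries} "
            f"({self.n_perm} permutations, q<{self.alpha:g})",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        out = self.table.reset_index(names="protein_id")
        out.to_csv(path, sep="\t", index=False)


class DifferentialAbundanceModel:
    """Two-group differential-abundance model for a log2 LFQ matrix.

    Parameters
    ----------
    matrix : AbundanceMatrix
        Already log2-transformed; may contain missing values, which are
        imputed during :meth:`fit` (downshifted normal) unless the matrix
        is complete.
    collapse_replicates : bool
        Average technical replicates to one value per NPC line before
        testing (the default analysis unit is the line).
    equal_var : bool
        Classical pooled-variance Student's t (default) or Welch.
    """

    def __init__(
        self,
        matrix: AbundanceMatrix,
        collapse_replicates: bool = True,
        equal_var: bool = True,
        width_frac: float = 0.3,
        downshift_sd: float = 1.8,
    ) -> None:
        self.matrix = matrix
        self.collapse_replicates = collapse_replicates
        self.equal_var = equal_var
        self.width_frac = width_frac
        self.downshift_sd = downshift_sd

    def fit(
        self, alpha: float = 0.05, n_perm: int = 1000, seed: int = 0
    ) -> DifferentialAbundanceResults:
        m = self.matrix
        if m.n_missing:
            m = impute_missing(m, self.width_frac, self.downshift_sd, seed=seed)
        m = median_normalize(m)
        if self.collapse_replicates:
            m = m.collapse_replicates()
        table = two_sample_test(m, alpha=alpha, equal_var=self.equal_var)
        table["fdr_flag"] = permutation_fdr(
            m, alpha=alpha, n_perm=n_perm, seed=seed, equal_var=self.equal_var
        )
        table["family"] = [classify_family(s) for s in table["gene_symbol"]]
        groups = m.groups
        return DifferentialAbundanceResults(
            table=table,
            alpha=alpha,
            n_perm=n_perm,
            n_control=int((groups == "control").sum()),
            n_case=int((groups == "case").sum()),
        )
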