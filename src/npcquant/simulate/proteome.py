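"""Synthetic label-free quantification matrices and SILAC ratio tables.

The default cohort layout mirrors a 6-control / 8-case NPC-line design run
in technical triplicate: control lines each come from a distinct donor,
case lines come in pairs per patient.  Missingness is
missing-not-at-random: the probability that a measurement drops out is a
logistic function of its true log2 intensity, so low-abundance proteins
are censored more often — the regime that downshifted-normal imputation
is designed for.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from npcquant.diffabund.containers import AbundanceMatrix

_FAMILY_PREFIXES = ("RPL", "RPS", "EIF", "EEF")


@dataclass(frozen=True)
class ProteomeSimSpec:
    """Design of a simulated label-free proteomics experiment.

    Parameters
    ----------
    n_proteins : int
        Total proteins quantified.
    n_family : int
        Number of translation-machinery proteins (ribosomal proteins,
        initiation and elongation factors) among ``n_proteins``.
    frac_up_family, frac_up_global : float
        Probability that an affected family / non-family protein moves up
        (rather than down) in the case group.
    effect_log2 : float
        log2 fold-change magnitude applied to affected proteins in case
        lines.
    noise_sd : float
        Measurement noise s.d. on the log2 scale, i.i.d. per measurement.
    missing_rate : float
        Overall expected fraction of missing entries.
    missing_intensity_slope : float
        Slope of the logistic intensity-dependent dropout; 0 gives
        missing-completely-at-random, larger values concentrate dropout at
        low intensities.
    n_control_lines, n_case_lines : int
        NPC lines per group; case lines are paired two-per-patient.
    n_tech_reps : int
        Technical replicates (injections) per line.
    frac_affected : float
        Fraction of proteins with a true group effect (1.0 means every
        protein carries the effect, as in a saturated design; 0 gives a
        pure null matrix).
    n_sample_dropout : int
        Whole samples (columns) removed at random, emulating failed runs.
    seed : int
        Generator seed; identical spec + seed gives identical output.
    """

    n_proteins: int = 2562
    n_family: int = 34
    frac_up_family: float = 0.97
    frac_up_global: float = 0.64
    effect_log2: float = 1.0
    noise_sd: float = 0.5
    missing_rate: float = 0.1
    missing_intensity_slope: float = 1.0
    n_control_lines: int = 6
    n_case_lines: int = 8
    n_tech_reps: int = 3
    frac_affected: float = 1.0
    n_sample_dropout: int = 0
    seed: int = 0
    baseline_mean: float = 26.0
    baseline_sd: float = 2.0

    def validate(self) -> None:
        for name in ("frac_up_family", "frac_up_global", "missing_rate", "frac_affected"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_proteins", "n_control_lines", "n_case_lines", "n_tech_reps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive count")
        if self.n_family < 0 or self.n_family > self.n_proteins:
            raise ValueError("n_family must satisfy 0 <= n_family <= n_proteins")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_sample_dropout < 0:
            raise ValueError("n_sample_dropout must be nonnegative")


@dataclass
class ProteomeTruth:
    """Per-protein ground truth serialized alongside simulated data."""

    table: pd.DataFrame = field(repr=False)

    def to_json(self) -> str:
        return self.table.to_json(orient="records")

    @property
    def directions(self) -> pd.Series:
        return self.table.set_index("protein_id")["direction"]


def _gene_symbols(spec: ProteomeSimSpec) -> list[str]:
    symbols = []
    for i in range(spec.n_family):
        prefix = _FAMILY_PREFIXES[i % len(_FAMILY_PREFIXES)]
        symbols.append(f"{prefix}{i // len(_FAMILY_PREFIXES) + 1}")
    symbols.extend(f"GENE{i + 1}" for i in range(spec.n_proteins - spec.n_family))
    return symbols


def _sample_meta(spec: ProteomeSimSpec) -> pd.DataFrame:
    rows = []
    for i in range(spec.n_control_lines):
        line = f"C{i + 1}"
        for r in range(spec.n_tech_reps):
            rows.append((f"{line}_r{r + 1}", "control", line, line, r + 1))
    for i in range(spec.n_case_lines):
        patient = f"P{i // 2 + 1}"
        line = f"{patient}{'AB'[i % 2]}"
        for r in range(spec.n_tech_reps):
            rows.append((f"{line}_r{r + 1}", "case", patient, line, r + 1))
    meta = pd.DataFrame(rows, columns=["sample", "group", "patient", "line", "replicate"])
    return meta.set_index("sample")


def _draw_directions(
    rng: np.random.Generator, spec: ProteomeSimSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Return (direction per protein, signed effect per protein)."""
    n = spec.n_proteins
    family = np.zeros(n, dtype=bool)
    family[: spec.n_family] = True
    affected = (rng.random(n) < spec.frac_affected) & (spec.effect_log2 != 0)
    p_up = np.where(family, spec.frac_up_family, spec.frac_up_global)
    up = rng.random(n) < p_up
    direction = np.where(affected, np.where(up, "up", "down"), "null")
    effect = np.where(affected, np.where(up, 1.0, -1.0) * spec.effect_log2, 0.0)
    return direction, effect


def _missingness_threshold(values: np.ndarray, slope: float, rate: float) -> float:
    """Solve for the logistic midpoint giving the requested overall rate."""
    lo, hi = values.min() - 60.0, values.max() + 60.0

    def mean_rate(x0: float) -> float:
        return float(expit(slope * (x0 - values)).mean()) - rate

    return brentq(mean_rate, lo, hi, xtol=1e-6)


def gen_lfq_matrix(spec: ProteomeSimSpec) -> tuple[AbundanceMatrix, ProteomeTruth]:
    """Simulate a proteins x samples log2 LFQ matrix with known truth.

    Family proteins shift up in case lines with probability
    ``frac_up_family`` (down otherwise); non-family proteins follow
    ``frac_up_global``.  Dropout probability rises logistically as the
    underlying intensity falls.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    meta = _sample_meta(spec)
    symbols = _gene_symbols(spec)
    protein_ids = [f"PROT{i + 1:05d}" for i in range(spec.n_proteins)]

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=spec.n_proteins)
    direction, effect = _draw_directions(rng, spec)

    is_case = (meta["group"] == "case").to_numpy()
    true_vals = baseline[:, None] + np.where(is_case[None, :], effect[:, None], 0.0)
    values = true_vals + rng.normal(0.0, spec.noise_sd, size=true_vals.shape)

    if spec.missing_rate > 0:
        if spec.missing_intensity_slope > 0:
            x0 = _missingness_threshold(
                true_vals.ravel(), spec.missing_intensity_slope, spec.missing_rate
            )
            p_miss = expit(spec.missing_intensity_slope * (x0 - true_vals))
        else:
            p_miss = np.full_like(true_vals, spec.missing_rate)
        values = np.where(rng.random(values.shape) < p_miss, np.nan, values)

    if spec.n_sample_dropout > 0:
        drop = rng.choice(meta.shape[0], size=spec.n_sample_dropout, replace=False)
        keep = np.setdiff1d(np.arange(meta.shape[0]), drop)
        values = values[:, keep]
        meta = meta.iloc[keep]

    frame = pd.DataFrame(values, index=protein_ids, columns=meta.index)
    matrix = AbundanceMatrix(
        values=frame,
        sample_meta=meta,
        gene_symbols=pd.Series(symbols, index=protein_ids, name="gene_symbol"),
    )
    truth = ProteomeTruth(
        pd.DataFrame(
            {
                "protein_id": protein_ids,
                "gene_symbol": symbols,
                "family": [i < spec.n_family for i in range(spec.n_proteins)],
                "direction": direction,
                "effect_log2": effect,
            }
        )
    )
    return matrix, truth


def gen_silac_pairs(
    spec: ProteomeSimSpec, n_pairs: int = 4
) -> tuple[list[pd.DataFrame], ProteomeTruth]:
    """Simulate pairwise SILAC comparison tables.

    ``spec.n_proteins`` is interpreted as the pooled count of significant
    protein entries across all pairs (as a published per-comparison total
    row would count them, duplicates included), ``spec.n_family`` the
    pooled count of significant translation-machinery entries.  Each table
    also carries an equal number of non-significant filler proteins.
    """
    spec.validate()
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(spec.seed)

    fam_per_pair = np.full(n_pairs, spec.n_family // n_pairs)
    fam_per_pair[: spec.n_family % n_pairs] += 1
    n_other = spec.n_proteins - spec.n_family
    other_per_pair = np.full(n_pairs, n_other // n_pairs)
    other_per_pair[: n_other % n_pairs] += 1

    tables: list[pd.DataFrame] = []
    truth_rows = []
    for p in range(n_pairs):
        pair = f"pair{p + 1}"
        rows = []
        fam_idx = 0
        for kind, count in (("family", fam_per_pair[p]), ("other", other_per_pair[p])):
            p_up = spec.frac_up_family if kind == "family" else spec.frac_up_global
            for j in range(int(count)):
                if kind == "family":
                    prefix = _FAMILY_PREFIXES[fam_idx % len(_FAMILY_PREFIXES)]
                    symbol = f"{prefix}{p + 1}_{fam_idx}"
                    fam_idx += 1
                else:
                    symbol = f"GENE{p + 1}_{j}"
                up = rng.random() < p_up
                mag = abs(rng.normal(spec.effect_log2, spec.noise_sd)) + 0.1
                ratio = mag if up else -mag
                rows.append((f"{pair}_{symbol}", symbol, ratio, True))
                truth_rows.append((pair, symbol, kind == "family", "up" if up else "down"))
        # non-significant filler proteins
        n_fill = len(rows)
        for j in range(n_fill):
            symbol = f"NS{p + 1}_{j}"
            rows.append((f"{pair}_{symbol}", symbol, rng.normal(0, spec.noise_sd), False))
            truth_rows.append((pair, symbol, False, "null"))
        tables.append(
            pd.DataFrame(rows, columns=["protein_id", "gene_symbol", "log2_ratio", "significant"])
        )
    truth = ProteomeTruth(
        pd.DataFrame(truth_rows, columns=["comparison", "gene_symbol", "family", "direction"])
        .assign(protein_id=lambda d: d["comparison"] + "_" + d["gene_symbol"])
    )
    return tables, truth


def null_spec(**overrides) -> ProteomeSimSpec:
    """A zero-effect spec for calibration runs; overrides applied on top."""
    base = dict(effect_log2=0.0, n_family=0, frac_affected=0.0)
    base.update(overrides)
    return dataclasses.replace(ProteomeSimSpec(), **base)
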