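"""Block-correlated data for coexpression-module recovery benchmarks.

Each planted module is driven by one latent factor: a member's profile is
``sqrt(r) * factor + sqrt(1-r) * noise`` so the expected Pearson
correlation between two members is ``r``.  Between-module correlation is
induced by sharing a common component across factors; background proteins
are pure noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ModuleSimSpec:
    """Design of a planted-module coexpression data set."""

    module_sizes: tuple[int, ...] = (60, 50, 40, 30)
    n_background: int = 50
    intra_cor: float = 0.75
    inter_cor: float = 0.05
    n_samples: int = 60
    seed: int = 0

    @property
    def n_proteins(self) -> int:
        return sum(self.module_sizes) + self.n_background

    def validate(self) -> None:
        if any(s <= 0 for s in self.module_sizes):
            raise ValueError("module sizes must be positive")
        if self.n_background < 0:
            raise ValueError("n_background must be nonnegative")
        if not 0.0 <= self.inter_cor < self.intra_cor <= 1.0:
            raise ValueError("require 0 <= inter_cor < intra_cor <= 1")
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4 for meaningful correlations")


@dataclass
class ModuleTruth:
    labels: pd.Series = field(repr=False)

    def to_json(self) -> str:
        return self.labels.to_json()


def gen_correlated_modules(spec: ModuleSimSpec) -> tuple[pd.DataFrame, ModuleTruth]:
    """Simulate a proteins x samples matrix with planted correlated blocks."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_mod = len(spec.module_sizes)

    # factor correlation c chosen so between-module member correlation
    # = intra_cor * c = inter_cor
    c = spec.inter_cor / spec.intra_cor
    shared = rng.standard_normal(spec.n_samples)
    factors = np.sqrt(c) * shared + np.sqrt(1 - c) * rng.standard_normal(
        (n_mod, spec.n_samples)
    )

    rows = []
    ids = []
    labels = []
    load = np.sqrt(spec.intra_cor)
    for m, size in enumerate(spec.module_sizes):
        name = f"M{m + 1}"
        noise = rng.standard_normal((size, spec.n_samples))
        rows.append(load * factors[m][None, :] + np.sqrt(1 - spec.intra_cor) * noise)
        ids.extend(f"{name}_P{i + 1}" for i in range(size))
        labels.extend([name] * size)
    if spec.n_background:
        rows.append(rng.standard_normal((spec.n_background, spec.n_samples)))
        ids.extend(f"BG_P{i + 1}" for i in range(spec.n_background))
        labels.extend(["background"] * spec.n_background)

    data = pd.DataFrame(
        np.vstack(rows), index=ids, columns=[f"S{j + 1}" for j in range(spec.n_samples)]
    )
    return data, ModuleTruth(pd.Series(labels, index=ids, name="module"))


def gen_scale_free_correlation(n: int = 500, rate: float = 6.2) -> pd.DataFrame:
    """Correlation matrix whose power adjacency turns scale-free at beta ~6.5.

    Node propensities ``e_i`` follow deterministic exponential quantiles
    with the given ``rate`` and correlations are ``exp(-(e_i + e_j))``,
    so the power adjacency at exponent beta has connectivity
    ``k_i ~ exp(-beta * e_i)`` — a power-law degree distribution whose
    log-log frequency slope turns negative (and the signed scale-free
    fit turns high) only once beta exceeds ``rate``.  With the default
    rate, beta = 6.5 is the smallest half-integer candidate at which the
    network is approximately scale-free.
    """
    u = (np.arange(n) + 0.5) / n
    e = -np.log(1.0 - u) / rate
    r = np.exp(-(e[:, None] + e[None, :]))
    np.fill_diagonal(r, 1.0)
    ids = [f"N{i + 1}" for i in range(n)]
    return pd.DataFrame(r, index=ids, columns=ids)
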