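"""In-memory containers for label-free quantification data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ProteinRecord:
    """Identification evidence for one protein group."""

    protein_id: str
    gene_symbol: str = ""
    peptide_count: int = 0
    unique_peptide_count: int = 0

    def __post_init__(self) -> None:
        if self.unique_peptide_count > self.peptide_count:
            raise ValueError(
                f"{self.protein_id}: unique_peptide_count "
                f"({self.unique_peptide_count}) exceeds peptide_count "
                f"({self.peptide_count})"
            )


@dataclass
class AbundanceMatrix:
    """Proteins x samples quantification matrix with sample metadata.

    ``values`` holds one row per protein and one column per sample; missing
    measurements are ``NaN``.  ``sample_meta`` is indexed by sample id and
    must provide ``group`` (``control``/``case``), ``patient``, ``line``
    and ``replicate`` columns.  ``gene_symbols`` maps protein id to gene
    symbol.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    gene_symbols: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.sample_meta.index):
            raise ValueError("values columns and sample_meta index must match")
        if "group" not in self.sample_meta.columns:
            raise ValueError("sample_meta must have a 'group' column")
        unknown = set(self.sample_meta["group"]) - {"control", "case"}
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")
        if self.gene_symbols is None:
            self.gene_symbols = pd.Series(
                self.values.index, index=self.values.index, name="gene_symbol"
            )
        if not self.gene_symbols.index.equals(self.values.index):
            raise ValueError("gene_symbols index must match protein ids")

    # -- basic views ---------------------------------------------------
    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    @property
    def groups(self) -> pd.Series:
        return self.sample_meta["group"]

    def with_values(self, values: pd.DataFrame) -> "AbundanceMatrix":
        return AbundanceMatrix(values, self.sample_meta.copy(), self.gene_symbols.copy())

    # -- replicate handling --------------------------------------------
    def collapse_replicates(self) -> "AbundanceMatrix":
        """Average technical replicates to one column per NPC line."""
        if "line" not in self.sample_meta.columns:
            raise ValueError("sample_meta must have a 'line' column to collapse")
        lines = self.sample_meta["line"]
        collapsed = self.values.T.groupby(lines, sort=False).mean().T
        meta = self.sample_meta.groupby(lines, sort=False).first()[["group", "patient"]]
        meta["line"] = meta.index
        meta["replicate"] = 1
        meta.index.name = "sample"
        return AbundanceMatrix(collapsed[meta.index], meta, self.gene_symbols.copy())

    # -- I/O -----------------------------------------------------------
    def to_tsv(self, values_path, meta_path=None) -> None:
        self.values.to_csv(values_path, sep="\t", na_rep="NA", index_label="protein_id")
        if meta_path is not None:
            self.sample_meta.to_csv(meta_path, sep="\t")

    @classmethod
    def from_tsv(cls, values_path, meta_path) -> "AbundanceMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col=0, na_values=["NA"])
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        meta = meta.loc[values.columns]
        return cls(values, meta)

    def checksum(self) -> str:
        """Stable content hash used by determinism checks."""
        import hashlib

        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.values.to_numpy()).tobytes())
        h.update("|".join(map(str, self.values.columns)).encode())
        h.update("|".join(map(str, self.values.index)).encode())
        return h.hexdigest()
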