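"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from npcquant.simulate import ImageSimSpec, ProteomeSimSpec, gen_image, gen_lfq_matrix


def match_cells(cells: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Match measured cells to truth records by nearest centroid.

    A match requires the centroid distance to be under the true cell's
    radius.  Returns one row per measured cell with the matched truth
    index (-1 when unmatched).
    """
    matches = []
    for _, row in cells.iterrows():
        d2 = (truth["cx"] - row["cx"]) ** 2 + (truth["cy"] - row["cy"]) ** 2
        j = d2.idxmin()
        ok = np.sqrt(d2[j]) < truth.loc[j, "diameter"] / 2
        matches.append(j if ok else -1)
    out = cells.copy()
    out["truth_idx"] = matches
    return out


def detection_scores(cells: pd.DataFrame, truth: pd.DataFrame) -> dict[str, float]:
    """Recall / precision / classification accuracy vs ground truth."""
    matched = match_cells(cells, truth)
    hits = matched[matched["truth_idx"] >= 0]
    unique_hits = hits["truth_idx"].nunique()
    recall = unique_hits / len(truth) if len(truth) else 1.0
    precision = len(hits) / len(cells) if len(cells) else 1.0
    if len(hits):
        correct = sum(
            truth.loc[j, "classification"] == c
            for j, c in zip(hits["truth_idx"], hits["classification"])
        )
        accuracy = correct / len(hits)
    else:
        accuracy = 0.0
    return {"recall": recall, "precision": precision, "accuracy": accuracy}


@pytest.fixture(scope="session")
def small_lfq():
    """A small complete-case LFQ matrix with effects, shared across tests."""
    spec = ProteomeSimSpec(n_proteins=300, n_family=20, missing_rate=0.05, seed=42)
    return gen_lfq_matrix(spec)


@pytest.fixture(scope="session")
def default_field():
    """One default 50-cell synthetic field plus ground truth."""
    return gen_image(ImageSimSpec(seed=3))
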