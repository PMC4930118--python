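"""Weighted protein coexpression network construction and module detection.

Pipeline: Pearson correlation -> soft-threshold power adjacency
``a_ij = |r_ij|^beta`` (beta picked for approximate scale-free topology)
-> topological overlap matrix (TOM) -> average-linkage clustering of the
TOM dissimilarity -> dynamic branch cutting into modules, labeled by a
fixed color palette ordered by module size, with poorly connected
proteins collected in 'grey'.  Hubness within a module is the sum of a
protein's power-transformed correlations to co-module members (kIM).

The front end mirrors statsmodels: build :class:`CoexpressionNetwork`
from a proteins x conditions matrix, call
:meth:`~CoexpressionNetwork.fit`, and interrogate the returned
:class:`CoexpressionResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom

#: Module color sequence (size-ordered); 'grey' is reserved for unassigned.
COLOR_PALETTE = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
)

GREY = "grey"


def correlation_matrix(data: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations between proteins (rows of ``data``).

    Uses pairwise-complete observations when values are missing.
    Zero-variance proteins are dropped with a warning.
    """
    if data.shape[1] < 4:
        raise ValueError("need at least 4 samples/conditions for correlations")
    variances = data.var(axis=1, ddof=1)
    degenerate = variances.index[(variances == 0) | variances.isna()]
    if len(degenerate):
        warnings.warn(
            f"dropping {len(degenerate)} zero-variance protein(s): "
            f"{list(degenerate[:5])}...",
            stacklevel=2,
        )
        data = data.drop(index=degenerate)
    cor = data.T.corr(min_periods=3)
    cor = cor.clip(-1.0, 1.0)
    np.fill_diagonal(cor.values, 1.0)
    return cor


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log degree-distribution fit.

    Connectivities are binned (equal-width, 10 bins), and log10 frequency
    is regressed on the log10 mean connectivity per bin.  The returned
    value is ``-sign(slope) * R^2``: a genuinely scale-free network has
    few high-k hubs and many low-k nodes, i.e. a *decreasing* frequency
    in k, so positively sloped fits are penalized rather than rewarded.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 2 or np.ptp(k) < 1e-12:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-9, n_bins + 1)
    idx = np.digitize(k, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        members = k[idx == b]
        if members.size == 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(members.size / k.size))
    if len(xs) < 3:
        return 0.0
    slope = np.polyfit(xs, ys, 1)[0]
    r = np.corrcoef(xs, ys)[0, 1]
    return float(-np.sign(slope) * r * r)


def pick_soft_threshold(
    cor: pd.DataFrame,
    candidate_betas: Sequence[float] = (1, 2, 3, 4, 5, 6, 6.5, 7, 8, 9, 10, 12),
    r2_target: float = 0.8,
    signed: bool = False,
) -> tuple[float, pd.DataFrame]:
    """Choose the smallest power giving approximate scale-free topology.

    Returns (beta, diagnostics) where diagnostics holds the fit R^2 and
    mean connectivity per candidate.  Falls back to the argmax R^2 when
    no candidate reaches ``r2_target``.
    """
    candidates = list(candidate_betas)
    if not candidates:
        raise ValueError("candidate_betas must be non-empty")
    rows = []
    for beta in candidates:
        adj = _power_adjacency(cor.to_numpy(), beta, signed)
        k = adj.sum(axis=1)
        if np.ptp(k) < 1e-12:
            warnings.warn(
                f"degenerate connectivity at beta={beta}; fit undefined",
                stacklevel=2,
            )
            rows.append((beta, 0.0, float(k.mean())))
            continue
        rows.append((beta, scale_free_fit(k), float(k.mean())))
    diag = pd.DataFrame(rows, columns=["beta", "r2", "mean_k"])
    reaching = diag[diag["r2"] >= r2_target]
    beta = float(
        reaching["beta"].iloc[0] if len(reaching) else diag.loc[diag["r2"].idxmax(), "beta"]
    )
    return beta, diag


def _power_adjacency(cor: np.ndarray, beta: float, signed: bool) -> np.ndarray:
    if signed:
        adj = ((1.0 + cor) / 2.0) ** beta
    else:
        adj = np.abs(cor) ** beta
    np.fill_diagonal(adj, 0.0)
    return adj


def adjacency(cor: pd.DataFrame, beta: float, signed: bool = False) -> pd.DataFrame:
    """Soft-threshold power adjacency ``|r|^beta`` (unsigned default).

    The diagonal is stored as 0 so that row sums are node connectivities.
    """
    if beta <= 0:
        raise ValueError("beta must be > 0")
    return pd.DataFrame(
        _power_adjacency(cor.to_numpy(dtype=float), beta, signed),
        index=cor.index,
        columns=cor.columns,
    )


def tom(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) off
    the diagonal, TOM_ii = 1.  Entries with nonpositive denominator
    (isolated pairs) are set to 0.
    """
    a = adj.to_numpy(dtype=float)
    shared = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (shared + a) / denom
    t[denom <= 0] = 0.0
    np.fill_diagonal(t, 1.0)
    return pd.DataFrame(t, index=adj.index, columns=adj.columns)


# ---------------------------------------------------------------------
# module detection


def _recursive_split(
    indices: np.ndarray,
    diss: np.ndarray,
    min_module_size: int,
    deep_split: int,
) -> list[np.ndarray]:
    """Deeper branch decomposition within one static-cut cluster.

    A candidate split re-cuts the cluster's own dendrogram at a height
    controlled by ``deep_split`` (larger values cut lower, splitting more
    aggressively) and is accepted only when every resulting piece meets
    ``min_module_size``.
    """
    if deep_split <= 0 or len(indices) < 2 * min_module_size:
        return [indices]
    sub = diss[np.ix_(indices, indices)]
    z = linkage(squareform(sub, checks=False), method="average")
    heights = z[:, 2]
    h_min, h_max = float(heights.min()), float(heights.max())
    if h_max - h_min < 1e-12:
        return [indices]
    h_cut = h_min + (1.0 - 0.2 * min(deep_split, 4)) * (h_max - h_min)
    labels = fcluster(z, t=h_cut, criterion="distance")
    parts = [indices[labels == lab] for lab in np.unique(labels)]
    if len(parts) < 2 or any(len(p) < min_module_size for p in parts):
        return [indices]
    out: list[np.ndarray] = []
    for part in parts:
        out.extend(_recursive_split(part, diss, min_module_size, deep_split))
    return out


def cluster_modules(
    tom_diss: pd.DataFrame,
    min_module_size: int = 18,
    cut_height: float = 0.99,
    deep_split: int = 2,
) -> pd.Series:
    """Average-linkage clustering plus dynamic branch cut into modules.

    The dendrogram is cut statically at ``cut_height``; branches are then
    decomposed recursively (see :func:`_recursive_split`).  Clusters
    below ``min_module_size`` are assigned 'grey'; surviving modules get
    palette colors in decreasing size order (ties broken by first member).
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    if tom_diss.shape[0] != tom_diss.shape[1]:
        raise ValueError("dissimilarity must be square")
    ids = tom_diss.index
    n = len(ids)
    if n == 1:
        return pd.Series([GREY], index=ids, name="module")
    diss = tom_diss.to_numpy(dtype=float)
    z = linkage(squareform(diss, checks=False), method="average")
    coarse = fcluster(z, t=cut_height, criterion="distance")

    clusters: list[np.ndarray] = []
    for lab in np.unique(coarse):
        members = np.nonzero(coarse == lab)[0]
        if len(members) < min_module_size:
            continue
        clusters.extend(_recursive_split(members, diss, min_module_size, deep_split))
    clusters = [c for c in clusters if len(c) >= min_module_size]
    clusters.sort(key=lambda c: (-len(c), int(c.min())))

    labels = np.full(n, GREY, dtype=object)
    for rank, members in enumerate(clusters):
        color = (
            COLOR_PALETTE[rank]
            if rank < len(COLOR_PALETTE)
            else f"module{rank + 1}"
        )
        labels[members] = color
    return pd.Series(labels, index=ids, name="module")


def within_module_connectivity(adj: pd.DataFrame, modules: pd.Series) -> pd.Series:
    """kIM: per protein, sum of adjacency weights to co-module members.

    Grey members are scored over the grey set but should be read as
    unassigned (flagged downstream).
    """
    modules = modules.loc[adj.index]
    a = adj.to_numpy(dtype=float)
    kim = np.zeros(len(adj))
    for color in modules.unique():
        members = np.nonzero((modules == color).to_numpy())[0]
        block = a[np.ix_(members, members)]
        kim[members] = block.sum(axis=1)
    return pd.Series(kim, index=adj.index, name="kIM")


def hub_proteins(
    conn: pd.Series, modules: pd.Series, top_n: int = 5, include_grey: bool = False
) -> dict[str, list[str]]:
    """Per-module protein ids ranked by kIM (descending, id tie-break)."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    out: dict[str, list[str]] = {}
    for color in modules.unique():
        if color == GREY and not include_grey:
            continue
        members = conn[modules == color]
        ranked = sorted(members.items(), key=lambda kv: (-kv[1], kv[0]))
        out[color] = [pid for pid, _ in ranked[:top_n]]
    return out


def module_enrichment(
    modules: pd.Series,
    gene_sets: Mapping[str, Iterable[str]],
    background: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of gene sets in each module.

    fold = (overlap / module size) / (set size / background size); the
    Bonferroni column multiplies the raw upper-tail p by the number of
    (module, set) tests, capped at 1.
    """
    background = set(background)
    if not background:
        raise ValueError("background must be non-empty")
    sets = {name: set(v) & background for name, v in gene_sets.items()}
    for name, members in sets.items():
        if not set(gene_sets[name]) <= background:
            raise ValueError(f"gene set {name!r} is not a subset of the background")
    colors = [c for c in modules.unique() if c != GREY]
    n_tests = max(len(colors) * len(sets), 1)
    rows = []
    for color in colors:
        module_members = set(modules.index[modules == color]) & background
        for name, members in sets.items():
            overlap = len(module_members & members)
            m, s, bg = len(module_members), len(members), len(background)
            p = float(hypergeom.sf(overlap - 1, bg, s, m)) if m and s else 1.0
            fold = (overlap / m) / (s / bg) if m and s else 0.0
            rows.append((color, name, m, s, overlap, fold, p, min(1.0, p * n_tests)))
    return pd.DataFrame(
        rows,
        columns=[
            "module", "gene_set", "module_size", "set_size", "overlap",
            "fold", "p", "p_bonferroni",
        ],
    )


# ---------------------------------------------------------------------
# model / results front end


@dataclass
class CoexpressionResults:
    """Fitted coexpression network: matrices, modules and connectivity."""

    correlation: pd.DataFrame = field(repr=False)
    adjacency: pd.DataFrame = field(repr=False)
    tom: pd.DataFrame = field(repr=False)
    modules: pd.Series = field(repr=False)
    connectivity: pd.Series = field(repr=False)
    beta: float = 6.5
    soft_threshold_diagnostics: pd.DataFrame | None = None

    @property
    def module_sizes(self) -> pd.Series:
        sizes = self.modules.value_counts()
        return sizes[sizes.index != GREY]

    @property
    def n_modules(self) -> int:
        return int((self.modules.value_counts().index != GREY).sum())

    def hub_proteins(self, top_n: int = 5) -> dict[str, list[str]]:
        return hub_proteins(self.connectivity, self.modules, top_n)

    def module_enrichment(self, gene_sets, background=None) -> pd.DataFrame:
        if background is None:
            background = list(self.modules.index)
        return module_enrichment(self.modules, gene_sets, background)

    def summary(self) -> str:
        sizes = self.module_sizes
        lines = [
            "Weighted coexpression network",
            f"  proteins:            {len(self.modules)}",
            f"  soft threshold beta: {self.beta:g}",
            f"  modules (non-grey):  {self.n_modules}",
        ]
        if len(sizes):
            lines.append(
                f"  module sizes:        {sizes.max()} (largest) .. "
                f"{sizes.min()} (smallest)"
            )
        lines.append(f"  grey (unassigned):   {int((self.modules == GREY).sum())}")
        return "\n".join(lines)

    # -- exports -------------------------------------------------------
    def assignment_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"module": self.modules, "kIM": self.connectivity}
        ).rename_axis("protein_id")

    def edge_list(self, min_adjacency: float = 0.0) -> pd.DataFrame:
        a = self.adjacency.to_numpy()
        t = self.tom.to_numpy()
        iu, ju = np.triu_indices(len(a), k=1)
        keep = a[iu, ju] >= min_adjacency
        ids = self.adjacency.index.to_numpy()
        return pd.DataFrame(
            {
                "i": ids[iu[keep]],
                "j": ids[ju[keep]],
                "adjacency": a[iu, ju][keep],
                "tom": t[iu, ju][keep],
            }
        )

    def to_graphml(self, path, min_adjacency: float = 0.0) -> None:
        import networkx as nx

        g = nx.Graph()
        for pid in self.modules.index:
            g.add_node(
                pid, module=str(self.modules[pid]), kIM=float(self.connectivity[pid])
            )
        for _, row in self.edge_list(min_adjacency).iterrows():
            g.add_edge(row["i"], row["j"], adjacency=row["adjacency"], tom=row["tom"])
        nx.write_graphml(g, path)


class CoexpressionNetwork:
    """Weighted coexpression network model for a proteins x conditions matrix.

    Parameters
    ----------
    data : DataFrame
        Proteins as rows, conditions (samples, ratios) as columns.
    beta : float, optional
        Soft-threshold power; when None it is chosen by the scale-free
        topology criterion over ``candidate_betas``.
    signed : bool
        Unsigned network ``|r|^beta`` (default) or signed
        ``((1+r)/2)^beta``.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        beta: float | None = 6.5,
        candidate_betas: Sequence[float] = (1, 2, 3, 4, 5, 6, 6.5, 7, 8, 9, 10, 12),
        r2_target: float = 0.8,
        min_module_size: int = 18,
        cut_height: float = 0.99,
        deep_split: int = 2,
        signed: bool = False,
    ) -> None:
        self.data = data
        self.beta = beta
        self.candidate_betas = candidate_betas
        self.r2_target = r2_target
        self.min_module_size = min_module_size
        self.cut_height = cut_height
        self.deep_split = deep_split
        self.signed = signed

    def fit(self) -> CoexpressionResults:
        cor = correlation_matrix(self.data)
        diag = None
        beta = self.beta
        if beta is None:
            beta, diag = pick_soft_threshold(
                cor, self.candidate_betas, self.r2_target, self.signed
            )
        adj = adjacency(cor, beta, self.signed)
        t = tom(adj)
        modules = cluster_modules(
            1.0 - t, self.min_module_size, self.cut_height, self.deep_split
        )
        conn = within_module_connectivity(adj, modules)
        return CoexpressionResults(
            correlation=cor,
            adjacency=adj,
            tom=t,
            modules=modules,
            connectivity=conn,
            beta=float(beta),
            soft_threshold_diagnostics=diag,
        )
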