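"""Descriptive statistics: log2 transform, correlation-distance clustering,
pooled-sd pairwise t-tests with BH correction.

The clustering mirrors the classical expression-heatmap recipe: samples are
compared by Pearson correlation between their signal profiles, distance
1 - r, agglomerated with average linkage.  The pairwise t-tests follow the
default behaviour of R's ``pairwise.t.test``: the standard deviation is
pooled across *all* tumor-type groups (not just the compared pair), with
Welch's per-pair test available behind a flag.  BH correction is applied
within each tumor-type pair across antibodies by default (``per_pair``);
``global`` pools all pairs into one family.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import t as t_dist

from .peaks import SignalMatrix
from .selection import bh_adjust

__all__ = [
    "ClusterTree",
    "PairwiseTestTable",
    "log2_transform",
    "hierarchical_cluster",
    "pairwise_ttests",
    "count_significant",
    "pooled_sd_ttest",
]


def log2_transform(matrix: SignalMatrix, floor: float = 1.0) -> SignalMatrix:
    """log2(max(value, floor)); missing entries stay missing."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    values = np.log2(matrix.values.clip(lower=floor))
    return SignalMatrix(values, matrix.signal_info.copy(), log2=True,
                        detection_floor=matrix.detection_floor)


@dataclass
class ClusterTree:
    """Average-linkage tree over samples on distance 1 - Pearson r."""

    linkage_matrix: np.ndarray
    labels: list[str]
    leaf_order: list[str]

    def to_newick(self) -> str:
        from skbio.tree import TreeNode
        tree = TreeNode.from_linkage_matrix(self.linkage_matrix, self.labels)
        return str(tree).strip()

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def correlation_distances(matrix: SignalMatrix, min_shared: int = 3) -> pd.DataFrame:
    """Pairwise 1 - r between sample columns, pairwise-complete observations.

    A zero-variance profile gets the maximal distance 2 to everything
    (with a warning); fewer than ``min_shared`` shared non-missing
    antibodies is an error.
    """
    samples = matrix.sample_ids
    vals = matrix.values
    n = len(samples)
    dist = np.zeros((n, n))
    warned = False
    for i, j in itertools.combinations(range(n), 2):
        x = vals.iloc[:, i].to_numpy(dtype=float)
        y = vals.iloc[:, j].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < min_shared:
            raise ValueError(f"samples {samples[i]} and {samples[j]} share "
                             f"only {int(ok.sum())} non-missing antibodies")
        xs, ys = x[ok], y[ok]
        if np.std(xs) == 0 or np.std(ys) == 0:
            if not warned:
                warnings.warn("zero-variance profile: distance set to maximum (2)")
                warned = True
            d = 2.0
        else:
            d = 1.0 - float(np.corrcoef(xs, ys)[0, 1])
        dist[i, j] = dist[j, i] = d
    return pd.DataFrame(dist, index=samples, columns=samples)


def _leaf_order(link: np.ndarray, labels: list[str]) -> list[str]:
    """Deterministic leaf order: smaller subtree first, lexicographic tie-break."""
    n = len(labels)

    def leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        left, right = int(link[node - n, 0]), int(link[node - n, 1])
        a, b = leaves(left), leaves(right)
        ka = (len(a), min(labels[i] for i in a))
        kb = (len(b), min(labels[i] for i in b))
        return a + b if ka <= kb else b + a

    return [labels[i] for i in leaves(2 * n - 2)]


def hierarchical_cluster(matrix: SignalMatrix, min_shared: int = 3) -> ClusterTree:
    """Agglomerative average-linkage tree on sample correlation distances."""
    if len(matrix.sample_ids) < 2:
        raise ValueError("need at least two samples to cluster")
    dist = correlation_distances(matrix, min_shared=min_shared)
    condensed = squareform(dist.to_numpy(), checks=False)
    link = linkage(condensed, method="average")
    labels = list(dist.index)
    return ClusterTree(link, labels, _leaf_order(link, labels))


def pooled_sd_ttest(values: np.ndarray, groups: np.ndarray,
                    pair: tuple[str, str]) -> tuple[float, float]:
    """t statistic and two-sided p for one group pair, sd pooled over all groups.

    Mirrors R ``pairwise.t.test(pool.sd = TRUE)``: s_p^2 = SS_within / (N - k)
    over every group present, t = (m_i - m_j) / (s_p * sqrt(1/n_i + 1/n_j)),
    df = N - k.
    """
    mask = ~np.isnan(values)
    values, groups = values[mask], groups[mask]
    uniq = [g for g in pd.unique(groups)]
    ns = {g: int((groups == g).sum()) for g in uniq}
    if ns.get(pair[0], 0) < 2 or ns.get(pair[1], 0) < 2:
        return float("nan"), float("nan")
    ss = sum(float(((values[groups == g] - values[groups == g].mean()) ** 2).sum())
             for g in uniq)
    df = int(len(values) - len(uniq))
    if df <= 0:
        return float("nan"), float("nan")
    sp = np.sqrt(ss / df)
    mi = float(values[groups == pair[0]].mean())
    mj = float(values[groups == pair[1]].mean())
    se = sp * np.sqrt(1.0 / ns[pair[0]] + 1.0 / ns[pair[1]])
    if se == 0:
        return (0.0, 1.0) if mi == mj else (float("inf"), 0.0)
    t = (mi - mj) / se
    p = 2.0 * float(t_dist.sf(abs(t), df))
    return t, min(p, 1.0)


@dataclass
class PairwiseTestTable:
    """BH-adjusted p-values per (tumor-type pair) x antibody, plus counts."""

    p_values: pd.DataFrame          # raw p; rows = "A|B" pairs, cols = signals
    p_bh: pd.DataFrame
    t_values: pd.DataFrame
    alpha: float = 0.05

    @property
    def significant_counts(self) -> pd.Series:
        return (self.p_bh < self.alpha).sum(axis=1)

    def significant_sets(self) -> dict[str, set[str]]:
        return {pair: set(self.p_bh.columns[(self.p_bh.loc[pair] < self.alpha).fillna(False)])
                for pair in self.p_bh.index}


def pairwise_ttests(matrix: SignalMatrix, metadata: pd.DataFrame,
                    panel: list[str] | None = None, alpha: float = 0.05,
                    bh_scope: str = "per_pair", welch: bool = False
                    ) -> PairwiseTestTable:
    """Per-antibody t-tests for every tumor-type pair, BH-corrected.

    ``panel`` optionally restricts the tested signal rows.  A pair is tested
    for an antibody only with >= 2 non-missing values per group; untestable
    cells stay missing and are excluded from the BH family size.
    """
    if bh_scope not in ("per_pair", "global"):
        raise ValueError("bh_scope must be 'per_pair' or 'global'")
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    groups = meta.loc[matrix.sample_ids, "tumor_type"].to_numpy(dtype=object)
    signals = list(panel) if panel is not None else matrix.signal_ids
    types = sorted(pd.unique(groups))
    pairs = [f"{a}|{b}" for a, b in itertools.combinations(types, 2)]
    t_tab = pd.DataFrame(np.nan, index=pairs, columns=signals)
    p_tab = pd.DataFrame(np.nan, index=pairs, columns=signals)
    for sig in signals:
        vals = matrix.values.loc[sig].to_numpy(dtype=float)
        for a, b in itertools.combinations(types, 2):
            if welch:
                from scipy.stats import ttest_ind
                xa = vals[(groups == a) & ~np.isnan(vals)]
                xb = vals[(groups == b) & ~np.isnan(vals)]
                if len(xa) < 2 or len(xb) < 2:
                    continue
                t, p = ttest_ind(xa, xb, equal_var=False)
            else:
                t, p = pooled_sd_ttest(vals, groups, (a, b))
            t_tab.loc[f"{a}|{b}", sig] = t
            p_tab.loc[f"{a}|{b}", sig] = p
    if bh_scope == "per_pair":
        p_bh = p_tab.apply(lambda row: pd.Series(bh_adjust(row.to_numpy()),
                                                 index=row.index), axis=1)
    else:
        flat = p_tab.to_numpy().ravel()
        p_bh = pd.DataFrame(bh_adjust(flat).reshape(p_tab.shape),
                            index=p_tab.index, columns=p_tab.columns)
    return PairwiseTestTable(p_tab, p_bh, t_tab, alpha=alpha)


def count_significant(table_ff: PairwiseTestTable, table_ffpe: PairwiseTestTable
                      ) -> pd.DataFrame:
    """Per tumor-type pair: significant counts in FF, FFPE, and their overlap."""
    if list(table_ff.p_bh.columns) != list(table_ffpe.p_bh.columns) or \
       list(table_ff.p_bh.index) != list(table_ffpe.p_bh.index):
        raise ValueError("tables cover different panels or pairs")
    sets_ff = table_ff.significant_sets()
    sets_ffpe = table_ffpe.significant_sets()
    rows = [{"pair": pair,
             "n_ff": len(sets_ff[pair]),
             "n_ffpe": len(sets_ffpe[pair]),
             "n_overlap": len(sets_ff[pair] & sets_ffpe[pair])}
            for pair in table_ff.p_bh.index]
    return pd.DataFrame(rows).set_index("pair")


def plot_heatmap(matrix: SignalMatrix, metadata: pd.DataFrame, path: str) -> None:
    """Optional clustered heatmap rendering (thin convenience, not a contract)."""
    import matplotlib
    matplotlib.use("Agg")
    import seaborn as sns
    data = matrix.values.fillna(matrix.values.min().min())
    g = sns.clustermap(data, method="average", metric="correlation",
                       cmap="viridis", xticklabels=True, yticklabels=False)
    g.savefig(path, dpi=120)
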