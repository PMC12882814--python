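"""Graph-neighborhood statistics over typed cell maps.

Three estimators over a spatial (Delaunay) graph:

* ``nh_sum`` — the cell × neighborhood-type count matrix within k cell
  layers (graph hops), plus an ``all`` column with the neighborhood size;
* ``permutation_enrichment`` — enrichment of a target type around a
  selected cell set, tested by shuffling the labels of non-selected
  cells (1,000 permutations by default);
* ``pairwise_enrichment`` — the asymmetric per-type-pair z-score matrix
  against a full label permutation null, optionally ignoring edges
  between same-labelled cells;
* ``group_composition`` — pseudocounted neighborhood-frequency ratios
  between a cell group and the rest of the population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "EnrichmentResult",
    "nh_sum",
    "permutation_enrichment",
    "pairwise_enrichment",
    "group_composition",
]


@dataclass
class EnrichmentResult:
    """Result of a permutation neighborhood-enrichment test."""

    observed: float            # mean per-cell neighborhood density of the target
    baseline: float            # target fraction among non-selected cells
    score: float               # observed / baseline (NaN when baseline == 0)
    null_scores: np.ndarray    # permutation null of the score
    p_value: float             # add-one upper-tail estimate
    n_perm: int
    seed: Optional[int]
    notes: list = field(default_factory=list)


def _node_order(cells: pd.DataFrame, graph: nx.Graph) -> list:
    ids = list(cells["cell_id"])
    missing = set(ids) - set(graph.nodes)
    if missing:
        raise KeyError(f"cells absent from graph: {sorted(missing, key=repr)[:5]}")
    return ids


def _khop_reach(graph: nx.Graph, ids: list, k: int) -> sp.csr_matrix:
    """Boolean n×n matrix: within-k-hop reachability, self excluded."""
    n = len(ids)
    pos = {cid: i for i, cid in enumerate(ids)}
    rows, cols = [], []
    for u, v in graph.edges():
        if u in pos and v in pos:
            rows += [pos[u], pos[v]]
            cols += [pos[v], pos[u]]
    A = sp.csr_matrix(
        (np.ones(len(rows), bool), (rows, cols)), shape=(n, n), dtype=bool
    )
    reach = A.copy()
    frontier = A
    for _ in range(k - 1):
        frontier = (frontier @ A).astype(bool)
        grown = (reach + frontier).astype(bool)
        if grown.nnz == reach.nnz:
            break
        reach = grown
    reach = sp.lil_matrix(reach)
    reach.setdiag(False)
    return reach.tocsr().astype(bool)


def nh_sum(cells: pd.DataFrame, graph: nx.Graph, k: int = 5) -> pd.DataFrame:
    """Cell × neighborhood-type count matrix within ``k`` cell layers.

    Row i counts, per cell type, the cells at graph distance 1..k from
    cell i; the ``all`` column is the neighborhood size (row sum).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    ids = _node_order(cells, graph)
    types = cells["cell_type"].to_numpy()
    classes = sorted(pd.unique(types))
    if k == 0:
        out = pd.DataFrame(0, index=ids, columns=classes + ["all"], dtype=int)
        out.index.name = "cell_id"
        return out
    reach = _khop_reach(graph, ids, k)
    onehot = np.zeros((len(ids), len(classes)), dtype=np.int64)
    for j, c in enumerate(classes):
        onehot[types == c, j] = 1
    counts = np.asarray(reach.astype(np.int64) @ onehot)
    out = pd.DataFrame(counts, index=ids, columns=classes)
    out["all"] = counts.sum(axis=1)
    out.index.name = "cell_id"
    return out


def permutation_enrichment(
    cells: pd.DataFrame,
    graph: nx.Graph,
    selected,
    target_type: str,
    k: int = 5,
    n_perm: int = 1000,
    seed: Optional[int] = None,
    average: str = "per_cell",
) -> EnrichmentResult:
    """Permutation test for target-type enrichment around selected cells.

    Observed statistic: mean over selected cells of the target density
    in their k-layer neighborhood (``average="per_cell"``; cells with an
    empty neighborhood contribute density 0) or the pooled target count
    over the pooled neighborhood size (``average="pooled"``).  Baseline:
    the target fraction among all non-selected cells.  The null shuffles
    the labels of the non-selected cells only, keeping the graph and the
    selected cells' labels fixed.  p is the add-one upper-tail estimate
    (1 + #{null ≥ observed}) / (1 + n_perm).
    """
    selected = set(selected)
    if not selected:
        raise ValueError("selected set is empty")
    ids = _node_order(cells, graph)
    pos = {cid: i for i, cid in enumerate(ids)}
    missing = selected - set(ids)
    if missing:
        raise KeyError(f"selected ids absent from cells: {sorted(missing, key=repr)[:5]}")
    types = cells["cell_type"].to_numpy()
    if average not in ("per_cell", "pooled"):
        raise ValueError("average must be 'per_cell' or 'pooled'")

    sel_idx = np.array(sorted(pos[c] for c in selected))
    ns_mask = np.ones(len(ids), dtype=bool)
    ns_mask[sel_idx] = False
    ns_idx = np.flatnonzero(ns_mask)

    reach = _khop_reach(graph, ids, k)
    M = reach[sel_idx].astype(np.float64).toarray()  # (n_sel, n)
    nh_size = M.sum(axis=1)
    notes = []
    if average == "per_cell":
        # per-cell density weights; empty neighborhoods contribute 0
        W = np.divide(M, np.maximum(nh_size, 1.0)[:, None])
        if (nh_size == 0).any():
            notes.append(f"{int((nh_size == 0).sum())} selected cells have empty neighborhoods")

        def stat(target_vec):
            return float((W @ target_vec).mean())
    else:
        total = max(float(nh_size.sum()), 1.0)

        def stat(target_vec):
            return float((M @ target_vec).sum() / total)

    is_target = (types == target_type).astype(np.float64)
    observed = stat(is_target)
    baseline = float(is_target[ns_idx].mean()) if len(ns_idx) else float("nan")

    rng = np.random.default_rng(seed)
    tgt_ns = is_target[ns_idx]
    null_obs = np.empty(n_perm)
    vec = is_target.copy()
    for b in range(n_perm):
        vec[ns_idx] = rng.permutation(tgt_ns)
        null_obs[b] = stat(vec)

    if baseline > 0:
        score = observed / baseline
        null_scores = null_obs / baseline
    else:
        score = float("nan")
        null_scores = np.full(n_perm, np.nan)
        notes.append("baseline density is 0; score undefined, raw densities reported")
    p = float((1 + np.sum(null_obs >= observed)) / (1 + n_perm))
    return EnrichmentResult(
        observed=observed,
        baseline=baseline,
        score=score,
        null_scores=null_scores,
        p_value=p,
        n_perm=n_perm,
        seed=seed,
        notes=notes,
    )


def pairwise_enrichment(
    cells: pd.DataFrame,
    graph: nx.Graph,
    n_perm: int = 1000,
    seed: Optional[int] = None,
    exclude_same_label: bool = True,
) -> pd.DataFrame:
    """Asymmetric source→target neighborhood-enrichment z-score matrix.

    For each ordered type pair (A, B) the observed statistic is the mean
    count of B cells among the direct graph neighbors of A cells.  With
    ``exclude_same_label`` edges between same-labelled cells are ignored
    (so a type's enrichment with itself is suppressed, mirroring
    "without intra-cluster edges").  z-scores are taken against a full
    label-permutation null; entries whose null is degenerate (zero
    variance, e.g. singleton classes) are NaN and listed in
    ``result.attrs["degenerate"]``.
    """
    ids = _node_order(cells, graph)
    types = cells["cell_type"].to_numpy()
    classes = sorted(pd.unique(types))
    if len(classes) < 2:
        raise ValueError("pairwise enrichment needs at least two label classes")
    n, T = len(ids), len(classes)
    pos = {cid: i for i, cid in enumerate(ids)}
    rows, cols = [], []
    for u, v in graph.edges():
        if u in pos and v in pos and u != v:
            rows += [pos[u], pos[v]]
            cols += [pos[v], pos[u]]
    A = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    cls_index = {c: j for j, c in enumerate(classes)}
    lab = np.array([cls_index[t] for t in types])

    def stat_matrix(lab_vec):
        onehot = np.zeros((n, T))
        onehot[np.arange(n), lab_vec] = 1.0
        counts = A @ onehot  # (n, T): neighbor type counts per cell
        if exclude_same_label:
            counts[np.arange(n), lab_vec] = 0.0
        out = np.empty((T, T))
        for s in range(T):
            mask = lab_vec == s
            out[s] = counts[mask].mean(axis=0) if mask.any() else np.nan
        return out

    obs = stat_matrix(lab)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, T, T))
    for b in range(n_perm):
        null[b] = stat_matrix(rng.permutation(lab))
    mu = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (obs - mu) / sd
    z[sd == 0] = np.nan
    out = pd.DataFrame(z, index=classes, columns=classes)
    out.index.name = "source"
    out.columns.name = "target"
    out.attrs["degenerate"] = [
        (classes[s], classes[t]) for s, t in zip(*np.where(sd == 0))
    ]
    out.attrs["observed"] = pd.DataFrame(obs, index=classes, columns=classes)
    return out


def group_composition(
    Y: pd.DataFrame,
    groups: dict,
    pseudocount: float = 0.001,
    renormalize_type: Optional[str] = None,
) -> pd.DataFrame:
    """Neighborhood-composition enrichment ratios per cell group.

    For group g and neighborhood type t,
    ``ratio = [(Σ_{i∈g} Y_it + ε) / (Σ_{i∈g} Y_i,all + ε)] /
    [(Σ_{i∉g} Y_it + ε) / (Σ_{i∉g} Y_i,all + ε)]`` with pseudocount ε.
    ``groups`` maps cell ids to group names and may cover only a subset
    of rows; the complement of each group is every other row of ``Y``.
    ``renormalize_type`` divides that type's column of ratios by its
    mean across groups (used to display within-type differences).
    """
    if "all" not in Y.columns:
        raise ValueError("Y must carry an 'all' column")
    type_cols = [c for c in Y.columns if c != "all"]
    eps = pseudocount
    group_names = sorted(set(groups.values()))
    member_ids = {g: [cid for cid, gg in groups.items() if gg == g] for g in group_names}
    for g, ids in member_ids.items():
        if not ids:
            raise ValueError(f"group {g!r} is empty")
        missing = set(ids) - set(Y.index)
        if missing:
            raise KeyError(f"group {g!r} ids absent from Y: {sorted(missing, key=repr)[:5]}")

    rows = []
    for g in group_names:
        in_g = Y.index.isin(member_ids[g])
        num = (Y.loc[in_g, type_cols].sum() + eps) / (Y.loc[in_g, "all"].sum() + eps)
        den = (Y.loc[~in_g, type_cols].sum() + eps) / (Y.loc[~in_g, "all"].sum() + eps)
        rows.append(num / den)
    out = pd.DataFrame(rows, index=group_names)
    out.index.name = "group"
    if renormalize_type is not None:
        out[renormalize_type] = out[renormalize_type] / out[renormalize_type].mean()
    return out
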