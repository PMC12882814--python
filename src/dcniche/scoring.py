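"""Gene-signature scoring with expression-matched control genes.

The per-cell score of a signature is the mean expression of the
signature genes minus the mean expression of a pooled control set
sampled, per signature gene, from genes of comparable dataset-mean
expression (25 expression bins, 50 controls per gene by default).  On
datasets with a discrete positive population the score distribution is
bimodal and cells are classified by a valley cutoff (0.5 or 1.5 in the
dialects this package mirrors; ``find_valley`` estimates the cutoff
from a kernel density when no printed value applies).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import argrelextrema
from scipy.stats import gaussian_kde

__all__ = [
    "ScoreResult",
    "gene_columns",
    "score_cells",
    "threshold_classify",
    "find_valley",
    "program_scores",
]


@dataclass
class ScoreResult:
    """Per-cell signature scores plus scoring metadata."""

    scores: pd.Series              # indexed by cell_id
    genes_used: list
    genes_missing: list
    n_bins: int
    ctrl_per_gene: int
    seed: Optional[int]
    labels: Optional[pd.Series] = None
    cutoff: Optional[float] = None
    notes: list = field(default_factory=list)


def gene_columns(cells: pd.DataFrame) -> list:
    """Expression columns of a CellMap table (``gene_*`` prefix)."""
    return [c for c in cells.columns if c.startswith("gene_")]


def _expr_matrix(cells: pd.DataFrame):
    genes = gene_columns(cells)
    if not genes:
        raise ValueError("CellMap carries no gene_* expression columns")
    X = cells[genes].to_numpy(float)
    return X, genes


def score_cells(
    cells: pd.DataFrame,
    signature,
    n_bins: int = 25,
    ctrl_per_gene: int = 50,
    seed: Optional[int] = None,
) -> ScoreResult:
    """Score every cell against a gene signature with binned controls.

    Genes are ranked by dataset-mean expression and cut into ``n_bins``
    equal-size bins; for each signature gene, ``ctrl_per_gene`` control
    genes are drawn (without replacement where possible) from its bin,
    excluding signature genes.  The score is the mean signature
    expression minus the mean over the pooled control set, per cell.
    Signature genes absent from the panel are dropped with a note; a
    signature with no present gene, or one leaving no control genes, is
    rejected.
    """
    X, genes = _expr_matrix(cells)
    sig_named = [g if g.startswith("gene_") else f"gene_{g}" for g in signature]
    present = [g for g in sig_named if g in genes]
    missing = [g for g in sig_named if g not in genes]
    if not present:
        raise ValueError("no signature gene present in the expression panel")
    pool = [g for g in genes if g not in set(present)]
    if not pool:
        raise ValueError("signature covers every gene; no control genes available")

    gene_means = X.mean(axis=0)
    order = pd.Series(gene_means, index=genes).rank(method="first")
    bins = pd.cut(order, bins=n_bins, labels=False)
    bin_of = dict(zip(genes, bins))

    rng = np.random.default_rng(seed)
    ctrl: set = set()
    pool_by_bin: dict = {}
    for g in pool:
        pool_by_bin.setdefault(bin_of[g], []).append(g)
    for g in present:
        candidates = pool_by_bin.get(bin_of[g], [])
        if not candidates:
            # empty bin after excluding the signature: fall back to the whole pool
            candidates = pool
        take = min(ctrl_per_gene, len(candidates))
        ctrl.update(rng.choice(candidates, size=take, replace=False))
    ctrl_list = sorted(ctrl)

    gi = {g: i for i, g in enumerate(genes)}
    sig_idx = [gi[g] for g in present]
    ctrl_idx = [gi[g] for g in ctrl_list]
    scores = X[:, sig_idx].mean(axis=1) - X[:, ctrl_idx].mean(axis=1)
    idx = cells["cell_id"] if "cell_id" in cells.columns else cells.index
    notes = []
    if missing:
        notes.append(f"{len(missing)} signature genes absent from the panel")
    return ScoreResult(
        scores=pd.Series(scores, index=pd.Index(idx, name="cell_id"), name="score"),
        genes_used=present,
        genes_missing=missing,
        n_bins=n_bins,
        ctrl_per_gene=ctrl_per_gene,
        seed=seed,
        notes=notes,
    )


def threshold_classify(scores, cutoff: float) -> pd.Series:
    """Binary classification at a bimodal-valley cutoff (strictly above → positive)."""
    s = scores.scores if isinstance(scores, ScoreResult) else pd.Series(scores)
    labels = pd.Series(
        np.where(s.to_numpy(float) > cutoff, "positive", "negative"),
        index=s.index,
        name="label",
    )
    if isinstance(scores, ScoreResult):
        scores.labels = labels
        scores.cutoff = cutoff
    return labels


def find_valley(scores, grid_size: int = 512) -> float:
    """Estimate the valley between the two largest modes of a score distribution.

    Kernel-density estimate on a uniform grid; returns the location of
    the density minimum between the two highest local maxima.  Intended
    for bimodal distributions; warns when fewer than two modes are found
    and falls back to the median.
    """
    s = scores.scores if isinstance(scores, ScoreResult) else pd.Series(scores)
    x = s.to_numpy(float)
    kde = gaussian_kde(x)
    lo, hi = x.min(), x.max()
    grid = np.linspace(lo, hi, grid_size)
    dens = kde(grid)
    maxima = argrelextrema(dens, np.greater)[0]
    if len(maxima) < 2:
        warnings.warn("score distribution does not look bimodal; falling back to median")
        return float(np.median(x))
    top2 = sorted(sorted(maxima, key=lambda i: dens[i], reverse=True)[:2])
    between = dens[top2[0]: top2[1] + 1]
    return float(grid[top2[0] + int(np.argmin(between))])


def program_scores(
    cells: pd.DataFrame,
    stimulatory,
    inhibitory,
    n_bins: int = 25,
    ctrl_per_gene: int = 50,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Stimulatory and inhibitory program scores per cell.

    Two independent ``score_cells`` runs (the second seeded from the
    first's generator stream so the control draws differ); returns a
    DataFrame with ``stimulatory`` and ``inhibitory`` columns indexed by
    cell id.
    """
    ss = np.random.SeedSequence(seed)
    s1, s2 = ss.spawn(2)
    stim = score_cells(cells, stimulatory, n_bins, ctrl_per_gene, seed=s1.generate_state(1)[0])
    inhib = score_cells(cells, inhibitory, n_bins, ctrl_per_gene, seed=s2.generate_state(1)[0])
    return pd.DataFrame({"stimulatory": stim.scores, "inhibitory": inhib.scores})
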