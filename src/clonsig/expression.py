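"""Expression handling: log-normalisation, marker signatures, cluster stats.

Counts live in an AnnData (cells × genes).  The log layer is
``ln(10,000 × UMIsGene / UMIsTotal + 1)`` — per-cell depth normalisation to
10,000 UMIs followed by a natural-log transform, so a zero count maps to 0.

Marker signatures for a condition (e.g. a vaccination time point) are genes
that discriminate the condition's cells from the rest: area under the ROC
curve strictly greater than ``auc_min`` (default 0.6) and adjusted
two-sided Mann–Whitney p-value at most ``alpha`` (default 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LogNormalizer",
    "log_normalize",
    "GeneSignature",
    "SignatureSelector",
    "derive_signature",
    "cluster_expression_stats",
]

DEFAULT_SCALE = 1e4
LOG_LAYER = "lognorm"


class LogNormalizer(TransformerMixin, BaseEstimator):
    """Stateless depth-normalising log transform, ln(scale·x/total + 1)."""

    def __init__(self, scale: float = DEFAULT_SCALE):
        self.scale = scale

    def fit(self, X, y=None):
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        dense = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)
        if (dense < 0).any():
            raise ValueError("counts must be non-negative")
        totals = dense.sum(axis=1)
        zero = np.flatnonzero(totals == 0)
        if zero.size:
            raise ValueError(f"cell at row {zero[0]} has zero total counts")
        return np.log1p(self.scale * dense / totals[:, None])


def log_normalize(adata, scale: float = DEFAULT_SCALE, layer: str = LOG_LAYER):
    """Attach the log layer and per-cell totals to an AnnData, in place.

    Raises on a cell with zero total counts, naming the cell.
    """
    X = adata.X
    dense = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)
    totals = dense.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"cell {adata.obs_names[zero[0]]!r} has zero total counts")
    adata.obs["total_counts"] = totals
    adata.layers[layer] = np.log1p(scale * dense / totals[:, None])
    return adata


@dataclass
class GeneSignature:
    """A named gene set, optionally with per-gene AUC/adjusted p from derivation."""

    name: str
    genes: list
    auc: dict = field(default_factory=dict)
    adj_pvalues: dict = field(default_factory=dict)
    direction: str = "up"

    def __len__(self) -> int:
        return len(self.genes)


def _rank_auc(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene AUC (target vs rest, ties mid-ranked) and two-sided MWU p."""
    n1, n0 = x.shape[0], y.shape[0]
    res = stats.mannwhitneyu(x, y, axis=0, alternative="two-sided")
    auc = res.statistic / (n1 * n0)
    return auc, res.pvalue


class SignatureSelector(BaseEstimator):
    """Select marker genes by ROC AUC and adjusted Mann–Whitney p.

    Parameters
    ----------
    auc_min : float, default 0.6
        Genes must exceed this AUC strictly.
    alpha : float, default 0.05
        Maximum adjusted p-value (inclusive).
    adjust_method : str, default "bonferroni"
        Any method accepted by ``statsmodels`` ``multipletests``
        (e.g. "fdr_bh").

    Attributes
    ----------
    auc_, pvalues_, qvalues_ : per-gene arrays
    support_ : boolean mask of selected genes
    """

    def __init__(self, auc_min: float = 0.6, alpha: float = 0.05, adjust_method: str = "bonferroni"):
        self.auc_min = auc_min
        self.alpha = alpha
        self.adjust_method = adjust_method

    def fit(self, X, y):
        """X: log-normalised values (cells × genes); y: boolean target mask."""
        X = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=bool)
        if y.shape[0] != X.shape[0]:
            raise ValueError("label mask must align with cells")
        n1, n0 = int(y.sum()), int((~y).sum())
        if n1 < 2 or n0 < 2:
            raise ValueError(f"each group needs >= 2 cells (got {n1} target, {n0} rest)")
        self.auc_, self.pvalues_ = _rank_auc(X[y], X[~y])
        self.qvalues_ = multipletests(self.pvalues_, method=self.adjust_method)[1]
        self.support_ = (self.auc_ > self.auc_min) & (self.qvalues_ <= self.alpha)
        self.n_features_in_ = X.shape[1]
        return self

    def get_support(self):
        return self.support_


def derive_signature(
    adata,
    target,
    name: str = "signature",
    auc_min: float = 0.6,
    alpha: float = 0.05,
    adjust_method: str = "bonferroni",
    layer: str = LOG_LAYER,
) -> GeneSignature:
    """Derive an up-signature for target cells vs the rest of an AnnData.

    ``target`` is a boolean mask over cells, or ``(obs_key, value)``.
    Members are returned AUC-descending (gene name breaks ties).
    """
    if isinstance(target, tuple):
        key, value = target
        mask = (adata.obs[key] == value).to_numpy()
    else:
        mask = np.asarray(target, dtype=bool)
    if layer not in adata.layers:
        log_normalize(adata, layer=layer)
    sel = SignatureSelector(auc_min=auc_min, alpha=alpha, adjust_method=adjust_method)
    sel.fit(adata.layers[layer], mask)
    genes = np.asarray(adata.var_names)
    idx = np.flatnonzero(sel.support_)
    order = sorted(idx, key=lambda i: (-sel.auc_[i], genes[i]))
    return GeneSignature(
        name=name,
        genes=[genes[i] for i in order],
        auc={genes[i]: float(sel.auc_[i]) for i in order},
        adj_pvalues={genes[i]: float(sel.qvalues_[i]) for i in order},
    )


def cluster_expression_stats(
    adata,
    cluster_key: str = "cluster",
    genes=None,
    layer: str = LOG_LAYER,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster z-scored mean expression and expressing fraction.

    Returns (zscores, fractions), both genes × clusters.  Mean log values
    per cluster are z-scored across clusters per gene (population SD); a
    gene with identical cluster means gets all-zero z-scores.  The
    expressing fraction counts cells with a raw count > 0.
    """
    if layer not in adata.layers:
        log_normalize(adata, layer=layer)
    clusters = adata.obs[cluster_key]
    levels = sorted(clusters.unique(), key=str)
    if len(levels) < 2:
        raise ValueError("need at least two clusters")
    if genes is None:
        genes = list(adata.var_names)
    sub = adata[:, genes]
    logx = np.asarray(sub.layers[layer])
    raw = sub.X.toarray() if sp.issparse(sub.X) else np.asarray(sub.X)
    means = np.vstack([logx[(clusters == lv).to_numpy()].mean(axis=0) for lv in levels])
    fracs = np.vstack([(raw[(clusters == lv).to_numpy()] > 0).mean(axis=0) for lv in levels])
    mu = means.mean(axis=0)
    sd = means.std(axis=0)
    z = np.where(sd > 0, (means - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    zdf = pd.DataFrame(z.T, index=genes, columns=levels)
    fdf = pd.DataFrame(fracs.T, index=genes, columns=levels)
    return zdf, fdf
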