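"""Clonal-family inference and repertoire diversity statistics.

Cells descend from the same B-cell clone when they share donor, V and J
genes and CDR3 length on both chains, and their CDR3 nucleotide identity
exceeds a threshold (default 80%, strictly) on both the heavy and the light
chain — equivalently, normalised Hamming distance strictly below 20%.
Because the family definition requires the rule to hold *between all
members*, families are built by complete-linkage agglomeration within each
candidate group; a true minimum clique cover would be NP-hard, and
complete linkage is the standard deterministic surrogate that still
guarantees every intra-family pair satisfies the rule.

Diversity of a cell population is summarised as the number of distinct
families (richness) and the Gini–Simpson index (probability that two
randomly chosen cells belong to different families).  Sharing of families
between transcriptional clusters is tested against a permutation null in
which family labels are shuffled across cells while cluster labels stay
fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .bcr import PairedBCR

__all__ = [
    "cdr3_identity",
    "ClonalFamilyClusterer",
    "ClonalPartition",
    "partition_families",
    "family_diversity",
    "simpson_index",
    "cluster_simpson",
    "overlap_table",
    "permutation_overlap_test",
]


def cdr3_identity(a: str, b: str) -> float:
    """Fraction of matching positions between two equal-length CDR3s.

    Identity is 1 − normalised Hamming distance.  Callers must pre-group
    candidates by length; unequal lengths are an error, not identity 0.
    """
    if len(a) != len(b):
        raise ValueError(f"CDR3 lengths differ ({len(a)} vs {len(b)}); group by length first")
    if not a:
        raise ValueError("empty CDR3")
    matches = sum(1 for x, y in zip(a, b) if x == y)
    return matches / len(a)


def _mismatches(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError(f"CDR3 lengths differ ({len(a)} vs {len(b)})")
    return sum(1 for x, y in zip(a, b) if x != y)


def _pair_distance(p: PairedBCR, q: PairedBCR, chain_mode: str) -> float:
    """Normalised Hamming distance between two cells' CDR3s.

    per_chain: max over chains (both chains must independently satisfy the
    identity rule).  joint: mismatches pooled over both chains and divided
    by the pooled length.  Each distance is one integer division, so a
    distance rationally equal to a decimal boundary (e.g. 3/15 vs a 20%
    cut) rounds to the boundary's own float and strict comparisons resolve
    exactly.
    """
    mh = _mismatches(p.heavy.cdr3_nt, q.heavy.cdr3_nt)
    ml = _mismatches(p.light.cdr3_nt, q.light.cdr3_nt)
    lh, ll = len(p.heavy.cdr3_nt), len(p.light.cdr3_nt)
    if chain_mode == "per_chain":
        return max(mh / lh, ml / ll)
    if chain_mode == "joint":
        return (mh + ml) / (lh + ll)
    raise ValueError(f"unknown chain_mode {chain_mode!r}")


def _agglomerate(dist: np.ndarray, dmax: float, linkage: str) -> list[int]:
    """Deterministic agglomerative clustering with a strict merge cut.

    Clusters are merged while the linkage distance of the closest pair is
    strictly below ``dmax``.  Ties are broken by the smallest pair of
    cluster representative indices (representative = smallest member), so
    the result is independent of floating-point library details and
    reproducible across platforms.  Returns a label per item.
    """
    n = dist.shape[0]
    clusters: list[list[int]] = [[i] for i in range(n)]
    agg = np.max if linkage == "complete" else np.min
    if linkage not in ("complete", "single"):
        raise ValueError(f"unknown linkage {linkage!r}")
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = float(agg(dist[np.ix_(clusters[a], clusters[b])]))
                key = (d, clusters[a][0], clusters[b][0])
                if best is None or key < best[0]:
                    best = (key, a, b)
        (d, _, _), a, b = best
        if not d < dmax:
            break
        merged = sorted(clusters[a] + clusters[b])
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)]
        clusters.append(merged)
        clusters.sort(key=lambda c: c[0])
    labels = np.empty(n, dtype=int)
    for lab, members in enumerate(sorted(clusters, key=lambda c: c[0])):
        for i in members:
            labels[i] = lab
    return list(labels)


@dataclass
class ClonalPartition:
    """Cells assigned to clonal families, plus the parameters that made it."""

    family_of_cell: dict  # cell_id -> family id
    members: dict = field(default_factory=dict)  # family id -> sorted cell ids
    params: dict = field(default_factory=dict)

    def restrict(self, cells) -> "ClonalPartition":
        sub = {c: self.family_of_cell[c] for c in cells}
        members: dict = {}
        for c, f in sub.items():
            members.setdefault(f, []).append(c)
        return ClonalPartition(sub, {f: sorted(m) for f, m in members.items()}, self.params)

    def to_frame(self) -> pd.DataFrame:
        rows = [(c, f) for c, f in sorted(self.family_of_cell.items())]
        return pd.DataFrame(rows, columns=["cell_id", "family_id"])


class ClonalFamilyClusterer(BaseEstimator):
    """Partition paired BCRs into clonal families.

    Parameters
    ----------
    identity_threshold : float, default 0.8
        CDR3 identity must be strictly greater than this within a family.
    chain_mode : {"per_chain", "joint"}, default "per_chain"
        Whether each chain must pass the identity rule independently or the
        rule is applied to the pooled heavy+light CDR3.
    linkage : {"complete", "single"}, default "complete"
        Complete linkage guarantees the rule between all members.
    use_germline_key : bool, default False
        Additionally require identical reconstructed germline FR1–FR3
        strings on both chains for co-membership.

    Attributes
    ----------
    labels_ : ndarray of family labels aligned with the fitted pairs.
    partition_ : ClonalPartition
    """

    def __init__(
        self,
        identity_threshold: float = 0.8,
        chain_mode: str = "per_chain",
        linkage: str = "complete",
        use_germline_key: bool = False,
    ):
        self.identity_threshold = identity_threshold
        self.chain_mode = chain_mode
        self.linkage = linkage
        self.use_germline_key = use_germline_key

    def fit(self, X, y=None):
        """Cluster a collection of :class:`PairedBCR` into families."""
        pairs = list(X)
        if not 0.0 < self.identity_threshold < 1.0:
            raise ValueError("identity_threshold must lie in (0, 1)")
        for p in pairs:
            if not p.donor:
                raise ValueError(f"cell {p.cell_id}: missing donor label")
        seen: set = set()
        for p in pairs:
            if p.cell_id in seen:
                raise ValueError(f"duplicate cell {p.cell_id}")
            seen.add(p.cell_id)

        # canonical input order: cells sorted by identifier
        order = sorted(range(len(pairs)), key=lambda i: pairs[i].cell_id)
        groups: dict[tuple, list[int]] = {}
        for i in order:
            p = pairs[i]
            key = (
                p.donor,
                p.heavy.v_call,
                p.heavy.j_call,
                p.light.v_call,
                p.light.j_call,
                len(p.heavy.cdr3_nt),
                len(p.light.cdr3_nt),
            )
            if self.use_germline_key:
                key = key + (p.germline_fr_heavy, p.germline_fr_light)
            groups.setdefault(key, []).append(i)

        # merge strictly below 1 - threshold; the epsilon guards against the
        # float of a rational distance landing a hair under the cut when the
        # decimal threshold itself is not exactly representable (distinct
        # CDR3 distances are spaced >= 1/length^2, far above it)
        dmax = (1.0 - self.identity_threshold) - 1e-9
        family_of_cell: dict[str, str] = {}
        raw_families: list[list[str]] = []
        for key in sorted(groups, key=str):
            idx = groups[key]
            cells = [pairs[i] for i in idx]
            m = len(cells)
            dist = np.zeros((m, m))
            for a in range(m):
                for b in range(a + 1, m):
                    dist[a, b] = dist[b, a] = _pair_distance(
                        cells[a], cells[b], self.chain_mode
                    )
            labels = _agglomerate(dist, dmax, self.linkage)
            for lab in sorted(set(labels)):
                raw_families.append(sorted(cells[i].cell_id for i in range(m) if labels[i] == lab))

        # family ids numbered by their smallest member, independent of grouping order
        raw_families.sort(key=lambda mem: mem[0])
        width = max(5, len(str(len(raw_families))))
        members: dict[str, list[str]] = {}
        for k, mem in enumerate(raw_families):
            fam = f"F{k + 1:0{width}d}"
            members[fam] = mem
            for c in mem:
                family_of_cell[c] = fam

        self.partition_ = ClonalPartition(
            family_of_cell,
            members,
            params=self.get_params(),
        )
        self.labels_ = np.array([family_of_cell[p.cell_id] for p in pairs])
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def partition_families(pairs, **params) -> ClonalPartition:
    """Functional wrapper over :class:`ClonalFamilyClusterer`."""
    return ClonalFamilyClusterer(**params).fit(pairs).partition_


def _check_grouping(partition: ClonalPartition, grouping) -> pd.Series:
    g = pd.Series(dict(grouping))
    missing = set(partition.family_of_cell) - set(g.index)
    if missing:
        raise ValueError(f"grouping is missing {len(missing)} cells, e.g. {sorted(missing)[:3]}")
    return g.loc[sorted(partition.family_of_cell)]


def family_diversity(partition: ClonalPartition, grouping) -> pd.Series:
    """Number of distinct clonal families with at least one member per cluster."""
    g = _check_grouping(partition, grouping)
    fam = pd.Series(partition.family_of_cell).loc[g.index]
    out = fam.groupby(g).nunique()
    out.index.name = "cluster"
    out.name = "n_families"
    return out.sort_index()


def simpson_index(family_labels, unbiased: bool = False) -> float:
    """Gini–Simpson index of a set of cells' family labels.

    With replacement (default): 1 − Σ p_i².  Unbiased (without
    replacement): 1 − Σ n_i(n_i−1) / (N(N−1)).
    """
    labels = pd.Series(list(family_labels))
    n = len(labels)
    if n == 0:
        raise ValueError("empty cluster: Simpson index undefined")
    counts = labels.value_counts().to_numpy(dtype=float)
    if unbiased:
        if n < 2:
            raise ValueError("unbiased Simpson index needs at least two cells")
        return 1.0 - float((counts * (counts - 1)).sum() / (n * (n - 1)))
    p = counts / n
    return 1.0 - float((p**2).sum())


def cluster_simpson(partition: ClonalPartition, grouping, unbiased: bool = False) -> pd.Series:
    """Simpson index of the family composition of every cluster."""
    g = _check_grouping(partition, grouping)
    fam = pd.Series(partition.family_of_cell).loc[g.index]
    out = fam.groupby(g).agg(lambda s: simpson_index(s, unbiased=unbiased))
    out.index.name = "cluster"
    out.name = "simpson"
    return out.sort_index()


def _codes(partition: ClonalPartition, grouping):
    g = _check_grouping(partition, grouping)
    fam = pd.Series(partition.family_of_cell).loc[g.index]
    fcodes, _ = pd.factorize(fam, sort=True)
    ccodes, clusters = pd.factorize(g, sort=True)
    return fcodes, ccodes, list(clusters)


def _overlap_matrix(fcodes: np.ndarray, ccodes: np.ndarray, nf: int, nc: int) -> np.ndarray:
    presence = np.zeros((nf, nc), dtype=bool)
    presence[fcodes, ccodes] = True
    return presence.T.astype(np.int64) @ presence.astype(np.int64)


def overlap_table(partition: ClonalPartition, grouping) -> pd.DataFrame:
    """Cluster × cluster counts of families shared between clusters.

    Entry (i, j) is the number of families with members in both cluster i
    and cluster j; the diagonal is the per-cluster family count.
    """
    fcodes, ccodes, clusters = _codes(partition, grouping)
    mat = _overlap_matrix(fcodes, ccodes, fcodes.max() + 1, len(clusters))
    return pd.DataFrame(mat, index=clusters, columns=clusters)


def permutation_overlap_test(
    partition: ClonalPartition,
    grouping,
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Permutation p-values for between-cluster family sharing.

    The null is generated by permuting the clonal-family annotation across
    cells while cluster labels stay fixed; 1000 permutations by default.
    p(i, j) = (1 + #{permuted overlap ≥ observed}) / (1 + n_perm) — the
    add-one estimator, which never returns 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    fcodes, ccodes, clusters = _codes(partition, grouping)
    nf, nc = fcodes.max() + 1, len(clusters)
    observed = _overlap_matrix(fcodes, ccodes, nf, nc)
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(observed)
    for _ in range(n_perm):
        perm = rng.permutation(fcodes)
        exceed += _overlap_matrix(perm, ccodes, nf, nc) >= observed
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    return pd.DataFrame(pvals, index=clusters, columns=clusters)
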