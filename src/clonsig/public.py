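"""Public (putatively antigen-specific) clonotype matching.

A repertoire cell is called public when its paired CDR3s are near-identical
to an experimentally validated antigen-specific reference clone: CDR3
lengths must agree on both chains, and nucleotide identity must reach a
threshold (default 80%, inclusive — a "minimum requirement").  The default
``joint`` mode pools both chains, counting identical nucleotides over the
summed CDR3 length; ``per_chain`` mode instead requires each chain to reach
the threshold on its own.
"""

from __future__ import annotations

import pandas as pd
from sklearn.base import BaseEstimator

from .bcr import PairedBCR

__all__ = ["joint_identity", "PublicCloneMatcher", "match_public"]


def _chain_identity(a: str, b: str) -> float | None:
    if len(a) != len(b):
        return None
    if not a:
        raise ValueError("empty CDR3")
    return sum(1 for x, y in zip(a, b) if x == y) / len(a)


def joint_identity(query: PairedBCR, ref: PairedBCR) -> float | None:
    """Pooled CDR3 identity of two paired BCRs, or None when incomparable.

    Incomparable means the CDR3 lengths differ on either chain; otherwise
    the value is (matching heavy nt + matching light nt) / (total length).
    """
    ih = _chain_identity(query.heavy.cdr3_nt, ref.heavy.cdr3_nt)
    il = _chain_identity(query.light.cdr3_nt, ref.light.cdr3_nt)
    if ih is None or il is None:
        return None
    lh, ll = len(query.heavy.cdr3_nt), len(query.light.cdr3_nt)
    return (ih * lh + il * ll) / (lh + ll)


class PublicCloneMatcher(BaseEstimator):
    """Match repertoire cells against a reference clonotype set.

    Parameters
    ----------
    threshold : float, default 0.8
        Minimum identity, inclusive (``identity >= threshold`` matches).
    mode : {"joint", "per_chain"}, default "joint"
        joint pools both chains' CDR3s; per_chain requires each chain to
        reach the threshold independently.
    require_vj : bool, default False
        Additionally require identical V and J calls on both chains.

    Attributes
    ----------
    reference_ : list of (clone id, PairedBCR, antigen label)
    """

    def __init__(self, threshold: float = 0.8, mode: str = "joint", require_vj: bool = False):
        self.threshold = threshold
        self.mode = mode
        self.require_vj = require_vj

    def fit(self, X, y=None):
        """Store the reference clones; ``y`` may carry antigen labels."""
        refs = list(X)
        labels = list(y) if y is not None else [""] * len(refs)
        if len(labels) != len(refs):
            raise ValueError("antigen labels must align with reference clones")
        if self.mode not in ("joint", "per_chain"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.reference_ = [(r.cell_id, r, lab) for r, lab in zip(refs, labels)]
        # length buckets are an optimisation only; matching must equal the
        # brute-force all-pairs scan
        self._buckets: dict[tuple, list] = {}
        for entry in self.reference_:
            key = (len(entry[1].heavy.cdr3_nt), len(entry[1].light.cdr3_nt))
            self._buckets.setdefault(key, []).append(entry)
        return self

    def match(self, X) -> pd.DataFrame:
        """All (query cell, reference clone) pairs meeting the criteria.

        A query cell may match several references; every match is reported
        and the best-identity match per cell is flagged.  Rows are ordered
        by (cell_id, reference id).
        """
        rows = []
        for q in X:
            key = (len(q.heavy.cdr3_nt), len(q.light.cdr3_nt))
            for ref_id, r, antigen in self._buckets.get(key, []):
                if self.require_vj and (
                    q.heavy.v_call != r.heavy.v_call
                    or q.heavy.j_call != r.heavy.j_call
                    or q.light.v_call != r.light.v_call
                    or q.light.j_call != r.light.j_call
                ):
                    continue
                ih = _chain_identity(q.heavy.cdr3_nt, r.heavy.cdr3_nt)
                il = _chain_identity(q.light.cdr3_nt, r.light.cdr3_nt)
                ji = joint_identity(q, r)
                if self.mode == "joint":
                    ok = ji >= self.threshold
                else:
                    ok = ih >= self.threshold and il >= self.threshold
                if ok:
                    rows.append((q.cell_id, ref_id, antigen, ji, ih, il))
        out = pd.DataFrame(
            rows,
            columns=[
                "cell_id",
                "reference_id",
                "antigen",
                "joint_identity",
                "identity_heavy",
                "identity_light",
            ],
        )
        out = out.sort_values(["cell_id", "reference_id"], kind="mergesort").reset_index(drop=True)
        out["best"] = False
        if len(out):
            best_idx = out.groupby("cell_id")["joint_identity"].idxmax()
            out.loc[best_idx, "best"] = True
        return out


def match_public(
    repertoire,
    reference,
    antigen_labels=None,
    threshold: float = 0.8,
    mode: str = "joint",
    require_vj: bool = False,
) -> pd.DataFrame:
    """Functional wrapper: match repertoire pairs against reference pairs."""
    matcher = PublicCloneMatcher(threshold=threshold, mode=mode, require_vj=require_vj)
    return matcher.fit(reference, antigen_labels).match(repertoire)
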