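"""Readers and writers: AIRR rearrangement TSV, Matrix Market trios, GMT.

Tabular artefacts are plain TSV; provenance is JSON.  Reading a
rearrangement table keeps every column as text so unknown extension columns
survive a round-trip byte-identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .bcr import REGION_COLUMNS, REGIONS, BCRContig, parse_mutation_events

REQUIRED_COLUMNS = [
    "sequence_id",
    "cell_id",
    "locus",
    "v_call",
    "j_call",
    "productive",
    "duplicate_count",
    "junction",
    "sequence_alignment",
    "fwr1",
    "cdr1",
    "fwr2",
    "cdr2",
    "fwr3",
]

_TRUE = {"T", "TRUE", "True", "true", "1"}


def read_rearrangements(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def write_rearrangements(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def _as_bool(value) -> bool:
    return str(value) in _TRUE


def _as_int(value, default=None):
    s = str(value).strip()
    if not s:
        return default
    return int(float(s))


def contigs_from_table(table: pd.DataFrame) -> list[BCRContig]:
    """Build contig objects from a rearrangement table.

    Raises on missing required columns, listing them.  ``complete_vdj`` is
    honoured when present; otherwise a contig counts as fully sequenced
    when all five V regions and the junction are non-empty.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"rearrangement table is missing columns: {missing}")
    contigs = []
    for rec in table.to_dict("records"):
        regions = {r: str(rec.get(REGION_COLUMNS[r], "") or "") for r in REGIONS}
        has_all = all(regions[r] for r in REGIONS) and bool(str(rec["junction"]))
        if "complete_vdj" in table.columns and str(rec["complete_vdj"]).strip():
            full = _as_bool(rec["complete_vdj"]) and has_all
        else:
            full = has_all
        contigs.append(
            BCRContig(
                sequence_id=str(rec["sequence_id"]),
                cell_id=str(rec["cell_id"]),
                locus=str(rec["locus"]),
                v_call=str(rec["v_call"]),
                j_call=str(rec["j_call"]),
                productive=_as_bool(rec["productive"]),
                full_length=full,
                cdr3_nt=str(rec["junction"]),
                gapped_observed=str(rec["sequence_alignment"]),
                regions=regions,
                mutation_table=parse_mutation_events(rec.get("mutation_events", "")),
                duplicate_count=_as_int(rec.get("duplicate_count", "")),
                consensus_count=_as_int(rec.get("consensus_count", "")),
                cdr3_aa=str(rec.get("junction_aa", "") or ""),
                isotype=str(rec.get("c_call", "") or ""),
                donor=str(rec.get("donor", "") or ""),
            )
        )
    return contigs


def pairs_from_table(table: pd.DataFrame):
    from .bcr import select_contigs

    return select_contigs(contigs_from_table(table))


def write_mtx_dir(adata, out_dir) -> None:
    """Write counts as genes × cells Matrix Market plus features/barcodes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    X = adata.X
    mat = sp.csr_matrix(X) if not sp.issparse(X) else X.tocsr()
    scipy.io.mmwrite(str(out / "matrix.mtx"), mat.T.astype(np.int64), field="integer")
    pd.Series(adata.var_names).to_csv(out / "features.tsv", sep="\t", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(out / "barcodes.tsv", sep="\t", index=False, header=False)


def read_mtx_dir(in_dir) -> ad.AnnData:
    path = Path(in_dir)
    mat = scipy.io.mmread(str(path / "matrix.mtx")).tocsr().T
    genes = pd.read_csv(path / "features.tsv", sep="\t", header=None)[0].astype(str)
    cells = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    return ad.AnnData(
        X=sp.csr_matrix(mat, dtype=np.int64),
        obs=pd.DataFrame(index=list(cells)),
        var=pd.DataFrame(index=list(genes)),
    )


def read_gmt(path) -> dict:
    """GMT: one set per line — name, description, then member genes."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: dict, path, descriptions: dict | None = None) -> None:
    with open(path, "w") as fh:
        for name in gene_sets:
            desc = (descriptions or {}).get(name, "")
            fh.write("\t".join([name, desc, *gene_sets[name]]) + "\n")


def write_annotations(mapping, path, column: str = "cluster") -> None:
    pd.DataFrame(
        sorted(dict(mapping).items()), columns=["cell_id", column]
    ).to_csv(path, sep="\t", index=False)


def read_annotations(path, column: str = "cluster") -> dict:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["cell_id"], df[column]))


def write_json_report(report: dict, path) -> None:
    from . import __version__

    payload = {"clonsig_version": __version__, **report}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
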