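"""Shared fixtures and builders for hand-crafted BCR objects."""

import numpy as np
import pytest

from clonsig.bcr import BCRContig, PairedBCR, REGIONS

BASES = "ACGT"


def make_regions(fr1=30, cdr1=9, fr2=24, cdr2=9, fr3=45, seed=0, gaps=0):
    """Deterministic region strings with optional gap columns in CDR1."""
    rng = np.random.default_rng(seed)
    lengths = dict(FR1=fr1, CDR1=cdr1, FR2=fr2, CDR2=cdr2, FR3=fr3)
    regions = {}
    for r in REGIONS:
        seq = "".join(BASES[i] for i in rng.integers(0, 4, lengths[r]))
        if r == "CDR1" and gaps:
            half = len(seq) // 2
            seq = seq[:half] + "." * gaps + seq[half:]
        regions[r] = seq
    return regions


def make_contig(
    cell="C1",
    locus="IGH",
    cdr3="TGTGCGAGAGAT",
    v_call="VH1",
    j_call="JH1",
    productive=True,
    full_length=True,
    dup=10,
    cons=20,
    seq_id=None,
    regions=None,
    events=(),
    donor="D1",
    seed=0,
    apply_events=True,
):
    regions = regions if regions is not None else make_regions(seed=seed)
    observed = "".join(regions[r] for r in REGIONS)
    if events and apply_events:
        chars = list(observed)
        for ev in events:
            chars[ev.position] = ev.observed_base
        observed = "".join(chars)
        offset = 0
        new_regions = {}
        for r in REGIONS:
            new_regions[r] = observed[offset : offset + len(regions[r])]
            offset += len(regions[r])
        regions = new_regions
    return BCRContig(
        sequence_id=seq_id or f"{cell}_{locus}",
        cell_id=cell,
        locus=locus,
        v_call=v_call,
        j_call=j_call,
        productive=productive,
        full_length=full_length,
        cdr3_nt=cdr3,
        gapped_observed=observed,
        regions=regions,
        mutation_table=tuple(events),
        duplicate_count=dup,
        consensus_count=cons,
        donor=donor,
    )


def make_pair(cell="C1", cdr3_h="TGTGCGAGAGATTAC", cdr3_l="TGTCAGCAGTAT", donor="D1", **kw):
    heavy = make_contig(cell=cell, locus="IGH", cdr3=cdr3_h, donor=donor,
                        v_call=kw.get("vh", "VH1"), j_call=kw.get("jh", "JH1"), seed=1)
    light = make_contig(cell=cell, locus="IGK", cdr3=cdr3_l, donor=donor,
                        v_call=kw.get("vl", "VL1"), j_call=kw.get("jl", "JL1"), seed=2)
    return PairedBCR(cell_id=cell, heavy=heavy, light=light, donor=donor)


def mutate(seq, positions, rng):
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([b for b in BASES if b != out[p]])
    return "".join(out)


@pytest.fixture(scope="session")
def small_repertoire():
    """60-cell, 10-clone simulated repertoire with its truth (seed 1)."""
    from clonsig.simulate import RepertoireSimConfig, simulate_repertoire

    cfg = RepertoireSimConfig(n_cells=60, n_clones=10, within_clone_divergence=0.1, seed=1)
    return simulate_repertoire(cfg)


@pytest.fixture(scope="session")
def small_expression():
    """300-cell, 800-gene expression data with a planted cluster-0 module."""
    from clonsig.simulate import ExpressionSimConfig, ModuleSpec, simulate_expression

    cfg = ExpressionSimConfig(
        n_genes=800, n_cells=300, n_clusters=3,
        module_specs=(ModuleSpec(name="m1", n_genes=40, clusters=(0,), log_fold=1.0),),
        seed=7,
    )
    return simulate_expression(cfg)
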