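"""Ground-truthed synthetic repertoire and expression data.

The repertoire generator emulates the tabulated output of single-cell V(D)J
assembly plus germline annotation: per-cell heavy/light contigs drawn from
a bundled synthetic germline segment library, organised into clonal
families with controlled within-clone CDR3 divergence, somatic
hypermutation planted as i.i.d. per-base substitutions on the V region
(recorded in a per-contig mutation table), and configurable nuisance
structure (unpaired cells, unproductive / partial / low-abundance extra
contigs) to exercise contig selection.

Separability is guaranteed by construction rather than by chance: each
clone owns a fixed set of mutable CDR3 positions of size
floor(divergence × length) per chain, and cells only vary within that set,
so any two clone-mates disagree at most at those positions and their CDR3
identity is at least 1 − divergence on every chain.  Decoy clones share
donor, V/J genes and CDR3 lengths with a partner clone but differ at
ceil((1 − ceiling) × length) positions per chain; the configuration is
rejected unless ceiling + 2 × divergence ≤ identity threshold, which
bounds the worst-case cross-clone identity below the clustering rule.

The expression generator draws negative-binomial UMI counts (gene-wise
log-normal baseline means, per-cell log-normal library-size factors,
common inverse-dispersion) and plants gene modules whose mean is scaled by
exp(log_fold) in target clusters only.  Module member genes are drawn from
genes whose baseline mean exceeds a floor, mirroring the fact that marker
genes of real cell states are expressed genes.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from importlib import resources

import anndata as ad
import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .bcr import GAP, REGIONS, MutationEvent, format_mutation_events

__all__ = [
    "RepertoireSimConfig",
    "ExpressionSimConfig",
    "ModuleSpec",
    "SimTruth",
    "load_segment_library",
    "simulate_repertoire",
    "simulate_expression",
    "plant_public_clones",
    "AIRR_COLUMNS",
]

BASES = "ACGT"

#: gapped column span of each region in the bundled V segments
V_LAYOUT = {
    "FR1": (0, 75),
    "CDR1": (75, 111),
    "FR2": (111, 162),
    "CDR2": (162, 192),
    "FR3": (192, 300),
}

AIRR_COLUMNS = [
    "sequence_id",
    "cell_id",
    "donor",
    "locus",
    "v_call",
    "j_call",
    "productive",
    "complete_vdj",
    "duplicate_count",
    "consensus_count",
    "junction",
    "junction_aa",
    "sequence_alignment",
    "germline_alignment",
    "fwr1",
    "cdr1",
    "fwr2",
    "cdr2",
    "fwr3",
    "fwr1_mut_count",
    "cdr1_mut_count",
    "fwr2_mut_count",
    "cdr2_mut_count",
    "fwr3_mut_count",
    "mutation_events",
    "c_call",
]

HEAVY_ISOTYPES = ("IGHM", "IGHG1", "IGHG2", "IGHA1", "IGHA2")


def load_segment_library() -> dict:
    """The bundled synthetic germline segments, id -> gapped nt sequence."""
    lib: dict[str, str] = {}
    text = resources.files("clonsig.data").joinpath("toy_segments.fasta").read_text()
    name = None
    chunks: list[str] = []
    for line in text.splitlines():
        if line.startswith(">"):
            if name is not None:
                lib[name] = "".join(chunks)
            name = line[1:].split()[0]
            chunks = []
        else:
            chunks.append(line.strip())
    if name is not None:
        lib[name] = "".join(chunks)
    return lib


@dataclass
class SimTruth:
    """Ground truth of one simulation run."""

    family_of_cell: dict = field(default_factory=dict)
    public_cells: set = field(default_factory=set)
    module_cells: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)


@dataclass
class RepertoireSimConfig:
    """Study conditions for the repertoire generator (see module docstring)."""

    n_cells: int = 500
    n_clones: int = 60
    clone_size_law: str = "power"  # or "uniform"
    power_alpha: float = 2.0
    cdr3_length_range: tuple = (30, 60)  # nt, lengths used are multiples of 3
    within_clone_divergence: float = 0.1
    shm_rate: float = 0.02
    decoy_fraction: float = 0.1
    decoy_identity_ceiling: float = 0.6
    identity_threshold: float = 0.8
    paired_fraction: float = 0.9
    extra_contig_fraction: float = 0.2
    donor_labels: tuple = ("D1",)
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells <= 0 or self.n_clones <= 0:
            raise ValueError("n_cells and n_clones must be positive")
        if self.n_clones > self.n_cells:
            raise ValueError("n_clones cannot exceed n_cells")
        if not 0.0 <= self.within_clone_divergence < 0.2:
            raise ValueError(
                "within_clone_divergence must lie in [0, 0.2): at 0.2 or above "
                "intra-clone CDR3 identity is no longer guaranteed to exceed 0.8"
            )
        lo, hi = self.cdr3_length_range
        if lo < 9 or hi < lo:
            raise ValueError("cdr3_length_range must satisfy 9 <= lo <= hi")
        if self.clone_size_law not in ("power", "uniform"):
            raise ValueError(f"unknown clone_size_law {self.clone_size_law!r}")
        n_decoy = int(self.decoy_fraction * self.n_clones)
        if 2 * n_decoy > self.n_clones:
            raise ValueError("decoy_fraction too large: decoys need distinct partner clones")
        if n_decoy and (
            self.decoy_identity_ceiling + 2 * self.within_clone_divergence
            > self.identity_threshold + 1e-12
        ):
            raise ValueError(
                "decoy_identity_ceiling + 2*within_clone_divergence must not exceed "
                "the identity threshold, or decoys may merge with their partner clone"
            )
        if not 0.0 <= self.paired_fraction <= 1.0:
            raise ValueError("paired_fraction must lie in [0, 1]")
        if not self.donor_labels:
            raise ValueError("at least one donor label required")


def _mutate_positions(rng, seq: str, positions) -> str:
    out = list(seq)
    for p in positions:
        choices = [b for b in BASES if b != out[p]]
        out[p] = choices[rng.integers(len(choices))]
    return "".join(out)


def _region_of(pos: int) -> str:
    for region, (a, b) in V_LAYOUT.items():
        if a <= pos < b:
            return region
    raise ValueError(f"position {pos} outside V layout")


@dataclass
class _Chain:
    v_call: str
    j_call: str
    junction: str
    mutable: np.ndarray  # CDR3 positions this clone may vary


def _sample_chain(rng, v_ids, j_ids, cfg: RepertoireSimConfig) -> _Chain:
    lo, hi = cfg.cdr3_length_range
    lengths = [length for length in range(lo, hi + 1) if length % 3 == 0]
    L = int(lengths[rng.integers(len(lengths))])
    junction = "".join(BASES[rng.integers(4)] for _ in range(L))
    k = math.floor(cfg.within_clone_divergence * L)
    mutable = rng.choice(L, size=k, replace=False) if k else np.empty(0, dtype=int)
    return _Chain(
        v_call=v_ids[rng.integers(len(v_ids))],
        j_call=j_ids[rng.integers(len(j_ids))],
        junction=junction,
        mutable=np.sort(mutable),
    )


def _decoy_junction(rng, junction: str, ceiling: float) -> str:
    L = len(junction)
    k = math.ceil((1.0 - ceiling) * L)
    positions = rng.choice(L, size=k, replace=False)
    return _mutate_positions(rng, junction, positions)


def _cell_junction(rng, chain: _Chain) -> str:
    if chain.mutable.size == 0:
        return chain.junction
    hit = chain.mutable[rng.random(chain.mutable.size) < 0.5]
    return _mutate_positions(rng, chain.junction, hit)


def _shm(rng, gapped: str, rate: float):
    """Substitute non-gap bases i.i.d. at ``rate``; return (observed, events)."""
    if rate <= 0:
        return gapped, ()
    out = list(gapped)
    events = []
    draws = rng.random(len(gapped))
    for pos, (base, u) in enumerate(zip(gapped, draws)):
        if base == GAP or u >= rate:
            continue
        new = _mutate_positions(rng, base, [0])
        out[pos] = new
        events.append(MutationEvent(_region_of(pos), pos, base, new))
    return "".join(out), tuple(events)


def _contig_row(
    seq_id, cell_id, donor, locus, chain: _Chain, junction, observed, germline, events, dup, cons,
    c_call, productive=True, complete=True, drop_region=None,
):
    regions = {r: observed[slice(*V_LAYOUT[r])] for r in REGIONS}
    if drop_region:
        regions[drop_region] = ""
    counts = {r: sum(1 for e in events if e.region == r) for r in REGIONS}
    return {
        "sequence_id": seq_id,
        "cell_id": cell_id,
        "donor": donor,
        "locus": locus,
        "v_call": chain.v_call,
        "j_call": chain.j_call,
        "productive": "T" if productive else "F",
        "complete_vdj": "T" if complete else "F",
        "duplicate_count": dup,
        "consensus_count": cons,
        "junction": junction,
        "junction_aa": str(Seq(junction).translate()),
        "sequence_alignment": "".join(regions[r] for r in REGIONS),
        "germline_alignment": germline if not drop_region else "",
        "fwr1": regions["FR1"],
        "cdr1": regions["CDR1"],
        "fwr2": regions["FR2"],
        "cdr2": regions["CDR2"],
        "fwr3": regions["FR3"],
        "fwr1_mut_count": counts["FR1"],
        "cdr1_mut_count": counts["CDR1"],
        "fwr2_mut_count": counts["FR2"],
        "cdr2_mut_count": counts["CDR2"],
        "fwr3_mut_count": counts["FR3"],
        "mutation_events": format_mutation_events(events),
        "c_call": c_call,
    }


def simulate_repertoire(config: RepertoireSimConfig | None = None, **kwargs):
    """Generate an AIRR-style rearrangement table with known clonal truth.

    Returns ``(table, truth)`` where ``truth.family_of_cell`` maps every
    simulated cell to its generating clone.
    """
    cfg = config if config is not None else RepertoireSimConfig(**kwargs)
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    lib = load_segment_library()
    hv = sorted(k for k in lib if k.startswith("TOYHV"))
    hj = sorted(k for k in lib if k.startswith("TOYHJ"))
    lv = sorted(k for k in lib if k.startswith("TOYLV"))
    lj = sorted(k for k in lib if k.startswith("TOYLJ"))

    n_decoy = int(cfg.decoy_fraction * cfg.n_clones)
    n_real = cfg.n_clones - n_decoy
    clones = []
    for _ in range(n_real):
        donor = cfg.donor_labels[rng.integers(len(cfg.donor_labels))]
        clones.append(
            {
                "donor": donor,
                "heavy": _sample_chain(rng, hv, hj, cfg),
                "light": _sample_chain(rng, lv, lj, cfg),
            }
        )
    for i in range(n_decoy):
        partner = clones[i]
        heavy = partner["heavy"]
        light = partner["light"]

        def _decoy(chain: _Chain) -> _Chain:
            junction = _decoy_junction(rng, chain.junction, cfg.decoy_identity_ceiling)
            k = chain.mutable.size
            mutable = (
                np.sort(rng.choice(len(junction), size=k, replace=False))
                if k
                else np.empty(0, dtype=int)
            )
            return _Chain(chain.v_call, chain.j_call, junction, mutable)

        clones.append({"donor": partner["donor"], "heavy": _decoy(heavy), "light": _decoy(light)})

    # cell -> clone: every clone seeded once, remainder by the size law
    assignment = list(range(cfg.n_clones))
    remaining = cfg.n_cells - cfg.n_clones
    if cfg.clone_size_law == "power":
        weights = (np.arange(cfg.n_clones) + 1.0) ** (-cfg.power_alpha)
    else:
        weights = np.ones(cfg.n_clones)
    weights = weights / weights.sum()
    assignment += list(rng.choice(cfg.n_clones, size=remaining, p=weights))
    assignment = np.array(assignment)
    rng.shuffle(assignment)

    cell_ids = [f"C{i + 1:05d}" for i in range(cfg.n_cells)]
    n_unpaired = int(round((1.0 - cfg.paired_fraction) * cfg.n_cells))
    unpaired = set(rng.choice(cfg.n_cells, size=n_unpaired, replace=False))
    n_extra = int(round(cfg.extra_contig_fraction * cfg.n_cells))
    extra = {int(i): j for j, i in enumerate(rng.choice(cfg.n_cells, size=n_extra, replace=False))}

    rows = []
    truth = SimTruth(params={"config": asdict(cfg)})
    for ci, cell in enumerate(cell_ids):
        clone = clones[assignment[ci]]
        truth.family_of_cell[cell] = f"clone{assignment[ci]:04d}"
        iso = HEAVY_ISOTYPES[rng.integers(len(HEAVY_ISOTYPES))]
        for locus, chain, c_call in (
            ("IGH", clone["heavy"], iso),
            ("IGK", clone["light"], "IGKC"),
        ):
            junction = _cell_junction(rng, chain)
            germ = lib[chain.v_call]
            observed, events = _shm(rng, germ, cfg.shm_rate)
            dup = int(rng.integers(3, 50))
            cons = dup * int(rng.integers(2, 5))
            rows.append(
                _contig_row(
                    f"{cell}_{locus}", cell, clone["donor"], locus, chain, junction,
                    observed, germ, events, dup, cons, c_call,
                )
            )
            if locus == "IGH" and ci in extra:
                kind = extra[ci] % 3
                if kind == 0:  # unproductive, more abundant
                    rows.append(
                        _contig_row(
                            f"{cell}_{locus}_x", cell, clone["donor"], locus, chain,
                            junction, observed, germ, events, dup + 10, cons, c_call,
                            productive=False,
                        )
                    )
                elif kind == 1:  # partial assembly, more abundant
                    partial = {r: observed[slice(*V_LAYOUT[r])] for r in REGIONS}
                    partial["FR1"] = ""
                    rows.append(
                        {
                            **_contig_row(
                                f"{cell}_{locus}_x", cell, clone["donor"], locus, chain,
                                junction, observed, germ, (), dup + 10, cons, c_call,
                                complete=False,
                            ),
                            "sequence_alignment": "".join(partial[r] for r in REGIONS),
                            "fwr1": "",
                        }
                    )
                else:  # productive duplicate at lower abundance, corrupted CDR3
                    bad = _mutate_positions(
                        rng, junction, rng.choice(len(junction), size=3, replace=False)
                    )
                    rows.append(
                        _contig_row(
                            f"{cell}_{locus}_x", cell, clone["donor"], locus, chain,
                            bad, observed, germ, events, 1, 2, c_call,
                        )
                    )
            if locus == "IGH" and ci in unpaired:
                break  # no light contig for this cell

    table = pd.DataFrame(rows, columns=AIRR_COLUMNS)
    return table, truth


@dataclass
class ModuleSpec:
    """A planted gene module: upregulated by exp(log_fold) in target clusters."""

    name: str = "module_1"
    n_genes: int = 50
    clusters: tuple = (0,)
    log_fold: float = 1.0


@dataclass
class ExpressionSimConfig:
    """Study conditions for the UMI-count generator."""

    n_genes: int = 2000
    n_cells: int = 1000
    n_clusters: int = 5
    module_specs: tuple = (ModuleSpec(),)
    baseline_log_mean: float = math.log(0.5)
    baseline_log_sd: float = 1.0
    dispersion: float = 10.0  # NB inverse-dispersion (gamma shape)
    libsize_log_mean: float = 0.0
    libsize_log_sd: float = 0.3
    mito_gene_fraction: float = 0.01
    module_baseline_min: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_genes, self.n_cells, self.n_clusters) <= 0:
            raise ValueError("n_genes, n_cells and n_clusters must be positive")
        total = sum(m.n_genes for m in self.module_specs)
        if total > self.n_genes:
            raise ValueError("module genes exceed n_genes")
        for m in self.module_specs:
            if any(c >= self.n_clusters or c < 0 for c in m.clusters):
                raise ValueError(f"module {m.name!r} targets a cluster outside range")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


def simulate_expression(config: ExpressionSimConfig | None = None, **kwargs):
    """Generate an AnnData of NB UMI counts with planted cluster modules.

    Returns ``(adata, truth)``; ``adata.obs['cluster']`` carries the cluster
    labels, ``truth.module_cells`` the cells where each module is active and
    ``truth.params['module_genes']`` its member genes.
    """
    cfg = config if config is not None else ExpressionSimConfig(**kwargs)
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    n_mito = int(cfg.mito_gene_fraction * cfg.n_genes)
    genes = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    for i in range(n_mito):
        genes[i] = f"MT-{genes[i]}"
    baseline = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=cfg.n_genes)

    # clusters as equal contiguous blocks
    labels = np.repeat(np.arange(cfg.n_clusters), math.ceil(cfg.n_cells / cfg.n_clusters))[
        : cfg.n_cells
    ]
    cells = [f"BC{i + 1:05d}" for i in range(cfg.n_cells)]

    eligible = [
        i for i, g in enumerate(genes)
        if not g.startswith("MT-") and baseline[i] >= cfg.module_baseline_min
    ]
    rng.shuffle(eligible)
    needed = sum(m.n_genes for m in cfg.module_specs)
    if needed > len(eligible):
        raise ValueError(
            f"only {len(eligible)} genes clear the module baseline floor; "
            f"{needed} module genes requested"
        )

    effect = np.ones((cfg.n_cells, cfg.n_genes))
    truth = SimTruth(params={"config": {**asdict(cfg), "module_specs": [asdict(m) for m in cfg.module_specs]}})
    truth.params["module_genes"] = {}
    cursor = 0
    for spec in cfg.module_specs:
        idx = np.array(sorted(eligible[cursor : cursor + spec.n_genes]))
        cursor += spec.n_genes
        cell_mask = np.isin(labels, list(spec.clusters))
        effect[np.ix_(cell_mask, idx)] = math.exp(spec.log_fold)
        truth.params["module_genes"][spec.name] = [genes[i] for i in idx]
        truth.module_cells[spec.name] = sorted(
            cells[i] for i in np.flatnonzero(cell_mask)
        )

    libsize = rng.lognormal(cfg.libsize_log_mean, cfg.libsize_log_sd, size=cfg.n_cells)
    mu = baseline[None, :] * libsize[:, None] * effect
    lam = rng.gamma(cfg.dispersion, mu / cfg.dispersion)
    counts = rng.poisson(lam).astype(np.int64)

    adata = ad.AnnData(
        X=counts,
        obs=pd.DataFrame(
            {"cluster": pd.Categorical([f"c{k}" for k in labels])}, index=cells
        ),
        var=pd.DataFrame(index=genes),
    )
    adata.var["mito"] = [g.startswith("MT-") for g in genes]
    return adata, truth


def plant_public_clones(
    repertoire: pd.DataFrame,
    n_public: int = 10,
    divergence: float = 0.0,
    seed: int | None = None,
    antigen_labels: tuple = ("spike", "tetanus"),
):
    """Build a reference clonotype table matching planted repertoire clones.

    ``n_public`` clonal families are sampled from the repertoire; for each,
    a reference clone is emitted whose CDR3s differ from the family template
    by round(divergence × pooled length) substitutions.  The returned truth
    lists every repertoire cell that matches the reference set at joint
    identity ≥ 0.8 with consistent lengths, established by a brute-force
    all-pairs scan.
    """
    from .clonal import partition_families
    from .io import contigs_from_table
    from .bcr import select_contigs

    if repertoire.empty:
        raise ValueError("repertoire table is empty")
    rng = np.random.default_rng(seed)
    pairs, _ = select_contigs(contigs_from_table(repertoire))
    partition = partition_families(pairs.values())
    families = sorted(partition.members)
    if n_public > len(families):
        raise ValueError(f"n_public={n_public} exceeds {len(families)} available clones")
    chosen = sorted(rng.choice(len(families), size=n_public, replace=False))

    ref_rows = []
    ref_pairs = []
    for k, fi in enumerate(chosen):
        template = pairs[partition.members[families[fi]][0]]
        lh, ll = len(template.heavy.cdr3_nt), len(template.light.cdr3_nt)
        kt = round(divergence * (lh + ll))
        kh = min(lh, round(kt * lh / (lh + ll)))
        kl = kt - kh
        jh = _mutate_positions(
            rng, template.heavy.cdr3_nt, rng.choice(lh, size=kh, replace=False)
        )
        jl = _mutate_positions(
            rng, template.light.cdr3_nt, rng.choice(ll, size=kl, replace=False)
        )
        antigen = antigen_labels[k % len(antigen_labels)]
        ref_id = f"REF{k + 1:04d}"
        for locus, contig, junction in (
            ("IGH", template.heavy, jh),
            ("IGK", template.light, jl),
        ):
            row = {c: "" for c in AIRR_COLUMNS}
            row.update(
                {
                    "sequence_id": f"{ref_id}_{locus}",
                    "cell_id": ref_id,
                    "donor": "REFPOOL",
                    "locus": locus,
                    "v_call": contig.v_call,
                    "j_call": contig.j_call,
                    "productive": "T",
                    "complete_vdj": "T",
                    "duplicate_count": 10,
                    "consensus_count": 20,
                    "junction": junction,
                    "junction_aa": str(Seq(junction).translate()),
                    "sequence_alignment": contig.gapped_observed,
                    "germline_alignment": contig.gapped_observed,
                    "fwr1": contig.regions["FR1"],
                    "cdr1": contig.regions["CDR1"],
                    "fwr2": contig.regions["FR2"],
                    "cdr2": contig.regions["CDR2"],
                    "fwr3": contig.regions["FR3"],
                    "fwr1_mut_count": 0,
                    "cdr1_mut_count": 0,
                    "fwr2_mut_count": 0,
                    "cdr2_mut_count": 0,
                    "fwr3_mut_count": 0,
                    "mutation_events": "",
                    "c_call": "IGHG1" if locus == "IGH" else "IGKC",
                }
            )
            row["antigen_label"] = antigen
            ref_rows.append(row)
        ref_pairs.append((ref_id, jh, jl))

    reference = pd.DataFrame(ref_rows, columns=AIRR_COLUMNS + ["antigen_label"])

    # brute-force truth scan, independent of the matcher's bucketing
    truth = SimTruth(params={"n_public": n_public, "divergence": divergence, "seed": seed})
    for cell_id, pair in pairs.items():
        qh, ql = pair.heavy.cdr3_nt, pair.light.cdr3_nt
        for _, jh, jl in ref_pairs:
            if len(qh) != len(jh) or len(ql) != len(jl):
                continue
            matches = sum(a == b for a, b in zip(qh, jh)) + sum(
                a == b for a, b in zip(ql, jl)
            )
            if matches / (len(qh) + len(ql)) >= 0.8:
                truth.public_cells.add(cell_id)
                break
    return reference, truth
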