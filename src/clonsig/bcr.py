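"""Per-cell B-cell-receptor data model.

A cell's BCR is represented by one selected heavy and one selected light
contig.  Each contig carries the gapped FR1-CDR1-FR2-CDR2-FR3 alignment of
its V region together with a table of somatic mutations (region, gapped
position, germline base, observed base), the form in which V(D)J annotation
services report per-region mutation statistics.  From these the germline
alignment can be reconstructed exactly, and somatic-hypermutation rates are
computed as mutations per nucleotide over a region group, summed across the
heavy and light chain of a cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

GAP = "."

#: canonical region order of the gapped V alignment
REGIONS = ("FR1", "CDR1", "FR2", "CDR2", "FR3")

#: AIRR column name for each region string
REGION_COLUMNS = {"FR1": "fwr1", "CDR1": "cdr1", "FR2": "fwr2", "CDR2": "cdr2", "FR3": "fwr3"}

FRAMEWORK_GROUP = ("FR1", "FR2", "FR3")
CDR_GROUP = ("CDR1", "CDR2")

HEAVY_LOCI = frozenset({"IGH"})
LIGHT_LOCI = frozenset({"IGK", "IGL"})


@dataclass(frozen=True)
class MutationEvent:
    """One somatic substitution in the gapped V alignment."""

    region: str  # one of REGIONS
    position: int  # 0-based column in the gapped alignment
    germline_base: str
    observed_base: str

    def __str__(self) -> str:
        return f"{self.region}:{self.position}:{self.germline_base}>{self.observed_base}"

    @classmethod
    def parse(cls, text: str) -> "MutationEvent":
        region, pos, change = text.split(":")
        germ, obs = change.split(">")
        return cls(region=region, position=int(pos), germline_base=germ, observed_base=obs)


def format_mutation_events(events) -> str:
    return ";".join(str(e) for e in events)


def parse_mutation_events(text: str) -> tuple:
    if not text or not str(text).strip():
        return ()
    return tuple(MutationEvent.parse(tok) for tok in str(text).split(";"))


@dataclass
class BCRContig:
    """One assembled BCR contig with its gapped V alignment and mutations."""

    sequence_id: str
    cell_id: str
    locus: str
    v_call: str
    j_call: str
    productive: bool
    full_length: bool
    cdr3_nt: str
    gapped_observed: str
    regions: dict  # region -> gapped slice of ``gapped_observed``
    mutation_table: tuple = ()
    duplicate_count: int | None = None
    consensus_count: int | None = None
    cdr3_aa: str = ""
    isotype: str = ""
    donor: str = ""

    def __post_init__(self) -> None:
        joined = "".join(self.regions.get(r, "") for r in REGIONS)
        if joined != self.gapped_observed:
            raise ValueError(
                f"contig {self.sequence_id}: region strings do not concatenate "
                "to the gapped observed sequence"
            )
        bounds = self.region_bounds()
        for ev in self.mutation_table:
            if ev.region not in bounds:
                raise ValueError(f"contig {self.sequence_id}: unknown region {ev.region!r}")
            start, end = bounds[ev.region]
            if not start <= ev.position < end:
                raise ValueError(
                    f"contig {self.sequence_id}: mutation at gapped position "
                    f"{ev.position} lies outside its stated region {ev.region} "
                    f"[{start}, {end})"
                )
            base = self.gapped_observed[ev.position]
            if base == GAP:
                raise ValueError(
                    f"contig {self.sequence_id}: mutation listed at gap column {ev.position}"
                )
            if base != ev.observed_base:
                raise ValueError(
                    f"contig {self.sequence_id}: observed base {base!r} at position "
                    f"{ev.position} does not match mutation table entry {ev}"
                )

    @property
    def is_heavy(self) -> bool:
        return self.locus in HEAVY_LOCI

    @property
    def is_light(self) -> bool:
        return self.locus in LIGHT_LOCI

    def region_bounds(self) -> dict:
        """Gapped [start, end) column span of each region."""
        bounds, offset = {}, 0
        for region in REGIONS:
            seq = self.regions.get(region, "")
            bounds[region] = (offset, offset + len(seq))
            offset += len(seq)
        return bounds

    def region_length(self, region: str) -> int:
        """Gap-excluded nucleotide length of a region."""
        return sum(1 for b in self.regions.get(region, "") if b != GAP)

    def region_mutation_count(self, region: str) -> int:
        return sum(1 for ev in self.mutation_table if ev.region == region)


@dataclass
class PairedBCR:
    """The selected heavy/light contig pair of one cell."""

    cell_id: str
    heavy: BCRContig
    light: BCRContig
    germline_fr_heavy: str = ""
    germline_fr_light: str = ""
    donor: str = ""

    def __post_init__(self) -> None:
        if not (self.heavy.is_heavy and self.light.is_light):
            raise ValueError(f"cell {self.cell_id}: chains assigned to wrong loci")
        if not self.germline_fr_heavy:
            self.germline_fr_heavy = reconstruct_germline(self.heavy)
        if not self.germline_fr_light:
            self.germline_fr_light = reconstruct_germline(self.light)
        if not self.donor:
            self.donor = self.heavy.donor or self.light.donor


@dataclass(frozen=True)
class MutationCounts:
    """Per-chain mutation counts and gap-excluded lengths for one region group."""

    region_group: str
    heavy_count: int
    heavy_length: int
    light_count: int
    light_length: int


@dataclass
class SelectionReport:
    """Accounting of the contig-selection filter."""

    n_cells_in: int = 0
    n_cells_paired: int = 0
    unpaired_cells: list = field(default_factory=list)

    @property
    def n_cells_dropped(self) -> int:
        return self.n_cells_in - self.n_cells_paired

    def as_dict(self) -> dict:
        return {
            "n_cells_in": self.n_cells_in,
            "n_cells_paired": self.n_cells_paired,
            "n_cells_dropped_unpaired": self.n_cells_dropped,
            "unpaired_cells": sorted(self.unpaired_cells),
        }


def _abundance_key(contig: BCRContig):
    if contig.duplicate_count is None:
        raise ValueError(
            f"contig {contig.sequence_id}: missing abundance (duplicate_count)"
        )
    reads = contig.consensus_count if contig.consensus_count is not None else 0
    return (-contig.duplicate_count, -reads, contig.sequence_id)


def select_contigs(contigs) -> tuple[dict, SelectionReport]:
    """Pick one heavy and one light contig per cell.

    Contigs are first filtered to productive and fully sequenced ones, then
    for each chain the most abundant contig is selected (UMI count, read
    count and contig identifier as successive tie-breakers).  Cells that do
    not retain both chains are dropped and listed in the report.
    """
    by_cell: dict[str, list[BCRContig]] = {}
    for contig in contigs:
        by_cell.setdefault(contig.cell_id, []).append(contig)

    report = SelectionReport(n_cells_in=len(by_cell))
    pairs: dict[str, PairedBCR] = {}
    for cell_id in sorted(by_cell):
        valid = [c for c in by_cell[cell_id] if c.productive and c.full_length]
        heavies = sorted((c for c in valid if c.is_heavy), key=_abundance_key)
        lights = sorted((c for c in valid if c.is_light), key=_abundance_key)
        if heavies and lights:
            pairs[cell_id] = PairedBCR(cell_id=cell_id, heavy=heavies[0], light=lights[0])
            report.n_cells_paired += 1
        else:
            report.unpaired_cells.append(cell_id)
    return pairs, report


def reconstruct_germline(contig: BCRContig) -> str:
    """Revert every listed somatic substitution, yielding the gapped germline.

    Position/region/base consistency is enforced by the contig invariants; a
    no-op entry (germline base equal to the observed base) is reported as a
    warning and left in place.
    """
    seq = list(contig.gapped_observed)
    for ev in contig.mutation_table:
        if ev.germline_base == ev.observed_base:
            warnings.warn(
                f"contig {contig.sequence_id}: no-op mutation entry {ev}",
                stacklevel=2,
            )
        seq[ev.position] = ev.germline_base
    return "".join(seq)


def mutation_counts(pair: PairedBCR, region_group: str = "FR1-3") -> MutationCounts:
    """Summed mutation counts and lengths per chain for a region group.

    ``"FR1-3"`` covers the three framework regions.  ``"CDR1-3"`` covers
    CDR1 and CDR2; the junction (CDR3) has no germline in the V-region
    mutation table, so it contributes neither counts nor length.
    """
    if region_group == "FR1-3":
        regions = FRAMEWORK_GROUP
    elif region_group == "CDR1-3":
        regions = CDR_GROUP
    else:
        raise ValueError(f"unknown region group {region_group!r}; use 'FR1-3' or 'CDR1-3'")
    hc = sum(pair.heavy.region_mutation_count(r) for r in regions)
    hl = sum(pair.heavy.region_length(r) for r in regions)
    lc = sum(pair.light.region_mutation_count(r) for r in regions)
    ll = sum(pair.light.region_length(r) for r in regions)
    return MutationCounts(region_group, hc, hl, lc, ll)


def mutation_rate(pair: PairedBCR, region_group: str = "FR1-3") -> float:
    """(heavy + light mutations) / (heavy + light nt length) for a region group."""
    counts = mutation_counts(pair, region_group)
    total_len = counts.heavy_length + counts.light_length
    if total_len == 0:
        raise ValueError(
            f"cell {pair.cell_id}: zero total {region_group} length, rate undefined"
        )
    return (counts.heavy_count + counts.light_count) / total_len


def swap_chain_labels(pair: PairedBCR) -> PairedBCR:
    """Relabel chains (testing aid for symmetry properties); loci are swapped too."""
    heavy = replace(pair.light, locus="IGH")
    light = replace(pair.heavy, locus="IGK")
    return PairedBCR(
        cell_id=pair.cell_id,
        heavy=heavy,
        light=light,
        germline_fr_heavy=pair.germline_fr_light,
        germline_fr_light=pair.germline_fr_heavy,
        donor=pair.donor,
    )
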