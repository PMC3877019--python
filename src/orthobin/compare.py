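"""Cross-dataset comparison of binned expression.

Orthologs are matched purely by (uppercased) gene symbol. Species-specific
genes are those High in one species and Very Low in the other, restricted to
genes with a curated (NM_) transcript accession in both datasets and not
removed by the duplicate-consistency filter. Concordance counts how much of
one dataset's High bin re-appears in another same-species dataset's High
bin. Gene-set profiles tabulate per-dataset bins and flag genes whose bins
differ by two or more ordered categories between a chosen dataset pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from orthobin.binning import BIN_INDEX, BINS, BinnedDataset
from orthobin.errors import FormatError
from orthobin.io import GeneSet

ABSENT = "-"


@dataclass(frozen=True)
class OrthologPair:
    gene_symbol: str
    bin_a: str
    bin_b: str
    percentile_a: float
    percentile_b: float
    curated_a: bool
    curated_b: bool


@dataclass
class OrthologTable:
    """Ortholog pairs between two binned datasets, with their provenance."""

    dataset_a: str
    dataset_b: str
    species_a: str
    species_b: str
    pairs: list[OrthologPair] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def cross_bin_counts(self) -> dict[tuple[str, str], int]:
        """4x4 contingency of (bin in a, bin in b) over all pairs."""
        counts = {(x, y): 0 for x in BINS for y in BINS}
        for p in self.pairs:
            counts[(p.bin_a, p.bin_b)] += 1
        return counts


@dataclass(frozen=True)
class SpecificityCall:
    gene_symbol: str
    specific_species: str
    other_species: str
    bin_specific: str = "H"
    bin_other: str = "VL"

    def __post_init__(self) -> None:
        if self.bin_specific != "H" or self.bin_other != "VL":
            raise FormatError(
                "specificity requires High in the specific species and "
                "Very Low in the other"
            )


@dataclass(frozen=True)
class ConcordanceRow:
    ref_dataset: str
    query_dataset: str
    n_query_high: int
    n_overlap: int
    pct_overlap: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_overlap <= self.n_query_high:
            raise FormatError("overlap count exceeds query High-set size")
        if self.pct_overlap != _round_half_up(100.0 * self.n_overlap / self.n_query_high):
            raise FormatError("pct_overlap inconsistent with counts")


@dataclass
class GeneSetBinProfile:
    set_name: str
    dataset_ids: list[str]
    per_gene: dict[str, dict[str, str]]
    histograms: dict[str, dict[str, int]]
    flag_pair: tuple[str, str]
    shifts: dict[str, int]
    flagged_shifts: dict[str, int]


def _round_half_up(x: float) -> int:
    import math

    return int(math.floor(x + 0.5))


def match_orthologs(a: BinnedDataset, b: BinnedDataset) -> OrthologTable:
    """Pair every gene symbol present in both datasets.

    Symbols found in only one dataset are excluded, as is any symbol the
    duplicate-consistency filter dropped in either dataset.
    """
    excluded = a.dropped_inconsistent | b.dropped_inconsistent
    shared = (set(a.genes) & set(b.genes)) - excluded
    pairs = [
        OrthologPair(
            gene_symbol=s,
            bin_a=a.genes[s].bin,
            bin_b=b.genes[s].bin,
            percentile_a=a.genes[s].percentile,
            percentile_b=b.genes[s].percentile,
            curated_a=a.genes[s].has_curated_accession,
            curated_b=b.genes[s].has_curated_accession,
        )
        for s in sorted(shared)
    ]
    return OrthologTable(
        dataset_a=a.dataset_id,
        dataset_b=b.dataset_id,
        species_a=a.species,
        species_b=b.species,
        pairs=pairs,
    )


def select_cross_bins(
    pairs: OrthologTable | list[OrthologPair], bin_in_a: str, bin_in_b: str
) -> list[str]:
    """Symbols with exactly the requested (bin in a, bin in b), sorted."""
    for b in (bin_in_a, bin_in_b):
        if b not in BINS:
            raise FormatError(f"unknown bin {b!r}")
    return sorted(
        p.gene_symbol for p in pairs if p.bin_a == bin_in_a and p.bin_b == bin_in_b
    )


def call_specific_genes(
    table: OrthologTable, specific_species: str
) -> list[SpecificityCall]:
    """Call genes specific to one species: H there, VL in the other.

    Only genes carrying a curated (NM_) accession in both datasets survive;
    consistency-filtered genes were already excluded during matching.
    """
    if specific_species == table.species_a:
        other = table.species_b
        want = lambda p: p.bin_a == "H" and p.bin_b == "VL"  # noqa: E731
    elif specific_species == table.species_b:
        other = table.species_a
        want = lambda p: p.bin_b == "H" and p.bin_a == "VL"  # noqa: E731
    else:
        raise FormatError(
            f"species {specific_species!r} matches neither dataset "
            f"({table.species_a!r}, {table.species_b!r})"
        )
    return [
        SpecificityCall(
            gene_symbol=p.gene_symbol,
            specific_species=specific_species,
            other_species=other,
        )
        for p in table.pairs
        if want(p) and p.curated_a and p.curated_b
    ]


def concordance(ref: BinnedDataset, query: BinnedDataset) -> ConcordanceRow:
    """Overlap of the query dataset's High bin with the reference's High bin.

    The percentage is taken over the query High set and rounded half-up to
    an integer.
    """
    if ref.species != query.species:
        raise FormatError(
            f"concordance requires matching species, got "
            f"{ref.species!r} vs {query.species!r}"
        )
    query_high = query.genes_in_bin("H")
    if not query_high:
        raise FormatError(f"query dataset {query.dataset_id!r} has an empty High bin")
    overlap = query_high & ref.genes_in_bin("H")
    return ConcordanceRow(
        ref_dataset=ref.dataset_id,
        query_dataset=query.dataset_id,
        n_query_high=len(query_high),
        n_overlap=len(overlap),
        pct_overlap=_round_half_up(100.0 * len(overlap) / len(query_high)),
    )


def bin_shift(bin_x: str, bin_y: str) -> int:
    """Distance between two bins under the total order VL < L < M < H."""
    return abs(BIN_INDEX[bin_x] - BIN_INDEX[bin_y])


def gene_set_profile(
    gene_set: GeneSet,
    datasets: list[BinnedDataset],
    flag_pair: tuple[str, str],
) -> GeneSetBinProfile:
    """Tabulate a gene set's bin per dataset and flag large shifts.

    Genes absent from a dataset are shown as ``-``. Shifts are computed
    between the two datasets named in ``flag_pair`` for genes present in
    both; a shift of two or more categories is flagged.
    """
    by_id = {d.dataset_id: d for d in datasets}
    if len(by_id) != len(datasets):
        raise FormatError("duplicate dataset ids in profile input")
    for did in flag_pair:
        if did not in by_id:
            raise FormatError(f"unknown dataset id {did!r} in flag_pair")

    dataset_ids = [d.dataset_id for d in datasets]
    per_gene: dict[str, dict[str, str]] = {}
    for symbol in sorted(gene_set.symbols):
        per_gene[symbol] = {
            did: (by_id[did].genes[symbol].bin if symbol in by_id[did].genes else ABSENT)
            for did in dataset_ids
        }

    histograms = {
        did: {
            b: sum(1 for row in per_gene.values() if row[did] == b) for b in BINS
        }
        for did in dataset_ids
    }

    x, y = flag_pair
    shifts = {
        symbol: bin_shift(row[x], row[y])
        for symbol, row in per_gene.items()
        if row[x] != ABSENT and row[y] != ABSENT
    }
    flagged = {s: d for s, d in shifts.items() if d >= 2}
    return GeneSetBinProfile(
        set_name=gene_set.name,
        dataset_ids=dataset_ids,
        per_gene=per_gene,
        histograms=histograms,
        flag_pair=(x, y),
        shifts=shifts,
        flagged_shifts=flagged,
    )
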