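"""Normalization, replicate averaging, probe collapsing and percentile binning.

The per-dataset pipeline is::

    quantile_normalize -> average_replicates -> collapse_probes
        -> percentile_rank -> assign_bins

Percentiles use the strict-lower-count definition
``p(g) = 100 * #{means < mean(g)} / N`` (ties share a percentile, values in
[0, 100)), and the four bins partition [0, 100) with half-open intervals
closed at the lower edge: VL = [0, 10), L = [10, 50), M = [50, 90),
H = [90, 100). A gene at exactly the upper cutoff is therefore in the top
bin, consistent with "strictly more than 90% of genes rank below it".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from orthobin.errors import FormatError
from orthobin.io import AnnotationTable, ExpressionMatrix, normalize_symbol

logger = logging.getLogger(__name__)

#: Bin labels in increasing expression order.
BINS: tuple[str, ...] = ("VL", "L", "M", "H")
BIN_INDEX: dict[str, int] = {b: i for i, b in enumerate(BINS)}


@dataclass(frozen=True)
class Cutoffs:
    """Percentile cut points separating the four bins."""

    low: float = 10.0
    mid: float = 50.0
    high: float = 90.0

    def __post_init__(self) -> None:
        if not (0.0 < self.low < self.mid < self.high < 100.0):
            raise FormatError(
                f"cutoffs must be strictly increasing within (0, 100), "
                f"got {(self.low, self.mid, self.high)}"
            )

    def __iter__(self):
        return iter((self.low, self.mid, self.high))

    def bin_of(self, percentile: float) -> str:
        if percentile >= self.high:
            return "H"
        if percentile >= self.mid:
            return "M"
        if percentile >= self.low:
            return "L"
        return "VL"


@dataclass(frozen=True)
class GeneSummary:
    """Per-gene outcome of the binning pipeline."""

    gene_symbol: str
    mean_log2: float
    percentile: float
    bin: str
    n_probes: int = 1
    has_curated_accession: bool = False
    cutoffs: Cutoffs = field(default=Cutoffs(), compare=False)

    def __post_init__(self) -> None:
        if self.bin not in BINS:
            raise FormatError(f"unknown bin {self.bin!r}")
        if not 0.0 <= self.percentile < 100.0:
            raise FormatError(f"percentile {self.percentile} outside [0, 100)")
        if self.cutoffs.bin_of(self.percentile) != self.bin:
            raise FormatError(
                f"gene {self.gene_symbol!r}: bin {self.bin} inconsistent with "
                f"percentile {self.percentile} under cutoffs {tuple(self.cutoffs)}"
            )
        if self.n_probes < 1:
            raise FormatError(f"gene {self.gene_symbol!r}: n_probes must be positive")


@dataclass
class BinnedDataset:
    """All gene summaries of one dataset plus the consistency-filter fallout."""

    dataset_id: str
    species: str
    genes: dict[str, GeneSummary]
    dropped_inconsistent: set[str] = field(default_factory=set)
    cutoffs: Cutoffs = field(default_factory=Cutoffs)

    def __post_init__(self) -> None:
        overlap = set(self.genes) & self.dropped_inconsistent
        if overlap:
            raise FormatError(
                f"genes present both as kept and dropped_inconsistent: {sorted(overlap)[:5]}"
            )

    def bin_counts(self) -> dict[str, int]:
        counts = {b: 0 for b in BINS}
        for g in self.genes.values():
            counts[g.bin] += 1
        return counts

    def genes_in_bin(self, bin_label: str) -> set[str]:
        if bin_label not in BINS:
            raise FormatError(f"unknown bin {bin_label!r}")
        return {s for s, g in self.genes.items() if g.bin == bin_label}


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Between-array quantile normalization on the log2 matrix.

    Each sample's sorted non-missing values are replaced by the mean of all
    samples' sorted value vectors; tied values within a sample receive the
    mean of the target values their rank positions would have received.
    Missing entries are excluded from the computation and stay missing.
    Samples with differing numbers of non-missing values are aligned by
    linear interpolation of the reference quantile curve.
    """
    X = m.values
    n_probes, n_samples = X.shape
    counts = np.sum(~np.isnan(X), axis=0)
    for j, count in enumerate(counts):
        if count == 0:
            raise FormatError(f"sample {m.sample_ids[j]!r} is entirely missing")

    n_ref = int(counts.max())
    ref_grid = np.linspace(0.0, 1.0, n_ref) if n_ref > 1 else np.array([0.5])
    # Reference distribution: mean over samples of each sample's empirical
    # quantile curve evaluated on a common grid.
    curves = np.empty((n_samples, n_ref))
    for j in range(n_samples):
        col = np.sort(X[:, j][~np.isnan(X[:, j])])
        if col.size == 1:
            curves[j, :] = col[0]
        else:
            sample_grid = np.linspace(0.0, 1.0, col.size)
            curves[j, :] = np.interp(ref_grid, sample_grid, col)
    reference = curves.mean(axis=0)

    out = np.full_like(X, np.nan)
    for j in range(n_samples):
        mask = ~np.isnan(X[:, j])
        col = X[mask, j]
        k = col.size
        order = np.argsort(col, kind="stable")
        if k == 1:
            targets_sorted = np.array([reference.mean()])
        else:
            positions = np.linspace(0.0, 1.0, k)
            targets_sorted = np.interp(positions, ref_grid, reference)
        normalized = np.empty(k)
        normalized[order] = targets_sorted
        # ties share the mean of the targets their positions received
        sorted_vals = col[order]
        start = 0
        for end in range(1, k + 1):
            if end == k or sorted_vals[end] != sorted_vals[start]:
                if end - start > 1:
                    tied_mean = targets_sorted[start:end].mean()
                    normalized[order[start:end]] = tied_mean
                start = end
        out[mask, j] = normalized
    return ExpressionMatrix(
        m.dataset_id, m.species, list(m.probe_ids), list(m.sample_ids), out
    )


def average_replicates(m: ExpressionMatrix) -> pd.Series:
    """Arithmetic mean per probe over non-missing samples.

    Probes with every sample missing are dropped with a warning (the
    ExpressionMatrix invariant normally forbids them, but tables assembled
    by other means may contain such rows).
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        means = np.nanmean(m.values, axis=1)
    keep = ~np.isnan(means)
    if not keep.all():
        dropped = [p for p, k in zip(m.probe_ids, keep) if not k]
        logger.warning(
            "%s: dropping %d probes with all samples missing (first: %s)",
            m.dataset_id, len(dropped), dropped[0],
        )
    return pd.Series(means[keep], index=[p for p, k in zip(m.probe_ids, keep) if k])


def percentile_rank(gene_means: pd.Series | np.ndarray) -> np.ndarray:
    """Percentile of each value: 100 * (count strictly below) / N.

    Ties share a percentile; the result lies in [0, 100). With N distinct
    values the top value gets 100 * (N-1) / N, so exactly ceil(N/10) values
    sit at or above the 90th percentile.
    """
    values = np.asarray(gene_means, dtype=float)
    if values.size == 0:
        raise FormatError("percentile_rank: empty input")
    if not np.isfinite(values).all():
        raise FormatError("percentile_rank: non-finite mean encountered")
    if values.size < 100:
        warnings.warn(
            f"percentile ranks over only {values.size} genes are coarse",
            stacklevel=2,
        )
    order = np.sort(values)
    below = np.searchsorted(order, values, side="left")
    return 100.0 * below / values.size


def assign_bins(percentiles: np.ndarray, cutoffs: Cutoffs = Cutoffs()) -> np.ndarray:
    """Map percentiles to bin labels using half-open, lower-closed intervals."""
    p = np.asarray(percentiles, dtype=float)
    if ((p < 0) | (p >= 100)).any():
        raise FormatError("percentiles must lie in [0, 100)")
    edges = np.array([cutoffs.low, cutoffs.mid, cutoffs.high])
    idx = np.searchsorted(edges, p, side="right")
    return np.array(BINS, dtype=object)[idx]


def _provisional_bins(probe_means: pd.Series, cutoffs: Cutoffs) -> pd.Series:
    pct = percentile_rank(probe_means)
    return pd.Series(assign_bins(pct, cutoffs), index=probe_means.index)


def collapse_probes(
    means: pd.Series,
    ann: AnnotationTable,
    cutoffs: Cutoffs = Cutoffs(),
) -> tuple[pd.DataFrame, set[str]]:
    """Collapse per-probe means to per-gene means with the consistency filter.

    Control probes and probes without a gene symbol are excluded first. For
    genes with several probes, provisional bins are computed from all probe
    means; if a gene's probe bins span more than one adjacent category
    (e.g. H together with L) the gene goes to ``dropped_inconsistent``,
    otherwise its mean is the mean of its probes' means.

    Returns a DataFrame indexed by gene symbol with columns ``mean_log2``,
    ``n_probes``, ``has_curated_accession``, plus the dropped-symbol set.
    """
    missing = [p for p in means.index if p not in ann]
    if missing:
        raise FormatError(f"probe {missing[0]!r} missing from annotation")

    keep_probes = [
        p for p in means.index
        if not ann[p].is_control and ann[p].gene_symbol
    ]
    if not keep_probes:
        raise FormatError("no annotated non-control probes to collapse")
    kept = means.loc[keep_probes]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=UserWarning)
        provisional = _provisional_bins(kept, cutoffs)

    # symbols are compared case-insensitively across species (ACE vs Ace)
    by_gene: dict[str, list[str]] = {}
    for probe in keep_probes:
        by_gene.setdefault(normalize_symbol(ann[probe].gene_symbol), []).append(probe)

    rows: dict[str, tuple[float, int, bool]] = {}
    dropped: set[str] = set()
    for symbol in sorted(by_gene):
        probes = by_gene[symbol]
        curated = any(ann[p].has_curated_accession for p in probes)
        if len(probes) > 1:
            bin_idx = [BIN_INDEX[provisional[p]] for p in probes]
            if max(bin_idx) - min(bin_idx) > 1:
                dropped.add(symbol)
                continue
        rows[symbol] = (float(kept.loc[probes].mean()), len(probes), curated)

    frame = pd.DataFrame.from_dict(
        rows, orient="index", columns=["mean_log2", "n_probes", "has_curated_accession"]
    )
    frame.index.name = "gene_symbol"
    return frame, dropped


def bin_dataset(
    m: ExpressionMatrix,
    ann: AnnotationTable,
    cutoffs: Cutoffs = Cutoffs(),
) -> BinnedDataset:
    """Run the full per-dataset pipeline and return the binned dataset.

    Percentiles are recomputed on the collapsed gene-level means, not reused
    from the provisional probe-level ranking.
    """
    normalized = quantile_normalize(m)
    probe_means = average_replicates(normalized)
    collapsed, dropped = collapse_probes(probe_means, ann, cutoffs)
    if collapsed.empty:
        raise FormatError(f"{m.dataset_id}: no genes survived probe collapsing")
    percentiles = percentile_rank(collapsed["mean_log2"])
    bins = assign_bins(percentiles, cutoffs)
    genes = {
        symbol: GeneSummary(
            gene_symbol=symbol,
            mean_log2=float(row.mean_log2),
            percentile=float(pct),
            bin=str(b),
            n_probes=int(row.n_probes),
            has_curated_accession=bool(row.has_curated_accession),
            cutoffs=cutoffs,
        )
        for symbol, row, pct, b in zip(
            collapsed.index, collapsed.itertuples(index=False), percentiles, bins
        )
    }
    logger.info(
        "%s: %d probes -> %d genes (%d dropped inconsistent); bins %s",
        m.dataset_id, len(m.probe_ids), len(genes), len(dropped),
        {b: sum(g.bin == b for g in genes.values()) for b in BINS},
    )
    return BinnedDataset(
        dataset_id=m.dataset_id,
        species=m.species,
        genes=genes,
        dropped_inconsistent=dropped,
        cutoffs=cutoffs,
    )
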