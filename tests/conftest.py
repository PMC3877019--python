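import numpy as np
import pytest

from orthobin.binning import BinnedDataset, Cutoffs, GeneSummary
from orthobin.io import AnnotationTable, ExpressionMatrix, ProbeRecord


def make_matrix(values, dataset_id="ds", species="human", probes=None, samples=None):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"P{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(dataset_id, species, probes, samples, values)


def make_annotation(entries):
    """entries: iterable of (probe_id, symbol, accession[, is_control])."""
    records = {}
    for entry in entries:
        probe_id, symbol, accession = entry[:3]
        is_control = entry[3] if len(entry) > 3 else False
        records[probe_id] = ProbeRecord(probe_id, symbol, accession, is_control)
    return AnnotationTable(records)


def make_binned(
    percentiles: dict[str, float],
    dataset_id="ds",
    species="human",
    curated=True,
    dropped=(),
    cutoffs=Cutoffs(),
):
    """Build a BinnedDataset straight from symbol -> percentile.

    ``curated`` may be a bool (applied to all genes) or a set of symbols.
    Gene means are synthesized monotone in percentile so invariants hold.
    """
    genes = {}
    for symbol, pct in percentiles.items():
        has_nm = curated if isinstance(curated, bool) else symbol in curated
        genes[symbol] = GeneSummary(
            gene_symbol=symbol,
            mean_log2=pct / 10.0,
            percentile=float(pct),
            bin=cutoffs.bin_of(pct),
            has_curated_accession=has_nm,
            cutoffs=cutoffs,
        )
    return BinnedDataset(
        dataset_id=dataset_id,
        species=species,
        genes=genes,
        dropped_inconsistent=set(dropped),
        cutoffs=cutoffs,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
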