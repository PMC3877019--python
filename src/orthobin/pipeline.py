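"""High-level pipeline stages driven by a :class:`PipelineConfig`.

Each stage writes deterministic TSV outputs with a provenance header
(tool version, config hash, cutoffs) and returns the in-memory result so
tests and the CLI share one code path.
"""

from __future__ import annotations

import logging
from pathlib import Path

from orthobin import __version__
from orthobin.binning import BINS, BinnedDataset, bin_dataset
from orthobin.compare import (
    ConcordanceRow,
    GeneSetBinProfile,
    OrthologTable,
    call_specific_genes,
    concordance,
    gene_set_profile,
    match_orthologs,
)
from orthobin.config import DatasetConfig, PipelineConfig
from orthobin.errors import ConfigError
from orthobin.io import read_annotation, read_expression_tsv, read_gene_sets, \
    read_series_matrix, write_binned_table

logger = logging.getLogger(__name__)


def _provenance(config: PipelineConfig) -> dict[str, str]:
    return {
        "tool": f"orthobin {__version__}",
        "config_hash": config.content_hash(),
        "bin_cutoffs": ",".join(str(c) for c in config.cutoffs),
    }


def load_dataset(dc: DatasetConfig):
    if dc.format == "series_matrix":
        matrix, _ = read_series_matrix(
            dc.path, dataset_id=dc.dataset_id, species=dc.species,
            log2_transform=dc.log2_transform,
        )
    else:
        matrix = read_expression_tsv(
            dc.path, dataset_id=dc.dataset_id, species=dc.species,
            missing_token=dc.missing_token,
        )
    annotation = read_annotation(dc.annotation)
    return matrix, annotation


def run_bin(config: PipelineConfig, dataset_id: str) -> BinnedDataset:
    """Normalize, collapse and bin one configured dataset; write its table."""
    config.validate_paths()
    dc = config.dataset(dataset_id)
    matrix, annotation = load_dataset(dc)
    binned = bin_dataset(matrix, annotation, config.cutoffs)
    counts = binned.bin_counts()
    logger.info(
        "%s: %d probes, %d genes, %d dropped inconsistent; "
        "VL=%d L=%d M=%d H=%d",
        dataset_id, len(matrix.probe_ids), len(binned.genes),
        len(binned.dropped_inconsistent),
        counts["VL"], counts["L"], counts["M"], counts["H"],
    )
    config.output_dir.mkdir(parents=True, exist_ok=True)
    out = config.output_dir / f"{dataset_id}.binned.tsv"
    write_binned_table(binned, out, provenance=_provenance(config))
    return binned


def run_compare(
    config: PipelineConfig, dataset_a: str, dataset_b: str
) -> dict[str, object]:
    """Cross-species comparison: specificity calls plus the 4x4 bin matrix."""
    dc_a, dc_b = config.dataset(dataset_a), config.dataset(dataset_b)
    if dc_a.species == dc_b.species:
        raise ConfigError(
            f"specificity is defined across species; both datasets are "
            f"{dc_a.species!r}"
        )
    binned_a = run_bin(config, dataset_a)
    binned_b = run_bin(config, dataset_b)
    table = match_orthologs(binned_a, binned_b)
    if len(table) == 0:
        raise ConfigError(
            f"no ortholog symbols shared between {dataset_a!r} and "
            f"{dataset_b!r}; check annotation gene symbols"
        )
    calls_a = call_specific_genes(table, dc_a.species)
    calls_b = call_specific_genes(table, dc_b.species)
    logger.info(
        "%s vs %s: %d ortholog pairs, %d %s-specific, %d %s-specific",
        dataset_a, dataset_b, len(table),
        len(calls_a), dc_a.species, len(calls_b), dc_b.species,
    )
    config.output_dir.mkdir(parents=True, exist_ok=True)
    prov = _provenance(config)
    _write_calls(
        config.output_dir / f"specific_{dc_a.species}.tsv", calls_a, binned_a,
        binned_b, prov,
    )
    _write_calls(
        config.output_dir / f"specific_{dc_b.species}.tsv", calls_b, binned_b,
        binned_a, prov,
    )
    _write_crossbin(
        config.output_dir / f"crossbin_{dataset_a}_vs_{dataset_b}.tsv",
        table, prov,
    )
    return {
        "ortholog_table": table,
        "calls_a": calls_a,
        "calls_b": calls_b,
        "cross_bin_counts": table.cross_bin_counts(),
    }


def _write_calls(path: Path, calls, binned_specific, binned_other, prov) -> None:
    with path.open("w") as fh:
        for key, value in prov.items():
            fh.write(f"# {key}={value}\n")
        fh.write(
            "gene_symbol\tspecific_species\tother_species\tbin_specific\t"
            "bin_other\tpercentile_specific\tpercentile_other\n"
        )
        for c in calls:
            ps = binned_specific.genes[c.gene_symbol].percentile
            po = binned_other.genes[c.gene_symbol].percentile
            fh.write(
                f"{c.gene_symbol}\t{c.specific_species}\t{c.other_species}\t"
                f"{c.bin_specific}\t{c.bin_other}\t{ps:.4f}\t{po:.4f}\n"
            )


def _write_crossbin(path: Path, table: OrthologTable, prov) -> None:
    counts = table.cross_bin_counts()
    with path.open("w") as fh:
        for key, value in prov.items():
            fh.write(f"# {key}={value}\n")
        fh.write(f"# rows={table.dataset_a} columns={table.dataset_b}\n")
        fh.write("bin\t" + "\t".join(BINS) + "\n")
        for x in BINS:
            fh.write(x + "\t" + "\t".join(str(counts[(x, y)]) for y in BINS) + "\n")


def run_concordance(config: PipelineConfig) -> list[ConcordanceRow]:
    """High-bin concordance of every query dataset against its species reference."""
    if not config.references:
        raise ConfigError("no reference dataset configured for any species")
    binned = {d.dataset_id: run_bin(config, d.dataset_id) for d in config.datasets}
    rows: list[ConcordanceRow] = []
    for species, ref_id in sorted(config.references.items()):
        ref = binned[ref_id]
        queries = [
            d for d in config.datasets
            if d.species == species and d.dataset_id != ref_id
        ]
        if not queries:
            logger.warning("no same-species query datasets for %s; row skipped", species)
            continue
        for q in queries:
            rows.append(concordance(ref, binned[q.dataset_id]))
    config.output_dir.mkdir(parents=True, exist_ok=True)
    out = config.output_dir / "concordance.tsv"
    with out.open("w") as fh:
        for key, value in _provenance(config).items():
            fh.write(f"# {key}={value}\n")
        fh.write("ref_dataset\tquery_dataset\tn_query_high\tn_overlap\tpct_overlap\n")
        for r in rows:
            fh.write(
                f"{r.ref_dataset}\t{r.query_dataset}\t{r.n_query_high}\t"
                f"{r.n_overlap}\t{r.pct_overlap}\n"
            )
    return rows


def run_profile(
    config: PipelineConfig,
    gene_set_path: str | Path,
    flag_pair: tuple[str, str],
) -> list[GeneSetBinProfile]:
    """Per-dataset bin profile of each gene set, with large shifts flagged."""
    binned = [run_bin(config, d.dataset_id) for d in config.datasets]
    profiles = []
    config.output_dir.mkdir(parents=True, exist_ok=True)
    for name, gene_set in sorted(read_gene_sets(gene_set_path).items()):
        profile = gene_set_profile(gene_set, binned, flag_pair)
        profiles.append(profile)
        out = config.output_dir / f"profile_{name}.tsv"
        _write_profile(out, profile, _provenance(config))
    return profiles


def _write_profile(path: Path, profile: GeneSetBinProfile, prov) -> None:
    with path.open("w") as fh:
        for key, value in prov.items():
            fh.write(f"# {key}={value}\n")
        fh.write(f"# gene_set={profile.set_name}\n")
        fh.write(f"# flag_pair={profile.flag_pair[0]},{profile.flag_pair[1]}\n")
        for did in profile.dataset_ids:
            hist = profile.histograms[did]
            fh.write(
                f"# histogram {did}: "
                + " ".join(f"{b}={hist[b]}" for b in BINS)
                + "\n"
            )
        fh.write("gene_symbol\t" + "\t".join(profile.dataset_ids) + "\tshift\tflagged\n")
        for symbol in sorted(profile.per_gene):
            row = profile.per_gene[symbol]
            shift = profile.shifts.get(symbol, "")
            flagged = int(symbol in profile.flagged_shifts)
            fh.write(
                symbol + "\t"
                + "\t".join(row[d] for d in profile.dataset_ids)
                + f"\t{shift}\t{flagged}\n"
            )
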